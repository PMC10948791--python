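# napkit

A toolkit for discovering **full-length noncapped RNAs (napRNAs)** from
boundary-tagged sequencing libraries, classifying them into ncRNA classes,
and scoring them by secondary structure and chemical-probing reactivity.

Most of the transcriptome's "dark matter" consists of RNAs without a 5' cap
— excised introns that refuse to degrade, snoRNA processing products, Pol
III transcripts from repetitive elements, spacers of miRNA clusters. A
NAP-seq-style library marks the *true* transcript boundaries: end-repaired
RNAs are ligated to specific 5'/3' adapters carrying randomized N6
barcodes, so a read whose edge retains an adapter pins the transcript's
5'-start or 3'-end at single-nucleotide resolution. `napkit` implements the
complete computational stack downstream of read mapping:

1. **trim** — detect/remove the specific adapters (edge-anchored
   semi-global alignment, error rate 0.1, min insert 15 nt) and N6
   barcodes, flagging which read ends are boundary-verified;
2. **tracks** — strand-specific coverage, verified 5'-start and 3'-end
   count tracks, with RPM normalization;
3. **call** — the napRNA caller: per covered contig it finds the candidate
   boundary pair and computes six statistics

   - `startReadNum`, `endReadNum` — verified boundary reads at the 5'/3' positions,
   - `startFC`, `endFC` — those counts vs. the verified-boundary reads in ±100 nt (candidate excluded, denominator floored at 1),
   - `up20ntFC`, `down20ntFC` — mean coverage inside vs. the 20-nt flanks,

   keeping calls with `startReadNum, endReadNum ≥ 7`, all four fold changes
   `≥ 2`, `length ≥ 100`, then requiring support in `≥ 2` libraries with a
   summed count `≥ 20`;
4. **classify** — interval rules for **sliRNA** (both ends shared with a
   known intron), **snotron** (one end on an intronic snoRNA, the other
   within ±10 nt of the host intron's splice site) and **misRNA**
   (spanning the spacer of a pre-miRNA cluster, members < 10 kb apart),
   plus motif scans for Pol III (A box / B box / 3' ≥4U), C/D box
   (RUGAUGA…CUGA + terminal stem) and H/ACA box (two hairpins, ANANNA
   hinge, 3' ACA, optional poly(A) pocket) architectures;
5. **capcall** — CAP-seq 5'-cap site calling (`upFC, downFC ≥ 2`,
   `endCov ≥ 10`, binomial enrichment `p < 0.05`, ≥2 replicates, inside a
   5'UTR) and the napRNA/cap-site overlap comparison;
6. **structure** — a base-pair-maximization folding oracle with hard
   constraints, mono-/dinucleotide shuffle z-scores
   (`z = (E_native − mean E_shuffled) / sd`; negative = more structured
   than chance), and SHAPE-MaP-style mutational-profiling reactivities
   (treated − untreated rates, 2–8% normalization) usable as folding
   constraints;
7. **simulate** — a seeded generator of complete test worlds: genome,
   nested annotations, implanted truth napRNAs of every class, and read
   libraries with the full adapter/barcode anatomy.

## Worked example

Simulate a small world, build tracks, call and classify:

```python
from napkit import SimConfig, simulate_world, simulate_libraries, build_tracks, call_napRNAs
from napkit.classify import classify_all

cfg = SimConfig(rng_seed=42, n_samples=2, adapter_retention_prob=1.0)
world = simulate_world(cfg)
libs = simulate_libraries(world)
lengths = {c: len(s) for c, s in world.genome.items()}
tracks = {s: build_tracks(reads, lengths)[s] for s, reads in libs.items()}

calls = call_napRNAs(tracks)
print(f"called {len(calls)} napRNAs from {len(world.truth)} implanted")
rows = classify_all([c.interval for c in calls], world.annotations, world.genome)
for c, r in zip(calls, rows):
    if r.labels:
        iv = c.interval
        print(f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})  len={len(iv)}  "
              f"startReadNum={c.startReadNum} endReadNum={c.endReadNum} "
              f"summary={c.summary_count}  labels={sorted(r.labels)}")
```

prints

```
called 16 napRNAs from 16 implanted
chr1:4862-5420(-)  len=558  startReadNum=10 endReadNum=10 summary=40  labels=['sliRNA']
chr1:5920-6378(+)  len=458  startReadNum=10 endReadNum=10 summary=40  labels=['sliRNA']
chr1:6882-7121(-)  len=239  startReadNum=10 endReadNum=10 summary=40  labels=['snotron']
chr1:7681-7979(+)  len=298  startReadNum=10 endReadNum=10 summary=40  labels=['snotron']
chr1:8541-8785(-)  len=244  startReadNum=10 endReadNum=10 summary=40  labels=['misRNA']
chr1:9343-9543(+)  len=200  startReadNum=10 endReadNum=10 summary=40  labels=['pol3']
chr1:10043-10243(-)  len=200  startReadNum=10 endReadNum=10 summary=40  labels=['pol3']
chr1:10743-10853(+)  len=110  startReadNum=10 endReadNum=10 summary=40  labels=['cd_box']
chr1:11353-11463(-)  len=110  startReadNum=10 endReadNum=10 summary=40  labels=['cd_box']
chr1:11963-12103(+)  len=140  startReadNum=10 endReadNum=10 summary=40  labels=['haca_box']
chr1:12603-12743(-)  len=140  startReadNum=10 endReadNum=10 summary=40  labels=['haca_box']
```

Every implanted napRNA is recovered with exact boundaries: each call shows
the 10 adapter-verified reads per end per library (`summary` = 40 over the
two libraries) and carries the class label its geometry or sequence was
designed to satisfy. The same workflow is available from the shell:

```bash
napkit simulate --out world/
napkit call --alignments world/sample1.alignments.tsv --genome world/genome.fa --out-prefix out
napkit zscore --fasta hairpins.fa --n-shuffles 100 --seed 0
```

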