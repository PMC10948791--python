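# Methods

This note documents the models, parameter choices and numerical conventions
behind `napkit`, including the places where the published description of
this style of analysis leaves the design genuinely open and the package had
to fix a convention.

## Coordinates and biological ends

All coordinates are 0-based half-open on an explicit strand (BED-native);
1-based representations exist only at serialization boundaries. Biological
ends are derived per strand: a feature's 5' end is `start` on `+` and
`end − 1` on `−`, its 3' end the mirror. Every classifier distance rule
compares these per-strand ends, and all outputs are emitted in a fixed sort
order (chrom, start, end, strand, name) so reruns are byte-identical.
Whether upstream pipelines compared classifier coordinates in 0- or 1-based
space is not knowable from the outside; `napkit` fixes BED space and
exposes every tolerance as a parameter instead.

## Adapter trimming

Library anatomy: `5'adapter(23 nt) + N6 + insert + N6 + 3'adapter(22 nt)`,
with adapters `AAGCAGTGGTATCAACGCAGAGT` / `AGTCGTAGTAAGTCTGTGCTCG`.
Defaults: error rate 0.1, minimum retained insert 15 nt, 6-nt barcodes,
minimum adapter overlap 10 nt; a long-read preset raises the error rate to
0.3 and the minimum length to 20 nt. Matching is edge-anchored semi-global
alignment with unit-cost edits: the adapter, possibly truncated at the read
edge, aligns from the read's first base (5') or to its last base (3'), and
qualifies when `errors / matched_length ≤ rate`.

Two tie-break conventions matter more than they look:

* candidates across truncation levels are ranked by **error rate** (then by
  matched length), not by raw error count — otherwise a short accidental
  1-error suffix match can outrank the true full-length 2-error adapter;
* an **ungapped** alignment within the error budget takes precedence over a
  gapped one, and among tied gapped end positions the one closest to the
  ungapped adapter length wins — otherwise a substitution at the adapter
  edge is silently re-read as an indel and the 6-nt barcode frame shifts.

With these rules, reads built with up to 2 substitutions per adapter trim
back to their exact inserts, flags and barcodes (verified on 10⁴ random
constructions). Reads with neither adapter are kept with both flags false:
they contribute coverage but can never witness a boundary. Mates of a pair
are trimmed independently and flags merged per fragment, since only the
fragment's outer edges can carry adapters. Barcodes are recorded but not
used for deduplication; whether the original pipeline collapsed duplicates
by N6 is unstated, so raw reads are counted.

## Signal tracks

Per chromosome and strand, three arrays: `cov` (each fragment increments
its whole footprint once — fragments, not mates, so nothing is double
counted), `start5` and `end3` (incremented at the biological end position
only for adapter-verified ends). RPM normalization multiplies by
`10⁶ / library_size` and always keeps the raw integer track alongside.
The simplified 7-column alignment TSV treats footprints as contiguous,
matching the caller's contig model; SAM input uses the alignment's
reference span and optional `n5`/`n3` tags.

## The caller

Contigs are maximal runs with `cov ≥ 1`. Within a contig the candidate 5'
position is the argmax of `start5` (ties resolved toward the biological 5'
side) and symmetrically for the 3' position; a 5' position downstream of
the 3' position emits nothing. Six statistics are computed per candidate:

* `startFC = startReadNum / max(1, Σ start5 over ±100 nt excluding the
  candidate position)` — the ±100-nt window is the published definition,
  but sum-vs-max and self-exclusion are not printed anywhere; the sum is
  the literal reading, exclusion avoids comparing the peak against itself,
  and the floor of 1 read avoids division by zero. `endFC` mirrors this.
* `up20ntFC = mean cov inside / max(ε, mean cov over the 20 nt upstream)`,
  with `ε = 0.05` (one read spread over a 20-nt flank) as the pseudo-
  coverage for empty flanks; means rather than sums so contig length
  cancels; flank windows are clipped at chromosome edges and renormalized
  by their actual length. `down20ntFC` mirrors this downstream.

Thresholds (all inclusive, all configurable): `startReadNum, endReadNum ≥
7`; `startFC, endFC ≥ 2`; `up20ntFC, down20ntFC ≥ 2`; `length ≥ 100 nt`.
Fold changes are evaluated on raw counts — within one library the ratios
are scale invariant, so RPM would change nothing.

Cross-sample reconciliation: calls whose 5' and 3' ends each agree within
±5 nt (configurable; 0 = exact) are single-linkage merged; a merged call
needs ≥ 2 supporting samples and a summed support ≥ 20. The per-sample
support count is defined as `startReadNum + endReadNum` — the boundary-
verified reads that witnessed the call — since the published "summary
count" is not given a formula. The representative interval comes from the
sample with the strongest support. One candidate per contig is emitted by
default; `multi_peak` mode emits all non-overlapping threshold-passing
pairs (greedy by support) for contigs housing several units, e.g. snoRNA
clusters.

## Cap-site calling

A cap site needs, in each of ≥ 2 replicates: `endCov ≥ 10`; `upFC =
endCov/upCov ≥ 2` and `downFC ≥ 2` (denominators floored at 1, one nt up-
and downstream, strand-aware); and binomial enrichment `p < 0.05`. The
published criteria name a p-value without a test; the one implemented is
the simplest null consistent with the fold-change logic: under a
local-uniform null, the site's count among the N total 5'-end counts in
±100 nt is Binomial(N, 1/201), and p is the upper tail at `endCov`.
Replicate agreement is exact-position by default (cap sites are
single-nucleotide features). The site must finally fall inside an
annotated 5'UTR; calling without a 5'UTR annotation is an error rather
than a silent skip. The napRNA cross-check counts napRNAs whose biological
5'-start coincides with a cap site within a tolerance (default 0): for
genuinely noncapped transcripts this fraction should be near zero.

## Classifiers

Interval rules (tolerances in nt, defaults in parentheses):

* **sliRNA** — both ends within tolerance (0) of one intron's ends.
* **snotron** — 5' end on an intronic snoRNA's 5' end (0) and 3' end
  within ±10 of the host intron's 3' splice site, or the mirror
  configuration. The snoRNA must lie inside the matched intron — implied
  but never stated by the rule's description; without containment a snoRNA
  straddling the intron boundary would qualify nonsensically.
* **misRNA** — intersects a same-strand cluster of pre-miRNAs (single
  linkage, inter-feature gap strictly < 10 kb) and is not wholly contained
  in any single pre-miRNA. Only clusters with ≥ 2 members qualify: a lone
  pre-miRNA has no spacer. End coincidence with mature-miRNA ends (±3) is
  recorded as evidence and only enforced on request, because the cluster
  rule and the end-coincidence observation come from different parts of
  the method's description.

Labels are independent flags with per-label evidence; classification is
order-invariant and the exclusion filter (any same-strand ≥1-nt overlap
with rRNA/tRNA/CDS-type features) runs first when an exclusion set is
given.

Motif classes use canonical literature consensi because the original
promoter/box models live in unpublished supplementary pipelines; every
consensus, offset and mismatch budget is a parameter. Defaults: Pol III =
A box `TRGCNNARYNNG` (≤2 mismatches) in the 5' half, B box `GTTCRANNC`
(≤1) downstream of it, and ≥4 consecutive U in the last 6 nt; C/D = C box
`RUGAUGA` (≤1) starting within 12 nt of the 5' end, D box `CUGA` (exact —
the canonical loss-of-function change CUGA→CUAG must kill the label) ending
within 12 nt of the 3' end, and a terminal stem of ≥4 consecutive pairs
(G·U allowed) between the ≤10-nt regions outside the boxes; H/ACA = ACA
with ≤3 trailing nt, H box `ANANNA` (≤1) in the middle third, and a
predicted structure (pluggable folder) with at least one hairpin loop on
each side of the hinge; a run of ≥6 unpaired A in the 5' hairpin is
annotated as a poly(A) pocket.

## Structure and reactivity

The built-in folder is Nussinov-style base-pair maximization (Watson–Crick
+ G·U, hairpin loops ≥ 3 nt) with energy = −(pair count). It was chosen
over a thermodynamic model because it is exactly verifiable against
exhaustive structure enumeration and keeps the package self-contained;
nearest-neighbor folders plug in through a `folder(seq) → (dotbracket,
energy)` callable. Traceback is deterministic (pair the left base when
possible, leftmost partner first). Positions marked `x` in a constraint
string are hard-excluded from pairing; high-reactivity positions are
exported this way rather than as pseudo-energies, since a pair-count model
has no free-energy scale.

Shuffle z-scores: order-1 shuffles permute bases; order-2 uses the
Euler-walk (Altschul–Erickson) dinucleotide shuffle, preserving all
dinucleotide counts exactly on every call. `z = (E_native − mean)/sd` with
the sample sd (n−1); `sd = 0` is flagged degenerate and reported as z = 0
rather than ±∞. Defaults: 100 shuffles, order 2, seeded.

Reactivities: per-position mutation rates from read pileups (a read counts
once per position regardless of how its mutations are listed), raw
reactivity = treated − untreated with negatives clipped to 0 (standard
mutational-profiling convention), positions under 100× depth in either
channel masked as no-data (never zero), and 2–8% normalization — drop the
top 2% of unmasked values, divide by the mean of the next 8% — which the
exact upstream pipelines inherit from ShapeMapper-style defaults without
restating; it is used here and labeled as such. An all-masked or
zero-signal profile raises instead of returning silent zeros.

## The simulator

`simulate_world` generates a uniform-composition genome (default 120 kb,
GC 0.5) and implants, with ~500-nt spacing: plain napRNAs (lengths uniform
in 100–600 nt), sliRNAs (exactly equal to a generated intron), snotrons
(snoRNA 30 nt inside its intron, napRNA from the snoRNA 5' end to 4 nt
short of the 3' splice site), misRNAs (two 80-nt pre-miRNAs 200 nt apart,
22-nt matures at the spacer-facing ends, napRNA flush with the mature
ends), and motif classes whose designed sequences are written into the
genome. The H/ACA design is T-free so its A-rich pads and pocket loop are
unpairable under any folding, guaranteeing the two-hairpin architecture.
Every implant satisfies its own classifier rule by construction, which the
suite verifies as a closure property.

`simulate_library` emits exact alignments (mapping is out of scope): per
truth napRNA, `reads_per_end` (10) reads per boundary whose boundary ends
carry adapters with probability `adapter_retention_prob` (0.5, matching
the observation that roughly half of real read ends retain an adapter —
note that at this realistic default a single library rarely reaches the
≥7 verified-read threshold, which is exactly why multiple libraries and
the cross-sample merge exist; noiseless validation runs set retention to
1.0). Background reads are Poisson-scattered at `background_read_rate`
per nt with a 10% stray-flag rate. Optional geometric end jitter models
imperfect processing (off by default). FASTQ output renders each aligned
read with the full adapter/barcode anatomy so the trimmer can be exercised
on realistic reads. With a fixed seed all outputs are byte-identical.

What the simulator does **not** emulate: sequencing errors, expression
heterogeneity, spliced alignments, multimapping, and chimeric artifacts.
Passing the end-to-end tests therefore demonstrates correctness of the
statistics and rules, not robustness to every failure mode of real
libraries.

## Verification sizes

The test suite and `scripts/acceptance.py` use: 1,000 fuzzed tracks of
3 kb for caller self-consistency; 50 implanted napRNAs in 2 libraries for
noiseless recovery; the 30-candidate hand-derived truth table; 100 random
windows for fold-change equivalence; 200 sequences of length ≤ 14 for
folding-DP/enumeration equivalence; 10⁴ dinucleotide shuffles; simulated
probing at depth 5,000 (single-stranded mutation rate 0.05, paired 0.005,
untreated 0.002); 10⁴ constructed reads for the trimmer round trip; and 40
fuzzed replicate pairs for cap-site re-verification. These sizes keep the
whole verification under a minute on one core while leaving each check
statistically meaningful.

## Known limitations

* Nanopore-style per-read calling is out of scope; long reads are handled
  only through the trimmer preset.
* The caller emits one candidate per contig unless `multi_peak` is set; it
  does not deconvolve overlapping isoforms within a contig.
* Motif classes are consensus scans, not trained models; on random
  sequence they have a nonzero false-positive rate (configurable budgets
  tighten them at the cost of sensitivity on real variants).
* The pair-count folder ignores loop entropies and stacking; z-scores are
  comparable within the package but not numerically to free-energy-based
  z-scores.
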