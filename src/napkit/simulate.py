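"""Seeded generator of complete NAP-seq test worlds.

A *world* is a random genome plus a truth set of implanted napRNAs — one or
more per ncRNA class — and the annotations (introns, snoRNAs, pre-/mature
miRNAs, 5'UTRs, exclusion features) their class rules refer to.  Implants
are constructed so every truth object satisfies its own classifier rule
(snoRNAs inside introns, spacer RNAs flush with mature-miRNA ends, promoter
and box motifs written into the genome), which closes the loop between the
simulator and the classifiers.

A *library* is the read set a NAP-seq run of that world would produce: per
truth napRNA, boundary-anchored reads whose ends at the true boundaries
carry the specific adapters with probability ``adapter_retention_prob``
(about half of real read ends retain their adapter), plus scattered
background reads.  The simulator emits exact alignments directly (mapping
is out of scope) and, on request, the corresponding FASTQ with the full
read anatomy 5'adapter + N6 + insert + N6 + 3'adapter so the trimmer can be
exercised on realistic reads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .genomic import (
    AnnotationSet,
    FeatureIndex,
    GenomicInterval,
    fetch_sequence,
    reverse_complement,
    write_bed,
    write_fasta,
)
from .tracks import AlignedReadRecord, write_alignment_tsv
from .trim import ADAPTER3, ADAPTER5, RawRead

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    rng_seed: int = 0
    genome_length: int = 120_000
    gc_fraction: float = 0.5
    n_samples: int = 3
    # per-class implant counts
    n_plain: int = 5
    n_sli: int = 2
    n_snotron: int = 2
    n_mis: int = 1
    n_pol3: int = 2
    n_cd: int = 2
    n_haca: int = 2
    n_exclusion: int = 2
    n_utr5: int = 2
    nap_len_range: tuple[int, int] = (100, 600)
    reads_per_end: int = 10
    adapter_retention_prob: float = 0.5
    background_read_rate: float = 0.0  # expected background reads per nt
    fragmentation: bool = False        # NGS-style fragmented reads
    end_jitter_prob: float = 0.0       # geometric boundary jitter, off by default
    feature_spacing: int = 500
    chrom: str = "chr1"


@dataclass(frozen=True)
class TruthNap:
    interval: GenomicInterval
    label: str  # plain | sliRNA | snotron | misRNA | pol3 | cd_box | haca_box


@dataclass
class SimWorld:
    genome: dict[str, str]
    truth: list[TruthNap]
    annotations: AnnotationSet
    config: SimConfig


# ---------------------------------------------------------------------------
# Designed motif sequences (written into the genome for the motif classes)
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _design_pol3(rng: np.random.Generator, length: int, gc: float) -> str:
    """A box (TRGCNNARYNNG instance) in the 5' half, B box (GTTCRANNC)
    downstream, >=4 T terminator at the 3' end."""
    s = list(_rand_seq(rng, length, gc))
    abox = "TAGCGCAACTAG"   # fits TRGCNNARYNNG exactly
    bbox = "GTTCGAATC"      # fits GTTCRANNC exactly
    a_off = 20
    b_off = max(a_off + len(abox) + 10, length // 2 + 5)
    s[a_off : a_off + len(abox)] = abox
    s[b_off : b_off + len(bbox)] = bbox
    s[-4:] = "TTTT"
    return "".join(s)


def _design_cd(rng: np.random.Generator, length: int, gc: float) -> str:
    """Terminal 5-bp stem, C box (ATGATGA) at offset 5, D box (CTGA) ending
    5 nt from the 3' end."""
    arm5, arm3 = "GGCAC", "GTGCC"  # 5 complementary pairs
    cbox, dbox = "ATGATGA", "CTGA"
    mid_len = length - len(arm5) - len(cbox) - len(dbox) - len(arm3)
    # middle avoids accidental D-box copies interfering with nothing; plain random
    mid = _rand_seq(rng, mid_len, gc)
    return arm5 + cbox + mid + dbox + arm3


def _design_haca(rng: np.random.Generator, length: int) -> str:
    """Two G/C hairpins (the 5' one with an 8-A pocket loop) around an
    ANANNA hinge, ending ACA + 2 nt tail.  The sequence carries no T, so
    every A is necessarily unpaired under any folding; the only paired
    regions are the designed arms.  Pure-A pads center the hinge."""
    arm1a, arm1b = "GCGGCGGG", "CCCGCCGC"
    arm2a, arm2b = "GGGCGGC", "GCCGCCC"
    pocket = "A" * 8
    hinge = "AGACCA"  # ANANNA instance, T-free
    loop2 = "A" * 5
    tail = "ACACC"    # ACA box + 2-nt tail
    hp1 = arm1a + pocket + arm1b
    hp2 = arm2a + loop2 + arm2b
    pad1_len = max(0, length // 2 - 3 - len(hp1))
    pad2_len = length - len(hp1) - pad1_len - len(hinge) - len(hp2) - len(tail)
    if pad2_len < 0:
        raise ValueError("H/ACA design needs length >= 60")
    return hp1 + "A" * pad1_len + hinge + hp2 + "A" * pad2_len + tail


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def simulate_world(config: Optional[SimConfig] = None) -> SimWorld:
    """Generate the genome, annotations and truth napRNA set."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    chrom = cfg.chrom

    lo, hi = cfg.nap_len_range
    if not 100 <= lo <= hi:
        raise ValueError("nap_len_range must satisfy 100 <= lo <= hi")

    n_features = (
        cfg.n_plain + cfg.n_sli + cfg.n_snotron + cfg.n_mis
        + cfg.n_pol3 + cfg.n_cd + cfg.n_haca + cfg.n_exclusion + cfg.n_utr5
    )
    required = 1000 + n_features * (hi + cfg.feature_spacing + 600)
    if cfg.genome_length < required:
        raise ValueError(
            f"genome too small for requested features: need >= {required} nt"
        )

    genome_arr = list(_rand_seq(rng, cfg.genome_length, cfg.gc_fraction))
    cursor = 500
    strands = ["+", "-"]
    s_idx = 0

    truth: list[TruthNap] = []
    introns: list[GenomicInterval] = []
    snornas: list[GenomicInterval] = []
    pre_mirnas: list[GenomicInterval] = []
    mature_mirnas: list[GenomicInterval] = []
    utr5: list[GenomicInterval] = []
    exclusion: list[GenomicInterval] = []
    snorna_subtype: dict[str, str] = {}
    mirna_parent: dict[str, str] = {}

    def place(span: int) -> int:
        nonlocal cursor
        start = cursor
        cursor += span + cfg.feature_spacing
        return start

    def next_strand() -> str:
        nonlocal s_idx
        s = strands[s_idx % 2]
        s_idx += 1
        return s

    def implant_seq(iv: GenomicInterval, seq: str) -> None:
        g = seq if iv.strand == "+" else reverse_complement(seq)
        genome_arr[iv.start : iv.end] = g

    # plain structured napRNAs (no class geometry)
    for i in range(cfg.n_plain):
        length = int(rng.integers(lo, hi + 1))
        start = place(length)
        iv = GenomicInterval(chrom, start, start + length, next_strand(), name=f"plain{i}")
        truth.append(TruthNap(iv, "plain"))

    # sliRNAs: truth exactly equals a known intron
    for i in range(cfg.n_sli):
        length = int(rng.integers(max(lo, 150), hi + 1))
        start = place(length)
        strand = next_strand()
        intron = GenomicInterval(chrom, start, start + length, strand, name=f"intron_sli{i}")
        introns.append(intron)
        truth.append(TruthNap(
            GenomicInterval(chrom, start, start + length, strand, name=f"sli{i}"), "sliRNA"
        ))

    # snotrons: snoRNA 5' end -> within 10 nt of the host intron's 3' splice site
    for i in range(cfg.n_snotron):
        intron_len = int(rng.integers(max(lo + 60, 260), hi + 60))
        start = place(intron_len)
        strand = next_strand()
        intron = GenomicInterval(chrom, start, start + intron_len, strand, name=f"intron_sno{i}")
        introns.append(intron)
        sno_len = 80
        if strand == "+":
            sno = GenomicInterval(chrom, start + 30, start + 30 + sno_len, strand, name=f"snoRNA{i}")
            nap = GenomicInterval(chrom, sno.start, intron.end - 4, strand, name=f"snotron{i}")
        else:
            sno = GenomicInterval(
                chrom, start + intron_len - 30 - sno_len, start + intron_len - 30, strand,
                name=f"snoRNA{i}",
            )
            nap = GenomicInterval(chrom, start + 4, sno.end, strand, name=f"snotron{i}")
        snornas.append(sno)
        snorna_subtype[sno.name] = "CD" if i % 2 == 0 else "HACA"
        truth.append(TruthNap(nap, "snotron"))

    # misRNAs: spacer between two clustered pre-miRNAs, ends on mature ends
    for i in range(cfg.n_mis):
        pre_len, mat_len, spacer = 80, 22, 200
        span = pre_len * 2 + spacer
        start = place(span)
        strand = next_strand()
        pre1 = GenomicInterval(chrom, start, start + pre_len, strand, name=f"pre_mir{i}a")
        pre2 = GenomicInterval(
            chrom, start + pre_len + spacer, start + span, strand, name=f"pre_mir{i}b"
        )
        m1 = GenomicInterval(chrom, pre1.end - mat_len, pre1.end, strand, name=f"mir{i}a")
        m2 = GenomicInterval(chrom, pre2.start, pre2.start + mat_len, strand, name=f"mir{i}b")
        pre_mirnas.extend([pre1, pre2])
        mature_mirnas.extend([m1, m2])
        mirna_parent[m1.name] = pre1.name
        mirna_parent[m2.name] = pre2.name
        nap = GenomicInterval(chrom, m1.start, m2.end, strand, name=f"mis{i}")
        truth.append(TruthNap(nap, "misRNA"))

    # motif classes: designed sequences written into the genome
    for i in range(cfg.n_pol3):
        length = max(lo, 200)
        start = place(length)
        iv = GenomicInterval(chrom, start, start + length, next_strand(), name=f"pol3_{i}")
        implant_seq(iv, _design_pol3(rng, length, cfg.gc_fraction))
        truth.append(TruthNap(iv, "pol3"))

    for i in range(cfg.n_cd):
        length = max(lo, 110)
        start = place(length)
        iv = GenomicInterval(chrom, start, start + length, next_strand(), name=f"cd{i}")
        implant_seq(iv, _design_cd(rng, length, cfg.gc_fraction))
        truth.append(TruthNap(iv, "cd_box"))

    for i in range(cfg.n_haca):
        length = max(lo, 140)
        start = place(length)
        iv = GenomicInterval(chrom, start, start + length, next_strand(), name=f"haca{i}")
        implant_seq(iv, _design_haca(rng, length))
        truth.append(TruthNap(iv, "haca_box"))

    # annotation-only features
    for i in range(cfg.n_exclusion):
        length = 300
        start = place(length)
        exclusion.append(
            GenomicInterval(chrom, start, start + length, next_strand(), name=f"rRNA{i}")
        )
    for i in range(cfg.n_utr5):
        length = 400
        start = place(length)
        utr5.append(
            GenomicInterval(chrom, start, start + length, next_strand(), name=f"utr5_{i}")
        )

    annotations = AnnotationSet(
        introns=FeatureIndex(introns),
        snornas=FeatureIndex(snornas),
        pre_mirnas=FeatureIndex(pre_mirnas),
        mature_mirnas=FeatureIndex(mature_mirnas),
        utr5=FeatureIndex(utr5),
        exclusion=FeatureIndex(exclusion),
        snorna_subtype=snorna_subtype,
        mirna_parent=mirna_parent,
    )
    annotations.validate()
    return SimWorld({chrom: "".join(genome_arr)}, truth, annotations, cfg)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, p: float) -> int:
    if p <= 0:
        return 0
    return int(rng.geometric(1 - p) - 1) * (1 if rng.random() < 0.5 else -1)


def simulate_library(
    world: SimWorld, sample_id: str, rng: np.random.Generator
) -> list[AlignedReadRecord]:
    """Aligned reads for one library (simulation bypasses mapping).

    Full-length mode (default) emits ``reads_per_end`` reads flagged at the
    5' boundary and the same number at the 3' boundary per truth napRNA;
    fragmentation mode emits boundary-anchored fragments plus a tiling of
    unflagged body fragments so coverage stays contiguous.
    """
    cfg = world.config
    chrom_len = {c: len(s) for c, s in world.genome.items()}
    reads: list[AlignedReadRecord] = []

    for t in world.truth:
        iv = t.interval
        for end in ("5p", "3p"):
            for _ in range(cfg.reads_per_end):
                j5 = _jitter(rng, cfg.end_jitter_prob) if end == "5p" else 0
                j3 = _jitter(rng, cfg.end_jitter_prob) if end == "3p" else 0
                start = max(0, iv.start + (j5 if iv.strand == "+" else j3))
                stop = min(chrom_len[iv.chrom], iv.end + (j3 if iv.strand == "+" else j5))
                if cfg.fragmentation:
                    flen = int(rng.integers(60, max(61, min(len(iv), 150) + 1)))
                    if (end == "5p") == (iv.strand == "+"):
                        frag = GenomicInterval(iv.chrom, start, min(start + flen, stop), iv.strand)
                    else:
                        frag = GenomicInterval(iv.chrom, max(stop - flen, start), stop, iv.strand)
                else:
                    frag = GenomicInterval(iv.chrom, start, stop, iv.strand)
                retained = rng.random() < cfg.adapter_retention_prob
                has5p = retained and end == "5p" and frag.five_prime == iv.five_prime
                has3p = retained and end == "3p" and frag.three_prime == iv.three_prime
                if not cfg.fragmentation:
                    # full-length reads can verify either end
                    has5p = end == "5p" and retained
                    has3p = end == "3p" and retained
                reads.append(AlignedReadRecord(frag, has5p, has3p, sample_id))
        if cfg.fragmentation:
            # unflagged body fragments tile the insert for contiguous coverage
            step = 50
            for s in range(iv.start, iv.end, step):
                frag = GenomicInterval(iv.chrom, s, min(s + 100, iv.end), iv.strand)
                reads.append(AlignedReadRecord(frag, False, False, sample_id))

    n_bg = int(rng.poisson(cfg.background_read_rate * cfg.genome_length))
    for _ in range(n_bg):
        length = 80
        start = int(rng.integers(0, cfg.genome_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = GenomicInterval(cfg.chrom, start, start + length, strand)
        reads.append(
            AlignedReadRecord(frag, rng.random() < 0.1, rng.random() < 0.1, sample_id)
        )
    return reads


def simulate_libraries(world: SimWorld) -> dict[str, list[AlignedReadRecord]]:
    """One read list per sample, all streams derived from the world seed."""
    out: dict[str, list[AlignedReadRecord]] = {}
    for i in range(world.config.n_samples):
        rng = np.random.default_rng((world.config.rng_seed, 1000 + i))
        sample = f"sample{i + 1}"
        out[sample] = simulate_library(world, sample, rng)
    return out


def reads_to_fastq(
    world: SimWorld, reads: list[AlignedReadRecord], rng: np.random.Generator
) -> list[RawRead]:
    """Render aligned records as raw reads with full adapter/barcode anatomy."""
    out: list[RawRead] = []
    for i, rec in enumerate(reads):
        insert = fetch_sequence(world.genome, rec.interval)
        bc5 = "".join(_BASES[rng.integers(0, 4, size=6)])
        bc3 = "".join(_BASES[rng.integers(0, 4, size=6)])
        seq = ""
        if rec.has5p:
            seq += ADAPTER5 + bc5
        seq += insert
        if rec.has3p:
            seq += bc3 + ADAPTER3
        out.append(RawRead(f"read{i}", seq, "I" * len(seq)))
    return out


# ---------------------------------------------------------------------------
# Probing simulation (reactivity validation data)
# ---------------------------------------------------------------------------

def simulate_probing(
    paired: np.ndarray,
    depth: int = 5000,
    ss_rate: float = 0.05,
    ds_rate: float = 0.005,
    untreated_rate: float = 0.002,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-position mutation rates for a treated and an untreated channel.

    ``paired`` is a boolean array (True = base-paired).  Single-stranded
    positions mutate at ``ss_rate`` under treatment, paired ones at
    ``ds_rate``; the untreated channel mutates uniformly at
    ``untreated_rate``.  Returns (treated_rate, treated_depth,
    untreated_rate, untreated_depth).
    """
    rng = np.random.default_rng(rng_seed)
    paired = np.asarray(paired, dtype=bool)
    n = len(paired)
    p_treat = np.where(paired, ds_rate, ss_rate)
    t_muts = rng.binomial(depth, p_treat)
    u_muts = rng.binomial(depth, untreated_rate, size=n)
    d = np.full(n, depth, dtype=np.int64)
    return t_muts / depth, d, u_muts / depth, d.copy()


# ---------------------------------------------------------------------------
# On-disk world
# ---------------------------------------------------------------------------

def write_world(world: SimWorld, outdir) -> None:
    """Write genome.fa, truth.bed, annotations/*.bed, per-sample alignment
    TSVs and FASTQs, and a config echo."""
    out = Path(outdir)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    write_fasta(world.genome, out / "genome.fa")
    truth_ivs = [
        GenomicInterval(
            t.interval.chrom, t.interval.start, t.interval.end, t.interval.strand,
            name=f"{t.interval.name}|{t.label}",
        )
        for t in world.truth
    ]
    write_bed(truth_ivs, out / "truth.bed")
    ann = world.annotations
    write_bed(list(ann.introns), out / "annotations" / "introns.bed")
    write_bed(list(ann.snornas), out / "annotations" / "snornas.bed")
    write_bed(list(ann.pre_mirnas), out / "annotations" / "pre_mirnas.bed")
    write_bed(list(ann.mature_mirnas), out / "annotations" / "mature_mirnas.bed")
    write_bed(list(ann.utr5), out / "annotations" / "utr5.bed")
    write_bed(list(ann.exclusion), out / "annotations" / "exclusion.bed")

    libs = simulate_libraries(world)
    from .trim import write_fastq, TrimmedRead

    for sample, reads in libs.items():
        write_alignment_tsv(reads, out / f"{sample}.alignments.tsv")
        rng = np.random.default_rng((world.config.rng_seed, hash(sample) % 2**16))
        raws = reads_to_fastq(world, reads, rng)
        with open(out / f"{sample}.fastq", "w") as fh:
            for r in raws:
                fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")

    cfg = asdict(world.config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)


__all__ = [
    "SimConfig",
    "TruthNap",
    "SimWorld",
    "simulate_world",
    "simulate_library",
    "simulate_libraries",
    "reads_to_fastq",
    "simulate_probing",
    "write_world",
]
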