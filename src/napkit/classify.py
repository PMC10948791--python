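"""Assign called napRNAs to ncRNA classes.

Interval-rule classes
---------------------
* **sliRNA** — stable linear intron RNA: shares both the 5'-start and 3'-end
  with a known intron (within a configurable end tolerance, default exact).
* **snotron** — one end coincides with an intronic snoRNA's end while the
  other lies within +/-10 nt of the host intron's splice site.
* **misRNA** — miRNA-spacer RNA: intersects a cluster of pre-miRNAs (members
  < 10 kb apart, strict), is not wholly contained in any single pre-miRNA,
  and (soft criterion) has ends flush with mature-miRNA ends.

Motif classes
-------------
* **pol3** — internal RNA Pol III promoter elements (A box, B box) plus a
  >=4-U terminator stretch at the 3' end.
* **cd_box** — 5'-proximal C box (RUGAUGA) and 3'-proximal D box (CUGA)
  closed by a terminal stem of >=4 pairs (G.U allowed).
* **haca_box** — two-hairpin architecture with an H-box hinge (ANANNA) and a
  3' ACA box; optionally annotated with a poly(A) pocket (>=6 unpaired A in
  the 5' hairpin).

Motif consensi are the canonical literature defaults and every offset and
mismatch budget is configurable, since promoter/box models vary between
pipelines.  Sequences may be given as DNA or RNA; matching is alphabet-
agnostic (U and T are equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .genomic import AnnotationSet, FeatureIndex, GenomicInterval

# ---------------------------------------------------------------------------
# IUPAC scanning helpers
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

# G.U wobble included: the stems here are RNA stems scanned in DNA space
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _mismatches(window: str, consensus: str) -> Optional[int]:
    """Mismatch count of ``window`` vs IUPAC ``consensus`` (N positions free);
    None if lengths differ."""
    if len(window) != len(consensus):
        return None
    mm = 0
    for b, c in zip(window, consensus):
        if c == "N":
            continue
        if b not in _IUPAC[c]:
            mm += 1
    return mm


def scan_motif(
    seq: str, consensus: str, max_mismatch: int, start: int = 0, stop: Optional[int] = None
) -> list[tuple[int, str, int]]:
    """All (offset, window, mismatches) hits of ``consensus`` in ``seq[start:stop]``,
    offsets relative to the full sequence, best (fewest-mismatch) first."""
    s = _dna(seq)
    cons = _dna(consensus)
    k = len(cons)
    stop = len(s) if stop is None else stop
    hits: list[tuple[int, str, int]] = []
    for i in range(start, min(stop, len(s) - k + 1)):
        mm = _mismatches(s[i : i + k], cons)
        if mm is not None and mm <= max_mismatch:
            hits.append((i, s[i : i + k], mm))
    hits.sort(key=lambda h: (h[2], h[0]))
    return hits


@dataclass(frozen=True)
class MotifHit:
    motif_kind: str
    offset: int
    matched_seq: str
    mismatches: int


# ---------------------------------------------------------------------------
# Novelty filter and interval-rule classes
# ---------------------------------------------------------------------------

def exclude_annotated(
    napRNAs: Iterable[GenomicInterval], annotations: AnnotationSet
) -> list[GenomicInterval]:
    """Drop napRNAs overlapping (>=1 nt, same strand) any exclusion feature."""
    return [n for n in napRNAs if not annotations.exclusion.overlap(n, same_strand=True)]


def classify_sliRNA(
    nap: GenomicInterval, introns: FeatureIndex, end_tolerance: int = 0
) -> Optional[dict]:
    """Full-length excised intron: both ends shared with one known intron."""
    for intron in introns.overlap(nap, same_strand=True):
        if (
            abs(nap.five_prime - intron.five_prime) <= end_tolerance
            and abs(nap.three_prime - intron.three_prime) <= end_tolerance
        ):
            return {"intron": intron.name}
    return None


def classify_snotron(
    nap: GenomicInterval,
    snornas: FeatureIndex,
    introns: FeatureIndex,
    splice_tolerance: int = 10,
    sno_end_tolerance: int = 0,
) -> Optional[dict]:
    """snoRNA-to-splice-site napRNA.

    Either the napRNA 5' end sits on an intronic snoRNA's 5' end and its 3'
    end within ``splice_tolerance`` of the host intron's 3' splice site, or
    the mirror configuration.  The snoRNA must lie inside the matched intron.
    """
    for sno in snornas.overlap(nap, same_strand=True):
        for intron in introns.overlap(sno, same_strand=True):
            if not intron.contains(sno):
                continue
            # 5' end on snoRNA, 3' end near the 3' splice site
            if (
                abs(nap.five_prime - sno.five_prime) <= sno_end_tolerance
                and abs(nap.three_prime - intron.three_prime) <= splice_tolerance
            ):
                return {"snoRNA": sno.name, "intron": intron.name, "config": "sno5p_to_3pSS"}
            # mirror: 3' end on snoRNA, 5' end near the 5' splice site
            if (
                abs(nap.three_prime - sno.three_prime) <= sno_end_tolerance
                and abs(nap.five_prime - intron.five_prime) <= splice_tolerance
            ):
                return {"snoRNA": sno.name, "intron": intron.name, "config": "5pSS_to_sno3p"}
    return None


@dataclass(frozen=True)
class MirnaCluster:
    members: tuple[GenomicInterval, ...]

    @property
    def span(self) -> GenomicInterval:
        m = self.members
        return GenomicInterval(
            m[0].chrom, min(x.start for x in m), max(x.end for x in m), m[0].strand,
            name="+".join(x.name for x in m),
        )


def cluster_premirnas(
    pre_mirnas: Iterable[GenomicInterval], max_gap: int = 10_000
) -> list[MirnaCluster]:
    """Single-linkage clustering of same-strand pre-miRNAs with inter-feature
    gap strictly below ``max_gap``."""
    by_group: dict[tuple[str, str], list[GenomicInterval]] = {}
    for p in pre_mirnas:
        by_group.setdefault((p.chrom, p.strand), []).append(p)
    clusters: list[MirnaCluster] = []
    for key in sorted(by_group):
        feats = sorted(by_group[key], key=lambda f: (f.start, f.end, f.name))
        current = [feats[0]]
        reach = feats[0].end
        for f in feats[1:]:
            if f.start - reach < max_gap:  # strict <
                current.append(f)
                reach = max(reach, f.end)
            else:
                clusters.append(MirnaCluster(tuple(current)))
                current, reach = [f], f.end
        clusters.append(MirnaCluster(tuple(current)))
    clusters.sort(key=lambda c: (c.span.chrom, c.span.start, c.span.end, c.span.strand))
    return clusters


def classify_misRNA(
    nap: GenomicInterval,
    clusters: list[MirnaCluster],
    mature_mirnas: FeatureIndex,
    end_tolerance: int = 3,
    enforce_mature_ends: bool = False,
) -> Optional[dict]:
    """miRNA-spacer napRNA.

    Must intersect a pre-miRNA cluster on the same strand and must not be
    wholly contained in any single pre-miRNA (that would just be a known
    pre/mature miRNA).  Only clusters with >= 2 members qualify: a lone
    pre-miRNA has no spacer.  End coincidence with mature-miRNA ends is
    recorded as evidence and only enforced when ``enforce_mature_ends``.
    """
    for cl in clusters:
        if len(cl.members) < 2:
            continue
        if not nap.overlaps(cl.span, same_strand=True):
            continue
        if any(p.contains(nap) for p in cl.members):
            return None
        mature_ends: set[int] = set()
        for m in mature_mirnas.overlap(cl.span, same_strand=True):
            mature_ends.update((m.five_prime, m.three_prime))
        ends_match = (
            any(abs(nap.five_prime - e) <= end_tolerance for e in mature_ends)
            and any(abs(nap.three_prime - e) <= end_tolerance for e in mature_ends)
        )
        if enforce_mature_ends and not ends_match:
            return None
        return {"cluster": cl.span.name, "mature_end_coincidence": ends_match}
    return None


# ---------------------------------------------------------------------------
# Motif classes
# ---------------------------------------------------------------------------

@dataclass
class MotifParams:
    abox_consensus: str = "TRGCNNARYNNG"
    abox_max_mismatch: int = 2
    bbox_consensus: str = "GTTCRANNC"
    bbox_max_mismatch: int = 1
    terminator_window: int = 6       # 4U stretch must fall in the last 6 nt
    terminator_min_u: int = 4
    cbox_consensus: str = "RTGATGA"
    cbox_max_mismatch: int = 1
    cbox_max_offset: int = 12        # C box must start within 12 nt of the 5' end
    dbox_consensus: str = "CTGA"
    dbox_max_mismatch: int = 0
    dbox_max_offset: int = 12        # D box must end within 12 nt of the 3' end
    stem_min_pairs: int = 4
    stem_max_span: int = 10
    hbox_consensus: str = "ANANNA"
    hbox_max_mismatch: int = 1
    aca_max_tail: int = 3            # nt allowed after the ACA box
    polya_min_run: int = 6


def detect_pol3(seq: str, params: Optional[MotifParams] = None) -> Optional[list[MotifHit]]:
    """Internal Pol III promoter (A box then B box) plus a 3' >=4-U stretch."""
    p = params or MotifParams()
    s = _dna(seq)
    if len(s) < 60:
        return None
    tail = s[-p.terminator_window:]
    t_run = "T" * p.terminator_min_u
    t_idx = tail.find(t_run)
    if t_idx < 0:
        return None
    a_hits = scan_motif(s, p.abox_consensus, p.abox_max_mismatch, 0, len(s) // 2)
    for a_off, a_seq, a_mm in a_hits:
        b_hits = scan_motif(
            s, p.bbox_consensus, p.bbox_max_mismatch, a_off + len(p.abox_consensus)
        )
        if b_hits:
            b_off, b_seq, b_mm = b_hits[0]
            return [
                MotifHit("Abox", a_off, a_seq, a_mm),
                MotifHit("Bbox", b_off, b_seq, b_mm),
                MotifHit("4U", len(s) - p.terminator_window + t_idx, t_run, 0),
            ]
    return None


def _max_stem_pairs(five_arm: str, three_arm: str, max_span: int) -> int:
    """Longest run of consecutive complementary pairs (G.U allowed) in an
    ungapped alignment of the 5' arm against the 3' arm (read 3'->5')."""
    a = five_arm[-max_span:]
    b = three_arm[:max_span][::-1]  # reversed so b[j] pairs a[j] in a stem
    best = 0
    for shift in range(-(len(b) - 1), len(a)):
        run = 0
        for j in range(len(b)):
            i = shift + j
            if 0 <= i < len(a) and (a[i], b[j]) in _PAIRS:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def detect_cd_box(seq: str, params: Optional[MotifParams] = None) -> Optional[list[MotifHit]]:
    """C/D box architecture: 5' C box, 3' D box, terminal stem."""
    p = params or MotifParams()
    s = _dna(seq)
    if len(s) < 50:
        return None
    c_hits = scan_motif(s, p.cbox_consensus, p.cbox_max_mismatch, 0, p.cbox_max_offset + 1)
    d_lo = len(s) - p.dbox_max_offset - len(p.dbox_consensus)
    d_hits = scan_motif(s, p.dbox_consensus, p.dbox_max_mismatch, max(0, d_lo))
    for c_off, c_seq, c_mm in c_hits:
        for d_off, d_seq, d_mm in d_hits:
            five_arm = s[:c_off]
            three_arm = s[d_off + len(p.dbox_consensus):]
            if _max_stem_pairs(five_arm, three_arm, p.stem_max_span) >= p.stem_min_pairs:
                return [
                    MotifHit("Cbox", c_off, c_seq, c_mm),
                    MotifHit("Dbox", d_off, d_seq, d_mm),
                ]
    return None


def _hairpin_loops(dotbracket: str) -> list[tuple[int, int]]:
    """(i, j) pairs closing hairpin loops: '(' ... ')' with nothing paired
    in between."""
    stack: list[int] = []
    loops: list[tuple[int, int]] = []
    last_open: Optional[int] = None
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
            last_open = idx
        elif ch == ")":
            i = stack.pop()
            if last_open == i:
                loops.append((i, idx))
            last_open = None
    return loops


def detect_haca_box(
    seq: str,
    folder: Optional[Callable[[str], tuple[str, float]]] = None,
    params: Optional[MotifParams] = None,
) -> Optional[list[MotifHit]]:
    """H/ACA architecture: two hairpins flanking an H-box hinge, 3' ACA box.

    ``folder`` maps a sequence to (dotbracket, energy); defaults to the
    built-in pair-maximization folder.  When positive, also annotates a
    poly(A) pocket (>= ``polya_min_run`` unpaired A) within the 5' hairpin
    if present.
    """
    p = params or MotifParams()
    s = _dna(seq)
    if len(s) < 60:
        return None
    # ACA box with at most aca_max_tail nt trailing it
    aca_off = -1
    for tail in range(p.aca_max_tail + 1):
        pos = len(s) - 3 - tail
        if pos >= 0 and s[pos : pos + 3] == "ACA":
            aca_off = pos
            break
    if aca_off < 0:
        return None
    third = len(s) // 3
    h_hits = scan_motif(s, p.hbox_consensus, p.hbox_max_mismatch, third, 2 * third)
    if not h_hits:
        return None

    if folder is None:
        from .structure import fold_pairmax

        folder = lambda x: (fold_pairmax(x).dotbracket, 0.0)  # noqa: E731
    dot, _ = folder(s)

    loops = _hairpin_loops(dot)
    for h_off, h_seq, h_mm in h_hits:
        h_end = h_off + len(p.hbox_consensus)
        up = [(i, j) for i, j in loops if j < h_off]
        down = [(i, j) for i, j in loops if i >= h_end]
        if not up or not down:
            continue
        hits = [
            MotifHit("Hbox", h_off, h_seq, h_mm),
            MotifHit("ACAbox", aca_off, "ACA", 0),
        ]
        # poly(A) pocket: run of unpaired A inside the 5' hairpin
        run_start, run = -1, 0
        for i in range(h_off):
            if s[i] == "A" and dot[i] == ".":
                if run == 0:
                    run_start = i
                run += 1
                if run >= p.polya_min_run:
                    pass
            else:
                if run >= p.polya_min_run:
                    hits.append(MotifHit("polyA_pocket", run_start, "A" * run, 0))
                run = 0
        if run >= p.polya_min_run:
            hits.append(MotifHit("polyA_pocket", run_start, "A" * run, 0))
        return hits
    return None


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ClassifyParams:
    sli_end_tolerance: int = 0
    snotron_splice_tolerance: int = 10
    snotron_sno_end_tolerance: int = 0
    mirna_cluster_gap: int = 10_000
    mis_end_tolerance: int = 3
    mis_enforce_mature_ends: bool = False
    motifs: MotifParams = field(default_factory=MotifParams)
    apply_exclusion: bool = True


@dataclass
class ClassifiedNapRNA:
    interval: GenomicInterval
    labels: set[str] = field(default_factory=set)
    evidence: dict[str, object] = field(default_factory=dict)


def classify_all(
    napRNAs: Iterable[GenomicInterval],
    annotations: AnnotationSet,
    genome: Optional[dict[str, str]] = None,
    params: Optional[ClassifyParams] = None,
    folder: Optional[Callable[[str], tuple[str, float]]] = None,
) -> list[ClassifiedNapRNA]:
    """Run the novelty filter and every classifier over a napRNA set.

    Motif classes are only evaluated when a genome is supplied.  Output
    order is deterministic (sorted by coordinate) regardless of input order.
    """
    from .genomic import fetch_sequence

    p = params or ClassifyParams()
    naps = sorted(napRNAs, key=lambda n: (n.chrom, n.start, n.end, n.strand, n.name))
    if p.apply_exclusion:
        naps = exclude_annotated(naps, annotations)
    clusters = cluster_premirnas(list(annotations.pre_mirnas), p.mirna_cluster_gap)

    out: list[ClassifiedNapRNA] = []
    for nap in naps:
        res = ClassifiedNapRNA(nap)
        ev = classify_sliRNA(nap, annotations.introns, p.sli_end_tolerance)
        if ev:
            res.labels.add("sliRNA")
            res.evidence["sliRNA"] = ev
        ev = classify_snotron(
            nap, annotations.snornas, annotations.introns,
            p.snotron_splice_tolerance, p.snotron_sno_end_tolerance,
        )
        if ev:
            res.labels.add("snotron")
            res.evidence["snotron"] = ev
        ev = classify_misRNA(
            nap, clusters, annotations.mature_mirnas,
            p.mis_end_tolerance, p.mis_enforce_mature_ends,
        )
        if ev:
            res.labels.add("misRNA")
            res.evidence["misRNA"] = ev
        if genome is not None:
            seq = fetch_sequence(genome, nap)
            hits = detect_pol3(seq, p.motifs)
            if hits:
                res.labels.add("pol3")
                res.evidence["pol3"] = hits
            hits = detect_cd_box(seq, p.motifs)
            if hits:
                res.labels.add("cd_box")
                res.evidence["cd_box"] = hits
            hits = detect_haca_box(seq, folder, p.motifs)
            if hits:
                res.labels.add("haca_box")
                res.evidence["haca_box"] = hits
        out.append(res)
    return out


LABELS = ("sliRNA", "snotron", "misRNA", "pol3", "cd_box", "haca_box")


def write_classified_tsv(rows: list[ClassifiedNapRNA], path, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            for hline in header.splitlines():
                fh.write(f"#{hline}\n")
        fh.write("#chrom\tstart\tend\tstrand\tname\t" + "\t".join(LABELS) + "\tevidence\n")
        for r in rows:
            iv = r.interval
            flags = "\t".join(str(int(lbl in r.labels)) for lbl in LABELS)
            ev = ";".join(f"{k}={r.evidence[k]}" for k in sorted(r.evidence))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{iv.name}\t{flags}\t{ev}\n")


__all__ = [
    "MotifHit",
    "MotifParams",
    "MirnaCluster",
    "ClassifyParams",
    "ClassifiedNapRNA",
    "LABELS",
    "scan_motif",
    "exclude_annotated",
    "classify_sliRNA",
    "classify_snotron",
    "cluster_premirnas",
    "classify_misRNA",
    "detect_pol3",
    "detect_cd_box",
    "detect_haca_box",
    "classify_all",
    "write_classified_tsv",
]
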