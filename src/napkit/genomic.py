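"""Core genomic coordinate types, annotation containers and flat-file I/O.

All coordinates in the toolkit are 0-based half-open (BED-native) on an
explicit strand.  Biological ends are derived per strand: the 5' end of a
feature is ``start`` on '+' and ``end - 1`` on '-'; the 3' end is ``end - 1``
on '+' and ``start`` on '-'.  Any 1-based representation exists only at a
serialization boundary (none is currently emitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, 0-based half-open genomic interval.

    Ordering is (chrom, start, end, strand, name) so sorted outputs are
    deterministic across runs and platforms.
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    score: str = "0"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(
                f"zero- or negative-length interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the biological 5' end (strand-aware boundary base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Position of the biological 3' end."""
        return self.end - 1 if self.strand == "+" else self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start <= other.start and other.end <= self.end


def end_distance(a_pos: int, b_pos: int, strand: str) -> int:
    """Signed distance from reference ``b_pos`` to ``a_pos``, oriented 5'->3'
    on ``strand`` (negative = upstream of the reference point)."""
    if strand not in STRANDS:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    d = a_pos - b_pos
    return d if strand == "+" else -d


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end, iv.strand, iv.name)


class FeatureIndex:
    """Interval index over a feature list with deterministic overlap queries.

    Backed by one :class:`intervaltree.IntervalTree` per chromosome; query
    results are returned sorted by (start, end, name) so they match a linear
    scan exactly, in a reproducible order.
    """

    def __init__(self, features: Iterable[GenomicInterval] = ()):  # noqa: D107
        self.features: list[GenomicInterval] = sorted(features, key=_sort_key)
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.features)

    def overlap(self, query: GenomicInterval, same_strand: bool = True) -> list[GenomicInterval]:
        """All features sharing >=1 nt with ``query`` (optionally same strand)."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(query.start, query.end)]
        if same_strand:
            hits = [h for h in hits if h.strand == query.strand]
        return sorted(hits, key=_sort_key)

    def stab(self, chrom: str, pos: int, strand: Optional[str] = None) -> list[GenomicInterval]:
        """Features covering a single position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.at(pos)]
        if strand is not None:
            hits = [h for h in hits if h.strand == strand]
        return sorted(hits, key=_sort_key)


@dataclass
class AnnotationSet:
    """Indexed annotation bundle used by the classifiers.

    ``snorna_subtype`` maps snoRNA name -> 'CD' | 'HACA'; ``mirna_parent``
    maps mature-miRNA name -> parent pre-miRNA name.  Exclusion features are
    the novelty filter set (rRNA/tRNA/snoRNA/CDS and similar).
    """

    introns: FeatureIndex = field(default_factory=FeatureIndex)
    snornas: FeatureIndex = field(default_factory=FeatureIndex)
    pre_mirnas: FeatureIndex = field(default_factory=FeatureIndex)
    mature_mirnas: FeatureIndex = field(default_factory=FeatureIndex)
    utr5: FeatureIndex = field(default_factory=FeatureIndex)
    exclusion: FeatureIndex = field(default_factory=FeatureIndex)
    snorna_subtype: dict[str, str] = field(default_factory=dict)
    mirna_parent: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        """Check that every mature miRNA is contained in its parent pre-miRNA."""
        pre_by_name = {p.name: p for p in self.pre_mirnas}
        for m in self.mature_mirnas:
            parent = self.mirna_parent.get(m.name)
            if parent is None:
                raise ValueError(f"mature miRNA {m.name} has no parent pre-miRNA")
            p = pre_by_name.get(parent)
            if p is None or not p.contains(m):
                raise ValueError(f"mature miRNA {m.name} not contained in parent {parent}")


# ---------------------------------------------------------------------------
# Flat-file readers / writers
# ---------------------------------------------------------------------------

def read_bed(path, feature_kind: str = "feature", allow_dot_strand: bool = False) -> list[GenomicInterval]:
    """Read a BED6 file into a list of :class:`GenomicInterval`.

    BED is already 0-based half-open, so coordinates pass through untouched.
    Lines starting with '#' or 'track' are skipped.  A '.' strand is rejected
    unless ``allow_dot_strand`` (strand-specific feature kinds need strands).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 requires >=6 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if strand == ".":
                if not allow_dot_strand:
                    raise ValueError(
                        f"{path}:{lineno}: '.' strand not allowed for {feature_kind}"
                    )
                strand = "+"
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name=name, score=score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, header: Optional[str] = None) -> None:
    """Write intervals as BED6 in deterministic sorted order."""
    with open(path, "w") as fh:
        if header:
            for hline in header.splitlines():
                fh.write(f"#{hline}\n")
        for iv in sorted(intervals, key=_sort_key):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Read an (uncompressed) FASTA into a dict of upper-case sequences."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate contig {name!r} in {path}")
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(genome: dict[str, str], iv: GenomicInterval) -> str:
    """Genomic-sense sequence of ``iv`` in transcript orientation (5'->3')."""
    if iv.chrom not in genome:
        raise KeyError(f"contig {iv.chrom!r} not in genome")
    s = genome[iv.chrom][iv.start : iv.end]
    if len(s) != len(iv):
        raise ValueError(f"interval {iv} exceeds contig bounds")
    return s if iv.strand == "+" else reverse_complement(s)


__all__ = [
    "GenomicInterval",
    "FeatureIndex",
    "AnnotationSet",
    "end_distance",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "fetch_sequence",
    "replace",
]
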