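"""Detection and removal of the NAP-seq library adapters and N6 barcodes.

The library anatomy is::

    [5' adapter][N6 barcode][   insert   ][N6 barcode][3' adapter]

The 5' adapter marks the transcript's true 5'-start and the 3' adapter its
true 3'-end, so a read whose edge carries an adapter is *boundary-verified*
at that end.  Roughly half of all read ends retain their adapter after
library fragmentation; the trimmer records ``has5p`` / ``has3p`` per read so
the caller can count verified boundaries.

Adapter matching is edge-anchored semi-global alignment with unit-cost edits
(substitutions and indels): the adapter, possibly truncated at the read edge,
must align starting at the read's first base (5') or ending at its last base
(3'), with at least ``min_overlap`` adapter bases and an edit fraction no
greater than ``max_error_rate``.  Ties are broken by fewest errors, then
longest matched adapter, then the alignment closest to the read edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO

import edlib

ADAPTER5 = "AAGCAGTGGTATCAACGCAGAGT"
ADAPTER3 = "AGTCGTAGTAAGTCTGTGCTCG"

_MAX_ADAPTER_LEN = 100


@dataclass(frozen=True)
class AdapterMatch:
    """One adapter alignment: read span [read_start, read_end), adapter bases
    matched, and edit errors."""

    read_start: int
    read_end: int
    matched_len: int
    errors: int


@dataclass
class RawRead:
    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty read {self.id}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"quality length mismatch for read {self.id}")


@dataclass
class TrimmedRead:
    id: str
    insert_seq: str
    qual: Optional[str]
    has5p: bool
    has3p: bool
    barcode5: str = ""
    barcode3: str = ""


@dataclass
class TrimConfig:
    """Trimming parameters; NGS defaults mirror the library protocol
    (error rate 0.1, min retained length 15, 6-nt barcodes at both ends)."""

    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    max_error_rate: float = 0.1
    min_length: int = 15
    barcode5_len: int = 6
    barcode3_len: int = 6
    min_overlap: int = 10

    @classmethod
    def nanopore(cls) -> "TrimConfig":
        """Long-read preset: higher error tolerance, overlap 10, min length 20."""
        return cls(max_error_rate=0.3, min_length=20, min_overlap=10)


def locate_adapter(
    seq: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 10,
    end: str = "5p",
) -> Optional[AdapterMatch]:
    """Find the best edge-anchored alignment of ``adapter`` in ``seq``.

    ``end='5p'``: the adapter (or a suffix of it, truncated off the read's
    left edge) aligns starting at read position 0.  ``end='3p'``: mirror case
    at the right edge.  Returns the qualifying alignment with fewest errors,
    then most adapter bases matched, then closest to the read edge, or None.
    """
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(adapter) > _MAX_ADAPTER_LEN:
        raise ValueError(f"adapter longer than {_MAX_ADAPTER_LEN} nt — misconfiguration?")
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")

    if end == "3p":
        m = locate_adapter(seq[::-1], adapter[::-1], max_error_rate, min_overlap, end="5p")
        if m is None:
            return None
        n = len(seq)
        return AdapterMatch(n - m.read_end, n - m.read_start, m.matched_len, m.errors)

    # candidate = (error_rate, -matched, errors, read_end)
    best: Optional[tuple[float, int, int, int]] = None
    m = len(adapter)
    # Truncation j0 strips the adapter prefix hanging off the read's 5' edge.
    for j0 in range(0, m - min_overlap + 1):
        sub = adapter[j0:]
        matched_len = m - j0
        max_err = int(max_error_rate * matched_len)
        # Window large enough to hold the adapter plus any allowed insertions.
        window = seq[: matched_len + max_err]
        if len(window) < 1:
            continue
        cand: Optional[tuple[float, int, int, int]] = None
        # An ungapped alignment within budget takes precedence over a gapped
        # one of equal or even lower edit cost: substitutions near the
        # adapter edge must not be re-read as indels, or the barcode shifts.
        if len(window) >= matched_len:
            ham = sum(a != b for a, b in zip(sub, window))
            if ham <= max_err:
                cand = (ham / matched_len, -matched_len, ham, matched_len)
        if cand is None:
            res = edlib.align(sub, window, mode="SHW", task="distance", k=max_err)
            if res["editDistance"] >= 0:
                d = res["editDistance"]
                cand = (d / matched_len, -matched_len, d, _best_end(sub, window, d))
        if cand is not None and (best is None or cand[:2] < best[:2]):
            best = cand
    if best is None:
        return None
    return AdapterMatch(0, best[3], -best[1], best[2])


def _best_end(sub: str, window: str, dist: int) -> int:
    """End position of an optimal alignment of ``sub`` against a window prefix.

    Several window prefixes can tie at the optimal edit distance (a
    substitution at the adapter edge costs the same as an edge deletion);
    the end closest to the ungapped adapter length is chosen, which makes
    substitution-only reads trim back to their exact inserts."""
    # Global in sub, anchored at window start, free end in window.
    prev = list(range(len(window) + 1))
    for i, a in enumerate(sub, start=1):
        cur = [i] + [0] * len(window)
        for j, b in enumerate(window, start=1):
            cur[j] = min(
                prev[j - 1] + (a != b),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    ends = [j for j, d in enumerate(prev) if d == dist]
    if not ends:
        raise AssertionError("edit-distance bookkeeping mismatch")
    return min(ends, key=lambda j: (abs(j - len(sub)), j))


def trim_read(read: RawRead, config: Optional[TrimConfig] = None) -> Optional[TrimmedRead]:
    """Strip NAP-seq adapters and barcodes from one read.

    Returns the trimmed read, or None when the retained insert is shorter
    than ``config.min_length``.  Reads with neither adapter are retained with
    both flags false: they still contribute coverage, just never boundary
    counts.  An adapter whose barcode region is truncated (fewer than the
    configured barcode bases remain) is treated as absent at that end.
    """
    cfg = config or TrimConfig()
    seq = read.seq
    istart, iend = 0, len(seq)
    has5p = has3p = False
    bc5 = bc3 = ""

    m5 = locate_adapter(seq, cfg.adapter5, cfg.max_error_rate, cfg.min_overlap, end="5p")
    if m5 is not None:
        if m5.read_end + cfg.barcode5_len <= len(seq):
            bc5 = seq[m5.read_end : m5.read_end + cfg.barcode5_len]
            istart = m5.read_end + cfg.barcode5_len
            has5p = True
        # else: barcode region truncated — treat as no 5' adapter

    m3 = locate_adapter(
        seq[istart:], cfg.adapter3, cfg.max_error_rate, cfg.min_overlap, end="3p"
    )
    if m3 is not None:
        adapter_start = istart + m3.read_start
        if adapter_start - cfg.barcode3_len >= istart:
            bc3 = seq[adapter_start - cfg.barcode3_len : adapter_start]
            iend = adapter_start - cfg.barcode3_len
            has3p = True

    insert = seq[istart:iend]
    if len(insert) < cfg.min_length:
        return None
    qual = read.qual[istart:iend] if read.qual is not None else None
    return TrimmedRead(read.id, insert, qual, has5p, has3p, bc5, bc3)


def trim_pair(
    read1: RawRead, read2: RawRead, config: Optional[TrimConfig] = None
) -> tuple[Optional[TrimmedRead], Optional[TrimmedRead], bool, bool]:
    """Trim a read pair independently and merge flags per fragment.

    Read 2 is the reverse-complemented mate, so it sees the 3' adapter at its
    own 5' edge; fragment-level ``has5p`` comes from read 1's 5' edge (or
    read 2's far edge on read-through), ``has3p`` symmetrically.
    """
    from .genomic import reverse_complement

    cfg = config or TrimConfig()
    cfg2 = TrimConfig(
        adapter5=reverse_complement(cfg.adapter3),
        adapter3=reverse_complement(cfg.adapter5),
        max_error_rate=cfg.max_error_rate,
        min_length=cfg.min_length,
        barcode5_len=cfg.barcode3_len,
        barcode3_len=cfg.barcode5_len,
        min_overlap=cfg.min_overlap,
    )
    t1 = trim_read(read1, cfg)
    t2 = trim_read(read2, cfg2)
    has5p = (t1 is not None and t1.has5p) or (t2 is not None and t2.has3p)
    has3p = (t2 is not None and t2.has5p) or (t1 is not None and t1.has3p)
    return t1, t2, has5p, has3p


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[RawRead]:
    """Iterate a (plain-text) FASTQ file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield RawRead(rec.id, str(rec.seq).upper(), qual or None)


def write_fastq(reads: Iterable[TrimmedRead], fh: TextIO) -> None:
    """Write trimmed reads with flag/barcode comment tags."""
    for r in reads:
        tag = f"np:5p={int(r.has5p)};3p={int(r.has3p)};bc5={r.barcode5};bc3={r.barcode3}"
        qual = r.qual if r.qual is not None else "I" * len(r.insert_seq)
        fh.write(f"@{r.id} {tag}\n{r.insert_seq}\n+\n{qual}\n")


@dataclass
class TrimStats:
    total: int = 0
    rejected: int = 0
    with5p: int = 0
    with3p: int = 0
    with_any: int = 0
    counts: dict = field(default_factory=dict)

    @property
    def adapter_fraction(self) -> float:
        """Fraction of retained reads carrying at least one specific adapter."""
        kept = self.total - self.rejected
        return self.with_any / kept if kept else 0.0


def trim_stream(
    reads: Iterable[RawRead], config: Optional[TrimConfig] = None
) -> tuple[list[TrimmedRead], TrimStats]:
    """Trim a read stream, collecting summary statistics."""
    stats = TrimStats()
    out: list[TrimmedRead] = []
    for read in reads:
        stats.total += 1
        t = trim_read(read, config)
        if t is None:
            stats.rejected += 1
            continue
        stats.with5p += t.has5p
        stats.with3p += t.has3p
        stats.with_any += t.has5p or t.has3p
        out.append(t)
    return out, stats


__all__ = [
    "ADAPTER5",
    "ADAPTER3",
    "AdapterMatch",
    "RawRead",
    "TrimmedRead",
    "TrimConfig",
    "TrimStats",
    "locate_adapter",
    "trim_read",
    "trim_pair",
    "trim_stream",
    "read_fastq",
    "write_fastq",
]
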