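"""Strand-specific coverage / 5'-start / 3'-end signal tracks.

Each aligned read contributes coverage over its genomic footprint; its
biological 5'-end position is counted in the ``start5`` track only when the
read carried the specific 5' adapter (``has5p``), and symmetrically for
``end3``.  These boundary tracks are the caller's raw material.  RPM
normalization (reads per million mapped reads) rescales every value by
``1e6 / library_size``; the raw integer tracks are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .genomic import GenomicInterval, STRANDS

SIGNALS = ("cov", "start5", "end3")


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned fragment: genomic footprint plus adapter-verification flags."""

    interval: GenomicInterval
    has5p: bool
    has3p: bool
    sample_id: str


@dataclass
class SignalTrack:
    """Per-(chrom, strand) arrays of coverage and verified boundary counts."""

    contig_lengths: dict[str, int]
    sample_id: str = ""
    library_size: int = 0
    arrays: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    rpm: bool = False

    def _arr(self, chrom: str, strand: str, signal: str) -> np.ndarray:
        key = (chrom, strand, signal)
        if key not in self.arrays:
            dtype = float if self.rpm else np.int64
            self.arrays[key] = np.zeros(self.contig_lengths[chrom], dtype=dtype)
        return self.arrays[key]

    def cov(self, chrom: str, strand: str) -> np.ndarray:
        return self._arr(chrom, strand, "cov")

    def start5(self, chrom: str, strand: str) -> np.ndarray:
        return self._arr(chrom, strand, "start5")

    def end3(self, chrom: str, strand: str) -> np.ndarray:
        return self._arr(chrom, strand, "end3")

    def add_read(self, rec: AlignedReadRecord) -> None:
        iv = rec.interval
        if iv.chrom not in self.contig_lengths:
            raise ValueError(f"read on unknown contig {iv.chrom!r}")
        if iv.end > self.contig_lengths[iv.chrom]:
            raise ValueError(f"read {iv} beyond contig bounds")
        self.cov(iv.chrom, iv.strand)[iv.start : iv.end] += 1
        if rec.has5p:
            self.start5(iv.chrom, iv.strand)[iv.five_prime] += 1
        if rec.has3p:
            self.end3(iv.chrom, iv.strand)[iv.three_prime] += 1
        self.library_size += 1


def build_tracks(
    reads: Iterable[AlignedReadRecord], contig_lengths: dict[str, int]
) -> dict[str, SignalTrack]:
    """Accumulate one :class:`SignalTrack` per ``sample_id``."""
    tracks: dict[str, SignalTrack] = {}
    for rec in reads:
        tr = tracks.get(rec.sample_id)
        if tr is None:
            tr = tracks[rec.sample_id] = SignalTrack(contig_lengths, rec.sample_id)
        tr.add_read(rec)
    return tracks


def rpm_normalize(track: SignalTrack) -> SignalTrack:
    """Return a reads-per-million copy of ``track`` (raw track untouched)."""
    if track.library_size <= 0:
        raise ValueError("library_size must be positive for RPM normalization")
    scale = 1e6 / track.library_size
    out = SignalTrack(track.contig_lengths, track.sample_id, track.library_size, rpm=True)
    for key, arr in track.arrays.items():
        out.arrays[key] = arr.astype(float) * scale
    return out


# ---------------------------------------------------------------------------
# I/O: simplified alignment TSV, SAM, bedGraph
# ---------------------------------------------------------------------------

def read_alignment_tsv(path) -> list[AlignedReadRecord]:
    """Read the 7-column alignment table
    (chrom, start, end, strand, has5p, has3p, sample)."""
    out: list[AlignedReadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            chrom, start, end, strand, h5, h3, sample = fields
            out.append(
                AlignedReadRecord(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    bool(int(h5)),
                    bool(int(h3)),
                    sample,
                )
            )
    return out


def write_alignment_tsv(reads: Iterable[AlignedReadRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\thas5p\thas3p\tsample\n")
        for r in reads:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{int(r.has5p)}\t{int(r.has3p)}\t{r.sample_id}\n"
            )


def read_alignment_sam(path, sample_id: Optional[str] = None) -> list[AlignedReadRecord]:
    """Read primary alignments from a SAM file.

    Adapter flags are taken from integer tags ``n5``/``n3`` when present
    (emitted by the trimmer's tagged FASTQ comments surviving into the
    aligner's output), else both false.  The footprint is the reference
    span of the alignment; mate/duplicate logic is the caller's concern.
    """
    import pysam

    out: list[AlignedReadRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            h5 = bool(aln.get_tag("n5")) if aln.has_tag("n5") else False
            h3 = bool(aln.get_tag("n3")) if aln.has_tag("n3") else False
            out.append(AlignedReadRecord(iv, h5, h3, sample_id or "sample1"))
    return out


def write_bedgraph(track: SignalTrack, signal: str, strand: str, path, header: Optional[str] = None) -> None:
    """Write one signal on one strand as bedGraph (zero runs omitted)."""
    if signal not in SIGNALS:
        raise ValueError(f"unknown signal {signal!r}")
    with open(path, "w") as fh:
        if header:
            for hline in header.splitlines():
                fh.write(f"#{hline}\n")
        for chrom in sorted(track.contig_lengths):
            key = (chrom, strand, signal)
            if key not in track.arrays:
                continue
            arr = track.arrays[key]
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], change, [len(arr)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = arr[s]
                if v != 0:
                    val = f"{v:.6g}" if track.rpm else str(int(v))
                    fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


__all__ = [
    "SIGNALS",
    "AlignedReadRecord",
    "SignalTrack",
    "build_tracks",
    "rpm_normalize",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "read_alignment_sam",
    "write_bedgraph",
]
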