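"""napSeeker: call full-length noncapped RNAs from boundary signal tracks.

The caller's model: a genuine full-length napRNA produces a pile of
adapter-verified 5'-start reads at one position and 3'-end reads at another,
with contiguous coverage between them that drops off sharply outside.  Per
covered contig it therefore measures six statistics,

* ``startReadNum`` / ``endReadNum`` — verified boundary-read counts at the
  candidate 5'/3' positions,
* ``startFC`` / ``endFC`` — those counts against the verified-boundary reads
  in the surrounding +/-100 nt (candidate position excluded, floor 1),
* ``up20ntFC`` / ``down20ntFC`` — mean candidate coverage against the mean
  coverage of the 20-nt flanks,

and keeps candidates with startReadNum, endReadNum >= 7; all four fold
changes >= 2; and length >= 100 nt.  Calls are then reconciled across
libraries: a napRNA must be called in at least 2 samples (ends agreeing
within a small tolerance) with a summed support count >= 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .genomic import GenomicInterval
from .tracks import SignalTrack

EPSILON_COV = 0.05  # pseudo-coverage: 1 read spread over a 20-nt flank


@dataclass
class SeekerParams:
    """Caller thresholds; defaults are the stringent published set."""

    cov_floor: int = 1
    boundary_window: int = 100
    flank: int = 20
    min_boundary_reads: int = 7
    min_boundary_fc: float = 2.0
    min_flank_fc: float = 2.0
    min_length: int = 100
    min_samples: int = 2
    min_summary: int = 20
    end_tolerance: int = 5
    multi_peak: bool = False


@dataclass(frozen=True)
class Contig:
    """Maximal run of positions at/above the coverage floor."""

    interval: GenomicInterval
    mean_cov: float


@dataclass
class NapCandidate:
    interval: GenomicInterval
    startReadNum: int
    endReadNum: int
    startFC: float
    endFC: float
    up20ntFC: float
    down20ntFC: float
    sample_id: str = ""
    counts_per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def support(self) -> int:
        """Boundary-verified reads supporting this call in its own sample."""
        return self.startReadNum + self.endReadNum

    @property
    def summary_count(self) -> int:
        """Total support across all samples recorded on this call."""
        if self.counts_per_sample:
            return sum(self.counts_per_sample.values())
        return self.support


def assemble_contigs(track: SignalTrack, cov_floor: int = 1) -> list[Contig]:
    """Maximal covered runs (cov >= cov_floor), per chromosome and strand."""
    if cov_floor < 1:
        raise ValueError("cov_floor must be >= 1")
    out: list[Contig] = []
    keys = sorted(k for k in track.arrays if k[2] == "cov")
    for chrom, strand, _ in keys:
        cov = track.arrays[(chrom, strand, "cov")]
        above = cov >= cov_floor
        if not above.any():
            continue
        diff = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1) + 1
        if above[0]:
            starts = np.concatenate(([0], starts))
        if above[-1]:
            ends = np.concatenate((ends, [len(cov)]))
        for s, e in zip(starts, ends):
            iv = GenomicInterval(chrom, int(s), int(e), strand)
            out.append(Contig(iv, float(cov[s:e].mean())))
    return out


def _window_sum_excluding(arr: np.ndarray, pos: int, radius: int) -> int:
    lo = max(0, pos - radius)
    hi = min(len(arr), pos + radius + 1)
    return int(arr[lo:hi].sum() - arr[pos])


def _flank_mean(cov: np.ndarray, lo: int, hi: int) -> float:
    """Mean coverage over [lo, hi) clipped to the contig, floored at EPSILON_COV."""
    lo, hi = max(0, lo), min(len(cov), hi)
    if hi <= lo:
        return EPSILON_COV
    return max(EPSILON_COV, float(cov[lo:hi].mean()))


def _stats_for_pair(
    track: SignalTrack,
    chrom: str,
    strand: str,
    p5: int,
    p3: int,
    sample_id: str,
    params: SeekerParams,
) -> Optional[NapCandidate]:
    """Six statistics for a (5'-position, 3'-position) pair, or None if the
    pair is not in biological order."""
    start5 = track.start5(chrom, strand)
    end3 = track.end3(chrom, strand)
    cov = track.cov(chrom, strand)
    w, f = params.boundary_window, params.flank

    if strand == "+":
        lo, hi = p5, p3 + 1
    else:
        lo, hi = p3, p5 + 1
    if hi <= lo:
        return None
    iv = GenomicInterval(chrom, lo, hi, strand)

    start_num = int(start5[p5])
    end_num = int(end3[p3])
    start_fc = start_num / max(1, _window_sum_excluding(start5, p5, w))
    end_fc = end_num / max(1, _window_sum_excluding(end3, p3, w))

    inside = float(cov[lo:hi].mean())
    if strand == "+":
        up_mean = _flank_mean(cov, p5 - f, p5)
        down_mean = _flank_mean(cov, p3 + 1, p3 + 1 + f)
    else:
        up_mean = _flank_mean(cov, p5 + 1, p5 + 1 + f)
        down_mean = _flank_mean(cov, p3 - f, p3)
    return NapCandidate(
        iv, start_num, end_num, start_fc, end_fc, inside / up_mean, inside / down_mean,
        sample_id=sample_id,
    )


def boundary_stats(
    contig: Contig, track: SignalTrack, params: Optional[SeekerParams] = None
) -> list[NapCandidate]:
    """Candidate boundaries and their statistics for one contig.

    Default mode emits the single best pair: the 5' position maximizing
    ``start5`` within the contig (ties broken toward the biological 5' side)
    and likewise for the 3' position.  ``multi_peak`` mode emits every
    non-overlapping threshold-passing pair, ranked by support.
    """
    p = params or SeekerParams()
    iv = contig.interval
    start5 = track.start5(iv.chrom, iv.strand)[iv.start : iv.end]
    end3 = track.end3(iv.chrom, iv.strand)[iv.start : iv.end]
    if start5.max(initial=0) == 0 or end3.max(initial=0) == 0:
        return []

    if not p.multi_peak:
        if iv.strand == "+":
            p5 = iv.start + int(np.argmax(start5))  # ties -> leftmost = most 5'
            rev3 = end3[::-1]
            p3 = iv.end - 1 - int(np.argmax(rev3))  # ties -> rightmost = most 3'
        else:
            rev5 = start5[::-1]
            p5 = iv.end - 1 - int(np.argmax(rev5))
            p3 = iv.start + int(np.argmax(end3))
        cand = _stats_for_pair(track, iv.chrom, iv.strand, p5, p3, track.sample_id, p)
        return [cand] if cand is not None else []

    pos5 = [iv.start + int(i) for i in np.flatnonzero(start5 >= p.min_boundary_reads)]
    pos3 = [iv.start + int(i) for i in np.flatnonzero(end3 >= p.min_boundary_reads)]
    cands: list[NapCandidate] = []
    for a in pos5:
        for b in pos3:
            c = _stats_for_pair(track, iv.chrom, iv.strand, a, b, track.sample_id, p)
            if c is not None and _passes(c, p):
                cands.append(c)
    cands.sort(key=lambda c: (-c.support, c.interval.start, c.interval.end))
    chosen: list[NapCandidate] = []
    for c in cands:
        if all(not c.interval.overlaps(k.interval) for k in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: (c.interval.start, c.interval.end))
    return chosen


def _passes(c: NapCandidate, p: SeekerParams) -> bool:
    return (
        c.startReadNum >= p.min_boundary_reads
        and c.endReadNum >= p.min_boundary_reads
        and c.startFC >= p.min_boundary_fc
        and c.endFC >= p.min_boundary_fc
        and c.up20ntFC >= p.min_flank_fc
        and c.down20ntFC >= p.min_flank_fc
        and len(c.interval) >= p.min_length
    )


def filter_candidates(
    cands: list[NapCandidate], params: Optional[SeekerParams] = None
) -> list[NapCandidate]:
    """Apply the six thresholds plus the minimum length (all inclusive)."""
    p = params or SeekerParams()
    return [c for c in cands if _passes(c, p)]


def call_sample(track: SignalTrack, params: Optional[SeekerParams] = None) -> list[NapCandidate]:
    """Contig assembly + boundary statistics + thresholds for one library."""
    p = params or SeekerParams()
    out: list[NapCandidate] = []
    for contig in assemble_contigs(track, p.cov_floor):
        out.extend(filter_candidates(boundary_stats(contig, track, p), p))
    return out


def merge_across_samples(
    per_sample_calls: dict[str, list[NapCandidate]],
    params: Optional[SeekerParams] = None,
) -> list[NapCandidate]:
    """Reconcile per-library calls into the final napRNA set.

    Calls whose 5' and 3' ends each agree within ``end_tolerance`` across
    samples are merged (single linkage); a merged call is kept when it is
    supported in >= ``min_samples`` libraries with a summed support count
    >= ``min_summary``.  The representative interval comes from the sample
    with the strongest support (ties broken by sample name).
    """
    p = params or SeekerParams()
    flat: list[NapCandidate] = []
    for sample in sorted(per_sample_calls):
        for c in per_sample_calls[sample]:
            flat.append(replace(c, sample_id=sample) if c.sample_id != sample else c)
    flat.sort(key=lambda c: (c.interval.chrom, c.interval.strand, c.interval.start, c.interval.end, c.sample_id))

    groups: list[list[NapCandidate]] = []
    for c in flat:
        placed = False
        for g in groups:
            if any(
                c.interval.chrom == m.interval.chrom
                and c.interval.strand == m.interval.strand
                and abs(c.interval.five_prime - m.interval.five_prime) <= p.end_tolerance
                and abs(c.interval.three_prime - m.interval.three_prime) <= p.end_tolerance
                for m in g
            ):
                g.append(c)
                placed = True
                break
        if not placed:
            groups.append([c])

    final: list[NapCandidate] = []
    for g in groups:
        samples = {m.sample_id for m in g}
        counts: dict[str, int] = {}
        for m in g:
            counts[m.sample_id] = counts.get(m.sample_id, 0) + m.support
        if len(samples) < p.min_samples or sum(counts.values()) < p.min_summary:
            continue
        rep = max(g, key=lambda m: (m.support, m.sample_id))
        merged = replace(rep, counts_per_sample=counts)
        final.append(merged)
    final.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.interval.strand))
    return final


def call_napRNAs(
    tracks: dict[str, SignalTrack], params: Optional[SeekerParams] = None
) -> list[NapCandidate]:
    """Full caller: per-sample calls, then cross-sample reconciliation."""
    p = params or SeekerParams()
    per_sample = {s: call_sample(t, p) for s, t in sorted(tracks.items())}
    return merge_across_samples(per_sample, p)


def write_candidates_tsv(cands: list[NapCandidate], path, header: Optional[str] = None) -> None:
    cols = (
        "chrom\tstart\tend\tstrand\tstartReadNum\tendReadNum\tstartFC\tendFC\t"
        "up20ntFC\tdown20ntFC\tsummary_count\tsamples"
    )
    with open(path, "w") as fh:
        if header:
            for hline in header.splitlines():
                fh.write(f"#{hline}\n")
        fh.write(f"#{cols}\n")
        for c in cands:
            iv = c.interval
            samples = ",".join(f"{k}:{v}" for k, v in sorted(c.counts_per_sample.items()))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{c.startReadNum}\t"
                f"{c.endReadNum}\t{c.startFC:.4g}\t{c.endFC:.4g}\t{c.up20ntFC:.4g}\t"
                f"{c.down20ntFC:.4g}\t{c.summary_count}\t{samples or c.sample_id}\n"
            )


__all__ = [
    "EPSILON_COV",
    "SeekerParams",
    "Contig",
    "NapCandidate",
    "assemble_contigs",
    "boundary_stats",
    "filter_candidates",
    "call_sample",
    "merge_across_samples",
    "call_napRNAs",
    "write_candidates_tsv",
]
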