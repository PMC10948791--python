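"""5'-cap site calling from CAP-seq 5'-end tracks, and napRNA cross-checks.

A capped transcription start produces a sharp, replicated pile of read 5'
ends inside an annotated mRNA 5'UTR.  A position is called a cap site when
all six criteria hold:

1. ``upFC = endCov / upCov >= 2`` (one nt upstream, denominator floored at 1),
2. ``downFC = endCov / downCov >= 2``,
3. ``endCov >= 10``,
4. enrichment p-value < 0.05 — a one-sided binomial test of ``endCov``
   successes out of the total 5'-end counts in the surrounding +/-100 nt
   window under a local-uniform null (success probability 1/(2w+1)),
5. criteria 1-4 hold in at least two replicates,
6. the position lies within an annotated 5'UTR on the same strand.

napRNAs, by definition noncapped, should almost never start at a called cap
site; :func:`compare_cap_overlap` measures exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats as _st

from .genomic import FeatureIndex, GenomicInterval
from .tracks import SignalTrack


@dataclass
class CapParams:
    min_fc: float = 2.0
    min_count: int = 10
    alpha: float = 0.05
    window: int = 100
    min_replicates: int = 2
    replicate_tolerance: int = 0  # cap sites are single-nucleotide features


@dataclass(frozen=True)
class CapSiteCandidate:
    chrom: str
    pos: int
    strand: str
    endCov: int
    upCov: int
    downCov: int
    upFC: float
    downFC: float
    pvalue: float
    replicates_supporting: int


def binomial_enrichment_pvalue(end_cov: int, window_total: int, window: int = 100) -> float:
    """P(X >= end_cov) for X ~ Binomial(window_total, 1/(2*window+1))."""
    if end_cov == 0:
        return 1.0
    p0 = 1.0 / (2 * window + 1)
    return float(_st.binom.sf(end_cov - 1, window_total, p0))


def _upstream_downstream(arr: np.ndarray, pos: int, strand: str) -> tuple[int, int]:
    """5'-end counts one nt upstream / downstream of ``pos`` (strand-aware)."""
    n = len(arr)
    if strand == "+":
        up = int(arr[pos - 1]) if pos - 1 >= 0 else 0
        down = int(arr[pos + 1]) if pos + 1 < n else 0
    else:
        up = int(arr[pos + 1]) if pos + 1 < n else 0
        down = int(arr[pos - 1]) if pos - 1 >= 0 else 0
    return up, down


def _replicate_sites(track: SignalTrack, params: CapParams) -> dict[tuple[str, int, str], CapSiteCandidate]:
    """Positions passing criteria 1-4 in one replicate."""
    out: dict[tuple[str, int, str], CapSiteCandidate] = {}
    for (chrom, strand, signal), arr in sorted(track.arrays.items()):
        if signal != "start5":
            continue
        for pos in np.flatnonzero(arr >= params.min_count):
            pos = int(pos)
            end_cov = int(arr[pos])
            up, down = _upstream_downstream(arr, pos, strand)
            up_fc = end_cov / max(up, 1)
            down_fc = end_cov / max(down, 1)
            if up_fc < params.min_fc or down_fc < params.min_fc:
                continue
            lo = max(0, pos - params.window)
            hi = min(len(arr), pos + params.window + 1)
            pval = binomial_enrichment_pvalue(end_cov, int(arr[lo:hi].sum()), params.window)
            if pval >= params.alpha:
                continue
            out[(chrom, pos, strand)] = CapSiteCandidate(
                chrom, pos, strand, end_cov, up, down, up_fc, down_fc, pval, 1
            )
    return out


def call_cap_sites(
    replicate_tracks: dict[str, SignalTrack],
    utr5: FeatureIndex,
    params: Optional[CapParams] = None,
) -> list[CapSiteCandidate]:
    """Apply the six cap-site criteria over >=2 replicate 5'-end tracks."""
    p = params or CapParams()
    if utr5 is None or len(utr5) == 0:
        raise ValueError("5'UTR annotation required: the 5'UTR criterion cannot be evaluated")
    if len(replicate_tracks) < p.min_replicates:
        raise ValueError(f"need >= {p.min_replicates} replicates, got {len(replicate_tracks)}")

    per_rep = [_replicate_sites(t, p) for _, t in sorted(replicate_tracks.items())]
    tally: dict[tuple[str, int, str], int] = {}
    for rep in per_rep:
        for key in rep:
            # replicate agreement within tolerance (0 = identical position)
            matched = None
            if p.replicate_tolerance == 0:
                matched = key if key in tally else None
            else:
                chrom, pos, strand = key
                for k2 in tally:
                    if k2[0] == chrom and k2[2] == strand and abs(k2[1] - pos) <= p.replicate_tolerance:
                        matched = k2
                        break
            if matched is not None:
                tally[matched] += 1
            else:
                tally[key] = tally.get(key, 0) + 1

    out: list[CapSiteCandidate] = []
    for key in sorted(tally):
        if tally[key] < p.min_replicates:
            continue
        chrom, pos, strand = key
        if not utr5.stab(chrom, pos, strand):
            continue
        best = max(
            (rep[key] for rep in per_rep if key in rep), key=lambda c: c.endCov
        )
        out.append(
            CapSiteCandidate(
                chrom, pos, strand, best.endCov, best.upCov, best.downCov,
                best.upFC, best.downFC, best.pvalue, tally[key],
            )
        )
    return out


def compare_cap_overlap(
    napRNAs: Iterable[GenomicInterval],
    cap_sites: Iterable[CapSiteCandidate],
    tolerance: int = 0,
) -> tuple[int, float]:
    """Count napRNAs whose biological 5'-start coincides with a cap site.

    Returns (count, fraction of napRNAs).  A low fraction is the expected
    signature of genuinely noncapped transcripts.
    """
    naps = list(napRNAs)
    sites = [(c.chrom, c.pos, c.strand) for c in cap_sites]
    n_hit = 0
    for nap in naps:
        p5 = nap.five_prime
        if any(
            s[0] == nap.chrom and s[2] == nap.strand and abs(s[1] - p5) <= tolerance
            for s in sites
        ):
            n_hit += 1
    return n_hit, (n_hit / len(naps) if naps else 0.0)


def write_cap_bed(sites: list[CapSiteCandidate], path, header: Optional[str] = None) -> None:
    """BED6 with score = -log10 p (capped at 300)."""
    from .genomic import write_bed

    ivs = [
        GenomicInterval(
            c.chrom, c.pos, c.pos + 1, c.strand,
            name=f"cap_{c.chrom}_{c.pos}_{c.strand}",
            score=f"{min(300.0, -np.log10(max(c.pvalue, 1e-300))):.3f}",
        )
        for c in sites
    ]
    write_bed(ivs, path, header=header)


__all__ = [
    "CapParams",
    "CapSiteCandidate",
    "binomial_enrichment_pvalue",
    "call_cap_sites",
    "compare_cap_overlap",
    "write_cap_bed",
]
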