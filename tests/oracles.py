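"""Independent brute-force oracles used by the test suite.

Every routine here recomputes a quantity by the most literal method
available (nested loops, exhaustive enumeration, direct summation) and is
kept free of any napkit internals beyond plain data types.
"""

from __future__ import annotations

import math

import numpy as np


def brute_overlap(query, features, same_strand=True):
    """Nested-loop interval overlap."""
    hits = []
    for f in features:
        if f.chrom != query.chrom:
            continue
        if same_strand and f.strand != query.strand:
            continue
        if f.start < query.end and query.start < f.end:
            hits.append(f)
    return sorted(hits, key=lambda f: (f.chrom, f.start, f.end, f.strand, f.name))


def brute_tracks(reads, lengths):
    """Position-by-position recount of coverage and boundary signals."""
    out = {}
    for r in reads:
        iv = r.interval
        key = (r.sample_id, iv.chrom, iv.strand)
        if key not in out:
            out[key] = {
                "cov": np.zeros(lengths[iv.chrom], dtype=int),
                "start5": np.zeros(lengths[iv.chrom], dtype=int),
                "end3": np.zeros(lengths[iv.chrom], dtype=int),
            }
        for p in range(iv.start, iv.end):
            out[key]["cov"][p] += 1
        p5 = iv.start if iv.strand == "+" else iv.end - 1
        p3 = iv.end - 1 if iv.strand == "+" else iv.start
        if r.has5p:
            out[key]["start5"][p5] += 1
        if r.has3p:
            out[key]["end3"][p3] += 1
    return out


def brute_contigs(cov, floor=1):
    """Run-length scan for maximal covered runs."""
    runs = []
    start = None
    for i, v in enumerate(cov):
        if v >= floor and start is None:
            start = i
        elif v < floor and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(cov)))
    return runs


def brute_boundary_stats(cov, start5, end3, p5, p3, strand, window=100, flank=20, eps=0.05):
    """Literal recomputation of the caller's six statistics."""
    n = len(cov)

    def winsum(arr, pos):
        return sum(arr[i] for i in range(max(0, pos - window), min(n, pos + window + 1)) if i != pos)

    start_num = int(start5[p5])
    end_num = int(end3[p3])
    start_fc = start_num / max(1, winsum(start5, p5))
    end_fc = end_num / max(1, winsum(end3, p3))
    lo, hi = (p5, p3 + 1) if strand == "+" else (p3, p5 + 1)
    inside = sum(cov[lo:hi]) / (hi - lo)

    def fmean(a, b):
        a, b = max(0, a), min(n, b)
        if b <= a:
            return eps
        return max(eps, sum(cov[a:b]) / (b - a))

    if strand == "+":
        up = fmean(p5 - flank, p5)
        down = fmean(p3 + 1, p3 + 1 + flank)
    else:
        up = fmean(p5 + 1, p5 + 1 + flank)
        down = fmean(p3 - flank, p3)
    return start_num, end_num, start_fc, end_fc, inside / up, inside / down


_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_max_pairs(seq, min_loop=3, blocked=frozenset()):
    """Exhaustive maximum over all nested structures (feasible for n <= ~16)."""
    s = seq.upper().replace("T", "U")

    def rec(i, j):
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if i in blocked or k in blocked or (s[i], s[k]) not in _PAIRS:
                continue
            best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1)


def brute_locate_adapter(seq, adapter, max_error_rate, min_overlap, end="5p"):
    """Exhaustive edge-anchored semi-global alignment.

    Returns (errors, matched_len, read_end) of the best qualifying match or
    None, with the same tie-breaks as the implementation: fewest errors,
    longest matched adapter, end closest to the read edge.
    """
    if end == "3p":
        m = brute_locate_adapter(seq[::-1], adapter[::-1], max_error_rate, min_overlap, "5p")
        return m

    best = None
    m = len(adapter)
    for j0 in range(0, m - min_overlap + 1):
        sub = adapter[j0:]
        matched = m - j0
        max_err = int(max_error_rate * matched)
        window = seq[: matched + max_err]
        if not window:
            continue
        cand = None
        # ungapped alignment takes precedence when it fits the budget
        if len(window) >= matched:
            ham = sum(a != b for a, b in zip(sub, window))
            if ham <= max_err:
                cand = (ham / matched, -matched, ham, matched)
        if cand is None:
            # full edit-distance DP, global in sub, free end in window
            prev = list(range(len(window) + 1))
            for a in sub:
                cur = [prev[0] + 1]
                for j, b in enumerate(window, start=1):
                    cur.append(min(prev[j - 1] + (a != b), prev[j] + 1, cur[j - 1] + 1))
                prev = cur
            dist = min(prev)
            if dist <= max_err:
                ends = [j for j, d in enumerate(prev) if d == dist]
                read_end = min(ends, key=lambda j: (abs(j - len(sub)), j))
                cand = (dist / matched, -matched, dist, read_end)
        if cand is not None and (best is None or cand[:2] < best[:2]):
            best = cand
    if best is None:
        return None
    return best[2], -best[1], best[3]


def binom_tail(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p) by direct term summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * (p ** i) * ((1 - p) ** (n - i))
    return min(total, 1.0)
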