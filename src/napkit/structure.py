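"""Structure evidence: folding, shuffle z-scores and chemical reactivities.

The built-in folder is a base-pair–maximization dynamic program (Watson–
Crick plus G·U, hairpin loops >= ``min_loop``) with energy = -(pair count).
It is deliberately simple so it can be verified exactly against exhaustive
structure enumeration, and it honors hard unpaired constraints.  External
thermodynamic folders (e.g. a ViennaRNA binding) plug in anywhere a
``folder(seq) -> (dotbracket, energy)`` callable is accepted.

The z-score of a sequence standardizes its folding energy against the
energies of order-1 (mononucleotide) or order-2 (dinucleotide, Euler-walk)
shuffles: z = (E_native - mean(E_shuffled)) / sd.  Negative z means more
stably structured than chance given the sequence composition.

Reactivity profiling follows the mutational-profiling convention: per-
position mutation rates in a chemically treated and an untreated channel,
raw reactivity = treated - untreated (negatives clipped to 0), low-depth
positions masked, and normalization by the 2-8% rule (drop the top 2% of
values, divide by the mean of the next 8%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}
_ALPHABET = set("ACGU")

MAX_FOLD_LEN = 2000


def _rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"invalid bases for folding: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class FoldResult:
    dotbracket: str
    energy: float  # -(pair count) for the built-in folder

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")


def fold_pairmax(seq: str, min_loop: int = 3, constraint: Optional[str] = None) -> FoldResult:
    """Maximum base-pairing structure by dynamic programming.

    ``constraint`` is a string over {'x', '.'} of the sequence length;
    positions marked 'x' are forced unpaired.  Traceback is deterministic:
    at each subproblem, pairing the left base is preferred over leaving it
    unpaired, with the leftmost admissible partner.
    """
    s = _rna(seq)
    n = len(s)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    if constraint is not None and len(constraint) != n:
        raise ValueError("constraint length must equal sequence length")
    blocked = [constraint is not None and constraint[i] == "x" for i in range(n)]

    def pairable(i: int, j: int) -> bool:
        return (
            j - i > min_loop
            and not blocked[i]
            and not blocked[j]
            and (s[i], s[j]) in _PAIRABLE
        )

    # N[i][j] = max pairs in s[i..j]
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable(i, k):
                    left = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            N[i][j] = best

    dot = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if pairable(i, k):
                left = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if 1 + left + right == N[i][j]:
                    dot[i], dot[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    db = "".join(dot)
    return FoldResult(db, -float(db.count("(")))


# ---------------------------------------------------------------------------
# Shuffles and z-score
# ---------------------------------------------------------------------------

def shuffle_seq(seq: str, order: int = 2, rng_seed: int | np.random.Generator = 0) -> str:
    """Composition-preserving shuffle.

    order 1 permutes bases (exact mononucleotide conservation); order 2 is
    the Euler-walk dinucleotide shuffle (exact dinucleotide conservation).
    Deterministic under a fixed seed.
    """
    if len(seq) < 3:
        raise ValueError("sequence too short to shuffle (n < 3)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    s = list(seq)
    if order == 1:
        return "".join(rng.permutation(s))
    if order != 2:
        raise ValueError("order must be 1 or 2")

    # Altschul–Erickson dinucleotide shuffle: shuffle the outgoing-edge lists
    # of the dinucleotide multigraph, keeping a spanning set of last-edges
    # into the terminal vertex so an Eulerian walk still exists.
    first, last = seq[0], seq[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | {last})

    nonterminal = [v for v in vertices if v != last and edges.get(v)]
    for _ in range(10_000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in nonterminal}
        # the chosen last-edges must lead every vertex to the terminal vertex
        ok = True
        for v in nonterminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely under retry
        raise RuntimeError("failed to sample a valid Eulerian last-edge tree")

    pools: dict[str, list[str]] = {}
    for v in vertices:
        out = list(edges.get(v, []))
        if v in last_edge:
            out.remove(last_edge[v])
        idx = rng.permutation(len(out))
        pools[v] = [out[i] for i in idx]
        if v in last_edge:
            pools[v].append(last_edge[v])

    walk = [first]
    cur = first
    positions = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = pools[cur][positions[cur]]
        positions[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


@dataclass(frozen=True)
class StructureScore:
    mfe_native: float
    shuffle_mean: float
    shuffle_sd: float
    z: float
    n_shuffles: int
    shuffle_order: int
    degenerate: bool = False


def z_score(
    seq: str,
    n_shuffles: int = 100,
    order: int = 2,
    folder: Optional[Callable[[str], FoldResult]] = None,
    rng_seed: int = 0,
) -> StructureScore:
    """Folding-energy z-score against composition-preserving shuffles."""
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    fold = folder or fold_pairmax
    rng = np.random.default_rng(rng_seed)
    native = fold(seq).energy
    energies = np.array(
        [fold(shuffle_seq(seq, order, rng)).energy for _ in range(n_shuffles)]
    )
    mean = float(energies.mean())
    sd = float(energies.std(ddof=1))
    if sd == 0.0:
        return StructureScore(native, mean, 0.0, 0.0, n_shuffles, order, degenerate=True)
    return StructureScore(native, mean, sd, (native - mean) / sd, n_shuffles, order)


# ---------------------------------------------------------------------------
# Mutational-profiling reactivities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappedRead:
    """One aligned read over a target: covered span [start, end) and the
    positions where it carries a mutation."""

    start: int
    end: int
    mutations: tuple[int, ...] = ()


def mutation_rates(reads: Iterable[MappedRead], target_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position mutation rate and read depth from a read pileup."""
    depth = np.zeros(target_length, dtype=np.int64)
    mut = np.zeros(target_length, dtype=np.int64)
    for r in reads:
        if not (0 <= r.start < r.end <= target_length):
            raise ValueError(f"read span [{r.start},{r.end}) outside target")
        depth[r.start : r.end] += 1
        for m in set(r.mutations):  # a read is mutated at a position once
            if not r.start <= m < r.end:
                raise ValueError(f"mutation at {m} outside aligned span [{r.start},{r.end})")
            mut[m] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(depth > 0, mut / np.maximum(depth, 1), np.nan)
    return rate, depth


@dataclass
class ReactivityProfile:
    treated_rate: np.ndarray
    untreated_rate: np.ndarray
    raw: np.ndarray        # NaN where masked
    norm: np.ndarray       # NaN where masked
    masked: np.ndarray     # True where no-data
    min_depth: int


def reactivity_profile(
    treated_rate: np.ndarray,
    treated_depth: np.ndarray,
    untreated_rate: np.ndarray,
    untreated_depth: np.ndarray,
    min_depth: int = 100,
) -> ReactivityProfile:
    """Background-subtracted, 2-8%-normalized reactivities.

    Positions below ``min_depth`` in either channel are masked (no-data, not
    zero).  Normalization excludes the top 2% of unmasked raw values and
    divides everything by the mean of the next 8%.
    """
    arrs = [np.asarray(a, dtype=float) for a in (treated_rate, untreated_rate)]
    depths = [np.asarray(d) for d in (treated_depth, untreated_depth)]
    if len({a.shape for a in arrs} | {d.shape for d in depths}) != 1:
        raise ValueError("all inputs must have equal length")
    t, u = arrs
    masked = (depths[0] < min_depth) | (depths[1] < min_depth) | np.isnan(t) | np.isnan(u)
    if masked.all():
        raise ValueError("all positions masked: no usable depth")

    raw = np.clip(t - u, 0.0, None)
    raw[masked] = np.nan

    vals = np.sort(raw[~masked])[::-1]
    n = len(vals)
    n_top = int(n * 0.02)
    n_band = int(n * 0.08)
    band = vals[n_top : n_top + max(n_band, 1)]
    denom = float(band.mean())
    if denom == 0.0:
        raise ValueError("2-8% normalization band is zero: no reactivity signal")
    norm = raw / denom
    return ReactivityProfile(t, u, raw, norm, masked, min_depth)


def reactivity_constraints(profile: ReactivityProfile, ss_threshold: float = 0.7) -> str:
    """Hard-constraint string: 'x' = force unpaired (high reactivity),
    '.' = unconstrained (including masked positions)."""
    out = []
    for m, v in zip(profile.masked, profile.norm):
        out.append("x" if (not m and v >= ss_threshold) else ".")
    return "".join(out)


def write_shape(profile: ReactivityProfile, path) -> None:
    """SHAPE 2-column text: 1-based position, reactivity (-999 = no data)."""
    with open(path, "w") as fh:
        for i, (m, v) in enumerate(zip(profile.masked, profile.norm), start=1):
            fh.write(f"{i}\t{-999 if m else round(float(v), 6)}\n")


__all__ = [
    "FoldResult",
    "StructureScore",
    "MappedRead",
    "ReactivityProfile",
    "fold_pairmax",
    "shuffle_seq",
    "z_score",
    "mutation_rates",
    "reactivity_profile",
    "reactivity_constraints",
    "write_shape",
    "MAX_FOLD_LEN",
]
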