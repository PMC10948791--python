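"""Folding DP, shuffles, z-scores, and reactivity profiling."""

import numpy as np
import pytest
from scipy import stats as st

from napkit.simulate import simulate_probing
from napkit.structure import (
    MappedRead,
    fold_pairmax,
    mutation_rates,
    reactivity_constraints,
    reactivity_profile,
    shuffle_seq,
    z_score,
)
from oracles import enumerate_max_pairs

BASES = np.array(list("ACGU"))

HAIRPIN_20BP = "GGGGCCCCGGGGCCCCGGGG" + "AAAA" + "CCCCGGGGCCCCGGGGCCCC"


class TestFoldPairmax:
    def test_unpairable_sequence(self):
        r = fold_pairmax("AAAAAAA")
        assert r.dotbracket == "......." and r.energy == 0

    def test_simple_hairpin_pair_count(self):
        assert fold_pairmax("GGGGAAAACCCC").n_pairs == 4
        assert fold_pairmax("GGGGAAAACCCC").energy == -4

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            fold_pairmax("ACGX")

    def test_dotbracket_well_formed(self, rng):
        for _ in range(50):
            seq = "".join(BASES[rng.integers(0, 4, size=int(rng.integers(5, 60)))])
            r = fold_pairmax(seq)
            assert len(r.dotbracket) == len(seq)
            depth = 0
            for c in r.dotbracket:
                depth += {"(": 1, ")": -1}.get(c, 0)
                assert depth >= 0
            assert depth == 0

    def test_matches_exhaustive_enumeration(self, rng):
        """DP pair count equals brute-force enumeration for n <= 14."""
        for _ in range(200):
            n = int(rng.integers(4, 15))
            seq = "".join(BASES[rng.integers(0, 4, size=n)])
            assert fold_pairmax(seq).n_pairs == enumerate_max_pairs(seq)

    def test_constraints_honored_and_reduce_pairs(self):
        free = fold_pairmax(HAIRPIN_20BP)
        # force the stem-closing base at position 0 (and partner region) unpaired
        constraint = "x" + "." * (len(HAIRPIN_20BP) - 1)
        con = fold_pairmax(HAIRPIN_20BP, constraint=constraint)
        assert con.dotbracket[0] == "."
        assert con.n_pairs <= free.n_pairs

    def test_constrained_matches_constrained_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 14))
            seq = "".join(BASES[rng.integers(0, 4, size=n)])
            blocked = {int(i) for i in rng.choice(n, size=2, replace=False)}
            constraint = "".join("x" if i in blocked else "." for i in range(n))
            got = fold_pairmax(seq, constraint=constraint).n_pairs
            assert got == enumerate_max_pairs(seq, blocked=frozenset(blocked))


class TestShuffle:
    def test_order1_preserves_base_counts(self):
        out = shuffle_seq("ACGU", order=1, rng_seed=5)
        assert sorted(out) == ["A", "C", "G", "U"]

    def test_order2_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        for _ in range(300):
            n = int(rng.integers(10, 80))
            seq = "".join(BASES[rng.integers(0, 4, size=n)])
            out = shuffle_seq(seq, order=2, rng_seed=int(rng.integers(2**31)))
            assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))
            assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_seeded_determinism(self):
        seq = "ACGUACGUGGCCAAUU"
        assert shuffle_seq(seq, 2, 42) == shuffle_seq(seq, 2, 42)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            shuffle_seq("AC", 1, 0)


class TestZScore:
    def test_degenerate_flag(self):
        # every shuffle of a homopolymer folds identically
        sc = z_score("A" * 30, n_shuffles=10, order=1, rng_seed=0)
        assert sc.degenerate and sc.z == 0.0

    def test_designed_hairpin_scores_below_minus_one(self):
        sc = z_score(HAIRPIN_20BP, n_shuffles=100, order=1, rng_seed=0)
        assert sc.z < -1

    def test_invariant_under_affine_energy_rescaling(self):
        from napkit.structure import FoldResult, fold_pairmax as base

        def scaled(seq):
            r = base(seq)
            return FoldResult(r.dotbracket, 3.0 * r.energy - 7.0)

        a = z_score(HAIRPIN_20BP, 50, 1, rng_seed=3)
        b = z_score(HAIRPIN_20BP, 50, 1, folder=scaled, rng_seed=3)
        assert a.z == pytest.approx(b.z, rel=1e-9)


class TestMutationRates:
    def test_basic_pileup(self):
        reads = [MappedRead(0, 10, (5,) if i < 2 else ()) for i in range(10)]
        rate, depth = mutation_rates(reads, 20)
        assert depth[5] == 10 and rate[5] == pytest.approx(0.2)
        assert np.isnan(rate[15])  # uncovered -> masked

    def test_mutation_outside_span_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            mutation_rates([MappedRead(0, 10, (12,))], 20)

    def test_matches_recount_oracle(self, rng):
        n = 100
        reads = []
        for _ in range(500):
            a = int(rng.integers(0, n - 10))
            b = a + int(rng.integers(5, n - a))
            muts = tuple(int(m) for m in rng.integers(a, b, size=rng.integers(0, 4)))
            reads.append(MappedRead(a, b, muts))
        rate, depth = mutation_rates(reads, n)
        for pos in rng.integers(0, n, size=30):
            cov = sum(r.start <= pos < r.end for r in reads)
            mut = sum(pos in r.mutations for r in reads)
            assert depth[pos] == cov
            if cov:
                assert rate[pos] == pytest.approx(mut / cov)


class TestReactivity:
    def test_background_subtraction_and_clipping(self):
        n = 200
        t = np.full(n, 0.05)
        u = np.full(n, 0.01)
        u[0] = 0.5  # negative raw -> clipped to 0
        d = np.full(n, 1000)
        prof = reactivity_profile(t, d, u, d)
        assert prof.raw[1] == pytest.approx(0.04)
        assert prof.raw[0] == 0.0

    def test_low_depth_masked_not_zero(self):
        t = np.array([0.05] * 10)
        u = np.array([0.01] * 10)
        d = np.array([1000] * 9 + [10])
        prof = reactivity_profile(t, d, u, d.copy())
        assert prof.masked[9] and np.isnan(prof.norm[9])

    def test_normalization_band_mean_is_one(self, rng):
        n = 500
        t = rng.uniform(0.0, 0.2, size=n)
        u = rng.uniform(0.0, 0.01, size=n)
        d = np.full(n, 5000)
        prof = reactivity_profile(t, d, u, d.copy())
        vals = np.sort(prof.raw[~prof.masked])[::-1]
        n_top, n_band = int(len(vals) * 0.02), int(len(vals) * 0.08)
        band = vals[n_top : n_top + n_band] / 1.0
        denom = band.mean()
        normed_band = np.sort(prof.norm[~prof.masked])[::-1][n_top : n_top + n_band]
        assert normed_band.mean() == pytest.approx(1.0, abs=1e-9)
        assert denom > 0

    def test_flat_profile_is_a_reported_error(self):
        n = 100
        t = np.full(n, 0.01)
        d = np.full(n, 1000)
        with pytest.raises(ValueError, match="zero"):
            reactivity_profile(t, d, t.copy(), d.copy())

    def test_single_stranded_positions_score_higher(self):
        """Simulated probing separates loops from stems (rank-sum p < 0.01)."""
        dot = fold_pairmax(HAIRPIN_20BP).dotbracket
        paired = np.array([c != "." for c in dot])
        t, td, u, ud = simulate_probing(paired, rng_seed=42)
        prof = reactivity_profile(t, td, u, ud)
        ss = prof.norm[~paired & ~prof.masked]
        ds = prof.norm[paired & ~prof.masked]
        assert ss.mean() > ds.mean()
        assert st.mannwhitneyu(ss, ds, alternative="greater").pvalue < 0.01


class TestConstraints:
    def test_high_reactivity_forced_unpaired(self):
        n = 150
        t = np.full(n, 0.02)
        t[40] = 0.5
        u = np.full(n, 0.001)
        d = np.full(n, 1000)
        prof = reactivity_profile(t, d, u, d.copy())
        cstr = reactivity_constraints(prof)
        assert cstr[40] == "x"

    def test_masked_positions_unconstrained(self):
        t = np.array([0.5, 0.5, 0.02, 0.3, 0.02] * 30)
        d = np.full(150, 1000)
        d[0] = 5
        prof = reactivity_profile(t, d, np.full(150, 0.001), np.full(150, 1000))
        assert reactivity_constraints(prof)[0] == "."

    def test_constrained_fold_loses_pairs(self):
        free = fold_pairmax(HAIRPIN_20BP)
        cstr = "x" * 20 + "." * (len(HAIRPIN_20BP) - 20)  # block the whole 5' arm
        con = fold_pairmax(HAIRPIN_20BP, constraint=cstr)
        assert con.n_pairs < free.n_pairs
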