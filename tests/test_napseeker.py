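"""The napRNA caller: contigs, boundary statistics, thresholds, merging."""

import numpy as np
import pytest

from napkit.genomic import GenomicInterval
from napkit.napseeker import (
    Contig,
    NapCandidate,
    SeekerParams,
    assemble_contigs,
    boundary_stats,
    call_sample,
    filter_candidates,
    merge_across_samples,
)
from napkit.tracks import SignalTrack
from oracles import brute_boundary_stats, brute_contigs

LEN = {"chr1": 3000}


def make_track(cov=None, start5=None, end3=None, strand="+", sample="s1"):
    tr = SignalTrack(LEN, sample)
    if cov is not None:
        tr.cov("chr1", strand)[: len(cov)] = cov
    if start5 is not None:
        for pos, v in start5.items():
            tr.start5("chr1", strand)[pos] = v
    if end3 is not None:
        for pos, v in end3.items():
            tr.end3("chr1", strand)[pos] = v
    tr.library_size = 1000
    return tr


class TestAssembleContigs:
    def test_empty_track(self):
        assert assemble_contigs(make_track()) == []

    def test_two_blocks(self):
        cov = np.zeros(3000, dtype=int)
        cov[100:300] = 2
        cov[400:500] = 1
        contigs = assemble_contigs(make_track(cov=cov))
        spans = [(c.interval.start, c.interval.end) for c in contigs]
        assert spans == [(100, 300), (400, 500)]
        assert contigs[0].mean_cov == 2.0

    def test_matches_run_length_oracle(self, rng):
        for _ in range(50):
            cov = rng.integers(0, 3, size=3000)
            floor = int(rng.integers(1, 3))
            got = assemble_contigs(make_track(cov=cov), cov_floor=floor)
            assert [(c.interval.start, c.interval.end) for c in got] == brute_contigs(cov, floor)


class TestBoundaryStats:
    def test_isolated_peak_floor_denominator(self):
        """A lone 5' peak with an empty +/-100 window divides by the floor 1."""
        cov = np.zeros(3000, dtype=int)
        cov[1000:1150] = 5
        tr = make_track(cov=cov, start5={1000: 10}, end3={1149: 9})
        (cand,) = boundary_stats(Contig(GenomicInterval("chr1", 1000, 1150, "+"), 5.0), tr)
        assert cand.startReadNum == 10 and cand.startFC == 10.0

    def test_window_sum_excludes_candidate_position(self):
        cov = np.zeros(3000, dtype=int)
        cov[950:1150] = 5
        tr = make_track(cov=cov, start5={1000: 10, 960: 2, 1050: 3}, end3={1149: 8})
        (cand,) = boundary_stats(Contig(GenomicInterval("chr1", 950, 1150, "+"), 5.0), tr)
        assert cand.startFC == pytest.approx(10 / 5)

    def test_flank_fold_changes(self):
        """Coverage 12 inside, flank means 2 (up) and 3 (down)."""
        cov = np.zeros(3000, dtype=int)
        cov[980:1000] = 2
        cov[1000:1150] = 12
        cov[1150:1170] = 3
        tr = make_track(cov=cov, start5={1000: 10}, end3={1149: 10})
        (cand,) = boundary_stats(Contig(GenomicInterval("chr1", 980, 1170, "+"), 1.0), tr)
        assert cand.up20ntFC == pytest.approx(12 / 2)
        assert cand.down20ntFC == pytest.approx(12 / 3)

    def test_degenerate_contig_emits_nothing(self):
        cov = np.zeros(3000, dtype=int)
        cov[1000:1100] = 3
        # 3' peak upstream of the 5' peak
        tr = make_track(cov=cov, start5={1090: 10}, end3={1010: 10})
        assert boundary_stats(Contig(GenomicInterval("chr1", 1000, 1100, "+"), 3.0), tr) == []

    def test_matches_brute_force_recomputation(self, rng):
        """Statistics equal a literal reimplementation on random windows."""
        for _ in range(100):
            strand = "+" if rng.random() < 0.5 else "-"
            cov = np.zeros(3000, dtype=int)
            a = int(rng.integers(100, 1500))
            b = a + int(rng.integers(100, 800))
            cov[a:b] = rng.integers(1, 20)
            tr = make_track(cov=cov, strand=strand)
            s5 = tr.start5("chr1", strand)
            e3 = tr.end3("chr1", strand)
            for _ in range(8):  # scatter boundary reads inside the contig
                s5[int(rng.integers(a, b))] += int(rng.integers(1, 15))
                e3[int(rng.integers(a, b))] += int(rng.integers(1, 15))
            contig = Contig(GenomicInterval("chr1", a, b, strand), float(cov[a:b].mean()))
            for cand in boundary_stats(contig, tr):
                iv = cand.interval
                p5, p3 = iv.five_prime, iv.three_prime
                want = brute_boundary_stats(cov, s5, e3, p5, p3, strand)
                got = (
                    cand.startReadNum, cand.endReadNum, cand.startFC,
                    cand.endFC, cand.up20ntFC, cand.down20ntFC,
                )
                assert got == pytest.approx(want, rel=1e-12)


def _cand(**kw):
    base = dict(
        interval=GenomicInterval("chr1", 1000, 1100, "+"),
        startReadNum=7, endReadNum=7, startFC=2.0, endFC=2.0,
        up20ntFC=2.0, down20ntFC=2.0,
    )
    base.update(kw)
    return NapCandidate(**base)


class TestFilterCandidates:
    def test_boundary_inclusive_pass(self):
        assert filter_candidates([_cand()]) != []

    @pytest.mark.parametrize(
        "kw",
        [
            {"startReadNum": 6},
            {"endReadNum": 6},
            {"startFC": 1.99},
            {"endFC": 1.99},
            {"up20ntFC": 1.99},
            {"down20ntFC": 1.99},
            {"interval": GenomicInterval("chr1", 1000, 1099, "+")},  # length 99
        ],
    )
    def test_single_criterion_failures(self, kw):
        assert filter_candidates([_cand(**kw)]) == []


class TestMergeAcrossSamples:
    def test_two_samples_summary_passes(self):
        a = _cand(startReadNum=7, endReadNum=5)   # support 12
        b = _cand(startReadNum=5, endReadNum=4)   # support 9 -> total 21
        merged = merge_across_samples({"s1": [a], "s2": [b]})
        assert len(merged) == 1
        assert merged[0].summary_count == 21
        assert merged[0].counts_per_sample == {"s1": 12, "s2": 9}

    def test_single_sample_dropped_regardless_of_count(self):
        assert merge_across_samples({"s1": [_cand(startReadNum=60, endReadNum=40)]}) == []

    def test_low_summary_dropped(self):
        a = _cand(startReadNum=5, endReadNum=4)  # 9 + 9 = 18 < 20
        b = _cand(startReadNum=5, endReadNum=4)
        assert merge_across_samples({"s1": [a], "s2": [b]}) == []

    def test_end_tolerance_merging(self):
        a = _cand()
        b = _cand(interval=GenomicInterval("chr1", 1003, 1104, "+"))
        merged = merge_across_samples({"s1": [a], "s2": [b]}, SeekerParams(end_tolerance=5))
        assert len(merged) == 1
        strict = merge_across_samples({"s1": [a], "s2": [b]}, SeekerParams(end_tolerance=0))
        assert strict == []


class TestSelfConsistency:
    def test_emitted_calls_reverify_under_brute_force(self, rng):
        """Fuzz: every call's statistics recomputed literally still pass."""
        p = SeekerParams()
        for _ in range(100):
            strand = "+" if rng.random() < 0.5 else "-"
            tr = make_track(strand=strand)
            cov = tr.cov("chr1", strand)
            for _ in range(int(rng.integers(1, 4))):
                a = int(rng.integers(0, 2500))
                cov[a : a + int(rng.integers(50, 400))] += int(rng.integers(1, 15))
            s5, e3 = tr.start5("chr1", strand), tr.end3("chr1", strand)
            for _ in range(int(rng.integers(0, 12))):
                s5[int(rng.integers(0, 3000))] += int(rng.integers(1, 20))
                e3[int(rng.integers(0, 3000))] += int(rng.integers(1, 20))
            for cand in call_sample(tr, p):
                iv = cand.interval
                sn, en, sfc, efc, ufc, dfc = brute_boundary_stats(
                    cov, s5, e3, iv.five_prime, iv.three_prime, strand
                )
                assert sn >= 7 and en >= 7
                assert sfc >= 2 and efc >= 2
                assert ufc >= 2 and dfc >= 2
                assert len(iv) >= 100
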