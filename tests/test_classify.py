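"""ncRNA classification: interval rules, motif scans, truth-table fidelity."""

import pytest

from napkit.classify import (
    ClassifyParams,
    classify_all,
    classify_misRNA,
    classify_sliRNA,
    classify_snotron,
    cluster_premirnas,
    detect_cd_box,
    detect_haca_box,
    detect_pol3,
    exclude_annotated,
)
from napkit.fixtures import classifier_fixture
from napkit.genomic import AnnotationSet, FeatureIndex, GenomicInterval
from oracles import brute_overlap


def iv(start, end, strand="+", name="x"):
    return GenomicInterval("chr1", start, end, strand, name=name)


class TestExcludeAnnotated:
    def test_overlap_removal_and_strand(self):
        ann = AnnotationSet(exclusion=FeatureIndex([iv(100, 400, "+", "rRNA")]))
        naps = [iv(200, 350, "+", "in"), iv(500, 700, "+", "out"), iv(200, 350, "-", "anti")]
        kept = exclude_annotated(naps, ann)
        assert [n.name for n in kept] == ["in", "out", "anti"][1:]

    def test_matches_brute_force_filter(self, rng):
        feats = [
            iv(int(s), int(s) + int(rng.integers(50, 400)),
               "+" if rng.random() < 0.5 else "-", f"e{i}")
            for i, s in enumerate(rng.integers(0, 50_000, size=200))
        ]
        ann = AnnotationSet(exclusion=FeatureIndex(feats))
        naps = [
            iv(int(s), int(s) + 150, "+" if rng.random() < 0.5 else "-", f"n{i}")
            for i, s in enumerate(rng.integers(0, 50_000, size=300))
        ]
        kept = exclude_annotated(naps, ann)
        want = [n for n in naps if not brute_overlap(n, feats, True)]
        assert kept == want


class TestSliRNA:
    introns = FeatureIndex([iv(1000, 1500, "+", "intronA")])

    def test_exact_end_sharing(self):
        assert classify_sliRNA(iv(1000, 1500), self.introns) == {"intron": "intronA"}

    def test_one_end_only_is_not_enough(self):
        assert classify_sliRNA(iv(1000, 1450), self.introns) is None

    def test_tolerance_monotonicity(self, rng):
        """A label found at tolerance t is never lost at tolerance t+k."""
        for _ in range(200):
            start = int(rng.integers(990, 1010))
            end = int(rng.integers(1490, 1510))
            nap = iv(start, end)
            hits = [
                classify_sliRNA(nap, self.introns, tol) is not None for tol in (0, 3, 10, 25)
            ]
            assert hits == sorted(hits)


class TestSnotron:
    snos = FeatureIndex([iv(5050, 5130, "+", "S")])
    introns = FeatureIndex([iv(5000, 5600, "+", "I")])

    def test_within_window(self):
        got = classify_snotron(iv(5050, 5596), self.snos, self.introns)
        assert got == {"snoRNA": "S", "intron": "I", "config": "sno5p_to_3pSS"}

    def test_exactly_outside_window(self):
        assert classify_snotron(iv(5050, 5589), self.snos, self.introns) is None

    def test_snorna_must_be_inside_intron(self):
        snos = FeatureIndex([iv(4950, 5030, "+", "S")])  # straddles intron start
        assert classify_snotron(iv(4950, 5596), snos, self.introns) is None


class TestMirnaClusters:
    def test_small_gap_clusters(self):
        pres = [iv(0, 80, "+", "a"), iv(300, 380, "+", "b")]
        (cl,) = cluster_premirnas(pres)
        assert len(cl.members) == 2

    def test_exact_10kb_gap_splits(self):
        pres = [iv(0, 80, "+", "a"), iv(10_080, 10_160, "+", "b")]
        assert len(cluster_premirnas(pres)) == 2
        pres_close = [iv(0, 80, "+", "a"), iv(10_079, 10_159, "+", "b")]
        assert len(cluster_premirnas(pres_close)) == 1

    def test_matches_union_find_oracle(self, rng):
        pres = [
            iv(int(s), int(s) + 80, "+", f"p{i}")
            for i, s in enumerate(sorted(rng.integers(0, 200_000, size=40)))
        ]
        clusters = cluster_premirnas(pres)
        # union-find over pairwise gap test
        parent = list(range(len(pres)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for a in range(len(pres)):
            for b in range(a + 1, len(pres)):
                gap = max(pres[b].start - pres[a].end, pres[a].start - pres[b].end)
                if gap < 10_000:
                    parent[find(b)] = find(a)
        want = len({find(i) for i in range(len(pres))})
        assert len(clusters) == want


class TestMisRNA:
    def setup_method(self):
        self.pres = [iv(0, 80, "+", "p1"), iv(280, 360, "+", "p2")]
        self.matures = FeatureIndex([iv(58, 80, "+", "m1"), iv(280, 302, "+", "m2")])
        self.clusters = cluster_premirnas(self.pres)

    def test_spacer_with_flush_ends(self):
        got = classify_misRNA(iv(58, 302), self.clusters, self.matures)
        assert got is not None and got["mature_end_coincidence"]

    def test_contained_in_single_pre_is_filtered(self):
        assert classify_misRNA(iv(10, 70), self.clusters, self.matures) is None

    def test_free_ends_soft_vs_enforced(self):
        nap = iv(100, 280)
        soft = classify_misRNA(nap, self.clusters, self.matures)
        assert soft is not None and not soft["mature_end_coincidence"]
        assert classify_misRNA(nap, self.clusters, self.matures, enforce_mature_ends=True) is None


POL3_POS = (
    "GGACT" + "TAGCGCAACTAG" + "C" * 40 + "GTTCGAATC" + "G" * 40 + "ACGACTTTT"
)


class TestMotifDetectors:
    def test_pol3_positive_and_4u_required(self):
        assert detect_pol3(POL3_POS) is not None
        assert detect_pol3(POL3_POS[:-4] + "TTAT") is None

    def test_pol3_box_order_required(self):
        # B box upstream of the A box: should not fire
        seq = "GGACT" + "GTTCGAATC" + "C" * 60 + "TAGCGCAACTAG" + "TTTT"
        got = detect_pol3(seq)
        assert got is None or got[0].offset < got[1].offset

    def test_cd_box_positive_and_dbox_mutation(self):
        seq = "GGCAC" + "ATGATGA" + "C" * 80 + "CTGA" + "GTGCC"
        hits = detect_cd_box(seq)
        assert hits is not None
        kinds = {h.motif_kind for h in hits}
        assert kinds == {"Cbox", "Dbox"}
        # the canonical loss-of-function change CTGA -> CTAG kills the label
        mutated = seq.replace("CTGA" + "GTGCC", "CTAG" + "GTGCC")
        assert detect_cd_box(mutated) is None

    def test_cd_box_needs_terminal_stem(self):
        seq = "AAAAA" + "ATGATGA" + "C" * 80 + "CTGA" + "AAAAA"  # arms cannot pair
        assert detect_cd_box(seq) is None

    def test_polyA_90mer_negative(self):
        assert detect_cd_box("A" * 90) is None
        assert detect_pol3("A" * 200) is None

    def test_haca_positive_negative_and_pocket(self):
        from napkit.simulate import _design_haca
        import numpy as np

        seq = _design_haca(np.random.default_rng(0), 140)
        hits = detect_haca_box(seq)
        assert hits is not None
        kinds = {h.motif_kind for h in hits}
        assert {"Hbox", "ACAbox"} <= kinds
        assert "polyA_pocket" in kinds  # the designed 8-A loop
        # breaking the terminal ACA box kills the label
        assert detect_haca_box(seq[:-5] + "CCCCC") is None


class TestTruthTable:
    def test_fixture_labels_match_hand_derivation(self):
        ann, cands, expected = classifier_fixture()
        rows = classify_all(cands, ann)
        got = {r.interval.name: r.labels for r in rows}
        for name, exp in expected.items():
            if exp == "EXCLUDED":
                assert name not in got
            else:
                assert got[name] == exp, name

    def test_order_invariance(self):
        ann, cands, _ = classifier_fixture()
        a = classify_all(cands, ann)
        b = classify_all(list(reversed(cands)), ann)
        assert [(r.interval.name, r.labels) for r in a] == [
            (r.interval.name, r.labels) for r in b
        ]

    def test_evidence_nonempty_for_every_label(self):
        ann, cands, _ = classifier_fixture()
        for r in classify_all(cands, ann):
            for label in r.labels:
                assert r.evidence.get(label)
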