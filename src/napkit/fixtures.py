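"""A hand-built classifier validation world with known expected labels.

The geometry exercises every interval rule and its boundary cases: exact
end sharing (sliRNA), both snotron configurations on both strands including
distances of exactly 10 and 11 nt from the splice site, snoRNA-not-in-
intron decoys, miRNA clusters with gaps of 200 nt, 9,999 nt (clustered) and
exactly 10,000 nt (NOT clustered, strict <), containment-in-pre-miRNA
filtering, strand mismatches, and the exclusion filter.

``EXPECTED_LABELS`` was derived by hand from the rules; the special value
``"EXCLUDED"`` marks a candidate removed by the novelty filter.
"""

from __future__ import annotations

from .genomic import AnnotationSet, FeatureIndex, GenomicInterval


def _iv(start: int, end: int, strand: str, name: str) -> GenomicInterval:
    return GenomicInterval("chr1", start, end, strand, name=name)


def classifier_fixture() -> tuple[AnnotationSet, list[GenomicInterval], dict[str, object]]:
    """Return (annotations, 30 candidate napRNAs, expected labels by name)."""
    introns = [
        _iv(1000, 1500, "+", "I1"),
        _iv(3000, 3400, "-", "I2"),
        _iv(5000, 5600, "+", "I3"),    # hosts S1
        _iv(8000, 8700, "-", "I4"),    # hosts S2
        _iv(12000, 12500, "+", "I5"),  # hosts S3
        _iv(15000, 15400, "+", "I6"),
        _iv(18000, 18600, "-", "I7"),
        _iv(21000, 21300, "+", "I8"),
        _iv(24000, 24800, "+", "I9"),  # hosts S4
        _iv(28000, 28500, "-", "I10"),
        _iv(31000, 31200, "+", "I11"),
        _iv(34000, 34500, "+", "I12"), # S5 straddles its start
    ]
    snornas = [
        _iv(5050, 5130, "+", "S1"),
        _iv(8570, 8650, "-", "S2"),
        _iv(12100, 12180, "+", "S3"),
        _iv(24100, 24180, "+", "S4"),
        _iv(33950, 34030, "+", "S5"),   # not contained in I12
        _iv(40000, 40080, "+", "S6"),   # not inside any intron
    ]
    pre_mirnas = [
        _iv(50000, 50080, "+", "P1"),   # cluster A: gap 200
        _iv(50280, 50360, "+", "P2"),
        _iv(60000, 60080, "+", "P3"),   # cluster B: gap 9999 (< 10 kb)
        _iv(70079, 70159, "+", "P4"),
        _iv(90000, 90080, "+", "P5"),   # gap to P6 exactly 10000 -> NOT clustered
        _iv(100080, 100160, "+", "P6"),
    ]
    mature_mirnas = [
        _iv(50058, 50080, "+", "M1"),
        _iv(50280, 50302, "+", "M2"),
        _iv(60058, 60080, "+", "M3"),
        _iv(70079, 70101, "+", "M4"),
        _iv(90058, 90080, "+", "M5"),
        _iv(100080, 100102, "+", "M6"),
    ]
    exclusion = [_iv(110000, 110500, "+", "rRNA1")]

    annotations = AnnotationSet(
        introns=FeatureIndex(introns),
        snornas=FeatureIndex(snornas),
        pre_mirnas=FeatureIndex(pre_mirnas),
        mature_mirnas=FeatureIndex(mature_mirnas),
        exclusion=FeatureIndex(exclusion),
        snorna_subtype={s.name: "CD" for s in snornas},
        mirna_parent={m.name: p for m, p in zip(mature_mirnas, "P1 P2 P3 P4 P5 P6".split())},
    )

    candidates = [
        _iv(1000, 1500, "+", "C01"),    # = I1 exactly
        _iv(3000, 3400, "-", "C02"),    # = I2 exactly, minus strand
        _iv(1000, 1450, "+", "C03"),    # 3' end off by 50
        _iv(1005, 1500, "+", "C04"),    # 5' end off by 5
        _iv(21000, 21300, "+", "C05"),  # = I8
        _iv(21000, 21300, "-", "C06"),  # wrong strand
        _iv(5050, 5596, "+", "C07"),    # S1 5' -> 4 nt short of I3 3'SS
        _iv(5050, 5600, "+", "C08"),    # S1 5' -> exactly at I3 3'SS
        _iv(5050, 5590, "+", "C09"),    # 10 nt from 3'SS: boundary PASS
        _iv(5050, 5589, "+", "C10"),    # 11 nt from 3'SS: boundary FAIL
        _iv(8004, 8650, "-", "C11"),    # minus-strand snotron, 4 nt from 3'SS
        _iv(12004, 12180, "+", "C12"),  # mirror config: S3 3' + 4 nt from 5'SS
        _iv(24100, 24810, "+", "C13"),  # 10 nt DOWNSTREAM of 3'SS: boundary PASS
        _iv(33950, 34510, "+", "C14"),  # S5 not contained in I12
        _iv(40000, 40200, "+", "C15"),  # S6 has no host intron
        _iv(50058, 50302, "+", "C16"),  # cluster A spacer, mature-flush ends
        _iv(50100, 50280, "+", "C17"),  # cluster A spacer, free ends
        _iv(50010, 50070, "+", "C18"),  # entirely inside P1
        _iv(50058, 50302, "-", "C19"),  # wrong strand
        _iv(60058, 70101, "+", "C20"),  # cluster B (9,999-nt gap) spacer
        _iv(90058, 100101, "+", "C21"), # P5-P6 gap exactly 10 kb: no cluster
        _iv(60000, 60200, "+", "C22"),  # overlaps cluster B, not contained
        _iv(110100, 110300, "+", "C23"),# inside rRNA -> excluded
        _iv(110100, 110300, "-", "C24"),# opposite strand of the rRNA
        _iv(100, 300, "+", "C25"),      # intergenic
        _iv(12004, 12180, "-", "C26"),  # strand mismatch vs I5/S3
        _iv(5000, 5600, "+", "C27"),    # = I3 exactly
        _iv(50280, 50360, "+", "C28"),  # = P2: contained in a pre-miRNA
        _iv(8000, 8700, "-", "C29"),    # = I4 exactly
        _iv(24000, 24800, "+", "C30"),  # = I9 exactly
    ]

    expected: dict[str, object] = {
        "C01": {"sliRNA"},
        "C02": {"sliRNA"},
        "C03": set(),
        "C04": set(),
        "C05": {"sliRNA"},
        "C06": set(),
        "C07": {"snotron"},
        "C08": {"snotron"},
        "C09": {"snotron"},
        "C10": set(),
        "C11": {"snotron"},
        "C12": {"snotron"},
        "C13": {"snotron"},
        "C14": set(),
        "C15": set(),
        "C16": {"misRNA"},
        "C17": {"misRNA"},
        "C18": set(),
        "C19": set(),
        "C20": {"misRNA"},
        "C21": set(),
        "C22": {"misRNA"},
        "C23": "EXCLUDED",
        "C24": set(),
        "C25": set(),
        "C26": set(),
        "C27": {"sliRNA"},
        "C28": set(),
        "C29": {"sliRNA"},
        "C30": {"sliRNA"},
    }
    return annotations, candidates, expected


__all__ = ["classifier_fixture"]
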