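"""Interval overlap, enhancer/tissue annotation rules, gene assignment."""

import numpy as np
import pandas as pd
import pytest

from updmr.annotate import (
    CATEGORY_BODY,
    CATEGORY_INTERGENIC,
    CATEGORY_PROMOTER,
    annotate_enhancer,
    annotate_tissue_overlap,
    map_gene,
    overlap_bp,
)
from updmr.io import GeneModel
from updmr.synth import generate_annotation_fixtures


class TestOverlapBp:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (150, 300), 50),
            ((100, 200), (200, 300), 0),  # half-open abutting
            ((100, 200), (100, 200), 100),
            ((100, 200), (500, 600), 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bp(a, b) == expected
        assert overlap_bp(b, a) == expected

    def test_chromosome_mismatch(self):
        assert overlap_bp(("chr1", 100, 200), ("chr2", 100, 200)) == 0
        assert overlap_bp(("chr1", 100, 200), ("chr1", 150, 250)) == 50

    def test_self_overlap_is_length(self, rng):
        for _ in range(20):
            s = int(rng.integers(0, 1000))
            e = s + int(rng.integers(1, 500))
            assert overlap_bp((s, e), (s, e)) == e - s


def seg(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


class TestEnhancerAnnotation:
    def test_summed_overlap_rule(self):
        # 30 bp of state 9 plus 25 bp of state 10 reaches the 50 bp total
        segments = seg(
            ("chrS", 1000, 1030, 9), ("chrS", 1030, 1055, 10), ("chrS", 1055, 2000, 1)
        )
        out = annotate_enhancer([("chrS", 1000, 1055)], segments)
        assert out.iloc[0]["enh_overlap_bp"] == 55
        assert bool(out.iloc[0]["is_enhancer_dmr"])

    def test_non_enhancer_state_contributes_nothing(self):
        segments = seg(("chrS", 0, 10_000, 1))
        out = annotate_enhancer([("chrS", 2000, 2500)], segments)
        assert out.iloc[0]["enh_overlap_bp"] == 0 and not bool(out.iloc[0]["is_enhancer_dmr"])

    def test_containment_gives_full_length(self):
        segments = seg(("chrS", 0, 10_000, 8))
        out = annotate_enhancer([("chrS", 2000, 2500)], segments)
        assert out.iloc[0]["enh_overlap_bp"] == 500

    def test_unknown_state_warns_and_is_ignored(self):
        segments = seg(("chrS", 0, 1000, 25), ("chrS", 1000, 2000, 9))
        with pytest.warns(UserWarning, match="unknown chromatin states"):
            out = annotate_enhancer([("chrS", 500, 1500)], segments)
        assert out.iloc[0]["enh_overlap_bp"] == 500

    def test_total_matches_per_bp_count(self, rng):
        """Brute-force per-basepair membership count on small instances."""
        for _ in range(10):
            bounds = np.sort(rng.choice(np.arange(0, 10_000), size=12, replace=False))
            rows = [
                ("chrS", int(bounds[i]), int(bounds[i + 1]), int(rng.integers(1, 19)))
                for i in range(len(bounds) - 1)
            ]
            segments = seg(*rows)
            s = int(rng.integers(0, 9000))
            e = s + int(rng.integers(100, 1000))
            out = annotate_enhancer([("chrS", s, e)], segments)
            member = np.zeros(10_000, dtype=bool)
            for _, r in segments.iterrows():
                if r["state"] in (3, 8, 9, 10):
                    member[r["start"]:r["end"]] = True
            assert out.iloc[0]["enh_overlap_bp"] == int(member[s:min(e, 10_000)].sum())


class TestTissueOverlap:
    sets = {
        "monocyte": [("chrS", 1000, 1400)],
        "skm": [("chrS", 1351, 1400), ("chrS", 1430, 1460)],  # 49 bp then 30 bp
    }

    def test_large_single_overlap_flags(self):
        out = annotate_tissue_overlap([("chrS", 1280, 1600)], self.sets)
        assert bool(out.iloc[0]["monocyte"]) and out.iloc[0]["monocyte_bp"] == 120

    def test_forty_nine_bp_does_not_flag(self):
        out = annotate_tissue_overlap([("chrS", 1351, 1600)], self.sets)
        assert out.iloc[0]["skm_bp"] == 49 and not bool(out.iloc[0]["skm"])

    def test_two_small_overlaps_do_not_sum(self):
        # 30 + 30 bp across two skm intervals: per-interval rule says no flag
        sets = {"skm": [("chrS", 1000, 1030), ("chrS", 1100, 1130)]}
        out = annotate_tissue_overlap([("chrS", 1000, 1130)], sets)
        assert not bool(out.iloc[0]["skm"]) and out.iloc[0]["skm_bp"] == 30

    def test_summary_column(self):
        out = annotate_tissue_overlap([("chrS", 1280, 1600)], self.sets)
        assert out.iloc[0]["tissue_overlaps"] == "monocyte"
        out2 = annotate_tissue_overlap([("chrS", 9000, 9100)], self.sets)
        assert out2.iloc[0]["tissue_overlaps"] == "."


@pytest.fixture(scope="module")
def genes():
    _, g = generate_annotation_fixtures(seed=0)
    return g


class TestMapGene:
    """Hand-computed assignments on the engineered gene table.

    ALPHA  + coding     20k-40k  -> promoter [15k,25k), body [25k,40k)
    NCRNA1 + non-coding 26k-39k  -> promoter [21k,31k), body [31k,39k)
    BETA   - coding     50k-70k  -> promoter [65k,75k), body [50k,65k)
    GAMMA  + coding     90k-92k  -> promoter [85k,95k), empty body
    DELTA  + coding    100k-130k -> promoter [95k,105k), body [105k,130k)
    EPSILON+ coding    120k-140k -> promoter [115k,125k), body [125k,140k)
    TIE1/2 + coding    160k-165k -> promoter [155k,165k), empty body
    """

    @pytest.mark.parametrize(
        "interval,expected",
        [
            # coding beats non-coding at equal promoter overlap
            (("chrS", 24_000, 24_500), ("ALPHA", CATEGORY_PROMOTER, 500)),
            # body category, coding priority over NCRNA1
            (("chrS", 32_000, 33_000), ("ALPHA", CATEGORY_BODY, 1000)),
            # minus-strand promoter sits at tx_end
            (("chrS", 68_000, 69_000), ("BETA", CATEGORY_PROMOTER, 1000)),
            # short gene: promoter window still applies over the whole span
            (("chrS", 89_000, 91_000), ("GAMMA", CATEGORY_PROMOTER, 2000)),
            # promoter precedence over an equally large body overlap
            (("chrS", 118_000, 122_000), ("EPSILON", CATEGORY_PROMOTER, 4000)),
            # deterministic lexicographic tie-break
            (("chrS", 158_000, 160_000), ("TIE1", CATEGORY_PROMOTER, 2000)),
            # intergenic with a nearby TSS
            (("chrS", 190_000, 190_500), ("TIE1", CATEGORY_INTERGENIC, 0)),
            # farther than the nearest-TSS cap
            (("chrS", 2_500_000, 2_500_400), (".", CATEGORY_INTERGENIC, 0)),
        ],
    )
    def test_assignments(self, genes, interval, expected):
        assert map_gene(interval, genes) == expected

    def test_non_coding_wins_when_no_coding_overlap(self, genes):
        # only NCRNA1's body covers [39k is exclusive] -> use 31k-39k window
        got = map_gene(("chrS", 38_500, 38_900), genes)
        # ALPHA body [25k,40k) also covers this; construct a purer case:
        extra = [GeneModel("LONELYNC", "LONELYNC.1", "chrS", "+", 600_000, 620_000, False)]
        got = map_gene(("chrS", 612_000, 612_400), genes + extra)
        assert got == ("LONELYNC", CATEGORY_BODY, 400)

    def test_larger_overlap_wins_within_category(self, genes):
        # spans ALPHA promoter by 2000 and NCRNA1 promoter by 2000+1000
        got = map_gene(("chrS", 23_000, 26_000), genes)
        assert got[0] == "ALPHA"  # coding still beats the larger non-coding hit

    def test_deterministic_under_permutation(self, genes, rng):
        interval = ("chrS", 118_000, 122_000)
        base = map_gene(interval, genes)
        for _ in range(5):
            perm = list(genes)
            rng.shuffle(perm)
            assert map_gene(interval, perm) == base

    def test_fixture_segmentation_covers_chromosome(self):
        seg, _ = generate_annotation_fixtures(seed=1)
        assert seg.iloc[0]["start"] == 0
        assert (seg["start"].to_numpy()[1:] == seg["end"].to_numpy()[:-1]).all()
        assert set(seg["state"]) <= set(range(1, 19))
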