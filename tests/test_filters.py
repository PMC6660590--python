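"""Retention rules (PMD / length / gap / size / endpoints) and intersection."""

import numpy as np
import pytest

from updmr.filters import Dmr, DmrParams, filter_regions, intersect_dmr_sets
from updmr.sitetests import SiteResults
from updmr.updist import CandidateRegion, up_tail_probability


def make_candidate(pos, p=None, pmd=35.0, chrom="chrS"):
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    p = np.full(n, 0.01) if p is None else np.asarray(p, dtype=float)
    pmd = np.full(n, pmd) if np.isscalar(pmd) else np.asarray(pmd, dtype=float)
    return CandidateRegion(
        chrom=chrom,
        start_idx=0,
        end_idx=n - 1,
        pos=pos,
        p=p,
        pmd=pmd,
        up_p=float(up_tail_probability(float(np.prod(p)), n)),
    )


def spaced(n, gap, start=1000):
    return start + gap * np.arange(n)


class TestFilterRegions:
    def test_all_rules_satisfied_is_retained(self):
        cand = make_candidate(spaced(6, 80), pmd=35.0)  # span 401 bp
        out = filter_regions([cand])
        assert len(out) == 1
        d = out[0]
        assert d.k == 6 and d.length_bp == 401 and d.direction == "hyper"

    def test_short_region_rejected(self):
        # 240 bp span, everything else fine
        cand = make_candidate(spaced(6, 48), pmd=35.0)
        assert filter_regions([cand]) == []

    def test_weak_pmd_rejected(self):
        cand = make_candidate(spaced(6, 80), pmd=18.0)
        assert filter_regions([cand]) == []

    def test_pmd_threshold_is_two_sided(self):
        cand = make_candidate(spaced(6, 80), pmd=-35.0)
        out = filter_regions([cand])
        assert len(out) == 1 and out[0].direction == "hypo"

    def test_gap_causes_split_and_small_fragments_drop(self):
        # 5 sites, 250 bp gap in the middle: fragments of 2 and 3 sites die
        pos = np.array([1000, 1050, 1100, 1350, 1400])
        cand = make_candidate(pos)
        assert filter_regions([cand]) == []

    def test_gap_split_keeps_valid_fragment(self):
        # 6-site fragment spanning 400 bp survives; 2-site tail does not
        pos = np.concatenate([spaced(6, 80), [2000, 2050]])
        cand = make_candidate(pos)
        out = filter_regions([cand])
        assert len(out) == 1
        assert out[0].pos.tolist() == spaced(6, 80).tolist()
        assert out[0].max_gap_bp <= 200

    def test_too_few_sites_rejected(self):
        cand = make_candidate(spaced(4, 120))
        assert filter_regions([cand]) == []

    def test_insignificant_endpoints_trimmed_then_rejected(self):
        p = [0.5, 0.01, 0.01, 0.01, 0.01]  # trims to 4 sites
        cand = make_candidate(spaced(5, 100), p=p)
        assert filter_regions([cand]) == []

    def test_up_rule_rechecked_on_fragment(self):
        # individually significant endpoints but a product too weak jointly
        p = [0.049, 0.9, 0.9, 0.9, 0.049]
        cand = make_candidate(spaced(5, 100), p=p)
        cand.up_p = 1e-9  # lie in the candidate; the filter must recompute
        assert filter_regions([cand]) == []

    def test_output_sites_subset_of_input(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            pos = np.cumsum(rng.integers(10, 300, n)) + 1000
            cand = make_candidate(pos, p=rng.random(n) * 0.06, pmd=float(rng.normal(30, 10)))
            for d in filter_regions([cand]):
                assert set(d.pos.tolist()) <= set(pos.tolist())

    def test_order_independent(self, rng):
        cands = []
        for i in range(6):
            pos = spaced(8, 70, start=1000 + 5000 * i)
            cands.append(make_candidate(pos, pmd=float(rng.normal(30, 5))))
        a = filter_regions(cands)
        b = filter_regions(cands[::-1])
        assert [(d.chrom, d.start_pos, d.end_pos) for d in a] == [
            (d.chrom, d.start_pos, d.end_pos) for d in b
        ]


def make_dmr(start, end, n=6, pmd=30.0, chrom="chrS"):
    pos = np.linspace(start, end, n).astype(np.int64)
    return Dmr(
        chrom=chrom,
        pos=pos,
        p=np.full(n, 0.01),
        pmd=np.full(n, pmd),
        up_p=1e-4,
        provenance="test",
    )


class TestIntersect:
    def test_same_direction_overlap_retained_with_pairwise_pmd(self):
        mc = make_dmr(1000, 1600, pmd=25.0)
        pw = make_dmr(1200, 1900, pmd=42.0)
        out = intersect_dmr_sets([pw], [mc])
        assert len(out) == 1
        d = out[0]
        # coordinates from the multi-control region, PMD from the pairwise one
        assert (d.start_pos, d.end_pos) == (1000, 1600)
        assert d.reported_pmd == pytest.approx(42.0)

    def test_direction_mismatch_dropped(self):
        mc = make_dmr(1000, 1600, pmd=25.0)
        pw = make_dmr(1200, 1900, pmd=-42.0)
        assert intersect_dmr_sets([pw], [mc]) == []

    def test_small_overlap_dropped(self):
        mc = make_dmr(1000, 1600)
        pw = make_dmr(1571, 2200)  # 30 bp of overlap
        assert intersect_dmr_sets([pw], [mc]) == []
        pw2 = make_dmr(1551, 2200)  # 50 bp
        assert len(intersect_dmr_sets([pw2], [mc])) == 1

    def test_self_intersection_identity(self):
        xs = [make_dmr(1000, 1600), make_dmr(9000, 9400, pmd=-30.0)]
        out = intersect_dmr_sets(xs, xs)
        assert [(d.start_pos, d.end_pos, d.direction) for d in out] == [
            (d.start_pos, d.end_pos, d.direction) for d in xs
        ]

    def test_reporting_sites_override(self):
        mc = make_dmr(1000, 1600)
        pw = make_dmr(1000, 1600, pmd=42.0)
        sites = SiteResults(
            chrom="chrS",
            pos=np.array([900, 1100, 1500, 1700]),
            p=np.full(4, 0.01),
            pmd=np.array([99.0, 10.0, 20.0, 99.0]),
        )
        out = intersect_dmr_sets([pw], [mc], reporting_sites={"chrS": sites})
        # only the sites inside [1000, 1600] count
        assert out[0].reported_pmd == pytest.approx(15.0)

    def test_different_chromosomes_never_intersect(self):
        mc = make_dmr(1000, 1600, chrom="chr1")
        pw = make_dmr(1000, 1600, chrom="chr2")
        assert intersect_dmr_sets([pw], [mc]) == []
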