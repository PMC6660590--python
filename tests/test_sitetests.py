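"""Per-CpG tests: Fisher exact values, logistic LRT, symmetry, agreement."""

import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from conftest import fisher_oracle
from updmr.sitetests import (
    fisher_site_test,
    fisher_test_counts,
    logistic_site_test,
    logistic_test_counts,
)

counts = hst.integers(min_value=0, max_value=25)


class TestFisher:
    def test_extreme_table_matches_enumeration(self):
        # both groups saturated in opposite directions: p = 2 / C(20, 10)
        r = fisher_site_test((10, 0), (0, 10))
        assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
        assert r.pmd == 100.0

    def test_identical_groups(self):
        r = fisher_site_test((5, 5), (5, 5))
        assert r.p_value == 1.0 and r.pmd == 0.0

    def test_moderate_table_matches_enumeration(self):
        r = fisher_site_test((3, 7), (7, 3))
        assert r.p_value == pytest.approx(fisher_oracle(3, 7, 7, 3), rel=1e-12)
        assert r.pmd == -40.0

    def test_zero_coverage_skipped(self):
        assert fisher_site_test((0, 0), (5, 5)) is None
        assert fisher_site_test((5, 5), (0, 0)) is None

    def test_agrees_with_scipy_on_random_tables(self, rng):
        a = rng.integers(0, 20, 300)
        b = rng.integers(0, 20, 300)
        c = rng.integers(0, 20, 300)
        d = rng.integers(0, 20, 300)
        keep = (a + b > 0) & (c + d > 0)
        a, b, c, d = a[keep], b[keep], c[keep], d[keep]
        p, _ = fisher_test_counts(a, a + b, c, c + d)
        expected = [st.fisher_exact([[ai, bi], [ci, di]])[1] for ai, bi, ci, di in zip(a, b, c, d)]
        np.testing.assert_allclose(p, expected, rtol=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=counts, b=counts, c=counts, d=counts)
    def test_symmetry(self, a, b, c, d):
        """Swapping case and reference negates the PMD and preserves p exactly."""
        if a + b == 0 or c + d == 0:
            return
        r1 = fisher_site_test((a, b), (c, d))
        r2 = fisher_site_test((c, d), (a, b))
        assert r1.p_value == r2.p_value
        assert r1.pmd == pytest.approx(-r2.pmd, abs=1e-12)


def _grid_ll(case, refs):
    """Independent oracle: maximize the two binomial likelihoods on a fine
    grid of probabilities and form the LRT statistic directly."""
    a, n1 = case[0], case[0] + case[1]
    mr = sum(r[0] for r in refs)
    tr = sum(r[0] + r[1] for r in refs)
    grid = np.linspace(1e-6, 1 - 1e-6, 200_001)

    def ll(m, t):
        return np.max(m * np.log(grid) + (t - m) * np.log(1 - grid))

    full = ll(a, n1) + ll(mr, tr)
    null = ll(a + mr, n1 + tr)
    return 2 * (full - null)


class TestLogistic:
    def test_matches_grid_likelihood_oracle(self):
        case, refs = (8, 2), [(2, 8), (3, 7), (2, 8)]
        stat = _grid_ll(case, refs)
        expected = st.chi2.sf(stat, 1)
        r = logistic_site_test(case, refs)
        assert r.p_value == pytest.approx(expected, abs=1e-4)

    def test_identical_groups_give_p_one(self):
        r = logistic_site_test((5, 5), [(5, 5), (5, 5), (5, 5)])
        assert r.p_value == 1.0 and r.pmd == 0.0 and not r.separation_corrected

    def test_complete_separation_fallback(self):
        r = logistic_site_test((10, 0), [(0, 10)])
        assert r.separation_corrected
        assert 0.0 < r.p_value < 1.0

    def test_quasi_separation_needs_no_correction(self):
        r = logistic_site_test((10, 0), [(3, 7), (2, 8)])
        assert not r.separation_corrected and 0 < r.p_value < 0.05

    def test_pmd_is_unweighted_mean_of_reference_fractions(self):
        # pooled fractions would weight the deep sample 10x; the unweighted
        # mean of 0.9 and 0.1 is 0.5
        r = logistic_site_test((8, 2), [(90, 10), (1, 9)])
        assert r.pmd == pytest.approx(100 * (0.8 - 0.5))

    def test_absent_reference_excluded(self):
        p, pmd, _ = logistic_test_counts(
            np.array([5]), np.array([10]),
            np.array([[5, 0]]), np.array([[10, 0]]),
        )
        r = logistic_site_test((5, 5), [(5, 5)])
        assert p[0] == r.p_value and pmd[0] == r.pmd

    def test_all_zero_reference_skipped(self):
        assert logistic_site_test((5, 5), [(0, 0)]) is None

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        tables = [((8, 2), [(2, 8), (3, 7)]), ((4, 16), [(10, 10), (12, 8), (9, 11)]),
                  ((15, 5), [(14, 6)])]
        for case, refs in tables:
            mr = sum(r[0] for r in refs)
            tr = sum(r[0] + r[1] for r in refs)
            endog = np.array([[case[0], case[1]], [mr, tr - mr]])
            exog = sm.add_constant(np.array([1.0, 0.0]))
            full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((2, 1)), family=sm.families.Binomial()).fit()
            stat = 2 * (full.llf - null.llf)
            r = logistic_site_test(case, refs)
            assert r.p_value == pytest.approx(st.chi2.sf(stat, 1), rel=1e-6)

    def test_rank_agreement_with_fisher_for_two_samples(self, rng):
        """For pairs of samples the logistic LRT and Fisher's exact test
        order sites almost identically.

        The grid keeps totals in 10..30: below ~10 reads the discrete
        conditional test and the asymptotic LRT genuinely order the most
        extreme tables differently.
        """
        n = 400
        t1 = rng.integers(10, 31, n)
        t2 = rng.integers(10, 31, n)
        a = rng.binomial(t1, rng.random(n))
        c = rng.binomial(t2, rng.random(n))
        pf, _ = fisher_test_counts(a, t1, c, t2)
        pl, _, _ = logistic_test_counts(a, t1, c[:, None], t2[:, None])
        rho = st.spearmanr(pf, pl).statistic
        assert rho > 0.99
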