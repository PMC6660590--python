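"""Per-CpG differential methylation tests.

Two test families are provided, matching the two kinds of comparison in the
workflow:

* :func:`fisher_site_test` / :func:`fisher_test_counts` — two-sided
  Fisher's exact test on the 2x2 table of methylated / unmethylated read
  counts for a pair of samples.  The batch variant evaluates the
  point-probability ("minimum likelihood") two-sided p-value with
  vectorised hypergeometric log-pmfs, since per-site calls to
  ``scipy.stats.fisher_exact`` are far too slow for genome-scale input; it
  agrees with scipy to floating-point precision.

* :func:`logistic_site_test` / :func:`logistic_test_counts` — binomial
  logistic regression of methylation state on a case-vs-reference group
  indicator, with significance from the 1-df likelihood-ratio test.  With a
  single binary covariate and grouped counts the maximum-likelihood fit has
  the closed form "fitted probability = group pooled fraction", so the LRT
  statistic is computed directly from binomial log-likelihoods rather than
  through an iterative solver.

The percent methylation difference (PMD) accompanying each p-value is the
case methylated-read fraction minus the reference fraction, times 100; for
group references the reference fraction is the unweighted mean of
per-sample fractions so that a single high-coverage control cannot
dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, xlogy
from scipy.stats import chi2

__all__ = [
    "SiteTestResult",
    "SiteResults",
    "fisher_site_test",
    "logistic_site_test",
    "fisher_test_counts",
    "logistic_test_counts",
]

# relative slack when comparing table probabilities to the observed one,
# as in R's fisher.test, to absorb floating-point noise in ties
_REL_ERR = 1.0 + 1e-7

_P_FLOOR = 1e-300  # keep p-values strictly positive


class SiteTestResult(NamedTuple):
    """Result of one per-CpG test."""

    chrom: str
    pos: int
    p_value: float
    pmd: float  # percent methylation difference, case - reference, in points
    n_case: int
    n_ref: int
    separation_corrected: bool = False


@dataclass
class SiteResults:
    """Ordered per-site test results for one chromosome (column arrays)."""

    chrom: str
    pos: np.ndarray
    p: np.ndarray
    pmd: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=float)
        self.pmd = np.asarray(self.pmd, dtype=float)
        if not (len(self.pos) == len(self.p) == len(self.pmd)):
            raise ValueError("pos, p, pmd must have equal length")
        if len(self.pos) > 1 and np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pos)


# ---------------------------------------------------------------------------
# Fisher's exact test (vectorised two-sided point-probability method)


def fisher_test_counts(
    case_meth: np.ndarray,
    case_total: np.ndarray,
    ref_meth: np.ndarray,
    ref_total: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher exact p-values and PMDs for arrays of 2x2 tables.

    Each table is ``[[case_meth, case_total-case_meth],
    [ref_meth, ref_total-ref_meth]]``.  Entries with a zero total in either
    sample get ``p = nan`` (callers skip them).  Returns ``(p, pmd)``.
    """
    a = np.asarray(case_meth, dtype=np.int64)
    n1 = np.asarray(case_total, dtype=np.int64)
    c = np.asarray(ref_meth, dtype=np.int64)
    n2 = np.asarray(ref_total, dtype=np.int64)
    if np.any(a > n1) or np.any(c > n2) or np.any(a < 0) or np.any(c < 0):
        raise ValueError("methylated counts must lie in [0, total]")
    valid = (n1 > 0) & (n2 > 0)
    m = a + c  # methylated margin
    k_lo = np.maximum(0, m - n2)
    k_hi = np.minimum(n1, m)
    width = int((k_hi - k_lo).max() + 1) if valid.any() else 1
    k = k_lo[:, None] + np.arange(width)[None, :]
    in_support = k <= k_hi[:, None]
    k = np.where(in_support, k, k_lo[:, None])
    # log hypergeometric pmf over the support of each table
    logpmf = (
        _logC(n1[:, None], k)
        + _logC(n2[:, None], m[:, None] - k)
        - _logC((n1 + n2)[:, None], m[:, None])
    )
    logpmf = np.where(in_support, logpmf, -np.inf)
    log_obs = (
        _logC(n1, a) + _logC(n2, c) - _logC(n1 + n2, m)
    )
    take = logpmf <= (log_obs[:, None] + np.log(_REL_ERR))
    vals = np.where(take, np.exp(logpmf), 0.0)
    vals.sort(axis=1)  # canonical summation order: exact case/ref symmetry
    p = vals.sum(axis=1)
    p = np.clip(p, _P_FLOOR, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmd = 100.0 * (a / n1 - c / n2)
    p = np.where(valid, p, np.nan)
    pmd = np.where(valid, pmd, np.nan)
    return p, pmd


def _logC(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_site_test(
    case: tuple[int, int],
    ref: tuple[int, int],
    chrom: str = "",
    pos: int = 0,
) -> SiteTestResult | None:
    """Fisher's exact test for one CpG in a pair of samples.

    ``case`` and ``ref`` are ``(n_meth, n_unmeth)`` pairs. Returns ``None``
    when either sample has zero reads (the site is skipped).
    """
    n1 = case[0] + case[1]
    n2 = ref[0] + ref[1]
    if n1 == 0 or n2 == 0:
        return None
    p, pmd = fisher_test_counts(
        np.array([case[0]]), np.array([n1]), np.array([ref[0]]), np.array([n2])
    )
    return SiteTestResult(chrom, pos, float(p[0]), float(pmd[0]), n1, n2)


# ---------------------------------------------------------------------------
# Binomial logistic regression, likelihood-ratio test


def _binom_ll(meth, total, p):
    return xlogy(meth, p) + xlogy(total - meth, 1.0 - p)


def logistic_test_counts(
    case_meth: np.ndarray,
    case_total: np.ndarray,
    ref_meth: np.ndarray,
    ref_total: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group-vs-group binomial logistic LRT for arrays of sites.

    ``ref_meth`` / ``ref_total`` have shape ``(n_sites, n_refs)``; absent
    reference samples are encoded by a zero total and excluded both from
    the pooled group and from the PMD average. Returns
    ``(p, pmd, separation_flag)``; sites with zero case total or no present
    reference get ``p = nan``.
    """
    a = np.asarray(case_meth, dtype=np.int64)
    n1 = np.asarray(case_total, dtype=np.int64)
    rm = np.atleast_2d(np.asarray(ref_meth, dtype=np.int64))
    rt = np.atleast_2d(np.asarray(ref_total, dtype=np.int64))
    if rm.shape != rt.shape:
        raise ValueError("ref_meth and ref_total shapes differ")
    present = rt > 0
    mr = np.where(present, rm, 0).sum(axis=1)
    tr = np.where(present, rt, 0).sum(axis=1)
    valid = (n1 > 0) & (tr > 0)

    # complete separation: one group entirely methylated, the other entirely
    # unmethylated -> Haldane 0.5 correction on the pooled 2x2 table
    sep = valid & (((a == n1) & (mr == 0)) | ((a == 0) & (mr == tr)))
    af = a.astype(float)
    n1f = n1.astype(float)
    mrf = mr.astype(float)
    trf = tr.astype(float)
    af = np.where(sep, af + 0.5, af)
    n1f = np.where(sep, n1f + 1.0, n1f)
    mrf = np.where(sep, mrf + 0.5, mrf)
    trf = np.where(sep, trf + 1.0, trf)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_case = af / n1f
        p_ref = mrf / trf
        p_null = (af + mrf) / (n1f + trf)
        ll_full = _binom_ll(af, n1f, p_case) + _binom_ll(mrf, trf, p_ref)
        ll_null = _binom_ll(af + mrf, n1f + trf, p_null)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = np.clip(chi2.sf(stat, df=1), _P_FLOOR, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac_sum = np.where(present, rm / np.maximum(rt, 1), 0.0).sum(axis=1)
        n_present = present.sum(axis=1)
        mean_ref_frac = np.where(n_present > 0, frac_sum / np.maximum(n_present, 1), np.nan)
        pmd = 100.0 * (a / np.where(n1 > 0, n1, 1) - mean_ref_frac)
    p = np.where(valid, p, np.nan)
    pmd = np.where(valid, pmd, np.nan)
    return p, pmd, sep


def logistic_site_test(
    case: tuple[int, int],
    refs: Sequence[tuple[int, int]],
    chrom: str = "",
    pos: int = 0,
) -> SiteTestResult | None:
    """Logistic-regression LRT for one CpG: case sample vs a reference group.

    Returns ``None`` when the case or every reference has zero reads.
    """
    n1 = case[0] + case[1]
    rm = np.array([[r[0] for r in refs]])
    rt = np.array([[r[0] + r[1] for r in refs]])
    p, pmd, sep = logistic_test_counts(
        np.array([case[0]]), np.array([n1]), rm, rt
    )
    if np.isnan(p[0]):
        return None
    return SiteTestResult(
        chrom, pos, float(p[0]), float(pmd[0]), n1, int(rt.sum()), bool(sep[0])
    )
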