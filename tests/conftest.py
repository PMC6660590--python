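"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately take the slow, direct route — exact rational
hypergeometric enumeration, log-sum-exp evaluation of the series form of
the uniform-product tail, brute-force all-window scanning — so that the
fast implementation paths are checked against computations that share no
code with them.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from updmr.sitetests import SiteResults
from updmr.updist import up_tail_probability


def make_sites(p, pmd=None, spacing=50, start=1000, chrom="chrS") -> SiteResults:
    """Build a SiteResults from a p-value list with regular spacing."""
    p = np.asarray(p, dtype=float)
    if pmd is None:
        pmd = np.full(len(p), 30.0)
    pos = start + spacing * np.arange(len(p), dtype=np.int64)
    return SiteResults(chrom=chrom, pos=pos, p=p, pmd=np.asarray(pmd, dtype=float))


# ---------------------------------------------------------------------------
# oracles


def up_closed_form(x: float, k: int) -> float:
    """x * sum_{j<k} (-ln x)^j / j!, evaluated stably via log-sum-exp."""
    t = -math.log(x)
    if t == 0.0:
        return 1.0
    logs = [math.log(x) + j * math.log(t) - math.lgamma(j + 1) for j in range(k)]
    m = max(logs)
    return math.exp(m) * sum(math.exp(L - m) for L in logs)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with the customary
    1e-7 relative slack on the comparison), using exact arithmetic.
    """
    n1, n2, m = a + b, c + d, a + c
    obs = math.comb(n1, a) * math.comb(n2, c)
    total = 0
    denom = math.comb(n1 + n2, m)
    for k in range(max(0, m - n2), min(n1, m) + 1):
        w = math.comb(n1, k) * math.comb(n2, m - k)
        if w * 10**7 <= obs * (10**7 + 1):
            total += w
    return float(Fraction(total, denom))


def scan_oracle(sites: SiteResults, alpha_site=0.05, alpha_region=0.05, min_sites=5):
    """Brute force: test every >= min_sites window, merge, trim.

    Returns a list of (start_idx, end_idx) inclusive spans.
    """
    n = len(sites)
    p = np.clip(sites.p, 1e-300, 1.0)
    wins = []
    for i in range(n):
        if p[i] > alpha_site:
            continue
        prod = p[i]
        for j in range(i + 1, n):
            prod = max(prod * p[j], 1e-300)
            k = j - i + 1
            if k < min_sites or p[j] > alpha_site:
                continue
            if up_tail_probability(prod, k) <= alpha_region:
                wins.append((i, j))
    if not wins:
        return []
    wins.sort()
    merged = [list(wins[0])]
    for i, j in wins[1:]:
        if i <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    sig = np.flatnonzero(p <= alpha_site)
    out = []
    for i, j in merged:
        lo = sig[np.searchsorted(sig, i)]
        hi = sig[np.searchsorted(sig, j, side="right") - 1]
        if hi - lo + 1 >= min_sites:
            out.append((int(lo), int(hi)))
    return out


def random_p_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform p-values with occasional planted low-p runs, to exercise both
    empty and busy scan outcomes."""
    p = rng.random(n)
    n_runs = rng.integers(0, 4)
    for _ in range(n_runs):
        ln = int(rng.integers(3, 12))
        if ln >= n:
            continue
        s = int(rng.integers(0, n - ln))
        p[s : s + ln] = rng.random(ln) * rng.choice([0.01, 0.05, 0.2])
    return np.clip(p, 1e-12, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
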