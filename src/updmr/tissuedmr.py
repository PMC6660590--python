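"""One-vs-rest tissue-specific DMR calling across a reference panel.

For a chosen target methylome, every CpG present in the target and in at
least ``min_nontarget_present`` of the non-target panel members is tested
with the binomial logistic likelihood-ratio test (target vs the pooled
non-targets), and the resulting site p-values feed the same UP scan and
filter chain used for the case/control analysis.  A hypomethylated call
means the target lies below the rest of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from updmr.filters import Dmr, DmrParams, filter_regions
from updmr.io import MethylomeMatrix
from updmr.sitetests import SiteResults, logistic_test_counts
from updmr.updist import scan_candidate_regions

__all__ = ["PanelComparison", "call_tissue_dmrs", "tissue_site_results"]


@dataclass
class PanelComparison:
    """A one-vs-rest comparison within a panel of samples.

    ``min_nontarget_present`` defaults to ``len(others) - 1``, generalising
    the 4-of-5 presence rule of a six-tissue panel.
    """

    target: str
    others: list[str]
    min_nontarget_present: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.target in self.others:
            raise ValueError("target must not appear among the non-targets")
        if self.min_nontarget_present < 0:
            self.min_nontarget_present = max(len(self.others) - 1, 1)
        if self.min_nontarget_present > len(self.others):
            raise ValueError("min_nontarget_present exceeds panel size")


def tissue_site_results(
    matrix: MethylomeMatrix,
    cmp: PanelComparison,
    min_coverage: int = 1,
) -> dict[str, SiteResults]:
    """Per-chromosome logistic site tests for one target vs the panel rest.

    Sites failing the presence rule (target absent, or fewer than
    ``min_nontarget_present`` non-targets with coverage) are excluded
    before testing.
    """
    ti = matrix.sample_index(cmp.target)
    oi = [matrix.sample_index(s) for s in cmp.others]
    out: dict[str, SiteResults] = {}
    for chrom, cc in matrix.iter_chromosomes():
        present = cc.present(min_coverage)
        testable = present[:, ti] & (
            present[:, oi].sum(axis=1) >= cmp.min_nontarget_present
        )
        if not testable.any():
            continue
        idx = np.flatnonzero(testable)
        ref_total = cc.total[idx][:, oi]
        ref_meth = cc.meth[idx][:, oi]
        # mask refs below the coverage floor so they join neither the pooled
        # group nor the PMD average
        below = ref_total < max(min_coverage, 1)
        ref_total = np.where(below, 0, ref_total)
        ref_meth = np.where(below, 0, ref_meth)
        p, pmd, _sep = logistic_test_counts(
            cc.meth[idx, ti], cc.total[idx, ti], ref_meth, ref_total
        )
        keep = ~np.isnan(p)
        if keep.any():
            out[chrom] = SiteResults(
                chrom=chrom, pos=cc.pos[idx][keep], p=p[keep], pmd=pmd[keep]
            )
    return out


def call_tissue_dmrs(
    matrix: MethylomeMatrix,
    cmp: PanelComparison,
    params: DmrParams | None = None,
) -> list[Dmr]:
    """Tissue-specific DMRs for one target sample.

    Runs the presence-filtered logistic site tests, the UP candidate scan
    and the standard filters with the same parameters as the case/control
    analysis.  ``direction == "hypo"`` marks tissue-hypomethylation (target
    below the panel).
    """
    params = params or DmrParams()
    if cmp.target not in matrix.samples:
        raise KeyError(f"target sample {cmp.target!r} not in matrix")
    per_chrom = tissue_site_results(matrix, cmp, params.min_coverage)
    dmrs: list[Dmr] = []
    for chrom in matrix.chroms:
        if chrom not in per_chrom:
            continue
        cands = scan_candidate_regions(
            per_chrom[chrom],
            alpha_site=params.alpha_site,
            alpha_region=params.alpha_region,
            min_sites=params.min_sites,
        )
        dmrs.extend(filter_regions(cands, params, provenance=f"tissue:{cmp.target}"))
    return dmrs
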