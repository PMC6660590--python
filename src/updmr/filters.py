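"""DMR retention rules and the pairwise/multi-control intersection.

Candidate regions from the UP scan are kept only when they satisfy, after
splitting at large inter-site gaps:

* at least ``min_sites`` member CpGs, beginning and ending with an
  individually significant site, with a combined UP probability at or
  below ``alpha_region`` (re-checked on every gap fragment);
* mean percent methylation difference of at least ``pmd_min`` in absolute
  value (default 20 points);
* evidence span (first to last member CpG, inclusive) longer than
  ``len_min_bp`` (default 250 bp);
* no gap between consecutive member CpGs above ``gap_max_bp``
  (default 200 bp) — enforced by splitting at each such gap and
  re-validating the fragments rather than discarding the whole region.

The final DMR set of a case/multi-control analysis is the intersection of
the pairwise and the multi-control DMR sets: a multi-control DMR survives
when a same-direction pairwise DMR overlaps it by at least
``min_overlap_bp``; coordinates come from the multi-control region while
the reported PMD is recomputed over those coordinates from the designated
reporting (pairwise) comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from updmr.annotate import overlap_bp
from updmr.sitetests import SiteResults
from updmr.updist import CandidateRegion, up_tail_from_log_product

__all__ = ["Dmr", "DmrParams", "filter_regions", "intersect_dmr_sets"]


@dataclass
class DmrParams:
    """Thresholds of the scan/filter chain (defaults are the published ones)."""

    alpha_site: float = 0.05
    alpha_region: float = 0.05
    min_sites: int = 5
    pmd_min: float = 20.0
    len_min_bp: int = 250
    gap_max_bp: int = 200
    min_overlap_bp: int = 50
    min_coverage: int = 1


@dataclass
class Dmr:
    """A retained differentially methylated region."""

    chrom: str
    pos: np.ndarray  # member CpG positions, 1-based
    p: np.ndarray
    pmd: np.ndarray
    up_p: float
    provenance: str = ""
    reported_pmd: float | None = None
    mean_pmd: float = field(init=False)
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.mean_pmd = float(np.mean(self.pmd))
        self.direction = "hyper" if self.mean_pmd > 0 else "hypo"

    @property
    def k(self) -> int:
        return len(self.pos)

    @property
    def start_pos(self) -> int:
        return int(self.pos[0])

    @property
    def end_pos(self) -> int:
        return int(self.pos[-1])

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def max_gap_bp(self) -> int:
        return int(np.diff(self.pos).max()) if self.k > 1 else 0

    def interval(self) -> tuple[int, int]:
        """0-based half-open genomic interval spanned by the member CpGs."""
        return (self.start_pos - 1, self.end_pos)


def _split_at_gaps(pos: np.ndarray, gap_max_bp: int) -> list[tuple[int, int]]:
    """Inclusive index fragments after cutting every gap > gap_max_bp."""
    cuts = np.flatnonzero(np.diff(pos) > gap_max_bp)
    starts = np.concatenate([[0], cuts + 1])
    ends = np.concatenate([cuts, [len(pos) - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def filter_regions(
    candidates: Iterable[CandidateRegion],
    params: DmrParams | None = None,
    provenance: str = "",
) -> list[Dmr]:
    """Apply the retention rules to scanned candidates.

    Each candidate is split at gaps above ``gap_max_bp``; every fragment is
    trimmed to significant endpoints and re-tested against the
    ``min_sites`` and UP rules before the PMD and length filters. The
    output is sorted by (chrom, start) and independent of input order.
    """
    params = params or DmrParams()
    out: list[Dmr] = []
    for cand in candidates:
        for lo, hi in _split_at_gaps(cand.pos, params.gap_max_bp):
            frag_p = cand.p[lo : hi + 1]
            sig = np.flatnonzero(frag_p <= params.alpha_site)
            if len(sig) == 0:
                continue
            lo2, hi2 = lo + int(sig[0]), lo + int(sig[-1])
            k = hi2 - lo2 + 1
            if k < params.min_sites:
                continue
            logp = np.log(np.clip(cand.p[lo2 : hi2 + 1], 1e-300, 1.0))
            up_p = max(float(up_tail_from_log_product(logp.sum(), k)), 5e-324)
            if up_p > params.alpha_region:
                continue
            pmd = cand.pmd[lo2 : hi2 + 1]
            if abs(float(np.mean(pmd))) < params.pmd_min:
                continue
            pos = cand.pos[lo2 : hi2 + 1]
            if int(pos[-1] - pos[0]) + 1 <= params.len_min_bp:
                continue
            out.append(
                Dmr(
                    chrom=cand.chrom,
                    pos=pos.copy(),
                    p=cand.p[lo2 : hi2 + 1].copy(),
                    pmd=pmd.copy(),
                    up_p=up_p,
                    provenance=provenance,
                )
            )
    out.sort(key=lambda d: (d.chrom, d.start_pos, d.end_pos))
    return out


def intersect_dmr_sets(
    pairwise_dmrs: Sequence[Dmr],
    multicontrol_dmrs: Sequence[Dmr],
    min_overlap_bp: int = 50,
    reporting_sites: Mapping[str, SiteResults] | None = None,
) -> list[Dmr]:
    """Final DMRs: multi-control regions confirmed by the pairwise analysis.

    A multi-control DMR is retained when some pairwise DMR of the same
    direction on the same chromosome overlaps it by at least
    ``min_overlap_bp``.  Coordinates (and member sites) come from the
    multi-control DMR.  ``reported_pmd`` is recomputed over those
    coordinates from ``reporting_sites`` (per-chromosome site results of
    the designated reporting comparison) when given, falling back to the
    best-overlapping pairwise DMR's member sites inside the span.
    """
    final: list[Dmr] = []
    for mc in multicontrol_dmrs:
        best: Dmr | None = None
        best_bp = 0
        for pw in pairwise_dmrs:
            if pw.chrom != mc.chrom or pw.direction != mc.direction:
                continue
            bp = overlap_bp(mc.interval(), pw.interval())
            if bp >= min_overlap_bp and bp > best_bp:
                best, best_bp = pw, bp
        if best is None:
            continue
        reported = _reporting_pmd(mc, best, reporting_sites)
        final.append(
            Dmr(
                chrom=mc.chrom,
                pos=mc.pos.copy(),
                p=mc.p.copy(),
                pmd=mc.pmd.copy(),
                up_p=mc.up_p,
                provenance="final",
                reported_pmd=reported,
            )
        )
    return final


def _reporting_pmd(
    mc: Dmr, pw: Dmr, reporting_sites: Mapping[str, SiteResults] | None
) -> float:
    if reporting_sites is not None and mc.chrom in reporting_sites:
        sr = reporting_sites[mc.chrom]
        inside = (sr.pos >= mc.start_pos) & (sr.pos <= mc.end_pos)
        if inside.any():
            return float(np.mean(sr.pmd[inside]))
    inside = (pw.pos >= mc.start_pos) & (pw.pos <= mc.end_pos)
    if inside.any():
        return float(np.mean(pw.pmd[inside]))
    return pw.mean_pmd
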