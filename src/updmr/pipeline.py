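"""Orchestration of the full DMR analysis.

``run_athero_from_matrix`` executes the case/control flow on an in-memory
matrix: (1) Fisher site tests of the case against the designated reporting
control and a UP scan + filter over them (the pairwise DMR set P); (2)
logistic site tests of the case against all controls, restricted to sites
present in every sample, scanned and filtered identically (the
multi-control set M); (3) the final set = same-direction intersection of P
and M with PMDs reported from the pairwise comparison.  With a single
control the logistic leg would duplicate the pairwise one, so M = P and
the final set is P.

``run_athero_analysis`` is the file-based wrapper driven by a
:class:`RunConfig`; ``run_tissue_analysis`` runs the one-vs-rest tissue
comparison for every panel member.  Every run can write its DMR sets plus
a JSON parameter manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from updmr import io as uio
from updmr.filters import Dmr, DmrParams, filter_regions, intersect_dmr_sets
from updmr.io import MethylomeMatrix
from updmr.sitetests import SiteResults, fisher_test_counts, logistic_test_counts
from updmr.tissuedmr import PanelComparison, call_tissue_dmrs
from updmr.updist import scan_candidate_regions

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "AtheroResult",
    "pairwise_site_results",
    "multicontrol_site_results",
    "scan_and_filter",
    "run_athero_from_matrix",
    "run_athero_analysis",
    "run_tissue_analysis",
]


@dataclass
class RunConfig:
    """Declarative configuration of a file-based run.

    ``manifest`` maps sample name to ``(path, role)`` with role in
    ``{"case", "control", "panel"}``.  ``reporting_pair`` names the
    comparison whose PMDs are reported on final DMRs; it defaults to the
    case and the first control.
    """

    manifest: dict[str, tuple[str, str]]
    params: DmrParams = field(default_factory=DmrParams)
    reporting_pair: tuple[str, str] | None = None
    dialect: str = "bismark-cov"
    outdir: str | None = None
    seed: int = 0

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, (_, r) in self.manifest.items() if r == role]

    def validate_athero(self) -> tuple[str, list[str]]:
        cases = self.samples_with_role("case")
        controls = self.samples_with_role("control")
        if len(cases) != 1:
            raise ValueError(f"exactly one case sample required, got {len(cases)}")
        if not controls:
            raise ValueError("at least one control sample required")
        if self.reporting_pair is not None:
            for name in self.reporting_pair:
                if name not in self.manifest:
                    raise ValueError(f"reporting-pair sample {name!r} not in manifest")
        return cases[0], controls


@dataclass
class AtheroResult:
    pairwise_dmrs: list[Dmr]
    multicontrol_dmrs: list[Dmr]
    final_dmrs: list[Dmr]
    stage_counts: dict[str, int]
    coverage_anomalies: list[dict]


def pairwise_site_results(
    matrix: MethylomeMatrix, case: str, control: str, min_coverage: int = 1
) -> dict[str, SiteResults]:
    """Fisher site tests per chromosome for sites covered in both samples."""
    ci = matrix.sample_index(case)
    ri = matrix.sample_index(control)
    out: dict[str, SiteResults] = {}
    for chrom, cc in matrix.iter_chromosomes():
        ok = (cc.total[:, ci] >= max(min_coverage, 1)) & (
            cc.total[:, ri] >= max(min_coverage, 1)
        )
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        p, pmd = fisher_test_counts(
            cc.meth[idx, ci], cc.total[idx, ci], cc.meth[idx, ri], cc.total[idx, ri]
        )
        out[chrom] = SiteResults(chrom=chrom, pos=cc.pos[idx], p=p, pmd=pmd)
    return out


def multicontrol_site_results(
    matrix: MethylomeMatrix, case: str, controls: list[str], min_coverage: int = 1
) -> dict[str, SiteResults]:
    """Logistic site tests of case vs pooled controls, restricted to sites
    present (at the coverage floor) in the case and in every control."""
    ci = matrix.sample_index(case)
    ris = [matrix.sample_index(c) for c in controls]
    out: dict[str, SiteResults] = {}
    for chrom, cc in matrix.iter_chromosomes():
        pres = cc.present(min_coverage)
        ok = pres[:, ci] & pres[:, ris].all(axis=1)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        p, pmd, _sep = logistic_test_counts(
            cc.meth[idx, ci],
            cc.total[idx, ci],
            cc.meth[idx][:, ris],
            cc.total[idx][:, ris],
        )
        keep = ~np.isnan(p)
        if keep.any():
            out[chrom] = SiteResults(
                chrom=chrom, pos=cc.pos[idx][keep], p=p[keep], pmd=pmd[keep]
            )
    return out


def scan_and_filter(
    per_chrom: dict[str, SiteResults],
    params: DmrParams,
    provenance: str,
    chrom_order: list[str] | None = None,
) -> list[Dmr]:
    """UP scan plus retention filters, chromosome by chromosome."""
    dmrs: list[Dmr] = []
    for chrom in chrom_order or sorted(per_chrom):
        if chrom not in per_chrom:
            continue
        cands = scan_candidate_regions(
            per_chrom[chrom],
            alpha_site=params.alpha_site,
            alpha_region=params.alpha_region,
            min_sites=params.min_sites,
        )
        kept = filter_regions(cands, params, provenance=provenance)
        logger.info(
            "%s %s: %d candidates -> %d DMRs", provenance, chrom, len(cands), len(kept)
        )
        dmrs.extend(kept)
    return dmrs


def _coverage_anomalies(
    matrix: MethylomeMatrix, dmrs: list[Dmr], rel_floor: float = 0.25
) -> list[dict]:
    """Flag DMRs where some sample's regional mean coverage collapses
    relative to its genome-wide mean (no automatic fallback is applied)."""
    global_mean = {}
    for j, s in enumerate(matrix.samples):
        tot = np.concatenate([cc.total[:, j] for _, cc in matrix.iter_chromosomes()])
        covered = tot[tot > 0]
        global_mean[s] = float(covered.mean()) if len(covered) else 0.0
    flags = []
    for i, d in enumerate(dmrs):
        cc = matrix.data.get(d.chrom)
        if cc is None:
            continue
        inside = (cc.pos >= d.start_pos) & (cc.pos <= d.end_pos)
        if not inside.any():
            continue
        low = [
            s
            for j, s in enumerate(matrix.samples)
            if global_mean[s] > 0
            and float(cc.total[inside, j].mean()) < rel_floor * global_mean[s]
        ]
        if low:
            flags.append(
                {
                    "dmr_index": i,
                    "chrom": d.chrom,
                    "start_pos": d.start_pos,
                    "end_pos": d.end_pos,
                    "low_coverage_samples": low,
                }
            )
    return flags


def run_athero_from_matrix(
    matrix: MethylomeMatrix,
    case: str,
    controls: list[str],
    reporting_control: str | None = None,
    params: DmrParams | None = None,
    outdir: str | None = None,
) -> AtheroResult:
    """Full case/control DMR analysis on a harmonized matrix."""
    params = params or DmrParams()
    if not controls:
        raise ValueError("at least one control required")
    reporting_control = reporting_control or controls[0]
    if reporting_control not in controls:
        raise ValueError("reporting control must be one of the controls")

    pw_sites = pairwise_site_results(matrix, case, reporting_control, params.min_coverage)
    if not pw_sites:
        raise ValueError(f"no sites shared by {case!r} and {reporting_control!r}")
    pairwise = scan_and_filter(pw_sites, params, "pairwise", matrix.chroms)

    if len(controls) == 1:
        multicontrol = pairwise
    else:
        mc_sites = multicontrol_site_results(matrix, case, controls, params.min_coverage)
        if not mc_sites:
            raise ValueError("no sites present in all samples")
        multicontrol = scan_and_filter(mc_sites, params, "multicontrol", matrix.chroms)

    final = intersect_dmr_sets(
        pairwise, multicontrol, params.min_overlap_bp, reporting_sites=pw_sites
    )
    counts = {
        "pairwise_dmrs": len(pairwise),
        "multicontrol_dmrs": len(multicontrol),
        "final_dmrs": len(final),
    }
    result = AtheroResult(
        pairwise_dmrs=pairwise,
        multicontrol_dmrs=multicontrol,
        final_dmrs=final,
        stage_counts=counts,
        coverage_anomalies=_coverage_anomalies(matrix, final),
    )
    if outdir is not None:
        _write_athero_outputs(result, params, matrix, outdir)
    return result


def _write_athero_outputs(result: AtheroResult, params: DmrParams, matrix, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    uio.write_dmr_bed(result.pairwise_dmrs, os.path.join(outdir, "pairwise.bed"))
    uio.write_dmr_bed(result.multicontrol_dmrs, os.path.join(outdir, "multicontrol.bed"))
    uio.write_dmr_bed(result.final_dmrs, os.path.join(outdir, "final.bed"))
    manifest = {
        "params": dataclasses.asdict(params),
        "samples": matrix.samples,
        "chroms": matrix.chroms,
        "stage_counts": result.stage_counts,
        "coverage_anomalies": result.coverage_anomalies,
        "version": _version(),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def _version() -> str:
    from updmr import __version__

    return __version__


def run_athero_analysis(config: RunConfig) -> AtheroResult:
    """File-based case/control analysis: read, harmonize, run, write."""
    case, controls = config.validate_athero()
    names = [case] + controls
    tables = []
    for name in names:
        path = config.manifest[name][0]
        if not os.path.exists(path):
            raise FileNotFoundError(f"input for sample {name!r} missing: {path}")
        tables.append(uio.read_cpg_counts(path, config.dialect))
    matrix = uio.harmonize_samples(tables, names)
    reporting_control = (
        config.reporting_pair[1] if config.reporting_pair else controls[0]
    )
    return run_athero_from_matrix(
        matrix,
        case,
        controls,
        reporting_control=reporting_control,
        params=config.params,
        outdir=config.outdir,
    )


def run_tissue_analysis(
    matrix: MethylomeMatrix,
    panel: list[str] | None = None,
    params: DmrParams | None = None,
    min_nontarget_present: int | None = None,
    outdir: str | None = None,
) -> dict[str, list[Dmr]]:
    """One-vs-rest tissue DMRs for every member of the panel."""
    params = params or DmrParams()
    panel = panel or list(matrix.samples)
    if len(panel) < 3:
        raise ValueError("tissue panel requires >= 3 samples")
    for s in panel:
        if s not in matrix.samples:
            raise KeyError(f"panel sample {s!r} not in matrix")
    out: dict[str, list[Dmr]] = {}
    for target in panel:
        others = [s for s in panel if s != target]
        cmp = PanelComparison(
            target=target,
            others=others,
            min_nontarget_present=(
                min_nontarget_present if min_nontarget_present is not None else -1
            ),
        )
        out[target] = call_tissue_dmrs(matrix, cmp, params)
        logger.info("tissue target %s: %d DMRs", target, len(out[target]))
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for target, dmrs in out.items():
            uio.write_dmr_bed(dmrs, os.path.join(outdir, f"tissue_{target}.bed"))
    return out
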