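"""Synthetic multi-sample CpG methylomes with planted DMRs.

The generator emulates the statistical structure the DMR workflow assumes:
CpGs arranged in clusters (short within-cluster gaps, kilobase-scale gaps
between clusters), a blockwise baseline methylation landscape shared by all
samples (Beta-distributed regional means, defaulting to a high-methylation
genome with hypomethylated blocks), negative-binomial read coverage, and
binomial methylated-read counts.  Planted regions shift the methylation
probability of designated samples by a known amount at a known run of
sites, recorded in a truth table so that recovery can be scored.

It does not emulate read-level artefacts: no bisulfite-conversion errors,
no strand asymmetry, no copy-number or SNP effects, and no spatial
correlation of coverage.  A green recovery test therefore establishes that
the statistical chain works on data matching its own model, not that the
thresholds are optimal on real methylomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from updmr.annotate import overlap_bp
from updmr.io import ChromCounts, GeneModel, MethylomeMatrix

__all__ = [
    "PlantedRegion",
    "SynthConfig",
    "RecoveryResult",
    "generate_methylome_panel",
    "generate_annotation_fixtures",
    "evaluate_recovery",
]


@dataclass
class PlantedRegion:
    """A differential block of known location and effect size.

    ``delta_pmd`` is in percentage points; positive values hypermethylate
    the ``affected_samples`` relative to the rest.  ``start_index`` pins
    the run to a site index; ``None`` places it at random (non-overlapping
    with other planted runs).
    """

    n_sites: int = 10
    span_bp: int = 600
    delta_pmd: float = 40.0
    affected_samples: tuple[str, ...] = ()
    start_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("planted region needs >= 2 sites")
        if not -98.0 <= self.delta_pmd <= 98.0:
            raise ValueError("delta_pmd must keep fractions inside [0.01, 0.99]")


@dataclass
class SynthConfig:
    """Stated world of the generator; defaults follow the analysed data:
    ~80% genome-wide methylation with hypomethylated blocks, ~30x coverage,
    CpG clusters with ~20 bp internal gaps separated by 1-2 kb."""

    samples: tuple[str, ...] = ("case", "ctrlA", "ctrlB", "ctrlC")
    n_sites: int = 20_000
    chrom: str = "chrS"
    cluster_size_mean: float = 8.0
    within_gap_mean: float = 20.0
    between_gap_mean: float = 1500.0
    block_len_mean_sites: float = 50.0
    baseline_beta: tuple[float, float] = (8.0, 2.0)
    site_jitter_sd: float = 0.03
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.2
    missing_rate: float = 0.0
    planted: tuple[PlantedRegion, ...] = ()
    seed: int = 0


def _geometric_gap(rng: np.random.Generator, mean: float) -> int:
    # CpGs are never closer than 2 bp
    return 2 + int(rng.geometric(1.0 / max(mean - 2.0, 1.0)))


def _place_planted(cfg: SynthConfig, rng: np.random.Generator) -> list[tuple[int, PlantedRegion]]:
    total = sum(r.n_sites for r in cfg.planted)
    if total > cfg.n_sites:
        raise ValueError("planted sites exceed n_sites")
    taken: list[tuple[int, int]] = []
    placed: list[tuple[int, PlantedRegion]] = []
    buffer = 5  # background sites kept between planted runs
    for r in cfg.planted:
        if r.start_index is not None:
            start = r.start_index
            if start + r.n_sites > cfg.n_sites:
                raise ValueError("planted region exceeds n_sites")
        else:
            for _ in range(10_000):
                start = int(rng.integers(0, cfg.n_sites - r.n_sites + 1))
                if all(
                    start + r.n_sites + buffer <= s or e + buffer <= start
                    for s, e in taken
                ):
                    break
            else:
                raise ValueError("could not place planted regions without overlap")
        if any(not (start + r.n_sites <= s or e <= start) for s, e in taken):
            raise ValueError("planted regions overlap")
        taken.append((start, start + r.n_sites))
        placed.append((start, r))
    placed.sort(key=lambda t: t[0])
    return placed


def _positions(cfg: SynthConfig, placed, rng: np.random.Generator) -> np.ndarray:
    pos = np.empty(cfg.n_sites, dtype=np.int64)
    starts = {s: r for s, r in placed}
    cur = 1000
    cluster_left = 0
    i = 0
    while i < cfg.n_sites:
        r = starts.get(i)
        if r is not None:
            cur += _geometric_gap(rng, cfg.between_gap_mean)
            step = max(r.span_bp // (r.n_sites - 1), 2)
            for j in range(r.n_sites):
                pos[i + j] = cur + j * step
            cur = int(pos[i + r.n_sites - 1])
            i += r.n_sites
            cluster_left = 0
            continue
        if cluster_left == 0:
            cur += _geometric_gap(rng, cfg.between_gap_mean)
            cluster_left = 1 + int(rng.geometric(1.0 / cfg.cluster_size_mean))
        else:
            cur += _geometric_gap(rng, cfg.within_gap_mean)
        pos[i] = cur
        cluster_left -= 1
        i += 1
    return pos


def _baseline(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    p = np.empty(cfg.n_sites)
    i = 0
    a, b = cfg.baseline_beta
    while i < cfg.n_sites:
        blk = 1 + int(rng.geometric(1.0 / cfg.block_len_mean_sites))
        j = min(i + blk, cfg.n_sites)
        p[i:j] = rng.beta(a, b)
        i = j
    p += rng.normal(0.0, cfg.site_jitter_sd, size=cfg.n_sites)
    return np.clip(p, 0.01, 0.99)


def generate_methylome_panel(
    cfg: SynthConfig, seed: int | None = None
) -> tuple[MethylomeMatrix, pd.DataFrame]:
    """Simulate the panel; returns ``(matrix, truth_table)``.

    Deterministic for a fixed seed (``cfg.seed`` unless overridden).  The
    truth table has one row per planted region with columns
    ``chrom, start_pos, end_pos, n_sites, delta_pmd, direction,
    affected_samples, positions``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    placed = _place_planted(cfg, rng)
    pos = _positions(cfg, placed, rng)
    base = _baseline(cfg, rng)

    n, s = cfg.n_sites, len(cfg.samples)
    prob = np.repeat(base[:, None], s, axis=1)
    truth_rows = []
    for start, r in placed:
        delta = r.delta_pmd / 100.0
        lo = 0.01 + max(0.0, -delta)
        hi = 0.99 - max(0.0, delta)
        block_base = np.clip(base[start : start + r.n_sites], lo, hi)
        cols_affected = [cfg.samples.index(a) for a in r.affected_samples]
        for j in range(s):
            prob[start : start + r.n_sites, j] = (
                block_base + delta if j in cols_affected else block_base
            )
        truth_rows.append(
            {
                "chrom": cfg.chrom,
                "start_pos": int(pos[start]),
                "end_pos": int(pos[start + r.n_sites - 1]),
                "n_sites": r.n_sites,
                "delta_pmd": r.delta_pmd,
                "direction": "hyper" if r.delta_pmd > 0 else "hypo",
                "affected_samples": ",".join(r.affected_samples),
                "positions": pos[start : start + r.n_sites].tolist(),
            }
        )

    r_nb = 1.0 / cfg.coverage_dispersion
    p_nb = r_nb / (r_nb + cfg.coverage_mean)
    total = rng.negative_binomial(r_nb, p_nb, size=(n, s))
    if cfg.missing_rate > 0:
        total = np.where(rng.random((n, s)) < cfg.missing_rate, 0, total)
    meth = rng.binomial(total, prob)

    keep = total.sum(axis=1) > 0
    matrix = MethylomeMatrix(
        samples=list(cfg.samples),
        chroms=[cfg.chrom],
        data={
            cfg.chrom: ChromCounts(pos=pos[keep], meth=meth[keep], total=total[keep])
        },
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "start_pos",
            "end_pos",
            "n_sites",
            "delta_pmd",
            "direction",
            "affected_samples",
            "positions",
        ],
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# annotation fixtures


def generate_annotation_fixtures(
    seed: int = 0, chrom: str = "chrS", chrom_length: int = 3_000_000
) -> tuple[pd.DataFrame, list[GeneModel]]:
    """A full-coverage 18-state segmentation and an engineered gene table.

    The gene models are fixed (seed-independent) and exercise every
    assignment branch: coding/non-coding body conflict, promoter-vs-body
    precedence, a minus-strand promoter, a short gene with an empty body, a
    lexicographic tie, and a region beyond the nearest-TSS cap.  The
    segmentation lengths and states are drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    start = 0
    while start < chrom_length:
        length = 200 + int(rng.exponential(2000.0))
        end = min(start + length, chrom_length)
        state = int(rng.integers(1, 19))
        rows.append({"chrom": chrom, "start": start, "end": end, "state": state,
                     "label": str(state)})
        start = end
    segments = pd.DataFrame(rows)

    genes = [
        # coding + strand; body overlapped by the non-coding NCRNA1
        GeneModel("ALPHA", "ALPHA.1", chrom, "+", 20_000, 40_000, True),
        GeneModel("NCRNA1", "NCRNA1.1", chrom, "+", 26_000, 39_000, False),
        # coding - strand: promoter window centred on tx_end
        GeneModel("BETA", "BETA.1", chrom, "-", 50_000, 70_000, True),
        # short gene: TES inside the promoter window, empty body
        GeneModel("GAMMA", "GAMMA.1", chrom, "+", 90_000, 92_000, True),
        # DELTA body overlaps EPSILON promoter: precedence conflict
        GeneModel("DELTA", "DELTA.1", chrom, "+", 100_000, 130_000, True),
        GeneModel("EPSILON", "EPSILON.1", chrom, "+", 120_000, 140_000, True),
        # identical spans: lexicographic tie-break
        GeneModel("TIE1", "TIE1.1", chrom, "+", 160_000, 165_000, True),
        GeneModel("TIE2", "TIE2.1", chrom, "+", 160_000, 165_000, True),
    ]
    return segments, genes


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryResult:
    sensitivity: float  # NaN when the truth table is empty
    false_discoveries: int
    n_truth: int
    n_called: int


def evaluate_recovery(
    called, truth: pd.DataFrame, min_reciprocal: float = 0.5
) -> RecoveryResult:
    """Score called DMRs against the planted truth.

    A truth region is recovered when a same-direction call overlaps it
    reciprocally by at least ``min_reciprocal`` of each span; calls
    matching no truth row (at any overlap) count as false discoveries.
    """
    n_truth = len(truth)
    matched = np.zeros(n_truth, dtype=bool)
    fd = 0
    for d in called:
        c_iv = (d.start_pos - 1, d.end_pos)
        c_len = c_iv[1] - c_iv[0]
        hit_any = False
        for t in range(n_truth):
            row = truth.iloc[t]
            if row["chrom"] != d.chrom:
                continue
            t_iv = (row["start_pos"] - 1, row["end_pos"])
            ov = overlap_bp(c_iv, t_iv)
            if ov == 0:
                continue
            hit_any = True
            t_len = t_iv[1] - t_iv[0]
            if (
                row["direction"] == d.direction
                and ov >= min_reciprocal * c_len
                and ov >= min_reciprocal * t_len
            ):
                matched[t] = True
        if not hit_any:
            fd += 1
    sens = float(matched.mean()) if n_truth else float("nan")
    return RecoveryResult(sens, fd, n_truth, len(called))
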