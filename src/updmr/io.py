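"""Readers and writers for CpG count tables, segmentation BEDs and gene models.

Coordinate conventions
----------------------
CpG sites are stored internally as 1-based positions of the cytosine on the
forward strand (the convention of bismark coverage files).  All interval
output (DMR BED, segmentations) is 0-based half-open, so a DMR whose first
and last member CpGs sit at 1-based positions ``s`` and ``e`` is written as
the BED interval ``[s-1, e)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CPG_DIALECTS = ("bismark-cov", "bedgraph-counts")


class CpGSiteRecord(NamedTuple):
    """One CpG with methylated / unmethylated read counts in one sample."""

    chrom: str
    pos: int  # 1-based position of the cytosine
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def fraction(self) -> float:
        return self.n_meth / self.coverage


@dataclass
class ChromatinSegment:
    """A labeled chromatin-state interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    state: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")


@dataclass
class GeneModel:
    """A transcript record used for DMR-to-gene assignment.

    ``tx_start``/``tx_end`` are 0-based half-open. The transcription start
    site is strand dependent: ``tx_start`` on ``+``, ``tx_end - 1`` on ``-``.
    """

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    is_protein_coding: bool

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"empty transcript {self.transcript_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class ChromCounts:
    """Per-chromosome count arrays of a :class:`MethylomeMatrix`.

    ``meth`` and ``total`` have shape ``(n_sites, n_samples)``; a total of
    zero marks the sample as absent at that site.
    """

    pos: np.ndarray  # (n_sites,) 1-based, strictly increasing
    meth: np.ndarray  # (n_sites, n_samples)
    total: np.ndarray  # (n_sites, n_samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def present(self, min_coverage: int = 1) -> np.ndarray:
        """Boolean (n_sites, n_samples) presence mask."""
        return self.total >= max(min_coverage, 1)


@dataclass
class MethylomeMatrix:
    """Genome-ordered per-CpG counts across harmonized samples."""

    samples: list[str]
    chroms: list[str]
    data: dict[str, ChromCounts] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return sum(c.n_sites for c in self.data.values())

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in matrix") from None

    def iter_chromosomes(self) -> Iterable[tuple[str, ChromCounts]]:
        for chrom in self.chroms:
            yield chrom, self.data[chrom]


# ---------------------------------------------------------------------------
# CpG count tables


def read_cpg_counts(path, dialect: str = "bismark-cov") -> pd.DataFrame:
    """Read one sample's CpG counts into a genome-sorted DataFrame.

    Dialects
    --------
    ``bismark-cov``
        ``chrom  start  end  meth%  n_meth  n_unmeth`` with 1-based
        ``start == end``.  The percentage column is ignored; fractions are
        always recomputed from the counts.
    ``bedgraph-counts``
        Four columns ``chrom  start  n_meth  n_unmeth`` with 0-based start
        (site position = start + 1).

    Zero-coverage lines are dropped.  Unsorted input is sorted with a
    warning.  Malformed lines raise ``ValueError`` naming the line number.
    """
    if dialect not in CPG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {CPG_DIALECTS}")
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    n_fields = 6 if dialect == "bismark-cov" else 4
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < n_fields:
                raise ValueError(f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}")
            try:
                if dialect == "bismark-cov":
                    pos = int(parts[1])
                    n_meth, n_unmeth = int(parts[4]), int(parts[5])
                else:
                    pos = int(parts[1]) + 1
                    n_meth, n_unmeth = int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if n_meth + n_unmeth == 0:
                continue
            chroms.append(parts[0])
            poss.append(pos)
            meths.append(n_meth)
            unmeths.append(n_unmeth)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="object"),
            "pos": pd.Series(poss, dtype=np.int64),
            "n_meth": pd.Series(meths, dtype=np.int64),
            "n_unmeth": pd.Series(unmeths, dtype=np.int64),
        }
    )
    if len(df) and not df.groupby("chrom", sort=False)["pos"].is_monotonic_increasing.all():
        warnings.warn(f"{path}: input not sorted by position; sorting", stacklevel=2)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def _merge_shifted_positions(per_sample_pos: list[np.ndarray]) -> dict[int, int]:
    """Map positions that differ by exactly 1 bp across samples onto the
    smaller coordinate.

    Only isolated pairs are unified: a run of >= 3 consecutive coordinates in
    the cross-sample union is ambiguous and left untouched.  A pair where one
    sample itself carries both coordinates (a genuine CpCpG) is kept as two
    sites with a warning.
    """
    union = np.unique(np.concatenate(per_sample_pos))
    mapping: dict[int, int] = {}
    if len(union) < 2:
        return mapping
    # runs of consecutive integers in the union
    breaks = np.flatnonzero(np.diff(union) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(union) - 1]])
    sample_sets = [set(p.tolist()) for p in per_sample_pos]
    for s, e in zip(starts, ends):
        if e - s != 1:  # isolated site or ambiguous >=3-run
            continue
        lo, hi = int(union[s]), int(union[e])
        if any(lo in ss and hi in ss for ss in sample_sets):
            warnings.warn(
                f"positions {lo} and {hi} co-occur within one sample (CpCpG); not merged",
                stacklevel=3,
            )
            continue
        mapping[hi] = lo
    return mapping


def harmonize_samples(
    tables: Sequence[pd.DataFrame],
    samples: Sequence[str] | None = None,
) -> MethylomeMatrix:
    """Align per-sample CpG tables into one :class:`MethylomeMatrix`.

    Sites reported 1 bp apart across samples (the same CpG called on
    opposite strands by different pre-processing routines) are unified to
    the smaller coordinate; no counts are summed. Idempotent.
    """
    if len(tables) < 2:
        raise ValueError("harmonize_samples requires >= 2 samples")
    if samples is None:
        samples = [f"sample{i}" for i in range(len(tables))]
    if len(samples) != len(tables):
        raise ValueError("one name per table required")
    chrom_order: list[str] = []
    for t in tables:
        for c in t["chrom"].unique():
            if c not in chrom_order:
                chrom_order.append(c)
    data: dict[str, ChromCounts] = {}
    n = len(tables)
    for chrom in chrom_order:
        subs = [t[t["chrom"] == chrom] for t in tables]
        per_pos = [s["pos"].to_numpy() for s in subs]
        mapping = _merge_shifted_positions([p for p in per_pos if len(p)])
        mapped = [np.array([mapping.get(int(p), int(p)) for p in pp], dtype=np.int64) for pp in per_pos]
        final_pos = np.unique(np.concatenate(mapped)) if any(len(m) for m in mapped) else np.empty(0, np.int64)
        meth = np.zeros((len(final_pos), n), dtype=np.int64)
        total = np.zeros((len(final_pos), n), dtype=np.int64)
        for j, (sub, mp) in enumerate(zip(subs, mapped)):
            idx = np.searchsorted(final_pos, mp)
            np.add.at(meth[:, j], idx, sub["n_meth"].to_numpy())
            np.add.at(total[:, j], idx, sub["n_meth"].to_numpy() + sub["n_unmeth"].to_numpy())
        data[chrom] = ChromCounts(pos=final_pos, meth=meth, total=total)
    return MethylomeMatrix(samples=list(samples), chroms=chrom_order, data=data)


def matrix_to_tables(matrix: MethylomeMatrix) -> list[pd.DataFrame]:
    """Explode a matrix back to per-sample count tables (absent sites dropped)."""
    out = []
    for j in range(len(matrix.samples)):
        frames = []
        for chrom, cc in matrix.iter_chromosomes():
            keep = cc.total[:, j] > 0
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": cc.pos[keep],
                        "n_meth": cc.meth[keep, j],
                        "n_unmeth": cc.total[keep, j] - cc.meth[keep, j],
                    }
                )
            )
        out.append(pd.concat(frames, ignore_index=True) if frames else pd.DataFrame())
    return out


def write_cpg_counts(df: pd.DataFrame, path, dialect: str = "bismark-cov") -> None:
    """Write a count table in one of the dialects :func:`read_cpg_counts` reads."""
    if dialect not in CPG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            cov = row.n_meth + row.n_unmeth
            if dialect == "bismark-cov":
                pct = 100.0 * row.n_meth / cov if cov else 0.0
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:.6g}\t{row.n_meth}\t{row.n_unmeth}\n")
            else:
                fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.n_meth}\t{row.n_unmeth}\n")


# ---------------------------------------------------------------------------
# DMR BED

DMR_BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "n_sites",
    "up_p",
    "mean_pmd",
    "direction",
    "enhancer_overlap_bp",
    "tissue_overlaps",
]


def write_dmr_bed(dmrs, path, annotation: pd.DataFrame | None = None) -> None:
    """Write called DMRs as a BED6+ file (0-based half-open intervals).

    ``name`` is the linked gene when an annotation table is supplied
    (column ``gene_name``), else ``"."``; ``score`` is ``round(|mean_pmd|)``.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMR_BED_COLUMNS) + "\n")
        for i, d in enumerate(dmrs):
            gene, enh_bp, tissues = ".", 0, "."
            if annotation is not None and i < len(annotation):
                row = annotation.iloc[i]
                gene = str(row.get("gene_name", "."))
                enh_bp = int(row.get("enh_overlap_bp", 0))
                tissues = str(row.get("tissue_overlaps", ".")) or "."
            fh.write(
                "\t".join(
                    [
                        d.chrom,
                        str(d.start_pos - 1),
                        str(d.end_pos),
                        gene,
                        str(round(abs(d.mean_pmd))),
                        ".",
                        str(d.k),
                        format(d.up_p, ".17g"),
                        format(d.mean_pmd, ".17g"),
                        d.direction,
                        str(enh_bp),
                        tissues,
                    ]
                )
                + "\n"
            )


def read_dmr_bed(path) -> pd.DataFrame:
    """Read a DMR BED written by :func:`write_dmr_bed`."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=DMR_BED_COLUMNS,
        skiprows=1,
        float_precision="round_trip",
    )
    return df


# ---------------------------------------------------------------------------
# chromHMM segmentation / refFlat


def read_chromhmm_bed(path) -> pd.DataFrame:
    """Read a chromHMM segmentation BED (``chrom start end state``).

    The state field may be a bare number (``9``) or a numbered label
    (``9_EnhA1``); the leading number is parsed into the ``state`` column
    and the full string kept as ``label``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 fields")
            state_str = parts[3]
            num = state_str.split("_")[0]
            try:
                start, end, state = int(parts[1]), int(parts[2]), int(num)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: cannot parse state {state_str!r}") from None
            rows.append((parts[0], start, end, state, state_str))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "label"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_chromhmm_bed(segments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in segments.itertuples(index=False):
            label = getattr(row, "label", "") or str(row.state)
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{label}\n")


def read_refflat(path) -> list[GeneModel]:
    """Read an 11-column refFlat gene table.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds. A transcript is protein
    coding iff ``cdsStart < cdsEnd``.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 tab-separated fields")
            try:
                tx_start, tx_end = int(parts[4]), int(parts[5])
                cds_start, cds_end = int(parts[6]), int(parts[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            genes.append(
                GeneModel(
                    gene_name=parts[0],
                    transcript_id=parts[1],
                    chrom=parts[2],
                    strand=parts[3],
                    tx_start=tx_start,
                    tx_end=tx_end,
                    is_protein_coding=cds_start < cds_end,
                )
            )
    return genes


def write_refflat(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cds = (g.tx_start, g.tx_end) if g.is_protein_coding else (g.tx_start, g.tx_start)
            fh.write(
                "\t".join(
                    [
                        g.gene_name,
                        g.transcript_id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(cds[0]),
                        str(cds[1]),
                        "1",
                        f"{g.tx_start},",
                        f"{g.tx_end},",
                    ]
                )
                + "\n"
            )
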