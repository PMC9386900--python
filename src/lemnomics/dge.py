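"""Adaptive-threshold DEG calling and core-set fingerprinting.

Operates on externally produced differential-expression tables (one row per
gene: normalized mean expression, raw and shrunk log2 fold change, p-value,
BH-adjusted p-value). A gene is called differentially expressed when it
passes both a statistical criterion (padj <= alpha) and an adaptive
effect-size criterion |shrunk lfc| >= LFcut, where LFcut is the 0.75
quantile of the absolute *non-shrunk* fold changes of the contrast. DEG
sets from a low and a high effect concentration are intersected into a
"core" fingerprint of early, consistently regulated genes; fingerprints are
compared across measurement levels (quadrant concordance, correlation) and
across compounds (overlap shares).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DGE_COLUMNS = ("gene_id", "mean_expression", "lfc_raw", "lfc_shrunk", "pvalue", "padj")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def read_dge_table(path: str | Path) -> pd.DataFrame:
    """Read a per-contrast differential-expression TSV.

    Requires the columns gene_id, mean_expression, lfc_raw, lfc_shrunk,
    pvalue, padj; missing values are allowed in the statistics columns.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id rows")
    return df


@dataclass
class DegSet:
    """Genes passing the dual DEG criterion for one contrast."""

    label: str
    lfcut: float
    genes: dict[str, str]  # gene_id -> "up" | "down"

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes)

    @property
    def up(self) -> set[str]:
        return {g for g, d in self.genes.items() if d == "up"}

    @property
    def down(self) -> set[str]:
        return {g for g, d in self.genes.items() if d == "down"}


def compute_lfcut(
    lfc_raw: Sequence[float] | np.ndarray | pd.Series, quantile: float = 0.75
) -> float:
    """Adaptive effect-size threshold: 0.75 quantile of |raw lfc|.

    Missing values are dropped first; the quantile uses order statistics with
    linear interpolation at rank h = (n - 1) * q + 1.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    x = np.asarray(lfc_raw, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("cannot compute LFcut: no finite lfc values")
    if x.size < 4:
        raise ValueError(f"cannot compute LFcut: need >= 4 finite values, got {x.size}")
    return float(np.quantile(np.abs(x), quantile))


def call_degs(
    table: pd.DataFrame,
    alpha: float = 0.05,
    label: str = "",
    lfcut_quantile: float = 0.75,
) -> DegSet:
    """Call DEGs by the dual criterion padj <= alpha AND |shrunk lfc| >= LFcut.

    Genes with missing padj (e.g. removed by upstream independent filtering)
    are never DEGs. Direction is the sign of the shrunk fold change.
    """
    lfcut = compute_lfcut(table["lfc_raw"], quantile=lfcut_quantile)
    padj = pd.to_numeric(table["padj"], errors="coerce")
    shrunk = pd.to_numeric(table["lfc_shrunk"], errors="coerce")
    passing = (padj <= alpha) & shrunk.abs().ge(lfcut) & shrunk.notna()
    genes = {
        str(g): ("up" if l > 0 else "down")
        for g, l in zip(table.loc[passing, "gene_id"], shrunk[passing])
    }
    return DegSet(label=label, lfcut=lfcut, genes=genes)


class DirectionSummary(NamedTuple):
    n_up: int
    n_down: int
    pct_up: int
    pct_down: int


def direction_summary(degs: DegSet) -> DirectionSummary:
    """Counts and integer percentages of up- and downregulated DEGs."""
    n_up, n_down = len(degs.up), len(degs.down)
    total = n_up + n_down
    if total == 0:
        return DirectionSummary(0, 0, 0, 0)
    return DirectionSummary(
        n_up,
        n_down,
        _round_half_up(100.0 * n_up / total),
        _round_half_up(100.0 * n_down / total),
    )


@dataclass
class CoreSet:
    """Intersection of low- and high-concentration DEG sets."""

    genes: set[str]
    n_low: int
    n_high: int
    pct_of_low: int
    pct_of_high: int
    label: str = ""


def core_set(degs_low: DegSet, degs_high: DegSet, label: str = "") -> CoreSet:
    """Core DEG set: genes differentially expressed at both concentrations.

    Overlap percentages are relative to each parent set and rounded to the
    nearest integer.
    """
    inter = degs_low.gene_ids & degs_high.gene_ids
    n_low, n_high = len(degs_low), len(degs_high)
    return CoreSet(
        genes=inter,
        n_low=n_low,
        n_high=n_high,
        pct_of_low=_round_half_up(100.0 * len(inter) / n_low) if n_low else 0,
        pct_of_high=_round_half_up(100.0 * len(inter) / n_high) if n_high else 0,
        label=label,
    )


def overlap_percent(n_intersection: int, n_parent: int) -> int:
    """Share of a parent set covered by an intersection, nearest integer."""
    if n_parent <= 0:
        return 0
    return _round_half_up(100.0 * n_intersection / n_parent)


class PearsonResult(NamedTuple):
    r: float
    pvalue: float
    n: int


def pearson(lfc_a: Sequence[float], lfc_b: Sequence[float]) -> PearsonResult:
    """Sample Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(a, b)
    return PearsonResult(r=float(res.statistic), pvalue=float(res.pvalue), n=int(a.size))


def quadrant_concordance(
    lfc_a: Sequence[float], lfc_b: Sequence[float]
) -> float:
    """Positive quadrant count ratio of two paired fold-change vectors.

    QCR = #{i : a_i * b_i > 0} / #{i : a_i * b_i != 0}; pairs with a zero
    product do not enter the denominator. Returns NaN when no pair has a
    nonzero product. Non-finite pairs are dropped.
    """
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    prod = a[keep] * b[keep]
    nonzero = prod != 0
    if not nonzero.any():
        return float("nan")
    return float(np.count_nonzero(prod > 0) / np.count_nonzero(nonzero))


@dataclass
class CompoundComparison:
    """Cross-compound overlap of two core DEG fingerprints."""

    intersection: set[str]
    pct_of_a: int
    pct_of_b: int
    only_a: set[str]
    only_b: set[str]


def compare_compounds(core_a: CoreSet | set[str], core_b: CoreSet | set[str]) -> CompoundComparison:
    """Intersect two compounds' core DEG sets and report each share.

    Also exports the compound-specific sets (core minus intersection), the
    discriminating part of each fingerprint.
    """
    a = core_a.genes if isinstance(core_a, CoreSet) else set(core_a)
    b = core_b.genes if isinstance(core_b, CoreSet) else set(core_b)
    inter = a & b
    return CompoundComparison(
        intersection=inter,
        pct_of_a=overlap_percent(len(inter), len(a)),
        pct_of_b=overlap_percent(len(inter), len(b)),
        only_a=a - inter,
        only_b=b - inter,
    )


def select_top_expressed(
    core_genes: Sequence[str] | set[str],
    mean_expression: Mapping[str, float] | pd.Series,
    k: int = 50,
) -> list[str]:
    """Top-k core DEGs by control mean expression, descending.

    Ties broken by gene id for determinism. If fewer than k genes are
    available, all are returned with a logged note.
    """
    if isinstance(mean_expression, pd.Series):
        mean_expression = mean_expression.to_dict()
    missing = [g for g in core_genes if g not in mean_expression]
    if missing:
        raise ValueError(f"mean expression missing for gene(s): {sorted(missing)[:5]}")
    ordered = sorted(core_genes, key=lambda g: (-float(mean_expression[g]), g))
    if len(ordered) < k:
        logger.info(
            "only %d core genes available (requested top %d); returning all",
            len(ordered), k,
        )
    return ordered[:k]


def recovery_percent(nominal: float, measured: float) -> float:
    """Measured over nominal concentration, in percent, one decimal."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be > 0")
    return math.floor(100.0 * measured / nominal * 10 + 0.5) / 10
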