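"""Two-condition differential-expression screening and phase set logic.

Quantile normalization, a Welch t-test on log2 intensities with optional
variance moderation, Benjamini–Hochberg adjustment, and the intersection /
subtraction set logic that defines the phase gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "DEGRecord",
    "quantile_normalize",
    "test_differential",
    "adjust_bh",
    "initiation_gene_set",
    "commitment_gene_set",
    "deg_table",
]


@dataclass
class ExpressionDataset:
    """Gene x sample intensity matrix (linear scale) with condition labels."""

    matrix: pd.DataFrame  # rows = genes, columns = samples
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.matrix.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (self.matrix.values <= 0).any():
            raise ValueError("all intensities must be > 0 before log transform")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.matrix.columns if self.condition_of[s] == condition]


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2FC: float
    p_raw: float
    p_adj: float
    direction: str  # up | down | ns


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same distribution (mean of sorted columns).

    Ties within a column receive the average of the reference values at the
    tied ranks. Idempotent, label-preserving.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    if matrix.isna().any().any():
        raise ValueError("missing values are not supported")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = np.apply_along_axis(stats.rankdata, 0, values)  # average-tie ranks
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def test_differential(
    dataset: ExpressionDataset,
    control: str,
    treatment: str,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    moderation: float = 0.0,
) -> list[DEGRecord]:
    """Per-gene Welch t-test on log2, quantile-normalized intensities.

    ``moderation`` in [0, 1) shrinks each gene's per-group variance toward
    the mean per-group variance across genes before forming the statistic
    (0 = plain Welch). log2FC is treatment minus control on the log2 scale;
    direction is called at BH-adjusted p < alpha and |log2FC| > lfc_min.
    """
    for label in (control, treatment):
        n = len(dataset.samples_for(label))
        if n < 2:
            raise ValueError(f"condition {label!r} has {n} samples; need >= 2")
    if not 0.0 <= moderation < 1.0:
        raise ValueError("moderation must be in [0, 1)")

    log2m = quantile_normalize(np.log2(dataset.matrix))
    xc = log2m[dataset.samples_for(control)].to_numpy()
    xt = log2m[dataset.samples_for(treatment)].to_numpy()
    nc, nt = xc.shape[1], xt.shape[1]

    mean_c, mean_t = xc.mean(axis=1), xt.mean(axis=1)
    var_c = xc.var(axis=1, ddof=1)
    var_t = xt.var(axis=1, ddof=1)
    if moderation > 0.0:
        var_c = (1 - moderation) * var_c + moderation * var_c.mean()
        var_t = (1 - moderation) * var_t + moderation * var_t.mean()

    lfc = mean_t - mean_c
    se2_c, se2_t = var_c / nc, var_t / nt
    se2 = se2_c + se2_t
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = lfc / np.sqrt(se2)
        df = se2**2 / (se2_c**2 / (nc - 1) + se2_t**2 / (nt - 1))
    # constant genes: no evidence either way
    t_stat = np.where(se2 > 0, t_stat, 0.0)
    df = np.where(se2 > 0, df, 1.0)
    p_raw = 2.0 * stats.t.sf(np.abs(t_stat), df)
    p_adj = np.asarray(adjust_bh(p_raw))

    records = []
    for gene, fc, pr, pa in zip(dataset.gene_ids, lfc, p_raw, p_adj):
        if pa < alpha and fc > lfc_min:
            direction = "up"
        elif pa < alpha and fc < -lfc_min:
            direction = "down"
        else:
            direction = "ns"
        records.append(DEGRecord(gene, float(fc), float(pr), float(pa), direction))
    return records


test_differential.__test__ = False  # not a pytest test despite the name


def deg_table(records: Iterable[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.log2FC, r.p_raw, r.p_adj, r.direction) for r in records],
        columns=["gene_id", "log2FC", "p_raw", "p_adj", "direction"],
    )


def _up_set(records: Iterable[DEGRecord]) -> set[str]:
    return {r.gene_id for r in records if r.direction == "up"}


def initiation_gene_set(deg_runs: Sequence[Sequence[DEGRecord]]) -> set[str]:
    """Intersection of the upregulated genes across >= 2 DEG runs."""
    if not deg_runs:
        raise ValueError("need at least one DEG run")
    sets = [_up_set(run) for run in deg_runs]
    common = set.intersection(*sets)
    if not common:
        logger.warning("upregulated sets are disjoint; empty intersection")
    logger.info(
        "initiation set: %s from up-set sizes %s", len(common), [len(s) for s in sets]
    )
    return common


def commitment_gene_set(
    up_committed: set[str], down_on_return: set[str]
) -> set[str]:
    """Up-in-committed genes minus those down-regulated on return to growth."""
    overlap = up_committed & down_on_return
    result = up_committed - down_on_return
    logger.info(
        "commitment set: |up|=%d |down|=%d |overlap|=%d -> |result|=%d",
        len(up_committed), len(down_on_return), len(overlap), len(result),
    )
    return result
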