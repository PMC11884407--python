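"""Per-cell cytotoxicity scoring and per-(tumor, subset) aggregation.

The score is the classic bin-matched control-gene module score: the mean
log-normalized expression of the 7 effector genes (NKG7, CCL5, CST7, PRF1,
GZMA, GZMB, IFNG) minus the mean of control genes sampled from matching
average-expression bins. Subtracting bin-matched controls removes the
depth/complexity component a plain mean would carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from suppressor_screen.io import CellCohort
from suppressor_screen.simulate import CYTOTOX_GENES


def normalize_log(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Depth-normalize each cell to ``target_sum`` and apply log1p.

    All-zero cells yield all-zero columns (with a warning) rather than NaN.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero cells normalized to all-zero columns",
            stacklevel=2,
        )
        totals[zero] = 1.0
    return np.log1p(counts * (target_sum / totals)[None, :])


def module_score(
    lognorm: np.ndarray,
    gene_ids: Sequence[str],
    gene_set: Sequence[str] = CYTOTOX_GENES,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched control module score per cell.

    Genes are ranked by mean expression across cells and cut into ``n_bins``
    equal-size quantile bins; for each score gene, ``n_ctrl`` control genes
    are drawn (seeded, without replacement up to bin size) from its bin.
    Score = mean over score genes - mean over all sampled controls.
    """
    gene_ids = list(gene_ids)
    missing = [g for g in gene_set if g not in gene_ids]
    if missing:
        raise KeyError(f"score genes absent from matrix: {missing}")
    n_genes = len(gene_ids)
    if n_genes < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes, have {n_genes}")

    gidx = {g: i for i, g in enumerate(gene_ids)}
    set_rows = np.array([gidx[g] for g in gene_set])
    means = np.asarray(lognorm).mean(axis=1)
    # equal-size quantile bins via the rank of each gene's mean (stable order)
    order = np.argsort(means, kind="stable")
    ranks = np.empty(n_genes, dtype=int)
    ranks[order] = np.arange(n_genes)
    bins = (ranks * n_bins) // n_genes

    rng = np.random.default_rng(seed)
    set_mask = np.zeros(n_genes, dtype=bool)
    set_mask[set_rows] = True
    ctrl_rows: list[np.ndarray] = []
    for row in set_rows:
        pool = np.flatnonzero((bins == bins[row]) & ~set_mask)
        if pool.size == 0:
            pool = np.flatnonzero(bins == bins[row])
        take = min(n_ctrl, pool.size)
        ctrl_rows.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.concatenate(ctrl_rows)
    return lognorm[set_rows].mean(axis=0) - lognorm[ctrl].mean(axis=0)


def aggregate_scores(
    per_cell: np.ndarray,
    cohort: CellCohort,
    subset_filter: Sequence[str],
    min_cells: int = 5,
) -> pd.DataFrame:
    """Mean per-cell score per (tumor, subset); small groups become NaN.

    Groups with fewer than ``min_cells`` cells are emitted as missing so
    downstream cross-tumor correlations drop them listwise.
    """
    subset_filter = list(subset_filter)
    if not subset_filter:
        raise ValueError("subset_filter must name at least one subset")
    unknown = set(subset_filter) - set(cohort.subsets)
    if unknown:
        raise ValueError(f"subsets not in cohort: {sorted(unknown)}")
    per_cell = np.asarray(per_cell, dtype=float)
    df = pd.DataFrame(
        {
            "tumor_id": cohort.tumor_id,
            "subset": cohort.subset,
            "score": per_cell,
        }
    )
    df = df[df["subset"].isin(subset_filter)]
    grouped = df.groupby(["tumor_id", "subset"], sort=True)["score"].agg(
        ["mean", "size"]
    )
    grouped.loc[grouped["size"] < min_cells, "mean"] = np.nan
    table = grouped["mean"].unstack("subset")
    table = table.reindex(index=sorted(cohort.tumors), columns=subset_filter)
    table.index.name = "tumor_id"
    return table


@dataclass
class CytotoxicityScore:
    """Per-cell scores plus their per-(tumor, subset) aggregation."""

    per_cell: np.ndarray
    per_group: pd.DataFrame
    gene_set: tuple[str, ...] = CYTOTOX_GENES
    params: dict = field(default_factory=dict)


def score_cohort(
    cohort: CellCohort,
    lognorm: np.ndarray | None = None,
    gene_set: Sequence[str] = CYTOTOX_GENES,
    receivers: Sequence[str] = ("NK", "CD8T", "gdT"),
    n_bins: int = 25,
    n_ctrl: int = 100,
    min_cells: int = 5,
    seed: int = 0,
) -> CytotoxicityScore:
    """Normalize (if needed), score every cell, and aggregate per group."""
    if lognorm is None:
        lognorm = normalize_log(cohort.counts)
    per_cell = module_score(
        lognorm, cohort.gene_ids, gene_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
    )
    per_group = aggregate_scores(per_cell, cohort, receivers, min_cells=min_cells)
    return CytotoxicityScore(
        per_cell=per_cell,
        per_group=per_group,
        gene_set=tuple(gene_set),
        params={"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed, "min_cells": min_cells},
    )
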