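"""The suppressor screen: negative-correlation overlay on inferred interactions.

For every (ligand, sender, receiver) channel, the ligand's per-tumor mean
expression in sender cells is correlated across tumors with the receiver
subset's per-tumor mean cytotoxicity score. A channel survives when the
correlation is significantly negative (r < 0, p < alpha) AND the channel's
interaction permutation p-value is < alpha. Surviving channels are grouped
per (ligand, sender); a candidate is selected when the sum of its r values
over the three receiver subsets is negative (missing or undefined r
contributes 0) — at least one significant channel is enough for inclusion.

No multiple-testing correction is applied at this stage; raw alpha filters
are the screen's operating point, with an optional Benjamini-Hochberg flag.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from suppressor_screen.io import CellCohort

DEFAULT_RECEIVERS = ("NK", "CD8T", "gdT")


def per_tumor_sender_means(
    cohort: CellCohort,
    lognorm: np.ndarray,
    gene: str,
    sender: str,
    min_cells: int = 5,
) -> pd.Series:
    """Mean log-normalized expression of ``gene`` in ``sender`` cells per
    tumor; tumors with fewer than ``min_cells`` sender cells are NaN."""
    row = cohort.gene_index(gene)
    vals = np.asarray(lognorm)[row]
    out = {}
    for t in cohort.tumors:
        idx = np.flatnonzero((cohort.tumor_id == t) & (cohort.subset == sender))
        out[t] = vals[idx].mean() if idx.size >= min_cells else np.nan
    return pd.Series(out, name=gene)


def cross_tumor_correlation(
    ligand_by_tumor: pd.Series | np.ndarray,
    cytotox_by_tumor: pd.Series | np.ndarray,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlation over tumors with two-sided p; listwise NaN drop.

    Constant input on either side yields (nan, nan, n) with a warning
    rather than an exception, so the caller can emit a non-passing record.
    """
    x = np.asarray(ligand_by_tumor, dtype=float)
    y = np.asarray(cytotox_by_tumor, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need >= 3 paired tumors, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return (np.nan, np.nan, n)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return (float(r), float(p), n)


def run_screen(
    cohort: CellCohort,
    lognorm: np.ndarray,
    interactions: pd.DataFrame,
    per_group_scores: pd.DataFrame,
    alpha: float = 0.05,
    min_cells: int = 5,
    method: str = "pearson",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Build one ScreenRecord row per tested (ligand, sender, receiver).

    ``interactions`` is the output of
    :func:`suppressor_screen.interactions.infer_interactions`;
    ``per_group_scores`` the tumors x receiver-subsets score table from
    :func:`suppressor_screen.scoring.aggregate_scores`.
    """
    records = []
    sender_means_cache: dict[tuple[str, str], pd.Series] = {}
    for _, row in interactions.iterrows():
        ligand, sender, receiver = row["ligand"], row["sender"], row["receiver"]
        if receiver not in per_group_scores.columns:
            continue
        key = (ligand, sender)
        if key not in sender_means_cache:
            sender_means_cache[key] = per_tumor_sender_means(
                cohort, lognorm, ligand, sender, min_cells=min_cells
            )
        lig = sender_means_cache[key]
        cyt = per_group_scores[receiver].reindex(lig.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p, n = cross_tumor_correlation(lig, cyt, method=method)
        records.append(
            {
                "ligand": ligand,
                "sender": sender,
                "receiver": receiver,
                "r": r,
                "r_pvalue": p,
                "interaction_pvalue": float(row["pvalue"]),
                "n_tumors_used": n,
            }
        )
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "ligand", "sender", "receiver", "r", "r_pvalue",
                "interaction_pvalue", "n_tumors_used",
                "passes_correlation", "passes_interaction",
            ]
        )
    r_p = df["r_pvalue"].copy()
    if bh_correct:
        ok = r_p.notna()
        r_p.loc[ok] = stats.false_discovery_control(r_p[ok].to_numpy())
    df["passes_correlation"] = (df["r"] < 0) & (r_p < alpha)
    df["passes_correlation"] = df["passes_correlation"].fillna(False)
    df["passes_interaction"] = df["interaction_pvalue"] < alpha
    return df


def overlay_select(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group records per (ligand, sender) and apply the negative-sum rule.

    ``sum_r`` sums the defined correlations over all receiver subsets
    (missing contributes 0); ``selected`` requires at least one channel
    passing both the correlation and interaction filters AND ``sum_r < 0``.
    """
    cols = ["ligand", "sender", "sum_r", "n_receivers", "receivers_hit", "selected"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    out = []
    for (ligand, sender), grp in records.groupby(["ligand", "sender"], sort=True):
        both = grp["passes_correlation"] & grp["passes_interaction"]
        sum_r = float(np.nansum(grp["r"].to_numpy())) if grp["r"].notna().any() else 0.0
        hits = sorted(grp.loc[both, "receiver"].tolist())
        out.append(
            {
                "ligand": ligand,
                "sender": sender,
                "sum_r": sum_r,
                "n_receivers": int(grp["receiver"].nunique()),
                "receivers_hit": ",".join(hits),
                "selected": bool(both.any()) and sum_r < 0,
            }
        )
    return pd.DataFrame(out, columns=cols)


def annotate_secreted(
    candidates: pd.DataFrame, secreted_genes: Sequence[str]
) -> pd.DataFrame:
    """Flag candidates whose ligand is in the secreted-protein list.

    Annotation only — candidates are never filtered on this flag. Matching
    is exact and case-sensitive; a case-insensitive-only match triggers a
    warning so symbol-case problems surface instead of silently failing.
    """
    secreted = list(secreted_genes)
    candidates = candidates.copy()
    if not secreted:
        warnings.warn("empty secreted-gene list: all candidates flagged False", stacklevel=2)
        candidates["secreted"] = False
        return candidates
    exact = set(secreted)
    lower = {g.lower() for g in secreted}
    flags = []
    for lig in candidates["ligand"]:
        hit = lig in exact
        if not hit and lig.lower() in lower:
            warnings.warn(
                f"{lig!r} matches the secreted list only case-insensitively; "
                "treated as not secreted (supply an alias map to fix)",
                stacklevel=2,
            )
        flags.append(hit)
    candidates["secreted"] = flags
    return candidates
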