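"""iBAQ computation and abundance ranking of secretome / whole-cell proteomes.

iBAQ here is the protein's non-normalized intensity divided by its number of
measurable peptides, a proxy for molar abundance. Proteins are ranked per
sample by descending iBAQ; top-k membership and worst-case percentile across
samples support "top 100" / "top X%" abundance statements.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from suppressor_screen.io import ProteomicsTable


def compute_ibaq(table: ProteomicsTable) -> ProteomicsTable:
    """Fill missing iBAQ as intensity / n_peptides.

    Rows with a precomputed iBAQ pass through unchanged; if a precomputed
    value disagrees with intensity/n_peptides by more than 1%, a warning is
    raised and the precomputed value wins.
    """
    df = table.data.copy()
    derivable = df["intensity"].notna() & df["n_peptides"].notna()
    derived = df.loc[derivable, "intensity"] / df.loc[derivable, "n_peptides"]
    pre = df["ibaq"].notna() & derivable
    if pre.any():
        rel = np.abs(df.loc[pre, "ibaq"] - derived[pre]) / np.maximum(
            derived[pre].abs(), 1e-300
        )
        bad = rel > 0.01
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} rows: precomputed iBAQ deviates >1% from "
                "intensity/n_peptides; precomputed value kept",
                stacklevel=2,
            )
    fill = df["ibaq"].isna() & derivable
    df.loc[fill, "ibaq"] = derived[fill]
    return ProteomicsTable(df)


def rank_and_report(
    table: ProteomicsTable,
    genes_of_interest: Sequence[str],
    k: int = 100,
) -> pd.DataFrame:
    """Per-sample descending-iBAQ ranks for the genes of interest.

    Rank 1 is the most abundant protein; ties break by protein_id
    (lexicographic, stable). A gene detected by several proteins takes its
    best (smallest) rank. Detection means a row with iBAQ > 0;
    ``consensus_all_samples`` is True when the gene is detected in every
    sample and in the top k of each.
    """
    table = compute_ibaq(table)
    df = table.data
    samples = table.sample_ids
    if not samples:
        raise ValueError("proteomics table has no samples")

    per_sample_ranks: dict[str, pd.DataFrame] = {}
    for s in samples:
        sub = df[df["sample_id"] == s].copy()
        sub = sub.sort_values(
            ["ibaq", "protein_id"], ascending=[False, True], kind="stable"
        )
        sub["rank"] = np.arange(1, len(sub) + 1)
        sub["n_proteins"] = len(sub)
        per_sample_ranks[s] = sub

    rows = []
    for gene in genes_of_interest:
        detected_in = []
        for s in samples:
            sub = per_sample_ranks[s]
            hit = sub[(sub["gene"] == gene) & (sub["ibaq"] > 0)]
            if len(hit):
                detected_in.append(s)
        for s in samples:
            sub = per_sample_ranks[s]
            hit = sub[(sub["gene"] == gene) & (sub["ibaq"] > 0)]
            n_prot = int(sub["n_proteins"].iloc[0]) if len(sub) else 0
            if len(hit):
                best = hit.loc[hit["rank"].idxmin()]
                rank = int(best["rank"])
                rows.append(
                    {
                        "sample_id": s,
                        "gene": gene,
                        "ibaq": float(best["ibaq"]),
                        "rank": rank,
                        "n_proteins": n_prot,
                        "percentile": 100.0 * rank / n_prot,
                        "in_top_k": rank <= k,
                        "detected": True,
                    }
                )
            else:
                rows.append(
                    {
                        "sample_id": s,
                        "gene": gene,
                        "ibaq": np.nan,
                        "rank": np.nan,
                        "n_proteins": n_prot,
                        "percentile": np.nan,
                        "in_top_k": False,
                        "detected": False,
                    }
                )
    out = pd.DataFrame(rows)
    consensus = {}
    for gene, grp in out.groupby("gene"):
        consensus[gene] = bool(grp["detected"].all() and grp["in_top_k"].all())
    out["consensus_all_samples"] = out["gene"].map(consensus)
    return out


def percentile_summary(
    reports: pd.DataFrame, genes_of_interest: Sequence[str] | None = None
) -> pd.DataFrame:
    """Worst (max) abundance percentile across samples per gene.

    The max-over-samples convention makes "top X%" claims hold in every
    sample where the gene was detected; genes missing from some samples are
    flagged rather than dropped.
    """
    if reports.empty:
        raise ValueError("empty rank report")
    genes = (
        list(genes_of_interest)
        if genes_of_interest is not None
        else list(pd.unique(reports["gene"]))
    )
    rows = []
    for gene in genes:
        grp = reports[reports["gene"] == gene]
        det = grp[grp["detected"]]
        rows.append(
            {
                "gene": gene,
                "max_percentile": float(det["percentile"].max()) if len(det) else np.nan,
                "n_samples_detected": int(len(det)),
                "n_samples": int(len(grp)),
                "detected_in_all": bool(len(det) == len(grp) and len(grp) > 0),
            }
        )
    return pd.DataFrame(rows)
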