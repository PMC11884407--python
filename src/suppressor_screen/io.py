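"""Shared data model and readers/writers for every format the pipeline touches.

Containers are small validated dataclasses rather than heavyweight objects:
the pipeline needs strict invariants (no duplicate gene symbols, declared
matrix orientation, exact round trips) on modest matrices, and silent
coercion is the classic failure mode this module exists to prevent.

Gene identifiers are symbols (MIF, MDK, NKG7, ...) matched case-sensitively.
Bulk expression is always linear scale (RPM-like); any log transform happens
inside downstream operations, never on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an input file violates the documented contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _check_unique(names: Sequence[str], what: str) -> None:
    ser = pd.Series(list(names))
    dup = ser[ser.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate {what}: {dup}")


@dataclass
class CellCohort:
    """Multi-tumor scRNA-seq counts with per-cell subset and tumor labels.

    ``counts`` is genes x cells, non-negative integer. ``subset`` holds the
    annotated cell-type label (e.g. "tumor", "NK", "CD8T", "gdT", "myeloid")
    and ``tumor_id`` the sample of origin; both are one label per cell.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    subset: np.ndarray
    tumor_id: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise FormatError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.subset = np.asarray(self.subset, dtype=object)
        self.tumor_id = np.asarray(self.tumor_id, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(self.subset) != n_cells or len(self.tumor_id) != n_cells:
            raise FormatError("subset/tumor_id must have one label per cell")
        _check_unique(self.gene_ids, "gene symbols")
        _check_unique(self.cell_ids, "cell barcodes")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def subsets(self) -> list[str]:
        return sorted(set(self.subset))

    @property
    def tumors(self) -> list[str]:
        return sorted(set(self.tumor_id))

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in cohort") from None

    def cells_of(self, subset: str) -> np.ndarray:
        return np.flatnonzero(self.subset == subset)


@dataclass(frozen=True)
class LRPair:
    """A ligand -> receptor(-complex) channel from the interaction database."""

    ligand: str
    receptor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ligand:
            raise FormatError("empty ligand symbol")
        if not self.receptor_subunits or any(not s for s in self.receptor_subunits):
            raise FormatError(f"empty receptor subunit for ligand {self.ligand!r}")
        object.__setattr__(self, "receptor_subunits", tuple(self.receptor_subunits))

    @property
    def pair_id(self) -> str:
        return f"{self.ligand}->{'+'.join(self.receptor_subunits)}"


@dataclass
class SurvivalCohort:
    """Bulk expression (genes x samples, linear scale) with follow-up data."""

    expression: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "EFS"
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = self.expression.shape[1]
        if len(self.time) != n or len(self.event) != n:
            raise FormatError("time/event length must match sample count")
        if np.any(self.time < 0):
            raise FormatError("negative follow-up times")
        if not np.isin(self.event, [0, 1]).all():
            bad = sorted(set(np.asarray(self.event).tolist()) - {0, 1})
            raise FormatError(f"event values outside {{0,1}}: {bad}")
        self.event = self.event.astype(int)
        _check_unique(list(self.expression.index), "gene symbols")
        _check_unique(list(self.expression.columns), "sample ids")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.expression.columns]


PROTEOMICS_COLUMNS = ["sample_id", "protein_id", "gene", "intensity", "n_peptides", "ibaq"]


@dataclass
class ProteomicsTable:
    """Long-format protein abundances; one row per (sample, protein).

    Each row carries either a precomputed iBAQ or the (intensity,
    n measurable peptides) pair it is derived from.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in PROTEOMICS_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[PROTEOMICS_COLUMNS]
        has_ibaq = df["ibaq"].notna()
        has_pair = df["intensity"].notna() & df["n_peptides"].notna()
        bad = df.index[~(has_ibaq | has_pair)].tolist()
        if bad:
            raise FormatError(
                f"rows {bad} have neither ibaq nor (intensity, n_peptides)"
            )
        if (df.loc[df["intensity"].notna(), "intensity"] < 0).any():
            raise FormatError("negative intensity")
        npep = df.loc[df["n_peptides"].notna(), "n_peptides"]
        if (npep < 1).any() or (npep != np.floor(npep)).any():
            raise FormatError("n_peptides must be a positive integer")
        dup = df.duplicated(subset=["sample_id", "protein_id"])
        if dup.any():
            raise FormatError(
                f"duplicate protein_id within sample: rows {df.index[dup].tolist()}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))


# ---------------------------------------------------------------------------
# Single-cell cohort IO
# ---------------------------------------------------------------------------


def _read_cell_annotation(cells_path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(cells_path, sep="\t", dtype=str, comment="#")
    required = {"cell_id", "subset", "tumor_id"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"cells file missing columns: {sorted(missing)}")
    _check_unique(list(ann["cell_id"]), "cell barcodes in annotation")
    return ann.set_index("cell_id")


def _align_annotation(ann: pd.DataFrame, cell_ids: list[str]) -> pd.DataFrame:
    missing = [c for c in cell_ids if c not in ann.index]
    if missing:
        raise FormatError(
            f"cells present in matrix but absent from annotation: {missing}"
        )
    return ann.loc[cell_ids]


def read_cell_cohort(
    matrix_path: str | Path | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    *,
    dense_csv_path: str | Path | None = None,
    orientation: str = "genes_by_cells",
) -> CellCohort:
    """Read a cohort from MatrixMarket + gene/cell TSVs, or from a dense CSV.

    ``orientation`` declares the matrix layout explicitly ("genes_by_cells"
    or "cells_by_genes"); it is never guessed from the shape.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise FormatError(f"unknown orientation {orientation!r}")
    if dense_csv_path is not None:
        if cells_path is None:
            raise FormatError("dense CSV input requires a cells annotation file")
        df = pd.read_csv(dense_csv_path, index_col=0)
        if orientation == "cells_by_genes":
            df = df.T
        ann = _read_cell_annotation(cells_path)
        cell_ids = [str(c) for c in df.columns]
        ann = _align_annotation(ann, cell_ids)
        return CellCohort(
            counts=df.to_numpy(),
            gene_ids=[str(g) for g in df.index],
            cell_ids=cell_ids,
            subset=ann["subset"].to_numpy(),
            tumor_id=ann["tumor_id"].to_numpy(),
        )

    if matrix_path is None or genes_path is None or cells_path is None:
        raise FormatError("need matrix, genes and cells paths (or dense_csv_path)")
    mat = scipy.io.mmread(str(matrix_path))
    counts = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat
    )
    if orientation == "cells_by_genes":
        counts = counts.T
    genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)[0].tolist()
    ann_df = _read_cell_annotation(cells_path)
    if len(ann_df) != counts.shape[1]:
        raise FormatError(
            f"matrix has {counts.shape[1]} cells but annotation has {len(ann_df)}"
        )
    return CellCohort(
        counts=counts,
        gene_ids=genes,
        cell_ids=[str(c) for c in ann_df.index],
        subset=ann_df["subset"].to_numpy(),
        tumor_id=ann_df["tumor_id"].to_numpy(),
    )


def write_cell_cohort(cohort: CellCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + cells.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    coo = scipy.sparse.coo_matrix(cohort.counts)
    scipy.io.mmwrite(str(paths["matrix"]), coo, field="integer")
    pd.Series(cohort.gene_ids).to_csv(
        paths["genes"], sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {
            "cell_id": cohort.cell_ids,
            "subset": cohort.subset,
            "tumor_id": cohort.tumor_id,
        }
    ).to_csv(paths["cells"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Ligand-receptor database
# ---------------------------------------------------------------------------


def read_lr_db(csv_path: str | Path) -> list[LRPair]:
    """Read a ligand/receptor CSV; receptor subunits are '+'-separated."""
    df = pd.read_csv(csv_path, dtype=str, comment="#")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"LR database missing column {col!r}")
    pairs: list[LRPair] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        ligand = (row["ligand"] or "").strip() if pd.notna(row["ligand"]) else ""
        receptor = (row["receptor"] or "").strip() if pd.notna(row["receptor"]) else ""
        if not ligand or not receptor:
            raise FormatError(f"empty ligand/receptor field at row {i}")
        subunits = tuple(s.strip() for s in receptor.split("+"))
        pair = LRPair(ligand=ligand, receptor_subunits=subunits)
        if pair.pair_id in seen:
            raise FormatError(f"duplicate pair_id {pair.pair_id!r} at row {i}")
        seen.add(pair.pair_id)
        pairs.append(pair)
    return pairs


def write_lr_db(pairs: Sequence[LRPair], csv_path: str | Path) -> None:
    pd.DataFrame(
        {
            "ligand": [p.ligand for p in pairs],
            "receptor": ["+".join(p.receptor_subunits) for p in pairs],
        }
    ).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Bulk survival cohorts
# ---------------------------------------------------------------------------


def read_survival_cohort(
    expr_csv: str | Path,
    surv_csv: str | Path,
    endpoint: str = "EFS",
    name: str | None = None,
) -> SurvivalCohort:
    """Read genes x samples expression plus a (sample_id, time, event) table.

    Survival rows are aligned to the expression sample order by sample_id, so
    row order in the survival file is irrelevant.
    """
    expr = pd.read_csv(expr_csv, index_col=0)
    expr.columns = [str(c) for c in expr.columns]
    surv = pd.read_csv(surv_csv, dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(surv.columns)
    if missing:
        raise FormatError(f"survival table missing columns: {sorted(missing)}")
    surv = surv.set_index("sample_id")
    absent = [s for s in expr.columns if s not in surv.index]
    if absent:
        raise FormatError(f"samples missing from survival table: {absent}")
    surv = surv.loc[list(expr.columns)]
    return SurvivalCohort(
        expression=expr,
        time=surv["time"].to_numpy(),
        event=surv["event"].to_numpy(),
        endpoint=endpoint,
        name=name or Path(expr_csv).stem,
    )


def write_survival_cohort(
    cohort: SurvivalCohort, expr_csv: str | Path, surv_csv: str | Path
) -> None:
    cohort.expression.to_csv(expr_csv)
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "time": cohort.time,
            "event": cohort.event,
        }
    ).to_csv(surv_csv, index=False)


# ---------------------------------------------------------------------------
# Proteomics, gene lists, generic TSV output
# ---------------------------------------------------------------------------


def read_proteomics(csv_path: str | Path) -> ProteomicsTable:
    df = pd.read_csv(csv_path, comment="#", dtype={"sample_id": str, "protein_id": str, "gene": str})
    return ProteomicsTable(df)


def write_proteomics(table: ProteomicsTable, csv_path: str | Path) -> None:
    table.data.to_csv(csv_path, index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    genes = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    _check_unique(genes, "genes in list")
    return genes


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    params: dict | None = None,
    index: bool = False,
) -> None:
    """Write a TSV with a commented header recording version and parameters."""
    from suppressor_screen import __version__

    header_lines = [f"# suppressor-screen version: {__version__}"]
    for key in sorted(params or {}):
        header_lines.append(f"# {key}: {params[key]}")
    with open(path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
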