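"""Sender -> receiver communication probabilities with a permutation null.

For each ligand-receptor channel between a sender and a receiver subset, the
ensemble ligand/receptor expression is a trimmed mean of log-normalized
expression over the subset's cells (geometric mean across subunits for
receptor complexes, zero if any subunit is zero). Communication probability
is the saturating mass-action form

    P = (L*R)^n / (Kh^n + (L*R)^n)

and significance comes from shuffling subset labels over all cells: the
p-value is the add-one-smoothed fraction of permuted probabilities at least
as large as the observed one, so it is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from suppressor_screen.io import CellCohort, LRPair


@dataclass
class InteractionResult:
    sender: str
    receiver: str
    pair: LRPair
    ensemble_L: float
    ensemble_R: float
    prob: float
    pvalue: float


def _trimmed_mean_1d(values: np.ndarray, trim: float) -> float:
    values = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(trim * values.size))
    if 2 * k >= values.size:
        raise ValueError(f"trim={trim} removes all {values.size} values")
    return float(values[k : values.size - k].mean())


def _trimmed_mean_rows(mat: np.ndarray, trim: float) -> np.ndarray:
    """Row-wise trimmed mean of a 2-D array."""
    mat = np.sort(mat, axis=1)
    k = int(np.floor(trim * mat.shape[1]))
    if 2 * k >= mat.shape[1]:
        raise ValueError(f"trim={trim} removes all {mat.shape[1]} values")
    return mat[:, k : mat.shape[1] - k].mean(axis=1)


def ensemble_expression(values: np.ndarray, trim: float = 0.10) -> float:
    """Trimmed mean (``trim`` fraction cut from each tail) of a gene's
    expression over one subset's cells."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty subset")
    return _trimmed_mean_1d(values, trim)


def complex_ensemble(ensembles: Sequence[float]) -> float:
    """Geometric mean across receptor subunits; 0 if any subunit is 0."""
    vals = np.asarray(ensembles, dtype=float)
    if np.any(vals == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def communication_probability(
    ensemble_L: float, ensemble_R: float, Kh: float = 0.5, hill_n: float = 1.0
) -> float:
    """Saturating probability of communication given ensemble L and R."""
    if ensemble_L < 0 or ensemble_R < 0:
        raise ValueError("ensemble expression must be non-negative")
    x = (ensemble_L * ensemble_R) ** hill_n
    return float(x / (Kh**hill_n + x))


def _permutation_matrix(
    cohort: CellCohort, n_perm: int, rng: np.random.Generator, stratified: bool
) -> np.ndarray:
    """(n_perm, n_cells) array of permuted cell indices; row i assigns cell
    P[i, j] to the label slot of cell j (optionally within each tumor)."""
    n = cohort.n_cells
    P = np.empty((n_perm, n), dtype=np.int64)
    if not stratified:
        for i in range(n_perm):
            P[i] = rng.permutation(n)
    else:
        tumor_groups = [np.flatnonzero(cohort.tumor_id == t) for t in cohort.tumors]
        for i in range(n_perm):
            row = np.empty(n, dtype=np.int64)
            for idx in tumor_groups:
                row[idx] = idx[rng.permutation(idx.size)]
            P[i] = row
    return P


class _NullEnsembles:
    """Caches per-(subset, gene) null ensemble vectors for one permutation set."""

    def __init__(self, cohort: CellCohort, lognorm: np.ndarray, P: np.ndarray, trim: float):
        self.cohort = cohort
        self.lognorm = np.asarray(lognorm)
        self.P = P
        self.trim = trim
        self._slots = {s: cohort.cells_of(s) for s in cohort.subsets}
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def __call__(self, subset: str, gene: str) -> np.ndarray:
        key = (subset, gene)
        if key not in self._cache:
            row = self.cohort.gene_index(gene)
            idx = self.P[:, self._slots[subset]]
            self._cache[key] = _trimmed_mean_rows(self.lognorm[row][idx], self.trim)
        return self._cache[key]


def infer_interactions(
    cohort: CellCohort,
    lognorm: np.ndarray,
    pairs: Sequence[LRPair],
    senders: Sequence[str],
    receivers: Sequence[str],
    n_perm: int = 100,
    trim: float = 0.10,
    Kh: float = 0.5,
    hill_n: float = 1.0,
    seed: int = 0,
    stratified_null: bool = False,
) -> pd.DataFrame:
    """Test every (pair, sender, receiver) channel; one shared permutation set.

    Pairs whose ligand or receptor genes are absent from the cohort are
    skipped with a warning. Returns a long DataFrame with columns ligand,
    receptor, pair_id, sender, receiver, ensemble_L, ensemble_R, prob,
    pvalue.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lognorm = np.asarray(lognorm)
    known = set(cohort.gene_ids)
    usable: list[LRPair] = []
    for p in pairs:
        missing = [g for g in (p.ligand, *p.receptor_subunits) if g not in known]
        if missing:
            warnings.warn(f"skipping {p.pair_id}: genes absent {missing}", stacklevel=2)
        else:
            usable.append(p)

    for s in list(senders) + list(receivers):
        if cohort.cells_of(s).size < 2:
            raise ValueError(f"subset {s!r} has fewer than 2 cells")

    rng = np.random.default_rng(seed)
    P = _permutation_matrix(cohort, n_perm, rng, stratified_null)
    null = _NullEnsembles(cohort, lognorm, P, trim)

    def observed_ensemble(subset: str, gene: str) -> float:
        cells = cohort.cells_of(subset)
        return ensemble_expression(lognorm[cohort.gene_index(gene), cells], trim)

    records = []
    for sender in senders:
        for receiver in receivers:
            if sender == receiver:
                continue
            for pair in usable:
                eL = observed_ensemble(sender, pair.ligand)
                eR = complex_ensemble(
                    [observed_ensemble(receiver, g) for g in pair.receptor_subunits]
                )
                prob = communication_probability(eL, eR, Kh, hill_n)

                nL = null(sender, pair.ligand)
                sub_nulls = np.vstack(
                    [null(receiver, g) for g in pair.receptor_subunits]
                )
                if sub_nulls.shape[0] == 1:
                    nR = sub_nulls[0]
                else:
                    zero = (sub_nulls == 0).any(axis=0)
                    with np.errstate(divide="ignore"):
                        nR = np.exp(np.mean(np.log(np.where(sub_nulls > 0, sub_nulls, 1.0)), axis=0))
                    nR[zero] = 0.0
                x = (nL * nR) ** hill_n
                null_prob = x / (Kh**hill_n + x)
                pvalue = (1.0 + np.sum(null_prob >= prob)) / (1.0 + n_perm)
                records.append(
                    {
                        "ligand": pair.ligand,
                        "receptor": "+".join(pair.receptor_subunits),
                        "pair_id": pair.pair_id,
                        "sender": sender,
                        "receiver": receiver,
                        "ensemble_L": eL,
                        "ensemble_R": eR,
                        "prob": prob,
                        "pvalue": pvalue,
                    }
                )
    return pd.DataFrame(records)


def permutation_test(
    cohort: CellCohort,
    lognorm: np.ndarray,
    pair: LRPair,
    sender: str,
    receiver: str,
    n_perm: int = 100,
    seed: int = 0,
    trim: float = 0.10,
    Kh: float = 0.5,
    hill_n: float = 1.0,
    stratified_null: bool = False,
) -> InteractionResult:
    """Single-channel convenience wrapper around :func:`infer_interactions`."""
    df = infer_interactions(
        cohort,
        lognorm,
        [pair],
        senders=[sender],
        receivers=[receiver],
        n_perm=n_perm,
        trim=trim,
        Kh=Kh,
        hill_n=hill_n,
        seed=seed,
        stratified_null=stratified_null,
    )
    if df.empty:
        raise KeyError(f"pair {pair.pair_id} not testable on this cohort")
    row = df.iloc[0]
    return InteractionResult(
        sender=sender,
        receiver=receiver,
        pair=pair,
        ensemble_L=float(row["ensemble_L"]),
        ensemble_R=float(row["ensemble_R"]),
        prob=float(row["prob"]),
        pvalue=float(row["pvalue"]),
    )
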