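"""Synthetic cohorts with planted, recoverable structure.

Every downstream stage of the screen is tested by recovery on data from this
module: a multi-tumor single-cell cohort in which planted "suppressor"
ligands anti-correlate across tumors with receiver-subset cytotoxicity, bulk
cohorts whose survival hazard depends on planted genes, and secretome tables
with planted top-decile proteins.

The single-cell model is a per-tumor latent-factor construction. Each tumor
``t`` carries a suppression level ``u_t ~ Uniform(0, 1)``. Writing ``z_t``
for the standardized ``u_t``, the negative-binomial mean of every
cytotoxicity gene in receiver cells of tumor ``t`` is scaled by
``exp(-c_amp * z_t)`` and the mean of a planted suppressor ligand in its
sender cells by ``exp(s_amp * l_t)`` with ``l_t = rho * z_t +
sqrt(1 - rho^2) * eps_t`` and ``rho = |effect_r|``. Because downstream
expression summaries are approximately linear in these log-scale factors,
the realized cross-tumor Pearson correlation between sender ligand
expression and receiver cytotoxicity approaches ``effect_r``.

Null ligands and all receptors are expressed uniformly across subsets and
independently of ``u_t``: under the label-permutation null they are
exchangeable, so interaction p-values for them are uniform by construction.

All randomness flows from one integer seed through ``numpy``
``SeedSequence.spawn`` (one child stream per independent noise source, in a
fixed documented order), so identical parameters and seed reproduce outputs
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from suppressor_screen.io import CellCohort, LRPair, ProteomicsTable, SurvivalCohort

CYTOTOX_GENES = ("NKG7", "CCL5", "CST7", "PRF1", "GZMA", "GZMB", "IFNG")

DEFAULT_SUBSET_SIZES = {"tumor": 60, "NK": 40, "CD8T": 40, "gdT": 30, "myeloid": 30}
DEFAULT_RECEIVERS = ("NK", "CD8T", "gdT")


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuppressorSpec:
    gene: str
    sender: str = "tumor"
    receivers: tuple[str, ...] = DEFAULT_RECEIVERS
    effect_r: float = -0.8


@dataclass(frozen=True)
class SurvivalGeneSpec:
    gene: str
    hazard_ratio: float  # per unit z of log2(1+expression)


@dataclass
class PlantedTruth:
    """Ground truth planted into the synthetic cohorts."""

    suppressor_ligands: list[SuppressorSpec] = field(default_factory=list)
    null_ligands: list[str] = field(default_factory=list)
    survival_genes: list[SurvivalGeneSpec] = field(default_factory=list)
    secretome_top_genes: list[str] = field(default_factory=list)
    # filled in by generate_cell_cohort: tumor_id -> realized latent
    # suppression level u_t in [0, 1]
    latent_suppression: dict[str, float] | None = None

    def __post_init__(self) -> None:
        sup = {s.gene for s in self.suppressor_ligands}
        if sup & set(self.null_ligands):
            raise ValueError(
                f"suppressor and null ligand sets overlap: {sorted(sup & set(self.null_ligands))}"
            )
        for s in self.suppressor_ligands:
            if not (-1.0 <= s.effect_r < 0.0):
                raise ValueError(
                    f"effect_r for {s.gene} must be in [-1, 0), got {s.effect_r}"
                )
        for g in self.survival_genes:
            if g.hazard_ratio <= 0:
                raise ValueError(f"hazard_ratio for {g.gene} must be > 0")

    @property
    def ligand_genes(self) -> list[str]:
        return [s.gene for s in self.suppressor_ligands] + list(self.null_ligands)

    def to_dict(self) -> dict:
        return {
            "suppressor_ligands": [
                {
                    "gene": s.gene,
                    "sender": s.sender,
                    "receivers": list(s.receivers),
                    "effect_r": s.effect_r,
                }
                for s in self.suppressor_ligands
            ],
            "null_ligands": list(self.null_ligands),
            "survival_genes": [
                {"gene": g.gene, "hazard_ratio": g.hazard_ratio}
                for g in self.survival_genes
            ],
            "secretome_top_genes": list(self.secretome_top_genes),
        }


def default_truth(
    n_null: int = 20, effect_r: float = -0.8, sender: str = "tumor"
) -> PlantedTruth:
    """One planted suppressor plus ``n_null`` inert ligands (study defaults)."""
    return PlantedTruth(
        suppressor_ligands=[SuppressorSpec("SUPL1", sender=sender, effect_r=effect_r)],
        null_ligands=[f"NULL{i:02d}" for i in range(1, n_null + 1)],
        survival_genes=[SurvivalGeneSpec("SUPL1", hazard_ratio=2.0)],
        secretome_top_genes=["SUPL1"],
    )


def receptor_gene(ligand: str) -> str:
    return f"{ligand}R"


def synthetic_lr_db(truth: PlantedTruth) -> list[LRPair]:
    """One single-subunit receptor per ligand, named '<ligand>R'."""
    return [LRPair(lig, (receptor_gene(lig),)) for lig in truth.ligand_genes]


# ---------------------------------------------------------------------------
# Single-cell cohort
# ---------------------------------------------------------------------------


def _gene_universe(truth: PlantedTruth, n_genes: int) -> list[str]:
    genes = list(CYTOTOX_GENES) + truth.ligand_genes
    genes += [receptor_gene(lig) for lig in truth.ligand_genes]
    n_filler = n_genes - len(genes)
    if n_filler < 25:
        raise ValueError(
            f"n_genes={n_genes} leaves {n_filler} filler genes; need >= 25 "
            "for control-gene binning"
        )
    genes += _filler_names("GENE", n_filler, set(genes))
    return genes


def _filler_names(prefix: str, n: int, used: set[str]) -> list[str]:
    out: list[str] = []
    i = 1
    while len(out) < n:
        name = f"{prefix}{i:04d}"
        if name not in used:
            out.append(name)
        i += 1
    return out


def generate_cell_cohort(
    n_tumors: int = 24,
    subset_sizes: dict[str, int] | None = None,
    n_genes: int = 300,
    truth: PlantedTruth | None = None,
    nb_dispersion: float = 10.0,
    libsize_sigma: float = 0.3,
    seed: int = 0,
    receivers: Sequence[str] = DEFAULT_RECEIVERS,
    cytotox_amplitude: float = 0.6,
    ligand_amplitude: float = 0.5,
) -> tuple[CellCohort, PlantedTruth]:
    """Simulate a multi-tumor scRNA-seq cohort with planted suppression.

    Counts are negative binomial (gene dispersion ``nb_dispersion``, i.e.
    var = mu + mu^2/dispersion) with log-normal per-cell library-size
    factors. See the module docstring for the latent-factor construction.
    """
    if n_tumors < 3:
        raise ValueError("n_tumors must be >= 3 (cross-tumor correlation undefined)")
    if truth is None:
        truth = default_truth()
    subset_sizes = dict(subset_sizes or DEFAULT_SUBSET_SIZES)
    receivers = tuple(receivers)
    for r in receivers:
        if r not in subset_sizes:
            raise ValueError(f"receiver subset {r!r} missing from subset_sizes")
    for s in truth.suppressor_ligands:
        if s.sender not in subset_sizes:
            raise ValueError(f"sender subset {s.sender!r} missing from subset_sizes")

    genes = _gene_universe(truth, n_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    subsets = list(subset_sizes)
    cells_per_tumor = sum(subset_sizes.values())
    n_cells = n_tumors * cells_per_tumor

    ss = np.random.SeedSequence(seed)
    rng_u, rng_eps, rng_base, rng_lib, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # Latent per-tumor suppression level and ligand drivers. The ligand
    # driver is built with EXACT sample correlation rho against the
    # suppression latent (Gram-Schmidt residualization of the noise), so the
    # cross-tumor correlation is calibrated at any n_tumors rather than only
    # in expectation.
    u = rng_u.uniform(0.0, 1.0, size=n_tumors)
    z = (u - u.mean()) / max(u.std(), 1e-12)  # sample-standardized
    drivers = {}
    for spec in truth.suppressor_ligands:
        rho = abs(spec.effect_r)
        eps = rng_eps.standard_normal(n_tumors)
        resid = eps - (eps @ z) / (z @ z) * z
        resid = resid / max(resid.std(), 1e-12)
        drivers[spec.gene] = rho * z + np.sqrt(1.0 - rho**2) * resid

    # base mean per (gene, subset)
    base = np.empty((len(genes), len(subsets)))
    filler_means = rng_base.lognormal(mean=np.log(0.3), sigma=1.0, size=len(genes))
    base[:] = filler_means[:, None]
    for g in CYTOTOX_GENES:
        base[gidx[g], :] = 0.05
        for r in receivers:
            base[gidx[g], subsets.index(r)] = 8.0
    for lig in truth.ligand_genes:
        base[gidx[lig], :] = 1.0
        base[gidx[receptor_gene(lig)], :] = 1.0
    for spec in truth.suppressor_ligands:
        base[gidx[spec.gene], :] = 0.05
        base[gidx[spec.gene], subsets.index(spec.sender)] = 8.0

    # Equalize the EXPECTED library size across subsets by rescaling filler
    # genes: otherwise depth normalization couples every gene to the
    # subset-specific cytotoxicity/ligand mass and null ligands would no
    # longer be exchangeable under the label-permutation null.
    def _e_exp_uniform(b: float) -> float:
        # E[exp(b*Z)] for Z uniform on [-sqrt(3), sqrt(3)] (unit variance)
        if b == 0:
            return 1.0
        return float(np.sinh(b * np.sqrt(3.0)) / (b * np.sqrt(3.0)))

    e_factor = np.ones_like(base)
    for g in CYTOTOX_GENES:
        for r in receivers:
            e_factor[gidx[g], subsets.index(r)] = _e_exp_uniform(-cytotox_amplitude)
    for spec in truth.suppressor_ligands:
        rho = abs(spec.effect_r)
        e_factor[gidx[spec.gene], subsets.index(spec.sender)] = _e_exp_uniform(
            ligand_amplitude * rho
        ) * np.exp(ligand_amplitude**2 * (1.0 - rho**2) / 2.0)
    filler_rows = np.array([gidx[g] for g in genes if g.startswith("GENE")])
    expected = (base * e_factor).sum(axis=0)
    nonfiller = expected - (base[filler_rows] * e_factor[filler_rows]).sum(axis=0)
    filler_mass = (base[filler_rows] * e_factor[filler_rows]).sum(axis=0)
    target = expected.max()
    scale = (target - nonfiller) / filler_mass
    base[filler_rows] = base[filler_rows] * scale[None, :]

    # per-(gene, tumor) multiplicative factors by subset role
    cyto_rows = [gidx[g] for g in CYTOTOX_GENES]
    cyto_factor = np.exp(-cytotox_amplitude * z)  # shape (n_tumors,)

    cell_subset: list[str] = []
    cell_tumor: list[str] = []
    cell_ids: list[str] = []
    mean = np.empty((len(genes), n_cells))
    col = 0
    for t in range(n_tumors):
        tname = f"T{t + 1:02d}"
        for s in subsets:
            n_s = subset_sizes[s]
            block = np.repeat(base[:, [subsets.index(s)]], n_s, axis=1)
            if s in receivers:
                block[cyto_rows, :] *= cyto_factor[t]
            for spec in truth.suppressor_ligands:
                if s == spec.sender:
                    block[gidx[spec.gene], :] *= np.exp(
                        ligand_amplitude * drivers[spec.gene][t]
                    )
            mean[:, col : col + n_s] = block
            cell_subset += [s] * n_s
            cell_tumor += [tname] * n_s
            cell_ids += [f"{tname}_C{col + i:05d}" for i in range(n_s)]
            col += n_s

    libsize = rng_lib.lognormal(mean=0.0, sigma=libsize_sigma, size=n_cells)
    mean *= libsize[None, :]
    theta = float(nb_dispersion)
    counts = rng_counts.negative_binomial(theta, theta / (theta + mean))

    cohort = CellCohort(
        counts=counts.astype(np.int64),
        gene_ids=genes,
        cell_ids=cell_ids,
        subset=np.array(cell_subset, dtype=object),
        tumor_id=np.array(cell_tumor, dtype=object),
    )
    truth.latent_suppression = {
        f"T{t + 1:02d}": float(u[t]) for t in range(n_tumors)
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# Bulk survival cohort
# ---------------------------------------------------------------------------


def generate_survival_cohort(
    n_samples: int = 498,
    n_genes: int = 200,
    truth: PlantedTruth | None = None,
    censoring_rate: float = 0.3,
    baseline_hazard: float = 0.1,
    seed: int = 0,
    endpoint: str = "EFS",
    name: str = "synthetic-bulk",
) -> SurvivalCohort:
    """Simulate a bulk cohort with survival driven by planted genes.

    A per-sample latent cytotoxic-infiltration level drives the 7 score
    genes up and each planted suppressor ligand down (at its ``effect_r``),
    reproducing the negative bulk correlation the screen replicates. Event
    times are exponential with log-hazard ``log(baseline_hazard) +
    sum_g log(hr_g) * z_g`` over planted survival genes; censoring is an
    independent exponential tuned so the expected censored fraction is
    ``censoring_rate`` in the covariate-free case.
    """
    if not (0.0 <= censoring_rate < 1.0):
        raise ValueError("censoring_rate must be in [0, 1)")
    if truth is None:
        truth = default_truth()

    genes = list(CYTOTOX_GENES) + truth.ligand_genes
    genes += [g.gene for g in truth.survival_genes if g.gene not in genes]
    n_filler = n_genes - len(genes)
    if n_filler < 0:
        raise ValueError(f"n_genes={n_genes} too small for planted genes")
    genes += _filler_names("BGENE", n_filler, set(genes))

    ss = np.random.SeedSequence(seed)
    rng_lat, rng_base, rng_noise, rng_eps, rng_t, rng_c = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    s_lat = rng_lat.standard_normal(n_samples)  # cytotoxic infiltration
    base = rng_base.lognormal(mean=np.log(100.0), sigma=1.0, size=len(genes))

    log2_expr = np.empty((len(genes), n_samples))
    sup_specs = {s.gene: s for s in truth.suppressor_ligands}
    for i, g in enumerate(genes):
        if g in CYTOTOX_GENES:
            sig, noise_sd = 1.0 * s_lat, 0.5
        elif g in sup_specs:
            rho = abs(sup_specs[g].effect_r)
            eps = rng_eps.standard_normal(n_samples)
            sig = 1.0 * (-rho * s_lat + np.sqrt(1 - rho**2) * eps)
            noise_sd = 0.2
        else:
            sig, noise_sd = 0.0, 1.0
        log2_expr[i] = np.log2(base[i]) + sig + rng_noise.normal(0.0, noise_sd, n_samples)
    expr = np.power(2.0, log2_expr)

    expression = pd.DataFrame(
        expr, index=genes, columns=[f"S{j + 1:04d}" for j in range(n_samples)]
    )

    log_hazard = np.full(n_samples, np.log(baseline_hazard))
    for spec in truth.survival_genes:
        x = np.log2(1.0 + expression.loc[spec.gene].to_numpy())
        sd = x.std(ddof=0)
        zg = (x - x.mean()) / sd if sd > 0 else np.zeros(n_samples)
        log_hazard += np.log(spec.hazard_ratio) * zg
    event_time = rng_t.exponential(1.0 / np.exp(log_hazard))
    if censoring_rate > 0:
        mu = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        censor_time = rng_c.exponential(1.0 / mu, size=n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    return SurvivalCohort(
        expression=expression, time=time, event=event, endpoint=endpoint, name=name
    )


# ---------------------------------------------------------------------------
# Secretome
# ---------------------------------------------------------------------------


def generate_secretome(
    n_proteins: int = 1000,
    n_samples: int = 3,
    truth: PlantedTruth | None = None,
    log_mu: float = 15.0,
    log_sigma: float = 2.0,
    seed: int = 0,
    peptide_range: tuple[int, int] = (5, 50),
) -> ProteomicsTable:
    """Simulate per-sample secretome tables with planted top-decile genes.

    Background intensities are log-normal with uniform-integer measurable
    peptide counts. Planted genes are placed in the upper decile of the
    per-sample iBAQ (intensity / n_peptides) distribution — the scale on
    which abundance ranks are computed — and their intensity back-derived,
    so a planted gene is in the top 10% most abundant proteins of every
    sample by construction.
    """
    if n_proteins < 100:
        raise ValueError("n_proteins must be >= 100")
    if truth is None:
        truth = default_truth()
    planted = list(truth.secretome_top_genes)
    n_bg = n_proteins - len(planted)

    ss = np.random.SeedSequence(seed)
    rng_int, rng_pep, rng_q, rng_pep2 = (np.random.default_rng(s) for s in ss.spawn(4))

    lo, hi = peptide_range
    rows = []
    for j in range(n_samples):
        sample = f"TUMOROID{j + 1}"
        intens = rng_int.lognormal(mean=log_mu, sigma=log_sigma, size=n_bg)
        npep = rng_pep.integers(lo, hi + 1, size=n_bg)
        bg_ibaq = intens / npep
        for i in range(n_bg):
            rows.append(
                {
                    "sample_id": sample,
                    "protein_id": f"P{i + 1:05d}",
                    "gene": f"SECG{i + 1:04d}",
                    "intensity": intens[i],
                    "n_peptides": int(npep[i]),
                    "ibaq": np.nan,
                }
            )
        for g, gene in enumerate(planted):
            # inset from the decile boundary so the planted protein's final
            # rank stays inside the top 10% after it is added to the table
            q = rng_q.uniform(0.91, 0.999)
            target_ibaq = float(np.quantile(bg_ibaq, q))
            np_g = int(rng_pep2.integers(lo, hi + 1))
            rows.append(
                {
                    "sample_id": sample,
                    "protein_id": f"PLANT{g + 1:03d}",
                    "gene": gene,
                    "intensity": target_ibaq * np_g,
                    "n_peptides": np_g,
                    "ibaq": np.nan,
                }
            )
    return ProteomicsTable(pd.DataFrame(rows))
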