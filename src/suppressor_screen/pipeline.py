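"""End-to-end orchestration: simulate -> score -> interactions -> screen ->
validate -> secretome, with a final candidate report.

Every stage's parameters and derived seed are recorded in ``summary.json``;
stage completion is tracked in ``MANIFEST.txt`` so partial runs are
auditable. All randomness descends from the single master seed through a
fixed-order ``SeedSequence.spawn``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from suppressor_screen import __version__, io, scoring, screen, secretome, simulate, survival
from suppressor_screen.config import RunConfig
from suppressor_screen.interactions import infer_interactions


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seeds(master: int) -> dict[str, int]:
    names = ["simulate_cells", "simulate_bulk", "simulate_secretome",
             "score", "interactions"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] & 0x7FFFFFFF) for n, c in zip(names, children)
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full screen; returns the run summary dict.

    With no input paths configured the synthetic benchmark (planted
    suppressor) is generated and screened; with paths, inputs are loaded
    instead. Stages whose inputs are absent are skipped and flagged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "MANIFEST.txt"
    manifest: list[str] = []
    summary: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    seeds = _stage_seeds(config.seed)
    summary["stage_seeds"] = seeds

    def done(stage: str, **info) -> None:
        manifest.append(stage)
        manifest_path.write_text("\n".join(manifest) + "\n")
        summary["stages"][stage] = info

    params = {"seed": config.seed, "alpha": config.alpha}

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        synthetic = config.cohort_dir is None
        truth = None
        if synthetic:
            truth = simulate.default_truth(
                n_null=config.n_null_ligands, effect_r=config.effect_r
            )
            cohort, truth = simulate.generate_cell_cohort(
                n_tumors=config.n_tumors,
                n_genes=config.n_genes,
                truth=truth,
                seed=seeds["simulate_cells"],
                receivers=config.receiver_subsets,
            )
            pairs = simulate.synthetic_lr_db(truth)
            secreted_genes = truth.ligand_genes
            bulk_cohorts = []
            bulk_ss = np.random.SeedSequence(seeds["simulate_bulk"]).spawn(
                len(config.bulk_n_samples)
            )
            for i, (n_s, ep, child) in enumerate(
                zip(config.bulk_n_samples, config.bulk_endpoints, bulk_ss)
            ):
                bulk_cohorts.append(
                    simulate.generate_survival_cohort(
                        n_samples=n_s,
                        truth=truth,
                        censoring_rate=config.censoring_rate,
                        baseline_hazard=config.baseline_hazard,
                        seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
                        endpoint=ep,
                        name=f"synthetic-bulk-{i + 1}",
                    )
                )
            proteomics = simulate.generate_secretome(
                n_proteins=config.secretome_n_proteins,
                n_samples=config.secretome_n_samples,
                truth=truth,
                seed=seeds["simulate_secretome"],
            )
            (out / "truth.json").write_text(
                json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
            )
        else:
            d = Path(config.cohort_dir)
            cohort = io.read_cell_cohort(
                d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv"
            )
            pairs = io.read_lr_db(config.lr_db_path)
            secreted_genes = (
                io.read_gene_list(config.secreted_list_path)
                if config.secreted_list_path
                else []
            )
            bulk_cohorts = [
                io.read_survival_cohort(e, s, endpoint=ep)
                for e, s, ep in zip(
                    config.bulk_expr_paths,
                    config.bulk_surv_paths,
                    list(config.bulk_endpoints) + ["EFS"] * len(config.bulk_expr_paths),
                )
            ]
            proteomics = (
                io.read_proteomics(config.proteomics_path)
                if config.proteomics_path
                else None
            )
        done(stage, synthetic=synthetic, n_genes=cohort.n_genes,
             n_cells=cohort.n_cells, n_pairs=len(pairs))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- score -----------------------------------------------------------
    stage = "score"
    try:
        lognorm = scoring.normalize_log(cohort.counts)
        cyt = scoring.score_cohort(
            cohort,
            lognorm,
            gene_set=config.cytotox_genes,
            receivers=config.receiver_subsets,
            n_bins=config.n_bins,
            n_ctrl=config.n_ctrl,
            min_cells=config.min_cells,
            seed=seeds["score"],
        )
        per_group = cyt.per_group
        io.write_tsv(per_group.reset_index(), out / "cytotoxicity_per_group.tsv", params=params)
        done(stage, n_groups=int(per_group.notna().sum().sum()))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- interactions ----------------------------------------------------
    stage = "interactions"
    try:
        senders = [s for s in cohort.subsets if s not in config.receiver_subsets]
        interactions_df = infer_interactions(
            cohort,
            lognorm,
            pairs,
            senders=senders,
            receivers=config.receiver_subsets,
            n_perm=config.n_perm,
            trim=config.trim,
            Kh=config.Kh,
            hill_n=config.hill_n,
            seed=seeds["interactions"],
            stratified_null=config.stratified_null,
        )
        io.write_tsv(interactions_df, out / "interactions.tsv", params=params)
        done(stage, n_tested=len(interactions_df),
             n_significant=int((interactions_df["pvalue"] < config.alpha).sum()))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- screen ----------------------------------------------------------
    stage = "screen"
    try:
        records = screen.run_screen(
            cohort,
            lognorm,
            interactions_df,
            per_group,
            alpha=config.alpha,
            min_cells=config.min_cells,
            method=config.correlation_method,
        )
        candidates = screen.overlay_select(records, alpha=config.alpha)
        candidates = screen.annotate_secreted(candidates, secreted_genes)
        io.write_tsv(records, out / "screen_records.tsv", params=params)
        io.write_tsv(candidates, out / "candidates.tsv", params=params)
        selected = candidates[candidates["selected"]]
        done(stage, n_records=len(records), n_candidates=len(candidates),
             n_selected=len(selected))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    selected_genes = sorted(set(selected["ligand"])) if len(selected) else []

    # ---- validate --------------------------------------------------------
    stage = "validate"
    if bulk_cohorts and selected_genes:
        try:
            repl = survival.replicate_candidates(
                bulk_cohorts, selected_genes, alpha=config.alpha,
                gene_set=config.cytotox_genes,
            )
            io.write_tsv(repl, out / "replication.tsv", params=params)
            scans = pd.concat(
                [
                    survival.scan_cohort(
                        c, selected_genes, min_group_frac=config.min_group_frac
                    )
                    for c in bulk_cohorts
                ],
                ignore_index=True,
            )
            io.write_tsv(scans, out / "scan_results.tsv", params=params)
            done(stage, n_replicated=int(
                repl.drop_duplicates("gene")["replicated"].sum()
            ), n_scans=len(scans))
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        repl, scans = None, None
        summary["stages"][stage] = {"skipped": True}

    # ---- secretome -------------------------------------------------------
    stage = "secretome"
    if proteomics is not None and selected_genes:
        try:
            reports = secretome.rank_and_report(
                proteomics, selected_genes, k=config.k_top
            )
            psummary = secretome.percentile_summary(reports, selected_genes)
            io.write_tsv(reports, out / "rank_report.tsv", params=params)
            io.write_tsv(psummary, out / "secretome_summary.tsv", params=params)
            done(stage, n_consensus=int(
                reports.drop_duplicates("gene")["consensus_all_samples"].sum()
            ))
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        reports, psummary = None, None
        summary["stages"][stage] = {"skipped": True}

    # ---- final report ----------------------------------------------------
    stage = "report"
    try:
        report = candidates.copy()
        if repl is not None:
            repl_flag = repl.drop_duplicates("gene").set_index("gene")["replicated"]
            report["replicated"] = report["ligand"].map(repl_flag)
        if scans is not None and len(scans):
            best_scan = scans.groupby("gene")["p_bonferroni"].min()
            report["scan_p_bonferroni"] = report["ligand"].map(best_scan)
        if psummary is not None:
            pct = psummary.set_index("gene")["max_percentile"]
            report["secretome_percentile"] = report["ligand"].map(pct)
        io.write_tsv(report, out / "final_report.tsv", params=params)
        done(stage, n_rows=len(report))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    return summary
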