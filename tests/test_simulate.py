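import numpy as np
import pytest

import suppressor_screen as sx
from suppressor_screen.screen import per_tumor_sender_means
from suppressor_screen.survival import logrank


def realized_suppressor_r(cohort, truth, seed=0):
    """Mean realized cross-tumor correlation over the three receivers."""
    lognorm = sx.normalize_log(cohort.counts)
    cyt = sx.score_cohort(cohort, lognorm, seed=seed)
    spec = truth.suppressor_ligands[0]
    lig = per_tumor_sender_means(cohort, lognorm, spec.gene, spec.sender)
    rs = [
        sx.cross_tumor_correlation(lig, cyt.per_group[r].reindex(lig.index))[0]
        for r in spec.receivers
    ]
    return float(np.mean(rs))


class TestPlantedTruth:
    def test_overlapping_ligand_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sx.PlantedTruth(
                suppressor_ligands=[sx.SuppressorSpec("MIF")],
                null_ligands=["MIF"],
            )

    @pytest.mark.parametrize("bad_r", [0.0, 0.5, -1.5])
    def test_effect_r_outside_range_rejected(self, bad_r):
        with pytest.raises(ValueError, match="effect_r"):
            sx.PlantedTruth(
                suppressor_ligands=[sx.SuppressorSpec("MIF", effect_r=bad_r)]
            )

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ValueError, match="hazard_ratio"):
            sx.PlantedTruth(survival_genes=[sx.SurvivalGeneSpec("MIF", 0.0)])


class TestCellCohortGenerator:
    def test_fewer_than_three_tumors_rejected(self):
        with pytest.raises(ValueError, match="n_tumors"):
            sx.generate_cell_cohort(n_tumors=2)

    def test_same_seed_bit_identical(self):
        a, _ = sx.generate_cell_cohort(n_tumors=4, seed=9)
        b, _ = sx.generate_cell_cohort(n_tumors=4, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.cell_ids == b.cell_ids

    def test_realized_correlation_near_target(self):
        truth = sx.default_truth(effect_r=-0.9)
        cohort, truth = sx.generate_cell_cohort(truth=truth, seed=1)
        r = realized_suppressor_r(cohort, truth, seed=1)
        assert abs(r - (-0.9)) < 0.15

    def test_calibration_mean_over_replicates(self):
        # mean realized correlation across many replicates stays within
        # +/-0.05 of the requested effect size (slow: ~200 cohorts)
        vals = []
        for seed in range(200):
            truth = sx.default_truth(effect_r=-0.8)
            cohort, truth = sx.generate_cell_cohort(truth=truth, seed=seed)
            vals.append(realized_suppressor_r(cohort, truth, seed=seed))
        assert abs(np.mean(vals) - (-0.8)) < 0.05

    def test_null_ligands_rarely_correlate(self):
        hits = total = 0
        for seed in range(5):
            truth = sx.PlantedTruth(null_ligands=[f"NULL{i:02d}" for i in range(1, 11)])
            cohort, truth = sx.generate_cell_cohort(truth=truth, seed=seed)
            lognorm = sx.normalize_log(cohort.counts)
            cyt = sx.score_cohort(cohort, lognorm, seed=seed)
            for lig in truth.null_ligands:
                means = per_tumor_sender_means(cohort, lognorm, lig, "tumor")
                for recv in ("NK", "CD8T", "gdT"):
                    r, _, _ = sx.cross_tumor_correlation(
                        means, cyt.per_group[recv].reindex(means.index)
                    )
                    total += 1
                    hits += abs(r) > 0.5
        assert hits / total < 0.05

    def test_score_tracks_latent_suppression(self):
        cohort, truth = sx.generate_cell_cohort(seed=3)
        lognorm = sx.normalize_log(cohort.counts)
        cyt = sx.score_cohort(cohort, lognorm, seed=3)
        u = truth.latent_suppression
        per_tumor = cyt.per_group.mean(axis=1)
        order = sorted(u, key=u.get)
        low_u = per_tumor.loc[order[:8]].mean()
        high_u = per_tumor.loc[order[-8:]].mean()
        assert low_u > high_u  # more suppression => lower cytotoxicity


class TestSurvivalGenerator:
    def test_censoring_rate_without_covariates(self):
        truth = sx.PlantedTruth()
        cohort = sx.generate_survival_cohort(
            n_samples=1000, n_genes=20, truth=truth, censoring_rate=0.3, seed=5
        )
        # binomial(1000, 0.7): 3 sigma ~ 0.043
        assert abs(cohort.event.mean() - 0.7) < 0.05

    def test_planted_hazard_detected_by_logrank(self):
        truth = sx.PlantedTruth(survival_genes=[sx.SurvivalGeneSpec("HRG", 3.0)])
        detected = 0
        for seed in range(100):
            c = sx.generate_survival_cohort(
                n_samples=500, n_genes=30, truth=truth, seed=seed
            )
            x = c.expression.loc["HRG"].to_numpy()
            low = x <= np.median(x)
            _, p = logrank(c.time[low], c.event[low], c.time[~low], c.event[~low])
            detected += p < 0.01
        assert detected >= 95

    def test_same_seed_identical(self):
        a = sx.generate_survival_cohort(n_samples=50, n_genes=60, seed=7)
        b = sx.generate_survival_cohort(n_samples=50, n_genes=60, seed=7)
        assert a.expression.equals(b.expression)
        np.testing.assert_array_equal(a.time, b.time)

    def test_invalid_censoring_rejected(self):
        with pytest.raises(ValueError, match="censoring"):
            sx.generate_survival_cohort(censoring_rate=1.0)


class TestSecretomeGenerator:
    def test_planted_gene_in_top_decile_every_sample(self):
        from suppressor_screen.secretome import rank_and_report

        for seed in range(20):
            table = sx.generate_secretome(
                n_proteins=500, n_samples=3, truth=sx.default_truth(), seed=seed
            )
            rep = rank_and_report(table, ["SUPL1"])
            assert (rep["rank"] <= int(np.ceil(0.1 * 500))).all()

    def test_ranks_are_permutation_without_planting(self):
        from suppressor_screen.secretome import compute_ibaq

        truth = sx.PlantedTruth()
        table = sx.generate_secretome(n_proteins=100, n_samples=2, truth=truth, seed=0)
        table = compute_ibaq(table)
        for _, sub in table.data.groupby("sample_id"):
            ranks = sub["ibaq"].rank(ascending=False, method="first").astype(int)
            assert sorted(ranks) == list(range(1, 101))

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError, match="n_proteins"):
            sx.generate_secretome(n_proteins=50)

    def test_same_seed_identical(self):
        a = sx.generate_secretome(n_proteins=120, seed=4)
        b = sx.generate_secretome(n_proteins=120, seed=4)
        assert a.data.equals(b.data)
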