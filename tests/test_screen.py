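import numpy as np
import pandas as pd
import pytest

import suppressor_screen as sx
from suppressor_screen.io import read_tsv, write_tsv
from suppressor_screen.screen import (
    annotate_secreted,
    cross_tumor_correlation,
    overlay_select,
    run_screen,
)

from oracles import selection_oracle


class TestCrossTumorCorrelation:
    def test_perfectly_anti_monotone(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = -x
        for method in ("pearson", "spearman"):
            r, p, n = cross_tumor_correlation(x, y, method=method)
            assert r == pytest.approx(-1.0)
            assert n == 5

    def test_positive_correlation_reported(self):
        r, p, n = cross_tumor_correlation([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        r, p, n = cross_tumor_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_constant_vector_warns_not_raises(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p, n = cross_tumor_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_listwise_nan_drop(self):
        x = np.array([1, 2, np.nan, 4, 5.0])
        y = np.array([5, 4, 3, 2, 1.0])
        r, p, n = cross_tumor_correlation(x, y)
        assert n == 4
        assert r == pytest.approx(-1.0)

    def test_too_few_tumors_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            cross_tumor_correlation([1, 2], [2, 1])


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "sender", "receiver", "r", "r_pvalue",
            "interaction_pvalue", "n_tumors_used",
            "passes_correlation", "passes_interaction",
        ],
    )


class TestOverlaySelect:
    def test_both_filters_required(self):
        rec = _records(
            [["L1", "tumor", "NK", -0.6, 0.01, 0.2, 24, True, False]]
        )
        out = overlay_select(rec)
        assert not out["selected"].iloc[0]

    def test_negative_sum_rule(self):
        rec = _records(
            [
                ["L1", "tumor", "NK", -0.5, 0.01, 0.01, 24, True, True],
                ["L1", "tumor", "CD8T", 0.2, 0.4, 0.01, 24, False, True],
                ["L1", "tumor", "gdT", -0.1, 0.6, 0.01, 24, False, True],
            ]
        )
        out = overlay_select(rec)
        assert out["sum_r"].iloc[0] == pytest.approx(-0.4)
        assert out["selected"].iloc[0]

    def test_positive_sum_blocks_selection(self):
        rec = _records(
            [
                ["L1", "tumor", "NK", -0.5, 0.01, 0.01, 24, True, True],
                ["L1", "tumor", "CD8T", 0.9, 0.001, 0.01, 24, False, True],
            ]
        )
        assert not overlay_select(rec)["selected"].iloc[0]

    def test_missing_receiver_contributes_zero(self):
        rec = _records(
            [
                ["L1", "tumor", "NK", -0.5, 0.01, 0.01, 24, True, True],
                ["L1", "tumor", "CD8T", np.nan, np.nan, 0.01, 24, False, True],
            ]
        )
        out = overlay_select(rec)
        assert out["sum_r"].iloc[0] == pytest.approx(-0.5)
        assert out["selected"].iloc[0]


class TestAnnotateSecreted:
    def _candidates(self, ligands):
        return pd.DataFrame({"ligand": ligands, "sender": "tumor", "selected": True})

    def test_membership(self):
        out = annotate_secreted(self._candidates(["MIF", "XYZ"]), ["MIF", "MDK"])
        assert out.loc[out.ligand == "MIF", "secreted"].iloc[0]
        assert not out.loc[out.ligand == "XYZ", "secreted"].iloc[0]

    def test_case_mismatch_warns_and_fails(self):
        with pytest.warns(UserWarning, match="case-insensitively"):
            out = annotate_secreted(self._candidates(["Mif"]), ["MIF"])
        assert not out["secreted"].iloc[0]

    def test_empty_list_warns_all_false(self):
        with pytest.warns(UserWarning, match="empty"):
            out = annotate_secreted(self._candidates(["MIF"]), [])
        assert not out["secreted"].any()


@pytest.fixture(scope="module")
def screened(default_cohort):
    cohort, truth, lognorm = default_cohort
    cyt = sx.score_cohort(cohort, lognorm, seed=1)
    pairs = sx.synthetic_lr_db(truth)
    inter = sx.infer_interactions(
        cohort, lognorm, pairs, ["tumor", "myeloid"], ["NK", "CD8T", "gdT"],
        n_perm=100, seed=1,
    )
    records = run_screen(cohort, lognorm, inter, cyt.per_group)
    return records, overlay_select(records)


class TestFullScreen:
    def test_planted_suppressor_selected(self, screened):
        _, candidates = screened
        sel = candidates[candidates["selected"]]
        assert ("SUPL1" == sel["ligand"]).any()

    def test_selection_matches_straight_line_oracle(self, screened, tmp_path):
        records, candidates = screened
        write_tsv(records, tmp_path / "records.tsv")
        back = read_tsv(tmp_path / "records.tsv")
        expected = selection_oracle(back)
        for _, row in candidates.iterrows():
            assert expected[(row["ligand"], row["sender"])] == row["selected"]

    def test_screen_is_deterministic(self, default_cohort):
        cohort, truth, lognorm = default_cohort
        pairs = sx.synthetic_lr_db(truth)[:4]

        def once():
            cyt = sx.score_cohort(cohort, lognorm, seed=2)
            inter = sx.infer_interactions(
                cohort, lognorm, pairs, ["tumor"], ["NK"], n_perm=50, seed=2
            )
            return run_screen(cohort, lognorm, inter, cyt.per_group)

        assert once().equals(once())

    def test_record_flags_recomputable(self, screened):
        records, _ = screened
        finite = records[records["r"].notna()]
        expected = (finite["r"] < 0) & (finite["r_pvalue"] < 0.05)
        assert (finite["passes_correlation"] == expected).all()
        assert (
            records["passes_interaction"] == (records["interaction_pvalue"] < 0.05)
        ).all()
        assert (records["n_tumors_used"] >= 3).all()
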