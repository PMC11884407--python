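import numpy as np
import pandas as pd
import pytest

import suppressor_screen as sx
from suppressor_screen.survival import (
    bulk_cytotox_score,
    kaplan_scan,
    km_curve,
    logrank,
    replicate_candidates,
)

from oracles import km_bruteforce, logrank_bruteforce


class TestBulkCytotoxScore:
    def test_identical_samples_score_zero_with_warning(self):
        expr = pd.DataFrame(
            np.ones((7, 4)) * 5.0, index=sx.CYTOTOX_GENES, columns=list("abcd")
        )
        with pytest.warns(UserWarning, match="constant"):
            score = bulk_cytotox_score(expr)
        np.testing.assert_allclose(score.to_numpy(), 0.0)

    def test_uniformly_highest_sample_tops_score(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(3, 1, size=(7, 5)), index=sx.CYTOTOX_GENES,
            columns=list("abcde"),
        )
        expr["e"] = expr.max(axis=1) * 10
        score = bulk_cytotox_score(expr)
        assert score.idxmax() == "e"

    def test_three_sample_hand_example(self):
        expr = pd.DataFrame(
            np.tile([0.0, 1.0, 3.0], (7, 1)), index=sx.CYTOTOX_GENES,
            columns=list("abc"),
        )
        logx = np.log2(1 + np.array([0.0, 1.0, 3.0]))
        z = (logx - logx.mean()) / logx.std()
        score = bulk_cytotox_score(expr)
        np.testing.assert_allclose(score.to_numpy(), z, atol=1e-12)

    def test_missing_gene_rejected(self):
        expr = pd.DataFrame(np.ones((2, 3)), index=["MIF", "MDK"], columns=list("abc"))
        with pytest.raises(KeyError, match="NKG7"):
            bulk_cytotox_score(expr)


class TestReplicateCandidates:
    def _cohort_with_wired_gene(self, seed, name):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.lognormal(5, 1, size=(7, 30)), index=sx.CYTOTOX_GENES,
            columns=[f"s{i}" for i in range(30)],
        )
        score = bulk_cytotox_score(expr)
        # log2(1 + MIF) == 30 - score exactly, so r must be exactly -1
        expr.loc["MIF"] = np.power(2.0, 30.0 - score.to_numpy()) - 1.0
        return sx.SurvivalCohort(
            expression=expr, time=np.ones(30), event=np.zeros(30, dtype=int),
            name=name,
        )

    def test_gene_tracking_negated_score_has_r_minus_one(self):
        cohorts = [
            self._cohort_with_wired_gene(0, "first"),
            self._cohort_with_wired_gene(1, "second"),
        ]
        rep = replicate_candidates(cohorts, ["MIF"])
        assert rep["r"].iloc[0] == pytest.approx(-1.0, abs=1e-9)
        assert rep["replicated"].all()

    def test_missing_gene_marks_cohort_and_blocks_single_cohort_replication(self):
        c1 = self._cohort_with_wired_gene(0, "first")
        c2 = self._cohort_with_wired_gene(1, "second")
        c2.expression = c2.expression.drop(index="MIF")
        rep = replicate_candidates([c1, c2], ["MIF"])
        assert rep.loc[rep.cohort == "first", "passes"].iloc[0]
        assert rep.loc[rep.cohort == "second", "missing"].iloc[0]
        # only one informative cohort left -> not called replicated
        assert not rep["replicated"].any()

    def test_no_cohorts_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            replicate_candidates([], ["MIF"])


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        times, s = km_curve([1, 2, 3], [0, 0, 0])
        assert times.size == 0  # no event times -> S stays 1 everywhere

    def test_all_events_closed_form(self):
        times, s = km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(s, [2 / 3, 1 / 3, 0.0])

    def test_textbook_fixture_matches_bruteforce(self):
        time = [6, 6, 6, 6, 7, 9, 10, 10, 11, 13]
        event = [1, 1, 1, 0, 1, 0, 1, 0, 0, 1]
        t1, s1 = km_curve(time, event)
        t2, s2 = km_bruteforce(time, event)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_curve_non_increasing(self, rng):
        for _ in range(10):
            n = rng.integers(5, 40)
            t = rng.exponential(1, n)
            e = rng.integers(0, 2, n)
            _, s = km_curve(t, e)
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all(s <= 1.0 + 1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(1, 50)
        e = rng.integers(0, 2, 50)
        times, s = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        np.testing.assert_allclose(
            s, kmf.survival_function_at_times(times).to_numpy(), atol=1e-10
        )


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 4, 5.0]
        e = [1, 1, 0, 1, 0]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_significant(self):
        chi2, p = logrank([1, 2, 3, 4, 5], [1] * 5, [10, 11, 12, 13, 14], [1] * 5)
        assert p < 0.01

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(1, 20), rng.exponential(2, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        c1, _ = logrank(ta, ea, tb, eb)
        c2, _ = logrank(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_no_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n, m = rng.integers(8, 30, 2)
            ta, tb = rng.exponential(1, n), rng.exponential(1.5, m)
            ea, eb = rng.integers(0, 2, n), rng.integers(0, 2, m)
            if ea.sum() + eb.sum() == 0:
                continue
            c1, p1 = logrank(ta, ea, tb, eb)
            c2, p2 = logrank_bruteforce(ta, ea, tb, eb)
            assert c1 == pytest.approx(c2, abs=1e-10)
            assert p1 == pytest.approx(p2, abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        ta, tb = rng.exponential(1, 30), rng.exponential(2, 30)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        chi2, _ = logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(logrank_test(ta, tb, ea, eb).test_statistic, abs=1e-10)


class TestKaplanScan:
    def _planted(self, seed):
        r = np.random.default_rng(seed)
        xa, xb = r.normal(1, 0.2, 100), r.normal(3, 0.2, 100)
        ta = r.exponential(1 / 0.1, 100)
        tb = r.exponential(1 / 0.4, 100)
        cen = r.exponential(1 / 0.05, 200)
        x = np.concatenate([xa, xb])
        tt = np.concatenate([ta, tb])
        return x, np.minimum(tt, cen), (tt <= cen).astype(int), xa, xb

    def test_planted_split_recovered(self):
        x, t, e, xa, xb = self._planted(0)
        res = kaplan_scan(x, t, e)
        assert res.p_bonferroni < 1e-3
        # split agrees with the planted populations for >= 90% of samples
        assert abs(res.n_low - 100) <= 20
        assert res.direction == "high"

    def test_single_cutoff_degenerate_case(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(10), np.ones(10)])
        t = rng.exponential(1, 20)
        e = np.ones(20, dtype=int)
        res = kaplan_scan(x, t, e, min_group_frac=0.5)
        assert res.n_cutoffs_tested == 1
        assert res.p_bonferroni == pytest.approx(res.p_raw)

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kaplan_scan(np.ones(30), np.arange(30.0), np.ones(30, dtype=int))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 20"):
            kaplan_scan(np.arange(10.0), np.arange(10.0), np.ones(10, dtype=int))

    def test_invariant_under_monotone_transform(self):
        x, t, e, *_ = self._planted(3)
        a = kaplan_scan(x, t, e)
        b = kaplan_scan(np.exp(x), t, e)
        assert a.p_bonferroni == pytest.approx(b.p_bonferroni, rel=1e-12)
        assert a.n_cutoffs_tested == b.n_cutoffs_tested
        assert a.n_low == b.n_low

    def test_bonferroni_never_below_raw(self):
        x, t, e, *_ = self._planted(4)
        res = kaplan_scan(x, t, e)
        assert res.p_bonferroni >= res.p_raw
        assert res.n_low + res.n_high == x.size
        assert res.cutoff in set(np.round(x, 12).tolist()) or res.cutoff in x
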