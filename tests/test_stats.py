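"""Repeated-measures statistics: ANOVA, Dunnett, Delta-WD, concordance, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from fnirs_fc.montage import SLEEP_STATES, TASK_STATES
from fnirs_fc.stats import (
    CohortResults, DeltaWD, brain_behavior_correlation,
    channelwise_contrast_map, delta_wd, dunnett_vs_rest, kendalls_w,
    log_transform, rm_anova, score_changes,
)


def make_long(values, subjects, factors):
    """values[s, i, j, ...] -> long-format frame over the given factors."""
    rows = []
    it = np.ndindex(*values.shape[1:])
    names = list(factors)
    for s in range(values.shape[0]):
        for idx in np.ndindex(*values.shape[1:]):
            row = {"subject": subjects[s], "value": values[(s,) + idx]}
            for (name, levels), k in zip(factors.items(), idx):
                row[name] = levels[k]
            rows.append(row)
    return pd.DataFrame(rows)


class TestLogTransform:
    @staticmethod
    def _results(vals):
        return CohortResults(table=pd.DataFrame({
            "subject": "S01", "sleep_state": "before_SD", "task_state": "Rest",
            "scheme": "surrogate", "parameter": 0.05, "metric": "WD",
            "value": vals,
        }))

    def test_unit_value_maps_to_zero(self):
        out = log_transform(self._results([1.0]), epsilon=0.0)
        assert out.table["value"].iloc[0] == 0.0

    def test_zero_maps_to_log_epsilon(self):
        out = log_transform(self._results([0.0]), epsilon=1e-6)
        assert out.table["value"].iloc[0] == pytest.approx(np.log(1e-6))

    def test_double_application_guarded(self):
        once = log_transform(self._results([1.0, 2.0]))
        with pytest.raises(ValueError, match="already"):
            log_transform(once)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log_transform(self._results([-0.1]))


class TestRmAnova:
    @staticmethod
    def _two_way(seed=3, n=8):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n, 2, 7)) + np.arange(7) * 0.1
        return make_long(vals, [f"S{i}" for i in range(n)], {
            "sleep_state": list(SLEEP_STATES), "task_state": list(TASK_STATES)})

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.anova import AnovaRM
        df = self._two_way()
        mine = rm_anova(df)
        ref = AnovaRM(df, "value", "subject",
                      within=["sleep_state", "task_state"]).fit().anova_table
        for effect, key in (("sleep_state", "sleep_state"),
                            ("task_state", "task_state"),
                            ("sleep_state*task_state",
                             "sleep_state:task_state")):
            assert mine[effect].f == pytest.approx(
                ref.loc[key, "F Value"], abs=1e-8)
            assert mine[effect].p == pytest.approx(
                ref.loc[key, "Pr > F"], abs=1e-8)
            assert mine[effect].df_num == ref.loc[key, "Num DF"]
            assert mine[effect].df_den == ref.loc[key, "Den DF"]

    def test_gg_epsilon_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((8, 4))
        df = make_long(vals, [f"S{i}" for i in range(8)],
                       {"task_state": ["a", "b", "c", "d"]})
        mine = rm_anova(df, within=("task_state",))["task_state"]
        ref = pg.rm_anova(data=df, dv="value", within="task_state",
                          subject="subject")
        assert mine.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]),
                                                abs=1e-8)
        assert mine.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]),
                                          abs=1e-8)

    def test_three_factor_design_dfs(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((6, 2, 7, 3))
        df = make_long(vals, [f"S{i}" for i in range(6)], {
            "sleep_state": list(SLEEP_STATES),
            "task_state": list(TASK_STATES),
            "threshold": [0.15, 0.2, 0.25]})
        res = rm_anova(df, within=("sleep_state", "task_state", "threshold"))
        assert res["sleep_state*task_state*threshold"].df_num == 1 * 6 * 2
        assert res["sleep_state*task_state*threshold"].df_den == 12 * 5
        assert res["threshold"].df_num == 2
        assert 0 <= res["task_state"].p <= 1

    def test_incomplete_design_rejected(self):
        df = self._two_way().iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(df)

    def test_constant_cells_rejected(self):
        vals = np.ones((3, 2, 2))
        df = make_long(vals, ["S0", "S1", "S2"], {
            "sleep_state": list(SLEEP_STATES), "task_state": ["Rest", "Stim1"]})
        with pytest.raises(ValueError, match="degenerate"):
            rm_anova(df)

    def test_epsilon_bounded_by_sphericity_limits(self):
        df = self._two_way(seed=11)
        res = rm_anova(df)
        for eff in res.effects.values():
            assert 1.0 / eff.df_num <= eff.gg_epsilon <= 1.0


class TestDunnett:
    @staticmethod
    def _frame(values):
        """values: (n_subjects, 7) array over TASK_STATES, one sleep state."""
        rows = []
        for s in range(values.shape[0]):
            for t, task in enumerate(TASK_STATES):
                rows.append({"subject": f"S{s}", "sleep_state": "before_SD",
                             "task_state": task, "value": values[s, t]})
        return pd.DataFrame(rows)

    def test_no_difference_gives_p_one(self, rng):
        base = rng.standard_normal(6)
        vals = np.tile(base[:, None], (1, 7))
        out = dunnett_vs_rest(self._frame(vals), "before_SD", n_draws=20_000)
        assert np.all(out["p_adjusted"] >= 0.999)

    def test_adjusted_never_below_unadjusted(self, rng):
        vals = rng.standard_normal((10, 7))
        out = dunnett_vs_rest(self._frame(vals), "before_SD", n_draws=50_000)
        assert np.all(out["p_adjusted"] >= out["p_unadjusted"] - 1e-12)

    def test_single_contrast_reduces_to_paired_t(self, rng):
        vals = rng.standard_normal((12, 2))
        rows = []
        for s in range(12):
            rows.append({"subject": f"S{s}", "sleep_state": "before_SD",
                         "task_state": "Rest", "value": vals[s, 0]})
            rows.append({"subject": f"S{s}", "sleep_state": "before_SD",
                         "task_state": "Stim1", "value": vals[s, 1]})
        out = dunnett_vs_rest(pd.DataFrame(rows), "before_SD", n_draws=400_000)
        t_p = sstats.ttest_rel(vals[:, 1], vals[:, 0]).pvalue
        assert out["p_adjusted"].iloc[0] == pytest.approx(t_p, abs=0.01)

    def test_missing_rest_rejected(self, rng):
        vals = rng.standard_normal((5, 7))
        frame = self._frame(vals)
        frame = frame[frame["task_state"] != "Rest"]
        with pytest.raises(ValueError, match="Rest"):
            dunnett_vs_rest(frame, "before_SD")

    def test_fixed_seed_reproducible(self, rng):
        vals = rng.standard_normal((8, 7))
        a = dunnett_vs_rest(self._frame(vals), "before_SD", n_draws=10_000)
        b = dunnett_vs_rest(self._frame(vals), "before_SD", n_draws=10_000)
        assert np.array_equal(a["p_adjusted"], b["p_adjusted"])


class TestDeltaWd:
    @staticmethod
    def _frame(per_subject):
        """per_subject: {sid: {(sleep, task): value}}"""
        rows = []
        for sid, cells in per_subject.items():
            for (sleep, task), v in cells.items():
                rows.append({"subject": sid, "sleep_state": sleep,
                             "task_state": task, "value": v})
        return pd.DataFrame(rows)

    @staticmethod
    def _cells(rest_b, stim_b, rest_a, stim_a):
        cells = {}
        for t in TASK_STATES:
            cells[("before_SD", t)] = rest_b if t == "Rest" else stim_b
            cells[("after_SD", t)] = rest_a if t == "Rest" else stim_a
        return cells

    def test_identical_states_give_zero(self):
        frame = self._frame({"S1": self._cells(0.4, 0.3, 0.4, 0.3)})
        assert delta_wd(frame).per_subject["delta"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # before: rest .5, stims .3 -> -0.2; after: rest .5, stims .5 -> 0
        frame = self._frame({"S1": self._cells(0.5, 0.3, 0.5, 0.5)})
        assert delta_wd(frame).per_subject["delta"].iloc[0] == pytest.approx(0.2)

    def test_antisymmetric_under_state_swap(self, rng):
        cells = {f"S{i}": self._cells(*rng.random(4)) for i in range(4)}
        frame = self._frame(cells)
        swapped = frame.copy()
        swapped["sleep_state"] = swapped["sleep_state"].map(
            {"before_SD": "after_SD", "after_SD": "before_SD"})
        d1 = delta_wd(frame).per_subject.set_index("subject")["delta"]
        d2 = delta_wd(swapped).per_subject.set_index("subject")["delta"]
        assert np.allclose(d1, -d2)

    def test_missing_cell_rejected(self):
        cells = self._cells(0.5, 0.3, 0.5, 0.5)
        del cells[("after_SD", "Stim6")]
        with pytest.raises(ValueError, match="missing"):
            delta_wd(self._frame({"S1": cells}))


class TestBrainBehavior:
    @staticmethod
    def _inputs(n=10, slope=-2.0, noise=0.0, drop_pal_for=None, seed=0):
        rng = np.random.default_rng(seed)
        delta = rng.standard_normal(n) * 0.1
        subjects = [f"S{i:02d}" for i in range(n)]
        dwd = DeltaWD(per_subject=pd.DataFrame({
            "subject": subjects, "wd_before": 0.0, "wd_after": delta,
            "delta": delta}))
        changes = pd.DataFrame({
            "subject": subjects,
            "PAL": slope * delta + noise * rng.standard_normal(n),
            "RTI": rng.standard_normal(n),
            "RVPA": rng.standard_normal(n),
        })
        if drop_pal_for is not None:
            changes.loc[changes["subject"] == drop_pal_for, "PAL"] = np.nan
        return dwd, changes

    def test_planted_negative_coupling_recovered(self):
        dwd, changes = self._inputs(slope=-2.0, noise=0.0)
        out = brain_behavior_correlation(dwd, changes).set_index("test")
        assert out.loc["PAL", "r"] == pytest.approx(-1.0, abs=1e-9)
        assert out.loc["PAL", "p"] < 1e-6

    def test_missing_score_reduces_n_pairwise(self):
        dwd, changes = self._inputs(n=10, drop_pal_for="S03")
        out = brain_behavior_correlation(dwd, changes).set_index("test")
        assert out.loc["PAL", "n"] == 9
        assert out.loc["RTI", "n"] == 10

    def test_fewer_than_three_pairs_rejected(self):
        dwd, changes = self._inputs(n=2)
        with pytest.raises(ValueError, match="3 paired"):
            brain_behavior_correlation(dwd, changes)


class TestKendallsW:
    def test_identical_rankings_give_one(self):
        assert kendalls_w(np.tile(np.arange(10), (5, 1))) == pytest.approx(1.0)

    def test_reversed_pair_gives_zero(self):
        ranks = np.array([np.arange(10), np.arange(10)[::-1]])
        assert kendalls_w(ranks) == pytest.approx(0.0)

    def test_matches_textbook_formula_on_fixture(self, rng):
        scores = rng.standard_normal((5, 10))
        ranks = np.apply_along_axis(sstats.rankdata, 1, scores)
        rank_sums = ranks.sum(axis=0)
        s = ((rank_sums - rank_sums.mean()) ** 2).sum()
        expected = 12 * s / (5**2 * (10**3 - 10))  # no ties in random floats
        assert kendalls_w(scores) == pytest.approx(expected, abs=1e-12)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            kendalls_w(np.arange(5)[None, :])


class TestContrastMaps:
    def test_constant_zero_differences(self):
        arr = np.ones((6, 2, 7, 48))
        out = channelwise_contrast_map(arr, "sd_effect")
        assert np.all(out["t"] == 0.0)
        assert np.all(out["p_uncorrected"] == 1.0)

    def test_planted_channels_have_smallest_fdr_p(self, rng):
        arr = rng.standard_normal((12, 2, 7, 48)) * 0.1
        planted = [3, 7, 11, 20, 33, 41]
        # large after-SD task increase in the planted channels
        arr[:, 1, 1:, planted] += 2.0
        out = channelwise_contrast_map(arr, "sd_effect")
        smallest = out.nsmallest(6, "p_fdr")["channel"].tolist()
        assert set(smallest) == set(planted)

    def test_bh_adjustment_is_monotone_step_up(self, rng):
        arr = rng.standard_normal((8, 2, 7, 48))
        out = channelwise_contrast_map(arr, "task_minus_rest_before")
        ordered = out.sort_values("p_uncorrected")
        assert np.all(np.diff(ordered["p_fdr"]) >= -1e-12)

    def test_unknown_contrast_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown contrast"):
            channelwise_contrast_map(np.zeros((3, 2, 7, 4)), "bogus")


class TestScoreChanges:
    def test_changes_are_visit_differences(self):
        scores = pd.DataFrame([
            {"subject_id": "S01", "visit": 1, "PAL": 10.0, "RTI": 300.0,
             "RVPA": 0.9},
            {"subject_id": "S01", "visit": 2, "PAL": 7.0, "RTI": 320.0,
             "RVPA": 0.95},
        ])
        out = score_changes(scores).set_index("subject")
        assert out.loc["S01", "PAL"] == pytest.approx(-3.0)
        assert out.loc["S01", "RTI"] == pytest.approx(20.0)
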