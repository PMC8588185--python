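import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from echocage.envelope import compute_envelope
from echocage.io import MISSING_DB
from echocage.stats import (
    build_event_table,
    classify_behavior,
    classify_level,
    composite_score,
    levene_test,
    score_event_table,
    synthetic_event_table,
    tukey_subsets,
    two_way_anova,
)

from oracles import anova_ss_oracle, levene_oracle, tukey_sig_oracle


class TestClassifyLevel:
    def test_lupara_very_high(self):
        assert classify_level(216.4) == "very_high"

    def test_background_93(self):
        assert classify_level(93.0) == "background"

    def test_165_is_high(self):
        assert classify_level(165.0) == "high"

    @pytest.mark.parametrize(
        "spl,expected",
        [
            (119.99, "background"),
            (120.0, "low"),
            (139.99, "low"),
            (140.0, "medium"),
            (149.99, "medium"),
            (150.0, "high"),
            (169.99, "high"),
            (170.0, "very_high"),
        ],
    )
    def test_half_open_bins(self, spl, expected):
        assert classify_level(spl) == expected

    def test_total_step_function(self):
        for spl in np.linspace(0, 250, 501):
            assert classify_level(spl) in (
                "background", "low", "medium", "high", "very_high",
            )


def _env_and_schedule(egram_factory, schedule_factory, n_events, span_s=None):
    dt = 5.0
    gap = 60.0
    span = span_s or (n_events * gap + 600.0)
    n_pings = int(span / dt)
    values = np.full((n_pings, 30), MISSING_DB)
    values[:, 11:13] = -40.0
    e = egram_factory(values, r0=0.0, dr=1.0, dt=dt)
    rows = [
        (f"e{i}", 300.0 + i * gap, 15.0, "tone", 50.0, 120.0 + (i % 5) * 12)
        for i in range(n_events)
    ]
    return e, compute_envelope(e, -70.0), schedule_factory(rows)


class TestEventTable:
    def test_35_events_day1(self, egram_factory, schedule_factory):
        e, env, sched = _env_and_schedule(egram_factory, schedule_factory, 35)
        table, skipped = build_event_table(sched, env, [], e.transducer_depth)
        assert len(table) <= 35
        assert len(table) + len(skipped) == 35

    def test_41_events_day2(self, egram_factory, schedule_factory):
        e, env, sched = _env_and_schedule(egram_factory, schedule_factory, 41)
        table, skipped = build_event_table(sched, env, [], e.transducer_depth)
        assert len(table) <= 41

    def test_empty_trace_table_no_crash(self, egram_factory, schedule_factory):
        e, env, sched = _env_and_schedule(egram_factory, schedule_factory, 5)
        table, _ = build_event_table(sched, env, [], e.transducer_depth)
        assert table["avg_trace_length"].isna().all()
        assert table["avg_depth"].notna().all()

    def test_out_of_span_events_reported(self, egram_factory, schedule_factory):
        e, env, sched = _env_and_schedule(egram_factory, schedule_factory, 3)
        rows = list(sched.rows.itertuples(index=False))
        far = pd.DataFrame(
            [("far", 1e6, 15.0, "tone", 50.0, 150.0)],
            columns=sched.rows.columns,
        )
        from echocage.io import EventSchedule

        sched2 = EventSchedule(pd.concat([sched.rows, far]))
        _, skipped = build_event_table(sched2, env, [], e.transducer_depth)
        assert skipped == ["far"]


class TestCompositeScore:
    def test_all_identical_to_baseline_all_b0(self):
        table = pd.DataFrame(
            {
                "delta_depth": np.zeros(6),
                "delta_extent": np.zeros(6),
                "delta_length": np.zeros(6),
                "delta_tilt": np.zeros(6),
            }
        )
        scores, _ = composite_score(table)
        assert np.all(classify_behavior(scores) == "B0")

    def test_single_variable_degenerate_case(self):
        vals = np.array([0.1, -0.2, 0.05, 3.0, -0.1, 0.15])
        table = pd.DataFrame({"delta_depth": vals})
        baseline = np.array([1, 1, 1, 0, 1, 1], dtype=bool)
        scores, loading = composite_score(
            table, baseline_mask=baseline, delta_cols=("delta_depth",)
        )
        mu = vals[baseline].mean()
        sd = vals[baseline].std(ddof=1)
        np.testing.assert_allclose(np.abs(scores), np.abs((vals - mu) / sd), rtol=1e-9)

    def test_responders_score_above_nulls(self, rng):
        n_null, n_resp = 40, 8
        table = pd.DataFrame(
            {
                "delta_depth": np.concatenate(
                    [rng.normal(0, 0.3, n_null), rng.normal(-4.0, 0.3, n_resp)]
                ),
                "delta_extent": np.concatenate(
                    [rng.normal(0, 0.4, n_null), rng.normal(-5.0, 0.4, n_resp)]
                ),
                "delta_length": rng.normal(0, 0.5, n_null + n_resp),
                "delta_tilt": rng.normal(0, 0.1, n_null + n_resp),
            }
        )
        baseline = np.arange(len(table)) < n_null
        scores, _ = composite_score(table, baseline_mask=baseline)
        null_scores = np.abs(scores[:n_null])
        resp_scores = np.abs(scores[n_null:])
        thresh = np.quantile(null_scores, 0.95)
        assert np.all(resp_scores > thresh)

    def test_monotone_classification(self):
        scores = np.array([0.0, 0.49, 0.5, 1.99, 2.0, 10.0, -3.0])
        classes = classify_behavior(scores, 0.5, 2.0)
        assert list(classes) == ["B0", "B0", "B1", "B1", "B2", "B2", "B2"]

    def test_all_missing_raises(self):
        table = pd.DataFrame({"delta_depth": [np.nan] * 5})
        with pytest.raises(ValueError):
            composite_score(table, delta_cols=("delta_depth",))


class TestLevene:
    def test_shifted_copies_w_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.concatenate([x, x + 10.0, x - 5.0])
        groups = np.repeat(["a", "b", "c"], 4)
        w, p = levene_test(values, groups)
        assert w == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_toy_matches_hand_oracle(self):
        g1 = [1.0, 2.0, 5.0]
        g2 = [2.0, 8.0, 2.0]
        values = np.array(g1 + g2)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        w, _ = levene_test(values, groups)
        assert w == pytest.approx(levene_oracle([g1, g2]), rel=1e-9)

    def test_matches_scipy_mean_centered(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 3, 20)
        w, p = levene_test(np.concatenate([a, b]), np.repeat(["a", "b"], [15, 20]))
        ws, ps = sps.levene(a, b, center="mean")
        assert w == pytest.approx(ws, rel=1e-9)
        assert p == pytest.approx(ps, rel=1e-9)

    def test_unequal_variance_detected(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 10, 20)
        _, p = levene_test(np.concatenate([a, b]), np.repeat(["a", "b"], 20))
        assert p < 0.05

    def test_singleton_group_named(self):
        with pytest.raises(ValueError, match="b"):
            levene_test(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


class TestTwoWayAnova:
    def test_identical_cells_f_zero(self):
        y = np.array([5.0] * 8)
        fa = np.repeat(["x", "y"], 4)
        fb = np.tile(["u", "v"], 4)
        res = two_way_anova(y, fa, fb)
        for eff in res.effects.itertuples():
            assert eff.ss == pytest.approx(0.0, abs=1e-18)
            assert eff.F == 0.0
            assert eff.p == 1.0

    def test_balanced_toy_matches_projection_oracle(self, rng):
        fa = np.repeat(["a1", "a2"], 6)
        fb = np.tile(np.repeat(["b1", "b2"], 3), 2)
        y = rng.normal(0, 1, 12) + (fa == "a2") * 2.0 + (fb == "b2") * 1.0
        res = two_way_anova(y, fa, fb)
        oracle = anova_ss_oracle(y, fa, fb)
        assert res.effects.loc["factor_a", "ss"] == pytest.approx(
            oracle["factor_a"], rel=1e-9
        )
        assert res.effects.loc["factor_b", "ss"] == pytest.approx(
            oracle["factor_b"], rel=1e-9
        )
        assert res.effects.loc["interaction", "ss"] == pytest.approx(
            oracle["interaction"], rel=1e-9
        )
        assert res.ss_resid == pytest.approx(oracle["resid"], rel=1e-9)

    def test_df_sum_to_n_minus_1(self, rng):
        fa = rng.choice(["a", "b", "c"], 30)
        fb = rng.choice(["u", "v"], 30)
        y = rng.normal(0, 1, 30)
        res = two_way_anova(y, fa, fb)
        assert res.effects["df"].sum() + res.df_resid == 29

    def test_one_factor_reduction_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 12)
        y = np.concatenate([a, b])
        fa = np.repeat(["a", "b"], [10, 12])
        res = two_way_anova(y, fa, None)
        t, _ = sps.ttest_ind(a, b)
        assert res.effects.loc["factor_a", "F"] == pytest.approx(t**2, rel=1e-9)

    def test_relabel_invariance(self, rng):
        fa = rng.choice(["a", "b", "c"], 40)
        fb = rng.choice(["u", "v"], 40)
        y = rng.normal(0, 1, 40)
        res1 = two_way_anova(y, fa, fb)
        relabel = {"a": "zz", "b": "qq", "c": "mm"}
        res2 = two_way_anova(y, np.array([relabel[x] for x in fa]), fb)
        np.testing.assert_allclose(
            np.sort(res1.effects["ss"]), np.sort(res2.effects["ss"]), rtol=1e-8
        )

    def test_constant_shift_invariance(self, rng):
        fa = rng.choice(["a", "b"], 24)
        fb = rng.choice(["u", "v", "w"], 24)
        y = rng.normal(0, 1, 24)
        res1 = two_way_anova(y, fa, fb)
        res2 = two_way_anova(y + 100.0, fa, fb)
        np.testing.assert_allclose(
            res1.effects["F"], res2.effects["F"], rtol=1e-7
        )

    def test_missing_cells_reduce_interaction_df(self):
        # 3x3 with several empty cells: full interaction df would be 4
        rng = np.random.default_rng(5)
        rows = []
        for a, b in [("t1", "lo"), ("t1", "hi"), ("t2", "lo"),
                     ("t2", "mid"), ("t3", "mid"), ("t3", "hi")]:
            for _ in range(4):
                rows.append((a, b, rng.normal()))
        fa = np.array([r[0] for r in rows])
        fb = np.array([r[1] for r in rows])
        y = np.array([r[2] for r in rows])
        res = two_way_anova(y, fa, fb)
        assert res.effects.loc["interaction", "df"] < 4
        assert res.effects["df"].sum() + res.df_resid == len(rows) - 1

    def test_aliased_design_raises(self):
        # factor_b fully determined by factor_a
        fa = np.repeat(["a", "b"], 6)
        fb = np.repeat(["u", "v"], 6)
        with pytest.raises(ValueError, match="aliased"):
            two_way_anova(np.arange(12.0), fa, fb)


class TestTukey:
    def test_identical_means_one_subset(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 10)
        values = np.concatenate([base, base, base])
        groups = np.repeat(["a", "b", "c"], 10)
        subsets, _ = tukey_subsets(values, groups, 0.05)
        assert len(subsets) == 1
        assert set(subsets[0]) == {"a", "b", "c"}

    def test_ten_sd_separation_singletons(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 10)
        b = rng.normal(10 * np.std(a, ddof=1) + a.mean() + 5, 1, 10)
        values = np.concatenate([a, b])
        groups = np.repeat(["a", "b"], 10)
        subsets, pairwise = tukey_subsets(values, groups, 0.05)
        assert len(subsets) == 2
        assert all(len(s) == 1 for s in subsets)
        sig = tukey_sig_oracle(values, groups, 0.05)
        assert pairwise.iloc[0].significant == sig[("a", "b")]

    def test_ab_close_c_far(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1, 12)
        b = rng.normal(0.1, 1, 12)
        c = rng.normal(25.0, 1, 12)
        values = np.concatenate([a, b, c])
        groups = np.repeat(["A", "B", "C"], 12)
        subsets, pairwise = tukey_subsets(values, groups, 0.05)
        assert sorted(map(sorted, subsets)) == [["A", "B"], ["C"]]
        sig = tukey_sig_oracle(values, groups, 0.05)
        for row in pairwise.itertuples():
            key = (row.group_1, row.group_2)
            key = key if key in sig else (key[1], key[0])
            assert row.significant == sig[key]

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(ValueError):
            tukey_subsets(np.array([1.0, 2.0]), np.array(["a", "a"]), 0.05)


class TestDetectionPower:
    def test_level_effect_power_and_type_false_positives(self):
        detected = 0
        type_fp = 0
        n_rep = 50
        for seed in range(n_rep):
            table = synthetic_event_table(seed, level_effect=1.0, type_effect=0.0)
            res = two_way_anova(
                table["avg_depth"], table["source_type"], table["level_class"]
            )
            if res.effects.loc["factor_b", "p"] < 0.05:
                detected += 1
            if res.effects.loc["factor_a", "p"] < 0.05:
                type_fp += 1
        assert detected >= 0.8 * n_rep
        assert type_fp <= 0.1 * n_rep


class TestScoreEventTable:
    def test_scores_and_classes_appended(self, rng):
        n = 12
        table = pd.DataFrame(
            {
                "level_class": ["background"] * 6 + ["high"] * 6,
                "delta_depth": np.concatenate(
                    [rng.normal(0, 0.3, 6), rng.normal(-4, 0.3, 6)]
                ),
                "delta_extent": np.concatenate(
                    [rng.normal(0, 0.3, 6), rng.normal(-3, 0.3, 6)]
                ),
                "delta_length": rng.normal(0, 0.3, n),
                "delta_tilt": rng.normal(0, 0.05, n),
            }
        )
        out = score_event_table(table)
        assert "composite_score" in out and "behavior_class" in out
        assert set(out["behavior_class"]) <= {"B0", "B1", "B2"}
        assert (
            np.abs(out[out.level_class == "high"]["composite_score"]).min()
            > np.abs(out[out.level_class == "background"]["composite_score"]).max()
        )
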