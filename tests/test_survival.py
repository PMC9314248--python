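"""Kaplan-Meier, log-rank, collinearity filter and Cox model."""

import numpy as np
import pandas as pd
import pytest

from mixture import survival as surv
from mixture import synthetic_cohort as synth


def _records(times, events, group="g"):
    return pd.DataFrame({"case_id": [f"c{i}" for i in range(len(times))],
                         "time": times, "event": events,
                         "group": [group] * len(times)})


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = surv.km_estimate(_records([5, 10, 15], [0, 0, 0]))
        assert np.all(km["g"]["survival"] == 1.0)

    def test_single_event_product_limit(self):
        km = surv.km_estimate(_records([5] + list(range(6, 15)),
                                       [1] + [0] * 9))
        g = km["g"]
        s_at_5 = g["survival"][g["times"] >= 5][0]
        assert s_at_5 == pytest.approx(0.9)

    def test_matches_product_limit_brute_force(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 50, 100).astype(float)
        events = rng.integers(0, 2, 100)
        km = surv.km_estimate(_records(times, events))["g"]
        # independent product over risk sets at each event time
        for t_query in (10.0, 25.0, 40.0):
            s = 1.0
            for t in sorted(set(times[events == 1])):
                if t > t_query:
                    break
                n_risk = np.sum(times >= t)
                d = np.sum((times == t) & (events == 1))
                s *= 1.0 - d / n_risk
            idx = np.searchsorted(km["times"], t_query, side="right") - 1
            assert km["survival"][idx] == pytest.approx(s, abs=1e-12)

    def test_curve_non_increasing_and_empirical_without_censoring(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(20, 50)
        km = surv.km_estimate(_records(times, np.ones(50, int)))["g"]
        assert np.all(np.diff(km["survival"]) <= 1e-12)
        # with no censoring KM equals the empirical survival function
        for tq in (5.0, 15.0, 30.0):
            idx = np.searchsorted(km["times"], tq, side="right") - 1
            assert km["survival"][idx] == pytest.approx(np.mean(times > tq))

    def test_horizon_survival_reported(self):
        km = surv.km_estimate(_records([100.0, 2000.0], [1, 0]),
                              horizons=(1826.0,))
        assert km["g"]["at_horizon"][1826.0] == pytest.approx(0.5)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        a = _records([5, 8, 12, 20], [1, 0, 1, 0], "A")
        b = _records([5, 8, 12, 20], [1, 0, 1, 0], "B")
        stat, p = surv.logrank_test(pd.concat([a, b]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_observed_minus_expected_on_six_records(self):
        # textbook two-group calculation, no ties across groups
        df = pd.concat([_records([1, 4, 6], [1, 1, 0], "A"),
                        _records([2, 3, 5], [1, 0, 1], "B")])
        stat, _ = surv.logrank_test(df)
        o_a, e_a, v = 0.0, 0.0, 0.0
        all_t = df["time"].to_numpy(); all_e = df["event"].to_numpy()
        grp_a = (df["group"] == "A").to_numpy()
        for t in sorted(set(all_t[all_e == 1])):
            at_risk = all_t >= t
            n = at_risk.sum()
            n_a = (at_risk & grp_a).sum()
            d = ((all_t == t) & (all_e == 1)).sum()
            d_a = ((all_t == t) & (all_e == 1) & grp_a).sum()
            o_a += d_a
            e_a += d * n_a / n
            if n > 1:
                v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_stat = (o_a - e_a) ** 2 / v
        assert stat == pytest.approx(expected_stat, rel=1e-6)

    def test_p_invariant_to_label_swap(self):
        rng = np.random.default_rng(3)
        df = pd.concat([_records(rng.exponential(10, 30), rng.integers(0, 2, 30), "A"),
                        _records(rng.exponential(14, 30), rng.integers(0, 2, 30), "B")])
        _, p1 = surv.logrank_test(df)
        swapped = df.assign(group=df["group"].map({"A": "B", "B": "A"}))
        _, p2 = surv.logrank_test(swapped)
        assert p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            surv.logrank_test(_records([1, 2], [1, 1]))


class TestFilterCollinear:
    def test_high_correlation_pair_pruned_to_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200)
        df = pd.DataFrame({"a": a, "b": a + 0.1 * rng.standard_normal(200)})
        kept, report = surv.filter_collinear(df, r_threshold=0.7)
        assert kept.shape[1] == 1
        assert report.iloc[0]["reason"] == "collinear"

    def test_independent_covariates_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        kept, report = surv.filter_collinear(df, r_threshold=0.7)
        assert list(kept.columns) == list("abcd") and len(report) == 0

    def test_three_mutually_correlated_leave_one(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(300)
        df = pd.DataFrame({c: base + 0.2 * rng.standard_normal(300)
                           for c in "xyz"})
        kept, _ = surv.filter_collinear(df, r_threshold=0.7)
        assert kept.shape[1] == 1

    def test_constant_covariate_dropped_with_reason(self):
        df = pd.DataFrame({"c": np.ones(50),
                           "x": np.random.default_rng(0).standard_normal(50)})
        kept, report = surv.filter_collinear(df, 0.7)
        assert list(kept.columns) == ["x"]
        assert (report["reason"] == "constant").any()

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(100)
        df = pd.DataFrame({"a": base, "b": base * 1.01, "c": -base,
                           "d": rng.standard_normal(100)})
        k1, r1 = surv.filter_collinear(df, 0.7)
        k2, r2 = surv.filter_collinear(df, 0.7)
        assert list(k1.columns) == list(k2.columns)
        pd.testing.assert_frame_equal(r1, r2)


def _cox_data(beta, n, censor_q=0.8, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, len(beta)))
    rate = 0.01 * np.exp(x @ beta)
    e_time = rng.exponential(1.0 / rate)
    horizon = np.quantile(e_time, censor_q)
    event = (e_time <= horizon).astype(int)
    t = np.minimum(e_time, horizon)
    df = pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))])
    df["case_id"] = [f"c{i}" for i in range(n)]
    df["time"], df["event"], df["group"] = t, event, "g"
    return df


class TestCox:
    def test_parameter_recovery_within_two_se(self):
        beta = np.array([0.5, -0.3])
        df = _cox_data(beta, 500, censor_q=0.8, seed=4)   # ~20% censoring
        res = surv.cox_fit(df, covariate_cols=["x0", "x1"])
        for i, b in enumerate(beta):
            row = res.summary.loc[f"x{i}"]
            assert abs(row["coef"] - b) < 2 * row["se"]

    def test_null_covariate_ci_covers_one(self):
        cover = 0
        for seed in range(100):
            df = _cox_data(np.array([0.0]), 120, censor_q=0.9, seed=seed)
            res = surv.cox_fit(df, covariate_cols=["x0"])
            row = res.summary.loc["x0"]
            cover += row["ci_lower"] <= 1.0 <= row["ci_upper"]
        assert cover >= 93

    def test_log_hr_scales_inversely_with_covariate(self):
        df = _cox_data(np.array([0.4]), 300, seed=6)
        res1 = surv.cox_fit(df, covariate_cols=["x0"])
        df2 = df.assign(x0=df["x0"] * 10.0)
        res2 = surv.cox_fit(df2, covariate_cols=["x0"])
        assert res2.summary.loc["x0", "coef"] == pytest.approx(
            res1.summary.loc["x0", "coef"] / 10.0, rel=1e-4)

    def test_binary_covariate_sign_agrees_with_logrank_direction(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 2, 200)
        t = rng.exponential(np.where(g == 1, 10, 25))
        df = pd.DataFrame({"case_id": [f"c{i}" for i in range(200)],
                           "time": t, "event": 1, "group": np.where(g == 1, "hi", "lo"),
                           "x0": g.astype(float)})
        res = surv.cox_fit(df, covariate_cols=["x0"])
        assert res.summary.loc["x0", "coef"] > 0   # group 1 dies faster
        km = surv.km_estimate(df)
        assert km["hi"]["at_horizon"][surv.FIVE_YEARS_DAYS] <= \
            km["lo"]["at_horizon"][surv.FIVE_YEARS_DAYS]

    def test_too_few_events_rejected(self):
        df = _cox_data(np.array([0.1, 0.2]), 20, seed=8)
        df["event"] = 0
        df.loc[df.index[:1], "event"] = 1
        with pytest.raises(ValueError):
            surv.cox_fit(df, covariate_cols=["x0", "x1"])

    def test_cohort_generator_null_effects_recovered(self):
        # beta = 0 in the slide generator: Cox on true compositions is null
        cfg = synth.SyntheticCohortConfig(
            n_cases=400, seed=11, cox_log_hr=np.zeros(4), base_size=64,
            region_grid=2)
        _, truth = synth.make_cohort(cfg)
        df = truth.rename(columns={"time_days": "time"})
        cols = ["prop_texture_0", "prop_texture_1", "prop_texture_2"]
        res = surv.cox_fit(df[["time", "event", *cols]].assign(
            case_id=truth["case_id"], group="g"), covariate_cols=cols)
        for c in cols:
            row = res.summary.loc[c]
            assert abs(row["coef"]) < 2 * row["se"]


class TestSubgroups:
    def test_duplicated_subgroups_identical_results(self):
        df = _cox_data(np.array([0.4]), 150, seed=9)
        both = pd.concat([df.assign(sub="p"), df.assign(sub="q")])
        out = surv.subgroup_analysis(both, "sub", covariate_cols=["x0"])
        assert set(out) == {"p", "q"}
        pd.testing.assert_frame_equal(out["p"].summary, out["q"].summary)

    def test_subgroup_effects_recovered_in_simulated_direction(self):
        rng = np.random.default_rng(10)
        frames = []
        for sub, b in (("s1", 0.8), ("s2", -0.5)):
            d = _cox_data(np.array([b]), 250, seed=int(rng.integers(2**31)))
            frames.append(d.assign(sub=sub))
        out = surv.subgroup_analysis(pd.concat(frames), "sub",
                                     covariate_cols=["x0"])
        assert out["s1"].summary.loc["x0", "coef"] > 0
        assert out["s2"].summary.loc["x0", "coef"] < 0

    def test_undersized_subgroup_skipped(self):
        df = _cox_data(np.array([0.3]), 100, seed=11)
        tiny = df.iloc[:2].assign(sub="tiny", event=0)
        out = surv.subgroup_analysis(pd.concat([df.assign(sub="big"), tiny]),
                                     "sub", covariate_cols=["x0"])
        assert "tiny" not in out and "big" in out
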