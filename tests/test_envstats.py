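import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from broilervision.datasets import load_trial_period_means
from broilervision.envstats import (aggregate_periods, compute_thi,
                                    correlate_periods, frame_to_summaries,
                                    kendall_pvalue, kendall_tau,
                                    read_sensor_csv, summaries_to_frame)


def tau_a_double_loop(x, y):
    """Independent oracle: the definitional double sum over ordered pairs."""
    n = len(x)
    s = 0.0
    for i in range(n):
        for j in range(n):
            s += math.copysign(1, x[i] - x[j]) * math.copysign(1, y[i] - y[j]) \
                if x[i] != x[j] and y[i] != y[j] else 0.0
    return s / (n * (n - 1))


class TestTHI:
    def test_vanishing_term_identity(self):
        """At T = 130/9 the humidity factor multiplies zero: THI = 58."""
        for rh in (0, 25, 60, 100):
            assert compute_thi(130 / 9, rh) == pytest.approx(58.0, abs=1e-9)

    def test_saturated_humidity_reduces_to_fahrenheit(self):
        for t in (-5, 0, 14, 30):
            assert compute_thi(t, 100) == pytest.approx(1.8 * t + 32, abs=1e-9)

    def test_hand_evaluated_example(self):
        assert compute_thi(20, 60) == pytest.approx(65.8, abs=1e-9)

    def test_out_of_range_humidity_rejected(self):
        with pytest.raises(ValueError):
            compute_thi(20, 101)


class TestAggregation:
    def _readings(self, rows):
        return pd.DataFrame(rows, columns=["timestamp", "nh3_ppm", "temp_c",
                                           "rh_pct"]).assign(
            timestamp=lambda d: pd.to_datetime(d["timestamp"]))

    def test_constant_window_mean(self):
        rows = [(f"2020-01-01 06:{m:02d}:00", 30.0, 15.0, 60.0)
                for m in range(60)]
        out = aggregate_periods(self._readings(rows))
        assert len(out) == 1
        s = out[0]
        assert s.mean_nh3 == 30.0
        assert s.thi == pytest.approx(compute_thi(15.0, 60.0))

    def test_hand_mean_and_window_edges(self):
        rows = [("2020-01-01 12:00:00", 10.0, 15.0, 60.0),
                ("2020-01-01 12:30:00", 20.0, 15.0, 60.0),
                ("2020-01-01 12:59:59", 30.0, 15.0, 60.0),
                ("2020-01-01 13:00:00", 99.0, 15.0, 60.0)]  # outside window
        out = aggregate_periods(self._readings(rows))
        assert len(out) == 1
        assert out[0].mean_nh3 == pytest.approx(20.0)

    def test_period_with_a_missing_field_is_dropped(self):
        rows = [("2020-01-01 12:10:00", None, 15.0, 60.0),
                ("2020-01-01 18:10:00", 12.0, 15.0, 60.0)]
        out = aggregate_periods(self._readings(rows))
        assert [s.period for s in out] == ["18:00-18:59"]

    def test_empty_input_is_empty_output(self):
        assert aggregate_periods(self._readings([])) == []

    def test_sensor_csv_round_trip(self, tmp_path):
        p = tmp_path / "sensors.csv"
        p.write_text("timestamp,nh3_ppm,temp_c,rh_pct\n"
                     "2020-01-01T06:00:00,30,15,60\n"
                     "2020-01-01T06:30:00,,15,60\n")
        df = read_sensor_csv(p)
        assert df["nh3_ppm"].isna().sum() == 1
        out = aggregate_periods(df)
        assert out[0].mean_nh3 == 30.0  # mean over present values only


class TestKendallTau:
    @pytest.mark.parametrize("variant", ["tau_a", "tau_b"])
    def test_perfect_concordance_and_discordance(self, variant):
        assert kendall_tau([1, 2, 3], [1, 2, 3], variant).tau == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3], [3, 2, 1], variant).tau == pytest.approx(-1.0)

    def test_hand_counted_four_point_example(self):
        # pairs: 5 concordant, 1 discordant -> (5-1)/6
        res = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4], "tau_a")
        assert res.tau == pytest.approx(4 / 6)

    def test_matches_definitional_double_loop_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.4:  # inject ties
                x = np.round(x)
                y = np.round(y)
            res = kendall_tau(x, y, "tau_a")
            assert res.tau == pytest.approx(tau_a_double_loop(x, y), abs=1e-12)

    def test_tau_b_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 60))
            x = np.round(rng.normal(size=n), 1)
            y = np.round(rng.normal(size=n), 1)
            ours = kendall_tau(x, y, "tau_b").tau
            ref = stats.kendalltau(x, y).statistic
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_variants_coincide_without_ties(self):
        rng = np.random.default_rng(6)
        x = rng.permutation(20).astype(float)
        y = rng.permutation(20).astype(float)
        assert kendall_tau(x, y, "tau_a").tau == pytest.approx(
            kendall_tau(x, y, "tau_b").tau)

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = kendall_tau(x, y, "tau_b").tau
        assert kendall_tau(np.exp(x), y, "tau_b").tau == pytest.approx(base)
        assert kendall_tau(x, 3 * y - 7, "tau_b").tau == pytest.approx(base)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            kendall_tau([1], [1])
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2], variant="tau_c")


class TestKendallPValue:
    def test_exact_p_for_perfect_concordance_of_three(self):
        """Of the 3! = 6 rank orders, two reach |tau| = 1: p = 1/3."""
        res = kendall_tau([1, 2, 3], [1, 2, 3])
        assert kendall_pvalue(res, method="exact") == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_null_centre_has_p_near_one(self):
        # two concordant blocks in discordant order: S = -n, nearly balanced
        x = np.arange(100, dtype=float)
        y = np.concatenate([np.arange(50, 100), np.arange(50)]).astype(float)
        res = kendall_tau(x, y)
        p = kendall_pvalue(res, method="normal_approx")
        assert abs(res.tau) < 0.1 and p > 0.5

    def test_exact_request_beyond_enumeration_falls_back_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        res = kendall_tau(x, y)
        p = kendall_pvalue(res, method="exact", n_resamples=100_000, seed=0)
        assert res.method == "permutation"
        assert 0 < p <= 1

    def test_exact_and_normal_agree_reasonably_midsize(self):
        x = np.arange(8, dtype=float)
        y = np.array([1.0, 0.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0])
        res = kendall_tau(x, y)
        pe = kendall_pvalue(res, method="exact")
        pn = kendall_pvalue(res, method="normal_approx")
        assert pe == pytest.approx(stats.kendalltau(x, y, method="exact").pvalue)
        assert abs(pe - pn) < 0.06


class TestCorrelatePeriods:
    def test_trial_tables_give_the_documented_association(self):
        """The bundled 24 winter-trial periods: strong positive THI-NH3 link."""
        res = correlate_periods(load_trial_period_means(), "thi", "mean_nh3",
                                variant="tau_b")
        assert res.n == 24
        assert res.tau == pytest.approx(0.512, abs=0.005)
        assert res.p_value < 0.01

    def test_self_correlation_is_one(self):
        res = correlate_periods(load_trial_period_means(), "thi", "thi")
        assert res.tau == pytest.approx(1.0)

    def test_monotone_toy_series_is_invariant_under_duplication(self):
        from broilervision.envstats import PeriodSummary

        rows = [PeriodSummary(date=f"2020-01-{d:02d}", period="06:00-06:59",
                              thi=float(d), mean_nh3=float(d * 2))
                for d in range(1, 6)]
        one = correlate_periods(rows, "thi", "mean_nh3", "tau_a").tau
        assert one == pytest.approx(1.0)

    def test_missing_values_are_dropped_listwise(self):
        rows = load_trial_period_means()
        rows[0].mean_nh3 = float("nan")
        res = correlate_periods(rows, "thi", "mean_nh3")
        assert res.n == 23

    def test_too_few_pairs_rejected(self):
        rows = load_trial_period_means()[:1]
        with pytest.raises(ValueError):
            correlate_periods(rows, "thi", "mean_nh3")

    def test_summary_csv_round_trip(self, tmp_path):
        rows = load_trial_period_means()
        df = summaries_to_frame(rows)
        p = tmp_path / "summaries.csv"
        df.to_csv(p, index=False)
        back = frame_to_summaries(pd.read_csv(p))
        assert [s.date for s in back] == [s.date for s in rows]
        assert np.allclose([s.thi for s in back], [s.thi for s in rows])


class TestCopulaRecovery:
    def test_estimated_tau_tracks_the_greiner_relation(self):
        """For bivariate Gaussians, tau -> (2/pi) arcsin(rho)."""
        rho, n, reps = 0.6, 500, 200
        target = 2 / np.pi * np.arcsin(rho)
        rng = np.random.default_rng(123)
        cov = [[1, rho], [rho, 1]]
        taus = []
        for _ in range(reps):
            z = rng.multivariate_normal([0, 0], cov, size=n)
            taus.append(kendall_tau(z[:, 0], z[:, 1], "tau_a").tau)
        taus = np.asarray(taus)
        se = taus.std(ddof=1) / np.sqrt(reps)
        assert abs(taus.mean() - target) <= 3 * se + 1e-3
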