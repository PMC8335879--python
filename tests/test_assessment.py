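import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from survmice.assessment import (
    bloom_rankits,
    calibration,
    calibration_slope,
    combined_d,
    d_statistic,
    km_estimate_at,
    ph_check,
    scaled_rankits_for,
    schoenfeld_residuals,
    uno_c,
    CalibrationResult,
)
from survmice.survival_models import fit_cox

from conftest import simulate_survival

SCALE = np.sqrt(np.pi / 8.0)


class TestBloomRankits:
    def test_single_subject_is_zero(self):
        assert bloom_rankits(1)[0] == 0.0

    def test_three_subjects_closed_form(self):
        z = bloom_rankits(3)
        assert z[1] == 0.0
        assert z[2] == pytest.approx(SCALE * norm.ppf(2.625 / 3.25), abs=1e-12)
        assert z[2] == pytest.approx(0.5449, abs=5e-4)

    @pytest.mark.parametrize("n", [2, 10, 1000, 10_000])
    def test_antisymmetric_and_increasing(self, n):
        z = bloom_rankits(n)
        assert np.max(np.abs(z + z[::-1])) < 1e-12
        assert np.all(np.diff(z) > 0)

    def test_large_n_sd_approaches_scale_factor(self):
        z = bloom_rankits(1000)
        assert np.std(z, ddof=1) == pytest.approx(SCALE, rel=0.02)

    def test_tied_pi_get_mid_rankits(self):
        z = scaled_rankits_for(np.array([1.0, 1.0, 2.0]))
        assert z[0] == z[1]
        # average rank 1.5 plugged into the Bloom formula
        assert z[0] == pytest.approx(SCALE * norm.ppf((1.5 - 0.375) / 3.25))


class TestDStatistic:
    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        pi = rng.normal(size=80)
        t = rng.exponential(10.0 / np.exp(pi))
        e = np.ones(80, int)
        d1, v1 = d_statistic(pi, t, e)
        d2, v2 = d_statistic(np.exp(pi), t, e)
        d3, _ = d_statistic(3 * pi - 7, t, e)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 == pytest.approx(d3, abs=1e-12)

    def test_toy_dataset_matches_independent_cox_on_rankits(self):
        """Six fixed subjects: D equals a brute-force maximisation of the
        explicit partial likelihood on the precomputed rankits."""
        from scipy.optimize import minimize_scalar

        pi = np.array([0.3, -1.2, 0.8, 0.1, -0.4, 1.5])
        time = np.array([5.0, 9.0, 2.0, 7.0, 1.0, 8.0])
        event = np.array([1, 1, 1, 0, 1, 1])
        d, var = d_statistic(pi, time, event)

        order = np.argsort(np.argsort(pi))  # ranks 0..5
        z = bloom_rankits(6)[order]

        def neg_pl(beta):
            ll = 0.0
            for i in range(6):
                if event[i]:
                    risk = np.exp(beta * z[time >= time[i]])
                    ll += beta * z[i] - np.log(risk.sum())
            return -ll

        res = minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-12})
        assert d == pytest.approx(res.x, abs=1e-8)
        assert var > 0

    def test_all_tied_pi_rejected(self):
        with pytest.raises(ValueError, match="all-tied"):
            d_statistic(np.ones(5), np.arange(1.0, 6.0), np.ones(5, int))

    def test_normal_pi_limit(self):
        """With PI ~ N(0, 1) and hazard proportional to exp(PI), D estimates
        sqrt(8/pi) * sigma ~ 1.596."""
        root = np.random.SeedSequence(314)
        ds = []
        for child in root.spawn(20):
            rng = np.random.default_rng(child)
            pi = rng.normal(size=2000)
            t = rng.exponential(1.0 / np.exp(pi))
            d, _ = d_statistic(pi, t, np.ones(2000, int))
            ds.append(d)
        assert np.mean(ds) == pytest.approx(np.sqrt(8 / np.pi), abs=0.1)


class TestCombinedD:
    def test_identical_imputations_have_zero_between_variance(self):
        rng = np.random.default_rng(1)
        pi = rng.normal(size=100)
        t = rng.exponential(5.0 / np.exp(pi))
        res = combined_d([pi, pi, pi], t, np.ones(100, int))
        assert res.pooled.between == 0.0

    def test_combined_is_mean_and_within_is_mean_variance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5.0, 200)
        pis = [rng.normal(size=200) for _ in range(4)]
        res = combined_d(pis, t, np.ones(200, int))
        per_d = [d for d, _ in res.per_imputation]
        per_v = [v for _, v in res.per_imputation]
        assert res.combined == pytest.approx(np.mean(per_d), abs=1e-12)
        assert res.pooled.within == pytest.approx(np.mean(per_v), abs=1e-12)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """times (1,2,3,4,5), censor at 3: S = 4/5, 3/5, 3/5, 3/10."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 0])
        s, lo, hi = km_estimate_at(time, event, 4.0)
        assert s == pytest.approx(0.3, abs=1e-12)
        assert lo < 0.3 < hi
        s2, *_ = km_estimate_at(time, event, 2.5)
        assert s2 == pytest.approx(0.6, abs=1e-12)

    def test_no_censoring_equals_empirical_fraction(self):
        time = np.arange(1.0, 11.0)
        event = np.ones(10, int)
        s, *_ = km_estimate_at(time, event, 5.5)
        assert s == pytest.approx(0.5, abs=1e-12)


def _fit_on_own_pi(n, rng, rate=0.05, censor_rate=0.01):
    X, time, event = simulate_survival(n, [0.8], rng, censor_rate=censor_rate,
                                       baseline=rate)
    fit = fit_cox(X, time, event, lam=0.001)
    return fit, X, time, event


class TestCalibration:
    def test_horizon_zero_is_all_ones(self):
        rng = np.random.default_rng(3)
        fit, X, time, event = _fit_on_own_pi(300, rng)
        cal = calibration([fit], [X], time, event, 0.0)
        tab = cal.tables[0]
        assert (tab["predicted"] == 1.0).all()
        assert np.allclose(tab["observed"].dropna(), 1.0)

    def test_identical_predictions_collapse_to_one_group(self):
        rng = np.random.default_rng(4)
        fit, X, time, event = _fit_on_own_pi(200, rng)
        X0 = pd.DataFrame({"x1": np.zeros(200)})
        cal = calibration([fit], [X0], time, event, 5.0)
        assert len(cal.tables[0]) == 1
        s, *_ = km_estimate_at(time, event, 5.0)
        assert cal.tables[0]["observed"].iloc[0] == pytest.approx(s)

    def test_well_specified_model_calibrates(self):
        """Predictions generated from the true model: the KM observed value
        should sit inside its CI around the predicted value for nearly all
        decile groups."""
        rng = np.random.default_rng(5)
        fit, X, time, event = _fit_on_own_pi(5000, rng, censor_rate=0.005)
        cal = calibration([fit], [X], time, event, 8.0)
        tab = cal.tables[0].dropna(subset=["observed"])
        inside = ((tab["ci_low"] <= tab["predicted"])
                  & (tab["predicted"] <= tab["ci_high"])).sum()
        assert inside >= 8

    def test_horizon_beyond_followup_rejected(self):
        rng = np.random.default_rng(6)
        fit, X, time, event = _fit_on_own_pi(100, rng)
        with pytest.raises(ValueError, match="beyond maximum follow-up"):
            calibration([fit], [X], time, event, time.max() * 2)


class TestCalibrationSlope:
    def _result(self, tables):
        return CalibrationResult(horizon=5.0, tables=tables)

    def test_identity_line_gives_slope_one(self):
        obs = np.linspace(0.3, 0.9, 10)
        tab = pd.DataFrame({"observed": obs, "predicted": obs})
        pooled, slopes = calibration_slope(self._result([tab]))
        assert pooled == pytest.approx(1.0, abs=1e-12)

    def test_affine_relation_recovers_slope(self):
        obs = np.linspace(0.3, 0.9, 10)
        tab = pd.DataFrame({"observed": obs, "predicted": 2 * obs - 0.3})
        pooled, _ = calibration_slope(self._result([tab]))
        assert pooled == pytest.approx(2.0, abs=1e-12)

    def test_pooled_is_mean_of_per_imputation_slopes(self):
        rng = np.random.default_rng(7)
        tabs = []
        for _ in range(10):
            obs = np.sort(rng.uniform(0.2, 0.95, 10))
            tabs.append(pd.DataFrame({
                "observed": obs,
                "predicted": obs * rng.uniform(0.5, 2.0) + rng.normal(0, 0.02, 10),
            }))
        pooled, slopes = calibration_slope(self._result(tabs))
        assert pooled == pytest.approx(np.mean(slopes), abs=1e-12)

    def test_too_few_points_rejected(self):
        tab = pd.DataFrame({"observed": [0.5], "predicted": [0.4]})
        with pytest.raises(ValueError, match="fewer than 2"):
            calibration_slope(self._result([tab]))


class TestPHCheck:
    def test_two_events_refused(self):
        X = pd.DataFrame({"x": [0.1, 0.2, 0.3]})
        fit = fit_cox(X, np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]), lam=0.001)
        with pytest.raises(ValueError, match="at least 3 events"):
            ph_check([fit], [X], np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]))

    def test_residuals_sum_to_zero_at_mle(self):
        rng = np.random.default_rng(8)
        X, time, event = simulate_survival(300, [0.7], rng, censor_rate=0.02)
        fit = fit_cox(X, time, event, lam=0.0)
        _, resid = schoenfeld_residuals(X, time, event, fit.coef)
        # the score vanishes at the MLE up to the solver's tolerance on beta
        assert abs(resid.sum()) < 1e-3 * np.abs(resid).sum()

    def test_power_against_reversing_effect(self):
        """Covariate effect flips sign at the median time: the residual-on-
        time regression should reject proportionality almost always."""
        root = np.random.SeedSequence(55)
        rejections = 0
        reps = 30
        for child in root.spawn(reps):
            rng = np.random.default_rng(child)
            n = 400
            x = rng.normal(size=n)
            t0, h0 = 10.0, 0.08
            e_std = rng.exponential(1.0, n)
            # piecewise hazard: exp(+x) before t0, exp(-x) after
            h1 = h0 * np.exp(x)
            t = np.where(e_std < h1 * t0, e_std / h1,
                         t0 + (e_std - h1 * t0) / (h0 * np.exp(-x)))
            X = pd.DataFrame({"x": x})
            event = np.ones(n, int)
            fit = fit_cox(X, t, event, lam=0.0)
            res = ph_check([fit], [X], t, event)
            rejections += res.any_violation
        assert rejections / reps >= 0.9


class TestUnoC:
    def test_perfect_anticoncordance_is_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pi = -time  # highest risk dies first
        assert uno_c(pi, time, np.ones(5, int), tau=4.5) == pytest.approx(1.0)

    def test_random_pi_near_half(self):
        rng = np.random.default_rng(9)
        n = 3000
        time = rng.exponential(10.0, n)
        pi = rng.normal(size=n)
        c = uno_c(pi, time, np.ones(n, int), tau=20.0)
        assert c == pytest.approx(0.5, abs=0.03)

    def test_five_subject_toy_matches_weighted_pair_enumeration(self):
        """One censored subject: exhaustive IPCW pair counting oracle."""
        time = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        event = np.array([1, 1, 0, 1, 1])
        pi = np.array([0.9, 0.1, 0.5, -0.3, -0.7])
        tau = 8.0
        # censoring-distribution KM (flip the indicator)
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(time, 1 - event)
        num = den = 0.0
        for i in range(5):
            if not event[i] or time[i] >= tau:
                continue
            g = float(kmf.predict(time[i]))
            w = 1.0 / g**2
            for j in range(5):
                if time[j] > time[i]:
                    den += w
                    if pi[i] > pi[j]:
                        num += w
                    elif pi[i] == pi[j]:
                        num += 0.5 * w
        expected = num / den
        assert uno_c(pi, time, event, tau=tau) == pytest.approx(expected, abs=1e-10)

    def test_equals_exhaustive_harrell_without_censoring(self):
        rng = np.random.default_rng(10)
        n = 60
        time = rng.exponential(5.0, n)
        pi = 0.5 * -np.log(time) + rng.normal(0, 0.5, n)
        event = np.ones(n, int)
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if time[i] < time[j]:
                    den += 1
                    if pi[i] > pi[j]:
                        num += 1
                    elif pi[i] == pi[j]:
                        num += 0.5
        assert uno_c(pi, time, event, tau=float(np.max(time)) + 1) == pytest.approx(
            num / den, abs=1e-10)

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            uno_c(np.array([0.1, 0.2]), np.array([1.0, 2.0]),
                  np.array([1, 1]), tau=0.0)
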