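"""Projection approaches against independent oracles: brute-force means,
normal-equations solutions, Box-Cox monotonicity, ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from baseline_ensemble import projection as proj
from baseline_ensemble.config import DEFAULT_VARIANT_SPANS, DRIVER_NAMES
from baseline_ensemble.synthetic_data import generate_panels


def _series(values, first_year=2000):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=np.arange(first_year, first_year + len(values)),
    )


def _window_means(panels, variant, window):
    start, length = window
    years = slice(start, start + length - 1)
    exog = pd.DataFrame(
        {p.jurisdiction_id: p.drivers_by_year.loc[years].mean() for p in panels}
    ).T
    actual = pd.Series(
        {
            p.jurisdiction_id: p.defor_by_variant[variant].loc[years].mean()
            for p in panels
        }
    )
    return exog, actual


class TestHistoricalAverage:
    def test_small_examples(self):
        assert proj.project_historical_average(
            _series([10, 12, 14]), (2000, 3)
        ).point_rate == pytest.approx(12.0)
        assert proj.project_historical_average(
            _series([5.0] * 12), (2003, 7)
        ).point_rate == pytest.approx(5.0)

    def test_hist_carries_no_uncertainty(self):
        r = proj.project_historical_average(_series([1, 2, 3, 4, 5]), (2000, 5))
        assert np.isnan(r.relative_uncertainty) and np.isnan(r.pi_lower)

    def test_brute_force_mean_oracle_100_windows(self):
        rng = np.random.default_rng(0)
        series = _series(rng.gamma(2.0, 10.0, size=40), 1990)
        for _ in range(100):
            start = int(rng.integers(1990, 2021))
            window = (start, 10)
            got = proj.project_historical_average(series, window).point_rate
            acc = 0.0  # independent re-summation
            for y in range(start, start + 10):
                acc += series.loc[y]
            assert got == pytest.approx(acc / 10.0, abs=1e-12)

    def test_window_outside_series_raises(self):
        with pytest.raises(proj.RangeError):
            proj.project_historical_average(_series([1, 2, 3]), (1999, 3))


class TestTimeFunction:
    def test_noiseless_linear_extrapolation(self):
        # rate(t) = 2 + t for t = 0..9 -> mean over t = 10..19 is 16.5
        r = proj.project_time_function(_series(2.0 + np.arange(10)), (2000, 10), 1)
        assert r.point_rate == pytest.approx(16.5, abs=1e-9)
        assert r.pi_upper - r.pi_lower == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_series_interpolated_exactly(self):
        t = np.arange(12, dtype=float)
        series = _series(3.0 + 0.5 * t + 0.25 * t**2)
        r = proj.project_time_function(series, (2000, 12), 2)
        c = r.diagnostics["coefficients"]
        fitted = c[0] + c[1] * t + c[2] * t**2
        np.testing.assert_allclose(fitted, series.to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("degree", [1, 2])
    def test_normal_equations_oracle_random_series(self, degree):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(degree + 3, 16))
            series = _series(rng.gamma(2.0, 5.0, size=n))
            r = proj.project_time_function(series, (2000, n), degree)
            t = np.arange(n, dtype=float)
            X = np.column_stack([t**d for d in range(degree + 1)])
            beta = np.linalg.solve(X.T @ X, X.T @ series.to_numpy())
            np.testing.assert_allclose(
                r.diagnostics["coefficients"], beta, atol=1e-8
            )

    def test_prediction_interval_widens_with_noise(self):
        rng = np.random.default_rng(5)
        base = 2.0 + np.arange(10.0)
        quiet = proj.project_time_function(
            _series(base + rng.normal(0, 0.01, 10)), (2000, 10), 1
        )
        loud = proj.project_time_function(
            _series(base + rng.normal(0, 2.0, 10)), (2000, 10), 1
        )
        assert (loud.pi_upper - loud.pi_lower) > (quiet.pi_upper - quiet.pi_lower)

    def test_too_short_window_raises(self):
        with pytest.raises(proj.RangeError):
            proj.project_time_function(_series([1, 2, 3]), (2000, 3), 2)


class TestBoxCox:
    @pytest.mark.parametrize("lam", [-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0])
    def test_inverse_preserves_ordering(self, lam):
        rng = np.random.default_rng(int(10 * (lam + 3)))
        z = np.sort(rng.normal(0.0, 2.0, size=300))
        y = proj.inv_boxcox(z, lam)
        # out-of-domain values saturate at 0 / +inf; cap so diff is defined
        assert np.all(np.diff(np.clip(y, 0.0, 1e18)) >= 0)
        assert np.all(y >= 0)

    def test_round_trip_against_scipy(self):
        import scipy.special

        rng = np.random.default_rng(3)
        y = rng.gamma(2.0, 3.0, size=200) + 0.1
        z, lam, offset = proj.boxcox_transform(y)
        assert offset == 0.0
        np.testing.assert_allclose(proj.inv_boxcox(z, lam), y, rtol=1e-9)
        np.testing.assert_allclose(
            proj.inv_boxcox(z, lam), scipy.special.inv_boxcox(z, lam), rtol=1e-9
        )

    def test_zero_responses_get_offset(self):
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 8.0])
        z, lam, offset = proj.boxcox_transform(y)
        assert offset == pytest.approx(0.5)
        assert np.all(np.isfinite(z))

    def test_constant_response_rejected(self):
        with pytest.raises(proj.FitError):
            proj.boxcox_transform(np.full(10, 3.0))


@pytest.fixture(scope="module")
def recovery_panels(request):
    """200 noise-free jurisdictions whose latent rate is an exact function
    of the drivers (shared module-level cache)."""
    from baseline_ensemble.config import GeneratorConfig

    cfg = GeneratorConfig(
        n_jurisdictions=200,
        seed=0,
        subdivision_threshold_km2=1e12,
        forest_area_sigma=0.0,
        ar1_coefficient=0.0,
        process_noise_sd=0.0,
        observation_noise_cv={v: 0.0 for v in DEFAULT_VARIANT_SPANS},
        dataset_bias_factors={v: 1.0 for v in DEFAULT_VARIANT_SPANS},
    )
    return [p for p, _ in generate_panels(cfg)]


class TestDriverModel:
    def test_underdetermined_scope_raises(self, recovery_panels):
        tiny = recovery_panels[:3]
        with pytest.raises(proj.FitError):
            proj.fit_driver_model(tiny, "global", "hansen30", (2001, 10))

    def test_noiseless_recovery_within_one_percent(self, recovery_panels):
        window = (2001, 10)
        model = proj.fit_driver_model(recovery_panels, "global", "hansen30", window)
        exog, actual = _window_means(recovery_panels, "hansen30", window)
        pred = proj.predict_driver_model_batch(model, exog)["point_rate"]
        rel = ((pred - actual).abs() / actual).median()
        assert rel < 0.01

    def test_stepwise_retains_planted_drivers(self, gen_config):
        retained = 0
        for s in range(5):
            cfg = gen_config(
                n_jurisdictions=200,
                seed=300 + s,
                ar1_coefficient=0.0,
                process_noise_sd=0.3,
                observation_noise_cv={v: 0.05 for v in DEFAULT_VARIANT_SPANS},
            )
            panels = [p for p, _ in generate_panels(cfg)]
            m = proj.fit_driver_model(panels, "global", "hansen30", (2001, 10))
            if set(DRIVER_NAMES[:4]) <= set(m.retained_drivers):
                retained += 1
        assert retained >= 4

    def test_prediction_is_linear_algebra_on_transformed_scale(self, recovery_panels):
        window = (2001, 10)
        model = proj.fit_driver_model(recovery_panels, "global", "hansen30", window)
        table = proj.build_fit_table(recovery_panels, "global", "hansen30", window)
        kept = table[~table["jurisdiction_id"].isin(model.outlier_ids)]
        z, lam, off = proj.boxcox_transform(table["response"].to_numpy())
        z_kept = z[~table["jurisdiction_id"].isin(model.outlier_ids).to_numpy()]
        X = np.column_stack(
            [np.ones(len(kept))]
            + [kept[d].to_numpy() for d in model.retained_drivers]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ z_kept)  # independent oracle
        drivers = kept.iloc[0][list(model.retained_drivers)]
        r = proj.predict_driver_model(model, drivers)
        expected_z = beta[0] + beta[1:] @ drivers.to_numpy(dtype=float)
        assert r.diagnostics["z_point"] == pytest.approx(expected_z, abs=1e-8)

    def test_prediction_at_sample_mean_is_mean_response(self, recovery_panels):
        # OLS with intercept passes through the mean of the fit sample
        window = (2001, 10)
        model = proj.fit_driver_model(recovery_panels, "global", "hansen30", window)
        table = proj.build_fit_table(recovery_panels, "global", "hansen30", window)
        kept = table[~table["jurisdiction_id"].isin(model.outlier_ids)]
        z, lam, off = proj.boxcox_transform(table["response"].to_numpy())
        z_kept = z[~table["jurisdiction_id"].isin(model.outlier_ids).to_numpy()]
        r = proj.predict_driver_model(model, kept[list(model.retained_drivers)].mean())
        assert r.diagnostics["z_point"] == pytest.approx(z_kept.mean(), abs=1e-8)

    def test_intervals_ordered_after_back_transform(self, gen_config):
        cfg = gen_config(n_jurisdictions=120, seed=21)
        panels = [p for p, _ in generate_panels(cfg)]
        window = (2001, 8)
        model = proj.fit_driver_model(panels, "global", "modis", window)
        exog, _ = _window_means(panels, "modis", window)
        batch = proj.predict_driver_model_batch(model, exog)
        finite = batch[np.isfinite(batch["pi_upper"])]
        assert len(finite) > 100
        assert (finite["pi_lower"] <= finite["point_rate"] + 1e-12).all()
        assert (finite["point_rate"] <= finite["pi_upper"] + 1e-12).all()


class TestEnsemble:
    def test_single_member_full_subset_collapses_to_plain_fit(self, recovery_panels):
        window = (2001, 10)
        em = proj.fit_ensemble(
            recovery_panels, "global", "hansen30", window,
            reps=1, size_range=(12, 12), seed=4,
        )
        assert em.n_members == 1 and em.member_subsets[0] == tuple(sorted(DRIVER_NAMES))
        full = proj.fit_driver_model(
            recovery_panels, "global", "hansen30", window, stepwise=False
        )
        drivers = recovery_panels[0].drivers_by_year.loc[2001:2010].mean()
        a = proj.predict_ensemble(em, drivers).point_rate
        b = proj.predict_driver_model(full, drivers).point_rate
        assert a == pytest.approx(b, rel=1e-12)

    def test_same_seed_reproduces_members_and_prediction(self, recovery_panels):
        window = (2001, 10)
        kw = dict(reps=10, size_range=(3, 11), seed=99)
        em1 = proj.fit_ensemble(recovery_panels, "global", "hansen30", window, **kw)
        em2 = proj.fit_ensemble(recovery_panels, "global", "hansen30", window, **kw)
        assert em1.member_subsets == em2.member_subsets
        drivers = recovery_panels[1].drivers_by_year.loc[2001:2010].mean()
        assert (
            proj.predict_ensemble(em1, drivers).point_rate
            == proj.predict_ensemble(em2, drivers).point_rate
        )

    def test_noiseless_single_driver_recovery_within_one_percent(self, noise_free_config):
        cfg = noise_free_config(
            n_jurisdictions=150, seed=11, n_drivers=1, n_active_drivers=1,
            driver_effect_sizes=(0.8,),
        )
        panels = [p for p, _ in generate_panels(cfg)]
        window = (2001, 10)
        em = proj.fit_ensemble(panels, "global", "hansen30", window, reps=20, seed=5)
        exog, actual = _window_means(panels, "hansen30", window)
        pred = proj.predict_ensemble_batch(em, exog)["point_rate"]
        assert ((pred - actual).abs() / actual).median() < 0.01


class TestScreenNonnegative:
    def _result(self, point, lo=np.nan, hi=np.nan):
        return proj.ProjectionResult(point, lo, hi, np.nan, "linear")

    def test_negative_rate_flagged_invalid(self):
        assert proj.screen_nonnegative(self._result(-3.0)).valid is False

    def test_zero_rate_is_valid(self):
        assert proj.screen_nonnegative(self._result(0.0)).valid is True

    def test_negative_lower_bound_floored(self):
        r = proj.screen_nonnegative(self._result(7.0, -1.0, 9.0))
        assert r.valid and r.pi_lower == 0.0 and r.pi_upper == 9.0


class TestStationarySeries:
    def test_all_approaches_agree_on_stationary_noise_free_panels(self, noise_free_config):
        # constant-in-time rates that are an exact function of one
        # time-constant driver: every approach should return (nearly) the
        # historical average
        cfg = noise_free_config(
            n_jurisdictions=120, seed=31, n_drivers=1, n_active_drivers=1,
            driver_effect_sizes=(0.6,), driver_drift_sd=0.0,
        )
        panels = [p for p, _ in generate_panels(cfg)]
        window = (2001, 10)
        series0 = panels[0].defor_by_variant["hansen30"]
        hist = proj.project_historical_average(series0, window).point_rate
        assert proj.project_time_function(series0, window, 1).point_rate == pytest.approx(hist, abs=1e-8)
        assert proj.project_time_function(series0, window, 2).point_rate == pytest.approx(hist, abs=1e-7)

        exog, actual = _window_means(panels, "hansen30", window)
        full = proj.fit_driver_model(panels, "global", "hansen30", window)
        pred_full = proj.predict_driver_model_batch(full, exog)["point_rate"]
        rel_full = ((pred_full - actual).abs() / actual).median()
        assert rel_full < 0.02

        region = panels[0].region
        in_region = [p for p in panels if p.region == region]
        reg = proj.fit_driver_model(in_region, region, "hansen30", window)
        exog_r, actual_r = _window_means(in_region, "hansen30", window)
        pred_reg = proj.predict_driver_model_batch(reg, exog_r)["point_rate"]
        assert ((pred_reg - actual_r).abs() / actual_r).median() < 0.02

        em = proj.fit_ensemble(panels, "global", "hansen30", window, reps=10, seed=1)
        pred_em = proj.predict_ensemble_batch(em, exog)["point_rate"]
        assert ((pred_em - actual).abs() / actual).median() < 0.02
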