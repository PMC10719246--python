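"""Deforestation-rate projection approaches and their 90% prediction intervals.

Seven approaches are implemented, in three families:

``hist``
    continuation of the average annual rate over the historical reference
    window (no model, hence no model-based uncertainty);
``linear`` / ``poly2``
    least-squares time functions (degree 1 / 2) fitted on the reference
    window and extrapolated as the mean prediction over the following
    window of equal length;
``global`` / ``regional``
    linear regressions of the (Box-Cox transformed) per-jurisdiction mean
    rate on up to 12 driver covariates, fitted on all jurisdictions
    (global) or per region, with one-pass studentized-residual outlier
    removal and bidirectional stepwise elimination by AIC;
``global_s`` / ``regional_s``
    multi-model ensembles: the mean of many repetitions of the above
    regression fitted on random subsets of 3-11 drivers.

Uncertainty is the 90% prediction interval — from the OLS predictive
distribution for time functions and driver models (back-transformed
through the monotone Box-Cox inverse), and from the 5th/95th percentiles
of member predictions for ensembles.  Relative uncertainty is the interval
half-width divided by the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from ._rng import stream
from .synthetic_data import DataError, JurisdictionPanel

__all__ = [
    "ProjectionResult",
    "DriverModel",
    "EnsembleModel",
    "RangeError",
    "FitError",
    "EnsembleError",
    "project_historical_average",
    "project_time_function",
    "fit_driver_model",
    "predict_driver_model",
    "fit_ensemble",
    "predict_ensemble",
    "ensemble_predict",
    "screen_nonnegative",
    "boxcox_transform",
    "inv_boxcox",
    "build_fit_table",
]

PI_ALPHA = 0.10  # two-sided 90% prediction interval


class RangeError(ValueError):
    """A requested window lies outside the available series."""


class FitError(RuntimeError):
    """A regression fit is infeasible (under-determined or degenerate)."""


class EnsembleError(RuntimeError):
    """Too many ensemble members failed to fit."""


@dataclass
class ProjectionResult:
    """A projected deforestation rate with a 90% prediction interval.

    ``pi_lower``/``pi_upper`` and ``relative_uncertainty`` are NaN when the
    approach assigns no model-based uncertainty (``hist``).
    """

    point_rate: float
    pi_lower: float
    pi_upper: float
    relative_uncertainty: float
    approach: str
    valid: bool = True
    diagnostics: dict = field(default_factory=dict)


def _rel_uncertainty(point: float, lo: float, hi: float) -> float:
    if not np.isfinite(lo) or not np.isfinite(hi) or not point > 0:
        return float("nan")
    return (hi - lo) / (2.0 * point)


def _window_years(window: tuple[int, int]) -> np.ndarray:
    start, length = window
    if length < 1:
        raise RangeError(f"window length {length} < 1")
    return np.arange(start, start + length)


def _window_slice(series: pd.Series, window: tuple[int, int]) -> pd.Series:
    years = _window_years(window)
    missing = [int(y) for y in years if y not in series.index]
    if missing:
        raise RangeError(f"window years {missing} outside series span")
    return series.loc[years]


# ---------------------------------------------------------------------------
# hist and time functions


def project_historical_average(
    series: pd.Series, window: tuple[int, int]
) -> ProjectionResult:
    """Arithmetic mean annual rate over the reference window.

    Carries no model-based uncertainty: prediction intervals are only
    derived from the time-function and driver models, so ``hist``
    combinations are excluded from uncertainty summaries downstream.
    """
    values = _window_slice(series, window)
    point = float(values.mean())
    return ProjectionResult(
        point_rate=point,
        pi_lower=float("nan"),
        pi_upper=float("nan"),
        relative_uncertainty=float("nan"),
        approach="hist",
        diagnostics={"n": len(values)},
    )


def project_time_function(
    series: pd.Series,
    window: tuple[int, int],
    degree: int,
    horizon: int | None = None,
) -> ProjectionResult:
    """Polynomial-in-time extrapolation of the reference window.

    Fits rate ~ poly(year) of the given degree over the window and projects
    the mean of the fitted curve over the ``horizon`` years immediately
    following the window (default: a future window of the same length).
    The 90% interval is the prediction interval for that mean of ``horizon``
    future observations: ``t_{0.95,df} * sqrt(c'Vc + sigma^2/h)`` where
    ``c`` is the mean future design row.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    values = _window_slice(series, window)
    length = len(values)
    if length < degree + 2:
        raise RangeError(f"window length {length} < degree + 2")
    if horizon is None:
        horizon = length
    t = values.index.to_numpy(dtype=float) - window[0]
    if np.ptp(t) == 0:
        raise FitError("degenerate design: all years identical")
    X = np.column_stack([t**d for d in range(degree + 1)])
    res = sm.OLS(values.to_numpy(dtype=float), X).fit()
    t_future = np.arange(length, length + horizon, dtype=float)
    C = np.column_stack([t_future**d for d in range(degree + 1)]).mean(axis=0)
    point = float(C @ res.params)
    var_mean = float(C @ res.cov_params() @ C)
    sigma2 = float(res.mse_resid) if res.df_resid > 0 else 0.0
    se = np.sqrt(max(var_mean + sigma2 / horizon, 0.0))
    tq = scipy.stats.t.ppf(1 - PI_ALPHA / 2, res.df_resid) if res.df_resid > 0 else 0.0
    lo, hi = point - tq * se, point + tq * se
    return ProjectionResult(
        point_rate=point,
        pi_lower=lo,
        pi_upper=hi,
        relative_uncertainty=_rel_uncertainty(point, lo, hi),
        approach={1: "linear", 2: "poly2"}[degree],
        diagnostics={"coefficients": res.params.tolist(), "sigma2": sigma2},
    )


# ---------------------------------------------------------------------------
# Box-Cox helpers


def boxcox_transform(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with ML lambda; zero values handled by an offset.

    The offset is half the smallest positive value and is added before the
    transform (and subtracted after back-transform).  Returns
    ``(transformed, lambda, offset)``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise FitError("responses must be >= 0")
    offset = 0.0
    if np.any(y == 0):
        positive = y[y > 0]
        if positive.size == 0:
            raise FitError("all responses are zero; transform undefined")
        offset = 0.5 * float(positive.min())
    shifted = y + offset
    if np.ptp(shifted) == 0:
        raise FitError("constant response; Box-Cox transform undefined")
    transformed, lam = scipy.stats.boxcox(shifted)
    return transformed, float(lam), offset


def inv_boxcox(z: float | np.ndarray, lam: float) -> float | np.ndarray:
    """Monotone inverse of the Box-Cox transform, extended to the closure.

    Transformed values outside the image of (0, inf) map to the boundary:
    for lambda > 0 the image is (-1/lambda, inf) and values below map to 0;
    for lambda < 0 the image is (-inf, -1/lambda) and values above map to
    +inf.  This keeps interval endpoints ordered after back-transform.
    """
    z = np.asarray(z, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        if lam == 0:
            out = np.exp(z)
        else:
            base = z * lam + 1.0
            out = np.where(
                base > 0,
                np.power(np.clip(base, 1e-300, None), 1.0 / lam),
                0.0 if lam > 0 else np.inf,
            )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# driver models


@dataclass
class DriverModel:
    """A fitted Box-Cox / stepwise driver regression."""

    scope: str  # "global" or a region name
    dataset_variant: str
    window: tuple[int, int]
    boxcox_lambda: float
    offset: float
    retained_drivers: tuple[str, ...]
    coefficients: dict[str, float]
    outlier_ids: tuple[str, ...]
    results: object  # statsmodels OLSResults on the transformed scale
    n_obs: int
    diagnostics: dict = field(default_factory=dict)


def build_fit_table(
    panels: Sequence[JurisdictionPanel],
    scope: str,
    dataset_variant: str,
    window: tuple[int, int],
) -> pd.DataFrame:
    """Per-jurisdiction responses and window-averaged drivers for a fit.

    Response = mean annual deforestation over the reference window for the
    given dataset variant; drivers are averaged over the same window.  Only
    jurisdictions in scope with a positive mean rate enter.
    """
    years = _window_years(window)
    rows = []
    for p in panels:
        if scope != "global" and p.region != scope:
            continue
        series = p.defor_by_variant.get(dataset_variant)
        if series is None or any(y not in series.index for y in years):
            continue
        y = float(series.loc[years].mean())
        if not y > 0:
            continue
        drv = p.drivers_by_year.loc[p.drivers_by_year.index.intersection(years)].mean()
        rows.append({"jurisdiction_id": p.jurisdiction_id, "response": y, **drv})
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _ols_aic(y: np.ndarray, Xmat: np.ndarray) -> float:
    """Gaussian AIC of an OLS fit (design already includes the constant);
    matches statsmodels' convention up to the shared constant term."""
    n = len(y)
    beta, _, _, _ = np.linalg.lstsq(Xmat, y, rcond=None)
    rss = float(np.sum((y - Xmat @ beta) ** 2))
    rss = max(rss, 1e-300)
    llf = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    return -2.0 * llf + 2.0 * Xmat.shape[1]


def _stepwise_aic(
    y: np.ndarray, X: pd.DataFrame, start: Sequence[str]
) -> list[str]:
    """Bidirectional stepwise search minimising AIC.

    Starts from the full supplied subset; at each step considers every
    single-variable drop and every single-variable re-addition and takes
    the best AIC improvement.  At least one driver is always retained.
    """
    pool = list(X.columns)
    cols_mat = {c: X[c].to_numpy(dtype=float) for c in pool}
    ones = np.ones(len(X))

    def aic(cols: list[str]) -> float:
        Xmat = np.column_stack([ones] + [cols_mat[c] for c in cols])
        return _ols_aic(y, Xmat)

    current = [c for c in pool if c in set(start)]
    best = aic(current)
    while True:
        candidates: list[tuple[float, list[str]]] = []
        if len(current) > 1:
            for c in current:
                cols = [x for x in current if x != c]
                candidates.append((aic(cols), cols))
        for c in pool:
            if c not in current:
                cols = [x for x in pool if x in current or x == c]
                candidates.append((aic(cols), cols))
        if not candidates:
            return current
        best_aic, cols = min(candidates, key=lambda t: t[0])
        if best_aic < best - 1e-10:
            best, current = best_aic, cols
        else:
            return current


def _studentized_external(y: np.ndarray, Xmat: np.ndarray) -> np.ndarray:
    """Externally studentized residuals of an OLS fit (QR-based leverage)."""
    n, p = Xmat.shape
    if n <= p + 1:
        return np.zeros(n)
    Q, _ = np.linalg.qr(Xmat)
    h = np.clip((Q**2).sum(axis=1), 0.0, 1.0 - 1e-10)
    beta, _, _, _ = np.linalg.lstsq(Xmat, y, rcond=None)
    e = y - Xmat @ beta
    rss = float(e @ e)
    mse = rss / (n - p)
    if mse <= 0:
        return np.zeros(n)
    r = e / np.sqrt(mse * (1.0 - h))
    # external variant: scale by the leave-one-out residual variance
    denom = np.maximum(n - p - r**2, 1e-12)
    return r * np.sqrt((n - p - 1.0) / denom)


def fit_driver_model(
    panels: Sequence[JurisdictionPanel],
    scope: str,
    dataset_variant: str,
    window: tuple[int, int],
    driver_subset: Sequence[str] | None = None,
    stepwise: bool = True,
    min_fit_margin: int = 5,
    _table: pd.DataFrame | None = None,
    _transform: tuple[np.ndarray, float, float] | None = None,
) -> DriverModel:
    """Fit one driver regression for a scope / variant / window cell.

    Pipeline: Box-Cox transform of the response (ML lambda), one-pass
    removal of observations with \\|studentized residual\\| > 3 from a
    preliminary fit on the full supplied subset, then (optionally)
    bidirectional stepwise elimination by AIC.
    """
    table = (
        _table
        if _table is not None
        else build_fit_table(panels, scope, dataset_variant, window)
    )
    available = [c for c in table.columns if c not in ("jurisdiction_id", "response")]
    subset = list(driver_subset) if driver_subset is not None else available
    if len(table) < len(subset) + min_fit_margin:
        raise FitError(
            f"{scope}/{dataset_variant}/{window}: {len(table)} jurisdictions "
            f"for {len(subset)} drivers (need >= {len(subset) + min_fit_margin})"
        )
    if _transform is not None:
        z, lam, offset = _transform
    else:
        z, lam, offset = boxcox_transform(table["response"].to_numpy())

    X = table[subset]
    Xmat = np.column_stack([np.ones(len(table))] + [X[c].to_numpy(float) for c in subset])
    student = _studentized_external(z, Xmat)
    keep = np.abs(np.nan_to_num(student)) <= 3.0
    outlier_ids = tuple(table.loc[~keep, "jurisdiction_id"])
    table_k, z_k = table.loc[keep], z[keep]
    if len(table_k) < len(subset) + 2:
        # outlier pass may not leave the system under-determined
        table_k, z_k, outlier_ids = table, z, ()

    X_k = table_k[subset]
    retained = _stepwise_aic(z_k, X_k, subset) if stepwise else list(subset)
    res = _ols(z_k, X_k[retained])
    coefs = dict(zip(res.model.exog_names, res.params))
    return DriverModel(
        scope=scope,
        dataset_variant=dataset_variant,
        window=window,
        boxcox_lambda=lam,
        offset=offset,
        retained_drivers=tuple(retained),
        coefficients=coefs,
        outlier_ids=outlier_ids,
        results=res,
        n_obs=len(table_k),
        diagnostics={"aic": float(res.aic), "r2": float(res.rsquared)},
    )


def predict_driver_model(
    model: DriverModel, drivers: Mapping[str, float], approach: str = "global"
) -> ProjectionResult:
    """Predict a jurisdiction's rate with a 90% prediction interval.

    The point and interval are computed on the transformed scale and mapped
    back through the monotone Box-Cox inverse (which preserves endpoint
    ordering), then the zero-handling offset is subtracted and the result
    floored at zero.
    """
    row = {}
    for d in model.retained_drivers:
        v = drivers.get(d) if hasattr(drivers, "get") else drivers[d]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise DataError(f"missing driver value {d!r}")
        row[d] = float(v)
    exog = pd.DataFrame([row])[list(model.retained_drivers)]
    exog = sm.add_constant(exog, has_constant="add")
    pred = model.results.get_prediction(exog)
    sf = pred.summary_frame(alpha=PI_ALPHA)
    z_point = float(sf["mean"].iloc[0])
    z_lo = float(sf["obs_ci_lower"].iloc[0])
    z_hi = float(sf["obs_ci_upper"].iloc[0])
    lam, off = model.boxcox_lambda, model.offset
    point = max(inv_boxcox(z_point, lam) - off, 0.0)
    lo = max(inv_boxcox(z_lo, lam) - off, 0.0)
    hi = max(inv_boxcox(z_hi, lam) - off, 0.0)
    return ProjectionResult(
        point_rate=float(point),
        pi_lower=float(lo),
        pi_upper=float(hi),
        relative_uncertainty=_rel_uncertainty(point, lo, hi),
        approach=approach,
        diagnostics={"z_point": z_point, "lambda": lam, "offset": off},
    )


def predict_driver_model_batch(
    model: DriverModel, exog_df: pd.DataFrame, approach: str = "global"
) -> pd.DataFrame:
    """Vectorised :func:`predict_driver_model` for many jurisdictions.

    ``exog_df`` has one row per jurisdiction and one column per driver;
    returns a frame (same index) with ``point_rate, pi_lower, pi_upper,
    relative_uncertainty`` on the rate scale.
    """
    missing = [d for d in model.retained_drivers if d not in exog_df.columns]
    if missing:
        raise DataError(f"missing driver column(s) {missing}")
    if exog_df[list(model.retained_drivers)].isna().any().any():
        raise DataError("missing driver value(s) in batch prediction")
    exog = sm.add_constant(exog_df[list(model.retained_drivers)], has_constant="add")
    sf = model.results.get_prediction(exog).summary_frame(alpha=PI_ALPHA)
    lam, off = model.boxcox_lambda, model.offset
    point = np.maximum(inv_boxcox(sf["mean"].to_numpy(), lam) - off, 0.0)
    lo = np.maximum(inv_boxcox(sf["obs_ci_lower"].to_numpy(), lam) - off, 0.0)
    hi = np.maximum(inv_boxcox(sf["obs_ci_upper"].to_numpy(), lam) - off, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(point > 0, (hi - lo) / (2.0 * point), np.nan)
    return pd.DataFrame(
        {
            "point_rate": point,
            "pi_lower": lo,
            "pi_upper": hi,
            "relative_uncertainty": rel,
        },
        index=exog_df.index,
    )


# ---------------------------------------------------------------------------
# random-subset ensembles


@dataclass
class EnsembleModel:
    """Members of a random-driver-subset ensemble for one fit cell."""

    scope: str
    dataset_variant: str
    window: tuple[int, int]
    members: list[DriverModel]
    member_subsets: list[tuple[str, ...]]
    n_failed: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def fit_ensemble(
    panels: Sequence[JurisdictionPanel],
    scope: str,
    dataset_variant: str,
    window: tuple[int, int],
    reps: int = 300,
    size_range: tuple[int, int] = (3, 11),
    seed: int = 0,
    driver_pool: Sequence[str] | None = None,
    member_stepwise: bool = False,
    min_fit_margin: int = 5,
) -> EnsembleModel:
    """Fit ``reps`` driver regressions on random subsets of 3-11 drivers.

    Subset sizes are drawn uniformly from ``size_range`` (clipped to the
    pool size) and drivers sampled without replacement.  Members whose fit
    fails are dropped and counted; more than 50% failures aborts.
    """
    table = build_fit_table(panels, scope, dataset_variant, window)
    if len(table) == 0:
        raise FitError(f"{scope}/{dataset_variant}/{window}: no jurisdictions in scope")
    transform = boxcox_transform(table["response"].to_numpy())
    rng = stream(seed, "ensemble", scope, dataset_variant, *window)
    if driver_pool is None:
        driver_pool = [
            c for c in table.columns if c not in ("jurisdiction_id", "response")
        ]
    pool = list(driver_pool)
    lo = min(size_range[0], len(pool))
    hi = min(size_range[1], len(pool))
    members, subsets, n_failed = [], [], 0
    for _ in range(reps):
        size = int(rng.integers(lo, hi + 1))
        subset = tuple(sorted(rng.choice(pool, size=size, replace=False)))
        subsets.append(subset)
        try:
            members.append(
                fit_driver_model(
                    panels,
                    scope,
                    dataset_variant,
                    window,
                    driver_subset=subset,
                    stepwise=member_stepwise,
                    min_fit_margin=min_fit_margin,
                    _table=table,
                    _transform=transform,
                )
            )
        except (FitError, DataError):
            n_failed += 1
    if n_failed > reps / 2:
        raise EnsembleError(
            f"{scope}/{dataset_variant}/{window}: {n_failed}/{reps} members failed"
        )
    return EnsembleModel(
        scope=scope,
        dataset_variant=dataset_variant,
        window=window,
        members=members,
        member_subsets=subsets,
        n_failed=n_failed,
    )


def predict_ensemble(
    model: EnsembleModel, drivers: Mapping[str, float], approach: str = "global_s"
) -> ProjectionResult:
    """Ensemble prediction: mean of member back-transformed points, with the
    interval taken as the 5th/95th percentiles of the member spread."""
    points = np.array(
        [predict_driver_model(m, drivers, approach).point_rate for m in model.members]
    )
    if points.size == 0:
        raise EnsembleError("ensemble has no members")
    with np.errstate(invalid="ignore"):
        point = float(points.mean())
        lo, hi = (float(v) for v in np.percentile(points, [5.0, 95.0]))
    return ProjectionResult(
        point_rate=point,
        pi_lower=lo,
        pi_upper=hi,
        relative_uncertainty=_rel_uncertainty(point, lo, hi),
        approach=approach,
        diagnostics={"n_members": model.n_members, "n_failed": model.n_failed},
    )


def predict_ensemble_batch(
    model: EnsembleModel, exog_df: pd.DataFrame, approach: str = "global_s"
) -> pd.DataFrame:
    """Vectorised :func:`predict_ensemble`: one member prediction pass per
    member, aggregated per jurisdiction (mean, 5th/95th percentiles)."""
    if not model.members:
        raise EnsembleError("ensemble has no members")
    points = np.vstack(
        [
            predict_driver_model_batch(m, exog_df, approach)["point_rate"].to_numpy()
            for m in model.members
        ]
    )
    with np.errstate(invalid="ignore"):
        point = points.mean(axis=0)
        lo, hi = np.percentile(points, [5.0, 95.0], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(point > 0, (hi - lo) / (2.0 * point), np.nan)
    return pd.DataFrame(
        {
            "point_rate": point,
            "pi_lower": lo,
            "pi_upper": hi,
            "relative_uncertainty": rel,
        },
        index=exog_df.index,
    )


def ensemble_predict(
    panels: Sequence[JurisdictionPanel],
    scope: str,
    dataset_variant: str,
    window: tuple[int, int],
    drivers: Mapping[str, float],
    reps: int = 300,
    size_range: tuple[int, int] = (3, 11),
    seed: int = 0,
    **kwargs,
) -> ProjectionResult:
    """One-shot fit + predict for a single jurisdiction's drivers."""
    model = fit_ensemble(
        panels, scope, dataset_variant, window, reps, size_range, seed, **kwargs
    )
    return predict_ensemble(model, drivers)


# ---------------------------------------------------------------------------
# screening


def screen_nonnegative(result: ProjectionResult) -> ProjectionResult:
    """Reject negative projected rates; floor valid intervals at zero.

    Negative projections are flagged invalid (and excluded from all
    downstream statistics) rather than clamped: a method producing them
    would be rejected outright in an actual baseline submission.
    """
    if result.point_rate < 0 or not np.isfinite(result.point_rate):
        result.valid = False
    else:
        result.valid = True
        if np.isfinite(result.pi_lower):
            result.pi_lower = max(result.pi_lower, 0.0)
    return result
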