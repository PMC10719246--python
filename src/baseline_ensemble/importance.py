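"""Bootstrapped random-forest variable importance over the method grid.

Which grid parameter (projection approach, forest dataset, reference
length, carbon mask / AGB / BGB / SOC source) moves the baseline most?
Many random-forest regressions of the baseline on the grid parameters are
fitted, each on a random subsample of rows, and permutation importance is
extracted per parameter from rows the model did not train on; means and
standard errors are taken across models.  Permutation importance is used
because it is comparable across mixed categorical/ordinal predictors and
invariant to monotone rescaling of the response; categorical parameters
are ordinal-encoded, which permutation (whole-column shuffling) treats
identically to any other encoding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from ._rng import stream, substream_seed

__all__ = ["DEFAULT_PARAMETERS", "variable_importance"]

log = logging.getLogger(__name__)

#: grid parameters used as predictors (start_year optional via config)
DEFAULT_PARAMETERS = (
    "approach",
    "defor_variant",
    "ref_length",
    "carbon_mask_variant",
    "agb_source",
    "bgb_source",
    "soc_source",
)


def variable_importance(
    baselines: pd.DataFrame,
    parameters=DEFAULT_PARAMETERS,
    n_models: int = 100,
    n_trees: int = 200,
    sample_rows: int = 900000,
    seed: int = 0,
    min_samples_leaf: int = 5,
    eval_rows: int = 10000,
    n_permutation_repeats: int = 2,
) -> pd.DataFrame:
    """Mean +/- SE permutation importance per grid parameter.

    Each of ``n_models`` forests trains on ``sample_rows`` rows drawn
    without replacement (auto-shrunk to the available rows, logged) and is
    scored by permutation importance on up to ``eval_rows`` out-of-sample
    rows.  Single-level parameters are dropped with a warning; a constant
    response yields importances indistinguishable from zero.

    Returns one row per parameter: ``parameter, importance_mean,
    importance_se, n_models, rank`` (rank 1 = most important).
    """
    df = baselines[
        baselines["valid"]
        & np.isfinite(baselines["baseline"].to_numpy(dtype=float))
    ]
    if len(df) == 0:
        raise ValueError("no valid baseline records")
    params = []
    for p in parameters:
        if df[p].nunique() < 2:
            log.warning("dropping single-level predictor %r", p)
        else:
            params.append(p)
    if not params:
        raise ValueError("no predictor has more than one level")

    X = np.column_stack(
        [pd.Categorical(df[p].astype(str)).codes.astype(np.float32) for p in params]
    )
    y = df["baseline"].to_numpy(dtype=np.float64)
    n = len(y)
    rows_per_model = min(sample_rows, n)
    if rows_per_model < sample_rows:
        log.info("sample_rows shrunk from %d to %d available rows", sample_rows, n)

    per_model = np.empty((n_models, len(params)))
    for m in range(n_models):
        rng = stream(seed, "importance", m)
        train_idx = rng.choice(n, size=rows_per_model, replace=False)
        if rows_per_model < n:
            mask = np.ones(n, dtype=bool)
            mask[train_idx] = False
            out_idx = np.flatnonzero(mask)
            if len(out_idx) > eval_rows:
                out_idx = rng.choice(out_idx, size=eval_rows, replace=False)
        else:
            out_idx = (
                train_idx
                if n <= eval_rows
                else rng.choice(n, size=eval_rows, replace=False)
            )
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            min_samples_leaf=min_samples_leaf,
            n_jobs=1,
            random_state=substream_seed(seed, "forest", m),
        )
        forest.fit(X[train_idx], y[train_idx])
        imp = permutation_importance(
            forest,
            X[out_idx],
            y[out_idx],
            n_repeats=n_permutation_repeats,
            random_state=substream_seed(seed, "perm", m),
            n_jobs=1,
        )
        per_model[m] = imp.importances_mean

    mean = per_model.mean(axis=0)
    se = per_model.std(axis=0, ddof=1) / np.sqrt(n_models) if n_models > 1 else np.zeros(len(params))
    out = pd.DataFrame(
        {
            "parameter": params,
            "importance_mean": mean,
            "importance_se": se,
            "n_models": n_models,
        }
    )
    out["rank"] = (
        out["importance_mean"].rank(ascending=False, method="first").astype(int)
    )
    out.attrs["per_model"] = per_model
    return out.sort_values("rank").reset_index(drop=True)
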