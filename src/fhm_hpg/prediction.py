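"""Posterior-predictive simulation: a pool of fish from the posterior.

Thinned MCMC draws are treated as a population; simulating a study samples
n parameter sets (with replacement) to represent its n fish, runs each fish
deterministically, and then draws observed endpoints from the lognormal
error model using the error variances of the same posterior iteration, so
parameter-variance correlation is preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import DEFAULT_PRIORS, var_column
from .dataset import ENDPOINTS
from .exposure import ExposureScenario
from .parameters import ModelParameters, Physiology
from .simulate import ENDPOINT_COLUMNS, SolverOptions, initialize_baseline, simulate

__all__ = ["sample_fish", "predict_endpoints", "posterior_predictive",
           "coverage_report", "relative_change"]

PREDICTION_PERCENTILES = (5, 10, 25, 50, 75, 90, 95)


def sample_fish(pool: pd.DataFrame, n: int, rng) -> pd.DataFrame:
    """Uniformly sample ``n`` parameter sets (with replacement) from the
    pooled posterior; each draw keeps its iteration's error variances."""
    if len(pool) == 0:
        raise ValueError("posterior pool is empty")
    if n < 1:
        raise ValueError("need n >= 1 fish")
    idx = rng.integers(0, len(pool), size=n)
    out = pool.iloc[idx].reset_index(drop=True)
    out.insert(0, "draw_index", idx)
    return out


def _params_from_row(row, base_params: ModelParameters) -> ModelParameters:
    updates = {k: float(row[k]) for k in DEFAULT_PRIORS if k in row.index}
    return base_params.replace(**updates)


def predict_endpoints(param_set: pd.Series, physiology: Physiology | None,
                      scenario: ExposureScenario | None, times, rng,
                      group: str = "unexposed",
                      base_params: ModelParameters | None = None,
                      solver: SolverOptions | None = None,
                      baseline: np.ndarray | None = None,
                      variances: dict | None = None) -> pd.DataFrame:
    """Deterministic predictions and lognormal observation draws for one fish.

    ``param_set`` is one posterior row (calibrated parameters + variance
    columns); missing physiology falls back to the population medians.
    Returns one row per (time, endpoint) with both the deterministic
    prediction and the sampled observation.
    """
    base_params = base_params or ModelParameters()
    physiology = physiology or Physiology()
    solver = solver or SolverOptions().coarse()
    params = _params_from_row(param_set, base_params)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if baseline is None:
        baseline = initialize_baseline(physiology, params, solver)
    grid = np.unique(np.concatenate(([0.0], times)))
    res = simulate(physiology, params, scenario, grid, y0=baseline,
                   solver=solver)
    obs = res.observables
    rows = []
    for e in ENDPOINTS:
        if variances is not None:
            v = variances[(group, e)]
        else:
            col = var_column(group, e)
            v = float(param_set[col]) if col in param_set.index else 0.0
        for t in times:
            yhat = float(obs.loc[res.times == t, ENDPOINT_COLUMNS[e]].iloc[0])
            draw = yhat
            if v > 0 and yhat > 0:
                draw = float(np.exp(rng.normal(np.log(yhat), np.sqrt(v))))
            rows.append({"time_hr": float(t), "endpoint": e,
                         "deterministic_pred": yhat, "sampled_obs": draw})
    return pd.DataFrame(rows)


def posterior_predictive(pool: pd.DataFrame, n: int,
                         scenario: ExposureScenario | None, times, rng,
                         group: str = "unexposed",
                         physiology: Physiology | None = None,
                         base_params: ModelParameters | None = None,
                         solver: SolverOptions | None = None) -> pd.DataFrame:
    """Simulate a study of ``n`` fish sampled from the posterior pool.

    Output is long-form: fish_id, draw_index, group, time_hr, endpoint,
    deterministic_pred, sampled_obs.  Baselines are warm-started across
    fish, which share the (median) physiology.
    """
    fish = sample_fish(pool, n, rng)
    solver = solver or SolverOptions().coarse()
    base_params = base_params or ModelParameters()
    physiology = physiology or Physiology()
    out, warm = [], None
    for i, (_, row) in enumerate(fish.iterrows()):
        params = _params_from_row(row, base_params)
        warm = initialize_baseline(physiology, params, solver, seed_state=warm)
        df = predict_endpoints(row, physiology, scenario, times, rng,
                               group=group, base_params=base_params,
                               solver=solver, baseline=warm)
        df.insert(0, "fish_id", i)
        df.insert(1, "draw_index", int(row["draw_index"]))
        df.insert(2, "group", group)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def coverage_report(predictions: pd.DataFrame,
                    observations: pd.DataFrame) -> pd.DataFrame:
    """Compare posterior-predictive draws with observed endpoint medians.

    Both frames are long-form with columns group, time_hr, endpoint and a
    value column (``sampled_obs`` for predictions, ``value`` for
    observations).  Per (group, endpoint, time): the 5/10/25/50/75/90/95
    prediction percentiles, the observed median, whether that median falls
    inside the central 95% prediction interval, and the median ratio.
    """
    keys = ["group", "endpoint", "time_hr"]
    rows = []
    for key, pred in predictions.groupby(keys, sort=True):
        obs = observations
        for col, val in zip(keys, key):
            obs = obs[obs[col] == val]
        draws = pred["sampled_obs"].to_numpy(dtype=float)
        pct = np.percentile(draws, PREDICTION_PERCENTILES)
        row = dict(zip(keys, key))
        row.update({f"pred_p{p}": v for p, v in
                    zip(PREDICTION_PERCENTILES, pct)})
        lo, hi = np.percentile(draws, [2.5, 97.5])
        if len(obs):
            med = float(np.median(obs["value"]))
            row["observed_median"] = med
            row["median_in_95ci"] = bool(lo <= med <= hi)
            row["median_ratio"] = row["pred_p50"] / med if med > 0 else np.nan
        else:
            row["observed_median"] = np.nan
            row["median_in_95ci"] = False
            row["median_ratio"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def relative_change(exposed: pd.DataFrame, control: pd.DataFrame,
                    endpoint: str = "VTG") -> np.ndarray:
    """Exposed / control ratios of sampled endpoint draws (assay-agnostic
    comparison used when absolute scales differ between ELISA methods)."""
    e = exposed.loc[exposed["endpoint"] == endpoint, "sampled_obs"].to_numpy()
    c = control.loc[control["endpoint"] == endpoint, "sampled_obs"].to_numpy()
    m = min(len(e), len(c))
    if m == 0:
        raise ValueError("no draws for the requested endpoint")
    return e[:m] / c[:m]
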