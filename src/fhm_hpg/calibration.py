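"""Bayesian calibration by Metropolis-within-Gibbs MCMC.

Seventeen structural parameters carry lognormal / (log)uniform priors and
are updated one at a time by random-walk Metropolis (log-space walks for
positive-support priors, linear for uniform ones, with the log-transform
Jacobian folded into the transformed posterior).  The nine grouped error
variances of the lognormal measurement model (3 exposure groups x 3 plasma
endpoints) carry conjugate inverse-gamma priors and are redrawn exactly by
a Gibbs sweep each iteration.

The measurement model: observed endpoints are lognormal with geometric mean
equal to the model prediction, so log-scale residuals are normal with the
cell's variance.  One forward simulation per candidate parameter set serves
every fish of a treatment group (groups share their median physiology).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .dataset import ENDPOINT_TO_COLUMN, ENDPOINTS, GROUPS, Dataset
from .parameters import ModelParameters, Physiology
from .simulate import ENDPOINT_COLUMNS, SolverOptions, initialize_baseline, simulate

__all__ = [
    "LognormalPrior", "LogUniformPrior", "UniformPrior", "InverseGammaPrior",
    "DEFAULT_PRIORS", "ERROR_VARIANCE_PRIORS", "variance_cells", "log_prior",
    "ForwardModel", "log_likelihood", "gibbs_update_variances",
    "metropolis_step", "run_chains", "McmcOptions", "McmcResult",
    "pool_posterior", "rhat", "summarize_posterior",
]


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------
class _Prior:
    log_scale = True      # propose on the log scale by default

    def logpdf(self, x: float) -> float:
        raise NotImplementedError

    def sample(self, rng, size=None):
        raise NotImplementedError

    def logpdf_transformed(self, u: float) -> float:
        """Log density in proposal space (adds the log-transform Jacobian)."""
        if self.log_scale:
            return self.logpdf(math.exp(u)) + u
        return self.logpdf(u)


@dataclass(frozen=True)
class LognormalPrior(_Prior):
    """Lognormal with geometric mean ``gm`` and geometric SD ``gsd``."""

    gm: float
    gsd: float
    log_scale = True

    def logpdf(self, x):
        if x <= 0:
            return -math.inf
        s = math.log(self.gsd)
        z = (math.log(x) - math.log(self.gm)) / s
        return -math.log(x * s) - 0.5 * math.log(2.0 * math.pi) - 0.5 * z * z

    def sample(self, rng, size=None):
        return self.gm * np.exp(math.log(self.gsd)
                                * rng.standard_normal(size))


@dataclass(frozen=True)
class LogUniformPrior(_Prior):
    lo: float
    hi: float
    log_scale = True

    def logpdf(self, x):
        if not (self.lo <= x <= self.hi):
            return -math.inf
        return -math.log(x) - math.log(math.log(self.hi / self.lo))

    def sample(self, rng, size=None):
        return np.exp(rng.uniform(math.log(self.lo), math.log(self.hi), size))


@dataclass(frozen=True)
class UniformPrior(_Prior):
    lo: float
    hi: float
    log_scale = False

    def logpdf(self, x):
        if not (self.lo <= x <= self.hi):
            return -math.inf
        return -math.log(self.hi - self.lo)

    def sample(self, rng, size=None):
        return rng.uniform(self.lo, self.hi, size)


@dataclass(frozen=True)
class InverseGammaPrior(_Prior):
    shape: float
    scale: float
    log_scale = True

    def logpdf(self, x):
        if x <= 0:
            return -math.inf
        a, b = self.shape, self.scale
        return a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(x) - b / x

    def sample(self, rng, size=None):
        return self.scale / rng.gamma(self.shape, 1.0, size)


#: priors of the 17 calibrated structural parameters (attribute names of
#: :class:`~fhm_hpg.parameters.ModelParameters`)
DEFAULT_PRIORS = {
    "lam_tb_bld": LogUniformPrior(1.0, 1.0e3),
    "kd_e2er_brn": LognormalPrior(8.6, 3.0),
    "rba_ee2_e2": LognormalPrior(1.66, 3.0),
    "rba_tb_t": LognormalPrior(6.03, 3.0),
    "rho_d_lh": LogUniformPrior(0.01, 1.0e3),
    "rho_u_lh": LogUniformPrior(0.01, 1.0e3),
    "n_t": LognormalPrior(1.8, 3.0),
    "rho_chol_gon": LogUniformPrior(1.0, 5.0e3),
    "sc_vmax_aro_gon": LogUniformPrior(2.3e-5, 0.23),
    "rho_e2_lhlr_gon": LogUniformPrior(0.1, 100.0),
    "sc_vmax_vtg_liv": LogUniformPrior(1.0, 1.0e4),
    "n_vtg": UniformPrior(1.0, 10.0),
    "pbg_er_liv": LogUniformPrior(5.0e-5, 0.5),
    "k_er_liv": LognormalPrior(0.08, 3.0),
    "pbg_ar_brn": LogUniformPrior(5.0e-5, 0.5),
    "k_ar_brn": LogUniformPrior(5.0e-4, 5.0),
    "mag_lh": LogUniformPrior(2.7e-7, 2.7e-3),
}

#: inverse-gamma (shape, scale) priors of the log-scale error variances,
#: shared by all three exposure groups
ERROR_VARIANCE_PRIORS = {
    "E2": InverseGammaPrior(2.0, 1.19),
    "T": InverseGammaPrior(2.0, 0.53),
    "VTG": InverseGammaPrior(2.0, 5.31),
}


def variance_cells():
    """The nine (group, endpoint) error-variance cells."""
    return [(g, e) for g in GROUPS for e in ENDPOINTS]


def var_column(group: str, endpoint: str) -> str:
    return f"var_{group}_{endpoint}"


def log_prior(theta: dict, priors: dict | None = None) -> float:
    """Sum of log prior densities; -inf outside any support."""
    priors = priors or DEFAULT_PRIORS
    total = 0.0
    for name, value in theta.items():
        total += priors[name].logpdf(value)
        if not np.isfinite(total):
            return -math.inf
    return float(total)


# --------------------------------------------------------------------------
# forward model and likelihood
# --------------------------------------------------------------------------
class ForwardModel:
    """Deterministic endpoint predictions for every record of a dataset.

    Fish of one exposure group share the group's median physiology, so one
    simulation per (group, scenario) covers the whole group; the baseline
    search is warm-started from the previous evaluation's baseline.
    """

    def __init__(self, dataset: Dataset, base_params: ModelParameters,
                 solver: SolverOptions | None = None,
                 per_fish_physiology: bool = False):
        self.dataset = dataset
        self.base_params = base_params
        self.solver = solver or SolverOptions().coarse()
        self.per_fish = per_fish_physiology
        df = dataset.fill_physiology()
        self._units = []          # (physiology, scenario, times) per sim unit
        self._rows = []           # per record: (unit_idx, time, cell, {endpoint: y})
        if per_fish_physiology:
            keys = df[["fish_id", "group", "scenario_id"]].drop_duplicates()
            grouper = ["fish_id", "group", "scenario_id"]
        else:
            grouper = ["group", "scenario_id"]
        for key, sub in df.groupby(grouper, sort=True):
            gid = key[-2] if per_fish_physiology else key[0]
            sid = key[-1]
            phys = Physiology(body_weight=float(sub["bw_kg"].median()),
                              gsi=float(sub["gsi_pct"].median()),
                              hsi=float(sub["hsi_pct"].median()))
            times = np.unique(sub["time_hr"].to_numpy(dtype=float))
            unit_idx = len(self._units)
            self._units.append((phys, dataset.scenario_for(sid), times))
            for _, row in sub.iterrows():
                obs = {}
                for e, col in ENDPOINT_TO_COLUMN.items():
                    if pd.notna(row[col]):
                        obs[e] = float(row[col])
                self._rows.append((unit_idx, float(row["time_hr"]),
                                   (gid, ), obs))
        # cells carry the group name; endpoint added per observation
        self._rows = [(u, t, g[0], obs) for (u, t, g, obs) in self._rows]
        self._warm = [None] * len(self._units)

    def reset_warm_start(self, baseline=None):
        seed = None if baseline is None else np.asarray(baseline).copy()
        self._warm = [seed] * len(self._units)

    def predict(self, theta: dict):
        """Endpoint predictions; returns {(unit, time, endpoint): yhat} or
        None when the forward integration fails.  Each simulation unit keeps
        its own warm-started baseline (per-unit physiology)."""
        params = self.base_params.replace(**theta)
        preds = {}
        for u, (phys, scenario, times) in enumerate(self._units):
            try:
                baseline = initialize_baseline(phys, params, self.solver,
                                               seed_state=self._warm[u])
            except Exception:
                return None
            self._warm[u] = baseline
            grid = np.unique(np.concatenate(([0.0], times)))
            try:
                res = simulate(phys, params, scenario, grid,
                               y0=baseline, solver=self.solver)
            except Exception:
                return None
            obs = res.observables
            for t, row in zip(res.times, obs.itertuples(index=False)):
                for e in ENDPOINTS:
                    preds[(u, float(t), e)] = getattr(row, ENDPOINT_COLUMNS[e])
        return preds

    def residual_stats(self, theta: dict):
        """(n, sum-of-squares) of log residuals per (group, endpoint) cell."""
        preds = self.predict(theta)
        if preds is None:
            return None
        stats_ = {cell: [0, 0.0] for cell in variance_cells()}
        for unit, t, group, obs in self._rows:
            for e, y in obs.items():
                yhat = preds[(unit, t, e)]
                if not (np.isfinite(yhat) and yhat > 0):
                    return None
                r = math.log(y) - math.log(yhat)
                cell = stats_[(group, e)]
                cell[0] += 1
                cell[1] += r * r
        return {c: (n, ss) for c, (n, ss) in stats_.items()}


def log_likelihood(resid_stats: dict, variances: dict) -> float:
    """Lognormal measurement log likelihood from per-cell residual stats.

    ``resid_stats`` maps (group, endpoint) to (n, SS) of log-scale
    residuals; ``variances`` maps the same cells to Var_ln.  The additive
    constant -sum(log y) is dropped (it cancels in every MCMC ratio).
    """
    if resid_stats is None:
        return -math.inf
    ll = 0.0
    for cell, (n, ss) in resid_stats.items():
        if n == 0:
            continue
        v = variances[cell]
        if v <= 0:
            return -math.inf
        ll += -0.5 * n * math.log(2.0 * math.pi * v) - ss / (2.0 * v)
    return ll


def gibbs_update_variances(resid_stats: dict, rng,
                           priors: dict | None = None) -> dict:
    """Exact conjugate draw of each error-variance cell.

    Posterior is inverse-gamma(shape + n/2, scale + SS/2); cells without
    data reduce to prior draws.
    """
    priors = priors or ERROR_VARIANCE_PRIORS
    out = {}
    for (group, endpoint) in variance_cells():
        n, ss = resid_stats.get((group, endpoint), (0, 0.0)) \
            if resid_stats else (0, 0.0)
        pr = priors[endpoint]
        out[(group, endpoint)] = float(
            (pr.scale + ss / 2.0) / rng.gamma(pr.shape + n / 2.0))
    return out


# --------------------------------------------------------------------------
# Metropolis kernel
# --------------------------------------------------------------------------
def metropolis_step(u: float, scale: float, logpost_u, current_lp: float,
                    rng) -> tuple:
    """One symmetric random-walk update in transformed space.

    ``logpost_u`` maps the transformed coordinate to the transformed-space
    log posterior.  Returns (u_new, lp_new, accepted).
    """
    u_prop = u + scale * rng.standard_normal()
    lp_prop = logpost_u(u_prop)
    if lp_prop - current_lp >= 0 or rng.random() < math.exp(lp_prop - current_lp):
        return u_prop, lp_prop, True
    return u, current_lp, False


@dataclass(frozen=True)
class McmcOptions:
    """Protocol settings; the defaults follow the full-scale study design
    (4 chains, 20,000 iterations, keep the last 10,000, thin by 10)."""

    n_chains: int = 4
    n_iter: int = 20000
    keep_last: int = 10000
    thin: int = 10
    burn_in_frac: float = 0.5       # adaptation window, as fraction of n_iter
    adapt_interval: int = 25
    target_accept: tuple = (0.23, 0.44)
    init_scale: float = 0.5         # proposal SD in transformed space
    start: str = "prior"            # or "default" (jittered defaults)


@dataclass
class McmcResult:
    chains: list                     # list of DataFrames, one per chain
    param_names: list
    options: McmcOptions
    seeds: list
    acceptance: list = field(default_factory=list)

    @property
    def quantity_names(self):
        return self.param_names + [var_column(g, e) for g, e in variance_cells()]

    def pool(self, keep_last=None, thin=None) -> pd.DataFrame:
        o = self.options
        return pool_posterior(self.chains,
                              keep_last=keep_last or o.keep_last,
                              thin=thin or o.thin)

    def rhat_table(self) -> pd.Series:
        """Gelman-Rubin statistic of every calibrated quantity, computed
        from the kept (post burn-in) iterations of each chain."""
        keep = min(self.options.keep_last, len(self.chains[0]))
        vals = {}
        for q in self.quantity_names:
            arr = np.stack([c[q].to_numpy()[-keep:] for c in self.chains])
            vals[q] = rhat(arr)
        return pd.Series(vals, name="rhat")


def _transform(prior, x):
    return math.log(x) if prior.log_scale else x


def _untransform(prior, u):
    return math.exp(u) if prior.log_scale else u


def _initial_theta(param_names, priors, defaults, rng, start):
    theta = {}
    for name in param_names:
        pr = priors[name]
        if start == "prior":
            theta[name] = float(pr.sample(rng))
        else:
            base = getattr(defaults, name)
            jitter = math.exp(0.2 * rng.standard_normal())
            val = base * jitter
            if not np.isfinite(pr.logpdf(val)):
                val = base
            theta[name] = val
    return theta


def run_chains(dataset: Dataset, param_names=None, priors=None,
               base_params: ModelParameters | None = None,
               options: McmcOptions | None = None,
               solver: SolverOptions | None = None,
               variance_priors: dict | None = None,
               seed: int = 0, per_fish_physiology: bool = False,
               progress: bool = False) -> McmcResult:
    """Run independent Metropolis-within-Gibbs chains.

    Deterministic given ``seed`` (each chain derives its stream from
    ``SeedSequence([seed, chain])``).  Proposal scales adapt toward the
    target acceptance window during the burn-in half and are frozen
    afterwards so the kept iterations are Markovian.
    """
    param_names = list(param_names or DEFAULT_PRIORS)
    priors = priors or DEFAULT_PRIORS
    base_params = base_params or ModelParameters()
    options = options or McmcOptions()
    variance_priors = variance_priors or ERROR_VARIANCE_PRIORS
    if options.n_chains < 2:
        raise ValueError("need at least two chains for convergence checks")

    # one reference baseline shared as each chain's warm start
    fm0 = ForwardModel(dataset, base_params, solver, per_fish_physiology)
    ref_baseline = initialize_baseline(Physiology(), base_params, fm0.solver)

    chains, seeds, acc_rates = [], [], []
    for chain_idx in range(options.n_chains):
        ss = np.random.SeedSequence([int(seed), chain_idx])
        rng = np.random.default_rng(ss)
        seeds.append(ss.entropy)
        fm = ForwardModel(dataset, base_params, solver, per_fish_physiology)
        fm.reset_warm_start(ref_baseline)
        trace, acc = _run_single_chain(fm, param_names, priors,
                                       variance_priors, base_params,
                                       options, rng, progress, chain_idx)
        chains.append(trace)
        acc_rates.append(acc)
    return McmcResult(chains=chains, param_names=param_names,
                      options=options, seeds=seeds, acceptance=acc_rates)


def _run_single_chain(fm, param_names, priors, variance_priors, base_params,
                      options, rng, progress, chain_idx):
    theta = _initial_theta(param_names, priors, base_params, rng, options.start)
    rs = fm.residual_stats(theta)
    tries = 0
    while rs is None and tries < 20:      # re-draw until integrable start
        theta = _initial_theta(param_names, priors, base_params, rng,
                               options.start)
        rs = fm.residual_stats(theta)
        tries += 1
    if rs is None:
        raise RuntimeError("could not find an integrable starting point")
    variances = gibbs_update_variances(rs, rng, variance_priors)
    ll = log_likelihood(rs, variances)

    scales = {k: options.init_scale for k in param_names}
    n_prop = {k: 0 for k in param_names}
    n_acc = {k: 0 for k in param_names}
    win_prop = {k: 0 for k in param_names}
    win_acc = {k: 0 for k in param_names}
    burn_end = int(options.burn_in_frac * options.n_iter)
    records = np.empty((options.n_iter,
                        len(param_names) + 9 + 1))
    cells = variance_cells()

    for it in range(options.n_iter):
        for k in param_names:
            pr = priors[k]
            u = _transform(pr, theta[k])
            lp_u = pr.logpdf_transformed(u) + ll
            u_prop = u + scales[k] * rng.standard_normal()
            x_prop = _untransform(pr, u_prop)
            lp_prior_prop = pr.logpdf_transformed(u_prop)
            accepted = False
            if np.isfinite(lp_prior_prop):
                theta_prop = dict(theta)
                theta_prop[k] = x_prop
                rs_prop = fm.residual_stats(theta_prop)
                ll_prop = log_likelihood(rs_prop, variances)
                delta = (lp_prior_prop + ll_prop) - lp_u
                if delta >= 0 or rng.random() < math.exp(delta):
                    theta, rs, ll = theta_prop, rs_prop, ll_prop
                    accepted = True
            n_prop[k] += 1
            win_prop[k] += 1
            if accepted:
                n_acc[k] += 1
                win_acc[k] += 1
            if (it < burn_end and win_prop[k] >= options.adapt_interval):
                rate = win_acc[k] / win_prop[k]
                lo, hi = options.target_accept
                if rate < lo:
                    scales[k] /= 1.5
                elif rate > hi:
                    scales[k] *= 1.5
                win_prop[k] = win_acc[k] = 0

        variances = gibbs_update_variances(rs, rng, variance_priors)
        ll = log_likelihood(rs, variances)

        row = [theta[k] for k in param_names]
        row += [variances[c] for c in cells]
        row.append(ll + log_prior(theta, priors))
        records[it] = row
        if progress and (it + 1) % max(1, options.n_iter // 10) == 0:
            print(f"chain {chain_idx}: iteration {it + 1}/{options.n_iter}")

    cols = (list(param_names) + [var_column(g, e) for g, e in cells]
            + ["log_posterior"])
    trace = pd.DataFrame(records, columns=cols)
    acc = {k: n_acc[k] / max(1, n_prop[k]) for k in param_names}
    if all(v == 0.0 for v in acc.values()):
        import warnings
        warnings.warn("chain accepted no proposals; check model/scales")
    return trace, acc


# --------------------------------------------------------------------------
# pooling and diagnostics
# --------------------------------------------------------------------------
def pool_posterior(chains, keep_last: int = 10000, thin: int = 10) -> pd.DataFrame:
    """Thin the last ``keep_last`` iterations of each chain by ``thin`` and
    concatenate chain-major: 4 chains x keep 10,000 / thin 10 -> 4,000 sets."""
    if not chains:
        raise ValueError("no chains to pool")
    n = len(chains[0])
    if keep_last > n:
        raise ValueError(f"keep_last={keep_last} exceeds chain length {n}")
    pooled = []
    for i, chain in enumerate(chains):
        kept = chain.iloc[n - keep_last:].iloc[::thin].copy()
        kept.insert(0, "chain", i)
        pooled.append(kept)
    return pd.concat(pooled, ignore_index=True)


def rhat(chains_values) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains_values`` is (n_chains, n_iterations).  With within-chain
    variance W and between-chain variance B (of the chain means, times n),
    Rhat = sqrt((n-1)/n + B/(n*W)).
    """
    x = np.asarray(chains_values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("need >= 2 chains of equal length >= 10")
    m, n = x.shape
    w = x.var(axis=1, ddof=1).mean()
    b = n * x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else math.inf
    return math.sqrt((n - 1) / n + b / (n * w))


def summarize_posterior(pool: pd.DataFrame, params=None) -> pd.DataFrame:
    """Mean / median / central 95% interval per calibrated quantity
    (linear-interpolation percentiles)."""
    if len(pool) == 0:
        raise ValueError("empty posterior pool")
    cols = params or [c for c in pool.columns
                      if c not in ("chain", "log_posterior")]
    rows = {}
    for c in cols:
        v = pool[c].to_numpy(dtype=float)
        lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
        rows[c] = {"mean": v.mean(), "median": med,
                   "ci_2.5": lo, "ci_97.5": hi}
    return pd.DataFrame(rows).T[["mean", "median", "ci_2.5", "ci_97.5"]]
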