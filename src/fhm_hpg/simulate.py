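"""Forward simulation: baseline initialisation, exposure runs, observables.

The stiff 48-state system is integrated with LSODA, restarting at exposure
segment boundaries so discontinuous water concentrations never cross a
solver step.  Baseline state is the 24-hr periodic orbit of the unexposed
system (the only forcing is the diurnal LH cycle), found by integrating
until consecutive daily snapshots agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from . import _kernel as K
from .exposure import ExposureScenario
from .parameters import (ModelParameters, Physiology, derive_geometry,
                         pack_params)

__all__ = [
    "SolverOptions", "SimulationResult", "InitializationError",
    "STATE_NAMES", "OBSERVABLE_NAMES", "simulate", "initialize_baseline",
    "extract_observables", "run_endpoints",
]

_COMPS = ("brn", "gon", "liv", "oth", "ven")
_CHEMS = ("E2", "T", "EE2", "TB", "LH", "VTG")

STATE_NAMES = (
    [f"C_{c}_{j}" for c in _CHEMS for j in _COMPS]
    + [f"C_E2ER_{j}" for j in _COMPS[:3]]
    + [f"C_EE2ER_{j}" for j in _COMPS[:3]]
    + [f"C_TAR_{j}" for j in _COMPS[:3]]
    + [f"C_TBAR_{j}" for j in _COMPS[:3]]
    + ["C_LHLR_gon", "C_E2SBP_ven", "C_TSBP_ven", "C_EE2SBP_ven",
       "C_ERfree_liv", "C_ARfree_brn"]
)

OBSERVABLE_NAMES = ("plasma_e2_ng_ml", "plasma_t_ng_ml", "plasma_vtg_mg_ml",
                    "plasma_lh_nmol_l", "liver_er_total_nmol_l",
                    "brain_ar_total_nmol_l")

#: endpoint name -> observable column used in likelihoods / datasets
ENDPOINT_COLUMNS = {"E2": "plasma_e2_ng_ml", "T": "plasma_t_ng_ml",
                    "VTG": "plasma_vtg_mg_ml"}


class InitializationError(RuntimeError):
    """Baseline integration failed to reach a periodic steady state."""


@dataclass(frozen=True)
class SolverOptions:
    """Integrator and baseline-search settings.

    rtol/atol are LSODA tolerances (atol in nmol/L); ``baseline_horizon``
    bounds the search for the periodic baseline and ``baseline_tol`` is the
    maximum relative change between consecutive 24-hr snapshots.
    """

    rtol: float = 1e-8
    atol: float = 1e-12
    mxstep: int = 500_000
    baseline_horizon: float = 6000.0
    baseline_tol: float = 1e-6

    def coarse(self) -> "SolverOptions":
        """A cheaper profile for sampling-intensive work."""
        return replace(self, rtol=1e-6, atol=1e-10)


@dataclass
class SimulationResult:
    times: np.ndarray           # hr
    states: np.ndarray          # (n_times, 48), nmol/L
    params: ModelParameters
    physiology: Physiology

    @property
    def observables(self) -> pd.DataFrame:
        return extract_observables(self.states, self.params)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=STATE_NAMES)
        df.insert(0, "time_hr", self.times)
        return pd.concat([df, self.observables], axis=1)


def _default_seed_state(params: ModelParameters) -> np.ndarray:
    y0 = np.zeros(K.N_STATE)
    for chem in (K.E2, K.T, K.LH, K.VTG):       # endogenous species only
        for j in range(5):
            y0[5 * chem + j] = 1e-3
    y0[K.IX_ERFREE_LIV] = params.pbg_er_liv / params.ke_er_liv
    y0[K.IX_ARFREE_BRN] = params.pbg_ar_brn / params.ke_ar_brn
    return y0


def _segment_exposure(scenario: ExposureScenario, t0: float) -> np.ndarray:
    """Exposure vector for the smooth span starting at t0."""
    expo = np.zeros(K.N_EXPO)
    for chem, base in (("EE2", K.X_C0_EE2), ("TB", K.X_C0_TB)):
        for seg in scenario.segments.get(chem, ()):
            if seg.t_start <= t0 < seg.t_end:
                expo[base] = seg.concentration
                expo[base + 1] = seg.decay_rate
                expo[base + 2] = seg.t_start
    return expo


def simulate(phys: Physiology, params: ModelParameters,
             scenario: ExposureScenario | None, times,
             y0: np.ndarray | None = None,
             solver: SolverOptions | None = None,
             *, enable_production: bool = True,
             enable_elimination: bool = True,
             enable_gill: bool = True) -> SimulationResult:
    """Integrate the model over ``times`` (hr, ascending, times[0] = start).

    ``y0`` defaults to the baseline periodic state.  The enable flags turn
    off whole process classes (used by conservation diagnostics).
    """
    scenario = scenario or ExposureScenario.zero()
    solver = solver or SolverOptions()
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be an ascending 1-D sequence")
    if y0 is None:
        y0 = initialize_baseline(phys, params, solver)
    p = pack_params(phys, params,
                    enable_production=enable_production,
                    enable_elimination=enable_elimination,
                    enable_gill=enable_gill)

    t_start, t_end = times[0], times[-1]
    cuts = [b for b in scenario.breakpoints if t_start < b < t_end]
    edges = np.array([t_start] + cuts + [t_end])
    out = np.empty((len(times), K.N_STATE))
    y = np.asarray(y0, dtype=float).copy()
    out[times == t_start] = y
    for a, b in zip(edges[:-1], edges[1:]):
        inner = times[(times > a) & (times <= b)]
        ts = np.concatenate(([a], inner))
        if ts[-1] < b:
            ts = np.append(ts, b)
        ts = np.unique(ts)
        expo = _segment_exposure(scenario, a)
        traj = odeint(K.rhs, y, ts, args=(p, expo), rtol=solver.rtol,
                      atol=solver.atol, mxstep=solver.mxstep, tfirst=False)
        if not np.all(np.isfinite(traj)):
            raise RuntimeError("integration produced non-finite state")
        y = traj[-1]
        for t_req in inner:
            out[times == t_req] = traj[np.searchsorted(ts, t_req)]
    return SimulationResult(times=times, states=out, params=params,
                            physiology=phys)


def initialize_baseline(phys: Physiology, params: ModelParameters,
                        solver: SolverOptions | None = None,
                        seed_state: np.ndarray | None = None) -> np.ndarray:
    """Periodic baseline state at diurnal phase t mod 24 = 0.

    Integrates the unexposed system in 24-hr windows from a small positive
    seed until the maximum relative change of every component between
    consecutive windows drops below ``baseline_tol``.
    """
    solver = solver or SolverOptions()
    p = pack_params(phys, params)
    y = (np.asarray(seed_state, dtype=float).copy() if seed_state is not None
         else _default_seed_state(params))
    expo = np.zeros(K.N_EXPO)
    n_windows = max(1, int(math.ceil(solver.baseline_horizon / 24.0)))
    floor = 1e-9        # nmol/L; scale floor for near-zero components
    for _ in range(n_windows):
        traj = odeint(K.rhs, y, np.array([0.0, 24.0]), args=(p, expo),
                      rtol=solver.rtol, atol=solver.atol, mxstep=solver.mxstep)
        y_new = traj[-1]
        scale = np.maximum(np.maximum(np.abs(y), np.abs(y_new)), floor)
        rel = np.max(np.abs(y_new - y) / scale)
        y = y_new
        if rel < solver.baseline_tol:
            return np.clip(y, 0.0, None)
    raise InitializationError(
        f"baseline not periodic within {solver.baseline_horizon:g} hr "
        f"(last window change {rel:.2e} > {solver.baseline_tol:g})")


def extract_observables(states: np.ndarray,
                        params: ModelParameters) -> pd.DataFrame:
    """Measurement-scale outputs from raw states.

    Plasma steroids are (free + SBP-bound) venous concentration divided by
    the plasma fraction, converted to ng/ml via molecular weight; VTG the
    same to mg/ml.  LH is plasma nmol/L; liver ER and brain AR totals
    (free + bound) are tissue nmol/L.
    """
    s = np.atleast_2d(np.asarray(states, dtype=float))
    fp = params.f_plasma_ven
    mw = params.mw
    e2_tot = s[:, 5 * K.E2 + K.VEN] + s[:, K.IX_E2SBP]
    t_tot = s[:, 5 * K.T + K.VEN] + s[:, K.IX_TSBP]
    vtg = s[:, 5 * K.VTG + K.VEN]
    lh = s[:, 5 * K.LH + K.VEN]
    return pd.DataFrame({
        "plasma_e2_ng_ml": e2_tot / fp * mw["E2"] / 1000.0,
        "plasma_t_ng_ml": t_tot / fp * mw["T"] / 1000.0,
        "plasma_vtg_mg_ml": vtg / fp * mw["VTG"] * 1e-9,
        "plasma_lh_nmol_l": lh / fp,
        "liver_er_total_nmol_l": (s[:, K.IX_ERFREE_LIV]
                                  + s[:, K.IX_E2ER + 2] + s[:, K.IX_EE2ER + 2]),
        "brain_ar_total_nmol_l": (s[:, K.IX_ARFREE_BRN]
                                  + s[:, K.IX_TAR] + s[:, K.IX_TBAR]),
    })


def run_endpoints(phys: Physiology, params: ModelParameters,
                  scenario: ExposureScenario | None, times,
                  solver: SolverOptions | None = None,
                  baseline: np.ndarray | None = None) -> pd.DataFrame:
    """Observables at the requested times (hr), starting from baseline."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    grid = np.unique(np.concatenate(([0.0], times)))
    res = simulate(phys, params, scenario, grid, y0=baseline, solver=solver)
    obs = res.observables
    obs.insert(0, "time_hr", res.times)
    return obs[obs["time_hr"].isin(times)].reset_index(drop=True)


def total_moles(states: np.ndarray, phys: Physiology,
                params: ModelParameters) -> pd.DataFrame:
    """Whole-body moles of each chemical, free plus receptor/SBP-bound.

    The bookkeeping oracle behind the conservation diagnostics: with
    productions, eliminations and gill exchange disabled each column is
    constant in time.
    """
    geom = derive_geometry(phys, params)
    v = geom.volumes
    s = np.atleast_2d(np.asarray(states, dtype=float))
    vols = np.array([v[c] for c in _COMPS])
    comp3 = np.array([v["brn"], v["gon"], v["liv"]])
    tot = {}
    for i, chem in enumerate(_CHEMS):
        m = s[:, 5 * i:5 * i + 5] @ vols
        if chem == "E2":
            m += s[:, K.IX_E2ER:K.IX_E2ER + 3] @ comp3 + s[:, K.IX_E2SBP] * v["ven"]
        elif chem == "EE2":
            m += s[:, K.IX_EE2ER:K.IX_EE2ER + 3] @ comp3 + s[:, K.IX_EE2SBP] * v["ven"]
        elif chem == "T":
            m += s[:, K.IX_TAR:K.IX_TAR + 3] @ comp3 + s[:, K.IX_TSBP] * v["ven"]
        elif chem == "TB":
            m += s[:, K.IX_TBAR:K.IX_TBAR + 3] @ comp3
        elif chem == "LH":
            m += s[:, K.IX_LHLR] * v["gon"]
        tot[chem] = m
    return pd.DataFrame(tot)
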