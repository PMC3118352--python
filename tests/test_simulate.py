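"""Whole-system integration properties: conservation, periodic baseline,
receptor bookkeeping, observable extraction, solver robustness."""

import numpy as np
import pytest

from fhm_hpg import _kernel as K
from fhm_hpg.exposure import ExposureScenario
from fhm_hpg.simulate import (InitializationError, SolverOptions,
                              STATE_NAMES, extract_observables,
                              initialize_baseline, run_endpoints, simulate,
                              total_moles)


def _seeded_state(rng):
    y = rng.uniform(0.05, 1.0, K.N_STATE)
    # keep complexes below their fixed receptor totals
    y[K.IX_TAR:K.IX_TAR + 3] *= 0.3
    y[K.IX_TBAR:K.IX_TBAR + 3] *= 0.3
    y[K.IX_LHLR] *= 0.5
    return y


class TestConservation:
    def test_closed_system_conserves_every_chemical(self, phys, params, rng):
        """With productions, eliminations and gill exchange off, total moles
        of each chemical (free + all bound forms) stay constant."""
        y0 = _seeded_state(rng)
        res = simulate(phys, params, None, np.linspace(0, 200, 9), y0=y0,
                       solver=SolverOptions(rtol=1e-10, atol=1e-14),
                       enable_production=False, enable_elimination=False,
                       enable_gill=False)
        totals = total_moles(res.states, phys, params)
        for chem in totals:
            m = totals[chem].to_numpy()
            assert np.max(np.abs(m - m[0])) <= 1e-6 * m[0], chem

    def test_gill_exchange_conserves_water_plus_fish(self, phys, params):
        """An exposed closed loop only gains what the gills take up: with
        eliminations off, d(total)/dt equals the gill uptake flux, so after
        depuration to equilibrium with clean water nothing remains."""
        sc = ExposureScenario.single("TB", 1.0, "ug/L", 0.0, 48.0)
        y0 = np.zeros(K.N_STATE)
        res = simulate(phys, params, sc, np.array([0.0, 48.0, 3000.0]),
                       y0=y0, solver=SolverOptions(rtol=1e-10, atol=1e-14),
                       enable_production=False, enable_elimination=False)
        tb = total_moles(res.states, phys, params)["TB"].to_numpy()
        assert tb[1] > 0                      # uptake happened
        assert tb[2] < 1e-4 * tb[1]           # washed back out via gills


class TestReceptorBookkeeping:
    def test_fixed_total_pools_never_overfill(self, phys, params, baseline,
                                              coarse_solver):
        sc = ExposureScenario.single("TB", 15, "ng/L", 0, 48).combined(
            ExposureScenario.single("EE2", 10, "ng/L", 0, 48))
        res = simulate(phys, params, sc, np.linspace(0, 96, 25), y0=baseline,
                       solver=coarse_solver)
        s = res.states
        atol = 1e-6
        assert np.all(s >= -atol)
        assert np.all(s[:, K.IX_E2ER] + s[:, K.IX_EE2ER]
                      <= params.er_brn_total + atol)          # brain ER
        assert np.all(s[:, K.IX_E2ER + 1] + s[:, K.IX_EE2ER + 1]
                      <= params.er_gon_total + atol)          # gonad ER
        assert np.all(s[:, K.IX_TAR + 1] + s[:, K.IX_TBAR + 1]
                      <= params.ar_gon_total + atol)          # gonad AR
        assert np.all(s[:, K.IX_LHLR] <= params.lr_gon_total + atol)
        assert np.all(s[:, K.IX_E2SBP] + s[:, K.IX_TSBP] + s[:, K.IX_EE2SBP]
                      <= params.sbp_ven_total + atol)         # venous SBP


class TestBaseline:
    def test_baseline_is_24h_periodic(self, phys, params, baseline,
                                      coarse_solver):
        res = simulate(phys, params, None, np.array([0.0, 24.0]),
                       y0=baseline, solver=coarse_solver)
        y24 = res.states[-1]
        # mixed tolerance: absolute floor absorbs integrator noise on the
        # identically-zero xenobiotic states
        assert np.all(np.abs(y24 - baseline) <= 1e-4 * np.abs(baseline) + 1e-8)

    def test_baseline_independent_of_seed_magnitude(self, phys, params,
                                                    coarse_solver, baseline):
        from fhm_hpg.simulate import _default_seed_state
        for factor in (10.0, 0.1):
            y = initialize_baseline(phys, params, coarse_solver,
                                    seed_state=_default_seed_state(params) * factor)
            scale = np.maximum(np.abs(baseline), 1e-6)
            assert np.max(np.abs(y - baseline) / scale) < 1e-2

    def test_baseline_produces_positive_endpoints(self, params, baseline):
        obs = extract_observables(baseline, params)
        assert float(obs["plasma_vtg_mg_ml"].iloc[0]) > 0
        assert float(obs["plasma_e2_ng_ml"].iloc[0]) > 0
        assert float(obs["plasma_t_ng_ml"].iloc[0]) > 0

    def test_observables_cycle_with_diurnal_lh(self, phys, params, baseline,
                                               coarse_solver):
        """Zero exposure: the only forcing is the diurnal LH cycle, so
        observables at the same phase on consecutive days agree while LH
        varies within a day."""
        res = simulate(phys, params, None, np.arange(0, 49, 6.0),
                       y0=baseline, solver=coarse_solver)
        lh = res.observables["plasma_lh_nmol_l"].to_numpy()
        assert lh[0] == pytest.approx(lh[4], rel=1e-4)     # t=0 vs t=24
        assert np.ptp(lh[:5]) > 0.01 * lh[0]               # diurnal swing

    def test_initialization_error_on_short_horizon(self, phys, params):
        with pytest.raises(InitializationError):
            initialize_baseline(phys, params,
                                SolverOptions(baseline_horizon=48.0))


class TestObservables:
    def test_unit_conversion_example(self, params):
        # 1 nmol/L total venous E2 at plasma fraction 0.45 -> ~0.605 ng/ml
        state = np.zeros(K.N_STATE)
        state[5 * K.E2 + K.VEN] = 1.0
        obs = extract_observables(state, params)
        assert float(obs["plasma_e2_ng_ml"].iloc[0]) == \
            pytest.approx(272.39 / 0.45 / 1000, rel=1e-9)

    def test_zero_state_zero_observables(self, params):
        obs = extract_observables(np.zeros(K.N_STATE), params)
        assert (obs.to_numpy() == 0).all()

    def test_sbp_bound_steroid_counts_as_plasma(self, params):
        free = np.zeros(K.N_STATE)
        free[5 * K.E2 + K.VEN] = 1.0
        bound = np.zeros(K.N_STATE)
        bound[K.IX_E2SBP] = 1.0
        a = extract_observables(free, params)["plasma_e2_ng_ml"].iloc[0]
        b = extract_observables(bound, params)["plasma_e2_ng_ml"].iloc[0]
        assert a == pytest.approx(b)

    def test_monotone_in_underlying_concentration(self, params, rng):
        s1 = np.abs(rng.normal(size=K.N_STATE))
        s2 = s1.copy()
        s2[5 * K.VTG + K.VEN] *= 2
        o1 = extract_observables(s1, params)
        o2 = extract_observables(s2, params)
        assert o2["plasma_vtg_mg_ml"].iloc[0] > o1["plasma_vtg_mg_ml"].iloc[0]


class TestSolverContracts:
    def test_tolerance_robustness(self, phys, params, baseline):
        """Halving rtol/atol moves day-10 observables by < 0.1%."""
        sc = ExposureScenario.single("TB", 0.5, "ug/L", 0.0, 504.0)
        obs = {}
        for f, label in ((1.0, "a"), (0.5, "b")):
            sol = SolverOptions(rtol=1e-8 * f, atol=1e-12 * f)
            res = run_endpoints(phys, params, sc, [240.0], sol,
                                baseline=baseline)
            obs[label] = res.drop(columns="time_hr").to_numpy()
        rel = np.abs(obs["a"] - obs["b"]) / np.abs(obs["a"])
        assert np.max(rel) < 1e-3

    def test_times_must_ascend(self, phys, params, baseline):
        with pytest.raises(ValueError):
            simulate(phys, params, None, [10.0, 5.0], y0=baseline)

    def test_trajectory_frame_schema(self, phys, params, baseline,
                                     coarse_solver):
        res = simulate(phys, params, None, [0.0, 12.0], y0=baseline,
                       solver=coarse_solver)
        df = res.to_frame()
        assert list(df.columns[:1]) == ["time_hr"]
        assert set(STATE_NAMES).issubset(df.columns)
        assert "plasma_vtg_mg_ml" in df.columns
        assert len(df) == 2
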