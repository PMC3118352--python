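"""Parameterisation of the female fathead minnow HPG-axis model.

The model carries two kinds of parameters:

* constants fixed from the literature or direct measurement (compartment
  percentages, receptor totals, binding rate constants, partition
  coefficients, elimination rate constants), and
* calibrated parameters whose shipped defaults are posterior means from the
  Bayesian calibration (blood:water partition of trenbolone, receptor
  affinities, feedback strengths, production-rate scalings, Hill exponents).

All concentrations are nmol/L, volumes L, flows L/hr, rates 1/hr, body
weight kg.  Derived quantities (EE2-ER and TB-AR dissociation constants via
relative binding affinities, brain aromatase capacity via the gonad scaling)
are recomputed on access so the table identities hold by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernel as K

__all__ = [
    "Physiology",
    "CompartmentGeometry",
    "ModelParameters",
    "CHEMICALS",
    "COMPARTMENTS",
    "MOLECULAR_WEIGHTS",
    "derive_geometry",
    "pack_params",
]

CHEMICALS = ("E2", "T", "EE2", "TB", "LH", "VTG")
COMPARTMENTS = ("brn", "gon", "liv", "oth", "ven")

#: g/mol; VTG is a configurable convention (large plasma glycolipoprotein)
MOLECULAR_WEIGHTS = {
    "E2": 272.39,
    "T": 288.43,
    "EE2": 296.41,
    "TB": 270.37,
    "VTG": 1.8e5,
}


@dataclass(frozen=True)
class Physiology:
    """Per-fish physiological inputs.

    body_weight in kg; gsi/hsi/bsi are organ weights as percent of body
    weight (gonad, liver, brain).  Defaults are the study-population medians.
    """

    body_weight: float = 0.0016
    gsi: float = 11.0
    hsi: float = 3.0
    bsi: float = 1.18

    def __post_init__(self):
        if not (self.body_weight > 0 and self.gsi > 0 and self.hsi > 0
                and self.bsi > 0):
            raise ValueError("physiology values must be strictly positive")
        if self.gsi + self.hsi + self.bsi >= 100:
            raise ValueError("somatic indices must sum to < 100%")


@dataclass(frozen=True)
class CompartmentGeometry:
    """Volumes (L) and blood flows (L/hr) derived from physiology."""

    volumes: dict       # compartment -> L
    flows: dict         # perfused compartment -> L/hr
    cardiac_output: float
    gill_water_flow: float
    plasma_fraction: float


@dataclass
class ModelParameters:
    """The complete named parameter vector of the model.

    Calibrated parameters default to their posterior means; everything else
    is a fixed constant.  ``ar_liv_total`` defaults to the gonad AR total.
    """

    # compartment percentages of body weight (gonad/liver/brain come from
    # per-fish physiology; these are the remaining fixed percentages)
    p_gil: float = 1.67
    p_ven: float = 2.59
    f_plasma_ven: float = 0.45

    # allometric flows: FW_gil = 10.6*BW^0.75, F_car = 2.06*BW^0.75
    fw_gil_coef: float = 10.6
    fw_gil_exp: float = 0.75
    f_car_coef: float = 2.06
    f_car_exp: float = 0.75

    # fraction of cardiac output perfusing each tissue ("other" = remainder)
    frac_flow_brn: float = 0.02
    frac_flow_gon: float = 0.05
    frac_flow_liv: float = 0.03

    # receptor / binding-protein totals (nmol/L)
    er_brn_total: float = 14.3
    er_gon_total: float = 29.0
    lr_gon_total: float = 2.0
    ar_gon_total: float = 1.05
    ar_liv_total: float | None = None
    sbp_ven_total: float = 400.0

    # ligand-receptor kinetics (k1 in L/nmol/hr, Kd in nmol/L)
    k1_e2er: float = 0.743
    kd_e2er_brn: float = 1.12          # calibrated
    rba_ee2_e2: float = 3.24           # calibrated
    k1_tar: float = 0.08
    kd_tar: float = 3.0
    rba_tb_t: float = 5.25             # calibrated
    k1_lhlr: float = 0.2
    kd_lhlr: float = 2.9
    k1_sbp: float = 5.6687
    kd_e2sbp: float = 3.13
    kd_tsbp: float = 4.89
    kd_ee2sbp: float = 0.58

    # LH production (brain)
    mag_lh: float = 8.86e-6            # calibrated, nmol/hr
    rho_u_lh: float = 238.0            # calibrated, nmol/L
    rho_d_lh: float = 0.11             # calibrated, nmol/L

    # brain AR dynamics
    pbg_ar_brn: float = 0.012          # calibrated, nmol/L/hr
    k_ar_brn: float = 3.95             # calibrated, nmol/L
    ke_ar_brn: float = 0.01

    # T production (gonad)
    sc_vmax_scc_gon: float = 1.1e5     # nmol/hr/kg^0.75
    k05_scc_gon: float = 190.0
    n_t: float = 1.03                  # calibrated
    k_t: float = 0.016                 # nmol/L
    rho_star_gon: float = 1.0
    rho_chol_gon: float = 2.37         # calibrated

    # aromatase (E2 production)
    sc_vmax_aro_gon: float = 1.56e-3   # calibrated, nmol/hr/mg protein
    km_aro_gon: float = 9.6
    km_aro_brn: float = 9.6
    aro_brn_gon_ratio: float = 4.6     # sc_Vmax_aro,brn = 4.6 x gonad value
    d_mp_gon: float = 3100.0           # mg microsomal protein / L
    rho_mp: float = 0.174              # gonad:brain microsomal protein ratio
    rho_e2_lhlr_gon: float = 79.84     # calibrated, L/nmol

    # VTG production (liver) and oocyte uptake (gonad)
    sc_vmax_vtg_liv: float = 175.0     # calibrated, nmol/hr/kg^0.75
    k05_vtg_liv: float = 1.0
    n_vtg: float = 2.88                # calibrated
    k_vtg_gon: float = 0.05

    # liver ER auto-regulation
    pbg_er_liv: float = 0.12           # calibrated, nmol/L/hr
    k_er_liv: float = 0.027            # calibrated, 1/hr
    ke_er_liv: float = 0.01

    # first-order eliminations in "other" (1/hr)
    ke_e2_oth: float = 0.1
    ke_t_oth: float = 0.1
    ke_ee2_oth: float = 0.1
    ke_tb_oth: float = 0.1
    ke_lh_oth: float = 0.1
    ke_vtg_oth: float = 0.001

    # partition coefficients
    lam_e2_bld: float = 300.0
    lam_ee2_bld: float = 300.0
    lam_tb_bld: float = 7.47           # calibrated
    lam_e2_liv: float = 3.0
    lam_ee2_liv: float = 3.0

    # molecular weights for unit conversion (g/mol)
    mw: dict = field(default_factory=lambda: dict(MOLECULAR_WEIGHTS))

    # ---- derived identities -------------------------------------------
    @property
    def kd_ee2er(self) -> float:
        return self.kd_e2er_brn / self.rba_ee2_e2

    @property
    def kd_tbar(self) -> float:
        return self.kd_tar / self.rba_tb_t

    @property
    def sc_vmax_aro_brn(self) -> float:
        return self.aro_brn_gon_ratio * self.sc_vmax_aro_gon

    @property
    def d_mp_brn(self) -> float:
        return self.d_mp_gon / self.rho_mp

    def _effective_ar_liv_total(self) -> float:
        return self.ar_gon_total if self.ar_liv_total is None else self.ar_liv_total

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v is not None and v <= 0:
                raise ValueError(f"parameter {f.name} must be positive, got {v}")

    def replace(self, **updates) -> "ModelParameters":
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def derive_geometry(phys: Physiology,
                    params: ModelParameters | None = None) -> CompartmentGeometry:
    """Compartment volumes and blood flows for one fish.

    Volumes use tissue density 1 kg/L, so V_j = BW * percent_j / 100.  The
    "other" percentage is the remainder after brain, gonad, liver, gill and
    venous blood.  Gill water flow and cardiac output follow the allometric
    power laws; tissue blood flows split cardiac output by fixed fractions
    with "other" as the remainder.
    """
    params = params or ModelParameters()
    if phys.body_weight <= 0:
        raise ValueError("body weight must be positive")
    bw = phys.body_weight
    p_oth = 100.0 - phys.bsi - phys.gsi - phys.hsi - params.p_gil - params.p_ven
    if p_oth <= 0:
        raise ValueError("compartment percentages exceed 100% of body weight")
    volumes = {
        "brn": bw * phys.bsi / 100.0,
        "gon": bw * phys.gsi / 100.0,
        "liv": bw * phys.hsi / 100.0,
        "gil": bw * params.p_gil / 100.0,
        "ven": bw * params.p_ven / 100.0,
        "oth": bw * p_oth / 100.0,
    }
    f_car = params.f_car_coef * bw ** params.f_car_exp
    fw_gil = params.fw_gil_coef * bw ** params.fw_gil_exp
    frac_oth = 1.0 - params.frac_flow_brn - params.frac_flow_gon - params.frac_flow_liv
    if frac_oth <= 0:
        raise ValueError("tissue blood-flow fractions exceed cardiac output")
    flows = {
        "brn": params.frac_flow_brn * f_car,
        "gon": params.frac_flow_gon * f_car,
        "liv": params.frac_flow_liv * f_car,
        "oth": frac_oth * f_car,
    }
    return CompartmentGeometry(volumes=volumes, flows=flows,
                               cardiac_output=f_car, gill_water_flow=fw_gil,
                               plasma_fraction=params.f_plasma_ven)


def pack_params(phys: Physiology, params: ModelParameters, *,
                enable_production: bool = True,
                enable_elimination: bool = True,
                enable_gill: bool = True) -> np.ndarray:
    """Pack physiology + parameters into the kernel's flat vector."""
    geom = derive_geometry(phys, params)
    p = np.ones(K.N_PARAM)
    v, f = geom.volumes, geom.flows
    p[K.P_V_BRN], p[K.P_V_GON], p[K.P_V_LIV] = v["brn"], v["gon"], v["liv"]
    p[K.P_V_OTH], p[K.P_V_VEN] = v["oth"], v["ven"]
    p[K.P_F_BRN], p[K.P_F_GON] = f["brn"], f["gon"]
    p[K.P_F_LIV], p[K.P_F_OTH] = f["liv"], f["oth"]
    p[K.P_F_CAR], p[K.P_FW_GIL] = geom.cardiac_output, geom.gill_water_flow

    p[K.P_K1_ER], p[K.P_KD_E2ER], p[K.P_KD_EE2ER] = \
        params.k1_e2er, params.kd_e2er_brn, params.kd_ee2er
    p[K.P_K1_AR], p[K.P_KD_TAR], p[K.P_KD_TBAR] = \
        params.k1_tar, params.kd_tar, params.kd_tbar
    p[K.P_K1_LHLR], p[K.P_KD_LHLR] = params.k1_lhlr, params.kd_lhlr
    p[K.P_K1_SBP] = params.k1_sbp
    p[K.P_KD_E2SBP], p[K.P_KD_TSBP], p[K.P_KD_EE2SBP] = \
        params.kd_e2sbp, params.kd_tsbp, params.kd_ee2sbp
    p[K.P_ER_BRN_TOT], p[K.P_ER_GON_TOT] = params.er_brn_total, params.er_gon_total
    p[K.P_AR_GON_TOT] = params.ar_gon_total
    p[K.P_AR_LIV_TOT] = params._effective_ar_liv_total()
    p[K.P_LR_GON_TOT], p[K.P_SBP_TOT] = params.lr_gon_total, params.sbp_ven_total

    p[K.P_MAG_LH], p[K.P_RHO_U_LH], p[K.P_RHO_D_LH] = \
        params.mag_lh, params.rho_u_lh, params.rho_d_lh
    p[K.P_PBG_AR], p[K.P_K_AR_BRN], p[K.P_KE_AR_BRN] = \
        params.pbg_ar_brn, params.k_ar_brn, params.ke_ar_brn

    bw75 = phys.body_weight ** 0.75
    p[K.P_VMAX_T] = params.sc_vmax_scc_gon * bw75
    p[K.P_K05_SCC], p[K.P_N_T], p[K.P_K_T] = \
        params.k05_scc_gon, params.n_t, params.k_t
    p[K.P_RHO_STAR], p[K.P_RHO_CHOL] = params.rho_star_gon, params.rho_chol_gon

    p[K.P_VMAX_ARO_GON] = params.sc_vmax_aro_gon * params.d_mp_gon * v["gon"]
    p[K.P_KM_ARO_GON] = params.km_aro_gon
    p[K.P_VMAX_ARO_BRN] = params.sc_vmax_aro_brn * params.d_mp_brn * v["brn"]
    p[K.P_KM_ARO_BRN] = params.km_aro_brn
    p[K.P_RHO_E2_LHLR] = params.rho_e2_lhlr_gon

    p[K.P_VMAX_VTG] = params.sc_vmax_vtg_liv * bw75
    p[K.P_K05_VTG], p[K.P_N_VTG] = params.k05_vtg_liv, params.n_vtg
    p[K.P_K_VTG_GON] = params.k_vtg_gon
    p[K.P_PBG_ER], p[K.P_K_ER_LIV], p[K.P_KE_ER_LIV] = \
        params.pbg_er_liv, params.k_er_liv, params.ke_er_liv

    kes = (params.ke_e2_oth, params.ke_t_oth, params.ke_ee2_oth,
           params.ke_tb_oth, params.ke_lh_oth, params.ke_vtg_oth)
    for i, ke in enumerate(kes):
        p[K.P_KE_OTH + i] = ke
    p[K.P_LAM_BLD_E2] = params.lam_e2_bld
    p[K.P_LAM_BLD_EE2] = params.lam_ee2_bld
    p[K.P_LAM_BLD_TB] = params.lam_tb_bld
    # tissue:blood partition coefficients (default 1 everywhere)
    p[K.P_LAM + 5 * K.E2 + K.LIV] = params.lam_e2_liv
    p[K.P_LAM + 5 * K.EE2 + K.LIV] = params.lam_ee2_liv

    p[K.P_ENABLE_PROD] = 1.0 if enable_production else 0.0
    p[K.P_ENABLE_ELIM] = 1.0 if enable_elimination else 0.0
    p[K.P_ENABLE_GILL] = 1.0 if enable_gill else 0.0
    return p
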