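"""Rate laws of the HPG-axis model, exposed one operation at a time.

These functions are the readable, validated surface over the same algebra
the compiled ODE kernel integrates; unit conventions follow
:mod:`fhm_hpg.parameters`.  Production rates are nmol/hr (whole-compartment)
unless noted; binding and receptor-balance terms are nmol/L/hr.
"""

from __future__ import annotations

from . import _kernel as K
from .parameters import CompartmentGeometry, ModelParameters, Physiology

__all__ = [
    "binding_net_flux", "gill_exchange", "lh_production_rate",
    "brain_ar_production_rate", "t_production_rate", "e2_production_rate",
    "vtg_production_rate", "liver_er_production_rate",
    "vtg_oocyte_uptake_rate", "elimination_rate",
]

_BLOOD_WATER_PARTITION = {
    "E2": "lam_e2_bld", "EE2": "lam_ee2_bld", "TB": "lam_tb_bld",
}
_KE_OTH = {
    "E2": "ke_e2_oth", "T": "ke_t_oth", "EE2": "ke_ee2_oth",
    "TB": "ke_tb_oth", "LH": "ke_lh_oth", "VTG": "ke_vtg_oth",
}


def _check_nonneg(**kwargs):
    for name, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def binding_net_flux(c_free: float, c_rfree: float, c_bound: float,
                     k1: float, kd: float) -> float:
    """Net complex formation rate d(bound)/dt (nmol/L/hr).

    Mass-action association ``k1*free*Rfree`` against first-order
    dissociation with ``koff = k1*kd`` (1/hr), so the equilibrium occupancy
    is the Langmuir isotherm free/(Kd + free).
    """
    _check_nonneg(c_free=c_free, c_rfree=c_rfree, c_bound=c_bound)
    return float(K.binding_flux(c_free, c_rfree, c_bound, k1, kd))


def gill_exchange(c_water: float, c_ven: float, chem: str,
                  geom: CompartmentGeometry, params: ModelParameters):
    """Branchial uptake/excretion for a water-exchanged chemical.

    Returns ``(c_art, uptake_flux)``: the arterial concentration (nmol/L)
    after gill passage and the net uptake flux (nmol/hr).  Exchange is
    limited by the smaller of gill water flow and ``F_car * lambda_bld``
    (thermodynamic consistency); the gill itself accumulates nothing.
    """
    if chem not in _BLOOD_WATER_PARTITION:
        raise ValueError(f"no blood:water partition coefficient for {chem!r}")
    _check_nonneg(c_water=c_water, c_ven=c_ven)
    lam = getattr(params, _BLOOD_WATER_PARTITION[chem])
    f_eff = min(geom.gill_water_flow, geom.cardiac_output * lam)
    uptake = f_eff * (c_water - c_ven / lam)
    c_art = c_ven + uptake / geom.cardiac_output
    return c_art, uptake


def lh_production_rate(t: float, c_erbd_brn: float, c_arbd_brn: float,
                       params: ModelParameters) -> float:
    """Brain LH synthesis rate (nmol/hr).

    A diurnal background ``Mag_LH * (1 + sin(2*pi*t/24))`` (period 24 hr,
    t=0 at lights-on) is up-regulated by bound ER and down-regulated by
    bound AR through hyperbolic factors.
    """
    _check_nonneg(t=t, c_erbd_brn=c_erbd_brn, c_arbd_brn=c_arbd_brn)
    return float(K.lh_production(t, c_erbd_brn, c_arbd_brn, params.mag_lh,
                                 params.rho_u_lh, params.rho_d_lh))


def brain_ar_production_rate(c_t_brn: float, c_tb_brn: float,
                             params: ModelParameters) -> float:
    """Androgen-repressed AR synthesis term in brain (nmol/L/hr)."""
    _check_nonneg(c_t_brn=c_t_brn, c_tb_brn=c_tb_brn)
    k = params.k_ar_brn
    return params.pbg_ar_brn * k / (k + c_t_brn + c_tb_brn)


def t_production_rate(c_lhlr_gon: float, c_erbd_gon: float,
                      phys: Physiology, params: ModelParameters) -> float:
    """Gonadal T synthesis rate (nmol/hr).

    Bound LH sets StAR, StAR sets deliverable cholesterol, and a Hill
    function of cholesterol drives the side-chain-cleavage capacity
    ``sc_Vmax * BW^0.75``; gonad bound ER represses hyperbolically.
    """
    _check_nonneg(c_lhlr_gon=c_lhlr_gon, c_erbd_gon=c_erbd_gon)
    c_chol = params.rho_chol_gon * params.rho_star_gon * c_lhlr_gon
    vmax = params.sc_vmax_scc_gon * phys.body_weight ** 0.75
    return (vmax * K.hill(c_chol, params.k05_scc_gon, params.n_t)
            / (1.0 + c_erbd_gon / params.k_t))


def e2_production_rate(c_t: float, c_lhlr_gon: float, compartment: str,
                       phys: Physiology, params: ModelParameters) -> float:
    """Aromatase E2 synthesis rate (nmol/hr) in gonad or brain.

    Michaelis-Menten in free T; the gonad rate is induced by bound LH,
    the brain has no LH induction but a 4.6-fold higher specific capacity
    on a larger microsomal protein pool.
    """
    _check_nonneg(c_t=c_t, c_lhlr_gon=c_lhlr_gon)
    from .parameters import derive_geometry
    geom = derive_geometry(phys, params)
    if compartment == "gon":
        vmax = params.sc_vmax_aro_gon * params.d_mp_gon * geom.volumes["gon"]
        induction = 1.0 + params.rho_e2_lhlr_gon * c_lhlr_gon
        return induction * vmax * c_t / (params.km_aro_gon + c_t)
    if compartment == "brn":
        vmax = params.sc_vmax_aro_brn * params.d_mp_brn * geom.volumes["brn"]
        return vmax * c_t / (params.km_aro_brn + c_t)
    raise ValueError(f"aromatase is modeled in 'gon' and 'brn', not {compartment!r}")


def vtg_production_rate(c_erbd_liv: float, phys: Physiology,
                        params: ModelParameters) -> float:
    """Hepatic VTG synthesis rate (nmol/hr), Hill in bound liver ER."""
    _check_nonneg(c_erbd_liv=c_erbd_liv)
    vmax = params.sc_vmax_vtg_liv * phys.body_weight ** 0.75
    return vmax * K.hill(c_erbd_liv, params.k05_vtg_liv, params.n_vtg)


def liver_er_production_rate(c_erbd_liv: float,
                             params: ModelParameters) -> float:
    """Auto-regulated ER synthesis term in liver (nmol/L/hr)."""
    _check_nonneg(c_erbd_liv=c_erbd_liv)
    return params.pbg_er_liv + params.k_er_liv * c_erbd_liv


def vtg_oocyte_uptake_rate(c_vtg_gon: float, geom: CompartmentGeometry,
                           params: ModelParameters) -> float:
    """First-order VTG absorption into oocytes (nmol/hr); a pure sink."""
    _check_nonneg(c_vtg_gon=c_vtg_gon)
    return params.k_vtg_gon * c_vtg_gon * geom.volumes["gon"]


def elimination_rate(c_oth: float, chem: str, geom: CompartmentGeometry,
                     params: ModelParameters) -> float:
    """First-order elimination flux in the "other" compartment (nmol/hr)."""
    if chem not in _KE_OTH:
        raise ValueError(f"unknown chemical {chem!r}")
    _check_nonneg(c_oth=c_oth)
    return getattr(params, _KE_OTH[chem]) * c_oth * geom.volumes["oth"]
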