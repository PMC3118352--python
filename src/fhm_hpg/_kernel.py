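"""Compiled right-hand side of the HPG-axis ODE system.

State layout (48 components, all nmol/L):
  y[5*i + j]      free chemical i in compartment j
                  i: 0=E2 1=T 2=EE2 3=TB 4=LH 5=VTG
                  j: 0=brain 1=gonad 2=liver 3=other 4=venous blood
  y[30..32]       E2-ER complex (brain, gonad, liver)
  y[33..35]       EE2-ER complex (brain, gonad, liver)
  y[36..38]       T-AR complex (brain, gonad, liver)
  y[39..41]       TB-AR complex (brain, gonad, liver)
  y[42]           LH-LR complex (gonad)
  y[43..45]       E2-SBP, T-SBP, EE2-SBP complexes (venous blood)
  y[46]           free ER, liver (dynamic, auto-regulated pool)
  y[47]           free AR, brain (dynamic, androgen-repressed pool)

Fixed-total receptor pools (brain/gonad ER, gonad/liver AR, gonad LR,
venous SBP) carry no free-receptor state: free = total - bound complexes.

The parameter vector ``p`` is packed by :func:`fhm_hpg.parameters.pack_params`;
index constants below are the single source of truth for its layout.
"""

import math

import numpy as np
from numba import njit

# ---- chemical / compartment indices -------------------------------------
E2, T, EE2, TB, LH, VTG = 0, 1, 2, 3, 4, 5
BRN, GON, LIV, OTH, VEN = 0, 1, 2, 3, 4

N_CHEM = 6
N_STATE = 48

# complex state indices
IX_E2ER = 30     # +0 brn, +1 gon, +2 liv
IX_EE2ER = 33
IX_TAR = 36
IX_TBAR = 39
IX_LHLR = 42
IX_E2SBP = 43
IX_TSBP = 44
IX_EE2SBP = 45
IX_ERFREE_LIV = 46
IX_ARFREE_BRN = 47


def state_index(chem: int, comp: int) -> int:
    return 5 * chem + comp


# ---- packed parameter vector layout --------------------------------------
P_V_BRN, P_V_GON, P_V_LIV, P_V_OTH, P_V_VEN = 0, 1, 2, 3, 4
P_F_BRN, P_F_GON, P_F_LIV, P_F_OTH = 5, 6, 7, 8
P_F_CAR, P_FW_GIL = 9, 10
P_K1_ER, P_KD_E2ER, P_KD_EE2ER = 11, 12, 13
P_K1_AR, P_KD_TAR, P_KD_TBAR = 14, 15, 16
P_K1_LHLR, P_KD_LHLR = 17, 18
P_K1_SBP, P_KD_E2SBP, P_KD_TSBP, P_KD_EE2SBP = 19, 20, 21, 22
P_ER_BRN_TOT, P_ER_GON_TOT = 23, 24
P_AR_GON_TOT, P_AR_LIV_TOT = 25, 26
P_LR_GON_TOT, P_SBP_TOT = 27, 28
P_MAG_LH, P_RHO_U_LH, P_RHO_D_LH = 29, 30, 31
P_PBG_AR, P_K_AR_BRN, P_KE_AR_BRN = 32, 33, 34
P_VMAX_T, P_K05_SCC, P_N_T, P_K_T, P_RHO_STAR, P_RHO_CHOL = 35, 36, 37, 38, 39, 40
P_VMAX_ARO_GON, P_KM_ARO_GON = 41, 42
P_VMAX_ARO_BRN, P_KM_ARO_BRN = 43, 44
P_RHO_E2_LHLR = 45
P_VMAX_VTG, P_K05_VTG, P_N_VTG, P_K_VTG_GON = 46, 47, 48, 49
P_PBG_ER, P_K_ER_LIV, P_KE_ER_LIV = 50, 51, 52
P_KE_OTH = 53            # 6 slots, chemical order above (53..58)
P_LAM_BLD_E2, P_LAM_BLD_EE2, P_LAM_BLD_TB = 59, 60, 61
P_LAM = 62               # 30 slots: tissue:blood partition, 5*i + j (62..91)
P_ENABLE_PROD, P_ENABLE_ELIM, P_ENABLE_GILL = 92, 93, 94
N_PARAM = 95

# exposure vector: piecewise segment, c_w(t) = c0 * exp(-kdec * (t - t0))
X_C0_EE2, X_KDEC_EE2, X_T0_EE2 = 0, 1, 2
X_C0_TB, X_KDEC_TB, X_T0_TB = 3, 4, 5
N_EXPO = 6

_TWO_PI_OVER_24 = 2.0 * math.pi / 24.0


@njit(cache=True)
def binding_flux(c_free, c_rfree, c_bound, k1, kd):
    """Net association flux d(bound)/dt = k1*free*Rfree - (k1*kd)*bound."""
    return k1 * c_free * c_rfree - k1 * kd * c_bound


@njit(cache=True)
def lh_production(t, c_erbd_brn, c_arbd_brn, mag_lh, rho_u, rho_d):
    """Diurnal LH synthesis, ER-bound induced, AR-bound repressed (nmol/hr)."""
    base = mag_lh * (1.0 + math.sin(_TWO_PI_OVER_24 * t))
    return base * (1.0 + c_erbd_brn / rho_u) / (1.0 + c_arbd_brn / rho_d)


@njit(cache=True)
def hill(x, k05, n):
    if x <= 0.0:
        return 0.0
    xn = x ** n
    return xn / (k05 ** n + xn)


@njit(cache=True)
def rhs(y, t, p, expo):
    """Time derivative of the full state (odeint call signature)."""
    dy = np.zeros(N_STATE)
    yc = np.empty(N_STATE)
    for k in range(N_STATE):
        v = y[k]
        yc[k] = v if v > 0.0 else 0.0

    prod_on = p[P_ENABLE_PROD] > 0.5
    elim_on = p[P_ENABLE_ELIM] > 0.5
    gill_on = p[P_ENABLE_GILL] > 0.5

    # ---- free receptor pools ----
    er_free_brn = p[P_ER_BRN_TOT] - yc[IX_E2ER + 0] - yc[IX_EE2ER + 0]
    er_free_gon = p[P_ER_GON_TOT] - yc[IX_E2ER + 1] - yc[IX_EE2ER + 1]
    er_free_liv = yc[IX_ERFREE_LIV]
    ar_free_brn = yc[IX_ARFREE_BRN]
    ar_free_gon = p[P_AR_GON_TOT] - yc[IX_TAR + 1] - yc[IX_TBAR + 1]
    ar_free_liv = p[P_AR_LIV_TOT] - yc[IX_TAR + 2] - yc[IX_TBAR + 2]
    lr_free = p[P_LR_GON_TOT] - yc[IX_LHLR]
    sbp_free = p[P_SBP_TOT] - yc[IX_E2SBP] - yc[IX_TSBP] - yc[IX_EE2SBP]
    if er_free_brn < 0.0:
        er_free_brn = 0.0
    if er_free_gon < 0.0:
        er_free_gon = 0.0
    if ar_free_gon < 0.0:
        ar_free_gon = 0.0
    if ar_free_liv < 0.0:
        ar_free_liv = 0.0
    if lr_free < 0.0:
        lr_free = 0.0
    if sbp_free < 0.0:
        sbp_free = 0.0

    # ---- receptor-ligand binding (per-compartment concentration fluxes) ----
    # estrogen receptors: E2 and EE2 in brain / gonad / liver
    er_free = (er_free_brn, er_free_gon, er_free_liv)
    for j in range(3):
        f = binding_flux(yc[5 * E2 + j], er_free[j], yc[IX_E2ER + j],
                         p[P_K1_ER], p[P_KD_E2ER])
        dy[IX_E2ER + j] += f
        dy[5 * E2 + j] -= f
        g = binding_flux(yc[5 * EE2 + j], er_free[j], yc[IX_EE2ER + j],
                         p[P_K1_ER], p[P_KD_EE2ER])
        dy[IX_EE2ER + j] += g
        dy[5 * EE2 + j] -= g
        if j == 2:
            dy[IX_ERFREE_LIV] -= f + g

    # androgen receptors: T and TB in brain / gonad / liver
    ar_free = (ar_free_brn, ar_free_gon, ar_free_liv)
    for j in range(3):
        f = binding_flux(yc[5 * T + j], ar_free[j], yc[IX_TAR + j],
                         p[P_K1_AR], p[P_KD_TAR])
        dy[IX_TAR + j] += f
        dy[5 * T + j] -= f
        g = binding_flux(yc[5 * TB + j], ar_free[j], yc[IX_TBAR + j],
                         p[P_K1_AR], p[P_KD_TBAR])
        dy[IX_TBAR + j] += g
        dy[5 * TB + j] -= g
        if j == 0:
            dy[IX_ARFREE_BRN] -= f + g

    # LH receptor in gonad
    f = binding_flux(yc[5 * LH + GON], lr_free, yc[IX_LHLR],
                     p[P_K1_LHLR], p[P_KD_LHLR])
    dy[IX_LHLR] += f
    dy[5 * LH + GON] -= f

    # steroid-binding protein in venous blood
    f = binding_flux(yc[5 * E2 + VEN], sbp_free, yc[IX_E2SBP],
                     p[P_K1_SBP], p[P_KD_E2SBP])
    dy[IX_E2SBP] += f
    dy[5 * E2 + VEN] -= f
    f = binding_flux(yc[5 * T + VEN], sbp_free, yc[IX_TSBP],
                     p[P_K1_SBP], p[P_KD_TSBP])
    dy[IX_TSBP] += f
    dy[5 * T + VEN] -= f
    f = binding_flux(yc[5 * EE2 + VEN], sbp_free, yc[IX_EE2SBP],
                     p[P_K1_SBP], p[P_KD_EE2SBP])
    dy[IX_EE2SBP] += f
    dy[5 * EE2 + VEN] -= f

    # ---- gill exchange -> arterial concentrations ----
    cart = np.empty(N_CHEM)
    for i in range(N_CHEM):
        cart[i] = yc[5 * i + VEN]
    if gill_on:
        # only chemicals with a blood:water partition coefficient
        for i in range(3):
            if i == 0:
                chem, lam = E2, p[P_LAM_BLD_E2]
                cw = 0.0
            elif i == 1:
                chem, lam = EE2, p[P_LAM_BLD_EE2]
                cw = expo[X_C0_EE2] * math.exp(
                    -expo[X_KDEC_EE2] * (t - expo[X_T0_EE2]))
            else:
                chem, lam = TB, p[P_LAM_BLD_TB]
                cw = expo[X_C0_TB] * math.exp(
                    -expo[X_KDEC_TB] * (t - expo[X_T0_TB]))
            f_eff = p[P_FW_GIL]
            lim = p[P_F_CAR] * lam
            if lim < f_eff:
                f_eff = lim
            uptake = f_eff * (cw - yc[5 * chem + VEN] / lam)   # nmol/hr
            cart[chem] = yc[5 * chem + VEN] + uptake / p[P_F_CAR]

    # ---- blood perfusion of tissue compartments ----
    vol = (p[P_V_BRN], p[P_V_GON], p[P_V_LIV], p[P_V_OTH])
    flow = (p[P_F_BRN], p[P_F_GON], p[P_F_LIV], p[P_F_OTH])
    for i in range(N_CHEM):
        venous_in = 0.0
        for j in range(4):
            lam = p[P_LAM + 5 * i + j]
            out = flow[j] * yc[5 * i + j] / lam          # nmol/hr to vein
            dy[5 * i + j] += (flow[j] * cart[i] - out) / vol[j]
            venous_in += out
        dy[5 * i + VEN] += (venous_in - p[P_F_CAR] * yc[5 * i + VEN]) / p[P_V_VEN]

    # ---- productions ----
    er_bd_brn = yc[IX_E2ER + 0] + yc[IX_EE2ER + 0]
    er_bd_gon = yc[IX_E2ER + 1] + yc[IX_EE2ER + 1]
    er_bd_liv = yc[IX_E2ER + 2] + yc[IX_EE2ER + 2]
    ar_bd_brn = yc[IX_TAR + 0] + yc[IX_TBAR + 0]
    if prod_on:
        # LH in brain (diurnal, ER-induced, AR-repressed)
        p_lh = lh_production(t, er_bd_brn, ar_bd_brn, p[P_MAG_LH],
                             p[P_RHO_U_LH], p[P_RHO_D_LH])
        dy[5 * LH + BRN] += p_lh / p[P_V_BRN]

        # brain AR synthesis, repressed by free androgens
        c_andro = yc[5 * T + BRN] + yc[5 * TB + BRN]
        dy[IX_ARFREE_BRN] += (p[P_PBG_AR] * p[P_K_AR_BRN]
                              / (p[P_K_AR_BRN] + c_andro))

        # T synthesis in gonad: LH-bound -> StAR -> cholesterol -> Hill,
        # repressed by gonad bound ER
        c_star = p[P_RHO_STAR] * yc[IX_LHLR]
        c_chol = p[P_RHO_CHOL] * c_star
        p_t = (p[P_VMAX_T] * hill(c_chol, p[P_K05_SCC], p[P_N_T])
               / (1.0 + er_bd_gon / p[P_K_T]))
        dy[5 * T + GON] += p_t / p[P_V_GON]

        # aromatase T -> E2 in gonad (LH-bound induced) and brain
        p_e2g = ((1.0 + p[P_RHO_E2_LHLR] * yc[IX_LHLR]) * p[P_VMAX_ARO_GON]
                 * yc[5 * T + GON] / (p[P_KM_ARO_GON] + yc[5 * T + GON]))
        dy[5 * E2 + GON] += p_e2g / p[P_V_GON]
        dy[5 * T + GON] -= p_e2g / p[P_V_GON]
        p_e2b = (p[P_VMAX_ARO_BRN] * yc[5 * T + BRN]
                 / (p[P_KM_ARO_BRN] + yc[5 * T + BRN]))
        dy[5 * E2 + BRN] += p_e2b / p[P_V_BRN]
        dy[5 * T + BRN] -= p_e2b / p[P_V_BRN]

        # VTG synthesis in liver (Hill in bound liver ER)
        p_vtg = p[P_VMAX_VTG] * hill(er_bd_liv, p[P_K05_VTG], p[P_N_VTG])
        dy[5 * VTG + LIV] += p_vtg / p[P_V_LIV]

        # liver ER auto-regulation
        dy[IX_ERFREE_LIV] += p[P_PBG_ER] + p[P_K_ER_LIV] * er_bd_liv

    # ---- eliminations and sinks ----
    if elim_on:
        for i in range(N_CHEM):
            dy[5 * i + OTH] -= p[P_KE_OTH + i] * yc[5 * i + OTH]
        dy[5 * VTG + GON] -= p[P_K_VTG_GON] * yc[5 * VTG + GON]
        # dynamic receptor pools turn over as whole pools: free receptor and
        # ligand-bound complexes degrade at the same rate (receptor-mediated
        # co-degradation of the ligand keeps the auto-induced liver ER loop
        # bounded)
        dy[IX_ERFREE_LIV] -= p[P_KE_ER_LIV] * yc[IX_ERFREE_LIV]
        dy[IX_E2ER + 2] -= p[P_KE_ER_LIV] * yc[IX_E2ER + 2]
        dy[IX_EE2ER + 2] -= p[P_KE_ER_LIV] * yc[IX_EE2ER + 2]
        dy[IX_ARFREE_BRN] -= p[P_KE_AR_BRN] * yc[IX_ARFREE_BRN]
        dy[IX_TAR + 0] -= p[P_KE_AR_BRN] * yc[IX_TAR + 0]
        dy[IX_TBAR + 0] -= p[P_KE_AR_BRN] * yc[IX_TBAR + 0]

    return dy
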