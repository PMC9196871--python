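"""Compiled numerical kernels: TP06 ionic rates and monodomain integrators.

The state vector of one cell has 19 entries (index constants below):
voltage, 12 Hodgkin–Huxley gates integrated with the Rush–Larsen scheme,
the ryanodine-receptor adaptation variable, and five ionic concentrations
integrated with forward Euler.  Parameters are a 19-entry row per node so
that tissue kernels can carry per-node heterogeneity (transmural variant,
cytokine perturbation) without branching.

Everything here is plain scalar code under ``numba.njit``; the public API
lives in :mod:`cardioinflam.cell_model` and the tissue modules.
"""

import math

import numpy as np
from numba import njit

# --- state layout ---------------------------------------------------------
SV_V = 0
SV_M = 1
SV_H = 2
SV_J = 3
SV_XR1 = 4
SV_XR2 = 5
SV_XS = 6
SV_R = 7
SV_S = 8
SV_D = 9
SV_F = 10
SV_F2 = 11
SV_FCASS = 12
SV_RQ = 13          # RyR adaptation gate (not Rush-Larsen shaped)
SV_CAI = 14
SV_CASR = 15
SV_CASS = 16
SV_NAI = 17
SV_KI = 18
N_STATE = 19

STATE_NAMES = (
    "Vm", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fCass", "R_rel", "Ca_i", "Ca_SR", "Ca_ss", "Na_i", "K_i",
)

# --- parameter layout -----------------------------------------------------
IP_GNA = 0
IP_GCAL = 1
IP_GTO = 2
IP_GKR = 3
IP_GKS = 4
IP_GK1 = 5
IP_GPCA = 6
IP_GPK = 7
IP_GBNA = 8
IP_GBCA = 9
IP_KNACA = 10
IP_PNAK = 11
IP_VMAXUP = 12
IP_VLEAK = 13
IP_VREL = 14
IP_VXFER = 15
IP_SHIFT_S = 16     # mV offset of the I_to inactivation steady state
IP_SHIFT_XR1 = 17   # mV offset of the I_Kr activation steady state
IP_ENDO_S = 18      # 1.0 -> endocardial s-gate kinetics, else epi/mid
N_PARAM = 19

# --- currents layout ------------------------------------------------------
CUR_INA = 0
CUR_ICAL = 1
CUR_ITO = 2
CUR_IKR = 3
CUR_IKS = 4
CUR_IK1 = 5
CUR_INACA = 6
CUR_INAK = 7
CUR_IPCA = 8
CUR_IPK = 9
CUR_IBNA = 10
CUR_IBCA = 11
CUR_JUP = 12
CUR_JLEAK = 13
CUR_JREL = 14
CUR_JXFER = 15
N_CUR = 16

CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_to", "I_Kr", "I_Ks", "I_K1", "I_NaCa", "I_NaK",
    "I_pCa", "I_pK", "I_bNa", "I_bCa", "J_up", "J_leak", "J_rel", "J_xfer",
)

# --- physical constants of the source model -------------------------------
R_GAS = 8314.472        # mJ/(mol K)
TEMP = 310.0            # K
FARADAY = 96485.3415    # C/mol
RTONF = R_GAS * TEMP / FARADAY
FORT = FARADAY / (R_GAS * TEMP)

KO = 5.4                # mM
NAO = 140.0
CAO = 2.0
V_C = 0.016404          # cytoplasmic volume (units of the source model)
V_SR = 0.001094
V_SS = 0.00005468
CAPACITANCE = 0.185     # membrane capacitance scaling of the source model

PK_NA = 0.03
KM_K = 1.0
KM_NA = 40.0
KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NACA = 0.35
ALPHA_NACA = 2.5
KP_CA = 0.0005

K1_PRIME = 0.15
K2_PRIME = 0.045
K3_REL = 0.060
K4_REL = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
K_UP = 0.00025

BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

SQRT_KO = math.sqrt(KO / 5.4)


@njit(cache=True)
def node_rates(S, P, i, istim, ginf, gtau, cur):
    """Ionic rates of node ``i``.

    Fills ``ginf``/``gtau`` (Rush-Larsen targets for the 12 HH gates, state
    order m..fCass) and ``cur`` (membrane currents in pA/pF, fluxes in
    mM/ms), and returns the time derivatives of the non-gate variables
    ``(dV, dRq, dCai, dCaSR, dCaSS, dNai, dKi)``.  ``dV`` excludes the
    stimulus; ``istim`` (depolarizing-positive, pA/pF) is only needed for
    the K+ bookkeeping of the stimulus current.
    """
    V = S[i, SV_V]
    m = S[i, SV_M]
    h = S[i, SV_H]
    jg = S[i, SV_J]
    xr1 = S[i, SV_XR1]
    xr2 = S[i, SV_XR2]
    xs = S[i, SV_XS]
    r = S[i, SV_R]
    s = S[i, SV_S]
    d = S[i, SV_D]
    f = S[i, SV_F]
    f2 = S[i, SV_F2]
    fcass = S[i, SV_FCASS]
    rq = S[i, SV_RQ]
    cai = S[i, SV_CAI]
    casr = S[i, SV_CASR]
    cass = S[i, SV_CASS]
    nai = S[i, SV_NAI]
    ki = S[i, SV_KI]

    ek = RTONF * math.log(KO / ki)
    ena = RTONF * math.log(NAO / nai)
    eks = RTONF * math.log((KO + PK_NA * NAO) / (ki + PK_NA * nai))
    eca = 0.5 * RTONF * math.log(CAO / cai)

    ina = P[i, IP_GNA] * m * m * m * h * jg * (V - ena)

    z = 2.0 * (V - 15.0) * FORT
    if abs(z) < 1e-7:
        zfac = 1.0
    else:
        zfac = z / math.expm1(z)
    ical = (P[i, IP_GCAL] * d * f * f2 * fcass * 2.0 * FARADAY * zfac
            * (0.25 * cass * math.exp(z) - CAO))

    ito = P[i, IP_GTO] * r * s * (V - ek)
    ikr = P[i, IP_GKR] * SQRT_KO * xr1 * xr2 * (V - ek)
    iks = P[i, IP_GKS] * xs * xs * (V - eks)

    vek = V - ek
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (vek - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (vek + 100.0)) + math.exp(0.1 * (vek - 10.0)))
           / (1.0 + math.exp(-0.5 * vek)))
    ik1 = P[i, IP_GK1] * SQRT_KO * ak1 / (ak1 + bk1) * vek

    vfort = V * FORT
    inaca = (P[i, IP_KNACA]
             * (1.0 / (KM_NAI ** 3 + NAO ** 3)) * (1.0 / (KM_CA + CAO))
             * (1.0 / (1.0 + K_SAT * math.exp((GAMMA_NACA - 1.0) * vfort)))
             * (math.exp(GAMMA_NACA * vfort) * nai ** 3 * CAO
                - math.exp((GAMMA_NACA - 1.0) * vfort) * NAO ** 3 * cai * ALPHA_NACA))

    inak = (P[i, IP_PNAK] * (KO / (KO + KM_K)) * (nai / (nai + KM_NA))
            / (1.0 + 0.1245 * math.exp(-0.1 * vfort) + 0.0353 * math.exp(-vfort)))

    ipca = P[i, IP_GPCA] * cai / (KP_CA + cai)
    ipk = P[i, IP_GPK] * vek / (1.0 + math.exp((25.0 - V) / 5.98))
    ibna = P[i, IP_GBNA] * (V - ena)
    ibca = P[i, IP_GBCA] * (V - eca)

    iion = (ina + ical + ito + ikr + iks + ik1 + inaca + inak
            + ipca + ipk + ibna + ibca)

    # --- HH gate targets (Rush-Larsen) ---
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    gtau[0] = am * bm
    tmp = 1.0 + math.exp((-56.86 - V) / 9.03)
    ginf[0] = 1.0 / (tmp * tmp)

    tmp = 1.0 + math.exp((V + 71.55) / 7.43)
    hinf = 1.0 / (tmp * tmp)
    ginf[1] = hinf
    ginf[2] = hinf
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
        aj = ((-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    gtau[1] = 1.0 / (ah + bh)
    gtau[2] = 1.0 / (aj + bj)

    # I_Kr activation: steady state optionally voltage-shifted, tau unshifted
    vx = V - P[i, IP_SHIFT_XR1]
    ginf[3] = 1.0 / (1.0 + math.exp((-26.0 - vx) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    gtau[3] = axr1 * bxr1

    ginf[4] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    gtau[4] = axr2 * bxr2

    ginf[5] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    gtau[5] = axs * bxs + 80.0

    ginf[6] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    gtau[6] = 9.5 * math.exp(-(V + 40.0) * (V + 40.0) / 1800.0) + 0.8

    # I_to inactivation: steady state optionally shifted, tau unshifted
    vs = V - P[i, IP_SHIFT_S]
    if P[i, IP_ENDO_S] > 0.5:
        ginf[7] = 1.0 / (1.0 + math.exp((vs + 28.0) / 5.0))
        gtau[7] = 1000.0 * math.exp(-(V + 67.0) * (V + 67.0) / 1000.0) + 8.0
    else:
        ginf[7] = 1.0 / (1.0 + math.exp((vs + 20.0) / 5.0))
        gtau[7] = (85.0 * math.exp(-(V + 45.0) * (V + 45.0) / 320.0)
                   + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    ginf[8] = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    cd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    gtau[8] = ad * bd + cd

    ginf[9] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    af = 1102.5 * math.exp(-(V + 27.0) * (V + 27.0) / 225.0)
    bf = 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
    cf = 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0
    gtau[9] = af + bf + cf

    ginf[10] = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    af2 = 562.0 * math.exp(-(V + 27.0) * (V + 27.0) / 240.0)
    bf2 = 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
    cf2 = 80.0 / (1.0 + math.exp((V + 30.0) / 10.0))
    gtau[10] = af2 + bf2 + cf2

    css2 = (cass / 0.05) * (cass / 0.05)
    ginf[11] = 0.6 / (1.0 + css2) + 0.4
    gtau[11] = 80.0 / (1.0 + css2) + 2.0

    # --- SR calcium handling ---
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) * (EC_SR / casr))
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    drq = K4_REL * (1.0 - rq) - k2 * cass * rq
    o_rel = k1 * cass * cass * rq / (K3_REL + k1 * cass * cass)
    jrel = P[i, IP_VREL] * o_rel * (casr - cass)
    jleak = P[i, IP_VLEAK] * (casr - cai)
    jup = P[i, IP_VMAXUP] / (1.0 + K_UP * K_UP / (cai * cai))
    jxfer = P[i, IP_VXFER] * (cass - cai)

    # instantaneous-buffering chain-rule factors
    bc = 1.0 / (1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) * (cai + K_BUF_C)))
    dcai = bc * ((jleak - jup) * V_SR / V_C + jxfer
                 - (ibca + ipca - 2.0 * inaca) * CAPACITANCE / (2.0 * V_C * FARADAY))
    bsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) * (casr + K_BUF_SR)))
    dcasr = bsr * (jup - jrel - jleak)
    bss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((cass + K_BUF_SS) * (cass + K_BUF_SS)))
    dcass = bss * (-ical * CAPACITANCE / (2.0 * V_SS * FARADAY)
                   + jrel * V_SR / V_SS - jxfer * V_C / V_SS)

    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CAPACITANCE / (V_C * FARADAY)
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk - istim) * CAPACITANCE / (V_C * FARADAY)

    cur[CUR_INA] = ina
    cur[CUR_ICAL] = ical
    cur[CUR_ITO] = ito
    cur[CUR_IKR] = ikr
    cur[CUR_IKS] = iks
    cur[CUR_IK1] = ik1
    cur[CUR_INACA] = inaca
    cur[CUR_INAK] = inak
    cur[CUR_IPCA] = ipca
    cur[CUR_IPK] = ipk
    cur[CUR_IBNA] = ibna
    cur[CUR_IBCA] = ibca
    cur[CUR_JUP] = jup
    cur[CUR_JLEAK] = jleak
    cur[CUR_JREL] = jrel
    cur[CUR_JXFER] = jxfer

    return -iion, drq, dcai, dcasr, dcass, dnai, dki


# --- voltage lookup tables (fast path for tissue/pacing kernels) ----------
# Rows tabulated on a uniform V grid; Rush-Larsen factors exp(-dt/tau) are
# baked in per dt, so tables are built per integrator step size.
TAB_M_INF = 0
TAB_M_RL = 1
TAB_H_INF = 2
TAB_H_RL = 3
TAB_J_INF = 4
TAB_J_RL = 5
TAB_XR1_INF = 6
TAB_XR1_RL = 7
TAB_XR2_INF = 8
TAB_XR2_RL = 9
TAB_XS_INF = 10
TAB_XS_RL = 11
TAB_R_INF = 12
TAB_R_RL = 13
TAB_S_INF_EPI = 14
TAB_S_RL_EPI = 15
TAB_S_INF_ENDO = 16
TAB_S_RL_ENDO = 17
TAB_D_INF = 18
TAB_D_RL = 19
TAB_F_INF = 20
TAB_F_RL = 21
TAB_F2_INF = 22
TAB_F2_RL = 23
TAB_EXP_G = 24      # exp(gamma*V*F/RT)
TAB_EXP_GM1 = 25    # exp((gamma-1)*V*F/RT)
TAB_NAK_RECT = 26
TAB_PK_RECT = 27
TAB_CAL_EXP = 28    # exp(2*(V-15)*F/RT)
TAB_CAL_ZFAC = 29   # z/expm1(z)
TAB_K1_RECT = 30    # vs (V - E_K)
N_TAB = 31

TAB_VMIN = -150.0
TAB_VMAX = 150.0
TAB_DV = 0.02


def build_tables(dt: float) -> tuple:
    """Tabulate the voltage-dependent coefficients for step size ``dt``.

    Returns ``(TAB, vmin, inv_dv)`` with ``TAB`` of shape (N_TAB, n_v).
    Linear interpolation on a 0.02 mV grid keeps the tabulation error far
    below the time-discretization error.
    """
    V = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    T = np.empty((N_TAB, len(V)))

    def rl(tau):
        return np.exp(-dt / tau)

    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    T[TAB_M_INF] = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    T[TAB_M_RL] = rl(am * bm)

    hinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    hi = V >= -40.0
    ah = np.where(hi, 0.0, 0.057 * np.exp(-(V + 80.0) / 6.8))
    bh = np.where(hi, 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
                  2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V))
    aj = np.where(hi, 0.0,
                  (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
                  * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
    bj = np.where(hi, 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
                  0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))))
    T[TAB_H_INF] = hinf
    T[TAB_H_RL] = rl(1.0 / (ah + bh))
    T[TAB_J_INF] = hinf
    T[TAB_J_RL] = rl(1.0 / (aj + bj))

    T[TAB_XR1_INF] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    T[TAB_XR1_RL] = rl((450.0 / (1.0 + np.exp((-45.0 - V) / 10.0)))
                       * (6.0 / (1.0 + np.exp((V + 30.0) / 11.5))))
    T[TAB_XR2_INF] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    T[TAB_XR2_RL] = rl((3.0 / (1.0 + np.exp((-60.0 - V) / 20.0)))
                       * (1.12 / (1.0 + np.exp((V - 60.0) / 20.0))))
    T[TAB_XS_INF] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    T[TAB_XS_RL] = rl((1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0)))
                      * (1.0 / (1.0 + np.exp((V - 35.0) / 15.0))) + 80.0)
    T[TAB_R_INF] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    T[TAB_R_RL] = rl(9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8)
    T[TAB_S_INF_EPI] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    T[TAB_S_RL_EPI] = rl(85.0 * np.exp(-(V + 45.0) ** 2 / 320.0)
                         + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    T[TAB_S_INF_ENDO] = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
    T[TAB_S_RL_ENDO] = rl(1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0)
    T[TAB_D_INF] = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    T[TAB_D_RL] = rl((1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25)
                     * (1.4 / (1.0 + np.exp((V + 5.0) / 5.0)))
                     + 1.0 / (1.0 + np.exp((50.0 - V) / 20.0)))
    T[TAB_F_INF] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    T[TAB_F_RL] = rl(1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0)
                     + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
                     + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    T[TAB_F2_INF] = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    T[TAB_F2_RL] = rl(562.0 * np.exp(-(V + 27.0) ** 2 / 240.0)
                      + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
                      + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))

    T[TAB_EXP_G] = np.exp(GAMMA_NACA * V * FORT)
    T[TAB_EXP_GM1] = np.exp((GAMMA_NACA - 1.0) * V * FORT)
    T[TAB_NAK_RECT] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V * FORT)
                             + 0.0353 * np.exp(-V * FORT))
    T[TAB_PK_RECT] = 1.0 / (1.0 + np.exp((25.0 - V) / 5.98))
    z = 2.0 * (V - 15.0) * FORT
    T[TAB_CAL_EXP] = np.exp(z)
    with np.errstate(invalid="ignore"):
        zfac = z / np.expm1(z)
    zfac[np.abs(z) < 1e-10] = 1.0
    T[TAB_CAL_ZFAC] = zfac
    vek = V  # the K1 row is indexed by (V - E_K)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (vek - 200.0)))
    bk1 = ((3.0 * np.exp(0.0002 * (vek + 100.0)) + np.exp(0.1 * (vek - 10.0)))
           / (1.0 + np.exp(-0.5 * vek)))
    T[TAB_K1_RECT] = ak1 / (ak1 + bk1)
    return np.ascontiguousarray(T), TAB_VMIN, 1.0 / TAB_DV


_TABLE_CACHE: dict = {}


def tables_for(dt: float) -> tuple:
    key = round(float(dt), 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = build_tables(key)
    return _TABLE_CACHE[key]


@njit(inline="always")
def _lut(T, row, u):
    i = int(u)
    fr = u - i
    return T[row, i] + fr * (T[row, i + 1] - T[row, i])


@njit(inline="always")
def _uidx(v, vmin, idv, nmax):
    u = (v - vmin) * idv
    if u < 0.0:
        u = 0.0
    elif u > nmax:
        u = nmax
    return u


@njit(cache=True)
def step_node_tab(S, P, i, istim, dt, T, vmin, idv):
    """Table-driven variant of :func:`step_node` (identical physics)."""
    V = S[i, SV_V]
    nmax = T.shape[1] - 1.001
    uv = _uidx(V, vmin, idv, nmax)

    nai = S[i, SV_NAI]
    ki = S[i, SV_KI]
    cai = S[i, SV_CAI]
    casr = S[i, SV_CASR]
    cass = S[i, SV_CASS]

    ek = RTONF * math.log(KO / ki)
    ena = RTONF * math.log(NAO / nai)
    eks = RTONF * math.log((KO + PK_NA * NAO) / (ki + PK_NA * nai))
    eca = 0.5 * RTONF * math.log(CAO / cai)
    vek = V - ek

    ina = P[i, IP_GNA] * S[i, SV_M] ** 3 * S[i, SV_H] * S[i, SV_J] * (V - ena)
    ical = (P[i, IP_GCAL] * S[i, SV_D] * S[i, SV_F] * S[i, SV_F2] * S[i, SV_FCASS]
            * 2.0 * FARADAY * _lut(T, TAB_CAL_ZFAC, uv)
            * (0.25 * cass * _lut(T, TAB_CAL_EXP, uv) - CAO))
    ito = P[i, IP_GTO] * S[i, SV_R] * S[i, SV_S] * vek
    ikr = P[i, IP_GKR] * SQRT_KO * S[i, SV_XR1] * S[i, SV_XR2] * vek
    iks = P[i, IP_GKS] * S[i, SV_XS] * S[i, SV_XS] * (V - eks)
    uvek = _uidx(vek, vmin, idv, nmax)
    ik1 = P[i, IP_GK1] * SQRT_KO * _lut(T, TAB_K1_RECT, uvek) * vek
    inaca = (P[i, IP_KNACA]
             * (1.0 / (KM_NAI ** 3 + NAO ** 3)) * (1.0 / (KM_CA + CAO))
             * (1.0 / (1.0 + K_SAT * _lut(T, TAB_EXP_GM1, uv)))
             * (_lut(T, TAB_EXP_G, uv) * nai ** 3 * CAO
                - _lut(T, TAB_EXP_GM1, uv) * NAO ** 3 * cai * ALPHA_NACA))
    inak = (P[i, IP_PNAK] * (KO / (KO + KM_K)) * (nai / (nai + KM_NA))
            * _lut(T, TAB_NAK_RECT, uv))
    ipca = P[i, IP_GPCA] * cai / (KP_CA + cai)
    ipk = P[i, IP_GPK] * vek * _lut(T, TAB_PK_RECT, uv)
    ibna = P[i, IP_GBNA] * (V - ena)
    ibca = P[i, IP_GBCA] * (V - eca)
    iion = (ina + ical + ito + ikr + iks + ik1 + inaca + inak
            + ipca + ipk + ibna + ibca)

    # Rush-Larsen gate updates; shifted steady states use a shifted lookup
    S[i, SV_M] = _lut(T, TAB_M_INF, uv) + (S[i, SV_M] - _lut(T, TAB_M_INF, uv)) * _lut(T, TAB_M_RL, uv)
    S[i, SV_H] = _lut(T, TAB_H_INF, uv) + (S[i, SV_H] - _lut(T, TAB_H_INF, uv)) * _lut(T, TAB_H_RL, uv)
    S[i, SV_J] = _lut(T, TAB_J_INF, uv) + (S[i, SV_J] - _lut(T, TAB_J_INF, uv)) * _lut(T, TAB_J_RL, uv)
    uxr1 = _uidx(V - P[i, IP_SHIFT_XR1], vmin, idv, nmax)
    xinf = _lut(T, TAB_XR1_INF, uxr1)
    S[i, SV_XR1] = xinf + (S[i, SV_XR1] - xinf) * _lut(T, TAB_XR1_RL, uv)
    S[i, SV_XR2] = _lut(T, TAB_XR2_INF, uv) + (S[i, SV_XR2] - _lut(T, TAB_XR2_INF, uv)) * _lut(T, TAB_XR2_RL, uv)
    S[i, SV_XS] = _lut(T, TAB_XS_INF, uv) + (S[i, SV_XS] - _lut(T, TAB_XS_INF, uv)) * _lut(T, TAB_XS_RL, uv)
    S[i, SV_R] = _lut(T, TAB_R_INF, uv) + (S[i, SV_R] - _lut(T, TAB_R_INF, uv)) * _lut(T, TAB_R_RL, uv)
    us = _uidx(V - P[i, IP_SHIFT_S], vmin, idv, nmax)
    if P[i, IP_ENDO_S] > 0.5:
        sinf = _lut(T, TAB_S_INF_ENDO, us)
        srl = _lut(T, TAB_S_RL_ENDO, uv)
    else:
        sinf = _lut(T, TAB_S_INF_EPI, us)
        srl = _lut(T, TAB_S_RL_EPI, uv)
    S[i, SV_S] = sinf + (S[i, SV_S] - sinf) * srl
    S[i, SV_D] = _lut(T, TAB_D_INF, uv) + (S[i, SV_D] - _lut(T, TAB_D_INF, uv)) * _lut(T, TAB_D_RL, uv)
    S[i, SV_F] = _lut(T, TAB_F_INF, uv) + (S[i, SV_F] - _lut(T, TAB_F_INF, uv)) * _lut(T, TAB_F_RL, uv)
    S[i, SV_F2] = _lut(T, TAB_F2_INF, uv) + (S[i, SV_F2] - _lut(T, TAB_F2_INF, uv)) * _lut(T, TAB_F2_RL, uv)
    css2 = (cass / 0.05) * (cass / 0.05)
    fcinf = 0.6 / (1.0 + css2) + 0.4
    fctau = 80.0 / (1.0 + css2) + 2.0
    S[i, SV_FCASS] = fcinf + (S[i, SV_FCASS] - fcinf) * math.exp(-dt / fctau)

    # SR calcium handling (identical to node_rates)
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) * (EC_SR / casr))
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    rq = S[i, SV_RQ]
    drq = K4_REL * (1.0 - rq) - k2 * cass * rq
    o_rel = k1 * cass * cass * rq / (K3_REL + k1 * cass * cass)
    jrel = P[i, IP_VREL] * o_rel * (casr - cass)
    jleak = P[i, IP_VLEAK] * (casr - cai)
    jup = P[i, IP_VMAXUP] / (1.0 + K_UP * K_UP / (cai * cai))
    jxfer = P[i, IP_VXFER] * (cass - cai)
    bc = 1.0 / (1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) * (cai + K_BUF_C)))
    dcai = bc * ((jleak - jup) * V_SR / V_C + jxfer
                 - (ibca + ipca - 2.0 * inaca) * CAPACITANCE / (2.0 * V_C * FARADAY))
    bsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) * (casr + K_BUF_SR)))
    dcasr = bsr * (jup - jrel - jleak)
    bss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((cass + K_BUF_SS) * (cass + K_BUF_SS)))
    dcass = bss * (-ical * CAPACITANCE / (2.0 * V_SS * FARADAY)
                   + jrel * V_SR / V_SS - jxfer * V_C / V_SS)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CAPACITANCE / (V_C * FARADAY)
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk - istim) * CAPACITANCE / (V_C * FARADAY)

    S[i, SV_V] += dt * (-iion + istim)
    S[i, SV_RQ] += dt * drq
    S[i, SV_CAI] += dt * dcai
    S[i, SV_CASR] += dt * dcasr
    S[i, SV_CASS] += dt * dcass
    S[i, SV_NAI] += dt * dnai
    S[i, SV_KI] += dt * dki


@njit(cache=True)
def step_node(S, P, i, istim, dt, ginf, gtau, cur):
    """Advance node ``i`` by one step: Rush-Larsen gates, forward Euler rest."""
    dv, drq, dcai, dcasr, dcass, dnai, dki = node_rates(S, P, i, istim, ginf, gtau, cur)
    S[i, SV_V] += dt * (dv + istim)
    for g in range(12):
        S[i, 1 + g] = ginf[g] + (S[i, 1 + g] - ginf[g]) * math.exp(-dt / gtau[g])
    S[i, SV_RQ] += dt * drq
    S[i, SV_CAI] += dt * dcai
    S[i, SV_CASR] += dt * dcasr
    S[i, SV_CASS] += dt * dcass
    S[i, SV_NAI] += dt * dnai
    S[i, SV_KI] += dt * dki


@njit(cache=True)
def pace_cell(S, P, dt, period, n_beats, amp, dur, record_from, record_dt,
              vrec, cairec, casrrec, T, vmin, idv):
    """Pace a single cell (row 0 of S/P) with a periodic stimulus train.

    Records Vm/Ca_i/Ca_SR every ``record_dt`` starting at ``record_from``
    (ms from the start of the run) into the preallocated arrays.  Returns
    ``(status, n_recorded, bad_step)``; status 1 flags instability.
    """
    steps_per_beat = int(round(period / dt))
    n_steps = steps_per_beat * n_beats
    rec_stride = max(1, int(round(record_dt / dt)))
    start_step = int(round(record_from / dt))
    k = 0
    for st in range(n_steps):
        if st >= start_step and (st - start_step) % rec_stride == 0 and k < vrec.shape[0]:
            vrec[k] = S[0, SV_V]
            cairec[k] = S[0, SV_CAI]
            casrrec[k] = S[0, SV_CASR]
            k += 1
        tb = (st % steps_per_beat) * dt
        istim = amp if tb < dur else 0.0
        step_node_tab(S, P, 0, istim, dt, T, vmin, idv)
        if st % 50 == 0:
            v = S[0, SV_V]
            if not (-200.0 < v < 200.0):
                return 1, k, st
    return 0, k, n_steps


@njit(cache=True)
def run_cell_quiescent(S, P, dt, duration, T, vmin, idv):
    """Integrate one unstimulated cell; returns (status, min Vm, max Vm)."""
    n_steps = int(round(duration / dt))
    vlo = S[0, SV_V]
    vhi = S[0, SV_V]
    for st in range(n_steps):
        step_node_tab(S, P, 0, 0.0, dt, T, vmin, idv)
        v = S[0, SV_V]
        if not (-200.0 < v < 200.0):
            return 1, vlo, vhi
        if v < vlo:
            vlo = v
        if v > vhi:
            vhi = v
    return 0, vlo, vhi


@njit(cache=True)
def run_strand(S, P, D, dx, dt, n_steps,
               stim_start, stim_dur, stim_amp, stim_lo, stim_hi,
               rec_stride, vrec, T, vmin, idv):
    """Monodomain cable with operator splitting (reaction then diffusion).

    Heterogeneous D is handled in conservative flux form with harmonic-mean
    interface diffusivities; boundaries are no-flux.  ``vrec`` receives Vm
    snapshots every ``rec_stride`` steps.  Returns
    ``(status, bad_node, last_step, n_recorded)``.
    """
    n = S.shape[0]
    w = np.empty(n - 1)
    for i in range(n - 1):
        w[i] = 2.0 * D[i] * D[i + 1] / (D[i] + D[i + 1])
    vnew = np.empty(n)
    rdx2 = dt / (dx * dx)
    n_stim = stim_start.shape[0]
    k = 0
    for st in range(n_steps):
        t = st * dt
        if st % rec_stride == 0 and k < vrec.shape[0]:
            for i in range(n):
                vrec[k, i] = S[i, SV_V]
            k += 1
        for i in range(n):
            istim = 0.0
            for q in range(n_stim):
                if (stim_start[q] <= t < stim_start[q] + stim_dur[q]
                        and stim_lo[q] <= i < stim_hi[q]):
                    istim += stim_amp[q]
            step_node_tab(S, P, i, istim, dt, T, vmin, idv)
        for i in range(n):
            fl = w[i - 1] * (S[i - 1, SV_V] - S[i, SV_V]) if i > 0 else 0.0
            fr = w[i] * (S[i + 1, SV_V] - S[i, SV_V]) if i < n - 1 else 0.0
            vnew[i] = S[i, SV_V] + rdx2 * (fl + fr)
        for i in range(n):
            v = vnew[i]
            if not (-200.0 < v < 200.0):
                return 1, i, st, k
            S[i, SV_V] = v
    return 0, -1, n_steps, k


@njit(cache=True)
def run_sheet(S, P, D, mask, nx, ny, dx, dt, n_steps,
              stim_start, stim_dur, stim_amp, stim_x0, stim_x1, stim_y0, stim_y1,
              rec_stride, vrec, T, vmin, idv):
    """Monodomain sheet on a masked grid (row-major flattened, node = y*nx+x).

    5-point Laplacian, harmonic-mean interface D, no-flux at mask edges.
    Stimuli are rectangles in grid coordinates.  ``vrec`` is float32
    (n_samples, nx*ny).  Returns (status, bad_node, last_step, n_recorded).
    """
    n = nx * ny
    vnew = np.empty(n)
    rdx2 = dt / (dx * dx)
    n_stim = stim_start.shape[0]
    k = 0
    for st in range(n_steps):
        t = st * dt
        if st % rec_stride == 0 and k < vrec.shape[0]:
            for i in range(n):
                vrec[k, i] = S[i, SV_V]
            k += 1
        for y in range(ny):
            base = y * nx
            for x in range(nx):
                i = base + x
                if mask[i] == 0:
                    continue
                istim = 0.0
                for q in range(n_stim):
                    if (stim_start[q] <= t < stim_start[q] + stim_dur[q]
                            and stim_x0[q] <= x < stim_x1[q]
                            and stim_y0[q] <= y < stim_y1[q]):
                        istim += stim_amp[q]
                step_node_tab(S, P, i, istim, dt, T, vmin, idv)
        for y in range(ny):
            base = y * nx
            for x in range(nx):
                i = base + x
                if mask[i] == 0:
                    vnew[i] = S[i, SV_V]
                    continue
                v = S[i, SV_V]
                acc = 0.0
                if x > 0 and mask[i - 1] == 1:
                    acc += 2.0 * D[i] * D[i - 1] / (D[i] + D[i - 1]) * (S[i - 1, SV_V] - v)
                if x < nx - 1 and mask[i + 1] == 1:
                    acc += 2.0 * D[i] * D[i + 1] / (D[i] + D[i + 1]) * (S[i + 1, SV_V] - v)
                if y > 0 and mask[i - nx] == 1:
                    acc += 2.0 * D[i] * D[i - nx] / (D[i] + D[i - nx]) * (S[i - nx, SV_V] - v)
                if y < ny - 1 and mask[i + nx] == 1:
                    acc += 2.0 * D[i] * D[i + nx] / (D[i] + D[i + nx]) * (S[i + nx, SV_V] - v)
                vnew[i] = v + rdx2 * acc
        for i in range(n):
            if mask[i] == 0:
                continue
            v = vnew[i]
            if not (-200.0 < v < 200.0):
                return 1, i, st, k
            S[i, SV_V] = v
    return 0, -1, n_steps, k


@njit(cache=True)
def run_strand_store(S, P, D, dx, dt, n_steps,
                     stim_start, stim_dur, stim_amp, stim_lo, stim_hi,
                     snap_stride, snaps, T, vmin, idv):
    """Like :func:`run_strand` but stores full state snapshots.

    ``snaps`` has shape (n_snap, n_nodes, N_STATE); snapshot ``k`` holds the
    state at t = k * snap_stride * dt.  Used to restart S2 trials at an
    arbitrary coupling interval without re-integrating the S1 episode.
    Returns (status, bad_node, last_step, n_snapped).
    """
    n = S.shape[0]
    w = np.empty(n - 1)
    for i in range(n - 1):
        w[i] = 2.0 * D[i] * D[i + 1] / (D[i] + D[i + 1])
    vnew = np.empty(n)
    rdx2 = dt / (dx * dx)
    n_stim = stim_start.shape[0]
    k = 0
    for st in range(n_steps + 1):
        if st % snap_stride == 0 and k < snaps.shape[0]:
            for i in range(n):
                for q in range(N_STATE):
                    snaps[k, i, q] = S[i, q]
            k += 1
        if st == n_steps:
            break
        t = st * dt
        for i in range(n):
            istim = 0.0
            for q in range(n_stim):
                if (stim_start[q] <= t < stim_start[q] + stim_dur[q]
                        and stim_lo[q] <= i < stim_hi[q]):
                    istim += stim_amp[q]
            step_node_tab(S, P, i, istim, dt, T, vmin, idv)
        for i in range(n):
            fl = w[i - 1] * (S[i - 1, SV_V] - S[i, SV_V]) if i > 0 else 0.0
            fr = w[i] * (S[i + 1, SV_V] - S[i, SV_V]) if i < n - 1 else 0.0
            vnew[i] = S[i, SV_V] + rdx2 * (fl + fr)
        for i in range(n):
            v = vnew[i]
            if not (-200.0 < v < 200.0):
                return 1, i, st, k
            S[i, SV_V] = v
    return 0, -1, n_steps, k


@njit(cache=True)
def run_sheet_store(S, P, D, mask, nx, ny, dx, dt, n_steps,
                    stim_start, stim_dur, stim_amp, stim_x0, stim_x1,
                    stim_y0, stim_y1, snap_t0_step, snap_stride, snaps,
                    T, vmin, idv):
    """Like :func:`run_sheet` but stores full-state snapshots.

    Snapshot ``k`` holds the state at step ``snap_t0_step + k*snap_stride``.
    Returns (status, bad_node, last_step, n_snapped).
    """
    n = nx * ny
    vnew = np.empty(n)
    rdx2 = dt / (dx * dx)
    n_stim = stim_start.shape[0]
    k = 0
    for st in range(n_steps + 1):
        if (st >= snap_t0_step and (st - snap_t0_step) % snap_stride == 0
                and k < snaps.shape[0]):
            for i in range(n):
                for q in range(N_STATE):
                    snaps[k, i, q] = S[i, q]
            k += 1
        if st == n_steps:
            break
        t = st * dt
        for y in range(ny):
            base = y * nx
            for x in range(nx):
                i = base + x
                if mask[i] == 0:
                    continue
                istim = 0.0
                for q in range(n_stim):
                    if (stim_start[q] <= t < stim_start[q] + stim_dur[q]
                            and stim_x0[q] <= x < stim_x1[q]
                            and stim_y0[q] <= y < stim_y1[q]):
                        istim += stim_amp[q]
                step_node_tab(S, P, i, istim, dt, T, vmin, idv)
        for y in range(ny):
            base = y * nx
            for x in range(nx):
                i = base + x
                if mask[i] == 0:
                    vnew[i] = S[i, SV_V]
                    continue
                v = S[i, SV_V]
                acc = 0.0
                if x > 0 and mask[i - 1] == 1:
                    acc += 2.0 * D[i] * D[i - 1] / (D[i] + D[i - 1]) * (S[i - 1, SV_V] - v)
                if x < nx - 1 and mask[i + 1] == 1:
                    acc += 2.0 * D[i] * D[i + 1] / (D[i] + D[i + 1]) * (S[i + 1, SV_V] - v)
                if y > 0 and mask[i - nx] == 1:
                    acc += 2.0 * D[i] * D[i - nx] / (D[i] + D[i - nx]) * (S[i - nx, SV_V] - v)
                if y < ny - 1 and mask[i + nx] == 1:
                    acc += 2.0 * D[i] * D[i + nx] / (D[i] + D[i + nx]) * (S[i + nx, SV_V] - v)
                vnew[i] = v + rdx2 * acc
        for i in range(n):
            if mask[i] == 0:
                continue
            v = vnew[i]
            if not (-200.0 < v < 200.0):
                return 1, i, st, k
            S[i, SV_V] = v
    return 0, -1, n_steps, k
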