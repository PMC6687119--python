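"""Numba kernels shared by the 0D cell and 2D tissue simulators.

The ionic model is a hybrid-minimal action-potential model: a small set
of currents each corresponding to a physiological counterpart (I_Na,
I_CaL, I_Kr-like, I_Ks-like, I_K1, I_NCX, small backgrounds) coupled to a
five-compartment Ca2+ handling system (dyadic space DS, sub-space SS,
bulk cytosol, network and junctional SR).  Cell-type and condition
variants are expressed purely as per-cell parameter scalings.

Everything here operates on flat float64 arrays so that one jitted
stepper serves a single cell (n=1) and tissue sheets alike.  Per-cell RNG
streams use splitmix64/xorshift so draws are independent of iteration
order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- state layout ----------------------------------------------------------
IV, IM, IH, IJ, ID, IF, IXR, IXS = 0, 1, 2, 3, 4, 5, 6, 7
ICADS, ICASS, ICACYTO, ICANSR, ICAJSR = 8, 9, 10, 11, 12
IRYRO, IRYRI = 13, 14
NVAR = 15

# --- parameter layout ------------------------------------------------------
PG_NA, PG_CAL, PG_K1, PG_KR, PG_KS, PG_NCX = 0, 1, 2, 3, 4, 5
PG_UP, PG_LEAK, PG_RYR, PTAU_DS, PTAU_SS, PTAU_TR = 6, 7, 8, 9, 10, 11
PK_CAL, PK_NCX, PG_BNA, PNA_VSHIFT = 12, 13, 14, 15
PRYR_ACT, PRYR_CLOSE, PRYR_INACT, PRYR_RECOV = 16, 17, 18, 19
PK_DS, PK_JSR, PHILL, PFCA_K, PSARCO, PG_BCA = 20, 21, 22, 23, 24, 25
NPAR = 26

# --- physical constants ----------------------------------------------------
RTF = 26.71  # mV
E_NA = 70.5  # mV (Na_i 10 mM, Na_o 140 mM)
E_K = -86.9  # mV (K_i 140 mM, K_o 5.4 mM)
E_CAL = 60.0  # mV, ohmic approximation for the L-type current
NAI3 = 1000.0  # Na_i^3 (mM^3)
NAO3 = 2.744e6  # Na_o^3
CAO = 1.8  # mM
NCX_DENOM = (87.5**3 + NAO3) * (1.38 + CAO)

# --- compartment volumes (relative to cytosol) and buffering factors -------
V_DS, V_SS, V_CYTO, V_NSR, V_JSR = 2.0e-3, 0.02, 1.0, 0.05, 0.010
B_DS, B_SS, B_CYTO, B_JSR = 1.0, 0.1, 0.025, 0.06

# SRF parameter-mode codes for the controller
SRF_OFF, SRF_DIRECT, SRF_GENERAL, SRF_DYNFIT = 0, 1, 2, 3

# controller phases
PH_IDLE, PH_SET, PH_ACTIVE = 0, 1, 2

# controller state layout (per cell)
CPHASE, CPOSTAP, CEXCITED, CCASR_ARM, CT_ARM = 0, 1, 2, 3, 4
CT_I, CLAM, CT_P, CN_PEAK, CN_PLAT, CHAS_WAVE = 5, 6, 7, 8, 9, 10
CLAST_AP, CLAST_CICR, CCA_PEAK, CAP_CAND, CEVENT_COUNT = 11, 12, 13, 14, 15
NCTRL = 16

MORPH_THRESHOLD = 300.0
LAM_FLOOR = 10.0
WIDTH_SCALE = 0.261
RYR_RECOVERY_THRESHOLD = 0.2
CASR_RECALC = 0.01  # mM
PLATEAU_MIN_TP_OFFSET = 42.5  # 25 + 17.5 ms


# ---------------------------------------------------------------------------
# per-cell RNG: splitmix64 seeding + xorshift64* stream
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def seed_streams(base_seed, n):
    out = np.empty(n, dtype=np.uint64)
    s = np.uint64(base_seed)
    for i in range(n):
        out[i] = _splitmix64(s + np.uint64(i) * np.uint64(0x9E3779B97F4A7C15))
        if out[i] == np.uint64(0):
            out[i] = np.uint64(0xDEADBEEF)
    return out


@njit(cache=True, inline="always")
def _rng_next(states, i):
    s = states[i]
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    states[i] = s
    x = (s * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return float(x >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# ---------------------------------------------------------------------------
# SRF waveform / sampling scalar kernels (mirrors srfsim.waveform/sampling)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sig(x):
    if x > 40.0:
        return 1.0
    if x < -40.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def waveform_value(t, t_i, lam, t_p, n_peak, n_plateau):
    """Scalar SRF waveform evaluation; dispatches on duration."""
    t_f = t_i + lam
    if lam > MORPH_THRESHOLD:
        base = n_plateau * _sig((t - (t_i + 17.5)) / 5.946) * _sig(-(t - (t_f - 17.5)) / 5.946)
        spike = (n_peak - n_plateau) * _sig((t - (t_p - 25.0)) / 5.946) * _sig(-(t - (t_p + 17.5)) / 5.946)
        return base + spike
    k1 = 0.1689 * (t_p - t_i) + 0.00255
    k2 = 0.1689 * (t_f - t_p) + 0.00255
    if k1 < 0.5:
        k1 = 0.5
    if k2 < 0.5:
        k2 = 0.5
    t1 = t_i + 0.5 * (t_p - t_i)
    t2 = t_p + 0.5 * (t_f - t_p)
    return n_peak * _sig((t - t1) / k1) * _sig(-(t - t2) / k2)


@njit(cache=True)
def sample_srf_waveform(states, i, ti_sep, cf, k_f1, k_f2, md, dw1, dw2, out):
    """Draw (t_i, lam, t_p, n_peak, n_plateau) into out[0:5]; 5 uniforms."""
    u0 = _rng_next(states, i)
    u1 = _rng_next(states, i)
    u2 = _rng_next(states, i)
    u3 = _rng_next(states, i)
    u4 = _rng_next(states, i)
    if u0 < 1e-12:
        u0 = 1e-12
    if u0 > 1.0 - 1e-12:
        u0 = 1.0 - 1e-12
    if u0 < cf:
        t_i = ti_sep - k_f1 * np.log(2.0 * cf / u0 - 1.0)
    else:
        t_i = ti_sep - k_f2 * np.log(2.0 * (1.0 - cf) / (u0 + 1.0 - 2.0 * cf) - 1.0)
    if t_i < 0.0:
        t_i = 0.0
    if u1 < 1e-12:
        u1 = 1e-12
    if u1 > 1.0 - 1e-12:
        u1 = 1.0 - 1e-12
    term = np.log(1.0 / u1 - 1.0)
    if u1 < 0.5:
        lam = md - WIDTH_SCALE * dw1 * term
    else:
        lam = md - WIDTH_SCALE * dw2 * term
    if lam < LAM_FLOOR:
        lam = LAM_FLOOR
    window = lam - 25.0 - 52.0
    if window > 0.0:
        t_p = t_i + 25.0 + u2 * window
    else:
        t_p = t_i + 0.5 * lam
    exp_peak = 692.99 * lam ** (-1.6) + 0.059
    if exp_peak > 1.0:
        exp_peak = 1.0
    n_peak = exp_peak + 0.05 * (u3 - 0.5)
    if n_peak < 0.0:
        n_peak = 0.0
    if n_peak > 1.0:
        n_peak = 1.0
    n_plateau = 0.0
    if lam > MORPH_THRESHOLD:
        exp_plat = 31.09 * (0.01 * lam) ** (-7.39) + 0.034
        if exp_plat > 1.0:
            exp_plat = 1.0
        n_plateau = (1.0 + 0.25 * (u4 - 0.5)) * exp_plat
        if n_plateau > n_peak:
            n_plateau = n_peak
        if t_p < t_i + PLATEAU_MIN_TP_OFFSET:
            t_p = t_i + PLATEAU_MIN_TP_OFFSET
    out[0] = t_i
    out[1] = lam
    out[2] = t_p
    out[3] = n_peak
    out[4] = n_plateau


@njit(cache=True)
def general_dynamic_eval(casr, gd, out):
    """Evaluate General Dynamic params gd[0:12] -> out[0:8].

    gd: threshold, p_range, casr_max, ti_sep_min, ti_sep_max, ti_w_min,
    ti_w_max, md_min, md_max, lam_w_min, lam_w_max, h_width.
    out: p_scr, ti_sep, cf, k_f1, k_f2, md, dw1, dw2.
    """
    thr, prange, cmax = gd[0], gd[1], gd[2]
    mid = thr + 0.5 * prange
    k = prange / (2.0 * np.log(49.0))
    p_scr = _sig((casr - mid) / k)
    x = (casr - thr) / (cmax - thr)
    if x < 0.0:
        x = 0.0
    if x > 1.0:
        x = 1.0
    ti_sep = gd[4] - (gd[4] - gd[3]) * x
    md = gd[8] - (gd[8] - gd[7]) * x
    xw = x ** gd[11]
    ti_w = gd[6] - (gd[6] - gd[5]) * xw
    lam_w = gd[10] - (gd[10] - gd[9]) * xw
    out[0] = p_scr
    out[1] = ti_sep
    out[2] = 0.4
    out[3] = WIDTH_SCALE * ti_w
    out[4] = WIDTH_SCALE * ti_w
    out[5] = md
    out[6] = lam_w
    out[7] = lam_w


@njit(cache=True)
def dynamic_fit_eval(casr, dc, out):
    """Evaluate packed Dynamic Fit coefficients dc[0:30] -> out[0:8].

    Layout: [casr_lo, casr_hi,
             p_scr: mid, k,
             ti_sep: ymin, a, mid, k,  md: ymin, a, mid, k,
             k_f1: ymin, a, mid, k,    k_f2: ymin, a, mid, k,
             dw1: ymin, a, mid, k,     dw2: ymin, a, mid, k,
             cf]
    """
    c = casr
    if c < dc[0]:
        c = dc[0]
    if c > dc[1]:
        c = dc[1]
    out[0] = _sig((c - dc[2]) / dc[3])
    for n in range(6):  # ti_sep, md, k_f1, k_f2, dw1, dw2
        base = 4 + 4 * n
        v = dc[base] + dc[base + 1] * _sig(-(c - dc[base + 2]) / dc[base + 3])
        if v < 1.0:
            v = 1.0
        if n == 0:
            out[1] = v
        elif n == 1:
            out[5] = v if v > LAM_FLOOR else LAM_FLOOR
        elif n == 2:
            out[3] = v
        elif n == 3:
            out[4] = v
        elif n == 4:
            out[6] = v
        else:
            out[7] = v
    out[2] = dc[28]



# ---------------------------------------------------------------------------
# voltage lookup tables (gate steady states, Rush-Larsen factors, rectifiers)
# ---------------------------------------------------------------------------

TAB_V0 = -150.0
TAB_DV = 0.05
TAB_N = int((80.0 - TAB_V0) / TAB_DV) + 2

_TAB_CACHE = {}


def build_voltage_table(dt: float) -> np.ndarray:
    """Tabulate the voltage-dependent gate functions for one time step.

    Rows: m/h/j/d/f/xr/xs steady states and Rush-Larsen decay factors,
    then the I_K1 rectification factor, the I_Kr rectification gate and
    the two NCX exponentials.  Linear interpolation at lookup keeps the
    error far below the Euler discretisation error.
    """
    key = round(float(dt), 9)
    if key in _TAB_CACHE:
        return _TAB_CACHE[key]
    v = TAB_V0 + TAB_DV * np.arange(TAB_N)
    sig = lambda x: 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    m_inf = sig((v + 40.0) / 5.5)
    tau_m = 0.12 + 0.35 * np.exp(-(((v + 45.0) / 15.0) ** 2))
    h_inf = sig(-(v + 72.0) / 5.5)
    tau_h = 0.5 + 12.0 * sig(-(v + 35.0) / 8.0)
    j_inf = h_inf
    tau_j = 4.0 + 80.0 * sig(-(v + 35.0) / 8.0)
    d_inf = sig((v + 8.0) / 6.5)
    tau_d = 0.8 + 2.5 * np.exp(-(((v + 10.0) / 20.0) ** 2))
    f_inf = sig(-(v + 22.0) / 6.0)
    tau_f = 25.0 + 180.0 * sig(-(v - 10.0) / 15.0)
    xr_inf = sig((v + 15.0) / 7.0)
    tau_xr = 60.0 + 300.0 * np.exp(-(((v + 30.0) / 35.0) ** 2))
    xs_inf = sig(v / 11.0)
    tau_xs = np.full_like(v, 450.0)
    k1_rect = 1.0 / (1.0 + np.exp(np.clip(0.08 * (v + 80.0), -500, 500)))
    kr_rect = sig(-(v - 10.0) / 15.0)
    e1 = np.exp(0.35 * v / RTF)
    e2 = np.exp(-0.65 * v / RTF)
    tab = np.ascontiguousarray(np.stack([
        m_inf, np.exp(-dt / tau_m),
        h_inf, np.exp(-dt / tau_h),
        j_inf, np.exp(-dt / tau_j),
        d_inf, np.exp(-dt / tau_d),
        f_inf, np.exp(-dt / tau_f),
        xr_inf, np.exp(-dt / tau_xr),
        xs_inf, np.exp(-dt / tau_xs),
        k1_rect, kr_rect, e1, e2,
    ]))
    _TAB_CACHE[key] = tab
    return tab


@njit(cache=True, inline="always")
def _lut(tab, row, v):
    x = (v - TAB_V0) * (1.0 / TAB_DV)
    if x < 0.0:
        x = 0.0
    elif x > TAB_N - 2:
        x = TAB_N - 2
    i0 = int(x)
    fr = x - i0
    return tab[row, i0] * (1.0 - fr) + tab[row, i0 + 1] * fr


# ---------------------------------------------------------------------------
# ionic model: one forward-Euler / Rush-Larsen step for all cells
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def step_cells(S, P, dt, t, istim, diff, override, tab):
    """Advance every cell by dt.

    S : (n, NVAR) state; P : (n, NPAR) parameters; istim : (n,) stimulus
    (pA/pF, depolarising positive); diff : (n,) voltage diffusion term
    (mV/ms, zero for isolated cells); override : (n,) SRF open-RyR
    override (< 0 means inactive, otherwise replaces the gated value);
    tab : voltage lookup table from build_voltage_table(dt).
    """
    n = S.shape[0]
    for i in range(n):
        v = S[i, IV]
        sarco = P[i, PSARCO]

        # --- gates (Rush-Larsen, tabulated rates) ---
        # the Na-channelopathy shift applies to the inactivation steady
        # state only (shifted lookup voltage for h_inf/j_inf)
        vsh = P[i, PNA_VSHIFT]
        S[i, IM] = _lut(tab, 0, v) + (S[i, IM] - _lut(tab, 0, v)) * _lut(tab, 1, v)
        h_inf = _lut(tab, 2, v + vsh)
        S[i, IH] = h_inf + (S[i, IH] - h_inf) * _lut(tab, 3, v)
        j_inf = _lut(tab, 4, v + vsh)
        S[i, IJ] = j_inf + (S[i, IJ] - j_inf) * _lut(tab, 5, v)
        S[i, ID] = _lut(tab, 6, v) + (S[i, ID] - _lut(tab, 6, v)) * _lut(tab, 7, v)
        S[i, IF] = _lut(tab, 8, v) + (S[i, IF] - _lut(tab, 8, v)) * _lut(tab, 9, v)
        S[i, IXR] = _lut(tab, 10, v) + (S[i, IXR] - _lut(tab, 10, v)) * _lut(tab, 11, v)
        S[i, IXS] = _lut(tab, 12, v) + (S[i, IXS] - _lut(tab, 12, v)) * _lut(tab, 13, v)

        ca_ds = S[i, ICADS]
        ca_ss = S[i, ICASS]
        ca_cyto = S[i, ICACYTO]
        ca_nsr = S[i, ICANSR]
        ca_jsr = S[i, ICAJSR]

        # --- RyR gating (deterministic whole-cell scheme) ---
        o = S[i, IRYRO]
        inact = S[i, IRYRI]
        hill = P[i, PHILL]
        act_ca = ca_ds ** hill / (ca_ds ** hill + P[i, PK_DS] ** hill)
        load = ca_jsr * ca_jsr / (ca_jsr * ca_jsr + P[i, PK_JSR] * P[i, PK_JSR])
        k_open = P[i, PRYR_ACT] * act_ca * load
        k_inact = P[i, PRYR_INACT] * act_ca
        # recovery is suppressed while dyadic Ca is elevated, so release
        # terminates instead of latching into a persistent leak state
        xr2 = (ca_ds / 5.0) ** 2
        k_recov = P[i, PRYR_RECOV] / (1.0 + xr2)
        do = k_open * (1.0 - o - inact) - P[i, PRYR_CLOSE] * o
        di = k_inact * o - k_recov * inact
        o += dt * do
        inact += dt * di
        if o < 0.0:
            o = 0.0
        if inact < 0.0:
            inact = 0.0
        if o + inact > 1.0:
            s = o + inact
            o /= s
            inact /= s
        S[i, IRYRO] = o
        S[i, IRYRI] = inact

        n_ryr_o = o
        if override[i] >= 0.0:
            n_ryr_o = override[i]

        # --- currents (pA/pF) ---
        i_na = P[i, PG_NA] * S[i, IM] ** 3 * S[i, IH] * S[i, IJ] * (v - E_NA)
        xca = ca_ss / P[i, PFCA_K]
        fca = 1.0 / (1.0 + xca * xca)
        i_cal = P[i, PG_CAL] * S[i, ID] * S[i, IF] * fca * (v - E_CAL)
        i_k1 = P[i, PG_K1] * (v - E_K) * _lut(tab, 14, v)
        i_kr = P[i, PG_KR] * S[i, IXR] * _lut(tab, 15, v) * (v - E_K)
        i_ks = P[i, PG_KS] * S[i, IXS] * S[i, IXS] * (v - E_K)
        e1 = _lut(tab, 16, v)
        e2 = _lut(tab, 17, v)
        ncx_num = e1 * NAI3 * CAO - e2 * NAO3 * (ca_cyto * 1.0e-3)
        i_ncx = P[i, PG_NCX] * ncx_num / (NCX_DENOM * (1.0 + 0.1 * e2))
        i_bna = P[i, PG_BNA] * (v - E_NA)
        i_bca = P[i, PG_BCA] * (v - E_CAL)

        i_ion = (i_na + i_k1 + i_kr + i_ks + i_bna) + sarco * (i_cal + i_ncx + i_bca)
        S[i, IV] = v + dt * (-(i_ion) + istim[i] + diff[i])

        # --- Ca fluxes ---
        j_rel = n_ryr_o * P[i, PG_RYR] * (ca_jsr * 1000.0 - ca_ds)
        j_cal = sarco * (-i_cal) * P[i, PK_CAL]           # into DS (uM/ms, DS volume)
        j_ncx = sarco * i_ncx * P[i, PK_NCX]              # into cytosol; forward mode is efflux
        j_bca = sarco * (-i_bca) * P[i, PK_NCX]           # background Ca influx into cytosol
        j_ds_ss = (ca_ds - ca_ss) / P[i, PTAU_DS]
        j_ss_cyto = (ca_ss - ca_cyto) / P[i, PTAU_SS]
        j_up = P[i, PG_UP] * ca_cyto * ca_cyto / (ca_cyto * ca_cyto + 0.25 * 0.25)
        j_leak = P[i, PG_LEAK] * (ca_nsr * 1000.0 - ca_cyto)
        j_tr = (ca_nsr - ca_jsr) / P[i, PTAU_TR]          # mM/ms in JSR volume

        ca_ds += dt * B_DS * (j_rel + j_cal - j_ds_ss)
        ca_ss += dt * B_SS * (j_ds_ss * (V_DS / V_SS) - j_ss_cyto)
        ca_cyto += dt * B_CYTO * (j_ss_cyto * (V_SS / V_CYTO) - j_up + j_leak + j_ncx + j_bca)
        ca_nsr += dt * ((j_up - j_leak) * (V_CYTO / V_NSR) * 1.0e-3 - j_tr * (V_JSR / V_NSR))
        ca_jsr += dt * B_JSR * (j_tr - j_rel * (V_DS / V_JSR) * 1.0e-3)

        if ca_ds < 1.0e-6:
            ca_ds = 1.0e-6
        if ca_ss < 1.0e-6:
            ca_ss = 1.0e-6
        if ca_cyto < 1.0e-6:
            ca_cyto = 1.0e-6
        if ca_nsr < 1.0e-6:
            ca_nsr = 1.0e-6
        if ca_jsr < 1.0e-6:
            ca_jsr = 1.0e-6
        S[i, ICADS] = ca_ds
        S[i, ICASS] = ca_ss
        S[i, ICACYTO] = ca_cyto
        S[i, ICANSR] = ca_nsr
        S[i, ICAJSR] = ca_jsr


@njit(cache=True)
def total_calcium(S):
    """Buffer/volume-weighted total Ca2+ per cell (uM, cytosol-volume units)."""
    n = S.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = (
            V_DS * S[i, ICADS] / B_DS
            + V_SS * S[i, ICASS] / B_SS
            + V_CYTO * S[i, ICACYTO] / B_CYTO
            + 1000.0 * V_NSR * S[i, ICANSR]
            + 1000.0 * V_JSR * S[i, ICAJSR] / B_JSR
        )
    return out


# ---------------------------------------------------------------------------
# SRF controller
# ---------------------------------------------------------------------------

@njit(cache=True)
def controller_update(C, S, rng_states, t, mode, variant, direct_params, gd_params,
                      df_params, override, cicr_ca_threshold):
    """Advance every cell's SRF controller to time t (called per macro step).

    C : (n, NCTRL) controller state.  ``variant[i]`` indexes the rows of
    the per-variant parameter tables.  ``direct_params`` is (nv, 8)
    [p_scr, ti_sep, cf, k_f1, k_f2, md, dw1, dw2]; ``gd_params`` (nv, 12)
    General Dynamic parameters; ``df_params`` (nv, 29) packed Dynamic Fit
    coefficients.  Writes the open-RyR override (>= 0 when active) and
    maintains AP/CICR bookkeeping used by the analysis layer.
    """
    n = C.shape[0]
    buf = np.empty(8)
    wf = np.empty(5)
    for i in range(n):
        v = S[i, IV]
        # --- AP detection and CICR bookkeeping ---
        if C[i, CEXCITED] == 0.0:
            if v > -20.0:
                C[i, CEXCITED] = 1.0
                C[i, CLAST_AP] = t
                C[i, CAP_CAND] = t
                C[i, CCA_PEAK] = 0.0
        else:
            if S[i, ICACYTO] > C[i, CCA_PEAK]:
                C[i, CCA_PEAK] = S[i, ICACYTO]
            if v < -60.0:
                C[i, CEXCITED] = 0.0
                C[i, CPOSTAP] = 1.0
                if C[i, CCA_PEAK] > cicr_ca_threshold:
                    C[i, CLAST_CICR] = C[i, CAP_CAND]
                # Direct Control (re)samples on every cellular excitation:
                # discard any pending event scheduled past this excitation.
                if mode == SRF_DIRECT and C[i, CPHASE] != PH_ACTIVE:
                    C[i, CPHASE] = PH_IDLE
                    C[i, CHAS_WAVE] = 0.0

        override[i] = -1.0
        if mode == SRF_OFF:
            continue

        vi = variant[i]
        casr = S[i, ICANSR]
        phase = int(C[i, CPHASE])

        if phase == PH_ACTIVE:
            if t > C[i, CT_ARM] + C[i, CT_I] + C[i, CLAM]:
                C[i, CPHASE] = PH_IDLE
                C[i, CHAS_WAVE] = 0.0
                C[i, CPOSTAP] = 0.0
            else:
                override[i] = waveform_value(
                    t - C[i, CT_ARM], C[i, CT_I], C[i, CLAM], C[i, CT_P],
                    C[i, CN_PEAK], C[i, CN_PLAT],
                )
            continue

        # parameters are never (re)set during excitation / low RyR availability
        recovered = S[i, IRYRI] < RYR_RECOVERY_THRESHOLD and C[i, CEXCITED] == 0.0

        if phase == PH_IDLE:
            # Direct Control references the time of cellular excitation and
            # needs no recovery gate; the dynamic modes arm on RyR recovery
            if mode == SRF_DIRECT:
                ready = C[i, CPOSTAP] == 1.0
            else:
                ready = C[i, CPOSTAP] == 1.0 and recovered
            if ready:
                # arm: evaluate distribution at current SR-Ca2+ and draw
                if mode == SRF_DIRECT:
                    for q in range(8):
                        buf[q] = direct_params[vi, q]
                elif mode == SRF_GENERAL:
                    general_dynamic_eval(casr, gd_params[vi], buf)
                else:
                    dynamic_fit_eval(casr, df_params[vi], buf)
                C[i, CCASR_ARM] = casr
                C[i, CT_ARM] = C[i, CLAST_AP] if mode == SRF_DIRECT else t
                C[i, CPHASE] = PH_SET
                u = _rng_next(rng_states, i)
                if u < buf[0]:
                    sample_srf_waveform(rng_states, i, buf[1], buf[2], buf[3],
                                        buf[4], buf[5], buf[6], buf[7], wf)
                    C[i, CT_I] = wf[0]
                    C[i, CLAM] = wf[1]
                    C[i, CT_P] = wf[2]
                    C[i, CN_PEAK] = wf[3]
                    C[i, CN_PLAT] = wf[4]
                    C[i, CHAS_WAVE] = 1.0
                else:
                    C[i, CHAS_WAVE] = 0.0
            continue

        # phase == PH_SET: waiting for initiation (or for nothing, if no
        # event was drawn -- SR-Ca2+ drift can still re-trigger a draw)
        if mode != SRF_DIRECT and abs(casr - C[i, CCASR_ARM]) > CASR_RECALC and recovered:
            if mode == SRF_GENERAL:
                general_dynamic_eval(casr, gd_params[vi], buf)
            else:
                dynamic_fit_eval(casr, df_params[vi], buf)
            C[i, CCASR_ARM] = casr
            C[i, CT_ARM] = t
            u = _rng_next(rng_states, i)
            if u < buf[0]:
                sample_srf_waveform(rng_states, i, buf[1], buf[2], buf[3],
                                    buf[4], buf[5], buf[6], buf[7], wf)
                C[i, CT_I] = wf[0]
                C[i, CLAM] = wf[1]
                C[i, CT_P] = wf[2]
                C[i, CN_PEAK] = wf[3]
                C[i, CN_PLAT] = wf[4]
                C[i, CHAS_WAVE] = 1.0
            else:
                C[i, CHAS_WAVE] = 0.0
        if C[i, CHAS_WAVE] == 1.0 and t >= C[i, CT_ARM] + C[i, CT_I]:
            C[i, CPHASE] = PH_ACTIVE
            C[i, CEVENT_COUNT] += 1.0
            override[i] = waveform_value(
                t - C[i, CT_ARM], C[i, CT_I], C[i, CLAM], C[i, CT_P],
                C[i, CN_PEAK], C[i, CN_PLAT],
            )


# ---------------------------------------------------------------------------
# tissue diffusion (isotropic 5-point Laplacian, no-flux boundaries)
# ---------------------------------------------------------------------------

@njit(cache=True)
def laplacian_vm(S, nx, ny, d_map, inv_dx2, out):
    """diff[i] = div(D grad Vm), heterogeneous D via face averaging."""
    for y in range(ny):
        for x in range(nx):
            i = y * nx + x
            vi = S[i, IV]
            di = d_map[i]
            acc = 0.0
            if x > 0:
                j = i - 1
                acc += 0.5 * (di + d_map[j]) * (S[j, IV] - vi)
            if x < nx - 1:
                j = i + 1
                acc += 0.5 * (di + d_map[j]) * (S[j, IV] - vi)
            if y > 0:
                j = i - nx
                acc += 0.5 * (di + d_map[j]) * (S[j, IV] - vi)
            if y < ny - 1:
                j = i + nx
                acc += 0.5 * (di + d_map[j]) * (S[j, IV] - vi)
            out[i] = acc * inv_dx2
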