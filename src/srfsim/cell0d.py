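"""Non-spatial (0D) cardiac cell model with SRF injection.

A hybrid-minimal action-potential model -- I_Na, I_CaL, rapid and slow
delayed-rectifier-like currents, I_K1, NCX and small backgrounds --
coupled to five-compartment Ca2+ handling (dyadic space, sub-space,
cytosol, network/junctional SR) and a deterministic whole-cell RyR gating
scheme for paced Ca2+-induced Ca2+ release.  Spontaneous release is
injected by the SRF controller: while a sampled waveform is active the
whole-cell open-RyR fraction is overridden by its analytical value,
driving the release flux and hence NCX-mediated depolarisation (DADs and
triggered action potentials).

Cell types (atrial, three transmural ventricular) and pro-arrhythmic
conditions (ISO, R_SERCA/NCX) are parameter scalings of the same model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from .sampling import (
    DynamicFitCoefficients,
    GeneralDynamicParams,
    SRFDistribution,
    normalise_condition,
)

__all__ = [
    "CellParams",
    "CellModel",
    "whole_cell_jrel",
    "run_pacing_protocol",
    "classify_dad_ta",
    "pack_direct",
    "pack_general",
    "pack_dynfit",
]

CELL_TYPES = ("atrial", "vent_endo", "vent_m", "vent_epi")

# cell-type scalings of the repolarising currents (relative to vent_endo)
_CELL_TYPE_SCALES = {
    "vent_endo": {},
    "vent_m": {"g_kr": 0.6, "g_ks": 0.4},
    "vent_epi": {"g_kr": 1.2, "g_ks": 1.3},
    "atrial": {"g_kr": 1.8, "g_k1": 0.85},
}

# condition multipliers (declared defaults; see docs/methods.md)
_CONDITION_SCALES = {
    "iso": {"g_up": 1.75, "g_cal": 1.5},
    "r_serca_ncx": {"g_up": 1.5, "g_ncx": 0.5, "g_k1": 0.7},
    # R_CRU-CRU acts through the SRF parameterisation in the 0D model
    "r_cru_cru": {},
}


@dataclass
class CellParams:
    """Hybrid-minimal model parameters (conductances in pA/pF per mV)."""

    cell_type: str = "vent_epi"
    g_na: float = 9.0
    g_cal: float = 0.175
    g_k1: float = 0.42
    g_kr: float = 0.08
    g_ks: float = 0.04
    g_ncx: float = 2200.0
    g_up: float = 0.40       # uM/ms max SERCA rate
    g_leak: float = 6.0e-5
    g_ryr: float = 3.0
    tau_ds: float = 0.1      # ms, DS <-> SS coupling
    tau_ss: float = 0.8      # ms, SS <-> cytosol coupling
    tau_tr: float = 30.0     # ms, NSR <-> JSR transfer
    k_cal: float = 100.0      # DS Ca flux per unit I_CaL
    k_ncx: float = 0.02      # SS Ca flux per unit I_NCX
    g_bna: float = 0.005
    g_bca: float = 2.0e-4
    ina_vshift: float = 0.0  # +5 mV with the Na channelopathy
    k_ryr_act: float = 1.0
    k_ryr_close: float = 0.15
    k_ryr_inact: float = 0.06
    k_ryr_recov: float = 0.004
    k_ds: float = 20.0       # uM, RyR Ca_ds half-activation
    k_jsr: float = 0.8       # mM, JSR load sensitivity
    hill_ryr: float = 6.0
    fca_k: float = 1.5       # uM, I_CaL Ca-dependent inactivation
    sarco_scale: float = 1.0  # 0 closes all sarcolemmal Ca fluxes
    iso: bool = False
    r_serca_ncx: bool = False
    r_cru_cru: bool = False
    na_channelopathy: bool = False

    def resolved(self) -> "CellParams":
        """Apply cell-type and condition scalings; returns a new instance."""
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        p = replace(self)
        scales: dict[str, float] = {}

        def mul(d):
            for k, v in d.items():
                scales[k] = scales.get(k, 1.0) * v

        mul(_CELL_TYPE_SCALES[self.cell_type])
        if self.iso:
            mul(_CONDITION_SCALES["iso"])
        if self.r_serca_ncx:
            mul(_CONDITION_SCALES["r_serca_ncx"])
        for k, v in scales.items():
            setattr(p, k, getattr(p, k) * v)
        if self.na_channelopathy:
            p.g_na *= 0.30
            p.ina_vshift = 5.0
        return p

    def to_array(self) -> np.ndarray:
        p = self.resolved()
        a = np.zeros(K.NPAR)
        a[K.PG_NA] = p.g_na
        a[K.PG_CAL] = p.g_cal
        a[K.PG_K1] = p.g_k1
        a[K.PG_KR] = p.g_kr
        a[K.PG_KS] = p.g_ks
        a[K.PG_NCX] = p.g_ncx
        a[K.PG_UP] = p.g_up
        a[K.PG_LEAK] = p.g_leak
        a[K.PG_RYR] = p.g_ryr
        a[K.PTAU_DS] = p.tau_ds
        a[K.PTAU_SS] = p.tau_ss
        a[K.PTAU_TR] = p.tau_tr
        a[K.PK_CAL] = p.k_cal
        a[K.PK_NCX] = p.k_ncx
        a[K.PG_BNA] = p.g_bna
        a[K.PNA_VSHIFT] = p.ina_vshift
        a[K.PRYR_ACT] = p.k_ryr_act
        a[K.PRYR_CLOSE] = p.k_ryr_close
        a[K.PRYR_INACT] = p.k_ryr_inact
        a[K.PRYR_RECOV] = p.k_ryr_recov
        a[K.PK_DS] = p.k_ds
        a[K.PK_JSR] = p.k_jsr
        a[K.PHILL] = p.hill_ryr
        a[K.PFCA_K] = p.fca_k
        a[K.PSARCO] = p.sarco_scale
        a[K.PG_BCA] = p.g_bca
        return a


def initial_state() -> np.ndarray:
    """Approximate resting state (settled further by pre-pacing)."""
    s = np.zeros(K.NVAR)
    s[K.IV] = -80.0
    s[K.IH] = 0.8
    s[K.IJ] = 0.8
    s[K.IF] = 1.0
    s[K.ICADS] = 0.12
    s[K.ICASS] = 0.12
    s[K.ICACYTO] = 0.12
    s[K.ICANSR] = 0.85
    s[K.ICAJSR] = 0.85
    return s


def whole_cell_jrel(n_ryr_o: float, g_ryr: float, ca_jsr_mM: float, ca_ds_uM: float) -> float:
    """Whole-cell release flux (uM/ms, DS volume): open fraction times
    maximal flux times the JSR-to-DS gradient (JSR converted to uM)."""
    return n_ryr_o * g_ryr * (ca_jsr_mM * 1000.0 - ca_ds_uM)


# ---------------------------------------------------------------------------
# SRF parameter packing for the jitted controller
# ---------------------------------------------------------------------------

def pack_direct(dists: "list[SRFDistribution] | SRFDistribution") -> np.ndarray:
    if isinstance(dists, SRFDistribution):
        dists = [dists]
    out = np.zeros((len(dists), 8))
    for i, d in enumerate(dists):
        out[i] = [d.p_scr, d.ti_sep, d.cf_ti_sep, d.k_f1, d.k_f2, d.md, d.dw1, d.dw2]
    return out


def pack_general(params: "list[GeneralDynamicParams] | GeneralDynamicParams") -> np.ndarray:
    if isinstance(params, GeneralDynamicParams):
        params = [params]
    out = np.zeros((len(params), 12))
    for i, p in enumerate(params):
        out[i] = [
            p.casr_threshold, p.casr_p_range, p.casr_max,
            p.ti_sep_min, p.ti_sep_max, p.ti_width_min, p.ti_width_max,
            p.md_min, p.md_max, p.lam_width_min, p.lam_width_max, p.h_width,
        ]
    return out


def pack_dynfit(coeffs: DynamicFitCoefficients, condition: str = "control") -> np.ndarray:
    """Pack one condition's Dynamic Fit curves for the jitted controller."""
    cond = normalise_condition(condition)
    table = coeffs.tables[cond]
    lo, hi = coeffs.casr_range[cond]
    out = np.zeros((1, 29))
    out[0, 0], out[0, 1] = lo, hi
    fam, c = table["p_scr"]
    out[0, 2], out[0, 3] = c[0], max(c[1], 1e-9)
    for n, name in enumerate(("ti_sep", "md", "k_f1", "k_f2", "dw1", "dw2")):
        fam, c = table[name]
        base = 4 + 4 * n
        if fam == "sigmoid_dec":
            out[0, base: base + 4] = [c[0], c[1], c[2], max(c[3], 1e-9)]
        elif fam == "constant":
            out[0, base: base + 4] = [c[0], 0.0, 0.0, 1.0]
        else:
            raise KeyError(f"cannot pack family {fam!r} for {name}")
    fam, c = table["cf_ti_sep"]
    out[0, 28] = c[0] if fam == "constant" else 0.4
    return out


_SRF_MODES = {"off": K.SRF_OFF, "direct": K.SRF_DIRECT,
              "general": K.SRF_GENERAL, "dynamic-fit": K.SRF_DYNFIT}

_EMPTY_DIRECT = np.zeros((1, 8))
_EMPTY_GD = np.ones((1, 12))
_EMPTY_DF = np.ones((1, 29))


class CellModel:
    """A single 0D cell (thin wrapper over the shared array kernels)."""

    def __init__(
        self,
        params: CellParams | None = None,
        srf_mode: str = "off",
        srf_params=None,
        dynfit_condition: str = "control",
        seed: int = 0,
        dt: float = 0.02,
        cicr_ca_threshold: float = 0.35,
    ):
        self.params = params or CellParams()
        if srf_mode not in _SRF_MODES:
            raise ValueError(f"srf_mode must be one of {sorted(_SRF_MODES)}")
        self.srf_mode = srf_mode
        self.dt = float(dt)
        if self.dt > 0.02:
            raise ValueError("dt must be <= 0.02 ms for Vm stability")
        self.cicr_ca_threshold = cicr_ca_threshold
        self.S = initial_state()[None, :].copy()
        self.P = self.params.to_array()[None, :].copy()
        self.C = np.zeros((1, K.NCTRL))
        self.rng_states = K.seed_streams(seed, 1)
        self.t = 0.0
        self._direct = _EMPTY_DIRECT
        self._gd = _EMPTY_GD
        self._df = _EMPTY_DF
        if srf_mode == "direct":
            self._direct = pack_direct(srf_params)
        elif srf_mode == "general":
            self._gd = pack_general(srf_params)
        elif srf_mode == "dynamic-fit":
            self._df = pack_dynfit(srf_params, dynfit_condition)
        self._mode_code = _SRF_MODES[srf_mode]
        self._variant = np.zeros(1, dtype=np.int64)
        self._override = np.full(1, -1.0)
        self._diff = np.zeros(1)
        self._stim = np.zeros(1)

    def run(
        self,
        duration: float,
        stim_times=(),
        stim_amplitude: float = 40.0,
        stim_duration: float = 2.0,
        record_dt: float = 1.0,
        record_states: bool = False,
    ) -> dict:
        """Advance the cell, returning recorded traces.

        ``stim_times`` are onset times (ms, relative to the current model
        time) of square stimulus pulses.
        """
        n_macro = int(round(duration / record_dt))
        sub = max(int(round(record_dt / self.dt)), 1)
        dt = record_dt / sub
        tab = K.build_voltage_table(dt)
        stim_times = np.sort(np.asarray(list(stim_times), dtype=float)) + self.t
        rec = {k: np.empty(n_macro) for k in
               ("t", "vm", "ca_cyto", "ca_nsr", "ca_jsr", "n_ryr_o", "ryr_inact")}
        if record_states:
            rec["states"] = np.empty((n_macro, K.NVAR))
        for step in range(n_macro):
            K.controller_update(self.C, self.S, self.rng_states, self.t,
                                self._mode_code, self._variant, self._direct,
                                self._gd, self._df, self._override,
                                self.cicr_ca_threshold)
            for _ in range(sub):
                idx = np.searchsorted(stim_times, self.t + 1e-9) - 1
                on = idx >= 0 and (self.t - stim_times[idx]) < stim_duration
                self._stim[0] = stim_amplitude if on else 0.0
                K.step_cells(self.S, self.P, dt, self.t, self._stim,
                             self._diff, self._override, tab)
                self.t += dt
            if not np.isfinite(self.S[0, K.IV]):
                raise FloatingPointError(
                    f"membrane potential diverged at t={self.t:.2f} ms; "
                    f"state={self.S[0]}"
                )
            rec["t"][step] = self.t
            rec["vm"][step] = self.S[0, K.IV]
            rec["ca_cyto"][step] = self.S[0, K.ICACYTO]
            rec["ca_nsr"][step] = self.S[0, K.ICANSR]
            rec["ca_jsr"][step] = self.S[0, K.ICAJSR]
            n_o = self._override[0] if self._override[0] >= 0 else self.S[0, K.IRYRO]
            rec["n_ryr_o"][step] = n_o
            rec["ryr_inact"][step] = self.S[0, K.IRYRI]
            if record_states:
                rec["states"][step] = self.S[0]
        return rec

    def total_calcium(self) -> float:
        return float(K.total_calcium(self.S)[0])

    def set_casr(self, casr: float) -> None:
        self.S[0, K.ICANSR] = casr
        self.S[0, K.ICAJSR] = casr


def classify_dad_ta(
    t: np.ndarray,
    vm: np.ndarray,
    window: "tuple[float, float]",
    ta_vm_threshold: float = -20.0,
    ta_dvdt_threshold: float = 5.0,
    dad_amplitude: float = 2.0,
) -> str:
    """Classify diastolic activity within a quiescent window.

    TA: Vm crosses -20 mV with dV/dt exceeding 5 V/s (a regenerative
    upstroke); DAD: a depolarisation of >= 2 mV above the
    post-repolarisation baseline without TA; otherwise none.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    lo, hi = window
    if hi - lo < 50.0:
        raise ValueError("quiescent window must be >= 50 ms")
    m = (t >= lo) & (t <= hi)
    if m.sum() < 3:
        raise ValueError("window not covered by the trace")
    tw, vw = t[m], vm[m]
    dvdt = np.gradient(vw, tw)  # mV/ms == V/s
    crossed = vw >= ta_vm_threshold
    if np.any(crossed) and np.max(dvdt) > ta_dvdt_threshold:
        return "TA"
    baseline = np.percentile(vw, 10)
    if np.max(vw) - baseline >= dad_amplitude:
        return "DAD"
    return "none"


def run_pacing_protocol(
    params: CellParams,
    bcl: float,
    n_beats: int = 5,
    quiescent: float = 2000.0,
    n_trials: int = 1,
    seed: int = 0,
    srf_mode: str = "off",
    srf_params=None,
    dynfit_condition: str = "control",
    n_prepace: int = 40,
    dt: float = 0.02,
) -> list[dict]:
    """Rapid-pacing / quiescent protocol.

    Pre-paces one SRF-off cell to a limit cycle at the given basic cycle
    length, caches the end-diastolic state, then runs ``n_trials``
    independent trials of ``n_beats`` paced beats followed by a quiescent
    window.  Each trial returns traces, the diastolic classification and
    SCRE event bookkeeping.
    """
    pre = CellModel(params, srf_mode="off", seed=seed, dt=dt)
    last = pre.S.copy()
    period2 = False
    for b in range(n_prepace):
        pre.run(bcl, stim_times=[2.0])
        if b == n_prepace - 2:
            last = pre.S.copy()
    if abs(pre.S[0, K.ICANSR] - last[0, K.ICANSR]) > 0.01:
        period2 = True
        import warnings

        warnings.warn(
            f"pre-pacing not converged at BCL={bcl} ms "
            f"(possible period-2 alternans)", stacklevel=2,
        )
    cached = pre.S.copy()

    trials = []
    pace_span = n_beats * bcl
    for trial in range(n_trials):
        cell = CellModel(params, srf_mode=srf_mode, srf_params=srf_params,
                         dynfit_condition=dynfit_condition,
                         seed=seed + 1000 + trial, dt=dt)
        cell.S[:] = cached
        rec = cell.run(pace_span + quiescent,
                       stim_times=[2.0 + b * bcl for b in range(n_beats)])
        window = (pace_span + 50.0, pace_span + quiescent)
        cls = classify_dad_ta(rec["t"], rec["vm"], window)
        trials.append({
            "trial": trial,
            "traces": rec,
            "classification": cls,
            "n_events": int(cell.C[0, K.CEVENT_COUNT]),
            "event_t_i": (float(cell.C[0, K.CT_ARM] + cell.C[0, K.CT_I])
                          if cell.C[0, K.CEVENT_COUNT] > 0 else None),
            "period2_warning": period2,
            "end_diastolic_casr": float(cached[0, K.ICANSR]),
        })
    return trials
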