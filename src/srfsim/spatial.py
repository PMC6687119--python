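"""Reduced stochastic 3D calcium-release-unit (CRU) cell model.

A 3D grid of CRUs, each holding a restricted dyadic space with ~100 RyR
channels (3-state Markov chains: closed / open / inactivated, simulated
by per-CRU counting with binomial transition draws) and ~10 L-type
channels, its own sub-space, cytosolic, network-SR and junctional-SR
compartments.  Sub-space, cytosolic and network-SR Ca2+ diffuse between
6-neighbour CRUs; spontaneous single-channel openings trigger sparks
which may recruit neighbours into propagating whole-cell Ca2+ waves when
the SR is sufficiently loaded.  The whole-cell open-RyR fraction
``N_RyR_O`` -- the variable the SRF approximates -- is the mean open
fraction over all CRUs.

The model is a functional stand-in with documented contracts (SR-load
threshold for whole-cell events; latency and duration falling with load;
lower threshold when inter-CRU coupling is tightened), not a re-derivation
of any particular published rate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .cell0d import CellParams

__all__ = [
    "SpatialParams",
    "SpatialCell",
    "ClampProtocol",
    "run_ca_clamp_ladder",
    "generate_scre_ensemble",
    "DETECT_ON",
    "DETECT_OFF",
]

DETECT_ON = 0.02   # whole-cell open fraction starting an SCRE
DETECT_OFF = 0.005  # ... ending it (after 50 ms below)

# compartment volume ratios and buffering, per CRU (cytosol = 1)
V_DS, V_SS, V_CYTO, V_NSR, V_JSR = 2.0e-3, 0.02, 1.0, 0.05, 0.010
B_SS, B_CYTO, B_JSR = 0.1, 0.025, 0.06


@dataclass
class SpatialParams:
    """Grid geometry, channel counts, rates and coupling time constants."""

    dims: tuple = (15, 10, 10)
    n_ryr: int = 100
    n_ltcc: int = 10
    g_ryr: float = 0.06      # per-channel release flux factor (uM/ms per uM)
    r_spont: float = 4.0e-7  # /ms per closed channel at full SR load
    r_max: float = 2.0       # /ms Ca_ds-activated opening at saturation
    k_ds: float = 45.0       # uM half-activation of opening
    hill_ds: float = 2.0
    k_jsr: float = 1.07      # mM, SR-load gate midpoint (sets the threshold)
    hill_jsr: float = 12.0
    r_close: float = 0.30    # /ms
    r_inact: float = 0.008   # /ms at saturating Ca_ds
    r_recov: float = 0.004   # /ms
    tau_ds: float = 0.08     # ms, DS <-> SS within a CRU
    tau_ss_intra: float = 0.8  # ms, SS <-> cytosol within a CRU
    tau_tr: float = 40.0     # ms, NSR <-> JSR
    tau_ss_cru: float = 50.0  # ms, inter-CRU sub-space coupling
    tau_cyto_cru: float = 25.0
    tau_nsr_cru: float = 60.0
    g_up: float = 0.40
    g_leak: float = 6.0e-5
    g_efflux: float = 0.12   # uM/ms max NCX-like cytosolic Ca efflux
    sarco_scale: float = 1.0
    r_cru_cru: bool = False   # tighter inter-CRU coupling, lower threshold
    r_serca_ncx: bool = False

    def resolved(self) -> "SpatialParams":
        p = replace(self)
        if self.r_cru_cru:
            p.tau_ss_cru = self.tau_ss_cru * 0.5
        if self.r_serca_ncx:
            # up-regulated SERCA, down-regulated NCX: faster reloading and
            # less Ca removed at the crawling wavefront (lower threshold)
            p.g_up = self.g_up * 1.5
            p.g_efflux = self.g_efflux * 0.5
        return p

    def to_array(self) -> np.ndarray:
        p = self.resolved()
        return np.array([
            p.g_ryr, p.r_spont, p.r_max, p.k_ds, p.hill_ds, p.k_jsr,
            p.hill_jsr, p.r_close, p.r_inact, p.r_recov, p.tau_ds,
            p.tau_ss_intra, p.tau_tr, p.tau_ss_cru, p.tau_cyto_cru,
            p.tau_nsr_cru, p.g_up, p.g_leak, p.sarco_scale, p.g_efflux,
        ])


@dataclass
class ClampProtocol:
    """Partial Ca2+-clamp ladder: stepped SR load, clamp released on SCRE."""

    casr_steps: tuple = (0.95, 1.05, 1.15, 1.25)
    step_duration: float = 2000.0  # ms
    ca_cyto_clamp: float = 0.1     # uM
    release_on_detection: bool = True

    def __post_init__(self) -> None:
        steps = np.asarray(self.casr_steps, dtype=float)
        if np.any(np.diff(steps) <= 0):
            raise ValueError("casr steps must be increasing")


@njit(cache=True, fastmath=True)
def _binom(n, p):
    # small-np shortcut: at most one success is ever likely
    if n <= 0 or p <= 0.0:
        return 0
    ev = n * p
    if ev < 0.02:
        return 1 if np.random.random() < ev else 0
    return np.random.binomial(n, p)


@njit(cache=True, fastmath=True)
def _step_grid(ca_ds, ca_ss, ca_cyto, ca_nsr, ca_jsr, n_o, n_i, pars, nbr,
               n_ryr, dt, clamped, clamp_cyto, clamp_casr):
    """One dt step of the full CRU grid; returns total open channels."""
    (g_ryr, r_spont, r_max, k_ds, hill_ds, k_jsr, hill_jsr, r_close,
     r_inact, r_recov, tau_ds, tau_ss_intra, tau_tr, tau_ss_cru,
     tau_cyto_cru, tau_nsr_cru, g_up, g_leak, sarco, g_efflux) = (
        pars[0], pars[1], pars[2], pars[3], pars[4], pars[5], pars[6],
        pars[7], pars[8], pars[9], pars[10], pars[11], pars[12], pars[13],
        pars[14], pars[15], pars[16], pars[17], pars[18], pars[19])
    n = ca_ds.shape[0]
    total_open = 0
    inv_tau_ds = 1.0 / tau_ds
    inv_tau_ss = 1.0 / tau_ss_intra
    inv_tau_tr = 1.0 / tau_tr
    inv_ss_cru = 1.0 / tau_ss_cru
    inv_cy_cru = 1.0 / tau_cyto_cru
    inv_nsr_cru = 1.0 / tau_nsr_cru
    kds2 = k_ds * k_ds
    # SR-load gate uses a fixed 12th-power Hill form (hill_jsr is kept in
    # the parameter vector for reporting; the exponent is hard-wired for
    # speed)
    kj2 = k_jsr * k_jsr
    kj4 = kj2 * kj2
    kj12 = kj4 * kj4 * kj4

    # channel transitions (rates checked against dt by the caller)
    for c in range(n):
        o = n_o[c]
        ii = n_i[c]
        ncl = n_ryr - o - ii
        x2 = ca_jsr[c] * ca_jsr[c]
        x4 = x2 * x2
        x12 = x4 * x4 * x4
        load = x12 / (x12 + kj12)
        a2 = ca_ds[c] * ca_ds[c]
        act = a2 / (a2 + kds2)
        r_open = (r_spont + r_max * act) * load
        d_open = _binom(ncl, r_open * dt)
        if o > 0:
            leave = r_close + r_inact * act
            n_leave = _binom(o, leave * dt)
            n_to_i = _binom(n_leave, r_inact * act / leave)
        else:
            n_leave = 0
            n_to_i = 0
        n_rec = _binom(ii, r_recov * dt) if ii > 0 else 0
        o = o + d_open - n_leave
        ii = ii + n_to_i - n_rec
        if o < 0:
            o = 0
        if ii < 0:
            ii = 0
        if o + ii > n_ryr:
            o = n_ryr - ii
        n_o[c] = o
        n_i[c] = ii
        total_open += o

    # fluxes and diffusion
    for c in range(n):
        jrel = n_o[c] * g_ryr * (ca_jsr[c] * 1000.0 - ca_ds[c])
        j_ds_ss = (ca_ds[c] - ca_ss[c]) * inv_tau_ds
        j_ss_cy = (ca_ss[c] - ca_cyto[c]) * inv_tau_ss
        cy = ca_cyto[c]
        j_up = g_up * cy * cy / (cy * cy + 0.0625)
        j_leak = g_leak * (ca_nsr[c] * 1000.0 - cy)
        j_eff = sarco * g_efflux * cy / (cy + 0.3)
        j_tr = (ca_nsr[c] - ca_jsr[c]) * inv_tau_tr

        dss = -j_ss_cy + j_ds_ss * (V_DS / V_SS)
        dcy = j_ss_cy * (V_SS / V_CYTO) - j_up + j_leak - j_eff
        dnsr = (j_up - j_leak) * (V_CYTO / V_NSR) * 1.0e-3 - j_tr * (V_JSR / V_NSR)
        for q in range(6):
            nb = nbr[c, q]
            if nb >= 0:
                dss += (ca_ss[nb] - ca_ss[c]) * inv_ss_cru
                dcy += (ca_cyto[nb] - ca_cyto[c]) * inv_cy_cru
                dnsr += (ca_nsr[nb] - ca_nsr[c]) * inv_nsr_cru

        ca_ds[c] += dt * (jrel - j_ds_ss)
        ca_ss[c] += dt * B_SS * dss
        ca_cyto[c] += dt * B_CYTO * dcy
        ca_nsr[c] += dt * dnsr
        ca_jsr[c] += dt * B_JSR * (j_tr - jrel * (V_DS / V_JSR) * 1.0e-3)
        if ca_ds[c] < 1e-6:
            ca_ds[c] = 1e-6
        if ca_ss[c] < 1e-6:
            ca_ss[c] = 1e-6
        if ca_cyto[c] < 1e-6:
            ca_cyto[c] = 1e-6
        if ca_nsr[c] < 1e-6:
            ca_nsr[c] = 1e-6
        if ca_jsr[c] < 1e-6:
            ca_jsr[c] = 1e-6
        if clamped:
            ca_cyto[c] = clamp_cyto
            ca_ss[c] = clamp_cyto
            ca_nsr[c] = clamp_casr
            ca_jsr[c] = clamp_casr
    return total_open


@njit(cache=True)
def _run_segment(ca_ds, ca_ss, ca_cyto, ca_nsr, ca_jsr, n_o, n_i, pars, nbr,
                 n_ryr, dt, n_macro, sub, clamped_in, clamp_cyto, clamp_casr,
                 release_on_detection, detect_on):
    """Run n_macro recording intervals of `sub` dt-steps; returns the
    whole-cell open-fraction trace and whether the clamp was released."""
    n_total = ca_ds.shape[0] * n_ryr
    trace = np.empty(n_macro)
    clamped = clamped_in
    for m in range(n_macro):
        tot = 0
        for _ in range(sub):
            tot = _step_grid(ca_ds, ca_ss, ca_cyto, ca_nsr, ca_jsr, n_o, n_i,
                             pars, nbr, n_ryr, dt, clamped, clamp_cyto,
                             clamp_casr)
        frac = tot / n_total
        trace[m] = frac
        if clamped and release_on_detection and frac >= detect_on:
            clamped = False
    return trace, clamped


def _neighbours(dims) -> np.ndarray:
    nx, ny, nz = dims
    n = nx * ny * nz
    nbr = np.full((n, 6), -1, dtype=np.int64)
    def idx(x, y, z):
        return (z * ny + y) * nx + x
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                i = idx(x, y, z)
                q = 0
                for dx, dy, dz in ((-1, 0, 0), (1, 0, 0), (0, -1, 0),
                                   (0, 1, 0), (0, 0, -1), (0, 0, 1)):
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        nbr[i, q] = idx(xx, yy, zz)
                        q += 1
    return nbr


class SpatialCell:
    """State container and stepper for the CRU grid."""

    MIN_DIMS = (10, 8, 8)

    def __init__(self, params: SpatialParams | None = None, seed: int = 0,
                 dt: float = 0.02):
        self.params = params or SpatialParams()
        dims = self.params.dims
        if any(d < m for d, m in zip(sorted(dims, reverse=True),
                                     sorted(self.MIN_DIMS, reverse=True))):
            raise ValueError(f"grid below supported minimum {self.MIN_DIMS}")
        self.dt = float(dt)
        p = self.params.resolved()
        max_rate = p.r_close + p.r_inact + p.r_max
        if max_rate * self.dt > 0.1:
            raise ValueError(
                f"rate*dt = {max_rate * self.dt:.3f} > 0.1; reduce dt"
            )
        self.n = dims[0] * dims[1] * dims[2]
        self.nbr = _neighbours(dims)
        self.pars = self.params.to_array()
        self.seed = int(seed)
        self.reset(casr=0.9, ca_cyto=0.1)

    def reset(self, casr: float, ca_cyto: float = 0.1) -> None:
        n = self.n
        self.ca_ds = np.full(n, ca_cyto)
        self.ca_ss = np.full(n, ca_cyto)
        self.ca_cyto = np.full(n, ca_cyto)
        self.ca_nsr = np.full(n, casr)
        self.ca_jsr = np.full(n, casr)
        self.n_o = np.zeros(n, dtype=np.int64)
        self.n_i = np.zeros(n, dtype=np.int64)

    @property
    def n_ryr_o(self) -> float:
        return float(self.n_o.sum()) / (self.n * self.params.n_ryr)

    def channel_counts_valid(self) -> bool:
        return bool(np.all((self.n_o >= 0) & (self.n_i >= 0)
                           & (self.n_o + self.n_i <= self.params.n_ryr)))

    def total_calcium(self) -> float:
        """Volume/buffer-weighted total Ca per CRU average (uM)."""
        tot = (V_DS * self.ca_ds + V_SS * self.ca_ss / B_SS
               + V_CYTO * self.ca_cyto / B_CYTO
               + 1000.0 * V_NSR * self.ca_nsr
               + 1000.0 * V_JSR * self.ca_jsr / B_JSR)
        return float(tot.mean())

    def run(self, duration: float, record_dt: float = 1.0, clamped: bool = False,
            clamp_cyto: float = 0.1, clamp_casr: float = 1.0,
            release_on_detection: bool = True, seed: int | None = None):
        """Advance the grid; returns (t, n_ryr_o trace, clamp state)."""
        if seed is not None:
            _seed_numba(seed)
        n_macro = int(round(duration / record_dt))
        sub = max(int(round(record_dt / self.dt)), 1)
        trace, still_clamped = _run_segment(
            self.ca_ds, self.ca_ss, self.ca_cyto, self.ca_nsr, self.ca_jsr,
            self.n_o, self.n_i, self.pars, self.nbr, self.params.n_ryr,
            record_dt / sub, n_macro, sub, clamped, clamp_cyto, clamp_casr,
            release_on_detection, DETECT_ON,
        )
        t = np.arange(1, n_macro + 1) * record_dt
        return t, trace, still_clamped


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


def run_ca_clamp_ladder(params: SpatialParams | None, protocol: ClampProtocol,
                        seed: int = 0) -> pd.DataFrame:
    """Run the stepped SR-load clamp protocol on one cell.

    At each step the intracellular and SR Ca2+ are clamped to the step
    values; once a whole-cell SCRE is detected the clamp is released and
    concentrations evolve freely until the end of the step.  Returns a
    long-format table (casr, t, n_ryr_o).
    """
    cell = SpatialCell(params, seed=seed)
    rows = []
    _seed_numba(seed & 0x7FFFFFFF)
    for k, casr in enumerate(protocol.casr_steps):
        cell.reset(casr=casr, ca_cyto=protocol.ca_cyto_clamp)
        t, trace, _ = cell.run(
            protocol.step_duration, clamped=True,
            clamp_cyto=protocol.ca_cyto_clamp, clamp_casr=casr,
            release_on_detection=protocol.release_on_detection,
        )
        rows.append(pd.DataFrame({
            "step": k, "casr": casr, "t": t, "n_ryr_o": trace,
        }))
    return pd.concat(rows, ignore_index=True)


def generate_scre_ensemble(
    params: SpatialParams | None,
    casr_values,
    n_runs_per_value: int = 50,
    seed: int = 0,
    duration: float = 2000.0,
    condition: str = "control",
    record_dt: float = 2.0,
) -> pd.DataFrame:
    """Whole-cell open-RyR traces for SCRE at clamped SR-Ca2+ levels.

    Each run starts clamped at (diastolic cytosolic Ca, the given SR
    load); the clamp is released when an event is detected.  Output is
    the long-format ensemble table consumed by the fitting pipeline:
    columns run_id, condition, casr, t, n_ryr_o.
    """
    cell = SpatialCell(params, seed=seed)
    rows = []
    run_id = 0
    for casr in casr_values:
        for r in range(n_runs_per_value):
            _seed_numba((seed * 1000003 + run_id * 7919 + 17) & 0x7FFFFFFF)
            cell.reset(casr=casr, ca_cyto=0.1)
            t, trace, _ = cell.run(duration, clamped=True, clamp_cyto=0.1,
                                   clamp_casr=casr, record_dt=record_dt)
            rows.append(pd.DataFrame({
                "run_id": run_id, "condition": condition, "casr": casr,
                "t": t, "n_ryr_o": trace,
            }))
            run_id += 1
    return pd.concat(rows, ignore_index=True)
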