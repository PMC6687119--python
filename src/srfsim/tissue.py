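"""2D monodomain tissue of coupled 0D cells.

Isotropic voltage diffusion (5-point finite differences, no-flux
boundaries) couples the hybrid-minimal cells of :mod:`srfsim.cell0d`;
every cell carries its own SRF controller with an independent RNG
stream, so spontaneous release is spatially uncorrelated unless the SR
load field makes it so.  Protocols cover edge pacing, cross-field and
phase-distribution re-entry induction, SCRE-variant heterogeneity
assignment, conduction-block scenarios and the re-entry/SCRE interaction
experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .cell0d import (
    CellModel,
    CellParams,
    _SRF_MODES,
    initial_state,
    pack_direct,
    pack_dynfit,
    pack_general,
)

__all__ = [
    "TissueSheet",
    "Stimulus",
    "assign_srf_heterogeneity",
    "init_reentry",
    "run_conduction_block_protocols",
    "run_reentry_scre_experiment",
    "HETEROGENEITY_SCHEMES",
]

#: heterogeneity schemes: fractions over (baseline, -0.05, +0.05, -0.10, +0.10)
#: threshold-shift variants; censored schemes reassign the higher-threshold
#: (less vulnerable) variants to baseline.
HETEROGENEITY_SCHEMES = ("homogeneous", "small", "large",
                         "small_censored", "large_censored")


@dataclass
class Stimulus:
    """A square current pulse applied to a cell mask."""

    t_on: float
    duration: float = 2.0
    amplitude: float = 40.0
    mask: np.ndarray | None = None  # boolean (ny, nx); None = everywhere

    def active(self, t: float) -> bool:
        # tolerant lower edge so float-accumulated time cannot miss the
        # onset by one sub-step; duration measured from the nominal onset
        return self.t_on - 1e-9 <= t and t - self.t_on < self.duration


def edge_mask(nx: int, ny: int, side: str = "left", width: int = 2) -> np.ndarray:
    m = np.zeros((ny, nx), dtype=bool)
    if side == "left":
        m[:, :width] = True
    elif side == "right":
        m[:, -width:] = True
    elif side == "bottom":
        m[:width, :] = True
    elif side == "top":
        m[-width:, :] = True
    else:
        raise ValueError(side)
    return m


class TissueSheet:
    """2D sheet of coupled cells with per-cell SRF controllers."""

    def __init__(
        self,
        nx: int = 60,
        ny: int = 60,
        dx: float = 0.25,           # mm
        D: float = 0.1,             # mm^2/ms
        cell_params: CellParams | None = None,
        cell_type_map: np.ndarray | None = None,
        srf_mode: str = "off",
        srf_params=None,
        dynfit_condition: str = "control",
        seed: int = 0,
        dt: float = 0.02,
        record_dt: float = 1.0,
    ):
        self.nx, self.ny = nx, ny
        self.n = nx * ny
        self.dx = float(dx)
        self.dt = float(dt)
        self.record_dt = float(record_dt)
        self.d_map = np.full(self.n, float(D))
        # CFL-style stability bound for the diffusion operator
        if self.dt > self.dx**2 / (4.0 * max(self.d_map.max(), 1e-12)) * 0.9:
            raise ValueError(
                f"dt={self.dt} violates diffusion stability for "
                f"dx={self.dx}, D={self.d_map.max()}"
            )
        from dataclasses import replace

        self.base_params = cell_params or CellParams()
        # cell_type_map codes index this tuple; with no map every cell uses
        # the base parameters' own cell type
        types = ("vent_endo", "vent_m", "vent_epi", "atrial")
        self.P = np.empty((self.n, K.NPAR))
        if cell_type_map is None:
            self.cell_type_map = np.full(
                (ny, nx), types.index(self.base_params.cell_type),
                dtype=np.int64)
            self.P[:] = self.base_params.to_array()[None, :]
        else:
            self.cell_type_map = np.asarray(cell_type_map, dtype=np.int64)
            if self.cell_type_map.shape != (ny, nx):
                raise ValueError("cell_type_map shape mismatch")
            flat_types = self.cell_type_map.ravel()
            for code in np.unique(flat_types):
                p = replace(self.base_params, cell_type=types[int(code)])
                self.P[flat_types == code] = p.to_array()

        self.S = np.tile(initial_state(), (self.n, 1))
        self.C = np.zeros((self.n, K.NCTRL))
        self.rng_states = K.seed_streams(seed, self.n)
        self.seed = int(seed)
        self.t = 0.0

        if srf_mode not in _SRF_MODES:
            raise ValueError(f"srf_mode must be one of {sorted(_SRF_MODES)}")
        self.srf_mode = srf_mode
        self._mode_code = _SRF_MODES[srf_mode]
        self._direct = np.zeros((1, 8))
        self._gd = np.ones((1, 12))
        self._df = np.ones((1, 29))
        if srf_mode == "direct":
            self._direct = pack_direct(srf_params)
        elif srf_mode == "general":
            self._gd = pack_general(srf_params if isinstance(srf_params, list)
                                    else [srf_params] if srf_params else [])
        elif srf_mode == "dynamic-fit":
            self._df = pack_dynfit(srf_params, dynfit_condition)
        self.variant = np.zeros(self.n, dtype=np.int64)
        self._override = np.full(self.n, -1.0)
        self._diff = np.zeros(self.n)
        self._stim = np.zeros(self.n)
        self.cicr_ca_threshold = 0.35

    # -- parameter helpers ---------------------------------------------------

    def scale_param(self, idx: int, factor: float, mask: np.ndarray | None = None) -> None:
        """Scale one kernel parameter for all (or masked) cells."""
        if mask is None:
            self.P[:, idx] *= factor
        else:
            self.P[np.asarray(mask, dtype=bool).ravel(), idx] *= factor

    def set_uniform_state(self, state: np.ndarray) -> None:
        self.S[:] = state[None, :]

    def set_casr(self, casr) -> None:
        casr = np.broadcast_to(np.asarray(casr, dtype=float).ravel()
                               if np.ndim(casr) else np.full(self.n, casr),
                               (self.n,))
        self.S[:, K.ICANSR] = casr
        self.S[:, K.ICAJSR] = casr

    @property
    def vm(self) -> np.ndarray:
        return self.S[:, K.IV].reshape(self.ny, self.nx)

    @property
    def casr(self) -> np.ndarray:
        return self.S[:, K.ICANSR].reshape(self.ny, self.nx)

    def recovery_times(self, t_query: float | None = None) -> np.ndarray:
        """Per-cell time since the last CICR-inducing AP (recovery map)."""
        tq = self.t if t_query is None else t_query
        last = self.C[:, K.CLAST_CICR].copy()
        never = last <= 0.0
        out = tq - last
        out[never] = tq  # sentinel: full simulation duration
        return out.reshape(self.ny, self.nx)

    # -- stepping ------------------------------------------------------------

    def run(
        self,
        duration: float,
        stimuli: "list[Stimulus] | None" = None,
        snapshot_dt: float | None = None,
        probes: "list[tuple[int, int]] | None" = None,
    ) -> dict:
        """Advance the sheet; optionally record Vm/SR-Ca2+ snapshot stacks
        and per-probe traces."""
        stimuli = list(stimuli or [])
        for s in stimuli:
            if s.mask is not None and s.mask.shape != (self.ny, self.nx):
                raise ValueError("stimulus mask shape mismatch")
        n_macro = int(round(duration / self.record_dt))
        sub = max(int(round(self.record_dt / self.dt)), 1)
        dt = self.record_dt / sub
        tab = K.build_voltage_table(dt)
        inv_dx2 = 1.0 / (self.dx * self.dx)
        snap_every = (max(int(round(snapshot_dt / self.record_dt)), 1)
                      if snapshot_dt else 0)
        snaps_vm, snaps_casr, snap_t = [], [], []
        probes = probes or []
        probe_idx = [y * self.nx + x for (x, y) in probes]
        probe_tr = np.empty((len(probes), n_macro))
        t_axis = np.empty(n_macro)

        masks = [(s, (np.ones(self.n, dtype=bool) if s.mask is None
                      else s.mask.ravel())) for s in stimuli]
        t0 = self.t
        for step in range(n_macro):
            K.controller_update(self.C, self.S, self.rng_states, self.t,
                                self._mode_code, self.variant, self._direct,
                                self._gd, self._df, self._override,
                                self.cicr_ca_threshold)
            for _ in range(sub):
                self._stim[:] = 0.0
                tt = self.t - t0
                for s, m in masks:
                    if s.active(tt):
                        self._stim[m] = s.amplitude
                K.laplacian_vm(self.S, self.nx, self.ny, self.d_map,
                               inv_dx2, self._diff)
                K.step_cells(self.S, self.P, dt, self.t, self._stim,
                             self._diff, self._override, tab)
                self.t += dt
            if not np.all(np.isfinite(self.S[:, K.IV])):
                raise FloatingPointError(f"Vm diverged at t={self.t:.2f} ms")
            t_axis[step] = self.t
            for q, pi in enumerate(probe_idx):
                probe_tr[q, step] = self.S[pi, K.IV]
            if snap_every and (step + 1) % snap_every == 0:
                snaps_vm.append(self.vm.copy())
                snaps_casr.append(self.casr.copy())
                snap_t.append(self.t)
        return {
            "t": t_axis,
            "probes": probe_tr,
            "vm_snaps": np.array(snaps_vm) if snaps_vm else None,
            "casr_snaps": np.array(snaps_casr) if snaps_casr else None,
            "snap_t": np.array(snap_t),
        }


# ---------------------------------------------------------------------------
# SRF heterogeneity assignment
# ---------------------------------------------------------------------------

def assign_srf_heterogeneity(sheet: TissueSheet, scheme: str, n_variants: int = 5,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Randomly assign SRF variants to cells.

    Variant 0 is the baseline; variants 1..4 carry SR-Ca2+ thresholds
    shifted by -0.05, +0.05, -0.10 and +0.10 mM (in that order).  The
    ``small`` scheme assigns 60% of cells to baseline and 10% to each
    alternative; ``large`` assigns 20% to each of the five.  Censored
    schemes reassign the higher-threshold variants (2 and 4) to baseline.
    """
    if scheme not in HETEROGENEITY_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_variants != 5 and scheme != "homogeneous":
        raise ValueError("heterogeneity schemes require five variants")
    rng = rng or np.random.default_rng(sheet.seed)
    if scheme == "homogeneous":
        v = np.zeros(sheet.n, dtype=np.int64)
    else:
        if scheme.startswith("small"):
            probs = [0.6, 0.1, 0.1, 0.1, 0.1]
        else:
            probs = [0.2] * 5
        v = rng.choice(5, size=sheet.n, p=probs).astype(np.int64)
        if scheme.endswith("censored"):
            v[(v == 2) | (v == 4)] = 0
    sheet.variant = v
    return v.reshape(sheet.ny, sheet.nx)


def threshold_shifted_variants(base, shifts=(-0.05, +0.05, -0.10, +0.10)):
    """Baseline General Dynamic params plus threshold-shifted variants.

    All other parameters are kept identical or relative to the threshold
    (the probability window and saturation point shift with it).
    """
    from dataclasses import replace

    out = [base]
    for s in shifts:
        out.append(replace(base, casr_threshold=base.casr_threshold + s,
                           casr_max=base.casr_max + s))
    return out


# ---------------------------------------------------------------------------
# re-entry induction
# ---------------------------------------------------------------------------

def _single_cell_cycle(params: CellParams, cycle: float, seed: int = 0,
                       n_prepace: int = 12) -> np.ndarray:
    """State trajectory over one paced cycle (for phase distribution)."""
    cell = CellModel(params, srf_mode="off", seed=seed)
    for _ in range(n_prepace):
        cell.run(cycle, stim_times=[1.0])
    rec = cell.run(cycle, stim_times=[1.0], record_states=True)
    return rec["states"]


def init_reentry(
    sheet: TissueSheet,
    method: str = "phase_distribution",
    cycle: float = 220.0,
    core: "tuple[float, float] | None" = None,
    s1_side: str = "left",
    s2_coupling: "tuple[float, float] | None" = None,
    seed: int = 0,
) -> dict:
    """Initiate re-entry on the sheet.

    ``phase_distribution`` assigns each cell a state from one paced cycle
    of the single-cell trajectory according to its angular position
    around the core, producing an immediate rotor.  ``cross_field``
    applies an S1 plane wave and an orthogonal S2; the vulnerable S2
    coupling interval is located by a bisection-style scan when not
    given.
    """
    if method == "phase_distribution":
        traj = _single_cell_cycle(sheet.base_params, cycle, seed=seed)
        ncyc = len(traj)
        cx, cy = core if core else (sheet.nx / 2.0, sheet.ny / 2.0)
        ys, xs = np.mgrid[0:sheet.ny, 0:sheet.nx]
        theta = np.arctan2(ys - cy, xs - cx)  # [-pi, pi)
        idx = ((theta + math.pi) / (2.0 * math.pi) * (ncyc - 1)).astype(int)
        sheet.S[:] = traj[idx.ravel()]
        return {"method": method, "induced": True}

    if method != "cross_field":
        raise ValueError(method)
    s1 = Stimulus(t_on=2.0, mask=edge_mask(sheet.nx, sheet.ny, s1_side))
    quad = np.zeros((sheet.ny, sheet.nx), dtype=bool)
    quad[: sheet.ny // 2, : sheet.nx // 2] = True
    lo, hi = s2_coupling if s2_coupling else (60.0, 220.0)
    state0 = sheet.S.copy()
    ctrl0 = sheet.C.copy()
    tried = []
    n_attempts = 1 if hi - lo < 5.0 else 6
    for _ in range(n_attempts):
        mid = 0.5 * (lo + hi)
        sheet.S[:] = state0
        sheet.C[:] = ctrl0
        res = sheet.run(mid + 400.0, stimuli=[
            s1, Stimulus(t_on=2.0 + mid, mask=quad, amplitude=60.0)])
        active = np.mean(sheet.S[:, K.IV] > -40.0)
        tried.append((mid, float(active)))
        if active > 0.05:  # still-propagating activity: re-entrant
            return {"method": method, "induced": True, "coupling": mid,
                    "scan": tried}
        # refractory (no capture) if everything is back at rest quickly
        hi = mid if mid > lo + 10 else hi
        lo = lo + 0.25 * (hi - lo)
    sheet.S[:] = state0
    sheet.C[:] = ctrl0
    return {"method": method, "induced": False, "scan": tried}


# ---------------------------------------------------------------------------
# conduction-block protocols
# ---------------------------------------------------------------------------

def run_conduction_block_protocols(
    scenario: str,
    nx: int = 42,
    ny: int = 21,
    seed: int = 0,
    srf_enabled: bool = True,
    coupling_interval: float = 500.0,
    D: float = 0.08,
    srf_params=None,
    prepace_bcl: float = 350.0,
    i_k1_patch_scale: float = 0.15,
) -> dict:
    """The two unidirectional conduction-block scenarios.

    ``dad_block``: homogeneous epicardial sheet with impaired sodium
    current (30% conductance, +5 mV inactivation shift); two uniform edge
    stimuli 500 ms apart; dense sub-threshold SCRE between them produce
    DADs that locally inactivate I_Na and break the second wave.  Reports
    the fraction of the far edge activated by S2.

    ``focal_block``: transmural 1:1:1 ENDO:M:EPI sheet; an early
    Direct-Control SCRE focus in a reduced-I_K1 patch fires a focal wave
    that blocks at the still-refractory M region, while a homogeneous
    (all-EPI) sheet propagates it uniformly.  Reports whether the far
    (EPI) edge was reached by the focal excitation.
    """
    from .sampling import SRFDistribution

    if scenario == "dad_block":
        params = CellParams(cell_type="vent_epi", na_channelopathy=True,
                            iso=True)
        if srf_params is None:
            # dense, tightly timed, sub-TA releases in the S1-S2 gap
            srf_params = SRFDistribution(
                p_scr=1.0, ti_sep=coupling_interval * 0.75, k_f1=25.0,
                k_f2=25.0, md=80.0, dw1=40.0, dw2=40.0)
        sheet = TissueSheet(
            nx, ny, D=D, cell_params=params, seed=seed,
            srf_mode="direct" if srf_enabled else "off",
            srf_params=srf_params if srf_enabled else None)
        cell = CellModel(params, seed=seed)
        for _ in range(10):
            cell.run(prepace_bcl, stim_times=[1.0])
        sheet.set_uniform_state(cell.S[0])
        s_mask = edge_mask(nx, ny, "left")
        res = sheet.run(
            coupling_interval + 300.0,
            stimuli=[Stimulus(t_on=2.0, mask=s_mask),
                     Stimulus(t_on=2.0 + coupling_interval, mask=s_mask)],
            snapshot_dt=5.0)
        vm = res["vm_snaps"]
        s2_on = 2.0 + coupling_interval
        window = (res["snap_t"] >= s2_on) & (res["snap_t"] <= s2_on + 250.0)
        far_act = (vm[window][:, :, -2:] > -20.0).any(axis=0)
        frac_far = float(far_act.mean())
        return {"scenario": scenario, "srf": srf_enabled,
                "far_edge_fraction": frac_far, "block": frac_far < 0.999,
                "result": res}

    if scenario != "focal_block":
        raise ValueError(scenario)

    third = nx // 3
    ctmap = np.zeros((ny, nx), dtype=np.int64)  # 0 endo
    ctmap[:, third: 2 * third] = 1              # 1 M
    ctmap[:, 2 * third:] = 2                    # 2 epi
    if srf_params is None:
        # early-timed, tightly synchronised, large-amplitude SCRE in all
        # cells; the reduced-I_K1 patch localises the focal source
        srf_params = SRFDistribution(p_scr=1.0, ti_sep=170.0, k_f1=6.0,
                                     k_f2=6.0, md=70.0, dw1=20.0, dw2=20.0)
    out = {}
    for label, het in (("heterogeneous", True), ("homogeneous", False)):
        sheet = TissueSheet(
            nx, ny, D=0.05, cell_params=CellParams(iso=True),
            cell_type_map=ctmap if het else np.full((ny, nx), 2, dtype=np.int64),
            seed=seed, srf_mode="direct", srf_params=srf_params)
        if het:
            # accentuated mid-myocardial plateau: stronger, slower-
            # inactivating L-type current and reduced rapid rectifier
            mmask = np.zeros((ny, nx), dtype=bool)
            mmask[:, third: 2 * third] = True
            sheet.scale_param(K.PG_CAL, 1.6, mmask)
            sheet.scale_param(K.PFCA_K, 8.0, mmask)
            sheet.scale_param(K.PG_KR, 0.15, mmask)
        # focus: reduced I_K1 patch on the EPI side; its early focal wave
        # must cross the (still refractory) M region to reach the far edge
        patch = np.zeros((ny, nx), dtype=bool)
        patch[ny // 2 - 4: ny // 2 + 4, nx - 13: nx - 5] = True
        sheet.scale_param(K.PG_K1, i_k1_patch_scale, patch)
        cell = CellModel(sheet.base_params, seed=seed)
        for _ in range(10):
            cell.run(prepace_bcl, stim_times=[1.0])
        sheet.set_uniform_state(cell.S[0])
        res = sheet.run(700.0,
                        stimuli=[Stimulus(t_on=2.0, mask=edge_mask(nx, ny, "left"))],
                        snapshot_dt=5.0)
        vm = res["vm_snaps"]
        # second (spontaneous) excitation: activity on the focus side after
        # the paced wave has cleared; far side = the ENDO (stimulated) edge
        late = res["snap_t"] > 160.0
        far_reached = bool((vm[late][:, :, :4] > -20.0).any())
        second = bool((vm[late][:, :, 2 * third:] > -20.0).any())
        out[label] = {"far_reached": far_reached, "second_excitation": second,
                      "result": res}
    out["block_in_heterogeneous_only"] = (
        not out["heterogeneous"]["far_reached"]
        and out["homogeneous"]["far_reached"]
        and out["heterogeneous"]["second_excitation"])
    return out


# ---------------------------------------------------------------------------
# re-entry / SCRE interaction experiment
# ---------------------------------------------------------------------------

def run_reentry_scre_experiment(
    gd_params,
    nx: int = 48,
    ny: int = 48,
    seed: int = 0,
    D: float = 0.06,
    reentry_duration: float = 2000.0,
    observe_duration: float = 1500.0,
    cycle: float = 160.0,
    apd_shorten: float = 4.0,
    snapshot_dt: float = 5.0,
    cell_params: CellParams | None = None,
    d_restore: float | None = None,
    core: "tuple[float, float] | None" = None,
) -> dict:
    """Induction -> sustained re-entry -> forced termination -> observation.

    Re-entry is induced by phase distribution on an AP-shortened sheet
    (raised delayed-rectifier conductance, reduced D), sustained for
    ``reentry_duration``, then terminated by restoring D and blocking the
    rapid delayed rectifier (a pragmatic parameter switch).  During the
    quiescent window the General Dynamic SRF controllers may fire focal
    excitations wherever re-entrant SR-Ca2+ loading exceeded threshold.
    """
    params = cell_params or CellParams(cell_type="vent_epi", iso=True,
                                       r_serca_ncx=True)
    from dataclasses import replace

    # reduced I_K1 brings the resting potential closer to the sodium
    # activation threshold, enabling triggered focal excitation
    params = replace(params, g_kr=params.g_kr * apd_shorten,
                     g_k1=params.g_k1 * 0.7)
    sheet = TissueSheet(nx, ny, D=D, cell_params=params, seed=seed,
                        srf_mode="general", srf_params=gd_params)
    init_reentry(sheet, "phase_distribution", cycle=cycle, core=core,
                 seed=seed)
    res_re = sheet.run(reentry_duration, snapshot_dt=snapshot_dt)
    casr_at_term = sheet.casr.copy()
    recovery_at_term = sheet.recovery_times()
    # termination: restore excitation-weakening parameters
    sheet.scale_param(K.PG_KR, 0.05)
    sheet.d_map[:] = d_restore if d_restore is not None else 2.0 * D
    res_term = sheet.run(300.0, snapshot_dt=snapshot_dt)
    sheet.scale_param(K.PG_KR, 1.0 / 0.05)
    t_term = sheet.t
    # finer snapshots during observation: focal onsets are fast and the
    # source is located from the earliest-activation cluster
    res_obs = sheet.run(observe_duration, snapshot_dt=min(snapshot_dt, 2.0))
    return {
        "casr_at_termination": casr_at_term,
        "recovery_at_termination": recovery_at_term,
        "t_termination": t_term,
        "reentry": res_re,
        "termination": res_term,
        "observation": res_obs,
        "sheet": sheet,
    }


# ---------------------------------------------------------------------------
# SR-Ca2+ -> focal-excitation experiment
# ---------------------------------------------------------------------------

def run_focal_emergence_trial(
    casr: float,
    gd_variants,
    scheme: str = "homogeneous",
    nx: int = 25,
    ny: int = 25,
    seed: int = 0,
    D: float = 0.1,
    observe: float = 1250.0,
    cell_params: CellParams | None = None,
) -> dict:
    """One trial of the imposed-SR-load focal-emergence protocol.

    The sheet is paced once with a uniform stimulus; after repolarisation
    and RyR recovery the SR-Ca2+ field is set to ``casr`` everywhere and
    the sheet observed.  A focal excitation is scored when at least half
    the sheet crosses the activation threshold during the observation
    window (DADs alone never do).
    """
    params = cell_params or CellParams(cell_type="vent_epi")
    sheet = TissueSheet(nx, ny, D=D, cell_params=params, seed=seed,
                        srf_mode="general", srf_params=list(gd_variants))
    assign_srf_heterogeneity(sheet, scheme)
    sheet.run(250.0, stimuli=[Stimulus(t_on=2.0)])
    sheet.set_casr(casr)
    res = sheet.run(observe, snapshot_dt=10.0)
    vm = res["vm_snaps"]
    frac_active = (vm > -20.0).reshape(len(vm), -1).mean(axis=1)
    return {"focal": bool(frac_active.max() >= 0.5),
            "max_active_fraction": float(frac_active.max()),
            "n_events": int(sheet.C[:, K.CEVENT_COUNT].sum()),
            "result": res, "sheet": sheet}


def focal_probability_curve(
    casr_values,
    gd_variants,
    scheme: str = "homogeneous",
    n_seeds: int = 6,
    seed: int = 0,
    **kw,
) -> "tuple[np.ndarray, np.ndarray]":
    """P(focal) over imposed SR-Ca2+ (fraction of seeds with focal excitation)."""
    casr_values = np.asarray(casr_values, dtype=float)
    p = np.empty(len(casr_values))
    for i, casr in enumerate(casr_values):
        hits = 0
        for s in range(n_seeds):
            r = run_focal_emergence_trial(casr, gd_variants, scheme=scheme,
                                          seed=seed + 97 * s + i, **kw)
            hits += r["focal"]
        p[i] = hits / n_seeds
    return casr_values, p


def logistic_max_slope(x, p, n_trials: int = 1) -> float:
    """Max slope (per mM) of a logistic fitted to a probability curve.

    Fits by binomial maximum likelihood on the per-level success counts,
    which uses the full information in partial probabilities; perfectly
    separated data pin the scale at its lower bound (a very steep curve).
    """
    from scipy import optimize

    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    # Jeffreys-style pseudo-counts: perfectly separated data then yield a
    # finite scale set by the gap between the outermost 0 and 1 levels
    succ = np.round(p * n_trials) + 0.5
    fail = n_trials - np.round(p * n_trials) + 0.5

    def nll(params):
        mid, logk = params
        k = np.exp(logk)
        z = np.clip((x - mid) / k, -500, 500)
        logp = -np.log1p(np.exp(-z))
        logq = -np.log1p(np.exp(z))
        return -np.sum(succ * logp + fail * logq)

    mid0 = float(np.interp(0.5, np.clip(p, 0.01, 0.99), x))
    best = None
    for logk0 in (np.log(0.05), np.log(0.01)):
        res = optimize.minimize(
            nll, [mid0, logk0], method="L-BFGS-B",
            bounds=[(x.min() - 0.5, x.max() + 0.5), (np.log(2e-3), np.log(10.0))])
        if best is None or res.fun < best.fun:
            best = res
    k = float(np.exp(best.x[1]))
    return 1.0 / (4.0 * k)


def run_matched_pacing_experiment(
    gd_params,
    nx: int = 36,
    ny: int = 36,
    seed: int = 0,
    D: float = 0.04,
    bcl: float = 140.0,
    n_beats: int = 10,
    observe_duration: float = 1100.0,
    apd_shorten: float = 4.0,
    cell_params: CellParams | None = None,
) -> dict:
    """Regular rapid edge pacing matched to the re-entry loading protocol.

    Same cell conditions and sheet as :func:`run_reentry_scre_experiment`,
    but SR-Ca2+ is loaded by uniform plane-wave pacing instead of
    re-entry, yielding a near-homogeneous load field (offset only by the
    conduction-delay pattern).  Used to contrast the spatial
    heterogeneity of loading and the timing of post-pacing focal
    excitations with the re-entrant case.
    """
    from dataclasses import replace

    params = cell_params or CellParams(cell_type="vent_epi", iso=True,
                                       r_serca_ncx=True)
    params = replace(params, g_kr=params.g_kr * apd_shorten,
                     g_k1=params.g_k1 * 0.7)
    sheet = TissueSheet(nx, ny, D=D, cell_params=params, seed=seed,
                        srf_mode="general", srf_params=gd_params)
    mask = edge_mask(nx, ny, "left")
    stims = [Stimulus(t_on=2.0 + b * bcl, mask=mask) for b in range(n_beats)]
    sheet.run(n_beats * bcl + 50.0, stimuli=stims)
    casr_loaded = sheet.casr.copy()
    t_last = sheet.t
    res_obs = sheet.run(observe_duration, snapshot_dt=2.0)
    return {
        "casr_after_pacing": casr_loaded,
        "t_last_paced": t_last,
        "observation": res_obs,
        "sheet": sheet,
    }
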