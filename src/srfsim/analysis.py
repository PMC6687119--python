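"""Post-processing of tissue simulations: maps, foci, localisation, symmetry.

All operations are pure functions over recorded field series or maps; the
simulation state is never mutated.  The activation convention is an
up-crossing of -20 mV; unexcited cells carry a sentinel value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ACTIVATION_THRESHOLD",
    "SENTINEL",
    "compute_activation_map",
    "compute_recovery_map",
    "detect_focal_sources",
    "localisation_distance",
    "longest_recovery_region",
    "classify_excitation_symmetry",
    "save_map",
    "load_map",
]

ACTIVATION_THRESHOLD = -20.0  # mV, up-crossing
SENTINEL = -1.0               # activation map value for unexcited cells


def compute_activation_map(vm_series: np.ndarray, t: np.ndarray,
                           window: "tuple[float, float] | None" = None) -> np.ndarray:
    """Per-cell first time Vm up-crosses -20 mV within the window.

    ``vm_series`` is (n_frames, ny, nx); returns (ny, nx) of activation
    times (ms), with ``SENTINEL`` for cells never activated.
    """
    t = np.asarray(t, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        vm_series, t = vm_series[m], t[m]
    if len(t) < 2:
        raise ValueError("field series does not cover the window")
    above = vm_series >= ACTIVATION_THRESHOLD
    up = above[1:] & ~above[:-1]
    # include cells already above threshold in the first frame
    first = np.full(vm_series.shape[1:], -1, dtype=int)
    any_up = up.any(axis=0)
    first[any_up] = up.argmax(axis=0)[any_up] + 1
    out = np.full(vm_series.shape[1:], SENTINEL)
    out[any_up] = t[first[any_up]]
    return out


def compute_recovery_map(last_cicr_times: np.ndarray, t_query: float,
                         sim_duration: float | None = None) -> np.ndarray:
    """Per-cell time since the last CICR-inducing AP.

    Cells with no logged event (non-positive time) receive the full
    simulation duration as sentinel.
    """
    last = np.asarray(last_cicr_times, dtype=float)
    out = t_query - last
    out[last <= 0.0] = sim_duration if sim_duration is not None else t_query
    if np.any(out < 0):
        raise ValueError("recovery map query precedes logged events")
    return out


@dataclass
class FocalSource:
    x: float
    y: float
    t: float
    n_cells: int = 0


def detect_focal_sources(vm_series: np.ndarray, t: np.ndarray,
                         dx: float = 0.25, min_extent_mm: float = 3.0,
                         early_window: float = 4.0,
                         edge_fraction: float = 0.8) -> "list[FocalSource]":
    """Detect focal excitations in a quiescent/post-termination window.

    A focal source is the centre of mass of the earliest-activated cell
    cluster of an excitation whose wavefront subsequently expands by at
    least ``min_extent_mm``.  Successive excitations are separated by
    requiring the tissue to return below threshold between them.
    """
    t = np.asarray(t, dtype=float)
    above = vm_series >= ACTIVATION_THRESHOLD
    frac = above.reshape(len(t), -1).mean(axis=1)
    sources: list[FocalSource] = []
    i = 0
    n = len(t)
    while i < n:
        if frac[i] == 0.0:
            i += 1
            continue
        # an excitation begins; find its end (tissue fully repolarised)
        j = i
        while j < n and frac[j] > 0.0:
            j += 1
        seg = slice(max(i - 1, 0), j)
        act = compute_activation_map(vm_series[seg], t[seg])
        activated = act != SENTINEL
        if activated.any():
            t0 = act[activated].min()
            early = activated & (act <= t0 + early_window)
            lab, nlab = ndimage.label(early)
            # earliest cluster = the one containing the global minimum
            iy, ix = np.unravel_index(
                np.argmin(np.where(activated, act, np.inf)), act.shape)
            cluster = lab == lab[iy, ix]
            com_y, com_x = ndimage.center_of_mass(cluster)
            extent = math.sqrt(activated.sum() / math.pi) * dx * 2.0
            # waves entering whole-edge-first (plane waves from an edge
            # stimulus) are not focal
            is_edge_line = (early[:, 0].mean() > edge_fraction
                            or early[:, -1].mean() > edge_fraction
                            or early[0, :].mean() > edge_fraction
                            or early[-1, :].mean() > edge_fraction)
            if extent >= min_extent_mm and not is_edge_line:
                sources.append(FocalSource(x=float(com_x), y=float(com_y),
                                           t=float(t0),
                                           n_cells=int(cluster.sum())))
        i = j
    return sources


def longest_recovery_region(recovery_map: np.ndarray, decile: float = 0.9) -> np.ndarray:
    """Boolean mask of the top-decile recovery-time contour."""
    thr = np.quantile(recovery_map, decile)
    return recovery_map >= thr


def localisation_distance(recovery_map: np.ndarray, source_xy: "tuple[float, float]",
                          dx: float = 0.25, decile: float = 0.9) -> float:
    """Distance (mm) from a focal source to the longest-recovery region.

    Zero when the source lies inside the top-decile recovery region;
    otherwise the Euclidean distance to the nearest cell of the region.
    """
    region = longest_recovery_region(recovery_map, decile)
    if not region.any():
        raise ValueError("empty longest-recovery region")
    x, y = source_xy
    iy, ix = int(round(y)), int(round(x))
    iy = min(max(iy, 0), recovery_map.shape[0] - 1)
    ix = min(max(ix, 0), recovery_map.shape[1] - 1)
    if region[iy, ix]:
        return 0.0
    ys, xs = np.nonzero(region)
    return float(np.min(np.hypot(ys - y, xs - x)) * dx)


def localisation_correlation(pairs) -> dict:
    """Spearman rank correlation of (distance, t_focal) pairs."""
    d = np.array([p[0] for p in pairs], dtype=float)
    tf = np.array([p[1] for p in pairs], dtype=float)
    rho, pval = stats.spearmanr(tf, d)
    return {"rho": float(rho), "p": float(pval), "n": len(pairs)}


def classify_excitation_symmetry(activation_map: np.ndarray,
                                 source_xy: "tuple[float, float]",
                                 radius: float = 8.0,
                                 coverage_threshold: float = 0.85,
                                 time_tolerance: float = 3.0) -> str:
    """Classify an excitation as non/symmetric/asymmetric focal.

    Samples the activation map on a ring of fixed radius around the
    source.  Symmetric focal: activation reaches at least 85% of the
    sampled directions within a time window of ``time_tolerance`` times
    the ring's median conduction delay spread; asymmetric otherwise.
    A missing source classifies as non-focal.
    """
    if source_xy is None:
        return "non_focal"
    ny, nx = activation_map.shape
    x0, y0 = source_xy
    angles = np.linspace(0.0, 2.0 * math.pi, 48, endpoint=False)
    times = []
    interior = []
    for a in angles:
        x = x0 + radius * math.cos(a)
        y = y0 + radius * math.sin(a)
        ix, iy = int(round(x)), int(round(y))
        if 0 <= ix < nx and 0 <= iy < ny:
            interior.append(True)
            times.append(activation_map[iy, ix])
        else:
            interior.append(False)
    times = np.array(times)
    if len(times) == 0:
        return "non_focal"
    act = times != SENTINEL
    coverage = act.mean()
    if coverage < coverage_threshold:
        return "asymmetric_focal"
    tt = times[act]
    spread = np.max(tt) - np.min(tt)
    med_delay = max(np.median(tt - np.min(tt)), 1.0)
    if spread <= time_tolerance * med_delay:
        return "symmetric_focal"
    return "asymmetric_focal"


# ---------------------------------------------------------------------------
# map I/O: flat binary arrays + JSON sidecar (lossless round trip)
# ---------------------------------------------------------------------------

def save_map(path, array: np.ndarray, meta: dict | None = None) -> None:
    """Write a 2D map as raw float64 plus a JSON sidecar header."""
    arr = np.asarray(array, dtype=np.float64)
    arr.tofile(str(path))
    header = {"shape": list(arr.shape), "dtype": "float64"}
    header.update(meta or {})
    with open(str(path) + ".json", "w") as fh:
        json.dump(header, fh, indent=1)


def load_map(path):
    with open(str(path) + ".json") as fh:
        header = json.load(fh)
    arr = np.fromfile(str(path), dtype=header["dtype"]).reshape(header["shape"])
    return arr, header
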