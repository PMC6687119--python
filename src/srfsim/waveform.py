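"""Analytical spontaneous-release-function (SRF) waveforms.

An SRF approximates the time course of the whole-cell open-RyR fraction
(``N_RyR_O``) during one spontaneous calcium release event (SCRE).  Two
morphologies are distinguished: short events (duration ``lam <= 300 ms``)
are spike-like, a product of a rising and a falling sigmoid; long events
are plateau-like, a low sustained plateau with a late superimposed spike.

A waveform is fully described by four (spike) or five (plateau)
parameters: initiation time ``t_i``, duration ``lam`` (so the final time
is ``t_f = t_i + lam``), peak time ``t_p``, peak amplitude ``n_peak`` and
-- for plateau events -- plateau amplitude ``n_plateau``.  All times are
in ms and amplitudes are open-RyR fractions in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SHAPE",
    "SRFWaveform",
    "WaveformShapeConstants",
    "InvalidWaveformError",
    "derived_spike_params",
    "eval_spike",
    "eval_plateau",
    "eval_waveform",
    "expected_amplitudes",
    "min_plateau_peak_time_offset",
]


class InvalidWaveformError(ValueError):
    """Raised for degenerate or out-of-contract waveform parameters."""


@dataclass(frozen=True)
class WaveformShapeConstants:
    """Fixed shape constants of the SRF waveform formulae.

    ``rise_slope``/``rise_offset`` set the sigmoid width of the spike
    edges as a linear function of the rise/decay interval; the plateau
    constants fix the plateau edge geometry and the 50 ms upstroke /
    35 ms decay of the spike embedded in a plateau event.
    """

    rise_slope: float = 0.1689
    rise_offset: float = 0.00255  # ms; negligible, kept for exactness
    plateau_edge_offset: float = 17.5  # ms
    plateau_k: float = 5.946  # ms
    spike_half_act_offset: float = 25.0  # ms (half-activation at t_p - 25)
    morphology_threshold: float = 300.0  # ms; plateau iff lam > this
    k_min: float = 0.5  # ms floor avoiding numerically vertical edges


SHAPE = WaveformShapeConstants()


def min_plateau_peak_time_offset(shape: WaveformShapeConstants = SHAPE) -> float:
    """Smallest admissible ``t_p - t_i`` for a plateau waveform.

    The embedded spike's half-activation sits at ``t_p - 25``; it must not
    precede the plateau's rising edge at ``t_i + 17.5``.
    """
    return shape.spike_half_act_offset + shape.plateau_edge_offset


@dataclass
class SRFWaveform:
    """One sampled SCRE waveform.

    Attributes
    ----------
    t_i, t_p : float
        Initiation and peak time (ms).
    lam : float
        Duration (ms); the final time is ``t_f = t_i + lam``.
    n_peak, n_plateau : float
        Peak and plateau open-RyR fractions; ``n_plateau`` is only used
        for plateau morphology (``lam > 300`` ms).
    """

    t_i: float
    lam: float
    t_p: float
    n_peak: float
    n_plateau: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lam > 0.0):
            raise InvalidWaveformError(f"duration must be positive, got {self.lam}")
        # boundary peaks (t_p == t_i or t_p == t_f) are admitted: the edge
        # widths then collapse to their offset/floor values
        if not (self.t_i <= self.t_p <= self.t_f):
            raise InvalidWaveformError(
                f"need t_i <= t_p <= t_f, got {self.t_i}, {self.t_p}, {self.t_f}"
            )
        if not (0.0 <= self.n_plateau <= self.n_peak <= 1.0):
            raise InvalidWaveformError(
                f"need 0 <= n_plateau <= n_peak <= 1, got "
                f"{self.n_plateau}, {self.n_peak}"
            )
        if self.morphology == "plateau":
            if self.t_p - self.t_i < min_plateau_peak_time_offset() - 1e-9:
                raise InvalidWaveformError(
                    "plateau spike window violated: t_p - 25 precedes the "
                    "plateau rising edge (t_i + 17.5)"
                )

    @property
    def t_f(self) -> float:
        return self.t_i + self.lam

    @property
    def morphology(self) -> str:
        return "plateau" if self.lam > SHAPE.morphology_threshold else "spike"

    def to_record(self) -> dict:
        return {
            "t_i": self.t_i,
            "lam": self.lam,
            "t_p": self.t_p,
            "n_peak": self.n_peak,
            "n_plateau": self.n_plateau,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "SRFWaveform":
        return cls(
            t_i=float(rec["t_i"]),
            lam=float(rec["lam"]),
            t_p=float(rec["t_p"]),
            n_peak=float(rec["n_peak"]),
            n_plateau=float(rec.get("n_plateau", 0.0)),
        )


def derived_spike_params(w: SRFWaveform, shape: WaveformShapeConstants = SHAPE) -> dict:
    """Sigmoid centres and widths of the spike morphology.

    The rising edge is centred midway between ``t_i`` and ``t_p`` and the
    falling edge midway between ``t_p`` and ``t_f``; the widths scale
    linearly with the corresponding interval.  ``k1``/``k2`` are returned
    exactly (no floor), the floor is applied at evaluation time.
    """
    if w.t_p < w.t_i or w.t_f < w.t_p or w.t_f <= w.t_i:
        raise InvalidWaveformError("degenerate spike waveform")
    t1 = w.t_i + 0.5 * (w.t_p - w.t_i)
    t2 = w.t_p + 0.5 * (w.t_f - w.t_p)
    k1 = shape.rise_slope * (w.t_p - w.t_i) + shape.rise_offset
    k2 = shape.rise_slope * (w.t_f - w.t_p) + shape.rise_offset
    return {"t1": t1, "t2": t2, "k1": k1, "k2": k2}


def _rise(t, t0, k):
    return 1.0 / (1.0 + np.exp(np.clip(-(t - t0) / k, -500.0, 500.0)))


def _fall(t, t0, k):
    return 1.0 / (1.0 + np.exp(np.clip((t - t0) / k, -500.0, 500.0)))


def eval_spike(t, w: SRFWaveform, shape: WaveformShapeConstants = SHAPE):
    """Spike-like waveform: rising sigmoid times falling sigmoid.

    Returns the open-RyR fraction at time(s) ``t`` (scalar or ndarray).
    """
    p = derived_spike_params(w, shape)
    k1 = max(p["k1"], shape.k_min)
    k2 = max(p["k2"], shape.k_min)
    t = np.asarray(t, dtype=float)
    out = w.n_peak * _rise(t, p["t1"], k1) * _fall(t, p["t2"], k2)
    return out if out.ndim else float(out)


def eval_plateau(t, w: SRFWaveform, shape: WaveformShapeConstants = SHAPE):
    """Plateau-like waveform (duration > 300 ms).

    A sustained plateau of height ``n_plateau`` between edges at
    ``t_i + 17.5`` and ``t_f - 17.5`` ms (edge width 5.946 ms), plus an
    embedded spike of additional height ``n_peak - n_plateau`` whose
    rising edge half-activates at ``t_p - 25`` and whose falling edge sits
    at ``t_p + 17.5``.
    """
    if w.morphology != "plateau":
        raise InvalidWaveformError("eval_plateau requires lam > morphology threshold")
    t = np.asarray(t, dtype=float)
    e = shape.plateau_edge_offset
    k = shape.plateau_k
    base = w.n_plateau * _rise(t, w.t_i + e, k) * _fall(t, w.t_f - e, k)
    spike = (
        (w.n_peak - w.n_plateau)
        * _rise(t, w.t_p - shape.spike_half_act_offset, k)
        * _fall(t, w.t_p + e, k)
    )
    out = base + spike
    return out if out.ndim else float(out)


def eval_waveform(t, w: SRFWaveform, shape: WaveformShapeConstants = SHAPE):
    """Evaluate an SRF waveform, dispatching on morphology."""
    if w.morphology == "plateau":
        return eval_plateau(t, w, shape)
    return eval_spike(t, w, shape)


def expected_amplitudes(lam: float) -> dict:
    """Expected peak (and, for plateau events, plateau) amplitude.

    The expectation of the peak open-RyR fraction falls off as a power law
    of the duration, ``692.99 * lam**-1.6 + 0.059``; the plateau level
    (defined only for ``lam > 300`` ms) as ``31.09 * (0.01*lam)**-7.39 +
    0.034``.  Both are clipped to <= 1.  The strong negative amplitude-
    duration correlation reflects the roughly conserved total Ca released.
    """
    if not lam > 0.0:
        raise InvalidWaveformError(f"duration must be positive, got {lam}")
    exp_peak = min(692.99 * lam ** (-1.6) + 0.059, 1.0)
    out = {"exp_peak": exp_peak}
    if lam > SHAPE.morphology_threshold:
        out["exp_plateau"] = min(31.09 * (0.01 * lam) ** (-7.39) + 0.034, 1.0)
    return out
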