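"""Parameter distributions and inverse-transform sampling of SRF waveforms.

The stochastic variability of SCRE is captured by two primary quantities:
the initiation time ``t_i`` and the duration ``lam``.  Their cumulative
frequency distributions are each described by a pair of sigmoids -- for
``t_i`` joined at a separation point ``ti_sep`` where the cumulative
frequency equals ``cf_ti_sep``, and for ``lam`` joined at the median
duration ``md``.  Peak time and amplitudes are derived quantities.

Three parameterisation modes set the distributions:

* **Direct Control** -- the user gives the 5-7 distribution parameters
  explicitly (:class:`SRFDistribution`).
* **Dynamic Fit** -- the parameters are evaluated from per-condition
  curves over SR-Ca2+ fitted to ensembles of the stochastic spatial cell
  model (:func:`dynamic_fit_map`).
* **General Dynamic** -- the parameters are generated from an intuitive
  user-level description of the SR-Ca2+ dependence
  (:class:`GeneralDynamicParams`, :func:`general_dynamic_map`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .waveform import SHAPE, SRFWaveform, min_plateau_peak_time_offset

__all__ = [
    "SRFDistribution",
    "DWFitParams",
    "GeneralDynamicParams",
    "DynamicFitCoefficients",
    "FIG11_BASELINE",
    "ti_cdf",
    "duration_cdf",
    "sample_ti",
    "sample_duration",
    "dw_from_md",
    "sample_tp",
    "sample_amplitudes",
    "sample_waveform",
    "general_dynamic_map",
    "dynamic_fit_map",
]

# Logistic scale relating a user-facing distribution "width" to the
# duration-CDF sigmoid; the same convention is reused when mapping the
# General Dynamic t_i width onto the k_F gradient parameters.
WIDTH_SCALE = 0.261

#: Minimum sampled duration (ms); avoids degenerate zero-length waveforms.
LAM_FLOOR = 10.0

#: t_p support within the event: [t_i + TP_MIN_OFFSET, t_f - TP_END_OFFSET].
TP_MIN_OFFSET = 25.0
TP_END_OFFSET = 52.0


class InvalidDistributionError(ValueError):
    pass


@dataclass
class SRFDistribution:
    """The 5-7 parameters defining the t_i and duration distributions.

    ``p_scr`` is the per-arming probability that an SCRE occurs at all.
    ``ti_sep``/``cf_ti_sep``/``k_f1``/``k_f2`` define the two-sigmoid
    initiation-time CDF; ``md``/``dw1``/``dw2`` the duration CDF.  When
    ``dw_mode == "from_md"`` the widths are derived from the median via
    :func:`dw_from_md` with the attached :class:`DWFitParams`.
    """

    p_scr: float
    ti_sep: float
    k_f1: float
    k_f2: float
    md: float
    dw1: float = 0.0
    dw2: float = 0.0
    cf_ti_sep: float = 0.4
    dw_mode: str = "explicit"
    dw_params: "DWFitParams | None" = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_scr <= 1.0):
            raise InvalidDistributionError(f"p_scr out of [0,1]: {self.p_scr}")
        if not (0.0 < self.cf_ti_sep < 1.0):
            raise InvalidDistributionError(f"cf_ti_sep out of (0,1): {self.cf_ti_sep}")
        if self.k_f1 <= 0 or self.k_f2 <= 0 or self.md <= 0:
            raise InvalidDistributionError("k_f1, k_f2, md must be positive")
        if self.dw_mode == "from_md":
            if self.dw_params is None:
                raise InvalidDistributionError("dw_mode='from_md' needs dw_params")
            dws = dw_from_md(self.md, self.dw_params)
            self.dw1, self.dw2 = dws["dw1"], dws["dw2"]
        if self.dw1 <= 0 or self.dw2 <= 0:
            raise InvalidDistributionError("dw1, dw2 must be positive")


@dataclass(frozen=True)
class DWFitParams:
    """Sigmoidal dependence of the duration-distribution widths on the median.

    ``dw = a_dw / (1 + exp(-(md - mid_dw)/k_dw)) + dw_min`` for each side.
    """

    a_dw1: float
    a_dw2: float
    mid_dw1: float
    mid_dw2: float
    k_dw1: float
    k_dw2: float
    dw1_min: float
    dw2_min: float

    def __post_init__(self) -> None:
        for name in ("a_dw1", "a_dw2", "mid_dw1", "mid_dw2", "k_dw1", "k_dw2",
                     "dw1_min", "dw2_min"):
            if getattr(self, name) <= 0:
                raise InvalidDistributionError(f"{name} must be positive")


@dataclass(frozen=True)
class GeneralDynamicParams:
    """User-level description of the SR-Ca2+ dependence of SCRE.

    ``casr_threshold`` (mM) is the SR-Ca2+ load above which whole-cell
    SCRE become possible; ``casr_p_range`` the load range over which the
    release probability rises from ~0 to ~1; ``casr_max`` the load above
    which the distributions saturate at their extreme (short/early)
    values.  The ``*_min``/``*_max`` pairs give the extremes of the
    separation point, median duration and distribution widths, and
    ``h_width`` the nonlinearity with which the widths shrink as the load
    rises.
    """

    casr_threshold: float
    casr_p_range: float
    casr_max: float
    ti_sep_min: float
    ti_sep_max: float
    ti_width_min: float
    ti_width_max: float
    md_min: float
    md_max: float
    lam_width_min: float
    lam_width_max: float
    h_width: float = 2.5
    cf_ti_sep: float = 0.4

    def __post_init__(self) -> None:
        if not self.casr_max > self.casr_threshold + self.casr_p_range:
            raise InvalidDistributionError(
                "need casr_max > casr_threshold + casr_p_range"
            )
        for lo, hi in (
            (self.ti_sep_min, self.ti_sep_max),
            (self.ti_width_min, self.ti_width_max),
            (self.md_min, self.md_max),
            (self.lam_width_min, self.lam_width_max),
        ):
            if lo > hi or lo <= 0:
                raise InvalidDistributionError("need 0 < min <= max for paired fields")
        if self.h_width <= 0:
            raise InvalidDistributionError("h_width must be positive")


#: Baseline General Dynamic parameter set used for the re-entry/SCRE
#: coupling studies (single delayed focal excitation regime).
FIG11_BASELINE = GeneralDynamicParams(
    casr_threshold=1.25,
    casr_p_range=0.05,
    casr_max=1.525,
    ti_sep_min=300.0,
    ti_sep_max=870.0,
    ti_width_min=200.0,
    ti_width_max=1000.0,
    md_min=150.0,
    md_max=600.0,
    lam_width_min=70.0,
    lam_width_max=300.0,
    h_width=2.5,
)


# ---------------------------------------------------------------------------
# CDFs and their analytic inverses
# ---------------------------------------------------------------------------

def ti_cdf(t, d: SRFDistribution):
    """Two-sigmoid cumulative frequency of the initiation time.

    Continuous at ``ti_sep`` where it equals ``cf_ti_sep``; the lower
    branch has gradient parameter ``k_f1``, the upper ``k_f2``.
    """
    t = np.asarray(t, dtype=float)
    cf, s = d.cf_ti_sep, d.ti_sep
    lower = 2.0 * cf / (1.0 + np.exp(-(t - s) / d.k_f1))
    upper = 2.0 * (1.0 - cf) / (1.0 + np.exp(-(t - s) / d.k_f2)) - 1.0 + 2.0 * cf
    out = np.where(t < s, lower, upper)
    return out if out.ndim else float(out)


def duration_cdf(lam, d: SRFDistribution):
    """Two-sigmoid cumulative frequency of the duration, joined at the median."""
    lam = np.asarray(lam, dtype=float)
    lo = 1.0 / (1.0 + np.exp(-(lam - d.md) / (WIDTH_SCALE * d.dw1)))
    hi = 1.0 / (1.0 + np.exp(-(lam - d.md) / (WIDTH_SCALE * d.dw2)))
    out = np.where(lam < d.md, lo, hi)
    return out if out.ndim else float(out)


def _clip_u(u):
    return np.clip(np.asarray(u, dtype=float), 1e-12, 1.0 - 1e-12)


def sample_ti(u, d: SRFDistribution):
    """Inverse-transform sample of the initiation time (ms, clamped >= 0).

    ``u`` is a uniform(0,1) draw (scalar or array).  Times are relative
    to the reference (arming) event.
    """
    u = _clip_u(u)
    cf, s = d.cf_ti_sep, d.ti_sep
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = s - d.k_f1 * np.log(2.0 * cf / u - 1.0)
        upper = s - d.k_f2 * np.log(2.0 * (1.0 - cf) / (u + 1.0 - 2.0 * cf) - 1.0)
    out = np.where(u < cf, lower, upper)
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def sample_duration(u, d: SRFDistribution):
    """Inverse-transform sample of the duration (ms, floored at 10 ms)."""
    u = _clip_u(u)
    term = np.log(1.0 / u - 1.0)  # positive below the median, negative above
    out = np.where(
        u < 0.5,
        d.md - WIDTH_SCALE * d.dw1 * term,
        d.md - WIDTH_SCALE * d.dw2 * term,
    )
    out = np.maximum(out, LAM_FLOOR)
    return out if out.ndim else float(out)


def dw_from_md(md: float, p: DWFitParams) -> dict:
    """Duration-distribution widths as sigmoidal functions of the median."""
    if md <= 0:
        raise InvalidDistributionError(f"md must be positive, got {md}")
    dw1 = p.a_dw1 / (1.0 + math.exp(-(md - p.mid_dw1) / p.k_dw1)) + p.dw1_min
    dw2 = p.a_dw2 / (1.0 + math.exp(-(md - p.mid_dw2) / p.k_dw2)) + p.dw2_min
    return {"dw1": dw1, "dw2": dw2}


def sample_tp(u, t_i, lam):
    """Peak time, uniform on [t_i + 25, t_f - 52] ms.

    For events too short to hold that window (``lam < 77`` ms) the peak
    falls back to the midpoint of the event.
    """
    u = np.asarray(u, dtype=float)
    t_i = np.asarray(t_i, dtype=float)
    lam = np.asarray(lam, dtype=float)
    window = lam - TP_MIN_OFFSET - TP_END_OFFSET
    out = np.where(
        window > 0.0,
        t_i + TP_MIN_OFFSET + u * np.maximum(window, 0.0),
        t_i + lam / 2.0,
    )
    return out if out.ndim else float(out)


def sample_amplitudes(u1, u2, lam):
    """Peak/plateau amplitudes: expectation from duration plus uniform jitter.

    ``n_peak = <n_peak>(lam) + 0.05*(u1 - 0.5)``;
    ``n_plateau = (1 + 0.25*(u2 - 0.5)) * <n_plateau>(lam)`` (plateau
    events only).  Clipped to [0, 1] with ``n_plateau <= n_peak``.
    """
    scalar = np.isscalar(lam)
    u1 = np.atleast_1d(np.asarray(u1, dtype=float))
    u2 = np.atleast_1d(np.asarray(u2, dtype=float))
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    exp_peak = np.minimum(692.99 * lam ** (-1.6) + 0.059, 1.0)
    n_peak = np.clip(exp_peak + 0.05 * (u1 - 0.5), 0.0, 1.0)
    plateau = lam > SHAPE.morphology_threshold
    with np.errstate(over="ignore"):
        exp_plat = np.where(
            plateau,
            np.minimum(31.09 * (0.01 * np.maximum(lam, 1.0)) ** (-7.39) + 0.034, 1.0),
            0.0,
        )
    n_plateau = np.clip((1.0 + 0.25 * (u2 - 0.5)) * exp_plat, 0.0, 1.0)
    n_plateau = np.minimum(n_plateau, n_peak)
    if scalar:
        return {"n_peak": float(n_peak[0]), "n_plateau": float(n_plateau[0])}
    return {"n_peak": n_peak, "n_plateau": n_plateau}


def sample_waveform(rng: np.random.Generator, d: SRFDistribution) -> SRFWaveform:
    """Draw one complete SRF waveform (five uniform draws).

    Deterministic given the generator state.  For plateau events whose
    sampled peak time would place the embedded spike before the plateau's
    rising edge, the peak is shifted right to the minimum admissible
    offset so that sampling is total.
    """
    u = rng.random(5)
    t_i = sample_ti(u[0], d)
    lam = sample_duration(u[1], d)
    t_p = sample_tp(u[2], t_i, lam)
    amps = sample_amplitudes(u[3], u[4], lam)
    if lam > SHAPE.morphology_threshold:
        t_p = max(t_p, t_i + min_plateau_peak_time_offset())
    return SRFWaveform(
        t_i=float(t_i),
        lam=float(lam),
        t_p=float(t_p),
        n_peak=amps["n_peak"],
        n_plateau=amps["n_plateau"],
    )


# ---------------------------------------------------------------------------
# General Dynamic mode: SR-Ca2+ -> distribution
# ---------------------------------------------------------------------------

# Release-probability logistic: p = 2% at the threshold and 98% at
# threshold + p_range, i.e. midpoint threshold + p_range/2 and slope
# p_range / (2 ln 49).
_P_LOGISTIC_SPAN = 2.0 * math.log(49.0)


def general_dynamic_p_scr(casr, p: GeneralDynamicParams):
    casr = np.asarray(casr, dtype=float)
    mid = p.casr_threshold + 0.5 * p.casr_p_range
    k = p.casr_p_range / _P_LOGISTIC_SPAN
    out = 1.0 / (1.0 + np.exp(np.clip(-(casr - mid) / k, -500.0, 500.0)))
    return out if out.ndim else float(out)


def general_dynamic_map(casr: float, p: GeneralDynamicParams) -> SRFDistribution:
    """Evaluate the General Dynamic model at one SR-Ca2+ load (mM).

    The separation point and median duration fall linearly from their
    maxima at ``casr_threshold`` (the lowest load of interest) to their
    minima at ``casr_max``; the distribution widths shrink between their
    extremes with nonlinearity ``x**h_width``.  The width parameters map
    onto the CDF gradient parameters via the shared 0.261 logistic scale
    for t_i, and directly onto ``dw1``/``dw2`` for the duration.
    """
    casr_min = p.casr_threshold
    x = float(np.clip((casr - casr_min) / (p.casr_max - casr_min), 0.0, 1.0))
    ti_sep = p.ti_sep_max - (p.ti_sep_max - p.ti_sep_min) * x
    md = p.md_max - (p.md_max - p.md_min) * x
    xw = x ** p.h_width
    ti_width = p.ti_width_max - (p.ti_width_max - p.ti_width_min) * xw
    lam_width = p.lam_width_max - (p.lam_width_max - p.lam_width_min) * xw
    k_f = WIDTH_SCALE * ti_width
    return SRFDistribution(
        p_scr=float(general_dynamic_p_scr(casr, p)),
        ti_sep=ti_sep,
        cf_ti_sep=p.cf_ti_sep,
        k_f1=k_f,
        k_f2=k_f,
        md=md,
        dw1=lam_width,
        dw2=lam_width,
    )


# ---------------------------------------------------------------------------
# Dynamic Fit mode: fitted per-condition curves over SR-Ca2+
# ---------------------------------------------------------------------------

_CONDITION_ALIASES = {
    "control": "control",
    "r_cru_cru": "r_cru_cru",
    "r_cru-cru": "r_cru_cru",
    "rcru": "r_cru_cru",
    "r_serca_ncx": "r_serca_ncx",
    "r_serca/ncx": "r_serca_ncx",
    "rserca": "r_serca_ncx",
}

CONDITIONS = ("control", "r_cru_cru", "r_serca_ncx")


def normalise_condition(name: str) -> str:
    key = name.strip().lower()
    if key not in _CONDITION_ALIASES:
        raise KeyError(f"unknown condition {name!r}; expected one of {CONDITIONS}")
    return _CONDITION_ALIASES[key]


def _eval_curve(family: str, coeffs, casr):
    c = coeffs
    if family == "logistic_inc":
        # rising logistic in [0,1]: p(casr) for release probability
        return 1.0 / (1.0 + math.exp(max(min(-(casr - c[0]) / max(c[1], 1e-9), 500), -500)))
    if family == "sigmoid_dec":
        # y_min + A * (1 - logistic): decreasing with casr
        return c[0] + c[1] / (1.0 + math.exp(max(min((casr - c[2]) / max(c[3], 1e-9), 500), -500)))
    if family == "constant":
        return c[0]
    raise KeyError(f"unknown curve family {family!r}")


@dataclass
class DynamicFitCoefficients:
    """Per-condition coefficient tables mapping SR-Ca2+ to SRF parameters.

    ``tables[condition][parameter] = (family, (c0, c1, c2, c3))`` where
    parameter ranges over p_scr, ti_sep, cf_ti_sep, k_f1, k_f2, md; the
    fitted SR-Ca2+ range is recorded per condition for clamping.
    """

    tables: dict
    casr_range: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for cond, params in self.tables.items():
            lo, hi = self.casr_range.get(cond, (float("nan"), float("nan")))
            for name, (family, coeffs) in params.items():
                cc = list(coeffs) + [0.0] * (4 - len(coeffs))
                rows.append(
                    {"condition": cond, "parameter": name, "family": family,
                     "c0": cc[0], "c1": cc[1], "c2": cc[2], "c3": cc[3],
                     "casr_lo": lo, "casr_hi": hi}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DynamicFitCoefficients":
        import pandas as pd

        df = pd.read_csv(path)
        tables: dict = {}
        casr_range: dict = {}
        for _, row in df.iterrows():
            cond = normalise_condition(str(row["condition"]))
            tables.setdefault(cond, {})[row["parameter"]] = (
                str(row["family"]),
                (float(row["c0"]), float(row["c1"]), float(row["c2"]), float(row["c3"])),
            )
            casr_range[cond] = (float(row["casr_lo"]), float(row["casr_hi"]))
        return cls(tables=tables, casr_range=casr_range)

    def threshold(self, condition: str) -> float:
        """SR-Ca2+ at which the fitted release probability reaches 0.5."""
        cond = normalise_condition(condition)
        family, c = self.tables[cond]["p_scr"]
        if family != "logistic_inc":
            raise KeyError("p_scr curve must be logistic_inc")
        return c[0]


def default_dynamic_fit_coefficients() -> DynamicFitCoefficients:
    """Coefficients shipped with the package (see srfsim/data).

    Regenerated by running the fitting pipeline over ensembles of the
    bundled stochastic spatial cell model (scripts in the repository);
    users may override with their own coefficient CSV.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("srfsim").joinpath("data/dynamic_fit_coefficients.csv")
    ) as path:
        return DynamicFitCoefficients.from_csv(path)


def dynamic_fit_map(
    casr: float,
    coeffs: DynamicFitCoefficients,
    condition: str = "control",
    dw_params: DWFitParams | None = None,
) -> SRFDistribution:
    """Evaluate the Dynamic Fit curves at one SR-Ca2+ load (mM).

    SR-Ca2+ outside the fitted range is clamped (with a warning) before
    evaluation.  Duration widths are derived from the fitted median via
    the condition-independent :func:`dw_from_md` relationship when
    ``dw_params`` is given, otherwise from the fitted k-width curves.
    """
    import warnings

    cond = normalise_condition(condition)
    table = coeffs.tables[cond]
    lo, hi = coeffs.casr_range.get(cond, (-math.inf, math.inf))
    c = float(casr)
    if not (lo <= c <= hi) and math.isfinite(lo):
        warnings.warn(
            f"SR-Ca2+ {c:.3f} mM outside fitted range [{lo:.3f}, {hi:.3f}] "
            f"for condition {cond}; clamping",
            stacklevel=2,
        )
        c = min(max(c, lo), hi)

    def ev(name):
        family, cc = table[name]
        return _eval_curve(family, cc, c)

    md = max(ev("md"), LAM_FLOOR)
    if dw_params is not None:
        dws = dw_from_md(md, dw_params)
        dw1, dw2 = dws["dw1"], dws["dw2"]
    elif "dw1" in table and "dw2" in table:
        dw1, dw2 = max(ev("dw1"), 1.0), max(ev("dw2"), 1.0)
    else:
        dw1 = dw2 = max(0.3 * md, 10.0)
    return SRFDistribution(
        p_scr=float(np.clip(ev("p_scr"), 0.0, 1.0)),
        ti_sep=max(ev("ti_sep"), 1.0),
        cf_ti_sep=float(np.clip(ev("cf_ti_sep"), 0.05, 0.95)),
        k_f1=max(ev("k_f1"), 1.0),
        k_f2=max(ev("k_f2"), 1.0),
        md=md,
        dw1=dw1,
        dw2=dw2,
    )
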