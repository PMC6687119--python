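"""Derivation pipeline: waveform features -> distribution fits -> SR-Ca2+ curves.

Ensembles of whole-cell open-RyR traces (from the stochastic spatial cell
model, or synthetic) are reduced to per-event features, the two-sigmoid
initiation-time and duration CDF models are fitted, the width-median and
amplitude-duration relationships are fitted, and finally smooth curves
over SR-Ca2+ are built for the Dynamic Fit parameterisation mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .sampling import (
    WIDTH_SCALE,
    DWFitParams,
    DynamicFitCoefficients,
    SRFDistribution,
    normalise_condition,
)
from .waveform import SHAPE

__all__ = [
    "EventFeatures",
    "DETECT_ON",
    "DETECT_OFF",
    "extract_event_features",
    "fit_ti_cdf",
    "fit_duration_dist",
    "fit_dw_vs_md",
    "fit_amplitude_duration",
    "build_dynamic_fit",
]

# Whole-cell open-fraction thresholds defining an event; shared with the
# spatial model's detector so that fitted features are consistent.
DETECT_ON = 0.02
DETECT_OFF = 0.005


@dataclass
class EventFeatures:
    """Features of one detected SCRE in a whole-cell open-RyR trace."""

    t_i: float
    t_f: float
    t_p: float
    lam: float
    n_peak: float
    n_plateau: float | None
    morphology: str
    run_id: int = -1
    casr: float = float("nan")
    n_events: int = 1


def extract_event_features(
    t: np.ndarray,
    n_ryr_o: np.ndarray,
    run_id: int = -1,
    casr: float = float("nan"),
) -> EventFeatures | None:
    """Reduce a uniformly sampled open-RyR trace to event features.

    ``t_i`` is the first up-crossing of 0.02, ``t_f`` the last
    down-crossing of 0.005 within the first event's envelope, ``t_p`` the
    argmax.  For events longer than the 300 ms morphology threshold the
    plateau level is the median over the middle 50% of [t_i, t_f].
    Returns ``None`` when no crossing occurs; if several disjoint events
    are present the first is returned with ``n_events`` flagging the count.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(n_ryr_o, dtype=float)
    above = y >= DETECT_ON
    if not above.any():
        return None
    i_on = int(np.argmax(above))
    t_i = t[i_on]
    # end of first event: first index after onset where the trace stays
    # below DETECT_OFF; later re-crossings count as further events
    below = y < DETECT_OFF
    i = i_on
    n = len(y)
    while i < n and not below[i]:
        i += 1
    i_off = i  # first sample below the off threshold (or n)
    n_events = 1
    j = i_off
    while j < n:
        if y[j] >= DETECT_ON:
            n_events += 1
            while j < n and y[j] >= DETECT_OFF:
                j += 1
        else:
            j += 1
    i_end = min(i_off, n - 1)
    t_f = t[i_end]
    seg = slice(i_on, i_end + 1)
    i_p = i_on + int(np.argmax(y[seg]))
    lam = t_f - t_i
    if lam <= 0:
        return None
    morphology = "plateau" if lam > SHAPE.morphology_threshold else "spike"
    n_plateau = None
    if morphology == "plateau":
        lo = t_i + 0.25 * lam
        hi = t_i + 0.75 * lam
        mid = (t >= lo) & (t <= hi)
        if mid.any():
            n_plateau = float(np.median(y[mid]))
    return EventFeatures(
        t_i=float(t_i),
        t_f=float(t_f),
        t_p=float(t[i_p]),
        lam=float(lam),
        n_peak=float(y[i_p]),
        n_plateau=n_plateau,
        morphology=morphology,
        run_id=run_id,
        casr=casr,
        n_events=n_events,
    )


def _ti_cdf_model(t, ti_sep, cf, k1, k2):
    t = np.asarray(t, dtype=float)
    lower = 2.0 * cf / (1.0 + np.exp(-(t - ti_sep) / k1))
    upper = 2.0 * (1.0 - cf) / (1.0 + np.exp(-(t - ti_sep) / k2)) - 1.0 + 2.0 * cf
    return np.where(t < ti_sep, lower, upper)


def fit_ti_cdf(ti_samples) -> dict:
    """Fit the two-sigmoid CDF model to initiation-time samples.

    Nonlinear least squares of the empirical CDF with all four parameters
    free; continuity at the separation point is built into the model.
    Returns a dict with the parameters, a convergence flag, and the KS
    distance between the fit and the empirical CDF.
    """
    ti = np.sort(np.asarray(ti_samples, dtype=float))
    n = len(ti)
    if n < 30:
        raise ValueError(f"need >= 30 samples, got {n}")
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    spread = max(float(ti[-1] - ti[0]), 1.0)
    bounds = ([ti[0] - spread, 0.01, 1e-3, 1e-3], [ti[-1] + spread, 0.99, 10 * spread, 10 * spread])
    converged = True
    # multistart over candidate separation quantiles (the objective has
    # distinct basins when the two branch widths differ strongly)
    best, best_sse = None, np.inf
    for q in (0.25, 0.40, 0.55):
        p0 = [float(np.percentile(ti, 100 * q)), q, spread / 8.0, spread / 8.0]
        try:
            cand, _ = optimize.curve_fit(
                _ti_cdf_model, ti, ecdf, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((_ti_cdf_model(ti, *cand) - ecdf) ** 2))
        if sse < best_sse:
            best, best_sse = cand, sse
    if best is None:
        converged = False
        res = optimize.least_squares(
            lambda p: _ti_cdf_model(ti, *p) - ecdf,
            [float(np.percentile(ti, 40)), 0.4, spread / 8.0, spread / 8.0],
            bounds=bounds)
        best = res.x
    popt = best
    # the model family has a soft ridge: moving the separation point along
    # the curve trades off against the frequency at that point.  Refit with
    # the separation frequency tied to its definition (the empirical CDF at
    # ti_sep), which collapses the ridge without constraining the shape.
    def tied(p3):
        s, k1, k2 = p3
        cf = float(np.interp(s, ti, ecdf))
        cf = min(max(cf, 0.01), 0.99)
        return _ti_cdf_model(ti, s, cf, k1, k2) - ecdf

    res = optimize.least_squares(
        tied, [popt[0], popt[2], popt[3]],
        bounds=([bounds[0][0], bounds[0][2], bounds[0][3]],
                [bounds[1][0], bounds[1][2], bounds[1][3]]))
    s, k1, k2 = res.x
    cf = min(max(float(np.interp(s, ti, ecdf)), 0.01), 0.99)
    popt = [s, cf, k1, k2]
    ks = float(np.max(np.abs(_ti_cdf_model(ti, *popt) - ecdf)))
    return {
        "ti_sep": float(popt[0]),
        "cf_ti_sep": float(popt[1]),
        "k_f1": float(popt[2]),
        "k_f2": float(popt[3]),
        "converged": converged,
        "ks": ks,
    }


def fit_duration_dist(lam_samples, dw_floor: float = 1.0) -> dict:
    """Fit the duration distribution: median plus per-side widths.

    The median is the sample median by definition; each width is a
    one-parameter least-squares fit of the corresponding half of the
    empirical CDF against its sigmoid.
    """
    lam = np.sort(np.asarray(lam_samples, dtype=float))
    n = len(lam)
    if n < 30:
        raise ValueError(f"need >= 30 samples, got {n}")
    md = float(np.median(lam))
    ecdf = (np.arange(1, n + 1) - 0.5) / n

    def side_fit(mask):
        x, f = lam[mask], ecdf[mask]
        if len(x) < 3 or np.ptp(x) < 1e-9:
            return dw_floor, True
        def resid(logdw):
            dw = math.exp(logdw[0])
            return 1.0 / (1.0 + np.exp(-(x - md) / (WIDTH_SCALE * dw))) - f
        res = optimize.least_squares(resid, [math.log(max(np.ptp(x), dw_floor))])
        return max(math.exp(res.x[0]), dw_floor), False

    dw1, deg1 = side_fit(lam < md)
    dw2, deg2 = side_fit(lam >= md)
    return {"md": md, "dw1": dw1, "dw2": dw2, "degenerate": deg1 or deg2}


def _dw_sigmoid(md, a, mid, k, dmin):
    return a / (1.0 + np.exp(-(np.asarray(md, dtype=float) - mid) / k)) + dmin


def fit_dw_vs_md(md_values, dw1_values, dw2_values) -> DWFitParams:
    """Fit the sigmoidal width-median relationship for both sides."""
    md = np.asarray(md_values, dtype=float)
    if len(md) < 5:
        raise ValueError("need >= 5 (md, dw) points")

    def one_side(dw):
        dw = np.asarray(dw, dtype=float)
        span = max(float(np.ptp(dw)), 1e-6)
        p0 = [span if span > 1e-3 else 1e-3, float(np.median(md)),
              max(float(np.ptp(md)) / 4.0, 1.0), max(float(dw.min()), 1e-3)]
        lo = [1e-6, md.min() - np.ptp(md) * 2 - 1, 1e-2, 1e-6]
        hi = [10 * span + 1, md.max() + np.ptp(md) * 2 + 1, 10 * max(np.ptp(md), 1.0), dw.max() + 1]
        try:
            popt, _ = optimize.curve_fit(_dw_sigmoid, md, dw, p0=p0,
                                         bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            popt = p0
        return popt

    a1, m1, k1, d1 = one_side(dw1_values)
    a2, m2, k2, d2 = one_side(dw2_values)
    return DWFitParams(
        a_dw1=float(max(a1, 1e-6)), a_dw2=float(max(a2, 1e-6)),
        mid_dw1=float(max(m1, 1e-6)), mid_dw2=float(max(m2, 1e-6)),
        k_dw1=float(max(k1, 1e-6)), k_dw2=float(max(k2, 1e-6)),
        dw1_min=float(max(d1, 1e-6)), dw2_min=float(max(d2, 1e-6)),
    )


def _power_law(lam, a, b, c):
    return a * np.asarray(lam, dtype=float) ** (-b) + c


def fit_amplitude_duration(lam_values, n_peak_values, trim: float = 0.05) -> dict:
    """Fit the amplitude-duration power law ``a * lam**-b + c``.

    Near-threshold low-amplitude outliers are removed by a residual-based
    trim: after an initial fit, the ``trim`` fraction of points with the
    most negative residuals is discarded and the fit repeated.
    """
    lam = np.asarray(lam_values, dtype=float)
    pk = np.asarray(n_peak_values, dtype=float)
    if len(lam) < 20:
        raise ValueError("need >= 20 pairs")
    if lam.max() / max(lam.min(), 1e-9) < 2.0:
        raise ValueError("duration spread must be >= 2x")

    def do_fit(x, y):
        p0 = [max((y.max() - y.min()) * x.min() ** 1.6, 1e-3), 1.6, max(y.min(), 0.0)]
        lo = [0.0, 0.05, 0.0]
        hi = [1e7, 8.0, 1.0]
        try:
            popt, _ = optimize.curve_fit(_power_law, x, y, p0=p0,
                                         bounds=(lo, hi), maxfev=20000)
            return popt, True
        except RuntimeError:
            return np.array(p0), False

    popt, ok = do_fit(lam, pk)
    if trim > 0 and len(lam) >= 40:
        resid = pk - _power_law(lam, *popt)
        keep = resid >= np.quantile(resid, trim)
        popt, ok = do_fit(lam[keep], pk[keep])
    resid = pk - _power_law(lam, *popt)
    return {"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2]),
            "rms": float(np.sqrt(np.mean(resid**2))), "converged": ok}


# ---------------------------------------------------------------------------
# Dynamic Fit construction over an SR-Ca2+ ladder
# ---------------------------------------------------------------------------

def _fit_logistic_inc(x, p):
    """Rising logistic fit for release probability vs SR-Ca2+."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    mid0 = float(np.interp(0.5, np.clip(p, 1e-3, 1 - 1e-3), x)) if p.max() > p.min() else float(np.mean(x))
    k0 = max(float(np.ptp(x)) / 8.0, 1e-3)

    def model(x, mid, k):
        return 1.0 / (1.0 + np.exp(-(x - mid) / k))

    try:
        popt, _ = optimize.curve_fit(
            model, x, p, p0=[mid0, k0],
            bounds=([x.min() - np.ptp(x) - 1, 1e-4], [x.max() + np.ptp(x) + 1, 10.0]),
            maxfev=20000,
        )
    except RuntimeError:
        popt = [mid0, k0]
    return ("logistic_inc", (float(popt[0]), float(popt[1]), 0.0, 0.0))


def _fit_sigmoid_dec(x, y):
    """Decreasing sigmoid fit ``y_min + A * (1 - logistic)`` for ti_sep/md/k."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    span = max(float(np.ptp(y)), 1e-6)

    def model(x, ymin, a, mid, k):
        return ymin + a / (1.0 + np.exp((x - mid) / k))

    p0 = [max(float(y.min()), 1e-6), span, float(np.mean(x)), max(float(np.ptp(x)) / 4.0, 1e-3)]
    lo = [0.0, 0.0, x.min() - np.ptp(x) - 1, 1e-4]
    hi = [float(y.max()) + 1, 10 * span + 1, x.max() + np.ptp(x) + 1, 10.0]
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError:
        popt = p0
    return ("sigmoid_dec", tuple(float(v) for v in popt))


def build_dynamic_fit(ensemble, condition: str = "control") -> DynamicFitCoefficients:
    """Build Dynamic Fit coefficient curves from an SR-Ca2+ ladder ensemble.

    ``ensemble`` is a long-format DataFrame with columns
    ``run_id, condition, casr, t, n_ryr_o`` (the spatial model's output
    format).  Per SR-Ca2+ level the release probability is the fraction
    of runs with a detected whole-cell event and the CDF models are
    fitted to the per-event features; smooth monotone curves are then
    fitted across SR-Ca2+.  Levels with no events contribute to the
    probability fit only.
    """
    import pandas as pd

    cond = normalise_condition(condition)
    df = ensemble[ensemble["condition"].map(lambda c: normalise_condition(str(c))) == cond]
    casr_levels = np.sort(df["casr"].unique())
    if len(casr_levels) < 4:
        raise ValueError("need >= 4 SR-Ca2+ levels")

    p_rows, param_rows = [], []
    for casr in casr_levels:
        level = df[df["casr"] == casr]
        feats = []
        n_runs = level["run_id"].nunique()
        for rid, run in level.groupby("run_id"):
            f = extract_event_features(
                run["t"].to_numpy(), run["n_ryr_o"].to_numpy(),
                run_id=int(rid), casr=float(casr),
            )
            if f is not None:
                feats.append(f)
        p_rows.append((float(casr), len(feats) / max(n_runs, 1)))
        if len(feats) >= 30:
            ti_fit = fit_ti_cdf([f.t_i for f in feats])
            lam_fit = fit_duration_dist([f.lam for f in feats])
            param_rows.append(
                {"casr": float(casr), **{k: ti_fit[k] for k in
                                         ("ti_sep", "cf_ti_sep", "k_f1", "k_f2")},
                 "md": lam_fit["md"], "dw1": lam_fit["dw1"], "dw2": lam_fit["dw2"]}
            )

    if len(param_rows) < 2:
        raise ValueError("too few SR-Ca2+ levels with enough events to fit")
    pr = pd.DataFrame(param_rows)
    x_p, y_p = zip(*p_rows)
    tables = {
        "p_scr": _fit_logistic_inc(np.array(x_p), np.array(y_p)),
        "ti_sep": _fit_sigmoid_dec(pr["casr"], pr["ti_sep"]),
        "md": _fit_sigmoid_dec(pr["casr"], pr["md"]),
        "k_f1": _fit_sigmoid_dec(pr["casr"], pr["k_f1"]),
        "k_f2": _fit_sigmoid_dec(pr["casr"], pr["k_f2"]),
        "dw1": _fit_sigmoid_dec(pr["casr"], pr["dw1"]),
        "dw2": _fit_sigmoid_dec(pr["casr"], pr["dw2"]),
        "cf_ti_sep": ("constant", (float(np.clip(pr["cf_ti_sep"].mean(), 0.05, 0.95)), 0.0, 0.0, 0.0)),
    }
    return DynamicFitCoefficients(
        tables={cond: tables},
        casr_range={cond: (float(casr_levels[0]), float(casr_levels[-1]))},
    )
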