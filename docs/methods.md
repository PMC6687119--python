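# Methods

This note documents the models implemented in `srfsim`, the parameter
choices that matter, the numerical schemes, and what the reduced-scale
simulations do and do not show.

## 1. Spontaneous release functions (SRF)

The SRF approximate the time course of the whole-cell open-RyR fraction
`N_RyR_O(t)` during one spontaneous calcium release event (SCRE).

**Spike morphology** (duration λ ≤ 300 ms): the product of a rising and a
falling sigmoid.  The printed product form of two rising sigmoids cannot
return to zero; we implement rise(t₁,k₁)·fall(t₂,k₂), the only form
consistent with the unimodal waveforms the function is meant to describe.
Centres sit midway between initiation/peak and peak/final time; widths are
k = 0.1689·(interval) + 0.00255 ms.  The additive 0.00255 is treated as
milliseconds (the same unit as k); at any realistic interval it is
negligible, and a floor of k ≥ 0.5 ms avoids numerically vertical edges
when the peak coincides with an endpoint.  A structural consequence of
k ∝ interval: the product peaks at ≈ 0.904·N_peak for every spike (each
sigmoid contributes ≈ 0.951 at t_p); N_peak is the waveform's amplitude
parameter, not its literal maximum.

**Plateau morphology** (λ > 300 ms): a plateau of height `N_plateau`
between edges at t_i + 17.5 ms and t_f − 17.5 ms (edge width 5.946 ms),
plus an embedded spike of additional height `N_peak − N_plateau` with a
50 ms upstroke (half-activation at t_p − 25 ms) and 35 ms decay (falling
edge at t_p + 17.5 ms).  If a sampled peak time would place the embedded
spike before the plateau's rising edge, the peak is shifted right to the
minimum admissible offset (t_i + 42.5 ms) so that sampling is total.

**Sampling.**  t_i and λ are drawn by inverse-transform sampling from
two-sigmoid cumulative-frequency models: for t_i the two branches join at
the separation point `ti_sep` where the CDF equals `cf_ti_sep` (default
0.4), with gradient parameters `k_F1`/`k_F2` either side; for λ they join
at the median `MD` with logistic scales 0.261·`DW1`/`DW2`.  The inverse
formulae are the analytic inversions of these CDFs (validated against the
CDFs by KS tests; the branch structure guarantees continuity at the joins).
The peak time is uniform on [t_i + 25, t_f − 52] ms, falling back to the
event midpoint for events shorter than 77 ms.  Amplitudes follow
⟨N_peak⟩ = 692.99 λ^−1.6 + 0.059 with ±0.025 uniform jitter and, for
plateau events, ⟨N_plateau⟩ = 31.09 (0.01 λ)^−7.39 + 0.034 with ±12.5%
multiplicative jitter; both are clipped to [0, 1] with
N_plateau ≤ N_peak.  Sampled t_i is clamped non-negative relative to the
arming event and λ is floored at 10 ms.  The strong negative
amplitude–duration correlation encodes the roughly conserved total Ca²⁺
released per event.

**Parameterisation modes.**
*Direct Control*: the user gives the 5–7 distribution parameters; the
controller (re)samples once per cellular excitation, referenced to the
excitation time.
*General Dynamic*: a user-level description of the SR-Ca²⁺ dependence.
The release probability is logistic with P = 0.02 at `CaSR_threshold` and
P = 0.98 at `CaSR_threshold + CaSR_P_range` (the stated "varies from 0 to
1" window, realised with 2%/98% endpoints so the curve is smooth and
total).  `CaSR_min` is identified with the threshold.  `ti_sep` and `MD`
fall linearly from their maxima at the threshold to their minima at
`CaSR_max`; the distribution widths shrink between their extremes with
nonlinearity x^`H_width` over the same normalised load x.  The t_i width
maps onto the gradient parameters through the same 0.261 logistic scale
used for durations, so "width" means the same thing for both
distributions.
*Dynamic Fit*: per-condition curves over SR-Ca²⁺ (rising logistic for the
release probability; decreasing four-parameter sigmoids for `ti_sep`,
`MD`, the k-widths and the duration widths; constant separation-point
frequency), fitted by the pipeline in §3 to ensembles of the stochastic
spatial model and shipped as a coefficient CSV.  Out-of-range SR-Ca²⁺ is
clamped to the fitted range with a warning.

## 2. The non-spatial (0D) cell model

A hybrid-minimal action-potential model in which every component
corresponds to a physiological current: fast sodium (m³hj gating), L-type
calcium (voltage gates d/f plus instantaneous Ca-dependent inactivation),
rapid and slow delayed-rectifier-like potassium currents, inward rectifier
I_K1, an electrogenic NCX (driven by cytosolic Ca²⁺), and small sodium and
calcium backgrounds.  Ca²⁺ handling uses five compartments — dyadic space
(DS), sub-space (SS), cytosol, network SR and junctional SR — with SERCA
uptake, SR leak, NSR→JSR transfer and instantaneous buffering expressed as
constant fractional factors per compartment, so the buffer-weighted total
Ca²⁺ is exactly conserved when the sarcolemmal fluxes are closed.

Whole-cell release flux: `J_rel = N_RyR_O · g_RyR · ([Ca]_JSR − [Ca]_DS)`
(JSR in mM converted to µM), feeding the dyadic space.  Deterministic RyR
gating is a three-state scheme (closed → open → inactivated → closed) with
a steep (Hill 6) dyadic-Ca activation gated by JSR load, so a paced beat
triggers a full transient while no regenerative release occurs at
diastolic dyadic Ca²⁺ at any SR load.  Recovery from inactivation is
suppressed while dyadic Ca²⁺ is elevated, which makes release strictly
transient (without this the scheme has a second stable fixed point — a
persistent leak state).

Defaults were tuned to qualitative contracts, not to any published data
set: resting potential ≈ −83 mV stable over seconds; overshoot > 0 mV with
repolarisation below −70 mV; APD ordering atrial < epi < endo < M;
diastolic cytosolic Ca ≈ 0.1 µM with transients ≈ 1 µM; end-diastolic SR
load monotone in pacing rate (≈ 1.24 mM at BCL 300 ms vs ≈ 0.76 mM at
600 ms in control) and strongly increased by the pro-arrhythmic condition
scalings (ISO: SERCA ×1.75, I_CaL ×1.5; R_SERCA/NCX: SERCA ×1.5, NCX ×0.5,
I_K1 ×0.7; the R_CRU-CRU condition acts purely through the SRF
parameterisation in the 0D model).  The sodium-channelopathy variant
scales g_Na by 0.30 and shifts the inactivation steady state by +5 mV.
NCX senses cytosolic (not sub-space) Ca²⁺; this sets the DAD scale —
injected releases depolarise the cell by a few mV at N_peak ≈ 0.05,
grading smoothly to triggered action potentials at N_peak ≈ 0.3 (lower
with reduced I_K1, reproducing the resting-potential mechanism of I_K1's
pro-arrhythmic role).

**SRF controller** (per cell): after an action potential, once the RyR
inactivation occupancy recovers below 0.2, the controller evaluates the
distribution at the current SR-Ca²⁺, draws the release Bernoulli and, if
release occurs, samples a waveform with times relative to the arming
moment.  If SR-Ca²⁺ drifts by more than 0.01 mM before initiation the
parameters are recalculated (with a fresh draw).  Parameters are never set
during excitation, so the SRF cannot interrupt ongoing CICR.  While a
waveform is active the cell's `N_RyR_O` is overridden by its analytical
value.  Direct Control instead arms at every excitation without the
recovery gate, discarding pending events scheduled past the next
excitation.

**Numerics**: forward Euler at dt = 0.02 ms for voltage and concentrations
(the constructor refuses larger steps), Rush–Larsen updates for the
gates.  Voltage-dependent gate functions are tabulated on a 0.05 mV grid
with linear interpolation; the tabulation error is far below the Euler
discretisation error (conduction velocity changes by < 2% when dt is
halved).

## 3. The reduced stochastic spatial cell model

A 3D grid of calcium release units (default 15×10×10; a minimum of
10×8×8 is enforced, and all thresholds are expressed in intensive units so
behaviour is robust to grid size above that minimum).  Each CRU holds 100
RyR channels as closed/open/inactivated *counts* advanced by binomial
transition draws (per-channel simulation is statistically equivalent at
these counts and far slower), its own DS/SS/cytosol/NSR/JSR compartments,
and 6-neighbour diffusive coupling of SS, cytosolic and NSR Ca²⁺.
Channel opening is dyadic-Ca-activated and gated by a sharp (12th-power)
JSR-load function — the SR-load threshold of the model; a small
load-gated spontaneous opening rate seeds sparks.  An NCX-like saturating
cytosolic efflux removes released Ca²⁺ (closed by the same switch as the
other sarcolemmal fluxes in conservation tests).  The membrane is not
simulated here: the protocols this model serves (partial Ca²⁺-clamp
ladder, SCRE ensemble generation) zero the excitatory currents by design
and consume only `N_RyR_O(t)`.

Rates were tuned to the qualitative contracts: below ≈ 0.9 mM the grid
shows only isolated sparks (whole-cell open fraction < 0.01 over 2 s);
near 0.95–1.0 mM single slow waves with long latency, long duration and
low amplitude; at 1.2–1.3 mM multiple rapid waves with short latency and
amplitudes ≈ 0.3–0.5.  Latency, duration and amplitude vary monotonically
with clamped load.  Tightened inter-CRU coupling (R_CRU-CRU, sub-space
coupling time constant halved) and reduced efflux with faster reuptake
(R_SERCA/NCX) both strengthen marginal near-threshold events, i.e. lower
the effective SR-load threshold.  The near-threshold events of this
desk-scale grid reach durations of ≈ 200–250 ms but rarely exceed the
300 ms plateau classification; the plateau branch of the waveform model
is therefore exercised with synthetically generated ensembles rather
than spatial-model output.

**Ca²⁺-clamp ladder**: at each step (2 s) intracellular and SR Ca²⁺ are
clamped, the SR level incrementing per step; the clamp is released when a
whole-cell event is detected (open fraction crossing 0.02; events end
below 0.005), after which concentrations evolve freely.

**Numerics**: dt = 0.02 ms (the stepper refuses rate·dt > 0.1; the
stiffest deterministic time constant, DS↔SS at 0.08 ms, remains stable
and accurate at this step).  Per-run seeding uses a dedicated
NumPy-seeded stream.

## 4. The derivation pipeline

`extract_event_features` reduces an `N_RyR_O(t)` trace to
(t_i, t_p, t_f, λ, N_peak, N_plateau): onset at the first up-crossing of
0.02, end at the following sustained down-crossing of 0.005 (thresholds
shared with the spatial model's detector), plateau level as the median
over the middle 50% of the event when λ > 300 ms; multiple disjoint
events are counted and the first returned.  `fit_ti_cdf` fits the
two-sigmoid CDF jointly (all four parameters free, continuity built into
the functional form, initialised at the empirical 40th percentile);
`fit_duration_dist` takes the median by definition and fits each width by
one-parameter least squares on its half of the empirical CDF;
`fit_dw_vs_md` and `fit_amplitude_duration` fit the width–median sigmoids
and the amplitude power law (the latter with a 5% residual-trimmed refit
to exclude near-threshold low-amplitude outliers).  `build_dynamic_fit`
assembles per-level release probabilities and distribution fits over an
SR-Ca²⁺ ladder and fits the smooth monotone curves of the Dynamic Fit
mode; levels with no events enter the probability fit only.

End-to-end, sampling 10⁴ waveforms from a known distribution and fitting
the ensemble recovers the distribution parameters within 5% (10% for the
width parameters).

## 5. Tissue

2D monodomain sheets: per-cell hybrid-minimal cells coupled by isotropic
voltage diffusion (5-point finite differences, face-averaged heterogeneous
D, no-flux boundaries; the constructor enforces the diffusion stability
bound).  Default dx = 0.25 mm with D = 0.04–0.1 mm²/ms (conduction
velocity ≈ 0.26–0.42 mm/ms; halving D slows conduction as expected, and
halving dx changes CV by a few percent at this resolution).  Every cell
carries an independent splitmix64/xorshift RNG stream, so stochastic
behaviour is reproducible bit-for-bit given (config, seed) and independent
of iteration order; with D = 0 each cell's trajectory is identical to the
isolated 0D model with the same stream.

**Heterogeneity assignment**: five SRF variants (baseline plus SR-Ca²⁺
thresholds shifted by ±0.05 and ±0.10 mM, all other parameters relative
to the threshold); `small` assigns 60% baseline / 10% each alternative,
`large` 20% each; censored variants reassign the higher-threshold (less
vulnerable) cells to baseline.

**Re-entry** is induced by phase distribution (per-cell states assigned
from one paced single-cell cycle by angle around a chosen core — an
immediate rotor) or by cross-field S1/S2 with an automated coupling-interval
scan.  Sustained rotors require AP shortening (rapid-delayed-rectifier
conductance ×4), reduced D, reduced I_K1 (×0.7 beyond the condition
scalings) and the ISO + R_SERCA/NCX loading conditions; on a 32×32–48×48
sheet a rotor at cycle ≈ 140–160 ms loads the SR to ≈ 1.4 mM mean within
1–2.5 s with strong spatial structure (SD ≈ 0.07–0.10 mM), the unexcited
core carrying the highest load and longest recovery time.  Termination is
a pragmatic parameter switch (rapid-rectifier block plus D restoration for
300 ms), after which the General Dynamic controllers fire focal
excitations wherever loading exceeded threshold.  Because the SR-Ca²⁺
decays toward its quiescent equilibrium during the ≈ 0.5 s the RyR
availability needs to recover after termination, the General Dynamic
threshold window for these experiments is set against the
post-termination load (≈ 1.05–1.15 mM), not the peak re-entrant load.

**Conduction block.**  *DAD-mediated*: homogeneous epicardial sheet with
the sodium channelopathy under ISO; two uniform edge stimuli at a 500 ms
coupling interval with dense, tightly timed sub-TA releases between them
(arriving at ≈ 75% of the interval).  The DADs (≈ 15–20 mV) inactivate
the impaired sodium current and the second wave fails; without SRF the
second stimulus propagates fully.  *Focal/repolarisation-gradient*: a
transmural ENDO:M:EPI (1:1:1) sheet whose M region carries an accentuated
plateau (L-type ×1.6 with 8× weaker Ca-dependent inactivation, rapid
rectifier ×0.15 — realising the long mid-myocardial APD that the simple
repolarising-current scaling cannot sustain against electrotonic
shortening in a 3.5 mm region); a reduced-I_K1 patch (×0.15) on the EPI
side fires an early (t_i ≈ 170 ms) focal wave that blocks against the
still-refractory M region, while an electrically homogeneous sheet
conducts the same focal wave to the far edge.

**Analysis** conventions: activation at the first up-crossing of −20 mV
(sentinel −1 for unexcited cells); recovery time is the time since the
last action potential whose Ca transient exceeded 0.35 µM (a
CICR-qualifying threshold of roughly half the paced transient); the
"longest-recovery region" is the top-decile contour of the recovery map; a
focal source is the centre of mass of the earliest-activated cluster
(within 4 ms of the first activation) of an excitation that expands by at
least 3 mm and does not enter as a whole-edge plane wave; symmetry is
classified on a ring of fixed radius around the source (≥ 85% of
directions activated within a tolerance window → symmetric).

## 6. What the synthetic data represent — and what they do not

All inputs are generated by the package itself.  The spatial CRU model is
a functional stand-in parameterised to contracts (threshold, monotone
latency/duration/amplitude trends, condition shifts), not a reproduction
of any measured rate set; the shipped Dynamic Fit tables inherit that
status.  Tissue experiments run at desk scale (20×20 to 48×48 cells,
0.5–3 s) with compressed action potentials, so quantities such as rotor
period, absolute SR loads and focal-excitation delays are
model-instance outcomes; what the tests establish are the mechanisms and
orderings — threshold behaviour, synchronisation against electrotonic
load, I_K1 modulation, block in the presence of the relevant gradient
only, localisation of foci to the maximal-recovery region, and the
heterogeneity contrast between re-entrant and paced loading.  In this
reduced model the post-re-entry localisation is essentially complete
(focal sources land inside the top-decile recovery contour), so the
distance–timing correlation reported for localisation batches degenerates
to its strong-localisation limit.  Real myocardium adds fibre anisotropy,
3D geometry, sub-cellular structural heterogeneity and far smaller
electrotonic space constants relative to cell size; none of these are
represented.

## 7. Known limitations

* The hybrid-minimal action potential is short (APD₉₀ ≈ 85–130 ms across
  cell types) and its transmural gradient is limited by electrotonic
  coupling in thin regions; the focal-block protocol therefore accentuates
  the M-cell plateau explicitly.
* The spatial model omits the sarcolemma and LTCC triggering; it cannot be
  paced, and near-threshold events rarely reach plateau durations.
* Fits are point estimates with residual diagnostics; no uncertainty
  quantification.
* The cross-field induction scan is coarse (bisection on the coupling
  interval with a simple activity criterion) and phase distribution is the
  reliable induction route at desk scale.
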