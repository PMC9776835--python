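# Methods

This note records the models, conventions and design choices behind
`ecisbarrier`, in the spirit of a package methods appendix: what is
computed, under which assumptions, with which defaults, and where the open
choices were resolved.

## Forward model

**Cell-free electrode.** The electrode–electrolyte interface is a
constant-phase element (CPE) in specific units, `Zn(ω) = A (jω)^−β` with
`A` in Ω·cm²·s^−β and `β ∈ (0, 1]`; `β = 1` reduces to an ideal capacitor.
The CPE is the standard empirical description of gold microelectrodes; no
electrode datasheet values exist for the modelled array, so the defaults
are a documented working point: `A = 5×10⁴`, `β = 0.95`, series
(solution + lead) resistance 300 Ω and active area 3.9×10⁻³ cm². These were
calibrated once so that a naked well reads ≈ 41 nF at 64 kHz, a confluent
vehicle well reads ≈ 2.4 kΩ at 4 kHz and ≈ 3.8 nF at 64 kHz — i.e. the
20 nF confluence criterion cleanly separates naked from covered
electrodes and the covered/naked resistance ratio peaks near 4 kHz, the
optimum analysis frequency for the barrier signal. All values are
configurable.

**Membranes.** The transcellular path is purely capacitive: apical and
basal membranes of capacitance `Cm` (µF/cm², per membrane) in series,
`Zm = 2/(jω Cm)`. No membrane conductance term is modelled.

**Cell-covered electrode.** The Giaever–Keese relation couples `Zn`, `Zm`,
the paracellular resistance `Rb` (Ω·cm²) and the cell–substrate constraint
parameter `α` (Ω^½·cm) through the quotient `(γ/2) I₀(γ)/I₁(γ)` with
`γ = α √(1/Zn + 1/Zm)` on the principal branch. Note on units: `α` is
sometimes printed with units Ω·cm^½; dimensional analysis of `γ`
(dimensionless) with `Zn, Zm` in Ω·cm² forces Ω^½·cm, which is what this
package uses and labels throughout.

Numerics: the Bessel quotient is evaluated with exponentially *scaled*
modified Bessel functions (`scipy.special.ive`), whose scale factors
cancel exactly in the ratio, so the quotient stays finite at large |γ|;
below |γ| = 10⁻³ the removable singularity at the origin is handled by the
series `1 + γ²/8` (truncation error < 10⁻¹³). The quotient is
independently cross-checked in the test suite against a 50-digit
power-series evaluation (mpmath) to 10⁻⁸ relative over |γ| ≤ 20 at all
complex arguments. At `Rb = α = 0` the covered impedance equals `Zn`
exactly (the layer is electrically invisible); at `Rb → ∞` it tends to
`Zn + Zm`.

**Well level.** Partial coverage mixes covered and naked area in
parallel: `Z_well = [φ/Zc + (1−φ)/Zn]⁻¹ / area + R_series`, with coverage
fraction `φ ∈ [0, 1]`. The measured reading is decomposed with the
series-equivalent convention: `R = Re Z`, `C = −1/(2πf · Im Z)`, defined
only in the capacitive regime (`Im Z < 0`); non-capacitive readings raise
an error carrying (well, time, frequency) context. The 1 µA excitation
current of the instrument is acquisition metadata; the model works in
impedance directly.

A known model property: |Z_well| grows monotonically with `Rb` only while
the paracellular term dominates (Rb up to ≈ 20 Ω·cm² on the default
electrode). Beyond that, current reroutes through the membranes, |Z|
saturates toward |Zn + Zm| and shows a sub-0.25% non-monotone ripple at
high frequency. The monotonicity test is therefore scoped to the
barrier-dominated regime.

## Inverse problem

Each time point of each well is fitted independently — no temporal
smoothing, matching instrument behaviour. The objective compares measured
and modelled spectra in log-ratio space: both the measured well and the
cell-free reference are reduced to series (R, C) per frequency, and the
fit minimises the squared residuals of `ln(R_meas/R_ref)` and
`ln(C_meas/C_ref)` against the same ratios predicted by the forward model
at full coverage (`φ = 1`; fitting assumes confluence, which the 20 nF
criterion establishes before treatment). Log-ratios make the objective
dimensionless, weight the R and C families equally and cancel
electrode-to-electrode gain. The exact objective of the vendor software is
proprietary; this is an informed reconstruction of standard practice, not
a claim about the vendor code.

Optimisation: bounded trust-region least squares (`scipy.optimize.
least_squares`, TRF) on `log₁₀(Rb, α, Cm)` with bounds 10⁻⁴–10³ Ω·cm²,
10⁻²–10² Ω^½·cm, 0.1–20 µF/cm², tolerances `xtol 10⁻¹²`/`ftol 10⁻¹⁴`. A
fixed 2×2×2 log-grid multi-start set (no RNG) is used for cold starts;
time courses warm-start each point from its predecessor and fall back to
the full start set when the warm fit's residual is anomalous relative to
the neighbouring point. Noiseless spectra are recovered to ≤ 0.1%
relative over the physiological box (Rb 0.5–50, α 2–20, Cm 0.5–4).

**The Rb = 0 rule.** A fitted Rb below `eps_rb` (default 0.05 Ω·cm²) is
indistinguishable from an absent barrier; the result is flagged
`rb_zero`, Rb is set to exactly 0 and α/Cm are reported as undefined —
empty cells in the output tables, never zeros. Boundary ties resolve in
favour of Rb = 0.

## Curve analytics

Treatment is applied at t = 0 and all normalization divides by the value
at t = 0 (the `Z_t/Z_0` convention); a curve whose reference value is zero
(an Rb curve already collapsed at t = 0) refuses normalization and is
analysed raw. AUC is the trapezoid on the sampled grid over the reporting
windows 0–2.5 h, 0–3.6 h and 0–30 h; early-terminated curves contribute
only their valid span, which is reported alongside the area. Endpoints
use the stored sample when the query time is on the grid and linear
interpolation otherwise; the 30 h endpoint is the last sample.

**Barrier-collapse timing.** "Rb becomes zero" is operationalized as the
earliest t > 0 with the curve ≤ eps and no later *rebound*. The fitted Rb
at a truly-zero barrier has an irreducible noise floor (the Cramér–Rao
bound of the per-point fit at 1% noise is σ(Rb) ≈ 0.13–0.33 Ω·cm²,
depending on α), so a strict "never again above eps" scan would be
dominated by isolated noise spikes over a 30 h record. A rebound is
therefore an excursion reaching `rebound_factor × eps` (default 5×, i.e.
0.25 on a normalized curve with eps 0.05) — an order of magnitude above
the noise floor yet half the size of the genuine low-dose-uncoupler
rebound, which peaks near 0.5 normalized. With `rebound_factor = 1` the
rule reduces to the strict scan; on clean curves the two agree. The
pipeline applies the rule to the normalized Rb curve, with eps in the
curve's own units. α and Cm curves are masked from the collapse time on
(curve termination), and an audit guarantees no α/Cm value is ever
reported at or after it.

Confluence detection declares a monolayer when the raw 64 kHz capacitance
has stayed below 20 nF continuously for a dwell of 2 h. Analysis
frequencies default to 4000 Hz (total resistance, near its optimum) and
64,000 Hz (capacitance/spreading), both overridable.

## Group statistics

Endpoint and AUC summaries are compared with a classical one-way ANOVA
(`(k−1, N−k)` df). Two post-hoc families are provided: Tukey HSD
(studentized range; the default, since multi-arm barrier studies report
Tukey in figure captions) and Bonferroni-corrected pairwise t-tests
(pooled variance by default, Welch by flag; adjusted p capped at 1).
Stars follow the conventional ladder, boundaries closed on the
significant side: `*` p ≤ 0.05, `**` p ≤ 0.01, `***` p ≤ 0.001,
`****` p ≤ 0.0001, `ns` above. The null calibration of the ANOVA is
tested empirically (type-I rate within [0.03, 0.07] at α = 0.05 over
1,000 seeded simulations).

LDH release is the background-corrected absorbance A490 − A680
(negative blank-level values are kept, flagged, never clamped),
normalized to the vehicle mean per timepoint before ANOVA + post hoc.
The kit's percent-cytotoxicity formula needs max-lysis controls and is
out of scope.

## Synthetic study generator

The generator emulates the study conditions end to end: 7 arms × 6 wells,
30 h horizon at 0.25 h steps, the 9-frequency octave grid, 1%
multiplicative Gaussian noise independently on Re and Im of every
reading, and a 5% lognormal well-to-well CV on the baseline (Rb, α, Cm)
(unit-mean multipliers; zero trajectory segments stay exactly zero). The
baseline state `Rb = 4 Ω·cm², α = 8 Ω^½·cm, Cm = 1.5 µF/cm²` is a
plausible endothelial working point, chosen once — no tabulated baselines
exist for these cells. Trajectories are monotone-cubic (PCHIP) ramps
through breakpoints: smooth, no overshoot, and pinned values (like
Rb ≡ 0) are hit exactly. Where the emulated narrative gives a range
(3.2–3.6 h, 28–30 h, 12–15 h, 5–10%), the default targets the midpoint.

Arm construction is structural, not tuned: the high-dose-uncoupler
plateau state (`Rb = 0`, elevated `Cm = 3 µF/cm²`) solves
`α` by root-finding so its noise-free 64 kHz normalized capacitance is
exactly 6.0× the vehicle baseline, and the low-dose-uncoupler α
trajectory passes through that same solved α at t = 20 h with identical
Cm from 10 h on — so the 6-fold plateau and the 20 h catch-up are
properties of the arm definitions, recovered (with noise) by the
analytics. The low-dose arm also carries the transient Rb rebound with
final collapse at 2.5 h and a 7% α dip recovering at 2.5 h; the
ATP-synthase arms collapse at 3.4 h (high dose, with the resistance
minimum near 13.5 h) or 29 h (low dose, after a mid-experiment dip and
recovery); the complex-I arms collapse immediately with dose-dependent
coverage loss through a transient spreading shoulder. The LDH plate adds
arm-specific effect sizes on a vehicle mean of 0.25 AU (sd 0.03,
background 0.05): +0.30 at 24 h for the two high-dose arms, with the
complex-I arms joining at 48 h (+0.20/+0.25) — calibrated to the
qualitative 24/48 h toxicity timeline, not to any printed effect size.

What the generator does *not* emulate: drift, electrode ageing,
frequency-correlated noise, well cross-talk, mechanistic dose–response
interpolation between the two printed concentrations, or the
pre-treatment growth phase (post-treatment arms start from confluence; a
coverage ramp exists only for testing confluence detection). Passing
tests therefore demonstrate correctness of the inference machinery under
idealized instrument statistics, not robustness to every artifact of
real recordings.

## Problem sizes and determinism

The default study is 45,738 impedance rows (42 wells × 9 frequencies ×
121 time points); the full-study fit is ~5,000 independent three-parameter
fits, and the end-to-end test suite fits the two arms whose timing
signatures are quantitative (12 wells). Identical seed and configuration
reproduce every table byte-for-byte; the fixed multi-start grid keeps the
fit deterministic without an RNG. Seeds for the impedance and LDH
simulations are derived from the single run seed.
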