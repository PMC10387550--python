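# Methods

This note documents the models, estimators and numerical choices behind
`aquaresp`, in the order the pipeline applies them, together with what
the synthetic generators do and do not emulate.

## Unit conversions

Dissolved oxygen is carried as % air saturation for whole-animal work
and µM for mitochondrial chambers; thresholds are reported in kPa.

* **Solubility.**  `o2_solubility(T, S)` evaluates the Garcia & Gordon
  (1992) combined fit (Benson–Krause scaling, mL L⁻¹ coefficient set,
  converted at 1.42905 mg mL⁻¹).  Valid −2…40 °C, 0…40 ppt; out-of-range
  inputs raise.  The test suite cross-checks it against the independent
  Benson–Krause air-saturation formula; the two published fits agree to
  0.03 % over 0–30 °C × 0–35 ppt.
* **Pressure.**  PO2 = (%sat/100) · 0.2095 · (P_bar − P_H2O(T)), with
  the Buck (1981) equation for water vapour pressure and a default
  barometric pressure of 101.325 kPa when unrecorded.  The inverse is
  exact; round trips are bijective to < 1e-9 relative.
* **Fish volume** defaults to body mass expressed in litres (1 g ≡ 1 mL
  of displaced water), overridable.

## Whole-animal respirometry

Per-cycle slopes are ordinary least squares over each contiguous
`measure` run after discarding a 30 s settle window (mixing transient;
config-exposed).  Cycles with R² < 0.90 — or undefined R² on a flat
trace — are flagged, never silently dropped.  Background respiration is
assumed to grow linearly between the pre- and post-run empty-chamber
rates; each cycle subtracts the value interpolated at its fit-window
midpoint.  Because an OLS slope over a symmetric uniform window equals
the derivative of a quadratic at the window centre, this correction is
exact for linearly drifting background.

SMR is the mean of the 10 lowest accepted values inside a caller-set
window; the recommended window runs from 1 h after chamber entry to the
start of the closed drawdown, so oxyconforming values cannot deflate the
estimate (which would make P_crit self-referential).  Ties are broken by
value then time (deterministic).  Leave-one-out outlier flagging (below)
is applied to the candidate low set so one artifactual near-zero cycle
cannot drag the mean.  MMR is the maximum accepted value, with its
timestamp; MS = MMR − SMR holds as an identity.  Q10 uses the
conventional ratio form (R₂/R₁)^(10/ΔT).

**Outlier rule.**  `flag_outliers` scores each value against the mean
and SD of the *other* values (leave-one-out).  A plain 2-SD rule cannot
flag a single gross outlier in small samples — the outlier inflates the
SD that judges it (the maximum attainable |z| in a sample of n is
(n−1)/√n, below 2 for n ≤ 5) — while the leave-one-out variant converges
to the plain rule for large n (≈ 4.6 % of a standard normal sample is
flagged at k = 2).

## Hypoxia tolerance

`drawdown_series` turns the closed-phase trace into (PO2, MO2) points
either by consecutive two-point chords paired with interval-midpoint PO2
(default; exact on clean data) or by OLS slopes over fixed-width bins
(recommended 120 s for noisy raw traces — differentiating a noisy trace
at the raw sample interval is hopeless).

`detect_pcrit` implements the SMR-intercept method: OLS through the
oxyconforming points, intersected with SMR.  Conforming points are the
maximal contiguous run at the low-PO2 end whose MO2 falls below
(1 − margin)·SMR, margin 5 % by default.  The contiguity rule excludes
spurious sub-SMR dips at high PO2; the margin keeps regulating-plateau
scatter out of the regression when the SMR estimate rides slightly above
the plateau — without it, a plateau sitting just under an over-estimated
SMR floods the fit and the intercept degenerates.  Both relaxations
(`smr_margin=0`, `contiguous_suffix=False`) are available for
sensitivity analysis.  Fewer than three conforming points, or a
non-positive fitted slope, is an error, not a number.  P_crit estimated
through a through-origin conforming line inherits the relative error of
the SMR estimate (ΔP_crit/P_crit ≈ ΔSMR/SMR); the estimator itself is
exact on noise-free input and has ≈ 0.07 kPa mean absolute error at 20
conforming points with σ = 5 mg kg⁻¹ h⁻¹ noise (1000-rep calibration).

`detect_ploe` is deliberately a lookup, not a detector: loss of
equilibrium is a behavioural observation, so the function linearly
interpolates the trace PO2 at the operator-annotated time.

`epoc_metrics` uses a threshold of 1.1 × SMR (fish recovering from
hypoxia keep some spontaneous activity and rarely settle to SMR
proper).  Recovery time is the first downward threshold crossing
sustained for ≥ 2 consecutive cycles (guards single-cycle dips), with
linear interpolation between the bracketing points.  The debt is the
trapezoidal area of the positive part of (MO2 − threshold); negative
excursions are clipped at zero so brief dips cannot cancel debt, and the
clipped fraction is reported (flag-worthy above 5 %).  A series that
never exceeds the threshold returns an all-zero flagged result; one that
never recrosses is right-censored with the debt integrated to the last
sample.  Trapezoidal error is second order: halving the sampling step
quarters the error, and 12-min sampling of an exponential recovery with
τ = 1 h is accurate to ≈ 0.3 %.

## Mitochondrial assays

JO2 is −d[O2]/dt · 1000 · V_chamber(mL) / m_tissue(mg), by default a
Savitzky–Golay local-quadratic derivative over a 20 s window (exact on
the linear declines of constant-flux states; raw central difference
available).  Titration events map onto the protocol stages in fixed
order (out-of-order events raise naming the violation; missing stages
are simply absent, so partial protocols work).

Per state the 2-min average is taken from the last 120 s ending 15 s
before the next titration, provided the flux CV there is below 10 %;
otherwise the most stable 120 s sub-window by rolling CV (5 s step) is
used and short windows are flagged.  A state window that runs into the
anoxic drawdown is truncated where chamber O2 first falls below 30 µM:
flux below that is O2-limited and belongs to the kinetics segment, not
the state mean.  ROX (post-antimycin A) is subtracted from every state
except the CCO pair, whose blank is azide: cco_net = (TMPD+Asc) − AZ.
Negative net fluxes are flagged, not dropped.  RCR = OXPHOS_CI+CII /
Leak_CI+CII on net fluxes; values outside the 10.6–21.6 band typical of
healthy heart preparations are logged as advisory, never fatal.

**P50.**  The kinetics segment is the post-succinate drawdown restricted
to midpoint O2 in [0.05, 20] µM — the O2-limited region; plateau points
carry no kinetic information — with the anoxic tail capped at 10 min.
Chord differentiation (stride 1 by default; ~10 s chords recommended for
noisy traces) avoids the bias a smoothing kernel would impose on the
fast segment.  The Hill fit initialises Jmax at the 95th-percentile
flux, P50 at the PO2 of half-maximal observed flux and h at 1, bounds
h ∈ [0.2, 10], tight `curve_fit` tolerances; R² is computed on raw flux
residuals and fits with R² ≤ 0.70 are returned `accepted=False` (white
noise lands far below the gate).  P50 is reported in the units of the
abscissa (µM from chamber traces; kPa when the caller converts first),
with the unit recorded.

**Membrane potential.**  The bath safranin concentration (calibrated
fluorescence channel) is averaged over the same state window, clipped at
the total added dye (measurement noise can exceed the physical bound),
and converted through the mass balance
safr_in = safr_out + (total − out)·V_chamber/V_mito, where
V_mito = tissue mass × 1 µL mg⁻¹ × 0.198 (matrix fraction of heart
tissue; density 1 mg ≡ 1 µL).  ΔΨm = 2.3026·RT/(zF)·log10(out/in) in mV
(−58.4 mV per accumulation decade at 21 °C); matrix accumulation gives
the negative sign of energized mitochondria.  Work is JO2/−ΔΨm per
state.

## Synthetic generators

Defaults encode the study conditions the package targets: SMR 132.3 /
MMR 464.2 mg O2 kg⁻¹ h⁻¹ at 21 °C and 35 ppt, P_crit 5.4 kPa, P_LOE
2.8 kPa, CI and CI+CII OXPHOS 53.3 / 66.3 pmol s⁻¹ mg⁻¹ with ΔΨm −147.5
/ −145.6 mV, RCR ≈ 15, 5 mg tissue in a 2 mL chamber, 2 µM total
safranin, flush/wait/measure of 300/90/300 s.  The hypoxia chamber
defaults to the small end (1.9 L) of the realistic 1.9–6.7 L range,
which puts a full drawdown at ≈ 49 min.  Activity is modelled as
lognormal multiplicative bursts (probability 0.25 per cycle, log-scale
−1.2 ± 0.8, 10-min exponential decay — resting fish burst for minutes,
not hours) on top of an exponential post-handling settle (50 % elevation,
2 h time constant); the post-chase block starts exactly at MMR and
relaxes with a 30-min time constant.  Background drifts linearly from
−0.5 to −2 %sat h⁻¹ across the record.

Two constructions make noise-free round trips exact to machine precision
rather than quadrature-limited.  Linear segments are stepped with the
midpoint rule, so OLS slopes recover encoded rates exactly even under
the drifting background.  Curved segments — the oxyconforming drawdown
and the Hill-limited anoxia approach — are stepped midpoint-implicitly:
each consecutive sample pair satisfies (C_n − C_{n+1})/Δt =
rate((C_n + C_{n+1})/2) exactly, so the analysis's chord/midpoint pairs
lie exactly on the generating model.  The oxyregulation→conformation
transition is an exact breakpoint with a sample placed on it, and the
mitochondrial generator holds state fluxes exactly constant above a
25 µM onset, expressing Hill kinetics only below it; smoothing-induced
estimator bias can thus be studied separately.  The mitochondrial
integration uses a fixed 1 s step — adequate given the slow dynamics
(flux changes only at titrations and near anoxia).

What the generators do **not** emulate: sensor drift and optode lag,
temperature fluctuation within a record, fish interacting with the
chamber (slope nonlinearity within a cycle), gradual rather than sharp
regulation→conformation transitions, diffusion-limited boundary layers
near anoxia, and safranin bleaching or binding kinetics.  Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to every instrument artifact.

## Problem sizes and tolerances

Test and acceptance runs use 40–60 respirometry cycles per overnight
record, 100-seed Monte-Carlo batches for the breakpoint (20 conforming
points, σ = 5 mg kg⁻¹ h⁻¹ → MAE bound 0.3 kPa) and Hill (200 points, 5 %
flux noise → median P50 error bound 10 %) estimators, and single ~57-min
mitochondrial traces at 1 Hz; these sizes make the whole suite run in a
few seconds while leaving the Monte-Carlo bounds comfortably resolved.
Noise-free recoveries are asserted at 1e-6 relative or tighter; noisy
state means at max(2 %, 0.5 pmol s⁻¹ mg⁻¹) — the absolute floor reflects
flux-resolution limits at the smallest (ROX-scale) fluxes.

## Known limitations

* The SMR-intercept P_crit is the only breakpoint estimator provided
  (interfaces leave room for broken-stick or nonlinear alternatives).
* P_crit and EPOC inherit SMR-estimate error; the package reports the
  SMR used so sensitivity can be propagated.
* Safranin calibration is assumed already applied (the fluorescence
  channel is in µM); raw-voltage calibration is out of scope.
* Group statistics stop at mean ± SE summaries and percent changes;
  inferential testing is left to general-purpose statistics packages.
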