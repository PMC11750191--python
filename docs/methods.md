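# Methods notes

This note records the scientific and numerical choices behind the
package: what each stage assumes, which parameters matter, what the
synthetic generators do and do not emulate, and the known limitations.

## Signal pipeline

**Units and conventions.** Everything internal is microvolts; lead order
is fixed to [I, II, V1..V6]; limb-derived leads (III, aVR, aVL, aVF) are
exact linear combinations and are recomputed on demand, never stored.
The derived vectorcardiogram uses the Kors regression matrix with X
positive leftward, Y positive inferior and Z positive posterior, the
convention under which a normal R wave in Y is positive and a normal
frontal QRS axis of ~55° has sine ~0.82.  Whether the original clinical
software used an identical Z-sign convention cannot be established from
published sources; the convention here is documented and pinned by tests.

**Filtering.** Zero-phase 2nd-order Butterworth high-pass at 0.5 Hz
(configurable) plus an optional powerline notch (50 Hz default, Q = 30).
The forward–backward pass squares the magnitude response, so a 10-Hz
component passes within 2 % while 0.1-Hz wander is attenuated by ~56 dB.
Padding for `sosfiltfilt` is set to three filter time constants
(3·fs/f_c samples); the default padding leaves visible 0.5-Hz edge
transients in a 10-s record.

**Median beat and isoelectric level.** Beats are aligned on the spatial
magnitude maximum and combined by a per-lead, per-sample median over a
300 ms / 500 ms window (robust to one artifactual beat in ten; no
morphology-based beat rejection is attempted — a documented limitation
for records with frequent ectopy).  AC-coupled filtering leaves the
baseline at minus the beat mean, so each lead of the median beat is
re-zeroed to the median of its first 80 ms (TP segment).  Without this
step the vector magnitude has a spurious floor of order 100 µV and the
5 %-threshold QRS bounds are meaningless.

**Fiducials.** All landmarks are located on the spatial vector magnitude
(the model's intervals are *spatial* intervals): QRS onset/offset by
outward search from R for a sustained (10 ms) drop below 5 % of the R
magnitude; T peak as the post-J magnitude maximum; T end by the tangent
method (steepest-descent tangent of the magnitude after T peak,
extrapolated to the zero baseline, with a Savitzky–Golay derivative for
noise robustness).  Both thresholds are configurable.  Every detection
criterion is *relative* to signal amplitude, making fiducial indices
exactly invariant to overall gain — a property the tests pin.  On
healthy-geometry synthetic records the delineation error is ≤ 5 ms for
QT and ≤ 3 ms for QRS duration; the advertised contract (≤ 10 ms in
≥ 90 % of draws) leaves headroom for noisier geometries.

**T-loop measures.** The T-segment SVD is computed on *uncentered*
samples (the loop is referenced to the isoelectric baseline, not its own
mean; a `centered` flag exists for sensitivity analysis), and
"eigenvalues" are squared singular values, i.e. eigenvalues of the
scatter matrix — the exponent convention is pinned by tests because the
intradipolar ratio EV2·EV3/EV1² is not invariant to it.  A measured loop
with a minor eigenvalue below 1e-4 of EV1 is treated as rank-deficient
(`DegenerateLoopError`): filtering residue and the QRS tail at J leave
relative minor eigenvalues of that order even for a perfectly planar
loop, and log ratios below that floor (< −13) are far outside any
physiological range.  T-loop angle statistics exclude samples with
magnitude under 1 µV to avoid atan2 blow-up near the origin; this is the
one absolute threshold in the pipeline, and under a gain change it can
admit a handful of extra samples (the homogeneity test allows a
2-degree tolerance for this measure only).

**Interpretive choices.** Two measure names admit multiple readings and
were fixed once: the *spatial T-wave axis* is the sine of the elevation
of the peak T vector (not the frontal-plane T axis), and the *elevation
vs azimuth mean difference* compares each T sample's frontal-plane angle
atan2(y, x) with its azimuth atan2(z, x), wrapping absolute differences
to [0, 180].  The frontal QRS axis uses the net (time-integral) QRS
vector — the common, noise-robust VCG convention — with a peak-vector
variant behind a flag.  QT/JT rate correction defaults to Bazett with
Fridericia available; the correction method is recorded in the output.

## The scoring model

Coefficients are frozen published constants (male: intercept −166.22 and
8 terms; female: intercept −200, a constant +4.20 folded into the linear
predictor, and 9 terms including the frontal QRS-axis sine, which the
male model lacks).  They are pinned by SHA-256 hashes and by two worked
examples computed by independent hand summation on the healthy-group
mean measures (47.34244 years male, 42.62059 years female).  The model
is applied exactly as printed — no symmetrization between sexes, no
clipping, no refitting.  Inputs outside the healthy reference mean ± 4 SD
trigger a warning (the score is then an extrapolation), never an error.
The gap dichotomization threshold is 10 years ≈ 2 × the 5.0-year healthy
gap SD, with a closed lower bound (gap = 10.0 is "at or above").

## Synthetic beats and records

The generator's contract is *controllable ground truth*, not
physiological realism.  A beat is built in VCG space: the QRS is a
planar elliptical loop — a sin² main lobe along the axis direction plus
a smaller (25 %) quadrature lobe tilted into Z — swept over the QRS
duration, and the T wave is built from the first three Hermite functions
along an orthonormal frame, which makes the T scatter eigenvalue ratios
equal the squared coefficients by construction and keeps the magnitude
peak exactly at the envelope centre.  Because the quadrature lobe
integrates to zero, the designed axis is exact; because it vanishes at
the envelope centre, the designed frontal maximum is exact.

Fiducial parameters are interpreted through their operational
definitions: the generator numerically solves its envelope spans so that
the sustained-5 %-crossing QRS bounds and the tangent-method T end of the
*noiseless analytic* signal land exactly on the requested onset, offset
and end.  The pipeline is then judged against these solved truths on the
noisy, lead-projected, filtered, median-beat-reconstructed signal — a
genuinely independent measurement path.

Records tile beats at the nominal RR with ≤ 2 % uniform jitter, project
to the 8 leads through the Moore–Penrose right inverse of the Kors
matrix (so the noiseless Kors round trip is exact to machine precision),
and add per-lead white noise (default 8 µV) and optional sinusoidal
drift.  Healthy-geometry draws sample QRS 80–95 ms, QT 380–410 ms, rate
58–70/min, axis 40–70°, loop 1300–1900 µV, T elevation 35–55° and
eigenvalue ratios EV2/EV1 0.05–0.18 — ranges chosen once so that every
derived measure of a clean adult beat lies inside the healthy reference
bands.  What the generator does **not** emulate: P waves (irrelevant to
this model), beat-to-beat morphology variation, ectopy, muscle artifact,
electrode misplacement, and between-visit biological variation.  Passing
plausibility tests therefore shows the pipeline is unbiased and precise
under clean conditions, not that it is robust to every clinical
confounder; the synthetic repeatability MDC (~0.2 years) is accordingly
far smaller than any clinically observed repeat-visit value, which is
dominated by biological variation the generator deliberately lacks.

## Synthetic cohorts

Subjects are drawn from three strata (healthy / risk factors / disease,
fractions 0.607 / 0.11 / 0.283) with stratum-wise Gaussian age and gap
distributions (gap 0.4 ± 5.0, 7.4 ± 6.8, 13.5 ± 8.3 years).  Event times
follow a proportional-hazards model with Weibull baseline (shape 1 =
exponential default; the choice of baseline is irrelevant for HR
recovery by a semiparametric Cox fit), linear predictor
β₅·gap/5 + β_cls·1[gap ≥ 10], and uniform censoring over 4.8–6.7 years.
The continuous per-5-year log-HR has no published value; the default is
ln(1.2) — a modest, realistic dose–response — with the dichotomized
effect defaulting to zero so a study sets one or the other explicitly.
The default baseline hazard 0.02/year yields roughly the observed ~19 %
event fraction over the follow-up window.  Stratum-wise covariate
prevalences (smoking, diabetes, hypertension, hypercholesterolaemia,
BMI) are plausible engineering defaults for adjusted-fit plumbing; they
are *not* calibrated to any published table and the generated covariates
are independent of the gap given the stratum, so adjusted and unadjusted
HRs coincide in expectation.

## Survival statistics

Cox fits use the partial likelihood with Efron tie handling (the
conventional default; the tie method is fixed for reproducibility) via
lifelines, with Wald 95 % CIs; HRs are reported per 5-year gap increment
for the continuous exposure.  The gap × age interaction is tested by
likelihood ratio (1 df).  Harrell's C counts usable pairs (the earlier
time must be an observed event), credits ties at 0.5, and takes its 95 %
CI from a leave-one-out jackknife — quadratic in n, so it is skipped
above n = 800 inside `fit_cox` (the standalone `concordance` accepts
larger limits).  The restricted cubic spline uses the natural
truncated-power basis with 3 knots at the 0.1/0.5/0.9 gap quantiles
(4–5 knots at evenly spaced quantiles are available); the curve is a
contrast against a reference gap (default 0), so HR(reference) = 1
exactly, with a pointwise Wald band.  MDC is 1.96·√2·SEM of paired
repeat differences (SD with ddof = 1); Bland–Altman agreement reports
bias, SD of differences and the R² of regressing one method on the
other.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
Distribution-recovery checks use n = 10 000–20 000 subjects; Cox
parameter-recovery suites use 50 replicates of n = 2000 (≥ 300 events
each); pipeline plausibility uses 50 records and delineation accuracy 20
parameter draws; brute-force concordance equivalence uses 100 cohorts of
n ≤ 100.  These sizes give standard errors comfortably inside the bands
being asserted while keeping the full suite fast.

## Known limitations

* CSV is the only ECG exchange format (WFDB conversion is up to the
  user); cohort tables are plain CSV.
* No per-beat delineation, arrhythmia classification or P-wave analysis
  (the last is excluded by the model's design).
* The published coefficients are applied, never refit; no uncertainty
  interval accompanies an individual Heart Age.
* Validation statistics assume right censoring and proportional hazards;
  no competing risks or time-varying covariates.
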