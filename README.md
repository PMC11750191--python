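# heartage

Explainable **A-ECG Heart Age** from a standard 10-second, 12-lead ECG —
with no P-wave information, so the score applies equally in sinus and
non-sinus rhythms — plus the synthetic data and survival statistics needed
to exercise and validate every stage.

## Who this is for

Researchers in electrocardiology and cardiovascular epidemiology who want
a transparent (non-deep-learning) estimate of cardiovascular age and the
**Heart Age gap** — Heart Age minus chronological age, in years of healthy
aging — as a risk communication and stratification tool, together with the
prognostic-validation machinery (Kaplan–Meier, Cox, concordance,
restricted-cubic-spline dose–response, repeatability).

## The model

From the 8 independent leads (I, II, V1–V6, microvolts) the pipeline

1. removes baseline wander (zero-phase 0.5 Hz high-pass + powerline notch),
2. detects R peaks on the spatial magnitude of the **Kors-derived
   vectorcardiogram** (X leftward, Y inferior, Z posterior),
3. forms a per-sample **median beat**, re-zeroed to the TP-segment
   isoelectric level,
4. locates fiducials on the median beat's vector magnitude (QRS bounds by
   sustained 5 %-of-peak crossings, T end by the tangent method), and
5. measures ten quantities: chronological age; R amplitude in derived
   lead Y (µV); sine of the frontal-plane QRS axis; maximum frontal-plane
   QRS loop amplitude (µV); ln of the T-loop *intradipolar ratio*
   100·EV2·EV3/EV1² (%) from the uncentered T-segment SVD; ln of the
   rate-corrected spatial QT (ms); rate-corrected spatial JT (ms); sine of
   the spatial T-wave axis (elevation of the peak T vector); and the mean
   |frontal-plane angle − azimuth| over T-loop samples (degrees).

Heart Age is then a fixed, published, sex-specific linear combination:

    HA_male   = −166.22 + 0.900·age + 27.5·ln QTc + 1.69·ln IDR − 0.00740·R_Y
                + 0.0580·JTc − 3.41·sin(T axis) + 0.00302·QRS_loop
                + 0.0279·ΔEA
    HA_female = −200 + 4.20 + 0.942·age − 9.59·sin(QRS axis) + 32.3·ln QTc
                − 0.00869·R_Y + 1.88·ln IDR + 0.0676·JTc − 3.77·sin(T axis)
                + 0.00345·QRS_loop + 0.0334·ΔEA

A gap of **≥ 10 years** (≈ 2 SD of the gap among healthy adults, 2 × 5.0)
marks the elevated-risk stratum.

## Worked example

```bash
heartage simulate-ecg --seed 5 --out sim       # synthetic 10-s 12-lead ECG
heartage compute --ecg sim/ecg.csv --age 39 --sex male
```

prints (abbreviated):

```json
{
 "heart_age": 44.29961788930036,
 "gap": 5.299617889300357,
 "gap_class": "below",
 "features": {
  "r_amp_y": 1300.2416,
  "frontal_qrs_axis_sine": 0.8191,
  "max_frontal_qrs_loop": 1584.6226,
  "ln_intradipolar_ratio": -0.6608,
  "ln_qtc_spatial": 5.989,
  "jtc_spatial": 310.7953,
  "t_axis_sine": 0.6676,
  "t_elev_azim_meandiff": 33.1564
 }
}
```

This 39-year-old "subject" (a synthetic record with healthy default
geometry: QRS axis 55°, frontal loop 1600 µV, QT 400 ms at 60/min) gets a
Heart Age of 44.3 years and a gap of +5.3 years — below the 10-year
threshold, i.e. no evidence of accelerated cardiovascular aging.  Every
feature is listed so the score can be audited term by term.

Cohort-level validation runs on a tidy CSV
(`gap, followup_time, event, age, sex, …`):

```bash
heartage simulate-cohort --seed 7 --out cohort.csv
heartage validate-cohort --cohort cohort.csv --adjust age,sex --out report.json
```

The report contains Kaplan–Meier curves by gap stratum, unadjusted /
adjusted / per-5-year Cox hazard ratios with 95 % CIs and Harrell's C, the
gap × age interaction likelihood-ratio p, and the spline HR-vs-gap curve.

## Library use

```python
from heartage import read_ecg, extract_features, compute_heart_age

record = read_ecg("ecg.csv", fs=500)        # or JSON sidecar with fs/unit
fv = extract_features(record, qtc_method="bazett")
result = compute_heart_age(fv)
print(result.heart_age, result.gap)
```

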