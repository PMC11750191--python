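"""Ground-truth synthetic ECGs and cohorts for every pipeline stage.

Two generators:

**Beats/records.** A beat is built directly in VCG space and mapped to the
8 independent leads through the Moore-Penrose right inverse of the Kors
matrix, so the derived VCG of a noiseless record equals the designed VCG
to machine precision.  The QRS is a planar elliptical loop (a sin^2 main
lobe along the axis direction plus a smaller quadrature lobe) swept over
the QRS duration; the T wave is a low-complexity loop built from the first
three Hermite functions along three orthonormal directions, which makes
the T-segment scatter eigenvalue ratios equal the squared component
coefficients by construction.  Fiducial parameters are interpreted by
their standard operational definitions — QRS bounds as sustained crossings
of 5% of the peak spatial magnitude, T end by the tangent method — and the
generator solves its envelope spans so the noiseless signal meets those
definitions at exactly the requested onset/offset/end.  The solved values
are returned as ground truth.

**Cohorts.** Subjects are drawn from three strata (healthy, risk factors,
established disease) with group-wise age and Heart Age gap distributions
matching the derivation-cohort description; event times follow a
proportional-hazards model (exponential baseline by default, Weibull
optional) with a continuous per-5-year gap effect and/or a dichotomized
gap effect, and uniform censoring over the follow-up window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ecg_io import ECGRecord, Subject
from .preprocessing import Fiducials
from .vcg import KORS_PINV, VCGBeat

# ---------------------------------------------------------------------------
# beat-level generator
# ---------------------------------------------------------------------------

#: fraction of the peak spatial magnitude defining the QRS bounds
QRS_BOUND_FRAC = 0.05
#: fine time step (ms) for the analytic solves
FINE_DT_MS = 0.05

_PI4 = math.pi ** 0.25


def _hermite0(u):
    return np.exp(-0.5 * u**2) / _PI4


def _hermite1(u):
    return math.sqrt(2.0) * u * np.exp(-0.5 * u**2) / _PI4


def _hermite2(u):
    return (2.0 * u**2 - 1.0) * np.exp(-0.5 * u**2) / (math.sqrt(2.0) * _PI4)


@dataclass
class BeatParams:
    """Controllable geometry of one synthetic beat (healthy defaults)."""

    qrs_duration_ms: float = 90.0
    qt_ms: float = 400.0
    heart_rate_bpm: float = 60.0
    qrs_frontal_max_uv: float = 1600.0
    qrs_axis_deg: float = 55.0
    qrs_ecc: float = 0.25  # quadrature-lobe fraction of the main lobe
    qrs_minor_tilt_deg: float = 60.0  # how far the minor axis leans into Z
    t_peak_uv: float = 500.0
    t_elevation_deg: float = 45.0
    t_azimuth_deg: float = 20.0
    ev2_ratio: float = 0.10  # target T-loop ev2/ev1
    ev3_ratio: float = 0.05  # target T-loop ev3/ev1
    t_sigma_ms: float = 38.0  # Gaussian half-width of the T envelope
    noise_sigma_uv: float = 8.0
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.qt_ms <= self.qrs_duration_ms:
            raise ValueError("qt_ms must exceed qrs_duration_ms")
        if min(self.qrs_frontal_max_uv, self.t_peak_uv, self.t_sigma_ms) <= 0:
            raise ValueError("amplitudes and widths must be positive")
        if self.heart_rate_bpm <= 0 or self.fs <= 0:
            raise ValueError("heart_rate_bpm and fs must be positive")
        if not 0 <= self.ev3_ratio <= self.ev2_ratio <= 1:
            raise ValueError("need 0 <= ev3_ratio <= ev2_ratio <= 1")

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm


class _BeatGeometry:
    """Solved analytic description of one beat, QRS centre at local t=0 ms."""

    def __init__(self, p: BeatParams):
        self.p = p
        th = math.radians(p.qrs_axis_deg)
        self.u = np.array([math.cos(th), math.sin(th), 0.0])
        ga = math.radians(p.qrs_minor_tilt_deg)
        self.v = math.cos(ga) * np.array([-math.sin(th), math.cos(th), 0.0]) + \
            math.sin(ga) * np.array([0.0, 0.0, 1.0])

        # T-loop orthonormal frame: w1 = peak direction; w3 horizontal
        el, az = math.radians(p.t_elevation_deg), math.radians(p.t_azimuth_deg)
        w1 = np.array(
            [math.cos(el) * math.cos(az), math.sin(el), math.cos(el) * math.sin(az)]
        )
        w3 = np.cross(w1, [0.0, 1.0, 0.0])
        w3 /= np.linalg.norm(w3)
        w2 = np.cross(w1, w3)
        self.w1, self.w2, self.w3 = w1, w2, w3
        self.c1 = math.sqrt(p.ev2_ratio)
        self.c2 = math.sqrt(p.ev3_ratio)

        # QRS envelope span: sustained 5%-of-peak crossings at +/- D/2
        ecc = p.qrs_ecc

        def mag_rel(s):
            return (
                math.sin(math.pi * s) ** 2
                * math.sqrt(1.0 + (ecc * math.sin(2 * math.pi * s)) ** 2)
                - QRS_BOUND_FRAC
            )

        s0 = brentq(mag_rel, 1e-9, 0.5)
        self.qrs_env_ms = p.qrs_duration_ms / (1.0 - 2.0 * s0)
        self.onset_ms = -p.qrs_duration_ms / 2.0
        self.offset_ms = +p.qrs_duration_ms / 2.0

        # T amplitude scale and tangent-method T end
        sig = p.t_sigma_ms
        u_grid = np.arange(0.0, 6.0, FINE_DT_MS / sig)
        prof = np.sqrt(
            _hermite0(u_grid) ** 2
            + (self.c1 * _hermite1(u_grid)) ** 2
            + (self.c2 * _hermite2(u_grid)) ** 2
        )
        self.t_scale = p.t_peak_uv / prof.max()
        m = self.t_scale * prof
        dm = np.gradient(m, FINE_DT_MS)
        i_peak = int(np.argmax(m))
        i_star = i_peak + int(np.argmin(dm[i_peak:]))
        slope = dm[i_star]
        tangent_rel_ms = i_star * FINE_DT_MS + m[i_star] / (-slope)
        # place the T centre so the tangent end lands at onset + QT
        self.t_end_ms = self.onset_ms + p.qt_ms
        self.t_center_ms = self.t_end_ms - tangent_rel_ms
        if self.t_center_ms - 3 * sig < self.offset_ms:
            raise ValueError(
                "T envelope overlaps the QRS: shrink t_sigma_ms or raise qt_ms"
            )

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """3 x len(t) VCG samples (uV) at local times t_ms."""
        p = self.p
        out = np.zeros((3, t_ms.size))
        # QRS loop
        s = (t_ms + self.qrs_env_ms / 2.0) / self.qrs_env_ms
        inside = (s > 0.0) & (s < 1.0)
        si = s[inside]
        main = np.sin(np.pi * si) ** 2
        minor = p.qrs_ecc * main * np.sin(2 * np.pi * si)
        out[:, inside] += p.qrs_frontal_max_uv * (
            np.outer(self.u, main) + np.outer(self.v, minor)
        )
        # T loop
        u_t = (t_ms - self.t_center_ms) / p.t_sigma_ms
        out += self.t_scale * (
            np.outer(self.w1, _hermite0(u_t))
            + self.c1 * np.outer(self.w2, _hermite1(u_t))
            + self.c2 * np.outer(self.w3, _hermite2(u_t))
        )
        return out


def designed_features(p: BeatParams, qtc_method: str = "bazett") -> dict:
    """Ground-truth values of each pipeline measure for a noiseless beat.

    Axis/amplitude/interval truths follow directly from the construction;
    the T-derived truths (peak-vector elevation sine, eigenvalue ratio,
    elevation/azimuth mean difference) are evaluated numerically on the
    analytic loop at fine resolution.
    """
    from .features import rate_correct  # local import to avoid cycles

    g = _BeatGeometry(p)
    t = np.arange(g.onset_ms - 20.0, g.t_end_ms + 60.0, FINE_DT_MS)
    xyz = g.evaluate(t)

    qrs_mask = (t >= g.onset_ms) & (t <= g.offset_ms)
    r_amp_y = float(xyz[1, qrs_mask].max())

    t_mask = (t >= g.offset_ms) & (t <= g.t_end_ms)
    seg = xyz[:, t_mask]
    mag = np.sqrt((seg**2).sum(axis=0))
    i_pk = int(np.argmax(mag))
    x, y, z = seg[:, i_pk]
    t_axis_sine = math.sin(math.atan2(y, math.hypot(x, z)))

    ev = np.linalg.svd(seg[:, mag >= 1e-9], compute_uv=False) ** 2
    if ev[1] > 1e-12 * ev[0]:
        ln_intra = float(np.log(100.0 * ev[1] * ev[2] / ev[0] ** 2))
    else:
        ln_intra = float("nan")

    keep = mag >= 1.0
    e = np.degrees(np.arctan2(seg[1, keep], seg[0, keep]))
    a = np.degrees(np.arctan2(seg[2, keep], seg[0, keep]))
    diff = np.abs(-((-(e - a) + 180.0) % 360.0 - 180.0))
    meandiff = float(np.mean(diff))

    qt, qrs = p.qt_ms, p.qrs_duration_ms
    jt = qt - qrs
    qtc = rate_correct(qt, p.rr_ms, qtc_method)
    jtc = rate_correct(jt, p.rr_ms, qtc_method)
    return {
        "frontal_qrs_axis_sine": math.sin(math.radians(p.qrs_axis_deg)),
        "max_frontal_qrs_loop": p.qrs_frontal_max_uv,
        "r_amp_y": r_amp_y,
        "qt_ms": qt,
        "qrs_duration_ms": qrs,
        "jt_ms": jt,
        "ln_qtc_spatial": math.log(qtc),
        "jtc_spatial": jtc,
        "t_axis_sine": t_axis_sine,
        "ln_intradipolar_ratio": ln_intra,
        "t_elev_azim_meandiff": meandiff,
    }


def simulate_vcg_beat(
    p: BeatParams, pre_ms: float = 300.0, post_ms: float = 500.0
) -> tuple[VCGBeat, Fiducials]:
    """One noiseless VCG beat sampled at ``p.fs`` plus its true fiducials.

    The beat window spans ``pre_ms`` before to ``post_ms`` after the R
    peak (the centre of the QRS loop, which is also the spatial-magnitude
    maximum).  Ground-truth fiducials are the operational-definition
    landmarks the generator solved for, converted to sample indices.
    """
    g = _BeatGeometry(p)
    pre = int(round(pre_ms / 1000.0 * p.fs))
    post = int(round(post_ms / 1000.0 * p.fs))
    idx = np.arange(pre + post)
    t_ms = (idx - pre) / p.fs * 1000.0
    xyz = g.evaluate(t_ms)
    beat = VCGBeat(x=xyz[0], y=xyz[1], z=xyz[2], fs=p.fs)

    def to_idx(ms: float) -> int:
        return pre + int(round(ms / 1000.0 * p.fs))

    fid = Fiducials(
        qrs_onset=to_idx(g.onset_ms),
        r_peak=pre,
        qrs_offset=to_idx(g.offset_ms),
        t_peak=to_idx(g.t_center_ms),
        t_end=to_idx(g.t_end_ms),
        heart_rate_bpm=p.heart_rate_bpm,
        fs=p.fs,
    )
    return beat, fid


def simulate_ecg_record(
    p: BeatParams,
    duration_s: float = 10.0,
    rr_jitter_frac: float = 0.02,
    drift_uv: float = 0.0,
    drift_hz: float = 0.15,
    age: float = 39.0,
    sex: str = "male",
    subject_id: str = "synthetic",
) -> tuple[ECGRecord, dict]:
    """A full 12-lead record tiled from the designed beat, with ground truth.

    Beats are placed at the nominal RR with uniform jitter up to
    ``rr_jitter_frac`` of the RR; the VCG stream is mapped to the 8
    independent leads through the Kors right inverse, and seeded Gaussian
    noise (``p.noise_sigma_uv``) plus optional sinusoidal baseline drift is
    added per lead.  Returns the record and a truth dict with the R-peak
    sample indices, per-beat absolute fiducials, and the designed feature
    values from :func:`designed_features`.
    """
    rng = np.random.default_rng(p.seed)
    g = _BeatGeometry(p)
    fs = p.fs
    n = int(round(duration_s * fs))
    total_ms = duration_s * 1000.0

    centers = []
    c = 400.0
    while c < total_ms:
        centers.append(c)
        c += p.rr_ms * (1.0 + rng.uniform(-rr_jitter_frac, rr_jitter_frac))

    xyz = np.zeros((3, n))
    half_span = 60.0 + max(-g.onset_ms, g.t_end_ms + 4 * p.t_sigma_ms)
    truth_fids = []
    r_idx = []
    for c in centers:
        lo = max(0, int((c - half_span) / 1000.0 * fs))
        hi = min(n, int((c + half_span) / 1000.0 * fs) + 1)
        t_local = np.arange(lo, hi) / fs * 1000.0 - c
        xyz[:, lo:hi] += g.evaluate(t_local)
        ci = int(round(c / 1000.0 * fs))
        r_idx.append(ci)

        def to_abs(ms: float) -> int:
            return int(round((c + ms) / 1000.0 * fs))

        if to_abs(g.onset_ms) >= 0 and to_abs(g.t_end_ms) < n:
            truth_fids.append(
                {
                    "qrs_onset": to_abs(g.onset_ms),
                    "r_peak": ci,
                    "qrs_offset": to_abs(g.offset_ms),
                    "t_peak": to_abs(g.t_center_ms),
                    "t_end": to_abs(g.t_end_ms),
                }
            )

    leads = KORS_PINV @ xyz
    if p.noise_sigma_uv > 0:
        leads = leads + rng.normal(0.0, p.noise_sigma_uv, size=leads.shape)
    if drift_uv > 0:
        tt = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=8)
        leads = leads + drift_uv * np.sin(
            2 * np.pi * drift_hz * tt[None, :] + phases[:, None]
        )

    record = ECGRecord(
        signal=leads,
        fs=fs,
        subject=Subject(age=age, sex=sex, id=subject_id),
    )
    truth = {
        "r_peaks": np.asarray(r_idx, dtype=int),
        "fiducials": truth_fids,
        "designed": designed_features(p),
        "params": p,
        "rr_ms_nominal": p.rr_ms,
    }
    return record, truth


def sample_healthy_beat_params(rng: np.random.Generator, fs: float = 500.0) -> BeatParams:
    """One random draw of healthy-geometry beat parameters.

    Ranges are chosen so that, for an adult with normal conduction and
    repolarization, every derived measure falls inside the healthy
    reference bands (QRS 80-95 ms, QT 380-410 ms, rate 58-70/min, normal
    axis, modest T-loop complexity).
    """
    ev2 = rng.uniform(0.05, 0.18)
    return BeatParams(
        qrs_duration_ms=rng.uniform(80.0, 95.0),
        qt_ms=rng.uniform(380.0, 410.0),
        heart_rate_bpm=rng.uniform(58.0, 70.0),
        qrs_frontal_max_uv=rng.uniform(1300.0, 1900.0),
        qrs_axis_deg=rng.uniform(40.0, 70.0),
        t_peak_uv=rng.uniform(400.0, 650.0),
        t_elevation_deg=rng.uniform(35.0, 55.0),
        t_azimuth_deg=rng.uniform(10.0, 35.0),
        ev2_ratio=ev2,
        ev3_ratio=rng.uniform(0.02, ev2),
        noise_sigma_uv=8.0,
        fs=fs,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# cohort-level generator
# ---------------------------------------------------------------------------

GROUPS = ("healthy", "risk", "disease")


def _default_fractions():
    return {"healthy": 0.607, "risk": 0.11, "disease": 0.283}


def _default_gap_params():
    return {"healthy": (0.4, 5.0), "risk": (7.4, 6.8), "disease": (13.5, 8.3)}


def _default_age_params():
    return {"healthy": (38.6, 13.0), "risk": (54.8, 11.2), "disease": (59.0, 13.2)}


def _default_male_fraction():
    return {"healthy": 0.594, "risk": 0.534, "disease": 0.616}


def _default_covariate_prevalence():
    # plausible stratum-wise prevalences: none by definition in the healthy
    # stratum (screened out), common in the risk/disease strata
    return {
        "healthy": {"smoking": 0.0, "diabetes": 0.0, "hypertension": 0.0,
                    "hypercholesterolaemia": 0.05, "bmi": (26.0, 4.0)},
        "risk": {"smoking": 0.30, "diabetes": 0.20, "hypertension": 0.50,
                 "hypercholesterolaemia": 0.40, "bmi": (29.0, 5.0)},
        "disease": {"smoking": 0.30, "diabetes": 0.25, "hypertension": 0.55,
                    "hypercholesterolaemia": 0.45, "bmi": (29.0, 5.0)},
    }


@dataclass
class CohortParams:
    """Generative description of a synthetic cohort.

    Stratum fractions and the group-wise gap/age distributions default to
    the derivation-cohort composition; the survival side defaults to an
    exponential baseline with a modest continuous gap effect and uniform
    censoring over the observed follow-up window (4.8-6.7 years).
    ``log_hr_gap_class`` adds a dichotomized (gap >= 10) effect; set the
    continuous effect to zero to study a purely binary exposure.
    """

    n: int = 731
    group_fractions: dict = field(default_factory=_default_fractions)
    gap_params: dict = field(default_factory=_default_gap_params)
    age_params: dict = field(default_factory=_default_age_params)
    male_fraction: dict = field(default_factory=_default_male_fraction)
    covariate_prevalence: dict = field(default_factory=_default_covariate_prevalence)
    log_hr_per_5y: float = math.log(1.2)
    log_hr_gap_class: float = 0.0
    gap_class_threshold: float = 10.0
    baseline_hazard: float = 0.02  # events / person-year at gap 0
    censor_window: tuple = (4.8, 6.7)  # years, uniform censoring
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.group_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"group fractions must sum to 1, got {tot}")
        for grp, (mu, sd) in self.gap_params.items():
            if sd <= 0:
                raise ValueError(f"gap SD for {grp} must be positive")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline hazard and Weibull shape must be positive")


def simulate_cohort(p: CohortParams) -> pd.DataFrame:
    """Draw a tidy cohort table with proportional-hazards survival structure.

    Event times are drawn by inverse transform from the Weibull
    (exponential if shape 1) proportional-hazards model
    ``h(t | gap) = h0 * k * t^(k-1) * exp(b5 * gap/5 + bcls * [gap >= thr])``;
    censoring is uniform over ``censor_window``.
    """
    rng = np.random.default_rng(p.seed)
    groups = rng.choice(GROUPS, size=p.n, p=[p.group_fractions[g] for g in GROUPS])

    age = np.empty(p.n)
    gap = np.empty(p.n)
    sex = np.empty(p.n, dtype=object)
    cov = {k: np.empty(p.n) for k in
           ("smoking", "diabetes", "hypertension", "hypercholesterolaemia", "bmi")}
    for g in GROUPS:
        m = groups == g
        k = int(m.sum())
        if k == 0:
            continue
        mu_a, sd_a = p.age_params[g]
        age[m] = np.clip(rng.normal(mu_a, sd_a, k), 18.0, 95.0)
        mu_g, sd_g = p.gap_params[g]
        gap[m] = rng.normal(mu_g, sd_g, k)
        sex[m] = np.where(rng.random(k) < p.male_fraction[g], "male", "female")
        prev = p.covariate_prevalence[g]
        for c in ("smoking", "diabetes", "hypertension", "hypercholesterolaemia"):
            cov[c][m] = (rng.random(k) < prev[c]).astype(float)
        mu_b, sd_b = prev["bmi"]
        cov["bmi"][m] = np.clip(rng.normal(mu_b, sd_b, k), 15.0, 60.0)

    lp = p.log_hr_per_5y * gap / 5.0 + p.log_hr_gap_class * (
        gap >= p.gap_class_threshold
    )
    rate = p.baseline_hazard * np.exp(lp)
    e = rng.exponential(1.0, p.n)
    t_event = (e / rate) ** (1.0 / p.weibull_shape)
    censor = rng.uniform(*p.censor_window, p.n)
    event = t_event <= censor
    followup = np.maximum(np.minimum(t_event, censor), 1e-6)

    return pd.DataFrame(
        {
            "id": [f"s{i:05d}" for i in range(p.n)],
            "group": groups,
            "age": age,
            "sex": sex,
            "heart_age": age + gap,
            "gap": gap,
            "followup_time": followup,
            "event": event,
            **cov,
        }
    )


def simulate_pipeline_cohort(
    n: int, seed: int = 0, fs: float = 500.0
) -> pd.DataFrame:
    """Slow full-pipeline cohort: one synthetic ECG per subject.

    For integration tests (keep ``n`` small, <= 50): each subject gets a
    randomized healthy-geometry record, the feature pipeline is run, and
    the Heart Age model produces the gap.  Returns features plus the
    resulting heart_age/gap per subject.
    """
    from .features import extract_features
    from .heartage_model import compute_heart_age

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        p = sample_healthy_beat_params(rng, fs=fs)
        age = float(np.clip(rng.normal(38.6, 13.0), 20.0, 80.0))
        sex = "male" if rng.random() < 0.594 else "female"
        record, _ = simulate_ecg_record(p, age=age, sex=sex, subject_id=f"p{i:04d}")
        fv = extract_features(record)
        res = compute_heart_age(fv, warn_extrapolation=False)
        row = fv.to_dict()
        row.update(id=f"p{i:04d}", heart_age=res.heart_age, gap=res.gap)
        rows.append(row)
    return pd.DataFrame(rows)
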