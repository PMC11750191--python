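"""The ten advanced-ECG measures that enter the Heart Age model.

All measures are computed on the median VCG beat between the fiducials:

* amplitude measures (uV): R-wave amplitude in derived lead Y, maximum
  amplitude of the frontal-plane QRS loop;
* axis measures (dimensionless sines): frontal-plane QRS axis from the
  net (time-integral) QRS vector, spatial T-wave axis as the sine of the
  elevation of the peak T vector;
* interval measures (ms): spatial QT (QRS onset to T end) and JT (J point
  to T end) on the vector magnitude, heart-rate corrected (Bazett by
  default, Fridericia optional), the QT entering the model as its natural
  logarithm;
* T-loop complexity: eigenvalues of the uncentered 3 x N T-segment scatter
  (squared singular values) and the "intradipolar ratio"
  100 * ev2 * ev3 / ev1^2 in percent, entering as its natural log;
* T-loop dispersion (degrees): mean absolute difference between each
  T-sample's frontal-plane angle and its azimuth.

Amplitude measures scale linearly with gain; axis, interval and
eigenvalue-ratio measures are gain-invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .ecg_io import ECGRecord
from .errors import (
    DegenerateLoopError,
    FiducialError,
    HeartAgeError,
    IncompleteFeatureError,
    UndefinedAxisError,
)
from .preprocessing import (
    Fiducials,
    compute_median_beat,
    detect_r_peaks,
    filter_baseline,
    locate_fiducials,
)
from .vcg import VCGBeat, frontal_angle_sine, kors_transform

#: Minimum number of samples for a T-segment SVD.
MIN_T_SAMPLES = 8
#: Samples below this spatial magnitude (uV) are excluded from T-loop
#: angle statistics to avoid atan2 blow-up near the origin.
T_ANGLE_MAGNITUDE_FLOOR_UV = 1.0
#: Relative eigenvalue (ev/ev1) below which a measured T loop is treated as
#: rank deficient.  Filtering residue and the QRS tail at J leave minor
#: eigenvalues of order 1e-4 even for a perfectly planar loop; below this
#: floor the log ratio (< -13) is far outside any physiologic range and
#: carries no information.
RANK_TOL = 1e-4


@dataclass
class TWaveSVD:
    """Eigenvalues (squared singular values) of the T-segment, descending, uV^2."""

    ev1: float
    ev2: float
    ev3: float


@dataclass
class FeatureVector:
    """The named inputs of the Heart Age model, with units as documented."""

    age: float  # years
    sex: str  # "male" | "female"
    r_amp_y: float  # uV
    frontal_qrs_axis_sine: float  # dimensionless
    max_frontal_qrs_loop: float  # uV
    ln_intradipolar_ratio: float  # ln(%)
    ln_qtc_spatial: float  # ln(ms)
    jtc_spatial: float  # ms
    t_axis_sine: float  # dimensionless
    t_elev_azim_meandiff: float  # degrees

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_csv_row(self) -> str:
        d = self.to_dict()
        return ",".join(str(d[k]) for k in d)


def t_wave_svd(vcg: VCGBeat, fid: Fiducials, centered: bool = False) -> TWaveSVD:
    """SVD of the 3 x N T-segment (J point to T end, inclusive).

    Samples are uncentered by default: the loop is referenced to the
    isoelectric baseline, not to its own mean.  Eigenvalues are the
    squared singular values (i.e. eigenvalues of the scatter matrix).
    """
    seg = vcg.as_matrix()[:, fid.qrs_offset : fid.t_end + 1]
    if seg.shape[1] < MIN_T_SAMPLES:
        raise FiducialError(
            f"T segment of {seg.shape[1]} samples too short for SVD"
        )
    if centered:
        seg = seg - seg.mean(axis=1, keepdims=True)
    s = np.linalg.svd(seg, compute_uv=False)
    ev = s**2
    return TWaveSVD(ev1=float(ev[0]), ev2=float(ev[1]), ev3=float(ev[2]))


def ln_intradipolar_ratio(svd: TWaveSVD) -> float:
    """Natural log of the intradipolar ratio 100 * ev2 * ev3 / ev1^2 (percent).

    Raises :class:`DegenerateLoopError` when the T loop is (numerically)
    rank deficient, since the ratio is then undefined on the log scale.
    """
    if svd.ev1 <= 0:
        raise DegenerateLoopError("zero T loop")
    if svd.ev2 <= RANK_TOL * svd.ev1 or svd.ev3 <= RANK_TOL * svd.ev1:
        raise DegenerateLoopError(
            f"rank-deficient T loop: eigenvalues {(svd.ev1, svd.ev2, svd.ev3)}"
        )
    return float(np.log(100.0 * svd.ev2 * svd.ev3 / svd.ev1**2))


def spatial_intervals(fid: Fiducials) -> tuple[float, float]:
    """(QT, JT) in ms: QRS onset to T end and J point to T end."""
    qt = (fid.t_end - fid.qrs_onset) / fid.fs * 1000.0
    jt = (fid.t_end - fid.qrs_offset) / fid.fs * 1000.0
    return qt, jt


def rate_correct(interval_ms: float, rr_ms: float, method: str = "bazett") -> float:
    """Heart-rate correct an interval: Bazett (RR^1/2) or Fridericia (RR^1/3)."""
    if interval_ms <= 0 or rr_ms <= 0:
        raise ValueError("interval and RR must be positive")
    rr_s = rr_ms / 1000.0
    if method == "bazett":
        return interval_ms / math.sqrt(rr_s)
    if method == "fridericia":
        return interval_ms / rr_s ** (1.0 / 3.0)
    raise ValueError(f"unknown correction method {method!r}")


def r_amplitude_y(vcg: VCGBeat, fid: Fiducials) -> float:
    """Maximum of derived lead Y over the QRS window, in uV."""
    return float(np.max(vcg.y[fid.qrs_onset : fid.qrs_offset + 1]))


def max_frontal_qrs_loop(vcg: VCGBeat, fid: Fiducials) -> float:
    """Maximum frontal-plane magnitude sqrt(x^2+y^2) over the QRS, in uV."""
    sl = slice(fid.qrs_onset, fid.qrs_offset + 1)
    return float(np.max(np.hypot(vcg.x[sl], vcg.y[sl])))


def frontal_qrs_axis(vcg: VCGBeat, fid: Fiducials, use_peak: bool = False) -> float:
    """Sine of the frontal-plane QRS axis.

    By default the axis is taken from the *net* QRS vector — the time
    integral of x and y over the QRS — the common noise-robust VCG
    convention.  ``use_peak=True`` instead uses the sample of maximal
    frontal magnitude.
    """
    sl = slice(fid.qrs_onset, fid.qrs_offset + 1)
    if use_peak:
        i = int(np.argmax(np.hypot(vcg.x[sl], vcg.y[sl])))
        vx, vy = vcg.x[sl][i], vcg.y[sl][i]
    else:
        dt = 1.0 / fid.fs
        vx = float(np.trapezoid(vcg.x[sl], dx=dt))
        vy = float(np.trapezoid(vcg.y[sl], dx=dt))
    if vx == 0.0 and vy == 0.0:
        raise UndefinedAxisError("zero net QRS vector")
    return frontal_angle_sine(vx, vy)


def spatial_t_axis(vcg: VCGBeat, fid: Fiducials) -> float:
    """Sine of the elevation angle of the peak T vector.

    The peak T vector is the sample of maximal spatial magnitude at the T
    peak fiducial; its elevation is ``atan2(y, sqrt(x^2+z^2))``.
    """
    x, y, z = vcg.x[fid.t_peak], vcg.y[fid.t_peak], vcg.z[fid.t_peak]
    denom = math.hypot(x, z)
    if denom == 0.0 and y == 0.0:
        raise UndefinedAxisError("zero peak T vector")
    return float(math.sin(math.atan2(y, denom)))


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return -((-a + 180.0) % 360.0 - 180.0)


def t_loop_elev_azim_meandiff(
    vcg: VCGBeat, fid: Fiducials, floor_uv: float = T_ANGLE_MAGNITUDE_FLOOR_UV
) -> float:
    """Mean |frontal-plane angle - azimuth| over T-loop samples, degrees.

    For each T sample (J point to T end) with spatial magnitude above the
    1-uV floor, the frontal-plane angle ``atan2(y, x)`` and the azimuth
    ``atan2(z, x)`` are compared; absolute differences are wrapped to
    [0, 180] and averaged.
    """
    sl = slice(fid.qrs_offset, fid.t_end + 1)
    x, y, z = vcg.x[sl], vcg.y[sl], vcg.z[sl]
    mag = np.sqrt(x**2 + y**2 + z**2)
    keep = mag >= floor_uv
    if not np.any(keep):
        raise DegenerateLoopError("no T-loop samples above the magnitude floor")
    e = np.degrees(np.arctan2(y[keep], x[keep]))
    a = np.degrees(np.arctan2(z[keep], x[keep]))
    diff = np.abs(_wrap_deg(e - a))
    return float(np.mean(diff))


def extract_features(
    record: ECGRecord,
    qtc_method: str = "bazett",
    centered_svd: bool = False,
    intermediates: dict | None = None,
) -> FeatureVector:
    """Run the full measurement pipeline on one record.

    filter -> R detection -> median beat -> Kors VCG -> fiducials -> the
    ten model measures.  Stage failures propagate with the stage named in
    the message.  If ``intermediates`` is a dict it is filled with the
    median beat, fiducials and raw interval values for auditing.
    """
    stage = "filter_baseline"
    try:
        filtered = filter_baseline(record)
        stage = "detect_r_peaks"
        r_peaks = detect_r_peaks(filtered)
        stage = "compute_median_beat"
        beat = compute_median_beat(filtered, r_peaks)
        stage = "kors_transform"
        vcg = kors_transform(beat.signal, fs=beat.fs)
        stage = "locate_fiducials"
        fid = locate_fiducials(beat)
        stage = "features"
        svd = t_wave_svd(vcg, fid, centered=centered_svd)
        qt_ms, jt_ms = spatial_intervals(fid)
        qtc = rate_correct(qt_ms, beat.mean_rr_ms, qtc_method)
        jtc = rate_correct(jt_ms, beat.mean_rr_ms, qtc_method)
        fv = FeatureVector(
            age=record.subject.age,
            sex=record.subject.sex,
            r_amp_y=r_amplitude_y(vcg, fid),
            frontal_qrs_axis_sine=frontal_qrs_axis(vcg, fid),
            max_frontal_qrs_loop=max_frontal_qrs_loop(vcg, fid),
            ln_intradipolar_ratio=ln_intradipolar_ratio(svd),
            ln_qtc_spatial=float(np.log(qtc)),
            jtc_spatial=jtc,
            t_axis_sine=spatial_t_axis(vcg, fid),
            t_elev_azim_meandiff=t_loop_elev_azim_meandiff(vcg, fid),
        )
    except HeartAgeError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    if intermediates is not None:
        intermediates.update(
            median_beat=beat,
            fiducials=fid,
            t_svd=svd,
            qt_ms=qt_ms,
            jt_ms=jt_ms,
            qtc_ms=qtc,
            jtc_ms=jtc,
            qtc_method=qtc_method,
        )
    _check_complete(fv)
    return fv


def _check_complete(fv: FeatureVector) -> None:
    for name, value in fv.to_dict().items():
        if name == "sex":
            continue
        if value is None or not np.isfinite(value):
            raise IncompleteFeatureError(f"feature {name!r} is missing or non-finite")
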