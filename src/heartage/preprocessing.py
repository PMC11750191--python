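"""Signal conditioning, beat detection, median beat and fiducial points.

The pipeline reduces a 10-s recording to one representative beat per
record, because every Heart Age measure is a single value per ECG:

1. zero-phase baseline filtering (0.5 Hz high-pass + powerline notch);
2. R-peak detection on the spatial vector magnitude of the Kors-derived
   VCG (threshold + refractory period);
3. per-lead, per-sample *median* across R-aligned beat windows — robust to
   a single artifactual beat in a 10-s strip;
4. fiducial location on the median beat's vector magnitude: QRS bounds by
   sustained crossing of a fraction of the QRS peak magnitude, T peak as
   the post-J magnitude maximum, T end by the tangent method on the
   descending T limb.

All detection thresholds are relative to signal amplitude, so the fiducial
indices are invariant to an overall gain change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ecg_io import ECGRecord
from .errors import ConfigError, FiducialError, InsufficientBeatsError
from .vcg import kors_transform, vector_magnitude

MIN_BEATS = 3
DEFAULT_PRE_MS = 300.0
DEFAULT_POST_MS = 500.0


@dataclass
class MedianBeat:
    """Representative R-centred beat: leads x samples (uV), 8 leads."""

    signal: np.ndarray
    fs: float
    window: tuple  # (pre_ms, post_ms)
    n_beats_used: int
    mean_rr_ms: float

    @property
    def r_index(self) -> int:
        """Sample index of the alignment point (R) within the window."""
        return int(round(self.window[0] / 1000.0 * self.fs))


@dataclass
class Fiducials:
    """Landmark sample indices on the median beat, plus rate context."""

    qrs_onset: int
    r_peak: int
    qrs_offset: int  # J point
    t_peak: int
    t_end: int
    heart_rate_bpm: float
    fs: float

    def __post_init__(self) -> None:
        if not (
            self.qrs_onset < self.r_peak < self.qrs_offset <= self.t_peak < self.t_end
        ):
            raise FiducialError(
                "fiducial ordering violated: "
                f"onset={self.qrs_onset} r={self.r_peak} j={self.qrs_offset} "
                f"tpeak={self.t_peak} tend={self.t_end}"
            )

    @property
    def qrs_duration_ms(self) -> float:
        return (self.qrs_offset - self.qrs_onset) / self.fs * 1000.0

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm


def filter_baseline(
    record: ECGRecord,
    highpass_hz: float = 0.5,
    notch_hz: float | None = 50.0,
    notch_q: float = 30.0,
) -> ECGRecord:
    """Zero-phase high-pass (baseline wander) plus optional powerline notch.

    A 2nd-order Butterworth high-pass applied forward-backward removes DC
    and sub-0.5 Hz drift while leaving ECG-band amplitudes (>= ~2 Hz)
    essentially untouched: a 10-Hz sinusoid passes within 2%.
    """
    nyq = record.fs / 2.0
    if highpass_hz >= nyq:
        raise ConfigError(f"high-pass {highpass_hz} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(2, highpass_hz / nyq, btype="highpass", output="sos")
    # pad on the scale of the filter's settling time (seconds at 0.5 Hz),
    # otherwise edge transients leak far into a 10-s record
    padlen = min(record.n_samples - 1, int(3.0 * record.fs / highpass_hz))
    filtered = sps.sosfiltfilt(sos, record.signal, axis=1, padlen=padlen)
    if notch_hz is not None and notch_hz < nyq:
        b, a = sps.iirnotch(notch_hz / nyq, notch_q)
        filtered = sps.filtfilt(b, a, filtered, axis=1)
    return ECGRecord(
        signal=filtered,
        fs=record.fs,
        lead_names=record.lead_names,
        subject=record.subject,
    )


def detect_r_peaks(
    record: ECGRecord,
    threshold_frac: float = 0.5,
    refractory_ms: float = 300.0,
    smooth_ms: float = 8.0,
) -> np.ndarray:
    """Detect R peaks on the VCG vector magnitude of the record.

    The magnitude is lightly smoothed, and peaks are kept when they exceed
    ``threshold_frac`` of a robust amplitude reference (the 99.5th
    percentile) and are separated by the refractory period.  Both criteria
    are relative, so detection is invariant to amplitude scaling.
    """
    vcg = kors_transform(record.independent_leads(), fs=record.fs)
    mag = vector_magnitude(vcg)
    win = max(1, int(round(smooth_ms / 1000.0 * record.fs)))
    smooth = np.convolve(mag, np.ones(win) / win, mode="same")
    ref = np.percentile(smooth, 99.5)
    if ref <= 0:
        raise InsufficientBeatsError("no signal energy: flat record")
    distance = max(1, int(round(refractory_ms / 1000.0 * record.fs)))
    peaks, _ = sps.find_peaks(smooth, height=threshold_frac * ref, distance=distance)
    if peaks.size < MIN_BEATS:
        raise InsufficientBeatsError(
            f"found only {peaks.size} beats (need >= {MIN_BEATS})"
        )
    # refine each peak on the unsmoothed magnitude
    half = max(1, int(round(0.02 * record.fs)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(mag.size, p + half + 1)
        refined.append(lo + int(np.argmax(mag[lo:hi])))
    return np.asarray(sorted(set(refined)), dtype=int)


def heart_rate_from_peaks(r_peaks: np.ndarray, fs: float) -> float:
    """Mean heart rate in bpm from detected R-peak indices."""
    rr = np.diff(np.asarray(r_peaks)) / fs * 1000.0
    if rr.size == 0:
        raise InsufficientBeatsError("need >= 2 peaks for a heart rate")
    return 60000.0 / float(np.mean(rr))


def compute_median_beat(
    record: ECGRecord,
    r_peaks: np.ndarray,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
    baseline_ms: float = 80.0,
) -> MedianBeat:
    """Per-lead, per-sample median across R-aligned beat windows.

    Beats whose window would cross a record boundary are dropped.  The
    sample-wise median makes the representative beat robust to a single
    artifact-laden beat without explicit morphology rejection.  After
    averaging, each lead is re-zeroed to its isoelectric level, estimated
    as the median over the earliest ``baseline_ms`` of the window (the
    TP segment, well before any QRS activity): AC-coupled filtering
    leaves the baseline at minus the beat-mean otherwise.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    pre = int(round(pre_ms / 1000.0 * record.fs))
    post = int(round(post_ms / 1000.0 * record.fs))
    leads = record.independent_leads()
    windows = [
        leads[:, p - pre : p + post]
        for p in r_peaks
        if p - pre >= 0 and p + post <= record.n_samples
    ]
    if len(windows) < MIN_BEATS:
        raise InsufficientBeatsError(
            f"only {len(windows)} beats fit the {pre_ms:.0f}/{post_ms:.0f} ms window"
        )
    stack = np.stack(windows, axis=0)  # beats x leads x samples
    median = np.median(stack, axis=0)
    base_n = max(1, int(round(baseline_ms / 1000.0 * record.fs)))
    median = median - np.median(median[:, :base_n], axis=1, keepdims=True)
    rr = np.diff(r_peaks) / record.fs * 1000.0
    return MedianBeat(
        signal=median,
        fs=record.fs,
        window=(pre_ms, post_ms),
        n_beats_used=len(windows),
        mean_rr_ms=float(np.mean(rr)),
    )


def _sustained_below(mag, start, step, thr, sustain):
    """March from ``start`` in direction ``step``; return the first index
    at which ``mag`` drops below ``thr`` and stays below it for ``sustain``
    consecutive samples.  Returns None if no such index exists."""
    i = start
    n = mag.size
    while 0 <= i < n:
        if mag[i] < thr:
            j_end = i + step * sustain
            if step > 0:
                seg = mag[i : min(n, j_end)]
            else:
                seg = mag[max(0, j_end + 1) : i + 1]
            if seg.size >= sustain and np.all(seg < thr):
                return i
        i += step
    return None


def locate_fiducials(
    beat: MedianBeat,
    qrs_threshold_frac: float = 0.05,
    sustain_ms: float = 10.0,
    t_search_start_ms: float = 40.0,
    t_tangent_span_ms: float = 250.0,
    t_min_frac: float = 0.04,
) -> Fiducials:
    """Locate QRS onset/offset, T peak and T end on the median beat.

    All landmarks are found on the spatial vector magnitude of the
    Kors-derived VCG, because the model's interval measures are "spatial"
    intervals.  QRS bounds: outward search from the R peak for a sustained
    (``sustain_ms``) drop below ``qrs_threshold_frac`` of the R magnitude.
    T peak: magnitude maximum from ``t_search_start_ms`` after J to the
    window end.  T end: tangent method — the steepest-descent tangent of
    the magnitude after T peak extrapolated to the zero baseline.
    """
    fs = beat.fs
    vcg = kors_transform(beat.signal, fs=fs)
    mag = vector_magnitude(vcg)
    n = mag.size
    sustain = max(1, int(round(sustain_ms / 1000.0 * fs)))

    # R peak: magnitude maximum near the alignment point
    guard = int(round(0.1 * fs))
    c = beat.r_index
    lo, hi = max(0, c - guard), min(n, c + guard + 1)
    r_peak = lo + int(np.argmax(mag[lo:hi]))
    peak_mag = mag[r_peak]
    if peak_mag <= 0:
        raise FiducialError("flat or zero median beat")
    thr = qrs_threshold_frac * peak_mag

    onset_cross = _sustained_below(mag, r_peak, -1, thr, sustain)
    offset_cross = _sustained_below(mag, r_peak, +1, thr, sustain)
    if onset_cross is None or offset_cross is None:
        raise FiducialError("QRS bounds not found (signal never settles)")
    qrs_onset = onset_cross + 1  # last sample above threshold going left
    qrs_offset = offset_cross  # first sustained sub-threshold sample (J)

    # T peak
    t_from = qrs_offset + int(round(t_search_start_ms / 1000.0 * fs))
    if t_from >= n - 2:
        raise FiducialError("no room for a T wave in the beat window")
    t_peak = t_from + int(np.argmax(mag[t_from:n]))
    if mag[t_peak] < t_min_frac * peak_mag:
        raise FiducialError("no T wave above the noise floor")

    # T end by the tangent method on the descending limb
    t_hi = min(n, t_peak + int(round(t_tangent_span_ms / 1000.0 * fs)))
    seg = mag[t_peak:t_hi]
    if seg.size < 5:
        raise FiducialError("descending T limb too short for tangent method")
    sg_win = min(seg.size if seg.size % 2 == 1 else seg.size - 1,
                 max(5, int(round(0.015 * fs)) | 1))
    deriv = sps.savgol_filter(seg, sg_win, polyorder=2, deriv=1)
    i_star = int(np.argmin(deriv))
    slope = deriv[i_star]
    if slope >= 0:
        raise FiducialError("no descending T limb found")
    t_end = t_peak + i_star + seg[i_star] / (-slope)
    t_end = int(round(t_end))
    if t_end >= n:
        raise FiducialError("tangent T end beyond the beat window")

    return Fiducials(
        qrs_onset=qrs_onset,
        r_peak=r_peak,
        qrs_offset=qrs_offset,
        t_peak=t_peak,
        t_end=t_end,
        heart_rate_bpm=60000.0 / beat.mean_rr_ms,
        fs=fs,
    )
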