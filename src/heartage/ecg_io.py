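"""Reading, validating and writing 12-lead ECG records and cohort tables.

The package's exchange format for raw ECGs is a plain CSV matrix — one
column per lead, one row per sample, a mandatory header naming the leads —
plus a JSON sidecar (``<file>.json``) or explicit keyword carrying the
sampling rate and amplitude unit.  The canonical in-memory representation
is :class:`ECGRecord`: the 8 independent leads [I, II, V1..V6] in
microvolts.  Limb-derived leads (III, aVR, aVL, aVF) are never stored;
they are exact linear combinations and are recomputed on demand.

Cohort tables for the survival analyses are tidy CSVs handled with pandas.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    FormatError,
    MissingLeadError,
    ValidationError,
)
from .vcg import INDEPENDENT_LEADS

#: Derived limb leads as combinations of (I, II): lead -> (coef_I, coef_II).
DERIVED_LIMB_LEADS = {
    "III": (-1.0, 1.0),
    "aVR": (-0.5, -0.5),
    "aVL": (1.0, -0.5),
    "aVF": (-0.5, 1.0),
}

#: Columns of a cohort table CSV.
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "heart_age",
    "gap",
    "followup_time",
    "event",
    "smoking",
    "diabetes",
    "hypertension",
    "hypercholesterolaemia",
    "bmi",
]

MIN_FS_HZ = 250.0
MIN_DURATION_S = 5.0
NOMINAL_DURATION_S = 10.0


@dataclass
class Subject:
    """Minimal metadata needed by the Heart Age model."""

    age: float = float("nan")
    sex: str = ""  # "male" | "female"
    id: str = ""


@dataclass
class ECGRecord:
    """A raw multi-lead recording: the entry point of the pipeline.

    ``signal`` is leads x samples in microvolts, rows ordered as
    ``lead_names`` (always normalized to [I, II, V1..V6]).
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple = INDEPENDENT_LEADS
    subject: Subject = field(default_factory=Subject)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.lead_names):
            raise ValidationError(
                f"signal shape {self.signal.shape} does not match "
                f"{len(self.lead_names)} lead names"
            )
        missing = [l for l in INDEPENDENT_LEADS if l not in self.lead_names]
        if missing:
            raise MissingLeadError(f"missing required leads: {missing}")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("ECG samples must all be finite")
        if self.fs < MIN_FS_HZ:
            raise ValidationError(f"fs must be >= {MIN_FS_HZ} Hz, got {self.fs}")
        if self.duration_s < MIN_DURATION_S:
            raise ValidationError(
                f"record of {self.duration_s:.2f} s is shorter than the "
                f"{MIN_DURATION_S:.0f} s minimum"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead by name, deriving limb leads III/aVR/aVL/aVF."""
        if name in self.lead_names:
            return self.signal[self.lead_names.index(name)]
        if name in DERIVED_LIMB_LEADS:
            ci, cii = DERIVED_LIMB_LEADS[name]
            return ci * self.lead("I") + cii * self.lead("II")
        raise MissingLeadError(f"unknown lead {name!r}")

    def independent_leads(self) -> np.ndarray:
        """The 8 x N matrix in canonical [I, II, V1..V6] order."""
        idx = [self.lead_names.index(l) for l in INDEPENDENT_LEADS]
        return self.signal[idx]


def _scale_factor(unit: str) -> float:
    unit = unit.lower()
    if unit in ("uv", "µv", "microvolt", "microvolts"):
        return 1.0
    if unit in ("mv", "millivolt", "millivolts"):
        return 1000.0
    raise ConfigError(f"unknown amplitude unit {unit!r} (use 'uV' or 'mV')")


def read_ecg(
    path,
    format: str = "csv",
    fs: float | None = None,
    unit: str | None = None,
    delimiter: str | None = None,
    subject: Subject | None = None,
) -> ECGRecord:
    """Read a 12-lead (or 8-lead) ECG file into an :class:`ECGRecord`.

    Only the CSV exchange format is supported: a header row of lead names,
    one column per lead, optional ``time`` column (ignored).  Sampling rate
    and unit come from the ``fs``/``unit`` arguments or from a JSON sidecar
    ``<path>.json`` with keys ``fs`` and optional ``unit`` (default uV) and
    ``delimiter``.  Amplitudes are converted to microvolts.
    """
    if format == "wfdb":
        raise ConfigError(
            "WFDB input is not supported by this build; convert the record "
            "to the CSV exchange format (see heartage.ecg_io docs)"
        )
    if format != "csv":
        raise ConfigError(f"unknown ECG format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sidecar = Path(str(path) + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ConfigError(
            f"sampling rate unknown for {path.name}: pass fs= or provide "
            f"a JSON sidecar {sidecar.name} with an 'fs' key"
        )
    unit = unit if unit is not None else meta.get("unit", "uV")
    delimiter = delimiter if delimiter is not None else meta.get("delimiter", ",")
    scale = _scale_factor(unit)

    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path.name} is empty") from None
        header = [h.strip() for h in header]
        keep = [i for i, h in enumerate(header) if h.lower() != "time"]
        names = [header[i] for i in keep]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                rows.append([float(row[i]) for i in keep])
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-numeric or short row"
                ) from exc

    missing = [l for l in INDEPENDENT_LEADS if l not in names]
    if missing:
        raise MissingLeadError(f"{path.name} is missing leads {missing}")
    data = np.asarray(rows, dtype=float).T * scale  # leads x samples
    order = [names.index(l) for l in INDEPENDENT_LEADS]
    sub = subject
    if sub is None:
        sub_meta = meta.get("subject", {})
        sub = Subject(
            age=float(sub_meta.get("age", "nan")),
            sex=sub_meta.get("sex", ""),
            id=str(sub_meta.get("id", path.stem)),
        )
    return ECGRecord(signal=data[order], fs=float(fs), subject=sub)


def write_ecg(record: ECGRecord, path, format: str = "csv", delimiter: str = ",") -> Path:
    """Write a record to the CSV exchange format with a JSON sidecar.

    Samples are written in microvolts at 0.1 uV resolution, so a
    write-then-read round trip reproduces the signal well within the
    declared 0.5 uV quantization.
    """
    if format != "csv":
        raise ConfigError(f"unknown ECG format {format!r}")
    path = Path(path)
    leads = record.independent_leads()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(INDEPENDENT_LEADS)
        for i in range(record.n_samples):
            writer.writerow([f"{v:.1f}" for v in leads[:, i]])
    sidecar = {
        "fs": record.fs,
        "unit": "uV",
        "delimiter": delimiter,
        "subject": {
            "age": None if math.isnan(record.subject.age) else record.subject.age,
            "sex": record.subject.sex,
            "id": record.subject.id,
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def validate_record(
    record: ECGRecord,
    heart_rate_bpm: float | None = None,
    qrs_duration_ms: float | None = None,
) -> list[str]:
    """Return applicability findings (warnings, not exceptions) for a record.

    The Heart Age model was validated on records with heart rate below
    100/min and QRS duration below 130 ms; records violating either are
    flagged, as are records shorter than the nominal 10 s.  Heart rate and
    QRS duration may be passed in (e.g. from an upstream run) or are
    recomputed from the record; if the pipeline itself fails, a
    ``pipeline_failed`` finding is emitted instead.
    """
    findings: list[str] = []
    if record.duration_s < NOMINAL_DURATION_S:
        findings.append("duration_lt_10s")
    if heart_rate_bpm is None or qrs_duration_ms is None:
        try:  # local import: preprocessing depends on this module
            from . import preprocessing

            filtered = preprocessing.filter_baseline(record)
            peaks = preprocessing.detect_r_peaks(filtered)
            beat = preprocessing.compute_median_beat(filtered, peaks)
            fid = preprocessing.locate_fiducials(beat)
            if heart_rate_bpm is None:
                heart_rate_bpm = fid.heart_rate_bpm
            if qrs_duration_ms is None:
                qrs_duration_ms = (fid.qrs_offset - fid.qrs_onset) / beat.fs * 1000.0
        except Exception:
            findings.append("pipeline_failed")
            return findings
    if heart_rate_bpm >= 100.0:
        findings.append("heart_rate_ge_100")
    if qrs_duration_ms >= 130.0:
        findings.append("qrs_ge_130ms")
    return findings


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table CSV and check its structural invariants."""
    df = pd.read_csv(path)
    missing = [c for c in ("gap", "followup_time", "event") if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    if (df["followup_time"] <= 0).any():
        raise ValidationError("followup_time must be positive")
    if {"heart_age", "age"} <= set(df.columns):
        if not np.allclose(df["gap"], df["heart_age"] - df["age"], atol=1e-9):
            raise ValidationError("gap must equal heart_age - age")
    df["event"] = df["event"].astype(bool)
    return df


def write_cohort(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
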