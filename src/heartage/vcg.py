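"""Derived vectorcardiography: the Kors transform and spatial geometry.

The standard 12-lead ECG carries 8 independent leads (I, II, V1-V6); the
remaining four limb leads are linear combinations.  The Kors regression
matrix maps those 8 leads to the three orthogonal Frank leads X (positive
leftward), Y (positive inferior) and Z (positive posterior), approximating
the cardiac dipole in 3D.  All "spatial" measures downstream — vector
magnitude intervals, loop amplitudes, axis angles, T-loop eigenvalues —
are computed on this derived vectorcardiogram (VCG).

Coordinate and angle conventions used throughout the package:

* frontal plane = X-Y plane; the frontal angle is ``atan2(y, x)``, zero
  along +X (leftward) and positive toward +Y (inferior) — the clinical
  QRS-axis convention, so a normal axis of ~55 degrees has sine ~0.82 and
  a normal R wave in Y is positive.
* azimuth = ``atan2(z, x)`` in the transverse plane; elevation =
  ``atan2(y, sqrt(x^2 + z^2))`` above the horizontal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingLeadError, UndefinedAxisError

#: Canonical order of the 8 independent leads for all matrix operations.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Kors regression matrix, rows X/Y/Z, columns in INDEPENDENT_LEADS order.
KORS_MATRIX = np.array(
    [
        [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
        [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
        [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
    ]
)

#: Moore-Penrose right inverse of the Kors matrix; K @ KORS_PINV == I3,
#: which makes lead synthesis from a VCG an exact round trip.
KORS_PINV = np.linalg.pinv(KORS_MATRIX)


@dataclass
class VCGBeat:
    """Derived Frank-lead signal on a common time base, in microvolts."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z must have equal lengths")
        if not (
            np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
            and np.all(np.isfinite(self.z))
        ):
            raise ValueError("VCG samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Return the 3 x N matrix [x; y; z]."""
        return np.vstack([self.x, self.y, self.z])


def kors_transform(leads8: np.ndarray, fs: float = 500.0) -> VCGBeat:
    """Map an 8 x N lead matrix (order I, II, V1..V6, microvolts) to a VCG.

    Parameters
    ----------
    leads8 : ndarray, shape (8, N)
        Samples of the 8 independent leads in canonical order.
    fs : float
        Sampling rate in Hz, carried through to the result.
    """
    leads8 = np.asarray(leads8, dtype=float)
    if leads8.ndim != 2 or leads8.shape[0] != 8:
        raise MissingLeadError(
            f"kors_transform expects an 8 x N matrix, got shape {leads8.shape}"
        )
    xyz = KORS_MATRIX @ leads8
    return VCGBeat(x=xyz[0], y=xyz[1], z=xyz[2], fs=fs)


def synthesize_leads_from_vcg(vcg: VCGBeat) -> np.ndarray:
    """Synthesize an 8 x N independent-lead matrix whose Kors transform is ``vcg``.

    Uses the Moore-Penrose right inverse of the Kors matrix; because the
    matrix has full row rank the round trip
    ``kors_transform(synthesize_leads_from_vcg(v)) == v`` holds to machine
    precision.  This is the workhorse of the synthetic ECG generator.
    """
    return KORS_PINV @ vcg.as_matrix()


def vector_magnitude(vcg: VCGBeat) -> np.ndarray:
    """Per-sample spatial magnitude sqrt(x^2 + y^2 + z^2), in microvolts."""
    return np.sqrt(vcg.x**2 + vcg.y**2 + vcg.z**2)


def frontal_angle_sine(x: float, y: float) -> float:
    """Sine of the frontal-plane angle of the vector (x, y).

    The angle is ``atan2(y, x)``: 0 along leftward X, positive toward the
    inferior Y direction (clinical axis convention).  Raises
    :class:`UndefinedAxisError` for the zero vector.
    """
    if x == 0.0 and y == 0.0:
        raise UndefinedAxisError("frontal angle undefined for the zero vector")
    return float(np.sin(np.arctan2(y, x)))


def azimuth_elevation(x: float, y: float, z: float) -> tuple[float, float]:
    """(azimuth, elevation) of a 3D vector, in degrees.

    Azimuth is the transverse-plane angle ``atan2(z, x)``; elevation is the
    angle above the horizontal plane ``atan2(y, sqrt(x^2 + z^2))``.
    """
    if x == 0.0 and y == 0.0 and z == 0.0:
        raise UndefinedAxisError("angles undefined for the zero vector")
    azimuth = np.degrees(np.arctan2(z, x))
    elevation = np.degrees(np.arctan2(y, np.hypot(x, z)))
    return float(azimuth), float(elevation)
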