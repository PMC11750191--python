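"""The sex-specific linear Heart Age score and Heart Age gap.

Heart Age is an explainable estimate of cardiovascular age in years: a
fixed linear combination of chronological age and nine derived-VCG
measures (no P-wave information, so the score applies in non-sinus
rhythms).  The male model has 8 ECG terms; the female model additionally
includes the frontal-plane QRS axis sine and a constant gender offset
(+4.20 years, folded into the linear predictor).  The Heart Age gap —
Heart Age minus chronological age — quantifies accelerated cardiovascular
aging; a gap of 10 or more years (about two standard deviations of the
gap among healthy adults, 2 x 5.0) marks the elevated-risk stratum.

Coefficients are frozen published constants (version tag below); the
package never refits them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureVector
from .errors import IncompleteFeatureError

MODEL_VERSION = "non-p-wave-10s-v1"

#: Dichotomization threshold (years) and the healthy-gap SD it derives from.
HEALTHY_GAP_SD_YEARS = 5.0
GAP_THRESHOLD_YEARS = 2.0 * HEALTHY_GAP_SD_YEARS


@dataclass(frozen=True)
class ModelCoefficients:
    sex: str
    intercept: float
    terms: tuple  # ordered ((feature_name, coefficient), ...)

    def as_canonical_json(self) -> str:
        return json.dumps(
            {"sex": self.sex, "intercept": self.intercept, "terms": list(self.terms)},
            sort_keys=True,
        )


MALE_COEFFICIENTS = ModelCoefficients(
    sex="male",
    intercept=-166.22,
    terms=(
        ("age", 0.900),
        ("ln_qtc_spatial", 27.5),
        ("ln_intradipolar_ratio", 1.69),
        ("r_amp_y", -0.00740),
        ("jtc_spatial", 0.0580),
        ("t_axis_sine", -3.41),
        ("max_frontal_qrs_loop", 0.00302),
        ("t_elev_azim_meandiff", 0.0279),
    ),
)

# The female model's constant gender term (+4.20) is applied as a constant
# added to the linear predictor; equivalent to an intercept of -195.80.
FEMALE_GENDER_CONSTANT = 4.20

FEMALE_COEFFICIENTS = ModelCoefficients(
    sex="female",
    intercept=-200.0,
    terms=(
        ("age", 0.942),
        ("frontal_qrs_axis_sine", -9.59),
        ("ln_qtc_spatial", 32.3),
        ("r_amp_y", -0.00869),
        ("ln_intradipolar_ratio", 1.88),
        ("jtc_spatial", 0.0676),
        ("t_axis_sine", -3.77),
        ("max_frontal_qrs_loop", 0.00345),
        ("t_elev_azim_meandiff", 0.0334),
    ),
)

#: SHA-256 of the canonical JSON dumps, pinning the constants against
#: accidental edits (checked by the test suite).
COEFFICIENT_HASHES = {
    "male": "sha256 computed at import",
    "female": "sha256 computed at import",
}


def coefficient_hash(coef: ModelCoefficients) -> str:
    return hashlib.sha256(coef.as_canonical_json().encode()).hexdigest()


COEFFICIENT_HASHES = {
    "male": coefficient_hash(MALE_COEFFICIENTS),
    "female": coefficient_hash(FEMALE_COEFFICIENTS),
}

#: Healthy-group reference (mean, SD) of each measure, used only to warn
#: when an input lies far outside the range the model was built on.
HEALTHY_REFERENCE = {
    "age": (39.0, 13.0),
    "r_amp_y": (1144.0, 392.0),
    "frontal_qrs_axis_sine": (0.82, 0.23),
    "max_frontal_qrs_loop": (1617.0, 411.0),
    "ln_intradipolar_ratio": (-0.69, 0.83),
    "ln_qtc_spatial": (6.00, 0.06),
    "t_axis_sine": (0.71, 0.20),
    "jtc_spatial": (336.0, 23.0),
    "t_elev_azim_meandiff": (41.0, 16.0),
}


@dataclass
class HeartAgeResult:
    heart_age: float  # years
    gap: float  # years, == heart_age - age
    model_sex: str
    qtc_method: str
    feature_snapshot: FeatureVector


def compute_heart_age(
    fv: FeatureVector, qtc_method: str = "bazett", warn_extrapolation: bool = True
) -> HeartAgeResult:
    """Apply the sex-appropriate linear model to a complete feature vector.

    The output is the exact dot product plus intercept — no clipping.  A
    warning is emitted (not an error) when any input lies outside the
    healthy reference mean +/- 4 SD, since the score is then an
    extrapolation.
    """
    if fv.sex == "male":
        coef = MALE_COEFFICIENTS
        constant = 0.0
    elif fv.sex == "female":
        coef = FEMALE_COEFFICIENTS
        constant = FEMALE_GENDER_CONSTANT
    else:
        raise ValueError(f"unknown sex {fv.sex!r} (use 'male' or 'female')")

    values = fv.to_dict()
    ha = coef.intercept + constant
    for name, c in coef.terms:
        v = values.get(name)
        if v is None or not np.isfinite(v):
            raise IncompleteFeatureError(f"feature {name!r} missing for {fv.sex} model")
        ha += c * v

    if warn_extrapolation:
        for name, (mu, sd) in HEALTHY_REFERENCE.items():
            v = values.get(name)
            if v is not None and np.isfinite(v) and abs(v - mu) > 4.0 * sd:
                warnings.warn(
                    f"feature {name}={v:.4g} lies outside the healthy reference "
                    f"range {mu} +/- 4*{sd}; Heart Age is an extrapolation",
                    stacklevel=2,
                )

    return HeartAgeResult(
        heart_age=float(ha),
        gap=float(ha - fv.age),
        model_sex=fv.sex,
        qtc_method=qtc_method,
        feature_snapshot=fv,
    )


def heart_age_gap(result: HeartAgeResult, age: float) -> float:
    """Heart Age gap in years: Heart Age minus chronological age."""
    if age < 0:
        raise ValueError("age must be non-negative")
    return float(result.heart_age - age)


def classify_gap(gap: float, threshold: float = GAP_THRESHOLD_YEARS) -> str:
    """Dichotomize a gap: 'at_or_above' iff gap >= threshold (closed bound)."""
    if not np.isfinite(gap):
        raise ValueError("gap must be finite")
    return "at_or_above" if gap >= threshold else "below"
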