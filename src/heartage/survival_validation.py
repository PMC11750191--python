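"""Prognostic-validation statistics for Heart Age gap cohorts.

Implements the validation toolbox used to assess whether an elevated
Heart Age gap carries prognostic information in a cohort with follow-up:

* Kaplan-Meier curves by gap stratum;
* Cox proportional-hazards fits (Efron tie handling, via lifelines) for a
  dichotomized gap (>= threshold) or the continuous gap per 5-year
  increment, unadjusted or covariate-adjusted, with an optional
  gap x age interaction tested by likelihood ratio;
* Harrell's concordance statistic with a jackknife 95% CI;
* a restricted-cubic-spline Cox dose-response curve of hazard ratio
  versus continuous gap, normalized to HR = 1 at a reference gap;
* repeatability (minimum detectable change) and method-agreement
  (Bland-Altman) statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy import stats

from .errors import DegenerateFitError, FitError
from .heartage_model import GAP_THRESHOLD_YEARS

ADJUSTMENT_COVARIATES = (
    "age",
    "sex",
    "smoking",
    "diabetes",
    "hypertension",
    "hypercholesterolaemia",
    "bmi",
)


@dataclass
class SurvivalFit:
    """Hazard ratio for the exposure term, with CI, concordance and terms."""

    hr: float
    ci: tuple
    c_statistic: float
    c_ci: tuple
    model_terms: list
    exposure: str
    lrt_p: float | None = None
    log_likelihood: float = float("nan")
    n_events: int = 0
    fitter: CoxPHFitter | None = field(default=None, repr=False)


@dataclass
class AgreementStats:
    """Bland-Altman style agreement between two measurements."""

    r2: float
    bias: float
    sd_diff: float
    mdc: float
    n: int


def km_curve(
    cohort: pd.DataFrame,
    threshold: float = GAP_THRESHOLD_YEARS,
    max_years: int | None = None,
) -> dict:
    """Product-limit survival per gap stratum, with yearly risk tables.

    Returns ``{label: {"times", "survival", "risk_table"}}`` where
    ``risk_table`` is a DataFrame of subjects at risk at yearly ticks.
    """
    out = {}
    labels = {
        "below": cohort["gap"] < threshold,
        "at_or_above": cohort["gap"] >= threshold,
    }
    if max_years is None:
        max_years = int(np.ceil(cohort["followup_time"].max()))
    ticks = np.arange(0, max_years + 1)
    for label, mask in labels.items():
        sub = cohort[mask]
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["followup_time"], event_observed=sub["event"], label=label)
        at_risk = [
            int((sub["followup_time"] >= t).sum()) for t in ticks
        ]
        out[label] = {
            "times": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[label].to_numpy(),
            "risk_table": pd.DataFrame({"year": ticks, "at_risk": at_risk}),
            "kmf": kmf,
        }
    return out


def _prepare_exposure(
    cohort: pd.DataFrame, exposure: str, threshold: float
) -> tuple[pd.DataFrame, str]:
    df = cohort.copy()
    if exposure == "gap_class":
        df["exposure"] = (df["gap"] >= threshold).astype(float)
    elif exposure == "gap_per_5y":
        df["exposure"] = df["gap"] / 5.0
    else:
        raise ValueError(f"unknown exposure {exposure!r}")
    return df, "exposure"


def fit_cox(
    cohort: pd.DataFrame,
    exposure: str = "gap_class",
    adjust: list | tuple = (),
    interaction_age: bool = False,
    threshold: float = GAP_THRESHOLD_YEARS,
) -> SurvivalFit:
    """Cox proportional-hazards fit for the Heart Age gap exposure.

    ``exposure`` is ``"gap_class"`` (indicator gap >= threshold) or
    ``"gap_per_5y"`` (continuous, HR per 5-year increment).  ``adjust``
    names covariate columns; ``sex`` is encoded as male=1.  With
    ``interaction_age`` the model is refit with an exposure x age term and
    the two models are compared by likelihood ratio test (1 df).
    """
    n_events = int(cohort["event"].sum())
    if n_events == 0:
        raise DegenerateFitError("no events in cohort: Cox model undefined")
    df, expo_col = _prepare_exposure(cohort, exposure, threshold)

    cols = [expo_col]
    for c in adjust:
        if c == "sex":
            df["sex_male"] = (df["sex"] == "male").astype(float)
            cols.append("sex_male")
        else:
            cols.append(c)
    n_terms = len(cols) + (1 if interaction_age else 0)
    if n_events < 10 * n_terms:
        warnings.warn(
            f"{n_events} events for {n_terms} terms (< 10 per term): "
            "estimates may be unstable",
            stacklevel=2,
        )

    data = df[cols + ["followup_time", "event"]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="followup_time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError and others
        raise FitError(f"Cox fit failed: {exc}") from exc

    lrt_p = None
    if interaction_age:
        if "age" not in df.columns:
            raise FitError("interaction_age requires an 'age' column")
        data_i = data.copy()
        data_i["exposure_x_age"] = df[expo_col] * df["age"]
        if "age" not in data_i.columns:
            data_i["age"] = df["age"].astype(float)
        cph_i = CoxPHFitter()
        try:
            cph_i.fit(data_i, duration_col="followup_time", event_col="event")
        except Exception as exc:
            raise FitError(f"interaction Cox fit failed: {exc}") from exc
        lr = 2.0 * (cph_i.log_likelihood_ - cph.log_likelihood_)
        lrt_p = float(stats.chi2.sf(max(lr, 0.0), df=len(data_i.columns) - len(data.columns)))

    hr = float(np.exp(cph.params_[expo_col]))
    ci_df = cph.confidence_intervals_
    lo = float(np.exp(ci_df.loc[expo_col].iloc[0]))
    hi = float(np.exp(ci_df.loc[expo_col].iloc[1]))
    risk = cph.predict_partial_hazard(data).to_numpy()
    # leave-one-out CI is quadratic in n; skip it for large cohorts
    c, c_ci = concordance(
        cohort["followup_time"].to_numpy(),
        cohort["event"].to_numpy(),
        risk,
        max_jackknife_n=800,
    )
    return SurvivalFit(
        hr=hr,
        ci=(lo, hi),
        c_statistic=c,
        c_ci=c_ci,
        model_terms=list(cph.params_.index),
        exposure=exposure,
        lrt_p=lrt_p,
        log_likelihood=float(cph.log_likelihood_),
        n_events=n_events,
        fitter=cph,
    )


def concordance(
    followup_time: np.ndarray,
    event: np.ndarray,
    risk_scores: np.ndarray,
    ci_method: str = "jackknife",
    max_jackknife_n: int = 3000,
) -> tuple[float, tuple]:
    """Harrell's C for risk scores against right-censored outcomes.

    C is the fraction of usable pairs in which the subject with the higher
    risk score fails earlier.  The 95% CI is a leave-one-out jackknife
    (skipped, returning NaNs, when n exceeds ``max_jackknife_n``).
    """
    t = np.asarray(followup_time, dtype=float)
    e = np.asarray(event, dtype=bool)
    r = np.asarray(risk_scores, dtype=float)
    if t.size < 2 or e.sum() == 0:
        raise DegenerateFitError("need >= 2 subjects and >= 1 event for concordance")
    # lifelines' concordance_index is for *predicted survival time*; pass
    # negated risk so higher risk means earlier expected failure
    c = float(concordance_index(t, -r, e))
    if ci_method != "jackknife" or t.size > max_jackknife_n:
        return c, (float("nan"), float("nan"))
    n = t.size
    mask = np.ones(n, dtype=bool)
    loo = np.empty(n)
    for i in range(n):
        mask[i] = False
        if e[mask].sum() == 0:
            loo[i] = c
        else:
            loo[i] = concordance_index(t[mask], -r[mask], e[mask])
        mask[i] = True
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return c, (c - 1.96 * se, c + 1.96 * se)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    For k knots the basis has k-1 columns: x itself plus k-2 nonlinear
    terms that are cubic between the boundary knots and linear beyond
    them.  Standard construction with the (t_k - t_1)^2 scaling.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    k = knots.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    scale = (tk - t1) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cube(x - tj)
            - cube(x - tk1) * (tk - tj) / (tk - tk1)
            + cube(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


def rcs_hr_curve(
    cohort: pd.DataFrame,
    n_knots: int = 3,
    ref_gap: float = 0.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cox restricted-cubic-spline dose-response of HR versus gap.

    Knots sit at the (0.1, 0.5, 0.9) gap quantiles for 3 knots (evenly
    spaced quantiles between 0.05 and 0.95 for 4-5 knots).  The returned
    curve is the hazard ratio relative to ``ref_gap`` with a pointwise
    Wald 95% band; HR(ref_gap) = 1 exactly by construction.
    """
    gap = cohort["gap"].to_numpy(dtype=float)
    if np.unique(gap).size < 50:
        raise FitError("need >= 50 distinct gap values for a spline fit")
    if int(cohort["event"].sum()) == 0:
        raise DegenerateFitError("no events in cohort")
    if n_knots == 3:
        qs = [0.1, 0.5, 0.9]
    elif n_knots in (4, 5):
        qs = list(np.linspace(0.05, 0.95, n_knots))
    else:
        raise ValueError("n_knots must be 3, 4 or 5")
    knots = np.quantile(gap, qs)
    if np.unique(knots).size < len(qs):
        raise FitError("degenerate knots: insufficient spread in gap")

    basis = rcs_basis(gap, knots)
    names = [f"rcs{j}" for j in range(basis.shape[1])]
    data = pd.DataFrame(basis, columns=names)
    data["followup_time"] = cohort["followup_time"].to_numpy(dtype=float)
    data["event"] = cohort["event"].to_numpy(dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="followup_time", event_col="event")
    except Exception as exc:
        raise FitError(f"spline Cox fit failed: {exc}") from exc

    if grid is None:
        grid = np.linspace(np.quantile(gap, 0.01), np.quantile(gap, 0.99), 101)
    grid = np.asarray(grid, dtype=float)
    bg = rcs_basis(grid, knots)
    b0 = rcs_basis(np.array([ref_gap]), knots)
    delta = bg - b0  # contrast vs the reference gap
    beta = cph.params_[names].to_numpy()
    cov = cph.variance_matrix_.loc[names, names].to_numpy()
    log_hr = delta @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, cov, delta))
    return pd.DataFrame(
        {
            "gap": grid,
            "log_hr": log_hr,
            "hr": np.exp(log_hr),
            "hr_lo": np.exp(log_hr - 1.96 * se),
            "hr_hi": np.exp(log_hr + 1.96 * se),
        }
    )


def minimum_detectable_change(first: np.ndarray, second: np.ndarray) -> float:
    """MDC in years: 1.96 * sqrt(2) * SEM of the paired repeat differences.

    ``first`` and ``second`` are repeated gap measurements of the same
    subjects; SEM = SD(differences, ddof=1) / sqrt(n).  The smallest
    change exceeding measurement noise at 95% confidence.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 equally sized measurement pairs")
    d = a - b
    sem = float(np.std(d, ddof=1) / np.sqrt(d.size))
    return 1.96 * np.sqrt(2.0) * sem


def bland_altman_agreement(a: np.ndarray, b: np.ndarray) -> AgreementStats:
    """Agreement between two measurement methods on the same subjects.

    Bias and SD of the differences a-b, R^2 of the least-squares
    regression of a on b, and the MDC computed from the same pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 equally sized pairs")
    d = a - b
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r2 = 1.0 if np.allclose(d, d[0]) else 0.0
    else:
        r2 = float(stats.linregress(b, a).rvalue ** 2)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return AgreementStats(
        r2=r2,
        bias=float(np.mean(d)),
        sd_diff=sd,
        mdc=minimum_detectable_change(a, b),
        n=a.size,
    )
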