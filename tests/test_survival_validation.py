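"""Survival statistics against hand oracles and brute-force enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heartage import (
    CohortParams,
    DegenerateFitError,
    bland_altman_agreement,
    concordance,
    fit_cox,
    km_curve,
    minimum_detectable_change,
    rcs_basis,
    rcs_hr_curve,
    simulate_cohort,
)


def _cohort(times, events, gaps=None, **extra):
    n = len(times)
    return pd.DataFrame({
        "followup_time": times,
        "event": events,
        "gap": gaps if gaps is not None else np.linspace(0, 20, n),
        **extra,
    })


def _km_oracle(times, events):
    """Hand product-limit: S(t) after each distinct event time."""
    order = np.argsort(times)
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    out = {}
    for ti in sorted(set(t[e])):
        at_risk = np.sum(t >= ti)
        d = np.sum((t == ti) & e)
        s *= 1.0 - d / at_risk
        out[ti] = s
    return out


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        df = _cohort([1.0, 2.0, 3.0, 4.0], [False] * 4, gaps=[0, 0, 20, 20])
        km = km_curve(df)
        for d in km.values():
            assert np.all(d["survival"] == 1.0)

    def test_hand_product_limit_four_subjects(self):
        df = _cohort([1.0, 1.5, 2.0, 3.0], [True, False, True, False],
                     gaps=[0.0, 0.0, 0.0, 0.0])
        km = km_curve(df)["below"]
        sf = dict(zip(km["times"], km["survival"]))
        assert sf[1.0] == pytest.approx(0.75)
        assert sf[2.0] == pytest.approx(0.375)

    def test_all_events_at_one_drop_to_zero(self):
        df = _cohort([1.0, 1.0, 1.0], [True] * 3, gaps=[0.0] * 3)
        km = km_curve(df)["below"]
        assert km["survival"][-1] == pytest.approx(0.0)

    def test_matches_oracle_on_random_small_tables(self, rng):
        for _ in range(25):
            n = rng.integers(3, 11)
            times = np.round(rng.exponential(3.0, n), 3) + 0.01
            events = rng.random(n) < 0.6
            if not events.any():
                continue
            df = _cohort(times, events, gaps=np.zeros(n))
            km = km_curve(df)["below"]
            sf = dict(zip(km["times"], km["survival"]))
            for ti, s in _km_oracle(times, events).items():
                assert sf[ti] == pytest.approx(s, abs=1e-12)


class TestCox:
    def test_identical_groups_give_unit_hr(self):
        times = np.r_[np.linspace(1, 5, 40), np.linspace(1, 5, 40)]
        events = np.r_[np.tile([True, False], 20), np.tile([True, False], 20)]
        gaps = np.r_[np.zeros(40), np.full(40, 20.0)]
        df = _cohort(times, events, gaps)
        fit = fit_cox(df, exposure="gap_class")
        assert fit.hr == pytest.approx(1.0, abs=1e-6)

    def test_no_events_raises(self):
        df = _cohort([1.0, 2.0, 3.0], [False] * 3)
        with pytest.raises(DegenerateFitError):
            fit_cox(df)

    def test_adjusted_fit_includes_covariates(self):
        p = CohortParams(n=800, baseline_hazard=0.04, seed=10)
        df = simulate_cohort(p)
        fit = fit_cox(df, exposure="gap_class",
                      adjust=["age", "sex", "smoking", "bmi"])
        assert set(fit.model_terms) >= {"exposure", "age", "sex_male",
                                        "smoking", "bmi"}
        assert fit.ci[0] <= fit.hr <= fit.ci[1]

    def test_interaction_lrt_reports_p_value(self):
        df = simulate_cohort(CohortParams(n=800, baseline_hazard=0.04, seed=11))
        fit = fit_cox(df, exposure="gap_class", adjust=["age"],
                      interaction_age=True)
        assert fit.lrt_p is not None and 0.0 <= fit.lrt_p <= 1.0

    def test_binary_exposure_recovery_single_seed(self):
        p = CohortParams(n=2000, log_hr_per_5y=0.0, log_hr_gap_class=np.log(2.0),
                         baseline_hazard=0.03, seed=42)
        df = simulate_cohort(p)
        fit = fit_cox(df, exposure="gap_class")
        assert fit.n_events >= 300
        assert 1.7 <= fit.hr <= 2.3
        assert fit.ci[0] <= 2.0 <= fit.ci[1]


def _brute_force_c(times, events, scores):
    """Pair-enumeration oracle for Harrell's C."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable pair: the earlier time is an observed event
            if times[i] < times[j] and events[i]:
                den += 1.0
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, True, True, True])
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        c, _ = concordance(t, e, scores, ci_method="none")
        assert c == pytest.approx(1.0)

    def test_three_subject_hand_enumeration(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([True, True, False])
        scores = np.array([3.0, 1.0, 2.0])
        c, _ = concordance(t, e, scores, ci_method="none")
        assert c == pytest.approx(2.0 / 3.0)

    def test_random_scores_near_half(self, rng):
        n = 4000
        t = rng.exponential(5.0, n)
        e = rng.random(n) < 0.5
        scores = rng.random(n)
        c, _ = concordance(t, e, scores, ci_method="none")
        assert c == pytest.approx(0.5, abs=0.05)

    def test_equals_brute_force_on_random_cohorts(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 101))
            t = rng.exponential(5.0, n)
            e = rng.random(n) < 0.6
            if not e.any():
                continue
            scores = rng.normal(size=n)
            c, _ = concordance(t, e, scores, ci_method="none")
            assert c == pytest.approx(_brute_force_c(t, e, scores), abs=1e-12)

    def test_jackknife_ci_brackets_estimate(self, rng):
        n = 120
        t = rng.exponential(5.0, n)
        e = rng.random(n) < 0.6
        scores = t + rng.normal(0, 3, n)
        c, (lo, hi) = concordance(t, e, -scores)
        assert lo <= c <= hi
        assert hi - lo < 0.5


class TestSplineCurve:
    def test_reference_gap_has_unit_hr_exactly(self):
        df = simulate_cohort(CohortParams(n=1500, baseline_hazard=0.03, seed=21))
        curve = rcs_hr_curve(df, ref_gap=0.0,
                             grid=np.array([-5.0, 0.0, 5.0, 10.0]))
        assert curve.loc[curve["gap"] == 0.0, "hr"].iloc[0] == pytest.approx(
            1.0, abs=1e-12
        )

    def test_loglinear_generator_matches_linear_fit(self):
        # data with exactly log-linear hazard in gap: the spline curve must
        # agree with the straight line within its own CI band
        p = CohortParams(n=3000, log_hr_per_5y=np.log(1.5), baseline_hazard=0.03,
                         seed=31)
        df = simulate_cohort(p)
        curve = rcs_hr_curve(df, ref_gap=0.0)
        fit = fit_cox(df, exposure="gap_per_5y")
        line = np.exp(np.log(fit.hr) * curve["gap"] / 5.0)
        inside = (line >= curve["hr_lo"]) & (line <= curve["hr_hi"])
        central = (curve["gap"] >= df["gap"].quantile(0.1)) & (
            curve["gap"] <= df["gap"].quantile(0.9)
        )
        assert inside[central].mean() >= 0.95

    def test_monotone_generator_gives_monotone_central_curve(self):
        p = CohortParams(n=2500, log_hr_per_5y=np.log(1.6), baseline_hazard=0.03,
                         seed=41)
        curve = rcs_hr_curve(simulate_cohort(p), ref_gap=0.0)
        gap = curve["gap"].to_numpy()
        lo, hi = np.quantile(gap, [0.1, 0.9])
        central = curve[(curve["gap"] >= lo) & (curve["gap"] <= hi)]
        assert np.all(np.diff(central["hr"]) > 0)

    def test_rcs_basis_linear_tails(self):
        knots = np.array([-2.0, 3.0, 12.0])
        x = np.linspace(15.0, 30.0, 10)  # beyond the last knot
        b = rcs_basis(x, knots)
        # second differences vanish where the spline is linear
        for col in range(b.shape[1]):
            assert np.allclose(np.diff(b[:, col], 2), 0.0, atol=1e-9)


class TestRepeatabilityAndAgreement:
    def test_identical_pairs_give_zero_mdc(self):
        a = np.array([1.0, 2.0, 3.0])
        assert minimum_detectable_change(a, a.copy()) == 0.0

    def test_formula_constant(self):
        # sem of differences == 1  ->  mdc == 1.96 * sqrt(2)
        diffs = np.array([2.0, -2.0, 2.0, -2.0])  # sd 2.3094, sem 1.1547
        sem = np.std(diffs, ddof=1) / 2.0
        mdc = minimum_detectable_change(diffs, np.zeros(4))
        assert mdc / sem == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-12)

    def test_four_pair_hand_oracle(self):
        first = np.array([1.0, -1.0, 2.0, -2.0])
        second = np.zeros(4)
        assert minimum_detectable_change(first, second) == pytest.approx(
            2.531, abs=1e-3
        )

    def test_identical_methods_agree_perfectly(self):
        a = np.linspace(30, 80, 40)
        stats = bland_altman_agreement(a, a.copy())
        assert stats.bias == 0.0
        assert stats.sd_diff == 0.0
        assert stats.r2 == pytest.approx(1.0)

    def test_noisy_agreement_simulation(self, rng):
        b = rng.uniform(30, 80, 5000)
        a = b + rng.normal(0, 6.7, 5000)
        stats = bland_altman_agreement(a, b)
        assert stats.bias == pytest.approx(0.0, abs=0.3)
        assert stats.sd_diff == pytest.approx(6.7, abs=0.3)
        assert 0.8 < stats.r2 <= 1.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(k=st.floats(0.1, 50.0), flip=st.booleans())
def test_mdc_scale_equivariance(k, flip):
    base = np.array([1.0, -0.5, 2.0, 0.25, -1.5])
    factor = -k if flip else k
    m1 = minimum_detectable_change(base, np.zeros(5))
    m2 = minimum_detectable_change(base * factor, np.zeros(5))
    assert m2 == pytest.approx(abs(factor) * m1, rel=1e-9)
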