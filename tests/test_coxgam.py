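"""Penalized additive Cox model: partial-likelihood machinery against
hand computation and brute-force oracles, penalty limits, and reporting."""

import numpy as np
import pandas as pd
import pytest

from accelcox.coxgam import (
    ModelSpec,
    breslow_loglik_grad_hess,
    covariate_hr_table,
    fit,
    fit_poisson_expanded,
    hr_per_mg_segment,
    intensity_weight_curve,
    volume_curve,
)
from accelcox.simulate import SimConfig, generate_cohort
from oracles import brute_force_cox_fit, naive_cox_loglik


def _parametric_cohort(n=120, seed=1, h0=0.04):
    cfg = SimConfig(
        n_participants=n,
        baseline_hazard=h0,
        volume_effect={"type": "null"},
        weight_function={"type": "null"},
        center_sd=0.0,
        seed=seed,
    )
    tab, _ = generate_cohort(cfg)
    return tab


PARAM_SPEC = ModelSpec(
    adjusted=True, include_volume=False, include_intensity=False,
    lambdas={"center": 1e9},
)


class TestPartialLikelihood:
    def test_score_at_zero_matches_hand_computation(self):
        """Six subjects, one binary covariate, no ties. At beta=0 the score
        is sum over deaths of (x_i - mean x over the risk set)."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 0, 1, 0])
        x = np.array([[1.0], [0.0], [1.0], [1.0], [0.0], [1.0]])
        # risk sets: t=1 -> all 6 (4 exposed); t=3 -> {3..6} (3 of 4);
        # t=5 -> {5,6} (1 of 2)
        hand_score = (1 - 4 / 6) + (1 - 3 / 4) + (0 - 1 / 2)
        ll, g, H = breslow_loglik_grad_hess(np.zeros(1), x, time, event)
        assert g[0] == pytest.approx(hand_score, abs=1e-12)
        # log-likelihood at 0 is -sum log |risk set|
        assert ll == pytest.approx(-(np.log(6) + np.log(4) + np.log(2)), abs=1e-12)

    def test_loglik_matches_naive_implementation(self, rng):
        time = np.round(rng.exponential(2.0, 50), 1) + 0.05
        event = rng.integers(0, 2, 50)
        event[:3] = 1
        X = rng.standard_normal((50, 3))
        beta = rng.standard_normal(3) * 0.5
        ll, _, _ = breslow_loglik_grad_hess(beta, X, time, event)
        assert ll == pytest.approx(naive_cox_loglik(beta, X, time, event), abs=1e-9)

    def test_parametric_fit_matches_brute_force(self):
        tab = _parametric_cohort(n=120, seed=2)
        tab = tab[["time_years", "event", "sex_male", "age_years",
                   "current_smoker"]].copy()
        X = tab[["sex_male", "age_years", "current_smoker"]].to_numpy()
        X = X - X.mean(axis=0)
        time = tab["time_years"].to_numpy()
        event = tab["event"].to_numpy()
        from accelcox.coxgam import _newton_penalized

        beta, *_ = _newton_penalized(
            X, time, event, np.zeros((3, 3)), np.zeros(3), grad_tol=1e-10
        )
        oracle = brute_force_cox_fit(X, time, event)
        assert np.abs(beta - oracle).max() < 1e-6

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        tab = _parametric_cohort(n=400, seed=3)
        cols = ["sex_male", "age_years", "degree_educated", "townsend",
                "poor_health", "longstanding_illness", "current_smoker",
                "exceeds_alcohol", "bmi_overweight", "bmi_obese"]
        f = fit(tab, PARAM_SPEC)
        cph = CoxPHFitter()
        cph.fit(tab[["time_years", "event"] + cols], "time_years", "event")
        ours = np.array([f.beta[f.design.par_cols[c]] for c in cols])
        assert np.abs(ours - cph.params_.reindex(cols).to_numpy()).max() < 1e-4


class TestPenaltyLimits:
    def test_infinite_penalty_kills_fully_penalized_terms(self, bins):
        """lambda -> infinity zeroes the intensity weight (empty null space
        after constraint) and the center effects; the volume smooth reduces
        to its unpenalized linear component."""
        cfg = SimConfig(n_participants=500, baseline_hazard=0.03, seed=6)
        tab, _ = generate_cohort(cfg, bins)
        spec = ModelSpec(
            adjusted=True,
            lambdas={"volume": 1e12, "intensity": 1e12, "center": 1e12},
        )
        f = fit(tab, spec, bins)
        w = intensity_weight_curve(f, np.linspace(3, 600, 50))
        np.testing.assert_allclose(w["fit"], 0.0, atol=1e-4)
        np.testing.assert_allclose(f.beta[f.design.blocks["center"]], 0.0, atol=1e-4)
        vc = volume_curve(f, np.linspace(15, 45, 30))
        # second differences of a line vanish
        d2 = np.diff(vc["fit"].to_numpy(), 2)
        np.testing.assert_allclose(d2, 0.0, atol=1e-6)

    def test_poisson_expansion_equivalence(self, bins):
        """Direct penalized partial-likelihood fit and the risk-set-expanded
        penalized Poisson fit agree on beta."""
        cfg = SimConfig(n_participants=200, baseline_hazard=0.025, seed=5)
        tab, _ = generate_cohort(cfg, bins)
        lam = {"volume": 1.5, "intensity": 0.2}
        spec = ModelSpec(adjusted=False, lambdas=lam)
        f = fit(tab, spec, bins)
        bp = fit_poisson_expanded(tab, spec, bins, lambdas=lam)
        assert np.abs(f.beta - bp).max() < 1e-4


class TestReporting:
    def test_hr_table_scales_and_exponentiates(self, fit_adjusted):
        t = covariate_hr_table(fit_adjusted).set_index("covariate")
        assert t.loc["age_years", "scale"] == 10.0
        assert t.loc["townsend", "scale"] == 2.8
        j = fit_adjusted.design.par_cols["sex_male"]
        assert t.loc["sex_male", "hr"] == pytest.approx(
            np.exp(fit_adjusted.beta[j])
        )
        assert (t["hr_lo"] <= t["hr"]).all() and (t["hr"] <= t["hr_hi"]).all()

    def test_hr_table_requires_adjusted_fit(self, fit_unadjusted):
        with pytest.raises(ValueError, match="unadjusted"):
            covariate_hr_table(fit_unadjusted)

    def test_segment_hr_is_chord_of_volume_curve(self, fit_unadjusted):
        """hr_per_mg_segment equals the chord of the fitted volume smooth."""
        seg = hr_per_mg_segment(fit_unadjusted, [(20.0, 30.0)]).iloc[0]
        vc = volume_curve(fit_unadjusted, np.array([20.0, 30.0]))
        chord = (vc["fit"].iloc[1] - vc["fit"].iloc[0]) / 10.0
        assert seg["hr_per_mg"] == pytest.approx(np.exp(chord), rel=1e-10)

    def test_linear_fit_gives_constant_segment_hr(self, bins):
        """When the fitted log-hazard in volume is exactly linear (infinite
        penalty), every segment reports the same per-mg hazard ratio."""
        cfg = SimConfig(n_participants=500, baseline_hazard=0.03, seed=6)
        tab, _ = generate_cohort(cfg, bins)
        spec = ModelSpec(adjusted=False, lambdas={"volume": 1e12, "intensity": 1.0})
        f = fit(tab, spec, bins)
        seg = hr_per_mg_segment(f, [(15.0, 20.0), (20.0, 40.0), (40.0, 60.0)])
        assert seg["hr_per_mg"].std() == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_segment_errors(self, fit_unadjusted):
        with pytest.raises(ValueError, match="degenerate"):
            hr_per_mg_segment(fit_unadjusted, [(20.0, 20.0)])

    def test_extrapolation_warns_and_flags(self, fit_unadjusted):
        lo, hi = fit_unadjusted.design.volume_range
        with pytest.warns(UserWarning, match="extrapolation"):
            vc = volume_curve(fit_unadjusted, np.array([lo - 5.0, lo + 5.0]))
        assert bool(vc["extrapolated"].iloc[0]) and not bool(vc["extrapolated"].iloc[1])

    def test_weight_curve_has_no_affine_component(self, fit_unadjusted, bins):
        """The fitted weight function projected onto {1, z} returns zero
        coefficients: the model cannot express mean-intensity information."""
        w = intensity_weight_curve(fit_unadjusted, bins.z)["fit"].to_numpy()
        A = np.column_stack([np.ones_like(bins.z), bins.z])
        coef = np.linalg.lstsq(A, w, rcond=None)[0]
        np.testing.assert_allclose(coef, 0.0, atol=1e-8)


class TestInvariances:
    def test_eta_invariant_to_affine_covariate_rescaling(self):
        """Rescaling a covariate rescales its coefficient exactly and leaves
        the linear predictor unchanged."""
        tab = _parametric_cohort(n=300, seed=9)
        f1 = fit(tab, PARAM_SPEC)
        tab2 = tab.copy()
        tab2["age_years"] = tab2["age_years"] / 10.0 - 6.0
        f2 = fit(tab2, PARAM_SPEC)
        j = f1.design.par_cols["age_years"]
        assert f2.beta[j] == pytest.approx(10.0 * f1.beta[j], rel=1e-5)
        # eta differs only by a constant (Cox is location-free)
        d = f2.eta - f1.eta
        assert d.std() == pytest.approx(0.0, abs=1e-5)

    def test_center_variance_recovered_within_half(self, bins):
        """With 22 centers of SD 0.5, the ridge-estimated center effects
        have variance within +/-50% of truth (averaged over 3 cohorts)."""
        est = []
        for seed in (1, 2, 3):
            cfg = SimConfig(
                n_participants=4000, baseline_hazard=0.0165, seed=seed,
                center_sd=0.5,
            )
            tab, _ = generate_cohort(cfg, bins)
            f = fit(tab, ModelSpec(adjusted=True), bins)
            est.append(f.beta[f.design.blocks["center"]].var())
        assert 0.125 <= np.mean(est) <= 0.375

    def test_too_few_events_rejected(self, bins):
        cfg = SimConfig(n_participants=60, baseline_hazard=0.0005, seed=2)
        tab, _ = generate_cohort(cfg, bins)
        with pytest.raises(ValueError, match="events"):
            fit(tab, ModelSpec(adjusted=False), bins)

    def test_rank_deficient_design_named(self, bins):
        tab = _parametric_cohort(n=200, seed=4)
        tab["degree_educated"] = tab["sex_male"]  # exact collinearity
        with pytest.raises(ValueError, match="rank deficient"):
            fit(tab, PARAM_SPEC)
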