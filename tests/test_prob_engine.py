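"""Competing-risk probability engine: closed forms, Monte-Carlo oracle, risk layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surrofrax import (
    RelativeRiskSpec,
    RiskProfile,
    StepHazard,
    compute_probabilities,
    intervention_thresholds,
    profile_hazard,
    read_risk_spec,
    ten_year_probability,
    write_risk_spec,
)
from surrofrax.prob_engine import ConfigError, death_hazard
from surrofrax.rates_io import rate_at_age

from conftest import flat_model


def mc_first_event_probability(h_f, h_d, horizon, n=200_000, seed=0):
    """Monte-Carlo oracle: paired competing exponential event times."""
    rng = np.random.default_rng(seed)
    t_f = rng.exponential(1 / h_f, n) if h_f > 0 else np.full(n, np.inf)
    t_d = rng.exponential(1 / h_d, n) if h_d > 0 else np.full(n, np.inf)
    hit = (t_f < t_d) & (t_f < horizon)
    p = hit.mean()
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    return p, se


class TestTenYearProbability:
    def test_zero_fracture_hazard(self):
        c = StepHazard.constant
        assert ten_year_probability(c(0.0), c(0.05), 0, 10) == 0.0

    def test_no_competing_risk_closed_form(self):
        c = StepHazard.constant
        p = ten_year_probability(c(0.05), c(0.0), 0, 10)
        assert p == pytest.approx(1 - math.exp(-0.5), abs=1e-12)
        assert p == pytest.approx(0.393469, abs=5e-7)

    def test_constant_competing_closed_form(self):
        c = StepHazard.constant
        p = ten_year_probability(c(0.02), c(0.03), 0, 10)
        # h_f/(h_f+h_d) * (1 - exp(-(h_f+h_d)*t))
        assert p == pytest.approx(0.4 * (1 - math.exp(-0.5)), abs=1e-12)
        assert p == pytest.approx(0.157388, abs=5e-7)
        mc, se = mc_first_event_probability(0.02, 0.03, 10)
        assert abs(p - mc) < 3 * se

    def test_monte_carlo_agreement_band_structure(self):
        # age-varying hazards: split into bands, compare against simulation on
        # the same step functions via piecewise inverse-cdf sampling
        edges = np.array([0.0, 3.0, 7.0])
        frac = StepHazard(edges, np.array([0.01, 0.03, 0.06]))
        death = StepHazard(edges, np.array([0.02, 0.05, 0.10]))
        p = ten_year_probability(frac, death, 0, 10)
        rng = np.random.default_rng(42)
        n = 200_000
        hits = 0
        # simulate minute-stepped discrete hazard as an independent check
        dt = 1 / 52
        ages = np.arange(0, 10, dt)
        hf = np.array([frac.rate(a) for a in ages])
        hd = np.array([death.rate(a) for a in ages])
        u = rng.random((n, ages.size))
        p_frac = 1 - np.exp(-hf * dt)
        p_death_given_no_frac = 1 - np.exp(-hd * dt)
        # sequential discrete competing draws
        frac_event = u < p_frac
        death_event = rng.random((n, ages.size)) < p_death_given_no_frac
        first_frac = np.where(frac_event.any(axis=1), frac_event.argmax(axis=1), ages.size)
        first_death = np.where(death_event.any(axis=1), death_event.argmax(axis=1), ages.size)
        hits = (first_frac < first_death) & (first_frac < ages.size)
        # tie-break: same step -> fracture first with prob hf/(hf+hd); rare, ignore via tolerance
        p_mc = hits.mean()
        se = math.sqrt(p_mc * (1 - p_mc) / n)
        assert abs(p - p_mc) < 3 * se + dt * 0.1  # discretisation slack

    def test_invalid_inputs(self):
        c = StepHazard.constant
        with pytest.raises(ValueError, match="horizon"):
            ten_year_probability(c(0.01), c(0.01), 50, 0)
        with pytest.raises(ValueError, match=">= 0"):
            StepHazard.constant(-0.01)

    @settings(max_examples=50, deadline=None)
    @given(
        hf=st.floats(0, 0.3),
        hd=st.floats(0, 0.3),
        split=st.floats(0.5, 9.5),
    )
    def test_segment_additivity(self, hf, hd, split):
        """Splitting a constant segment at any interior point changes nothing."""
        c = StepHazard.constant
        whole = ten_year_probability(c(hf), c(hd), 0, 10)
        split_frac = StepHazard(np.array([0.0, split]), np.array([hf, hf]))
        split_death = StepHazard(np.array([0.0, split]), np.array([hd, hd]))
        resplit = ten_year_probability(split_frac, split_death, 0, 10)
        assert resplit == pytest.approx(whole, abs=1e-14)

    @settings(max_examples=50, deadline=None)
    @given(
        hf=st.floats(1e-4, 0.3),
        hd=st.floats(1e-4, 0.3),
        scale=st.floats(1.01, 3.0),
    )
    def test_monotonicity(self, hf, hd, scale):
        """P rises with fracture hazard and horizon, falls with death hazard."""
        c = StepHazard.constant
        base = ten_year_probability(c(hf), c(hd), 0, 10)
        assert ten_year_probability(c(hf * scale), c(hd), 0, 10) > base
        assert ten_year_probability(c(hf), c(hd * scale), 0, 10) < base
        assert ten_year_probability(c(hf), c(hd), 0, 10 * scale) > base

    def test_limits(self):
        c = StepHazard.constant
        # h_d -> 0 recovers 1 - exp(-H_f)
        p = ten_year_probability(c(0.04), c(1e-14), 0, 10)
        assert p == pytest.approx(1 - math.exp(-0.4), abs=1e-10)
        # horizon -> 0 vanishes linearly with slope h_f(start)
        for eps in (1e-4, 1e-6):
            p = ten_year_probability(c(0.04), c(0.02), 0, eps)
            assert p == pytest.approx(0.04 * eps, rel=1e-3)


class TestRiskLayer:
    def test_neutral_profile_reproduces_baseline(self):
        model = flat_model()
        profile = RiskProfile(age=60, sex="female")  # no CRFs, no T-score
        hz = profile_hazard(model, profile, "hip")
        for age in (50, 62.5, 95):
            assert hz.rate(age) == pytest.approx(
                rate_at_age(model.hip_incidence.female, age), abs=1e-15
            )

    def test_single_crf_multiplicativity(self):
        model = flat_model()
        hr = model.risk_coefficients.fracture_hr["current_smoking"]
        off = profile_hazard(model, RiskProfile(age=60, sex="male"), "mof")
        on = profile_hazard(
            model, RiskProfile(age=60, sex="male", crf={"current_smoking"}), "mof"
        )
        assert on.rate(70) == pytest.approx(hr * off.rate(70), rel=1e-12)

    def test_bmd_gradient_log_linear(self):
        """HR between T-scores one SD apart equals the gradient, at any age."""
        model = flat_model()
        a = profile_hazard(model, RiskProfile(age=60, sex="female", tscore=-2.5), "hip")
        b = profile_hazard(model, RiskProfile(age=60, sex="female", tscore=-1.5), "hip")
        grad = model.risk_coefficients.bmd_gradient
        for age in (55, 75, 92):
            assert a.rate(age) / b.rate(age) == pytest.approx(grad, rel=1e-12)
        # closed form: multiplier = gradient ** (tscore_ref - tscore)
        assert a.rate(60) == pytest.approx(model.hip_incidence.female.rate[0] * grad**2.5, rel=1e-12)

    def test_calibration_divisor_deflates(self):
        from dataclasses import replace

        model = flat_model()
        spec = replace(model.risk_coefficients, calibration_divisor=1.25)
        model2 = replace(model, risk_coefficients=spec)
        h1 = profile_hazard(model, RiskProfile(age=60, sex="male"), "hip").rate(60)
        h2 = profile_hazard(model2, RiskProfile(age=60, sex="male"), "hip").rate(60)
        assert h2 == pytest.approx(h1 / 1.25, rel=1e-12)

    def test_death_hazard_crf_default_off(self):
        model = flat_model()
        plain = death_hazard(model, RiskProfile(age=60, sex="male"))
        smoking = death_hazard(model, RiskProfile(age=60, sex="male", crf={"current_smoking"}))
        assert plain.rate(70) == smoking.rate(70)

    def test_unknown_crf_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            RiskProfile(age=60, sex="male", crf={"tea_drinking"})
        with pytest.raises(ConfigError):
            RelativeRiskSpec(fracture_hr={"tea_drinking": 2.0})


class TestComputeProbabilities:
    def test_zero_incidence_model(self):
        model = flat_model(hip=0.0, mof=0.0)
        res = compute_probabilities(model, RiskProfile(age=70, sex="female", tscore=-2.0))
        assert res.p_mof == res.p_hip == 0.0

    def test_hip_never_exceeds_mof(self, reference_model):
        rng = np.random.default_rng(11)
        crfs = list(RelativeRiskSpec.synthetic_default().fracture_hr)
        for _ in range(100):
            profile = RiskProfile(
                age=float(rng.uniform(50, 85)),
                sex=rng.choice(["male", "female"]),
                crf=frozenset(c for c in crfs if rng.random() < 0.5),
                tscore=float(rng.uniform(-3.5, 0)),
            )
            res = compute_probabilities(reference_model, profile)
            assert 0 <= res.p_hip <= res.p_mof <= 1


class TestInterventionThresholds:
    def test_zero_incidence_gives_zero_thresholds(self):
        model = flat_model(hip=0.0, mof=0.0)
        assert set(intervention_thresholds(model, [50, 70]).values()) == {0.0}

    def test_dominates_no_crf_woman(self, reference_model):
        """Prior fracture (HR > 1, death unmodified) raises the threshold."""
        ages = list(range(50, 91, 5))
        thresholds = intervention_thresholds(reference_model, ages)
        assert sorted(thresholds) == [float(a) for a in ages]
        for age in ages:
            base = compute_probabilities(
                reference_model, RiskProfile(age=age, sex="female")
            ).p_mof
            assert 0 <= base < thresholds[age] <= 1


class TestRiskSpecIO:
    def test_round_trip(self, tmp_path):
        spec = RelativeRiskSpec.synthetic_default()
        path = tmp_path / "coef.cfg"
        write_risk_spec(spec, path)
        back = read_risk_spec(path)
        assert back == spec

    def test_flat_keys_parsed(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text(
            "# demo\nprior_fracture.fracture_hr = 1.7\nprior_fracture.death_hr = 1.1\n"
            "bmd.gradient_per_sd = 1.5\ncalibration.divisor = 1.2\n"
        )
        spec = read_risk_spec(path)
        assert spec.fracture_hr == {"prior_fracture": 1.7}
        assert spec.death_hr == {"prior_fracture": 1.1}
        assert spec.bmd_gradient == 1.5
        assert spec.calibration_divisor == 1.2

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text("frobnication.level = 3\n")
        with pytest.raises(ConfigError):
            read_risk_spec(path)
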