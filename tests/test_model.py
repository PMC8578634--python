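"""Constitutive-core unit tests: structure kinetics, flow curve, stress ODEs."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from tevp.model import (
    FITTED_PARAMETER_NAMES,
    PARAMETER_ROLES,
    StressState,
    StructureState,
    TEVPParameters,
    first_normal_stress_difference,
    lambda_rate,
    lambda_ss,
    relaxation_time,
    scalar_stress_rate,
    sigma_ss,
    tensor_stress_rhs,
)


def P(**kw) -> TEVPParameters:
    base = dict(t_r1=1.0, t_r2=1.0, sigma_y0=0.0, eta_ST=0.0, eta_inf=1.0,
                tau_lambda=1.0, G=1.0)
    base.update(kw)
    return TEVPParameters(**base)


class TestParameters:
    def test_nine_constants_with_fixed_and_fitted_roles(self):
        p = P()
        assert len(dataclasses.fields(p)) == 9
        assert {n for n, r in PARAMETER_ROLES.items() if r == "fixed"} == {"d", "m"}
        assert {n for n, r in PARAMETER_ROLES.items() if r == "steady_state"} == \
            {"t_r1", "t_r2", "sigma_y0", "eta_ST", "eta_inf"}
        assert {n for n, r in PARAMETER_ROLES.items() if r == "transient"} == \
            {"tau_lambda", "G"}
        assert len(FITTED_PARAMETER_NAMES) == 7

    def test_default_exponents(self):
        p = P()
        assert p.d == 0.5 and p.m == 1.5

    @pytest.mark.parametrize("kw", [
        dict(eta_inf=0.0), dict(G=0.0), dict(t_r1=-1.0), dict(d=0.0),
        dict(d=1.0), dict(m=0.0), dict(sigma_y0=float("nan")),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            P(**kw)

    def test_json_round_trip_preserves_values_and_roles(self, tmp_path, blood_params):
        path = tmp_path / "params.json"
        blood_params.to_json(path)
        back = TEVPParameters.from_json(path)
        assert back == blood_params
        d = blood_params.to_dict()
        assert d["d"]["role"] == "fixed" and d["G"]["role"] == "fitted"
        assert d["sigma_y0"]["unit"] == "Pa"

    def test_fitted_vector_round_trip(self, blood_params):
        x = blood_params.fitted_vector()
        assert len(x) == 7
        assert blood_params.with_fitted_vector(x) == blood_params


class TestStructure:
    @pytest.mark.parametrize("params, gdot, expected", [
        (P(), 0.0, 1.0),                       # no shear: fully built
        (P(t_r1=1.0, t_r2=1.0), 1.0, 2.0 / 3.0),
        (P(t_r1=2.0, t_r2=0.0), 1.0, 1.0 / 3.0),
    ])
    def test_lambda_ss_examples(self, params, gdot, expected):
        assert lambda_ss(params, gdot) == pytest.approx(expected, rel=1e-14)

    def test_lambda_ss_sign_irrelevant(self):
        p = P(t_r1=3.0, t_r2=0.7)
        assert lambda_ss(p, -5.0) == lambda_ss(p, 5.0)

    def test_lambda_ss_rejects_non_finite(self):
        with pytest.raises(ValueError):
            lambda_ss(P(), float("inf"))

    @pytest.mark.parametrize("lam, gdot, tau, expected", [
        (1.0, 0.0, 1.0, 0.0),     # built structure at rest: nothing to do
        (0.0, 0.0, 2.0, 0.5),     # pure Brownian build-up rate 1/tau
    ])
    def test_lambda_rate_examples(self, lam, gdot, tau, expected):
        assert lambda_rate(P(tau_lambda=tau), lam, gdot) == pytest.approx(expected, abs=1e-15)

    def test_lambda_rate_rejects_degenerate_kinetics(self):
        with pytest.raises(ValueError):
            lambda_rate(P(tau_lambda=0.0), 0.5, 1.0)

    def test_steady_state_is_kinetics_fixed_point(self, blood_params, rate_grid):
        """Root of the kinetic equation in λ coincides with the algebraic
        steady-state expression on a decade grid of shear rates."""
        for g in rate_grid:
            root = brentq(lambda lam: lambda_rate(blood_params, lam, g), 0.0, 1.0,
                          xtol=1e-16, rtol=8.9e-16)
            assert root == pytest.approx(lambda_ss(blood_params, g), rel=1e-12)

    @given(st.floats(0.0, 1e3), st.floats(0.0, 1e3), st.floats(0.0, 1e3))
    def test_lambda_ss_bounded(self, t_r1, t_r2, gdot):
        val = lambda_ss(P(t_r1=t_r1, t_r2=t_r2), gdot)
        assert 0.0 < val <= 1.0

    @given(st.floats(0.0, 1e3))
    def test_lambda_rate_pushes_into_unit_interval(self, gdot):
        p = P(t_r1=2.0, t_r2=0.5, tau_lambda=3.0)
        assert lambda_rate(p, 0.0, gdot) >= 0.0
        assert lambda_rate(p, 1.0, gdot) <= 0.0


class TestFlowCurve:
    def test_zero_shear_gives_yield_stress(self):
        p = P(sigma_y0=0.042)
        assert sigma_ss(p, 0.0) == pytest.approx(0.042, rel=1e-14)

    def test_newtonian_limit(self):
        p = P(sigma_y0=0.0, eta_ST=0.0, eta_inf=0.005)
        assert sigma_ss(p, 100.0) == pytest.approx(0.5, rel=1e-14)

    def test_structured_value(self):
        p = P(t_r1=1.0, t_r2=1.0, sigma_y0=1.0, eta_ST=1.0, eta_inf=1.0)
        expected = 2.0 / 3.0 + (2.0 / 3.0) ** 1.5 + 1.0
        assert sigma_ss(p, 1.0) == pytest.approx(expected, rel=1e-14)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            sigma_ss(P(), -1.0)


class TestStressRates:
    def test_fixed_point_has_zero_rate(self, blood_params):
        lam, g = 0.4, 2.0
        eta = lam**1.5 * blood_params.eta_ST + blood_params.eta_inf
        sigma = lam * blood_params.sigma_y0 + eta * g
        assert scalar_stress_rate(blood_params, lam, sigma, g) == pytest.approx(0.0, abs=1e-14)

    def test_unit_maxwell_rate(self):
        assert scalar_stress_rate(P(), 1.0, 0.0, 1.0) == pytest.approx(1.0, rel=1e-14)

    def test_pure_relaxation_at_rest(self):
        p = P(eta_ST=0.5, eta_inf=0.1, G=2.0)
        lam, sigma = 0.8, 0.3
        eta = lam**1.5 * 0.5 + 0.1
        assert scalar_stress_rate(p, lam, sigma, 0.0) == pytest.approx(-2.0 * sigma / eta, rel=1e-13)

    def test_zero_relaxation_denominator_rejected(self):
        p = P(eta_ST=1.0, eta_inf=1e-300)
        # eta_inf must be > 0 at construction; force the degenerate case directly
        with pytest.raises(ValueError):
            TEVPParameters(t_r1=1, t_r2=1, sigma_y0=0, eta_ST=1, eta_inf=0,
                           tau_lambda=1, G=1)
        assert scalar_stress_rate(p, 0.0, 0.0, 1.0)  # tiny but valid denominator

    def test_quiescent_state_is_stationary(self):
        rates = tensor_stress_rhs(P(), 0.7, StressState(), 0.0)
        assert rates == (0.0, 0.0, 0.0, 0.0)

    def test_normal_components_decay_homogeneously(self):
        p = P(eta_ST=0.3, eta_inf=0.2, G=4.0)
        st_ = StressState(sigma_xx=1.0, sigma_yy=0.0, sigma_zz=0.0, sigma_yx=0.5)
        _, d_yy, d_zz, _ = tensor_stress_rhs(p, 0.5, st_, 10.0)
        assert d_yy == 0.0 and d_zz == 0.0

    @pytest.mark.parametrize("lam, syx, g", [
        (0.3, 0.02, 5.0), (1.0, -0.1, -2.0), (0.0, 0.0, 0.0), (0.6, 0.5, 0.1),
    ])
    def test_yx_rate_matches_scalar_form_when_syy_zero(self, blood_params, lam, syx, g):
        st_ = StressState(sigma_xx=0.7, sigma_yy=0.0, sigma_zz=0.0, sigma_yx=syx)
        d_yx = tensor_stress_rhs(blood_params, lam, st_, g)[3]
        assert d_yx == pytest.approx(scalar_stress_rate(blood_params, lam, syx, g), rel=1e-13, abs=1e-15)

    def test_steady_shear_normal_stress_fixed_point(self, blood_params):
        """At the constant-shear fixed point σ_xx = 2 τ(λ_ss) σ_yx γ̇."""
        g = 3.0
        lam = lambda_ss(blood_params, g)
        eta = lam**1.5 * blood_params.eta_ST + blood_params.eta_inf
        syx = lam * blood_params.sigma_y0 + eta * g
        sxx = 2.0 * relaxation_time(blood_params, lam) * syx * g
        st_ = StressState(sigma_xx=sxx, sigma_yy=0.0, sigma_zz=0.0, sigma_yx=syx)
        rates = tensor_stress_rhs(blood_params, lam, st_, g)
        assert all(abs(r) < 1e-13 for r in rates)

    def test_yield_sign_none_breaks_odd_symmetry(self):
        p = P(sigma_y0=0.5, eta_ST=0.1)
        fwd = scalar_stress_rate(p, 1.0, 0.0, 1.0, yield_sign="none")
        bwd = scalar_stress_rate(p, 1.0, 0.0, -1.0, yield_sign="none")
        assert fwd != pytest.approx(-bwd)
        fwd = scalar_stress_rate(p, 1.0, 0.0, 1.0)
        bwd = scalar_stress_rate(p, 1.0, 0.0, -1.0)
        assert fwd == pytest.approx(-bwd, rel=1e-14)


class TestNormalStressDifference:
    def test_equal_normals_cancel(self):
        assert first_normal_stress_difference(StressState(sigma_xx=1.3, sigma_yy=1.3)) == 0.0

    def test_definition(self):
        assert first_normal_stress_difference(StressState(sigma_xx=2.0)) == 2.0

    def test_structure_state_bounds(self):
        with pytest.raises(ValueError):
            StructureState(lam=1.5)
        with pytest.raises(ValueError):
            StressState(sigma_xx=math.nan)
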