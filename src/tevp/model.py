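"""Thixo-visco-plastic constitutive core for human blood.

Blood is a thixo-elasto-visco-plastic (TEVP) suspension: red blood cells
aggregate into rouleaux at low shear and disperse at high shear, giving the
fluid a yield stress, shear thinning, and a time-dependent (thixotropic)
viscosity.  The model implemented here tracks a scalar structure parameter
``lam`` (λ ∈ [0, 1]; 1 = fully built rouleaux network, 0 = fully dispersed
cells) with first-order kinetics balancing shear breakdown against shear and
Brownian aggregation, and couples it to a Maxwell-type stress evolution with a
structure-dependent yield term and structural viscosity.

The stress can be evolved either as a single shear component (scalar form) or
as the four tensor components (xx, yy, zz, yx) of simple shear, which in
addition yields the first normal stress difference N1 = σ_xx − σ_yy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np

__all__ = [
    "TEVPParameters",
    "StructureState",
    "StressState",
    "lambda_ss",
    "lambda_rate",
    "sigma_ss",
    "structural_viscosity",
    "relaxation_time",
    "yield_direction",
    "scalar_stress_rate",
    "tensor_stress_rhs",
    "first_normal_stress_difference",
]

#: role of each physical constant in the standard fitting workflow:
#: the two power-law exponents are fixed at literature reference values,
#: five constants are identified from the steady-state flow curve, and the
#: remaining two (structure-kinetics time scale and elastic modulus) from
#: transient step-shear data.
PARAMETER_ROLES = {
    "t_r1": "steady_state",
    "t_r2": "steady_state",
    "d": "fixed",
    "m": "fixed",
    "sigma_y0": "steady_state",
    "eta_ST": "steady_state",
    "eta_inf": "steady_state",
    "tau_lambda": "transient",
    "G": "transient",
}

PARAMETER_UNITS = {
    "t_r1": "s",
    "t_r2": "s^d",
    "d": "-",
    "m": "-",
    "sigma_y0": "Pa",
    "eta_ST": "Pa.s",
    "eta_inf": "Pa.s",
    "tau_lambda": "s",
    "G": "Pa",
}

#: the five steady-state-fit constants followed by the two transient-fit
#: constants; this is the canonical ordering used by the fitting module.
FITTED_PARAMETER_NAMES = (
    "t_r1",
    "t_r2",
    "sigma_y0",
    "eta_ST",
    "eta_inf",
    "tau_lambda",
    "G",
)


@dataclass(frozen=True)
class TEVPParameters:
    """The nine constants of the tensorial TEVP blood model.

    Parameters
    ----------
    t_r1 : float
        Ratio of rouleaux shear breakdown to Brownian buildup, s.
    t_r2 : float
        Ratio of shear aggregation to Brownian buildup, s^d.
    sigma_y0 : float
        Yield stress of the fully structured material, Pa.
    eta_ST : float
        Structural (rouleaux) viscosity, Pa·s.
    eta_inf : float
        Infinite-shear (solvent-limit) viscosity, Pa·s.
    tau_lambda : float
        Total rouleaux agglomeration time constant, s.
    G : float
        Elastic modulus, Pa.
    d : float, default 1/2
        Power-law exponent of shear aggregation (fixed reference value).
    m : float, default 3/2
        Structural-viscosity power-law exponent (fixed reference value).
    """

    t_r1: float
    t_r2: float
    sigma_y0: float
    eta_ST: float
    eta_inf: float
    tau_lambda: float
    G: float
    d: float = 0.5
    m: float = 1.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name!r} must be >= 0, got {v!r}")
        if self.eta_inf <= 0:
            raise ValueError("eta_inf must be > 0 (solvent-limit viscosity)")
        if self.G <= 0:
            raise ValueError("G must be > 0 (it enters relaxation-time denominators)")
        if not 0 < self.d < 1:
            raise ValueError(f"d must lie in (0, 1), got {self.d}")
        if self.m <= 0:
            raise ValueError(f"m must be > 0, got {self.m}")

    # -- fitting helpers -------------------------------------------------
    def fitted_vector(self) -> np.ndarray:
        """The 7 fitted constants in canonical order (see FITTED_PARAMETER_NAMES)."""
        return np.array([getattr(self, n) for n in FITTED_PARAMETER_NAMES])

    def with_fitted_vector(self, x: np.ndarray) -> "TEVPParameters":
        """Return a copy with the 7 fitted constants replaced by ``x``."""
        if len(x) != len(FITTED_PARAMETER_NAMES):
            raise ValueError(f"expected {len(FITTED_PARAMETER_NAMES)} values, got {len(x)}")
        return replace(self, **dict(zip(FITTED_PARAMETER_NAMES, map(float, x))))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-ready mapping with value, unit and fixed/fitted role per constant."""
        return {
            f.name: {
                "value": getattr(self, f.name),
                "unit": PARAMETER_UNITS[f.name],
                "role": "fixed" if PARAMETER_ROLES[f.name] == "fixed" else "fitted",
                "fit_stage": PARAMETER_ROLES[f.name],
            }
            for f in fields(self)
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TEVPParameters":
        kwargs = {}
        for name, entry in d.items():
            kwargs[name] = entry["value"] if isinstance(entry, dict) else float(entry)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "TEVPParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class StructureState:
    """Dimensionless rouleaux structure parameter, constrained to [0, 1]."""

    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"structure parameter must lie in [0, 1], got {self.lam}")


@dataclass
class StressState:
    """Stress tensor components (Pa) of simple shear flow."""

    sigma_xx: float = 0.0
    sigma_yy: float = 0.0
    sigma_zz: float = 0.0
    sigma_yx: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_xx", "sigma_yy", "sigma_zz", "sigma_yx"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _check_finite(gamma_dot) -> np.ndarray:
    g = np.asarray(gamma_dot, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("shear rate must be finite")
    return g


def lambda_ss(params: TEVPParameters, gamma_dot) -> float | np.ndarray:
    """Steady-state structure parameter at shear rate ``gamma_dot`` (s⁻¹).

    λ_ss = (t_r2 |γ̇|^d + 1) / (t_r1 |γ̇| + t_r2 |γ̇|^d + 1); the sign of the
    shear rate is irrelevant.  Lies in (0, 1], equal to 1 at rest.
    """
    g = np.abs(_check_finite(gamma_dot))
    build = params.t_r2 * g**params.d + 1.0
    out = build / (params.t_r1 * g + build)
    return float(out) if out.ndim == 0 else out


def lambda_rate(params: TEVPParameters, lam, gamma_dot) -> float | np.ndarray:
    """Structure-kinetics rate dλ/dt (s⁻¹).

    Balances shear breakdown (−t_r1 |γ̇| λ) against shear aggregation
    (t_r2 |γ̇|^d (1−λ)) and Brownian aggregation ((1−λ)), all on the
    rouleaux agglomeration time scale tau_lambda.
    """
    if params.tau_lambda == 0:
        raise ValueError("tau_lambda must be > 0 for structure kinetics")
    g = np.abs(_check_finite(gamma_dot))
    lam = np.asarray(lam, dtype=float)
    out = (
        -params.t_r1 * g * lam
        + params.t_r2 * g**params.d * (1.0 - lam)
        + (1.0 - lam)
    ) / params.tau_lambda
    return float(out) if out.ndim == 0 else out


def sigma_ss(params: TEVPParameters, gamma_dot) -> float | np.ndarray:
    """Steady-state shear stress (Pa) of the flow curve at ``gamma_dot`` ≥ 0.

    σ_ss = σ_y0 λ_ss + η_ST λ_ss^m γ̇ + η_∞ γ̇ — a structure-weighted yield
    stress plus structural and solvent viscous contributions.
    """
    g = _check_finite(gamma_dot)
    if np.any(g < 0):
        raise ValueError("flow-curve convention requires gamma_dot >= 0")
    lss = lambda_ss(params, g)
    out = params.sigma_y0 * lss + params.eta_ST * np.asarray(lss) ** params.m * g + params.eta_inf * g
    return float(out) if np.ndim(out) == 0 else out


def structural_viscosity(params: TEVPParameters, lam) -> float | np.ndarray:
    """Total structure-dependent viscosity η(λ) = λ^m η_ST + η_∞ (Pa·s)."""
    out = np.asarray(lam, dtype=float) ** params.m * params.eta_ST + params.eta_inf
    return float(out) if out.ndim == 0 else out


def relaxation_time(params: TEVPParameters, lam) -> float | np.ndarray:
    """Maxwell relaxation time τ(λ) = η(λ)/G (s)."""
    out = np.asarray(structural_viscosity(params, lam)) / params.G
    return float(out) if out.ndim == 0 else out


def yield_direction(gamma_dot_yx, convention: Literal["shear_rate", "none"] = "shear_rate"):
    """Direction factor s applied to the yield term λσ_y0.

    ``shear_rate`` (default): s = sign(γ̇_yx), 0 at γ̇ = 0, so the yield
    contribution always opposes the imposed deformation and the stress
    response keeps its odd symmetry under flow reversal (as in LAOS).
    ``none``: s = 1 regardless of the flow direction.
    """
    if convention == "shear_rate":
        return np.sign(gamma_dot_yx)
    if convention == "none":
        return np.ones_like(np.asarray(gamma_dot_yx, dtype=float)) if np.ndim(gamma_dot_yx) else 1.0
    raise ValueError(f"unknown yield_sign convention {convention!r}")


def _eta_checked(params: TEVPParameters, lam) -> float | np.ndarray:
    eta = structural_viscosity(params, lam)
    if np.any(np.asarray(eta) == 0):
        raise ValueError("zero relaxation denominator: lam^m * eta_ST + eta_inf = 0")
    return eta


def scalar_stress_rate(
    params: TEVPParameters,
    lam,
    sigma,
    gamma_dot,
    yield_sign: Literal["shear_rate", "none"] = "shear_rate",
) -> float | np.ndarray:
    """Scalar Maxwell-type stress evolution dσ/dt (Pa·s⁻¹).

    dσ/dt = G/η(λ) · (λ σ_y0 s + η(λ) γ̇ − σ), with s the yield-direction
    factor (see :func:`yield_direction`).  The fixed point at constant shear
    reproduces the steady-state flow curve.
    """
    eta = _eta_checked(params, lam)
    s = yield_direction(gamma_dot, yield_sign)
    out = params.G / np.asarray(eta) * (
        np.asarray(lam) * params.sigma_y0 * s + np.asarray(eta) * gamma_dot - sigma
    )
    return float(out) if np.ndim(out) == 0 else out


def tensor_stress_rhs(
    params: TEVPParameters,
    lam: float,
    state: StressState,
    gamma_dot_yx: float,
    yield_sign: Literal["shear_rate", "none"] = "shear_rate",
) -> tuple[float, float, float, float]:
    """Rates (Pa·s⁻¹) of the four stress components under simple shear.

    Upper-convected-Maxwell-like system with relaxation time τ(λ) = η(λ)/G:

        τ (σ̇_xx − 2 σ_yx γ̇) + σ_xx = 0
        τ σ̇_yy            + σ_yy = 0
        τ σ̇_zz            + σ_zz = 0
        τ (σ̇_yx − 2 σ_yy γ̇) + σ_yx = λ σ_y0 s + η(λ) γ̇

    Returns ``(d sigma_xx, d sigma_yy, d sigma_zz, d sigma_yx)``.  With
    σ_yy ≡ 0 the yx equation coincides with :func:`scalar_stress_rate`.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"structure parameter must lie in [0, 1], got {lam}")
    eta = _eta_checked(params, lam)
    tau = eta / params.G
    s = yield_direction(gamma_dot_yx, yield_sign)
    d_xx = 2.0 * state.sigma_yx * gamma_dot_yx - state.sigma_xx / tau
    d_yy = -state.sigma_yy / tau
    d_zz = -state.sigma_zz / tau
    d_yx = (
        2.0 * state.sigma_yy * gamma_dot_yx
        + (lam * params.sigma_y0 * s + eta * gamma_dot_yx - state.sigma_yx) / tau
    )
    return (d_xx, d_yy, d_zz, d_yx)


def first_normal_stress_difference(state: StressState) -> float:
    """First normal stress difference N1 = σ_xx − σ_yy (Pa)."""
    return state.sigma_xx - state.sigma_yy
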