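"""Numerical integration of the coupled structure/stress system over a protocol.

The state vector is (λ, σ_xx, σ_yy, σ_zz, σ_yx) — or (λ, σ_yx) for the scalar
formulation.  Integration is segment-wise with an implicit, stiffness-capable
method; within oscillatory segments the integration is additionally restarted
at the known zero crossings of the shear rate, where the yield term of the
stress equation switches direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    StressState,
    StructureState,
    TEVPParameters,
    lambda_rate,
    lambda_ss,
    relaxation_time,
    structural_viscosity,
    yield_direction,
)
from .protocols import Segment, ShearProtocol

__all__ = [
    "SimOptions",
    "RheoTimeSeries",
    "equilibrate",
    "integrate",
    "simulated_flow_curve",
    "lissajous_projections",
]


@dataclass(frozen=True)
class SimOptions:
    """Numerical and physical options of the ODE driver.

    ``warmup_periods`` oscillation periods are integrated (and discarded)
    before the recorded window of an oscillatory segment so that the recorded
    periods sit at steady alternance.  ``formulation`` selects the full
    tensorial system or the single-component scalar stress equation.
    """

    method: str = "Radau"
    rtol: float = 1e-8
    atol: float = 1e-10
    points_per_period: int = 200
    points_per_segment: int = 200
    warmup_periods: int = 10
    explicit_preshear: bool = False
    yield_sign: str = "shear_rate"
    formulation: str = "tensor"
    lambda_clip_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.formulation not in ("tensor", "scalar"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.points_per_period < 200:
            raise ValueError("points_per_period must be >= 200 for harmonic analysis")


@dataclass
class RheoTimeSeries:
    """Aligned rheometer-style arrays of one simulated or measured run.

    All stress entries are in Pa, time in s, shear rate in s⁻¹; ``lam`` is the
    dimensionless structure parameter.  Normal components may be NaN for
    scalar runs or measured data.
    """

    time: np.ndarray
    shear_rate: np.ndarray
    strain: np.ndarray
    sigma_yx: np.ndarray
    sigma_xx: np.ndarray | None = None
    sigma_yy: np.ndarray | None = None
    sigma_zz: np.ndarray | None = None
    lam: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.time)
        for name in ("shear_rate", "strain", "sigma_yx", "sigma_xx", "sigma_yy", "sigma_zz", "lam"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            setattr(self, name, v)
            if len(v) != n:
                raise ValueError(f"column {name!r} has length {len(v)}, expected {n}")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("non-monotone time axis")
        if self.lam is not None and n and (np.nanmin(self.lam) < -1e-12 or np.nanmax(self.lam) > 1 + 1e-12):
            raise ValueError("structure parameter out of [0, 1]")

    def __len__(self) -> int:
        return len(self.time)

    def first_normal_stress_difference(self) -> np.ndarray:
        if self.sigma_xx is None or self.sigma_yy is None:
            raise ValueError("normal components unavailable")
        return self.sigma_xx - self.sigma_yy

    def to_csv(self, path) -> None:
        from .io import write_timeseries_csv

        write_timeseries_csv(path, self)


def equilibrate(params: TEVPParameters, gamma_dot: float,
                yield_sign: str = "shear_rate") -> tuple[StructureState, StressState]:
    """Constant-shear fixed point of the full system at ``gamma_dot`` ≥ 0.

    λ = λ_ss(γ̇); σ_yx = λ σ_y0 s + η(λ) γ̇; σ_xx = 2 τ(λ) σ_yx γ̇;
    σ_yy = σ_zz = 0.  This is the default post-preshear initial condition.
    """
    if gamma_dot < 0:
        raise ValueError("equilibrate expects gamma_dot >= 0")
    lam = lambda_ss(params, gamma_dot)
    s = yield_direction(gamma_dot, yield_sign)
    syx = lam * params.sigma_y0 * s + structural_viscosity(params, lam) * gamma_dot
    sxx = 2.0 * relaxation_time(params, lam) * syx * gamma_dot
    return StructureState(lam=lam), StressState(sigma_xx=sxx, sigma_yy=0.0, sigma_zz=0.0, sigma_yx=syx)


def _rhs_factory(params: TEVPParameters, seg: Segment, options: SimOptions):
    """Right-hand side f(t, y) for one segment, t in segment-local time."""
    scalar = options.formulation == "scalar"
    ys = options.yield_sign
    eta_inf, eta_ST, m, G, sy0 = params.eta_inf, params.eta_ST, params.m, params.G, params.sigma_y0

    def rhs(t, y):
        lam = min(max(y[0], 0.0), 1.0)
        g = seg.shear_rate(t)
        dlam = lambda_rate(params, lam, g)
        eta = lam**m * eta_ST + eta_inf
        s = yield_direction(g, ys)
        if scalar:
            dyx = G / eta * (lam * sy0 * s + eta * g - y[1])
            return [dlam, dyx]
        sxx, syy, szz, syx = y[1], y[2], y[3], y[4]
        inv_tau = G / eta
        return [
            dlam,
            2.0 * syx * g - sxx * inv_tau,
            -syy * inv_tau,
            -szz * inv_tau,
            2.0 * syy * g + (lam * sy0 * s + eta * g - syx) * inv_tau,
        ]

    return rhs


def _segment_chunks(seg: Segment, t0: float, t1: float) -> list[tuple[float, float]]:
    """Split [t0, t1] at shear-rate sign changes (yield-term discontinuities)."""
    if seg.kind != "laos":
        return [(t0, t1)]
    # cos(ωt) = 0 at t = (k + 1/2) π / ω
    w = seg.omega
    k0 = math.ceil(t0 * w / math.pi - 0.5)
    cuts = []
    k = k0
    while True:
        tc = (k + 0.5) * math.pi / w
        if tc >= t1 - 1e-12 * max(1.0, abs(t1)):
            break
        if tc > t0 + 1e-12 * max(1.0, abs(t0)):
            cuts.append(tc)
        k += 1
    pts = [t0, *cuts, t1]
    return list(zip(pts[:-1], pts[1:]))


def _integrate_segment(params, seg, y0, t_record, t_start, options: SimOptions,
                       t_final: float | None = None):
    """Integrate one segment from local time t_start, sampling at t_record.

    Returns (samples at t_record, state at local time ``t_final``, which
    defaults to the last sampling time).
    """
    rhs = _rhs_factory(params, seg, options)
    t_record = np.asarray(t_record, dtype=float)
    t_end = t_final if t_final is not None else (float(t_record[-1]) if len(t_record) else t_start)
    y = np.asarray(y0, dtype=float)
    pieces = []
    first = True
    for a, b in _segment_chunks(seg, t_start, t_end):
        tol = 1e-9 * max(1.0, abs(b))
        if first:
            mask = (t_record >= a - tol) & (t_record <= b + tol)
        else:  # chunk-start time was already emitted by the previous chunk
            mask = (t_record > a + tol) & (t_record <= b + tol)
        t_eval = list(np.clip(t_record[mask], a, b))
        need_end = not t_eval or t_eval[-1] < b - tol
        sol = solve_ivp(rhs, (a, b), y, method=options.method, rtol=options.rtol,
                        atol=options.atol, t_eval=t_eval + ([b] if need_end else []))
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on segment {seg.kind!r} over [{a:g}, {b:g}] s: {sol.message}")
        y = sol.y[:, -1]
        if t_eval:
            pieces.append(sol.y[:, : len(t_eval)].T)
        first = False
    samples = np.concatenate(pieces) if pieces else np.empty((0, len(y)))
    return samples, y


def _initial_state(params: TEVPParameters, protocol: ShearProtocol,
                   options: SimOptions,
                   initial: tuple[StructureState, StressState] | None):
    if initial is not None:
        struct, stress = initial
    elif protocol.preshear is not None:
        if options.explicit_preshear:
            struct0, stress0 = StructureState(1.0), StressState()
            y0 = _pack(struct0, stress0, options)
            pre = protocol.preshear
            _, y_end = _integrate_segment(params, pre, y0, np.array([pre.duration]), 0.0, options)
            return y_end
        struct, stress = equilibrate(params, protocol.preshear.gamma_dot, options.yield_sign)
    else:
        # start from rest: fully built structure, no stress
        struct, stress = StructureState(1.0), StressState()
    return _pack(struct, stress, options)


def _pack(struct: StructureState, stress: StressState, options: SimOptions) -> np.ndarray:
    if options.formulation == "scalar":
        return np.array([struct.lam, stress.sigma_yx])
    return np.array([struct.lam, stress.sigma_xx, stress.sigma_yy, stress.sigma_zz, stress.sigma_yx])


def integrate(params: TEVPParameters, protocol: ShearProtocol,
              options: SimOptions | None = None,
              initial: tuple[StructureState, StressState] | None = None,
              sample_times: np.ndarray | None = None) -> RheoTimeSeries:
    """Integrate the model over ``protocol`` and return the sampled time series.

    The initial condition is, in order of precedence: the explicit ``initial``
    state, the preshear steady state (or an explicitly integrated preshear if
    ``options.explicit_preshear``), or rest (λ = 1, zero stress).  Oscillatory
    segments are preceded by ``options.warmup_periods`` discarded periods.
    ``sample_times`` (global, strictly increasing, within the protocol span)
    overrides the default uniform sampling grid.
    """
    options = options or SimOptions()
    y = _initial_state(params, protocol, options, initial)

    if sample_times is not None:
        sample_times = np.asarray(sample_times, dtype=float)
        if np.any(sample_times < 0) or np.any(sample_times > protocol.duration + 1e-9):
            raise ValueError("sample_times must lie within the protocol span")
        if np.any(np.diff(sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")

    times, states = [], []
    offset = 0.0
    ends = protocol.boundaries()
    for i, seg in enumerate(protocol.segments):
        if sample_times is not None:
            hi = ends[i]
            mask = (sample_times > offset + 1e-12) | ((sample_times >= offset) & (i == 0))
            mask &= sample_times <= min(hi, sample_times[-1]) + 1e-12
            t_rec = np.clip(sample_times[mask] - offset, 0.0, seg.duration)
        elif seg.kind == "constant_rate":
            t_rec = np.linspace(0.0, seg.duration, options.points_per_segment + 1)
        else:
            T = seg.period
            n_per = max(2, int(round(seg.duration / T)))
            t_rec = np.linspace(0.0, seg.duration, options.points_per_period * n_per + 1)
        t_start = -options.warmup_periods * seg.period if seg.kind != "constant_rate" else 0.0
        samples, y = _integrate_segment(params, seg, y, t_rec, t_start, options,
                                        t_final=seg.duration)
        skip = 1 if (times and len(t_rec) and t_rec[0] == 0.0 and sample_times is None) else 0
        times.append(t_rec[skip:] + offset)
        states.append(samples[skip:])
        offset += seg.duration

    t = np.concatenate(times)
    ystack = np.concatenate(states, axis=0)
    lam = ystack[:, 0]
    clip_excess = max(float(np.max(lam - 1.0, initial=0.0)), float(np.max(-lam, initial=0.0)))
    if clip_excess > options.lambda_clip_tol:
        warnings.warn(
            f"structure parameter exceeded [0, 1] by {clip_excess:.3e}; "
            "solver tolerances may be too loose", RuntimeWarning)
    lam = np.clip(lam, 0.0, 1.0)

    meta = {
        "protocol": protocol.name,
        "yield_sign": options.yield_sign,
        "formulation": options.formulation,
    }
    try:
        _, osc, osc_start = protocol.oscillatory_segment()
        meta.update(kind=osc.kind, gamma0=osc.gamma0, omega=osc.omega, osc_start=osc_start)
    except ValueError:
        pass

    if options.formulation == "scalar":
        return RheoTimeSeries(
            time=t, shear_rate=protocol.shear_rate(t), strain=protocol.strain(t),
            sigma_yx=ystack[:, 1], lam=lam, metadata=meta)
    return RheoTimeSeries(
        time=t, shear_rate=protocol.shear_rate(t), strain=protocol.strain(t),
        sigma_yx=ystack[:, 4], sigma_xx=ystack[:, 1], sigma_yy=ystack[:, 2],
        sigma_zz=ystack[:, 3], lam=lam, metadata=meta)


def steady_state_horizon(params: TEVPParameters, gamma_dot: float, factor: float = 40.0) -> float:
    """Integration time after which transients at constant shear are negligible.

    ``factor`` multiples of the slower of the structure-kinetics and elastic
    relaxation time scales.
    """
    g = abs(gamma_dot)
    t_struct = params.tau_lambda / (params.t_r1 * g + params.t_r2 * g**params.d + 1.0)
    t_elastic = structural_viscosity(params, 1.0) / params.G
    return factor * max(t_struct, t_elastic)


def simulated_flow_curve(params: TEVPParameters, rates, options: SimOptions | None = None,
                         factor: float = 40.0) -> np.ndarray:
    """Long-time σ_yx from ODE integration at each constant rate (from rest).

    Independent of the algebraic steady-state flow curve; used to verify that
    the transient model relaxes onto it.
    """
    options = options or SimOptions()
    out = np.empty(len(rates))
    for i, g in enumerate(np.asarray(rates, dtype=float)):
        seg = Segment(kind="constant_rate", gamma_dot=float(g),
                      duration=steady_state_horizon(params, g, factor))
        proto = ShearProtocol(segments=[seg], preshear=None, name=f"flowcurve_{g:g}")
        ts = integrate(params, proto, options)
        out[i] = ts.sigma_yx[-1]
    return out


def lissajous_projections(ts: RheoTimeSeries, omega: float | None = None,
                          gamma0: float | None = None):
    """Elastic (σ vs γ_osc) and viscous (σ vs γ̇_osc) loops over the last period.

    For UD-LAOS runs the steady strain drift is removed, so both abscissae are
    the oscillatory components γ0 sin(ωt) and γ0 ω cos(ωt).  Returns
    ``((gamma_osc, sigma), (gamma_dot_osc, sigma))``.
    """
    omega = omega if omega is not None else ts.metadata.get("omega")
    gamma0 = gamma0 if gamma0 is not None else ts.metadata.get("gamma0")
    if omega is None or gamma0 is None:
        raise ValueError("omega and gamma0 required (missing from metadata)")
    T = 2.0 * math.pi / omega
    t_end = ts.time[-1]
    if t_end - ts.time[0] < T * (1.0 - 1e-9):
        raise ValueError("time series does not cover a full oscillation period")
    mask = ts.time >= t_end - T * (1.0 + 1e-9)
    t = ts.time[mask]
    sigma = ts.sigma_yx[mask]
    t0 = ts.metadata.get("osc_start", 0.0)
    gamma_osc = gamma0 * np.sin(omega * (t - t0))
    gdot_osc = gamma0 * omega * np.cos(omega * (t - t0))
    return (gamma_osc, sigma), (gdot_osc, sigma)
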