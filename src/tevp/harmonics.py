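"""Fourier-transform rheology: harmonic moduli, I3/I1, and sweeps.

The periodic stress response to γ(t) = γ0 sin(ωt) is expanded in odd
harmonics,

    σ(t) = γ0 Σ_{n odd} [G′_n sin(nωt) + G″_n cos(nωt)],

with G′_n / G″_n the n-th storage and loss moduli.  The coefficients are
obtained by linear least squares on the {sin(nωt), cos(nωt)} basis (A = b·x
normal equations), which tolerates non-uniform sampling; an FFT path is
available for uniform grids.  The nonlinearity metric is the intensity ratio
I3/I1 = √((G′3² + G″3²)/(G′1² + G″1²)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import TEVPParameters
from .protocols import (
    AMPLITUDE_SWEEP_OMEGA,
    FREQUENCY_SWEEP_GAMMA0,
    make_laos,
    make_udlaos,
)
from .simulator import RheoTimeSeries, SimOptions, integrate

__all__ = [
    "HarmonicSpectrum",
    "SweepResult",
    "decompose",
    "decompose_fft",
    "harmonic_ratio",
    "reconstruct",
    "amplitude_sweep",
    "frequency_sweep",
]


@dataclass
class HarmonicSpectrum:
    """Odd-harmonic storage/loss moduli of one oscillatory run."""

    gamma0: float
    omega: float
    orders: np.ndarray          # odd harmonic orders, ascending
    Gp: np.ndarray              # storage moduli G'_n, Pa
    Gpp: np.ndarray             # loss moduli G''_n, Pa
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.Gp = np.asarray(self.Gp, dtype=float)
        self.Gpp = np.asarray(self.Gpp, dtype=float)
        if not (len(self.orders) == len(self.Gp) == len(self.Gpp)):
            raise ValueError("orders, Gp, Gpp must have equal length")
        if np.any(np.diff(self.orders) <= 0):
            raise ValueError("harmonic orders must be strictly ascending")
        if not (np.all(np.isfinite(self.Gp)) and np.all(np.isfinite(self.Gpp))):
            raise ValueError("moduli must be finite")

    def modulus(self, n: int) -> tuple[float, float]:
        idx = np.nonzero(self.orders == n)[0]
        if len(idx) == 0:
            raise KeyError(f"harmonic order {n} not present")
        return float(self.Gp[idx[0]]), float(self.Gpp[idx[0]])


@dataclass
class SweepResult:
    """First-harmonic moduli and I3/I1 along a swept amplitude or frequency."""

    variable: str               # "gamma0" or "omega"
    values: np.ndarray
    Gp1: np.ndarray
    Gpp1: np.ndarray
    I3_I1: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = np.diff(self.values)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("swept variable must be strictly monotone")


def _design_matrix(t: np.ndarray, omega: float, orders: np.ndarray) -> np.ndarray:
    cols = []
    for n in orders:
        cols.append(np.sin(n * omega * t))
        cols.append(np.cos(n * omega * t))
    return np.column_stack(cols)


def decompose(ts: RheoTimeSeries, omega: float | None = None, gamma0: float | None = None,
              n_max: int = 11, include_even: bool = False) -> HarmonicSpectrum:
    """Least-squares odd-harmonic decomposition of the stress waveform.

    ``ts`` must span an integer number of periods at steady alternance; for
    UD-LAOS runs the drift-free oscillatory stress is decomposed unchanged
    (the steady bias, and even overtones, are absorbed only if
    ``include_even`` adds a constant and even orders as diagnostics).
    """
    omega = omega if omega is not None else ts.metadata.get("omega")
    gamma0 = gamma0 if gamma0 is not None else ts.metadata.get("gamma0")
    if omega is None or gamma0 is None:
        raise ValueError("omega and gamma0 required (missing from metadata)")
    if n_max % 2 == 0:
        raise ValueError("n_max must be odd")
    orders = np.arange(1, n_max + 1, 1 if include_even else 2)
    t0 = ts.metadata.get("osc_start", 0.0)
    t = ts.time - t0
    X = _design_matrix(t, omega, orders)
    if include_even:
        X = np.column_stack([np.ones_like(t), X])
    if X.shape[0] < X.shape[1]:
        raise ValueError(
            f"too few samples ({X.shape[0]}) for {X.shape[1]} harmonic coefficients")
    coef, *_ = np.linalg.lstsq(X, ts.sigma_yx, rcond=None)
    if include_even:
        coef = coef[1:]
    a = coef[0::2] / gamma0   # sin coefficients -> G'_n
    b = coef[1::2] / gamma0   # cos coefficients -> G''_n
    odd = orders % 2 == 1
    return HarmonicSpectrum(gamma0=gamma0, omega=omega, orders=orders[odd],
                            Gp=a[odd], Gpp=b[odd],
                            metadata={"n_max": n_max, "method": "lstsq",
                                      "drift_removed": ts.metadata.get("kind") == "udlaos"})


def decompose_fft(ts: RheoTimeSeries, omega: float | None = None,
                  gamma0: float | None = None, n_max: int = 11) -> HarmonicSpectrum:
    """FFT-based decomposition for uniformly sampled integer-period windows.

    Agrees with :func:`decompose` on uniform grids; provided as the fast path
    and as an internal cross-check.
    """
    omega = omega if omega is not None else ts.metadata.get("omega")
    gamma0 = gamma0 if gamma0 is not None else ts.metadata.get("gamma0")
    if omega is None or gamma0 is None:
        raise ValueError("omega and gamma0 required (missing from metadata)")
    dt = np.diff(ts.time)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=0):
        raise ValueError("FFT path requires uniform sampling")
    T = 2.0 * math.pi / omega
    span = ts.time[-1] - ts.time[0] + dt[0]  # open interval: last point + dt closes the period
    n_periods = span / T
    if abs(n_periods - round(n_periods)) > 1e-6:
        raise ValueError("FFT path requires an integer number of periods (endpoint excluded)")
    n_periods = int(round(n_periods))
    sigma = ts.sigma_yx
    N = len(sigma)
    t0 = ts.metadata.get("osc_start", 0.0)
    spec = np.fft.rfft(sigma) / N
    orders = np.arange(1, n_max + 1, 2)
    Gp = np.empty(len(orders))
    Gpp = np.empty(len(orders))
    phase0 = omega * (ts.time[0] - t0)
    for i, n in enumerate(orders):
        c = 2.0 * spec[n * n_periods]            # bin of harmonic n
        c *= np.exp(-1j * n * phase0)            # re-reference phase to osc start
        Gp[i] = -c.imag / gamma0
        Gpp[i] = c.real / gamma0
    return HarmonicSpectrum(gamma0=gamma0, omega=omega, orders=orders, Gp=Gp, Gpp=Gpp,
                            metadata={"n_max": n_max, "method": "fft"})


def harmonic_ratio(spec: HarmonicSpectrum) -> float:
    """Third-to-first harmonic intensity ratio I3/I1."""
    Gp1, Gpp1 = spec.modulus(1)
    Gp3, Gpp3 = spec.modulus(3)
    denom = Gp1**2 + Gpp1**2
    if denom == 0:
        raise ValueError("zero first harmonic; I3/I1 undefined")
    return math.sqrt((Gp3**2 + Gpp3**2) / denom)


def reconstruct(spec: HarmonicSpectrum, t: np.ndarray) -> np.ndarray:
    """Stress waveform rebuilt from the retained harmonics."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for n, gp, gpp in zip(spec.orders, spec.Gp, spec.Gpp):
        out += spec.gamma0 * (gp * np.sin(n * spec.omega * t) + gpp * np.cos(n * spec.omega * t))
    return out


def _sweep_point(params: TEVPParameters, gamma0: float, omega: float, kind: str,
                 n_max: int, options: SimOptions) -> tuple[float, float, float]:
    factory = make_laos if kind == "laos" else make_udlaos
    proto = factory(gamma0, omega, n_periods=1)
    ts = integrate(params, proto, options)
    spec = decompose(ts, n_max=n_max)
    gp1, gpp1 = spec.modulus(1)
    return gp1, gpp1, harmonic_ratio(spec)


def amplitude_sweep(params: TEVPParameters, gamma0_grid,
                    omega: float = AMPLITUDE_SWEEP_OMEGA, kind: str = "laos",
                    n_max: int = 11, options: SimOptions | None = None) -> SweepResult:
    """G′1, G″1 and I3/I1 versus strain amplitude at fixed ω (default 12.566 rad/s)."""
    gamma0_grid = np.asarray(gamma0_grid, dtype=float)
    if np.any(gamma0_grid <= 0):
        raise ValueError("strain amplitudes must be positive")
    options = options or SimOptions()
    rows = [_sweep_point(params, g0, omega, kind, n_max, options) for g0 in gamma0_grid]
    gp, gpp, ratio = map(np.array, zip(*rows))
    return SweepResult(variable="gamma0", values=gamma0_grid, Gp1=gp, Gpp1=gpp, I3_I1=ratio,
                       metadata={"omega": omega, "kind": kind, "n_max": n_max})


def frequency_sweep(params: TEVPParameters, omega_grid,
                    gamma0: float = FREQUENCY_SWEEP_GAMMA0, kind: str = "laos",
                    n_max: int = 11, options: SimOptions | None = None) -> SweepResult:
    """G′1, G″1 and I3/I1 versus angular frequency at fixed γ0 (default 10)."""
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid <= 0):
        raise ValueError("frequencies must be positive")
    options = options or SimOptions()
    rows = [_sweep_point(params, gamma0, w, kind, n_max, options) for w in omega_grid]
    gp, gpp, ratio = map(np.array, zip(*rows))
    return SweepResult(variable="omega", values=omega_grid, Gp1=gp, Gpp1=gpp, I3_I1=ratio,
                       metadata={"gamma0": gamma0, "kind": kind, "n_max": n_max})
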