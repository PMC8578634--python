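"""Parameter estimation: cost functions, parallel tempering, and AIC/BIC.

The identification workflow fits the seven free constants of the model
simultaneously to one steady-state flow curve and six transient step-shear
tiers, minimizing the sum of a normalized steady-state cost

    F_ss = (1/N) sqrt( Σ ((y_i − f_i)/y_i)² )

and a per-tier-averaged transient cost

    F_trans = (1/M) Σ_tiers (1/N) sqrt( Σ (y_i − f_i)² ).

Oscillatory predictions are scored with F_LAOS = (1/N) sqrt(Σ (y−f)²) and
sweeps with a mean absolute moduli error.  Model comparison uses
RSS = Σ |y_i − f_i| together with AIC = 2k + 2 ln RSS and
BIC = 2k ln n + 2 ln RSS (an L1 residual norm and doubled BIC penalty; the
conventional quadratic forms are available behind a convention switch).

The global optimizer is a parallel-tempering Metropolis sampler: several
chains explore the (log-transformed) bounded parameter space at increasing
temperatures and periodically exchange states, letting hot chains hand
basin-escaping moves down to the cold chain.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import (
    FITTED_PARAMETER_NAMES,
    TEVPParameters,
    lambda_ss,
    sigma_ss,
    structural_viscosity,
    yield_direction,
)

__all__ = [
    "cost_steady_state",
    "cost_transient",
    "cost_laos",
    "cost_sweep",
    "rss",
    "aic",
    "bic",
    "StepTier",
    "predict_step_stress",
    "JointObjective",
    "PTConfig",
    "FitResult",
    "parallel_tempering_fit",
    "identifiability",
    "fit_tevp",
    "DEFAULT_BOUNDS",
    "COMPARISON_MODELS",
    "compare_models",
]


# ---------------------------------------------------------------------------
# cost functions
# ---------------------------------------------------------------------------

def _pair(y, f) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError(f"data/prediction length mismatch: {y.shape} vs {f.shape}")
    if y.size == 0:
        raise ValueError("empty dataset")
    return y, f


def cost_steady_state(y, f) -> float:
    """Normalized flow-curve cost (1/N)·sqrt(Σ((y−f)/y)²); dimensionless."""
    y, f = _pair(y, f)
    if np.any(y == 0):
        raise ValueError("steady-state normalization undefined for zero stress data")
    return float(np.sqrt(np.sum(((y - f) / y) ** 2)) / len(y))


def cost_transient(tiers: Sequence[tuple]) -> float:
    """Mean over step tiers of (1/N)·sqrt(Σ(y−f)²); units Pa."""
    if len(tiers) == 0:
        raise ValueError("at least one transient tier required")
    total = 0.0
    for y, f in tiers:
        y, f = _pair(y, f)
        total += np.sqrt(np.sum((y - f) ** 2)) / len(y)
    return float(total / len(tiers))


def cost_laos(y, f) -> float:
    """Oscillatory waveform cost (1/N)·sqrt(Σ(y−f)²); units Pa."""
    y, f = _pair(y, f)
    return float(np.sqrt(np.sum((y - f) ** 2)) / len(y))


def cost_sweep(Gp_data, Gpp_data, Gp_model, Gpp_model) -> float:
    """Mean absolute storage+loss moduli error Σ(|ΔG′|+|ΔG″|)/(2n); units Pa."""
    gp_d, gp_m = _pair(Gp_data, Gp_model)
    gpp_d, gpp_m = _pair(Gpp_data, Gpp_model)
    if gp_d.shape != gpp_d.shape:
        raise ValueError("G' and G'' arrays must have equal length")
    n = len(gp_d)
    return float(np.sum(np.abs(gp_d - gp_m) + np.abs(gpp_d - gpp_m)) / (2 * n))


def rss(y, f, convention: str = "printed") -> float:
    """Residual sum used by the information criteria.

    ``printed`` (default): Σ sqrt((y−f)²) = Σ|y−f|, the L1 residual norm.
    ``squared``: the conventional Σ(y−f)².
    """
    y, f = _pair(y, f)
    if convention == "printed":
        return float(np.sum(np.abs(y - f)))
    if convention == "squared":
        return float(np.sum((y - f) ** 2))
    raise ValueError(f"unknown rss convention {convention!r}")


def aic(k: int, rss_value: float, n: int | None = None, convention: str = "printed") -> float:
    """Akaike information criterion.

    ``printed`` (default): AIC = 2k + 2 ln(RSS).  ``standard``: the
    least-squares form 2k + n ln(RSS/n), which requires ``n``.
    """
    if k < 1:
        raise ValueError("parameter count k must be >= 1")
    if rss_value <= 0:
        raise ValueError("RSS must be > 0 (log undefined); floor it if needed")
    if convention == "printed":
        return 2.0 * k + 2.0 * math.log(rss_value)
    if convention == "standard":
        if n is None or n < 1:
            raise ValueError("standard AIC requires the data count n")
        return 2.0 * k + n * math.log(rss_value / n)
    raise ValueError(f"unknown aic convention {convention!r}")


def bic(k: int, n: int, rss_value: float, convention: str = "printed") -> float:
    """Bayesian information criterion.

    ``printed`` (default): BIC = 2k ln(n) + 2 ln(RSS).  ``standard``: the
    least-squares form k ln(n) + n ln(RSS/n).
    """
    if k < 1:
        raise ValueError("parameter count k must be >= 1")
    if n < 2:
        raise ValueError("data count n must be >= 2 (ln penalty degenerates)")
    if rss_value <= 0:
        raise ValueError("RSS must be > 0 (log undefined); floor it if needed")
    if convention == "printed":
        return 2.0 * k * math.log(n) + 2.0 * math.log(rss_value)
    if convention == "standard":
        return k * math.log(n) + n * math.log(rss_value / n)
    raise ValueError(f"unknown bic convention {convention!r}")


# ---------------------------------------------------------------------------
# fast step-response evaluator
# ---------------------------------------------------------------------------

@dataclass
class StepTier:
    """One step-shear tier: plateau at ``gamma_dot_initial``, step to
    ``gamma_dot_step`` at t = 0, stress sampled at ``time`` (s, > 0)."""

    gamma_dot_initial: float
    gamma_dot_step: float
    time: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if len(self.time) != len(self.stress):
            raise ValueError("time and stress must have equal length")
        if np.any(self.time <= 0) or np.any(np.diff(self.time) <= 0):
            raise ValueError("tier times must be positive and strictly increasing")


def predict_step_stress(params: TEVPParameters, t, gamma_dot_initial: float,
                        gamma_dot_step: float, yield_sign: str = "shear_rate",
                        refine: int = 2) -> np.ndarray:
    """Shear stress after a rate step, evaluated at times ``t`` (s).

    The pre-step state is the constant-shear fixed point at the initial rate.
    The structure parameter follows its exact exponential relaxation (the
    kinetics are linear in λ at constant rate); the stress equation, linear in
    σ with time-varying coefficients, is advanced with an exponential
    midpoint integrator on the data grid (each interval split ``refine``
    times).  Matches the full ODE solver to well below typical measurement
    noise, at a fraction of the cost — this is the evaluator used inside
    optimization loops.
    """
    t = np.asarray(t, dtype=float)
    g = abs(gamma_dot_step)
    sgn = yield_direction(gamma_dot_step, yield_sign)
    lam0 = lambda_ss(params, gamma_dot_initial)
    eta0 = structural_viscosity(params, lam0)
    sig = lam0 * params.sigma_y0 * yield_direction(gamma_dot_initial, yield_sign) \
        + eta0 * gamma_dot_initial
    # λ(t) = λ_inf + (λ0 − λ_inf) e^{−A t}, exactly
    A = (params.t_r1 * g + params.t_r2 * g**params.d + 1.0) / params.tau_lambda
    lam_inf = lambda_ss(params, g)
    dlam = lam0 - lam_inf

    eta_ST, eta_inf, m, G, sy0 = params.eta_ST, params.eta_inf, params.m, params.G, params.sigma_y0
    exp = math.exp
    out = np.empty(len(t))
    t_prev = 0.0
    for i, ti in enumerate(t):
        dt_sub = (ti - t_prev) / refine
        for j in range(refine):
            tm = t_prev + (j + 0.5) * dt_sub
            lam_m = lam_inf + dlam * exp(-A * tm)
            eta_m = lam_m**m * eta_ST + eta_inf
            k_m = G / eta_m
            target = lam_m * sy0 * sgn + eta_m * gamma_dot_step
            sig = target + (sig - target) * exp(-k_m * dt_sub)
        out[i] = sig
        t_prev = ti
    return out


# ---------------------------------------------------------------------------
# joint objective
# ---------------------------------------------------------------------------

@dataclass
class JointObjective:
    """Simultaneous steady-state + transient objective over the 7 fitted constants.

    Called with the canonical fitted-parameter vector (see
    ``FITTED_PARAMETER_NAMES``); invalid parameter combinations return +inf so
    stochastic optimizers simply reject them.
    """

    flow_rates: np.ndarray
    flow_stress: np.ndarray
    tiers: list[StepTier]
    template: TEVPParameters
    weight_transient: float = 1.0
    yield_sign: str = "shear_rate"
    refine: int = 2

    def params_from(self, x) -> TEVPParameters:
        return self.template.with_fitted_vector(np.asarray(x, dtype=float))

    def components(self, x) -> dict[str, float]:
        params = self.params_from(x)
        f_ss = cost_steady_state(self.flow_stress, sigma_ss(params, self.flow_rates))
        pairs = [
            (tier.stress,
             predict_step_stress(params, tier.time, tier.gamma_dot_initial,
                                 tier.gamma_dot_step, self.yield_sign, self.refine))
            for tier in self.tiers
        ]
        f_tr = cost_transient(pairs)
        return {"ss": f_ss, "trans": f_tr}

    def __call__(self, x) -> float:
        try:
            c = self.components(x)
        except (ValueError, OverflowError, FloatingPointError):
            return math.inf
        val = c["ss"] + self.weight_transient * c["trans"]
        return val if math.isfinite(val) else math.inf

    def residual_pairs(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (data, prediction) over all datasets, for RSS/AIC/BIC."""
        params = self.params_from(x)
        ys = [self.flow_stress]
        fs = [np.asarray(sigma_ss(params, self.flow_rates))]
        for tier in self.tiers:
            ys.append(tier.stress)
            fs.append(predict_step_stress(params, tier.time, tier.gamma_dot_initial,
                                          tier.gamma_dot_step, self.yield_sign, self.refine))
        return np.concatenate(ys), np.concatenate(fs)


# ---------------------------------------------------------------------------
# parallel tempering
# ---------------------------------------------------------------------------

#: blood-plausible search decades for the 7 fitted constants, in canonical order.
DEFAULT_BOUNDS = {
    "t_r1": (1e-4, 1e3),
    "t_r2": (1e-4, 1e3),
    "sigma_y0": (1e-5, 1.0),
    "eta_ST": (1e-4, 1.0),
    "eta_inf": (1e-4, 0.1),
    "tau_lambda": (1e-2, 1e3),
    "G": (1e-4, 10.0),
}


@dataclass(frozen=True)
class PTConfig:
    """Parallel-tempering hyperparameters.

    The temperature ladder is geometric from 1 to ``t_max`` over ``n_chains``
    chains.  Proposals are Gaussian with standard deviation ``proposal_scale``
    of the bound span, applied in log10 space by default (the bounds span
    several decades).  ``polish`` runs a deterministic Nelder–Mead refinement
    from the best sampled point.
    """

    seed: int
    n_chains: int = 8
    t_max: float = 50.0
    n_steps: int = 5000
    swap_interval: int = 10
    proposal_scale: float = 0.05
    log_space: bool = True
    polish: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_steps < 1 or self.swap_interval < 1:
            raise ValueError("n_chains, n_steps and swap_interval must be >= 1")
        if self.t_max < 1.0:
            raise ValueError("t_max must be >= 1 (cold chain sits at T = 1)")

    def temperatures(self) -> np.ndarray:
        if self.n_chains == 1:
            return np.array([1.0])
        return np.geomspace(1.0, self.t_max, self.n_chains)


@dataclass
class FitResult:
    """Outcome of a fit: best parameters, costs, information criteria, diagnostics."""

    x: np.ndarray
    cost: float
    params: TEVPParameters | None = None
    components: dict = field(default_factory=dict)
    rss: float | None = None
    aic: float | None = None
    bic: float | None = None
    n_data: int | None = None
    k_parameters: int | None = None
    seed: int | None = None
    bounds: np.ndarray | None = None
    n_evaluations: int = 0
    acceptance_rates: np.ndarray | None = None
    swap_acceptance: float | None = None
    trace_best: np.ndarray | None = None
    parameter_correlation: np.ndarray | None = None
    weakly_identified: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        d = {k: conv(v) for k, v in vars(self).items() if k != "params"}
        if self.params is not None:
            d["params"] = self.params.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _reflect(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-bounds proposals back into [lo, hi]."""
    span = hi - lo
    z = np.mod(z - lo, 2.0 * span)
    z = np.where(z > span, 2.0 * span - z, z)
    return lo + z


def parallel_tempering_fit(objective: Callable[[np.ndarray], float], bounds,
                           config: PTConfig) -> FitResult:
    """Minimize ``objective`` over box ``bounds`` by parallel tempering.

    ``bounds`` is an (n, 2) array of finite box constraints.  Deterministic
    for a fixed ``config.seed``.  Non-finite objective values are treated as
    rejected proposals, never raised.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be an (n, 2) array")
    if not np.all(np.isfinite(bounds)) or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be finite with lower < upper")
    if config.log_space and np.any(bounds <= 0):
        raise ValueError("log-space sampling requires strictly positive bounds")

    to_x = (lambda z: 10.0**z) if config.log_space else (lambda z: z)
    lo = np.log10(bounds[:, 0]) if config.log_space else bounds[:, 0]
    hi = np.log10(bounds[:, 1]) if config.log_space else bounds[:, 1]
    span = hi - lo

    def energy(z: np.ndarray) -> float:
        v = objective(to_x(z))
        return v if math.isfinite(v) else math.inf

    rng = np.random.default_rng(config.seed)
    temps = config.temperatures()
    nC, nD = len(temps), len(lo)

    z = lo + rng.random((nC, nD)) * span
    E = np.array([energy(zi) for zi in z])
    n_eval = nC
    best_E_chain = E.copy()
    best_z_chain = z.copy()

    # the ladder is dimensionless; anchor it to the best energy found so far,
    # so the cold chain is genuinely greedy at the landscape's own scale
    # whatever the cost units are (re-anchored as the search descends)
    def anchored(best: float) -> np.ndarray:
        scale = best if (math.isfinite(best) and best > 0) else 1.0
        return temps * scale

    accepted = np.zeros(nC)
    swaps_tried = swaps_ok = 0
    trace = []
    # per-chain step scaled with sqrt(T): hot chains take wider strides, which
    # roughly equalizes acceptance across the ladder
    sigma = config.proposal_scale * span[None, :] * np.sqrt(temps)[:, None]

    T = anchored(float(np.min(best_E_chain[np.isfinite(best_E_chain)], initial=np.inf)))
    for step in range(config.n_steps):
        prop = _reflect(z + rng.standard_normal((nC, nD)) * sigma, lo, hi)
        for c in range(nC):
            E_new = energy(prop[c])
            n_eval += 1
            dE = E_new - E[c]
            if dE <= 0 or (math.isfinite(E_new) and rng.random() < math.exp(-dE / T[c])):
                z[c], E[c] = prop[c], E_new
                accepted[c] += 1
                if E_new < best_E_chain[c]:
                    best_E_chain[c], best_z_chain[c] = E_new, prop[c]
        if (step + 1) % config.swap_interval == 0:
            for c in range(nC - 1):
                swaps_tried += 1
                dBeta = 1.0 / T[c] - 1.0 / T[c + 1]
                dE = E[c] - E[c + 1]
                arg = dBeta * dE
                if math.isfinite(arg) and (arg <= 0 or rng.random() < math.exp(-arg)):
                    z[[c, c + 1]] = z[[c + 1, c]]
                    E[[c, c + 1]] = E[[c + 1, c]]
                    swaps_ok += 1
            T = anchored(float(np.min(best_E_chain)))
        if (step + 1) % max(1, config.n_steps // 100) == 0:
            trace.append(float(np.min(best_E_chain)))

    order = np.argsort(best_E_chain)
    best_E = float(best_E_chain[order[0]])
    best_z = best_z_chain[order[0]].copy()
    if config.polish:
        # refine from every chain's personal best: chains trapped in different
        # basins act as a deterministic multi-start for the local search
        for c in order:
            if not math.isfinite(best_E_chain[c]):
                continue
            res = minimize(energy, best_z_chain[c], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
            n_eval += res.nfev
            if res.fun < best_E and np.all(res.x >= lo) and np.all(res.x <= hi):
                best_E, best_z = float(res.fun), res.x

    return FitResult(
        x=np.asarray(to_x(best_z), dtype=float), cost=best_E, seed=config.seed,
        bounds=bounds, n_evaluations=n_eval,
        acceptance_rates=accepted / config.n_steps,
        swap_acceptance=(swaps_ok / swaps_tried) if swaps_tried else None,
        trace_best=np.array(trace),
    )


def identifiability(objective: JointObjective, x, corr_threshold: float = 0.85,
                    noise_floor: float = 1e-5) -> tuple[np.ndarray, list[str]]:
    """Local identifiability diagnostic at parameter vector ``x``.

    Computes the correlation matrix of the linearized (Fisher) parameter
    covariance from the noise-weighted prediction Jacobian in log-parameter
    space.  Per-point noise follows the multiplicative torque-noise model of
    a strain-controlled rheometer, sd_i = c·|y_i| + floor, with the relative
    level c estimated robustly (scaled MAD) from the residuals at ``x``.
    Parameters involved in a pair with |correlation| ≥ ``corr_threshold``
    form a sloppy direction: the data constrain a combination of them far
    better than each individually, so their point estimates can drift along
    the valley by much more than the residual level suggests.  Returns
    (correlation matrix, names of weakly identified parameters).
    """
    x = np.asarray(x, dtype=float)
    y, f0 = objective.residual_pairs(x)
    scale = np.maximum(np.abs(y), 1e-12)
    rel_hat = 1.4826 * float(np.median(np.abs(y - f0) / scale))
    sd = np.maximum(rel_hat * scale + noise_floor, 1e-12)

    def predictions(xx):
        return objective.residual_pairs(xx)[1]

    J = np.empty((len(f0), len(x)))
    h = 1e-6
    for j in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[j] *= 1.0 + h
        xm[j] *= 1.0 - h
        J[:, j] = (predictions(xp) - predictions(xm)) / (2.0 * h * sd)
    JTJ = J.T @ J
    try:
        cov = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        return np.full((len(x), len(x)), np.nan), list(FITTED_PARAMETER_NAMES)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    weak = set()
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if abs(corr[i, j]) >= corr_threshold:
                weak.add(FITTED_PARAMETER_NAMES[i])
                weak.add(FITTED_PARAMETER_NAMES[j])
    return corr, sorted(weak)


def fit_tevp(objective: JointObjective, config: PTConfig,
             bounds: dict | None = None,
             rss_convention: str = "printed",
             criteria_convention: str = "printed") -> FitResult:
    """Fit the 7 free model constants to flow-curve + step-tier data.

    Runs parallel tempering on the joint objective, then evaluates the
    per-protocol costs, RSS and information criteria at the optimum (k = 9
    total constants including the two fixed exponents), and attaches an
    identifiability diagnostic — a warning names any parameters whose point
    estimates sit in a sloppy (strongly correlated) direction of the data.
    """
    bdict = dict(DEFAULT_BOUNDS)
    if bounds:
        bdict.update(bounds)
    barr = np.array([bdict[n] for n in FITTED_PARAMETER_NAMES])
    result = parallel_tempering_fit(objective, barr, config)
    result.params = objective.params_from(result.x)
    result.components = objective.components(result.x)
    y, f = objective.residual_pairs(result.x)
    result.n_data = len(y)
    result.k_parameters = 9
    result.rss = rss(y, f, rss_convention)
    result.aic = aic(result.k_parameters, result.rss, result.n_data, criteria_convention)
    result.bic = bic(result.k_parameters, result.n_data, result.rss, criteria_convention)
    result.parameter_correlation, result.weakly_identified = identifiability(objective, result.x)
    if result.weakly_identified:
        warnings.warn(
            "weakly identified parameters (sloppy correlated directions): "
            + ", ".join(result.weakly_identified), UserWarning)
    return result


# ---------------------------------------------------------------------------
# model-comparison registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonModel:
    """Registry entry for a model competing on AIC/BIC.

    ``evaluator`` (optional) maps (x, protocol data) to predictions; entries
    without one carry parameter-count metadata only and can still be ranked
    from externally supplied RSS values.
    """

    name: str
    n_parameters: int
    n_fitted: int
    evaluator: Callable | None = None


#: built-in registry: this package's model plus the 13-parameter contemporary
#: tensorial ethixo-mHAWB framework (count metadata only; no evaluator).
COMPARISON_MODELS: dict[str, ComparisonModel] = {
    "t-e-TVP": ComparisonModel("t-e-TVP", n_parameters=9, n_fitted=7),
    "t-ethixo-mHAWB": ComparisonModel("t-ethixo-mHAWB", n_parameters=13, n_fitted=10),
}


def compare_models(entries: dict[str, tuple[float, int]],
                   convention: str = "printed") -> list[dict]:
    """Rank registered models by AIC given {name: (rss, n_data)}.

    Returns a list of dicts (name, k, rss, aic, bic) sorted by ascending AIC.
    """
    rows = []
    for name, (rss_value, n) in entries.items():
        if name not in COMPARISON_MODELS:
            raise KeyError(f"model {name!r} is not registered")
        k = COMPARISON_MODELS[name].n_parameters
        rows.append({
            "name": name, "k": k, "n": n, "rss": rss_value,
            "aic": aic(k, rss_value, n, convention),
            "bic": bic(k, n, rss_value, convention),
        })
    rows.sort(key=lambda r: r["aic"])
    return rows
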