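"""Synthetic rheometer datasets with planted parameters.

Emulates the full strain-controlled experimental suite for a blood sample —
steady-state flow curve, step-down and step-up shear tiers, LAOS and UD-LAOS
at ω = 1 rad/s, and amplitude/frequency sweeps — from a known ("planted")
parameter set, with multiplicative measurement noise applied to the stress
and moduli observables only.  Every fitting and prediction stage of the
package is thereby testable end-to-end without any external data download.

The noise model (multiplicative relative scatter plus a small additive floor)
mimics torque noise of a strain-controlled rotational rheometer; it does not
attempt instrument inertia, gap-loading or evaporation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import StepTier
from .harmonics import SweepResult, amplitude_sweep, frequency_sweep
from .model import TEVPParameters
from .protocols import (
    AMPLITUDE_SWEEP_OMEGA,
    FREQUENCY_SWEEP_GAMMA0,
    STEP_DOWN_INITIAL,
    STEP_DOWN_TARGETS,
    STEP_UP_INITIAL,
    STEP_UP_TARGETS,
    make_laos,
    make_udlaos,
)
from .simulator import RheoTimeSeries, Segment, ShearProtocol, SimOptions, equilibrate, integrate

__all__ = [
    "NoiseModel",
    "DonorMetadata",
    "donor_fixtures",
    "SyntheticBundle",
    "generate_suite",
    "BLOOD_LIKE_PARAMS",
]

#: representative healthy-donor parameter set used as the default planted
#: truth: yield stress of a few mPa, solvent-limit viscosity ~5 mPa·s,
#: structural viscosity tens of mPa·s, elastic modulus well under 1 Pa, and
#: rouleaux kinetics of a few seconds — the ranges whole blood occupies at
#: 37 °C.
BLOOD_LIKE_PARAMS = TEVPParameters(
    t_r1=2.5,       # s
    t_r2=1.2,       # s^(1/2)
    sigma_y0=0.008,  # Pa
    eta_ST=0.020,   # Pa.s
    eta_inf=0.0048,  # Pa.s
    tau_lambda=7.0,  # s
    G=0.35,         # Pa
)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: y → y(1 + sd·ε1) + floor·ε2 with ε ~ N(0, 1)."""

    rel_sd: float = 0.02
    floor: float = 1e-5     # Pa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_sd < 0 or self.floor < 0:
            raise ValueError("noise levels must be >= 0")

    def apply(self, rng: np.random.Generator, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = values * (1.0 + self.rel_sd * rng.standard_normal(values.shape))
        out += self.floor * rng.standard_normal(values.shape)
        return out


@dataclass(frozen=True)
class DonorMetadata:
    """Blood-panel metadata of one donor (labels only; the model takes no covariates)."""

    donor_id: int
    hct_pct: float
    fibrinogen_mg_dl: float
    total_cholesterol_mg_ml: float
    triglycerides_mg_ml: float
    hdl_mg_ml: float
    ldl_mg_ml: float

    def __post_init__(self) -> None:
        for name in ("hct_pct", "fibrinogen_mg_dl", "total_cholesterol_mg_ml",
                     "triglycerides_mg_ml", "hdl_mg_ml", "ldl_mg_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def donor_fixtures() -> list[DonorMetadata]:
    """The two reference donors' blood-panel values."""
    return [
        DonorMetadata(donor_id=1, hct_pct=38.3, fibrinogen_mg_dl=0.333,
                      total_cholesterol_mg_ml=145.0, triglycerides_mg_ml=144.0,
                      hdl_mg_ml=39.0, ldl_mg_ml=82.0),
        DonorMetadata(donor_id=2, hct_pct=45.2, fibrinogen_mg_dl=0.214,
                      total_cholesterol_mg_ml=187.0, triglycerides_mg_ml=57.0,
                      hdl_mg_ml=65.0, ldl_mg_ml=108.0),
    ]


# dataset-size conventions of the generator (point counts per test are not a
# standardized quantity; these are desk-scale values typical of the instrument
# software, recorded in the bundle manifest)
FLOW_CURVE_RATES = (1e-2, 1e3, 30)   # (lo, hi, n) log-spaced, 1/s
TIER_TIME_GRID = (1e-2, 30.0, 100)   # (t_min, t_max, n) log-spaced, s
SWEEP_GAMMA0_GRID = (1e-2, 30.0, 10)
SWEEP_OMEGA_GRID = (1e-1, 30.0, 10)


def _tier_truth(params: TEVPParameters, g_init: float, g_step: float,
                times: np.ndarray, options: SimOptions) -> np.ndarray:
    """Noiseless step-tier stress from the full ODE simulator."""
    seg = Segment(kind="constant_rate", gamma_dot=g_step, duration=float(times[-1]))
    proto = ShearProtocol(segments=[seg], preshear=None, name=f"tier_{g_init:g}_{g_step:g}")
    init = equilibrate(params, g_init, options.yield_sign)
    ts = integrate(params, proto, options, initial=init, sample_times=times)
    return ts.sigma_yx


@dataclass
class SyntheticBundle:
    """One synthetic experimental campaign with its planted truth."""

    truth: TEVPParameters
    noise: NoiseModel
    flow_rates: np.ndarray
    flow_stress: np.ndarray
    tiers: list[StepTier]
    laos: RheoTimeSeries | None = None
    udlaos: RheoTimeSeries | None = None
    amp_sweep: SweepResult | None = None
    freq_sweep: SweepResult | None = None
    manifest: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        """Write the bundle: one directory per protocol, truth.json, manifest.yaml."""
        from .io import write_timeseries_csv

        root = Path(directory)
        root.mkdir(parents=True, exist_ok=True)
        self.truth.to_json(root / "truth.json")

        ss_dir = root / "steady_state"
        ss_dir.mkdir(exist_ok=True)
        pd.DataFrame({"shear_rate_1_per_s": self.flow_rates,
                      "sigma_yx_Pa": self.flow_stress}).to_csv(
            ss_dir / "flow_curve.csv", index=False, float_format="%.17g")

        tier_dir = root / "step_tiers"
        tier_dir.mkdir(exist_ok=True)
        for i, tier in enumerate(self.tiers):
            pd.DataFrame({"time_s": tier.time, "sigma_yx_Pa": tier.stress}).to_csv(
                tier_dir / f"tier_{i:02d}_{tier.gamma_dot_initial:g}_to_"
                           f"{tier.gamma_dot_step:g}.csv",
                index=False, float_format="%.17g")

        for name, ts in (("laos", self.laos), ("udlaos", self.udlaos)):
            if ts is not None:
                d = root / name
                d.mkdir(exist_ok=True)
                write_timeseries_csv(d / "timeseries.csv", ts)
        for name, sw in (("amplitude_sweep", self.amp_sweep), ("frequency_sweep", self.freq_sweep)):
            if sw is not None:
                d = root / name
                d.mkdir(exist_ok=True)
                pd.DataFrame({sw.variable: sw.values, "Gp1_Pa": sw.Gp1,
                              "Gpp1_Pa": sw.Gpp1, "I3_I1": sw.I3_I1}).to_csv(
                    d / "sweep.csv", index=False, float_format="%.17g")
        with open(root / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)

    @classmethod
    def load(cls, directory) -> "SyntheticBundle":
        """Read back a written bundle (flow curve, tiers, truth, manifest)."""
        from .io import read_timeseries_csv

        root = Path(directory)
        truth = TEVPParameters.from_json(root / "truth.json")
        with open(root / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        fc = pd.read_csv(root / "steady_state" / "flow_curve.csv",
                         float_precision="round_trip")
        tiers = []
        for f in sorted((root / "step_tiers").glob("tier_*.csv")):
            parts = f.stem.split("_")
            g_init, g_step = float(parts[2]), float(parts[4])
            df = pd.read_csv(f, float_precision="round_trip")
            tiers.append(StepTier(g_init, g_step, df["time_s"].to_numpy(),
                                  df["sigma_yx_Pa"].to_numpy()))
        laos = udlaos = None
        if (root / "laos" / "timeseries.csv").exists():
            laos = read_timeseries_csv(root / "laos" / "timeseries.csv")
        if (root / "udlaos" / "timeseries.csv").exists():
            udlaos = read_timeseries_csv(root / "udlaos" / "timeseries.csv")
        noise = NoiseModel(**manifest.get("noise", {}))
        return cls(truth=truth, noise=noise,
                   flow_rates=fc["shear_rate_1_per_s"].to_numpy(),
                   flow_stress=fc["sigma_yx_Pa"].to_numpy(),
                   tiers=tiers, laos=laos, udlaos=udlaos, manifest=manifest)


def generate_suite(true_params: TEVPParameters = BLOOD_LIKE_PARAMS,
                   noise: NoiseModel = NoiseModel(),
                   include_oscillatory: bool = True,
                   include_sweeps: bool = False,
                   laos_gamma0: float = 10.0, laos_omega: float = 1.0,
                   options: SimOptions | None = None) -> SyntheticBundle:
    """Simulate the full experimental suite and apply measurement noise.

    Noise touches only the stress/moduli observables; time, shear rate and
    the sweep abscissae are exact.  Deterministic for a fixed ``noise.seed``.
    Sweeps are comparatively expensive and off by default.
    """
    options = options or SimOptions()
    rng = np.random.default_rng(noise.seed)
    from .model import sigma_ss

    lo, hi, n = FLOW_CURVE_RATES
    flow_rates = np.geomspace(lo, hi, int(n))
    flow_truth = np.asarray(sigma_ss(true_params, flow_rates))
    flow_stress = noise.apply(rng, flow_truth)

    t0, t1, nt = TIER_TIME_GRID
    tier_times = np.geomspace(t0, t1, int(nt))
    tiers = []
    tier_specs = [(STEP_DOWN_INITIAL, g) for g in STEP_DOWN_TARGETS] \
        + [(STEP_UP_INITIAL, g) for g in STEP_UP_TARGETS]
    for g_init, g_step in tier_specs:
        truth = _tier_truth(true_params, g_init, g_step, tier_times, options)
        tiers.append(StepTier(g_init, g_step, tier_times, noise.apply(rng, truth)))

    laos_ts = udlaos_ts = None
    if include_oscillatory:
        for factory in (make_laos, make_udlaos):
            ts = integrate(true_params, factory(laos_gamma0, laos_omega, n_periods=3), options)
            ts.sigma_yx = noise.apply(rng, ts.sigma_yx)
            ts.metadata["noise_applied"] = True
            if factory is make_laos:
                laos_ts = ts
            else:
                udlaos_ts = ts

    amp = freq = None
    if include_sweeps:
        g_lo, g_hi, g_n = SWEEP_GAMMA0_GRID
        amp = amplitude_sweep(true_params, np.geomspace(g_lo, g_hi, int(g_n)),
                              omega=AMPLITUDE_SWEEP_OMEGA, options=options)
        w_lo, w_hi, w_n = SWEEP_OMEGA_GRID
        freq = frequency_sweep(true_params, np.geomspace(w_lo, w_hi, int(w_n)),
                               gamma0=FREQUENCY_SWEEP_GAMMA0, options=options)
        for sw in (amp, freq):
            sw.Gp1 = noise.apply(rng, sw.Gp1)
            sw.Gpp1 = noise.apply(rng, sw.Gpp1)

    manifest = {
        "noise": {"rel_sd": noise.rel_sd, "floor": noise.floor, "seed": noise.seed},
        "flow_curve": {"rates_1_per_s": [lo, hi], "n_points": int(n)},
        "step_tiers": [{"initial": gi, "step": gs, "t_max_s": t1,
                        "n_points": int(nt), "sampling": "log"}
                       for gi, gs in tier_specs],
        "oscillatory": ({"gamma0": laos_gamma0, "omega_rad_s": laos_omega, "n_periods": 3}
                        if include_oscillatory else None),
        "i3_i1_drift_removed": True,
    }
    return SyntheticBundle(truth=true_params, noise=noise, flow_rates=flow_rates,
                           flow_stress=flow_stress, tiers=tiers, laos=laos_ts,
                           udlaos=udlaos_ts, amp_sweep=amp, freq_sweep=freq,
                           manifest=manifest)
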