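"""Applied-deformation histories of the standard blood-rheometry test suite.

A :class:`ShearProtocol` is an ordered list of analytic segments — constant
shear rate, LAOS (strain γ(t) = γ0 sin ωt) or UD-LAOS (the same oscillation
superposed on a steady drift so the shear rate never reverses) — optionally
preceded by a high-shear preshear that erases the sample's mechanical memory.
Factories cover the full experimental suite: flow curve, step up/down tiers,
LAOS/UD-LAOS, and amplitude/frequency sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Segment",
    "ShearProtocol",
    "make_preshear",
    "make_constant_rate",
    "make_step_sequence",
    "make_laos",
    "make_udlaos",
    "oscillatory_component",
    "step_down_tiers",
    "step_up_tiers",
    "standard_suite",
    "PRESHEAR_RATE",
    "PRESHEAR_DURATION",
    "MAX_SHEAR_RATE",
    "AMPLITUDE_SWEEP_OMEGA",
    "FREQUENCY_SWEEP_GAMMA0",
]

#: preshear conditioning used before every test: 300 s⁻¹ for 30 s.
PRESHEAR_RATE = 300.0
PRESHEAR_DURATION = 30.0
#: instrument ceiling respected by the suite factories.
MAX_SHEAR_RATE = 1000.0
#: default angular frequency of the amplitude sweep, rad/s.
AMPLITUDE_SWEEP_OMEGA = 12.566
#: default strain amplitude of the frequency sweep, dimensionless.
FREQUENCY_SWEEP_GAMMA0 = 10.0


@dataclass(frozen=True)
class Segment:
    """One piece of a protocol: kind ∈ {constant_rate, laos, udlaos}."""

    kind: str
    duration: float
    gamma_dot: float = 0.0      # constant_rate only, s^-1
    gamma0: float = 0.0         # oscillatory kinds, dimensionless
    omega: float = 0.0          # oscillatory kinds, rad/s

    def __post_init__(self) -> None:
        if self.kind not in ("constant_rate", "laos", "udlaos"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.kind in ("laos", "udlaos") and (self.gamma0 <= 0 or self.omega <= 0):
            raise ValueError("oscillatory segments require gamma0 > 0 and omega > 0")

    @property
    def period(self) -> float:
        if self.kind == "constant_rate":
            raise ValueError("constant_rate segment has no period")
        return 2.0 * math.pi / self.omega

    def shear_rate(self, t):
        """Shear rate at local time t (array-friendly)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant_rate":
            out = np.full_like(t, self.gamma_dot)
        elif self.kind == "laos":
            out = self.gamma0 * self.omega * np.cos(self.omega * t)
        else:  # udlaos: cos term shifted up so the rate never goes negative
            out = self.gamma0 * self.omega * (np.cos(self.omega * t) + 1.0)
        return float(out) if out.ndim == 0 else out

    def strain(self, t):
        """Accumulated strain within the segment (zero at local t = 0)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant_rate":
            out = self.gamma_dot * t
        elif self.kind == "laos":
            out = self.gamma0 * np.sin(self.omega * t)
        else:
            out = self.gamma0 * np.sin(self.omega * t) + self.gamma0 * self.omega * t
        return float(out) if out.ndim == 0 else out


@dataclass
class ShearProtocol:
    """Piecewise-analytic applied shear-rate history γ̇(t).

    ``segments`` excludes the optional preshear, which is carried separately
    so the simulator can either integrate it explicitly or replace it by its
    steady-state equivalent.  Global time t = 0 is the start of the first
    (post-preshear) segment; strain accumulates continuously across segments.
    """

    segments: list[Segment]
    preshear: Segment | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.preshear is not None and self.preshear.kind != "constant_rate":
            raise ValueError("preshear must be a constant_rate segment")

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, length = number of segments."""
        return np.cumsum([s.duration for s in self.segments])

    def _locate(self, t: float) -> tuple[int, float]:
        ends = self.boundaries()
        i = int(np.searchsorted(ends, t, side="right"))
        i = min(i, len(self.segments) - 1)
        start = 0.0 if i == 0 else ends[i - 1]
        return i, t - start

    def shear_rate(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        for j, tj in enumerate(t_arr):
            i, tl = self._locate(tj)
            out[j] = self.segments[i].shear_rate(tl)
        return float(out[0]) if np.ndim(t) == 0 else out

    def strain(self, t):
        """Strain at global time t: running integral of the shear rate."""
        ends = self.boundaries()
        starts = np.concatenate([[0.0], ends[:-1]])
        seg_strains = np.array([s.strain(s.duration) for s in self.segments])
        cum = np.concatenate([[0.0], np.cumsum(seg_strains)[:-1]])
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        for j, tj in enumerate(t_arr):
            i, tl = self._locate(tj)
            out[j] = cum[i] + self.segments[i].strain(tl)
        return float(out[0]) if np.ndim(t) == 0 else out

    def oscillatory_segment(self) -> tuple[int, Segment, float]:
        """Return (index, segment, global start time) of the oscillatory part."""
        start = 0.0
        for i, s in enumerate(self.segments):
            if s.kind in ("laos", "udlaos"):
                return i, s, start
            start += s.duration
        raise ValueError("protocol has no oscillatory segment")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "segments": [
                {k: v for k, v in vars(s).items() if v or k in ("kind", "duration")}
                for s in self.segments
            ],
        }
        if self.preshear is not None:
            d["preshear"] = {"gamma_dot": self.preshear.gamma_dot, "duration": self.preshear.duration}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ShearProtocol":
        segs = [Segment(**s) for s in d["segments"]]
        pre = None
        if "preshear" in d and d["preshear"] is not None:
            pre = Segment(kind="constant_rate", **d["preshear"])
        return cls(segments=segs, preshear=pre, name=d.get("name", ""))

    @classmethod
    def from_yaml(cls, path) -> "ShearProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_preshear(gamma_dot: float = PRESHEAR_RATE, duration: float = PRESHEAR_DURATION) -> Segment | None:
    """Standard preshear conditioning segment; duration 0 disables it."""
    if duration == 0:
        return None
    return Segment(kind="constant_rate", gamma_dot=gamma_dot, duration=duration)


def make_constant_rate(gamma_dot: float, duration: float, preshear: bool = True,
                       name: str = "") -> ShearProtocol:
    """Single constant-shear-rate test."""
    return ShearProtocol(
        segments=[Segment(kind="constant_rate", gamma_dot=gamma_dot, duration=duration)],
        preshear=make_preshear() if preshear else None,
        name=name or f"constant_{gamma_dot:g}",
    )


def make_step_sequence(rates: Sequence[float], durations: Sequence[float],
                       preshear: bool = True, name: str = "") -> ShearProtocol:
    """Piecewise-constant step test through ``rates`` with matching ``durations``."""
    if len(rates) != len(durations):
        raise ValueError("rates and durations must have equal length")
    if any(r <= 0 for r in rates):
        raise ValueError("step rates must be positive")
    segs = [Segment(kind="constant_rate", gamma_dot=r, duration=d) for r, d in zip(rates, durations)]
    return ShearProtocol(segments=segs, preshear=make_preshear() if preshear else None,
                         name=name or "step_" + "_".join(f"{r:g}" for r in rates))


def make_laos(gamma0: float, omega: float, n_periods: int = 3, preshear: bool = True,
              name: str = "") -> ShearProtocol:
    """Large-amplitude oscillatory shear: γ(t) = γ0 sin(ωt), γ̇ = γ0 ω cos(ωt)."""
    if gamma0 <= 0 or omega <= 0:
        raise ValueError("gamma0 and omega must be positive")
    if n_periods < 1 or n_periods != int(n_periods):
        raise ValueError("n_periods must be a positive integer")
    seg = Segment(kind="laos", gamma0=gamma0, omega=omega,
                  duration=n_periods * 2.0 * math.pi / omega)
    return ShearProtocol(segments=[seg], preshear=make_preshear() if preshear else None,
                         name=name or f"laos_g{gamma0:g}_w{omega:g}")


def make_udlaos(gamma0: float, omega: float, n_periods: int = 3, preshear: bool = True,
                name: str = "") -> ShearProtocol:
    """Unidirectional LAOS: γ(t) = γ0 sin(ωt) + γ0 ω t, so γ̇ = γ0 ω (cos ωt + 1) ≥ 0."""
    if gamma0 <= 0 or omega <= 0:
        raise ValueError("gamma0 and omega must be positive")
    if n_periods < 1 or n_periods != int(n_periods):
        raise ValueError("n_periods must be a positive integer")
    seg = Segment(kind="udlaos", gamma0=gamma0, omega=omega,
                  duration=n_periods * 2.0 * math.pi / omega)
    return ShearProtocol(segments=[seg], preshear=make_preshear() if preshear else None,
                         name=name or f"udlaos_g{gamma0:g}_w{omega:g}")


def oscillatory_component(protocol: ShearProtocol, t):
    """Oscillatory strain and shear rate (γ0 sin ωt, γ0 ω cos ωt) at global time t.

    For UD-LAOS the steady drift is removed; this is the abscissa convention
    of Lissajous–Bowditch elastic/viscous projections.
    """
    _, seg, start = protocol.oscillatory_segment()
    tl = np.asarray(t, dtype=float) - start
    g_osc = seg.gamma0 * np.sin(seg.omega * tl)
    gd_osc = seg.gamma0 * seg.omega * np.cos(seg.omega * tl)
    return g_osc, gd_osc


# ---------------------------------------------------------------------------
# experiment-suite factories
# ---------------------------------------------------------------------------

#: step-down tiers: conditioning plateau at 5 s⁻¹ stepping to each target.
STEP_DOWN_INITIAL = 5.0
STEP_DOWN_TARGETS = (2.5, 1.0, 0.5)
#: step-up tiers: conditioning plateau at 0.25 s⁻¹ stepping up.
STEP_UP_INITIAL = 0.25
STEP_UP_TARGETS = (1.0, 2.5, 5.0)
#: default plateau duration per step segment, s.
STEP_PLATEAU_DURATION = 30.0


def step_down_tiers(targets: Sequence[float] = STEP_DOWN_TARGETS,
                    initial: float = STEP_DOWN_INITIAL,
                    duration: float = STEP_PLATEAU_DURATION) -> list[ShearProtocol]:
    """The step-down tier set (default 5 → 2.5, 1, 0.5 s⁻¹), one protocol per tier."""
    return [
        make_step_sequence([initial, g], [duration, duration], name=f"step_down_{initial:g}_to_{g:g}")
        for g in targets
    ]


def step_up_tiers(targets: Sequence[float] = STEP_UP_TARGETS,
                  initial: float = STEP_UP_INITIAL,
                  duration: float = STEP_PLATEAU_DURATION) -> list[ShearProtocol]:
    """The step-up tier set (default 0.25 → 1, 2.5, 5 s⁻¹)."""
    return [
        make_step_sequence([initial, g], [duration, duration], name=f"step_up_{initial:g}_to_{g:g}")
        for g in targets
    ]


def standard_suite(laos_gamma0: float = 10.0, laos_omega: float = 1.0,
                n_periods: int = 3) -> dict[str, ShearProtocol | list[ShearProtocol]]:
    """The full experimental protocol suite as a name → protocol mapping.

    Steady-state flow curve rates are handled separately (they are algebraic
    in this model); this factory provides the transient and oscillatory runs.
    All shear rates stay below the 1000 s⁻¹ instrument ceiling.
    """
    suite: dict[str, ShearProtocol | list[ShearProtocol]] = {
        "step_down": step_down_tiers(),
        "step_up": step_up_tiers(),
        "laos": make_laos(laos_gamma0, laos_omega, n_periods),
        "udlaos": make_udlaos(laos_gamma0, laos_omega, n_periods),
    }
    for p in list(suite["step_down"]) + list(suite["step_up"]) + [suite["laos"], suite["udlaos"]]:
        rates = [abs(s.gamma_dot) if s.kind == "constant_rate" else 2.0 * s.gamma0 * s.omega
                 for s in p.segments]
        if max(rates) > MAX_SHEAR_RATE:
            raise ValueError(f"protocol {p.name} exceeds the {MAX_SHEAR_RATE} 1/s ceiling")
    return suite
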