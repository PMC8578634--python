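# tevp — thixo-elasto-visco-plastic modelling of human blood

Whole blood is a thixo-elasto-visco-plastic (TEVP) fluid: red blood cells
aggregate into coin-stack *rouleaux* at low shear and disperse at high shear,
giving blood a small yield stress, strong shear thinning, elasticity, and a
time-dependent (thixotropic) viscosity. Capturing all of this with few
parameters matters for hemorheological diagnostics and for constitutive
models that can be embedded in blood-flow simulations.

`tevp` implements a nine-constant tensorial TEVP model and everything needed
to exercise it against strain-controlled rheometer experiments:

- **Structure kinetics.** A dimensionless structure parameter λ ∈ [0, 1]
  (1 = fully built rouleaux network) evolves as

  dλ/dt = (1/τ_λ) [ −t_r1 |γ̇| λ + t_r2 |γ̇|^d (1 − λ) + (1 − λ) ],

  balancing shear breakdown against shear-driven and Brownian aggregation,
  with the steady state λ_ss = (t_r2 |γ̇|^d + 1) / (t_r1 |γ̇| + t_r2 |γ̇|^d + 1).

- **Stress evolution.** An upper-convected-Maxwell-type system for the
  (xx, yy, zz, yx) stress components with relaxation time
  τ(λ) = (λ^m η_ST + η_∞)/G and a structure-weighted yield term λσ_y0, whose
  constant-shear fixed point is the flow curve
  σ_ss = σ_y0 λ_ss + η_ST λ_ss^m γ̇ + η_∞ γ̇ and which predicts the first
  normal stress difference N1 = σ_xx − σ_yy. A scalar single-component form
  is provided and is exactly equivalent when σ_yy ≡ 0.

- **Protocols.** The full experimental suite as analytic protocol objects:
  preshear conditioning (300 s⁻¹ for 30 s), flow curves, step-down
  (5 → 2.5, 1, 0.5 s⁻¹) and step-up (0.25 → 1, 2.5, 5 s⁻¹) tiers, LAOS
  (γ = γ0 sin ωt) and unidirectional LAOS (γ̇ = γ0ω(cos ωt + 1) ≥ 0), and
  amplitude/frequency sweeps.

- **Fourier-transform rheology.** Odd-harmonic storage/loss moduli G′n, G″n
  by least squares, the nonlinearity ratio I3/I1, Lissajous–Bowditch
  elastic/viscous projections, amplitude and frequency sweeps.

- **Fitting and model comparison.** The normalized steady-state and
  transient cost functions, a seeded parallel-tempering global optimizer
  with identifiability diagnostics, and RSS/AIC/BIC model ranking against a
  registry of competing models (a 13-parameter contemporary model ships as
  count metadata for comparison).

- **Synthetic data.** A generator that emulates the entire campaign with a
  planted parameter set and multiplicative rheometer noise, so the whole
  pipeline is testable without instrument data.

## Worked example

```python
import numpy as np
from tevp import (BLOOD_LIKE_PARAMS, make_laos, integrate, decompose,
                  harmonic_ratio, sigma_ss)

params = BLOOD_LIKE_PARAMS               # representative healthy-donor set

# steady-state flow curve at three rates
print(np.round(sigma_ss(params, np.array([0.1, 10.0, 100.0])), 5))
# -> [0.00881 0.0622  0.50237]  (Pa; yield plateau -> shear thinning -> solvent slope)

# three recorded LAOS periods at gamma0 = 10, omega = 1 rad/s
ts = integrate(params, make_laos(10.0, 1.0, n_periods=3))
spec = decompose(ts)
print(round(spec.modulus(1)[1], 5), round(harmonic_ratio(spec), 4))
# -> 0.00663 0.0627
```

The loss modulus G″1 ≈ 6.6 mPa exceeds |G′1| by two orders of magnitude —
blood at these amplitudes is far more liquid than solid — and I3/I1 ≈ 0.063
quantifies the nonlinearity of the stress waveform.

Fitting a synthetic campaign from the command line:

```bash
tevp synth --seed 7 --out bundle/
tevp fit --bundle bundle/ --seed 3 --out fit/
tevp compare --entry t-e-TVP 0.42 630 --entry t-ethixo-mHAWB 0.42 630
```

`fit` reports the joint cost, RSS, AIC and BIC and writes `fit/fit.json`
with the estimated parameters, optimizer diagnostics and an identifiability
report; `compare` ranks models by AIC (at equal residual the 9-constant
model wins by 8 AIC points over a 13-constant competitor).

## Layout

| module | contents |
| --- | --- |
| `tevp.model` | parameters, structure kinetics, scalar/tensor stress rates |
| `tevp.protocols` | protocol objects and experiment-suite factories |
| `tevp.simulator` | stiff ODE driver, equilibration, Lissajous projections |
| `tevp.harmonics` | harmonic decomposition, I3/I1, sweeps |
| `tevp.fitting` | cost functions, parallel tempering, AIC/BIC, registry |
| `tevp.synthetic` | noise model, campaign generator, donor metadata |
| `tevp.io` / `tevp.cli` | CSV/JSON/YAML schemas and the `tevp` command |

See `docs/methods.md` for the model assumptions, numerical choices, and
known limitations.
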