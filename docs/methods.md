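# Methods

## The model

Blood's rouleaux microstructure is tracked by a scalar structure parameter
λ ∈ [0, 1] with first-order kinetics

dλ/dt = (1/τ_λ) [ −t_r1 |γ̇| λ + t_r2 |γ̇|^d (1 − λ) + (1 − λ) ]

whose three terms are shear breakdown, shear aggregation, and Brownian
aggregation. At constant shear rate the kinetics are linear in λ with the
closed-form steady state λ_ss = (t_r2|γ̇|^d + 1)/(t_r1|γ̇| + t_r2|γ̇|^d + 1):
λ_ss = 1 at rest and decays toward 0 at high shear.

Stress evolves through a Maxwell-type system with structure-dependent
viscosity η(λ) = λ^m η_ST + η_∞ and relaxation time τ(λ) = η(λ)/G. In simple
shear the four tracked tensor components obey

- τ(λ)(σ̇_xx − 2 σ_yx γ̇) + σ_xx = 0
- τ(λ) σ̇_yy + σ_yy = 0, and likewise for σ_zz
- τ(λ)(σ̇_yx − 2 σ_yy γ̇) + σ_yx = λ σ_y0 s + η(λ) γ̇

so the shear component relaxes toward a structure-weighted yield stress plus
the viscous stress, and σ_xx is driven convectively by σ_yx γ̇, giving a
nonzero first normal stress difference N1 = σ_xx − σ_yy in steady shear
(N1 = 2τ(λ_ss) σ_yx γ̇ at the fixed point). The yy/zz equations are
homogeneous: from the natural initial condition σ_yy = σ_zz = 0 they remain
zero, and the yx equation then coincides exactly with the scalar form — this
equivalence is verified to 1e-8 in the tests. Note the convective coupling
carries coefficient 2 on both σ_yx γ̇ and σ_yy γ̇ terms; with σ_yy ≡ 0 the
latter never acts.

The nine constants split into two fixed exponents (d = 1/2, m = 3/2,
literature reference values for blood), five constants identified by
steady-state behaviour (t_r1 [s], t_r2 [s^d], σ_y0 [Pa], η_ST [Pa·s],
η_∞ [Pa·s]) and two by transient behaviour (τ_λ [s], G [Pa]).

**Yield-term direction.** A direction-less yield term λσ_y0 breaks the odd
symmetry σ(−γ̇) = −σ(t) that oscillatory shear demands. The yield term is
therefore multiplied by s = sign(γ̇) (s = 0 at γ̇ = 0), which restores odd
symmetry of the alternance waveform to solver precision; `yield_sign="none"`
retains the unsigned form for comparison. An alternative, s = sign(σ_yx)
(kinematic-hardening style), is not implemented; for the unidirectional
protocols the two coincide.

**Representative parameter set.** The default "blood-like" values
(t_r1 = 2.5 s, t_r2 = 1.2 s^½, σ_y0 = 8 mPa, η_ST = 20 mPa·s,
η_∞ = 4.8 mPa·s, τ_λ = 7 s, G = 0.35 Pa) sit in the ranges healthy whole
blood occupies at 37 °C: a yield stress of a few millipascal, a
solvent-limit viscosity near 5 mPa·s, an elastic modulus well below 1 Pa,
and rouleaux kinetics of a few seconds. They are the planted truth of the
synthetic campaign and the operating point of all headline computations.

## Numerical integration

The coupled (λ, stress) system is integrated with Radau (implicit,
stiffness-capable; rtol 1e-8, atol 1e-10 by default). Integration restarts
at every protocol segment boundary, and within LAOS segments also at the
analytically known zero crossings of γ̇, where the signed yield term is
discontinuous — an implicit solver stepping across an interior discontinuity
would otherwise lose local accuracy. λ is clipped to [0, 1] only as a guard
when assembling output; a clip beyond 1e-9 raises a warning because the
kinetics themselves cannot leave the interval (the rate is ≥ 0 at λ = 0 and
≤ 0 at λ = 1) — any excursion is solver error, not model behaviour.

Initial conditions default to the constant-shear fixed point of the
preshear (λ = λ_ss(γ̇_pre), stresses at their steady values, σ_yy = σ_zz = 0).
Integrating the 30 s preshear explicitly instead changes subsequent
predictions by < 1e-4 relative (tested); protocols without preshear start
from rest (λ = 1, zero stress). Oscillatory segments are preceded by 10
discarded warm-up periods (configurable) so the recorded three periods sit
at steady alternance; period-to-period drift is then below 1e-6 of the
waveform norm.

## Harmonic analysis

Stress waveforms are decomposed on the odd {sin nωt, cos nωt} basis by
linear least squares, which is exact on noiseless data (coefficients
recovered to 1e-10) and tolerant of non-uniform sampling; an FFT path for
uniform integer-period grids agrees to 1e-8 and serves as an internal
cross-check. The truncation default n_max = 11 captures ≥ 99.9% of the
stress variance for smooth model output at the study conditions. For
UD-LAOS the drift-free oscillatory stress is decomposed the same way and
I3/I1 is reported on it (flagged in the spectrum metadata); even harmonics
can be retained as diagnostics. Moduli follow from dividing the regression
coefficients by γ0; I3/I1 = √((G′3² + G″3²)/(G′1² + G″1²)). Sweeps default
to ω = 12.566 rad/s (amplitude) and γ0 = 10 (frequency), with 200 samples
per period and sweep grids chosen to keep γ0ω below the 1000 s⁻¹ instrument
ceiling.

## Cost functions and information criteria

The steady-state cost is relative, (1/N)√Σ((y−f)/y)², making it scale-free;
the transient cost averages per-tier absolute RMS-style terms
(1/M)Σ(1/N)√Σ(y−f)²; LAOS waveforms are scored by (1/N)√Σ(y−f)² over three
periods and sweeps by the mean absolute moduli error Σ(|ΔG′|+|ΔG″|)/(2n).
The residual sum feeding the information criteria is the L1 norm Σ|y−f|,
and the criteria are AIC = 2k + 2 ln RSS and BIC = 2k ln n + 2 ln RSS.
These latter three differ from the most common textbook forms (quadratic
RSS; k ln n BIC penalty); the package treats the forms above as canonical
and exposes `squared`/`standard` switches for the conventional variants.
Under either convention, at equal residual the 9-constant model beats a
13-constant competitor (ΔAIC = −8 as printed).

## Parameter estimation

The seven free constants are fit simultaneously to one flow curve and six
step tiers by minimizing F_ss + F_trans (unit weight by default,
configurable). The optimizer is parallel tempering: 8 Metropolis chains on
a geometric temperature ladder (1 → 50), Gaussian proposals, swaps between
adjacent temperatures every 10 steps, 5000 steps per chain, mandatory seed.
Three implementation choices matter:

- **Log-space proposals.** The default bounds span three to seven decades
  per parameter, so proposals are taken in log10 coordinates (5% of the
  log-span, scaled by √T per chain); linear-span steps cannot resolve
  parameters near the low end of their range.
- **Scale-anchored ladder.** The dimensionless ladder is multiplied by the
  best energy found so far (re-anchored at swap intervals). Without this,
  an objective of magnitude ~1e-3 makes every chain accept ~100% of moves
  and the sampler degenerates into parallel random walks.
- **Multi-start polish.** After sampling, a deterministic Nelder–Mead
  refinement runs from each chain's personal best; chains trapped in
  different basins act as a multi-start for the local search.

Inside the optimizer loop the step-tier prediction uses the model's
structure at constant rate: λ(t) is the exact exponential relaxation and the
stress equation, linear in σ, is advanced by an exponential midpoint
integrator on the data grid. This evaluator deviates from the Radau
reference by at most ~2e-3 relative (far below the 2% measurement noise) at
a fraction of the cost; the full ODE solver remains the truth path for data
generation and all reported predictions.

**Identifiability.** The data constrain the structure-kinetics block
{t_r1, t_r2, η_ST, τ_λ} only as strong combinations: at the optimum their
pairwise Fisher correlations (log-parameter space, multiplicative-noise
weighting with a MAD-estimated level) reach 0.88–0.97, while {σ_y0, η_∞, G}
stay below 0.7. Parameters in a pair with |ρ| ≥ 0.85 are flagged "weakly
identified" and a warning is emitted with the fit. Practically: on 2%-noise
synthetic campaigns the optimizer reaches a cost at or below the planted
truth's, {σ_y0, η_∞, G} come back within a few percent, and the flagged
block can drift 10–35% along its sloppy valley without the fit quality
distinguishing the alternatives. Point estimates of the flagged constants
should be interpreted jointly (e.g., via λ_ss and the relaxation rate they
imply), not individually.

## Synthetic campaign

The generator emulates the full strain-controlled experiment suite with a
planted parameter set: a 30-point log-spaced flow curve over 0.01–1000 s⁻¹;
six step tiers (5 → 2.5, 1, 0.5 and 0.25 → 1, 2.5, 5 s⁻¹) sampled at 100
log-spaced times over 0.01–30 s (log sampling is the instrument convention
for step transients and is what renders the elastic time η/G visible);
three recorded periods of LAOS and UD-LAOS at ω = 1 rad/s, γ0 = 10; and
optional amplitude (ω = 12.566 rad/s) and frequency (γ0 = 10) sweeps.
Noise is y → y(1 + 0.02 ε₁) + 10⁻⁵ Pa ε₂ (multiplicative torque noise with
a small additive floor), applied to stress and moduli observables only —
never to time, shear rate, or sweep abscissae — with a mandatory seed.
Point counts and plateau durations are desk-scale conventions recorded in
the bundle manifest.

What passing recovery tests on these data do **not** show about real
experiments: the generator draws from the same model family that is fitted
(no model misspecification), noise is uncorrelated and homoscedastic in
relative terms (real torque noise is neither, especially near the
transducer floor at low rates), and instrument artefacts — inertia, gap
loading, slip, sedimentation, evaporation — are absent. Donor blood-panel
metadata (hematocrit, fibrinogen, lipids) are carried as labels only; the
model takes no physiological covariates.

## Known limitations

- Simple shear only: no extensional kinematics, no spatially resolved
  (gap-dependent) flow, no inertia or secondary Couette flows.
- No temperature dependence or wall slip.
- The comparison-model registry ships parameter counts only for the
  13-constant competitor; its evaluator is a plugin slot.
- Uncertainty reporting is limited to the linearized identifiability
  diagnostic; no posterior sampling.
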