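# Methods

## Constitutive model

The plantar aponeurosis is modelled as an incompressible ground matrix
reinforced by a single collagen-fiber family aligned with the loading
(proximal–distal) axis. With `C = FᵀF`, `J = det F`, and the modified
invariants `Ĩ₁ = tr C̃`, `Ĩ₄ = C̃:(M⊗M)` of `C̃ = J^(−2/3)C`, the strain
energy density is

    W = U_mat(J) + (μ/2)(Ĩ₁ − 3)
        + (k/(2α)) [exp(α⟨Ĩ₄ − 1⟩) − α⟨Ĩ₄ − 1⟩ − 1]

where `⟨x⟩ = max(x, 0)` is the tension switch: fibers carry load only
when stretched. The fiber term is written so that both the energy and
its `Ĩ₄`-derivative, `(k/2)[exp(α⟨Ĩ₄−1⟩) − 1]`, vanish at `Ĩ₄ = 1`; the
reference state is therefore stress free and fibers engage with
continuous stress (the tangent stiffness has a finite kink at λ = 1,
which is physical for a fiber-recruitment model).

Incompressibility is enforced exactly rather than penalized: on the
uniaxial path `λ_t = λ^(−1/2)` (transverse symmetry), and the
hydrostatic variable `p` of `U_mat` is eliminated analytically by the
zero-transverse-stress condition, giving the closed-form axial Cauchy
stress

    σ(λ) = μ(λ² − 1/λ) + k λ² [exp(α⟨λ² − 1⟩) − 1].

Nominal and second Piola–Kirchhoff values follow from `σ = λ S_nom =
λ² S_pk2` at `J = 1`. The correctness anchor is a central
finite-difference of the energy along the constrained path,
`σ = λ dŴ/dλ`, which the closed form matches to 1e-6 relative over
randomized parameter sets (property-tested).

### Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| μ | ground-matrix shear stiffness at small strain | MPa | 14.449 |
| k | fiber stiffness scale | MPa | 254.02 |
| α | fiber strain-stiffening exponent | — | 10.397 |

The defaults are the tensile-fit values for human plantar aponeurosis
used throughout the package (`PAPER_HYPERELASTIC`). Note that with
this fiber-term normalization they imply a rather stiff response
(~750 MPa Cauchy stress at 6% strain); every quantity this package
reports (relaxation ratios, secant-modulus *ratios*, deficit
percentages) is invariant to the elastic scale, so the analysis is
insensitive to this.

## Quasi-linear viscoelasticity

The time-dependent axial second-PK stress is

    S(t) = S_e(λ(t)) − Σᵢ Qᵢ(t),
    dQᵢ/dt + Qᵢ/τᵢ = (γᵢ/τᵢ) S_e(λ(t)),   Qᵢ(−∞) = 0,

with relative stiffnesses `γᵢ ∈ (0,1]`, `Σγᵢ ≤ 1`, and relaxation
times `τᵢ > 0` (a Prony series). On the uniaxial path the tensorial
deviatoric bookkeeping (`DEV[2∂W/∂C]` driving the branches, with the
lateral-zero condition re-imposed on the total stress) reduces to this
scalar form: the lateral components of the deviatoric overstress are
proportional to the axial one, so re-solving the hydrostatic term
rescales the branch contribution by a constant factor that is absorbed
into `γᵢ`. Holds, ramps, and the relaxation ratio are unchanged by
this reduction; it is exact for the observables this package computes.

For a constant-strain hold the equations integrate in closed form to
the reduced relaxation function

    R(t) = S(t)/S(0) = 1 − Σᵢ γᵢ (1 − e^(−t/τᵢ)),

independent of strain level — the quasi-linearity that the
strain-level ANOVA tests on data.

### Time integration

Arbitrary strain histories use the recursive exponential update over a
step `[tₙ, tₙ₊₁]`, `x = Δt/τᵢ`:

    Qᵢⁿ⁺¹ = e^(−x) Qᵢⁿ + γᵢ [ S_eⁿ (1 − e^(−x))
            + (S_eⁿ⁺¹ − S_eⁿ)(1 − (1 − e^(−x))/x) ]

which is the *exact* solution of the evolution equation for a
piecewise-linear elastic drive. Consequences used throughout:

- for step holds the integrator reproduces the closed form to machine
  precision at any Δt (the drive is piecewise constant);
- the grid may be non-uniform with no loss of accuracy, so ramps are
  resolved finely (default: duration/500) and 240 s holds sampled on a
  log grid (default: 25 points/decade from 0.01 s, plus the reporting
  instants 0.1/6/72/240 s) without paying for 10⁴ uniform steps;
- for curved drives the error is O(Δt²) from drive linearization; the
  convergence test observes error ratios ≥ 1.8 per halving.

The virgin state (`Qᵢ = 0` at the start) encodes causality; a nonzero
strain at t = 0 is an instantaneous step applied to virgin material.

### Fitted viscous parameters

The packaged branch sets (`FITTED_PRONY_BY_M`) come from the
relaxation characterization; the working three-branch set is
γ = (0.19, 0.11, 0.12), τ = (1.00, 7.02, 75.21) s — short-, medium-
and long-term processes roughly one decade apart. Its headline
consequences, recomputed by `scripts/acceptance.py`: residual stress
R(240 s) ≈ 58.5%, terminal decay rate ≈ 0.0066 %/s, ramp-viscosity
deficit ≈ 0.49% for the 0.067 s ramp to 8%, and a ≈ 24% secant-modulus
difference between 0.006/s and 0.24/s ramps to 6%.

## Fitting

Traces are normalized to the stress at the first recorded hold sample
(0.01 s by default — experiments cannot sample t = 0), pooled into a
mean ratio `R_exp(t)`, and scored by

    χ = √[(1/N) Σᵢ (1 − R_exp(tᵢ)/R(η, tᵢ))²]

at N = 40 log-spaced instants in [0.05, 240] s (uniform coverage of
each relaxation decade). Because the data are referenced to 0.01 s,
the model ratio in χ is referenced to the same instant,
`R(t)/R(t_ref)`; without this the comparison carries a ~0.2%
systematic bias that dominates noiseless fits. The residual is a
*ratio*, as stated, which weights late times more heavily than an
absolute residual would — appropriate for multiplicative measurement
noise.

The minimizer is stochastic–deterministic: a seeded simulated
annealing stage (1500 proposals, geometric cooling; τ proposed on the
log scale within [10⁻², 10³] s, γ projected onto the simplex
{γᵢ ≥ 0, Σγᵢ ≤ 1}; three independent restarts, one seeded from a warm
start when given) followed by Nelder–Mead refinement of each
candidate. Branches are returned sorted by ascending τ, resolving
label switching. The whole procedure is bit-reproducible given the
seed. Fitting the loading ramp is deliberately omitted (the hold is
treated as a step): at 120%/s the viscous development during the ramp
is below 0.5% of the stress, which the generator's true-ramp mode
makes directly testable.

Branch-count selection fits m = 1..4, warm-starting each fit from the
previous optimum plus one negligible branch so χ is non-increasing in
m, and recommends the smallest m that is either essentially exact
(χ ≤ 1e-4 — at that level further branches fit numerical residue, and
a relative-improvement rule would be meaningless) or whose successor
improves χ by less than 5% relative.

### Identifiability under noise

Multi-exponential fitting is notoriously ill-conditioned. At the
noise levels of interest the χ valley is long and curved: with iid
multiplicative noise of cv 0.05 per time sample on 8 traces, the
Cramér–Rao bound already gives sd(γ₁) ≈ 0.025 and a 41% relative sd
on τ₂, and the nonlinearity inflates the realized scatter of the
χ-minimizer beyond that. Between-sample variability of the *smooth*
biological kind (the dominant source in real relaxation data, modelled
here as multiplicative γ scatter) is far more benign: the pooled mean
trace remains an exact Prony curve, and recovery of the population
parameters is essentially limited only by the sample mean of the
scatter. The recovery tests therefore exercise the latter regime at
the observed 0.05 SD level of normalized stress; per-point white noise
at the same magnitude degrades τ identifiability fundamentally, not
through any defect of the optimizer.

## Statistics

`summarize` reports mean and sample SD (n−1) of normalized stress per
strain level at the reporting instants, interpolated linearly on the
sampling grid. `anova_by_strain` computes the classical one-way F
statistic from between/within sums of squares (implemented directly;
cross-checked against `scipy.stats.f_oneway` in the tests) with
p-values from the F distribution at significance 0.05. Donors are
pooled by default; a donor filter is exposed. On model-generated data
the expected outcome at every instant is non-significance, since the
model is quasi-linear by construction; the type-I error simulation
confirms the test rejects at its nominal rate on null data.

## Synthetic experiments

The generator emulates the study design: 3 donors contributing 7, 8
and 9 strips (24 samples); strips ~5 mm wide, donor-mean thicknesses
2.40/2.41/2.57 mm, 10 mm gauge length; three consecutive relaxation
tests per sample at 4/6/8% nominal strain, ramped at 120%/s and held
240 s, with full viscous recovery between tests (consecutive tests are
independent).

Noise model and defaults:

| source | mechanism | default |
|---|---|---|
| between-sample | log-normal γᵢ scatter, re-projected to Σγ ≤ 1 | sd 0.15 (log) |
| geometry | log-normal width/thickness scatter | cv 0.05 |
| measurement | multiplicative Gaussian per stress sample | cv 0.03 |
| force quantization | rounding to load-cell resolution | 0.2 N |
| displacement quantization | rounding of commanded elongation | 0.001 mm |

Between-sample variability enters through γ (relaxation-*shape*
scatter) rather than τ, because the observed cross-sample SDs are on
normalized stress; τ scatter is available but off by default. The
defaults put the summary-table SDs in [0.02, 0.09], bracketing the
0.03–0.07 range seen in real data (checked in the tests). Stress is
converted to force through the strip cross-section before quantization
and back after, so the machine resolutions act where they physically
do (their effect is negligible at these stress levels).

What the generator does *not* emulate: preconditioning memory, grip or
hydration artifacts, damage, early-time processes faster than ~0.01 s,
and donor-level systematic differences (donors differ only in geometry
means). Passing recovery tests on generated data therefore show the
pipeline is correct and well-conditioned for Prony-type relaxation
with these noise structures — not that real tissue obeys the model;
notably, real data show more early-time (≤ 0.1 s) relaxation than the
fitted three-branch model reproduces, and the generator follows the
model, leaving that discrepancy visible.

## Numerical choices and degenerate inputs

- Tolerances: χ local stage runs Nelder–Mead to xatol = fatol = 1e-12
  (capped at 2·10⁴ evaluations); noiseless recovery lands at χ ≈ 3e-5,
  limited by linear interpolation of the trace onto the eval grid.
- γ projection floor 1e-6 keeps branches strictly positive during the
  search; τ positivity is by log-parameterization.
- `m = 0` is supported everywhere and means purely elastic.
- Equal τ values are allowed (the model is then over-parameterized but
  valid); branches are stably sorted by τ.
- Degenerate inputs raise: non-positive stretch, negative time,
  non-monotone grids, zero initial stress in normalization, ANOVA
  groups with fewer than two observations.
- Secant moduli interpolate on the monotone loading branch only;
  decay rates use the local gradient of the normalized trace and
  require at least one earlier sample.

## Problem sizes

Defaults were chosen so a full analysis is interactive on one core:
holds sampled at ~117 points over 4.4 decades, ramps at 500 steps,
fits ~10⁴ function evaluations (~0.5 s each), the recovery study 50
replicates × 8 traces, and the type-I simulation 200 replicates of the
24-sample protocol (closed-form step mode).
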