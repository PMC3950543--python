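# plantarvisc

Viscohyperelastic characterization of human plantar aponeurosis — the
collagen-rich sheet that supports the longitudinal foot arch and is
loaded proximal–distally during gait. The package is for tissue
biomechanists who run stress-relaxation tests on aponeurotic or
tendinous strips and want a tested pipeline from raw time–stress
tables to fitted viscoelastic parameters, and for modellers who need
the calibrated material law for foot simulations.

## The model

The tissue is a transversely isotropic fiber-reinforced hyperelastic
solid with quasi-linear viscoelasticity (QLV). Elasticity, with
modified invariants Ĩ₁, Ĩ₄ of the isochoric Cauchy–Green tensor and
fibers along the loading axis:

    W = U_mat(J) + (μ/2)(Ĩ₁ − 3) + (k/2α)[exp(α⟨Ĩ₄−1⟩) − α⟨Ĩ₄−1⟩ − 1]

Under incompressible uniaxial tension this gives the closed-form axial
Cauchy stress σ(λ) = μ(λ² − 1/λ) + kλ²[exp(α⟨λ²−1⟩) − 1]. Time
dependence enters through viscous internal stresses Qᵢ,

    S(t) = S_e(λ(t)) − Σᵢ Qᵢ,   Q̇ᵢ + Qᵢ/τᵢ = (γᵢ/τᵢ) S_e,

so a constant-strain hold relaxes by the Prony reduced relaxation
function R(t) = 1 − Σᵢ γᵢ(1 − e^(−t/τᵢ)), independent of strain level.
The package provides the stress solvers (closed-form holds, exact
exponential integration of arbitrary strain histories), a
stochastic–deterministic Prony fit minimizing the relative-residual
error χ with branch-count selection, strain-level ANOVA of the
normalized relaxation, and a seeded generator of virtual experiments
(24 samples, 3 donors, 4/6/8% strain, 120%/s ramps, 240 s holds) so
every stage is testable without laboratory data. See
`docs/methods.md` for the full account.

## Worked example

Simulate the full virtual protocol, fit three viscous branches to all
72 traces, and test strain-level dependence:

```python
from plantarvisc import (PAPER_HYPERELASTIC, FITTED_PRONY_3, FitConfig,
                         Protocol, anova_by_strain, fit_prony,
                         generate_population, simulate_experiment, summarize)

pop = generate_population(PAPER_HYPERELASTIC, FITTED_PRONY_3, seed=1)
ds = simulate_experiment(pop, Protocol(), seed=2)   # 72 traces (24 x 3 strains)

res = fit_prony(ds.traces, FitConfig(m=3, seed=42))
print(res.chi)                    # 0.0031
print(res.prony.gammas.round(3))  # [0.19  0.098 0.126]
print(res.prony.taus.round(2))    # [ 1.12  8.37 75.9 ]

print(summarize(ds.traces).formatted())
#             0.1          6.0          72.0         240.0
# 0.04  0.99 (0.05)  0.76 (0.04)  0.64 (0.04)   0.6 (0.04)
# 0.06  0.99 (0.04)  0.75 (0.03)  0.64 (0.02)  0.59 (0.03)
# 0.08  0.99 (0.05)  0.75 (0.04)  0.64 (0.03)  0.59 (0.03)

a = anova_by_strain(ds.traces, 240.0)
print(f"F({a.df_between},{a.df_within}) = {a.f_stat:.2f}, p = {a.p_value:.3f}")
# F(2,69) = 0.60, p = 0.550
```

The fit recovers the generating branches — γ within a few hundredths
and τ within ~20% despite per-sample scatter and measurement noise —
and χ ≈ 0.003 is the pooled noise floor. The summary table shows the
relaxation ratio falling to ≈ 0.59 after 240 s with no systematic
strain-level trend, and the ANOVA confirms non-significance (p ≫ 0.05)
at every instant: the normalized relaxation is strain-independent,
the defining property of QLV.

Rate-dependent stiffness from the same material:

```python
from plantarvisc import ramp_curve, secant_modulus
slow = secant_modulus(ramp_curve(PAPER_HYPERELASTIC, FITTED_PRONY_3, 0.006, 0.06), 0.06)
fast = secant_modulus(ramp_curve(PAPER_HYPERELASTIC, FITTED_PRONY_3, 0.24,  0.06), 0.06)
print(f"{slow:.0f} vs {fast:.0f} MPa: +{100*(fast-slow)/slow:.1f}%")
# 9888 vs 12246 MPa: +23.8%
```

The same pipeline is available from the shell:

```sh
plantarvisc simulate --seed 4 --out dataset/
plantarvisc fit --input dataset/ --branches 3 --seed 42 --out fit.json
plantarvisc select-model --input dataset/ --min 1 --max 4 --out selection.json
plantarvisc summarize --input dataset/ --out table.csv
plantarvisc predict-ramp --rates 0.006,0.012,0.024,0.24 --to 0.06 --out ramps/
```

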