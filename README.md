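# shearfold

Coarse-grained simulation and analysis of shear- and force-induced protein
unfolding, built around the biology of von Willebrand factor (vWf): the A2
domain hides the Tyr1605–Met1606 scissile bond that the protease ADAMTS13
can only cut once flow forces unfold the domain and expose it.  The package
is aimed at molecular-modelling researchers who want a desk-scale,
fully-testable reimplementation of that pipeline: bead–spring models of the
A1-L12-A2-L23-A3 construct, Langevin dynamics coupled to an imposed Couette
flow, burial/contact observables, and censored maximum-likelihood
first-passage kinetics.

## What it computes

**Models** (`shearfold.model`): elastic-network domains (springs between all
native pairs within a 6 Å cutoff, k = 5 kcal mol⁻¹ Å⁻²), one-bead-per-residue
linkers (r₀ = 3.8 Å, k_b = 149 kcal mol⁻¹ Å⁻², θ₀ = 110°, hydrophobic/polar
non-bonded classes), a structure-based (Gō-like) flexible representation
with breakable 12-10 native wells, and the native backbone O···HN hydrogen
bond catalogue (3 Å cutoff) labelled by β-strand pair.

**Dynamics** (`shearfold.dynamics`): BAOAB Langevin integration with a
Stokes-like drag toward the local fluid velocity,

    m dv/dt = F_C − γ (v − u(x)) + F_R,    u = (γ̇ (z − z_ref), 0, 0),

constant-force pulling protocols and free shear runs, deterministic for a
given seed.

**Observables** (`shearfold.observables`): coordination number of the
cleavage-site residue (backbone atoms within 10 Å; exposure below a
threshold), smooth native-contact counts

    C(t) = Σ_contacts 1 / (1 + exp{a (d(t) − d_ref)}),   a = 0.5 Å⁻¹,

end-to-end distances, and the moving-averaged tensile force
f̄ = ⟨k (d(t) − d₀)⟩_τw on instrumented terminal bonds (69.48 pN per
kcal mol⁻¹ Å⁻¹).

**Kinetics** (`shearfold.kinetics`): right-censored maximum likelihood for
two first-passage models — the exponential law f(τ; k) = k e^{−kτ} with
Bell's force dependence k = k₀ e^{βFδx}, and the inverse Gaussian law

    f(τ; μ, λ) = sqrt(λ / 2πτ³) exp(−λ(τ − μ)² / (2μ²τ)),

the first-passage distribution of Brownian motion with drift (μ = α/ν,
λ = α²/σ²), fitted with a single λ shared across force conditions.

**Rotation** (`shearfold.rotation`): orientational time correlation
functions c(τ) = ⟨R̂(t+τ)·R̂(t)⟩ of inter-domain vectors, their first zero
crossing, angular velocities in the shear plane, the field rotational
period Tr = 4π/γ̇, and collapse/extension scans versus shear rate.

**Synthetic data** (`shearfold.synthetic`): seed-deterministic generators
for everything the tests need without downloads — censored exponential and
inverse Gaussian samples, a Brownian-drift first-passage oracle, a rigid
dumbbell tumbling probe, a β-hairpin PDB, a four-strand β-sheet with a
buried cleavage-site bead, and three-blob multi-domain constructs.

## Worked example

```python
import shearfold as sf
from shearfold.synthetic import make_toy_sheet, pull_toy_sheet

sheet = make_toy_sheet(seed=0)
obs, cens = [], []
for rep in range(6):
    traj = pull_toy_sheet(sheet, force_pN=600.0, seed=rep)
    status, t_ns = sf.exposure_time(traj, sheet.model, sheet.criterion)
    (obs if status == "unfolded" else cens).append(t_ns)

ds = sf.FirstPassageDataset(600.0, obs, censored=cens)
fit = sf.fit_exponential(ds)
print(f"k = {fit.params['k']:.3f} ns^-1, mean exposure time "
      f"{1 / fit.params['k']:.4f} ns ({ds.n_censored} censored)")
```

prints

```
k = 15.083 ns^-1, mean exposure time 0.0663 ns (0 censored)
```

i.e. at 600 pN all six replicas expose the buried site, with a mean first
exposure time of 0.066 ns under the toy sheet's calibrated burial
criterion.  The same loop at lower forces yields longer times and censored
runs, which the censored-likelihood fits absorb; `shearfold demo` (or
`shearfold.synthetic.demo_pipeline`) runs the full three-force version and
also reports the joint inverse Gaussian and Bell fits.

The command-line entry point `shearfold` exposes the pipeline stages
(`build`, `assemble`, `simulate-pull`, `simulate-shear`, `analyze-exposure`,
`analyze-rotation`, `fit-kinetics`, `synth`, `demo`); see `--help`.

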