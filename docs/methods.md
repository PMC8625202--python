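# Methods

This note documents the models, numerical choices and study conditions
behind `shearfold`, and states what the synthetic fixtures do and do not
establish about real proteins.

## The physical problem

Von Willebrand factor's A2 domain buries the Tyr1605–Met1606 scissile bond
(local residues 111–112 counting from the A2 N-terminus) inside a
six-stranded β-sheet core.  ADAMTS13 can cleave it only after mechanical
unfolding — by direct tension or by the elongational component of a shear
flow acting on the A1A2A3 construct — exposes first the recognition
residues (local 118/120 plus ~25 Å of C-terminal chain) and then the
cleavage site.  The package models this at bead–spring resolution and
treats exposure as a first-passage problem with right censoring.

## Coarse-grained models

* **Elastic networks** (stable domains, A1/A3): every pair of sites closer
  than a cutoff (default 6 Å) in the reference structure is joined by a
  harmonic spring at its native length with k = 5 kcal mol⁻¹ Å⁻².  The
  native configuration is, by construction, the exact global minimum.
* **Linkers** (one bead per residue): bonds r₀ = 3.8 Å,
  k_b = 149 kcal mol⁻¹ Å⁻²; angles θ₀ = 110°,
  k_θ = 1.5 × 10⁻³ kcal mol⁻¹ deg⁻² (the angle energy is
  ½k_θ(θ − θ₀)² with θ in degrees — the magnitude of the constant is only
  sensible per squared degree); torsions φ₀ = 180°, n = 2,
  k_φ = 1 kcal mol⁻¹.  Non-bonded interactions use a two-class
  hydrophobic/polar table (hydrophobic = positive Kyte–Doolittle
  hydropathy: Ala, Val, Leu, Ile, Met, Phe, Cys) with 12-6 wells of
  0.5 kcal/mol (HH) and 0.2 kcal/mol (PP/HP) at a 6 Å contact distance.
  These well depths are package defaults, chosen once as
  representative short-range attraction strengths; no published table
  exists for this reduced representation.
* **Structure-based (Gō-like) flexible domains**: bonds/angles/torsions at
  the native geometry plus attractive 12-10 wells for every bead pair at
  least 3 residues apart and closer than 6.5 Å.  The well depth (default
  0.35–0.5 kcal/mol) is the single stability knob; it is calibrated so
  that unfolding under several hundred pN completes within ~10⁵ steps.
  This stands in for a transferable flexible force field: it preserves
  the observables (native contacts, exposure, unfolding order) at desk
  scale but has no sequence-specific energetics.
* **Construct assembly**: segments A1-L12-A2-L23-A3 are chained along +x.
  The two bonds joining the central domain's termini to the linker ends
  are instrumented for the tensile-force readout f̄ = ⟨k(d(t) − d₀)⟩_τw
  (centered boxcar, default window 2.1 ns, truncated at series edges).
  Junction equilibrium lengths default to the assembled distance so the
  initial state is unstressed.  The default construct carries 37- and
  15-residue linkers; their amino-acid sequences are placeholders of the
  correct lengths and are configurable.

## Dynamics

Langevin dynamics with a BAOAB splitting: half-kick, half-drift, an exact
Ornstein–Uhlenbeck friction/noise step, half-drift, half-kick.  The OU step
relaxes velocities toward the *local fluid velocity* u(x) of an imposed
Couette profile u_x = γ̇ (z − z_ref), which implements the Stokes-like drag
F = −γ(v − u) with exact fluctuation–dissipation at any γ and reduces to
pure exponential relaxation at T = 0.  The fluid velocity is evaluated at
the bead centre; coupling is one-way (the protein does not perturb the
flow) — resolving the back-reaction requires a lattice fluid solver and is
out of scope.  Non-bonded forces may be refreshed on a slower clock
(defaults 3 fs bonded / 9 fs non-bonded).

Units: Å, fs, amu, kcal/mol; 1 kcal mol⁻¹ Å⁻¹ = 69.48 pN; shear rates are
quoted in s⁻¹ and converted by 10⁻¹⁵.  γ defaults to the Stokes value
6πηr ≈ 2.5 amu/fs (r = 2.5 Å in water) for shear runs; for the toy
unfolding runs a smaller γ = 0.3 amu/fs is used — the drag coefficient is
an adjustable parameter of the coupling scheme, and the smaller value
keeps chain transport fast enough for desk-scale runs while remaining
strongly overdamped.

**Tumbling and the weak-coupling regime.**  The field rotational period of
a Couette flow is Tr = 4π/γ̇ (vorticity γ̇/2).  A two-bead rod with
isotropic point drag does *not* tumble at T = 0 in the overdamped limit:
it obeys θ̇ = −γ̇ sin²θ (the infinite-aspect-ratio Jeffery orbit) and
parks flow-aligned.  The dumbbell probe therefore runs in the
weak-coupling regime (γ/m = 0.02 γ̇) and is started on the steady tumbling
orbit (rigid rotation at γ̇/2); angular momentum then carries it through
the aligned orientation and the measured period matches Tr to ~1.5%.
For the deformable three-blob construct the TCF analysis instead uses the
overdamped sweep: a construct tilted at 135° to the flow sweeps toward
alignment on a timescale ∝ 1/γ̇, so first-zero times of the orientational
TCF scale inversely with shear rate without any tumbling assumption.

## Observables

* **Coordination number**: count of backbone sites (excluding the site's
  own residue) strictly within r_c = 10 Å of any site atom.  The
  atomistic convention counts backbone heavy atoms with an exposure
  threshold of 50; in the coarse-grained representation there are ~4×
  fewer backbone sites, so the threshold is re-calibrated per fixture:
  the toy builders set it midway between the native and the fully
  extended coordination of the buried site and assert that both sides
  clear it.  Exposure time is the first frame below threshold; otherwise
  the run is right-censored at its final time.
* **Native H-bond contacts**: catalogued from reference O···HN pairs
  within 3 Å (donor and acceptor at least 2 residues apart), evaluated
  per frame through the logistic switch with a = 0.5 Å⁻¹.  A contact at
  its native distance contributes exactly ½, so the *initial* value — not
  the catalogue size — is the natural reference for "half-maximum lost".
  Amide hydrogens missing from atomistic inputs can be rebuilt by the
  standard planar construction from N, Cα and the preceding carbonyl C.
* **Orientational TCF**: unit inter-domain COM vectors (normalization
  makes c(0) = 1 and the zero crossing scale-free); all overlapping time
  origins are averaged; the first zero is linearly interpolated between
  bracketing lags and reported as censored if absent within the maximum
  lag.  Angular velocity is the unsigned |ΔR̂|/Δt projected on the
  flow–gradient (XZ) plane.
* **Collapse scan**: per-trajectory time-averaged inter-domain distances,
  pooled per shear rate; the lowest scanned rate defines the collapsed
  baseline and a rate is classified extended/cyclic when a distance
  exceeds the baseline by ≥ 50% (configurable margin; no standard numeric
  criterion exists).

## First-passage kinetics

The censored likelihood L(θ) = Π f(τ_i; θ) · Π S(τ_j^c; θ) is maximized:

* exponential model — closed form k̂ = N/(Στ_i + Στ_j^c), the inverse of
  the censoring-corrected mean first unfolding time; a numeric
  score-root route is kept as an independent cross-check.  Bell's law
  k = k₀e^{βFδx} is fitted log-linearly with R² reported, so
  drift-diffusion-generated rate sets are visibly non-exponential.
* inverse Gaussian model — density and survival implemented in closed
  form (the survival's e^{2λ/μ}Φ(·) term is computed in log space to
  avoid overflow) and cross-checked against an independent library
  parameterization in the tests.  The joint fit shares one λ across
  conditions with a per-condition μ, optimized in log-parameter space by
  a simplex search with gradient polish and 8 deterministic multi-starts
  seeded from moment estimates.  λ is force-independent by construction:
  it reflects the escape distance and the elementary Brownian step, not
  the drift.  All-censored conditions contribute survival terms only.
  Standard errors (observed information) are reported but not load-bearing.

The Brownian-drift oracle integrates x(t+dt) = x(t) + ν dt + σ√dt ξ from
x = 0 with absorption at α by Euler stepping (default drift per step
α/400), assigning crossings to the midpoint of the crossing step to remove
the half-step recording bias; its sample distribution matches the inverse
Gaussian law with μ = α/ν, λ = α²/σ² by Kolmogorov–Smirnov at the 1%
level at n = 2000.  Residual discrete-monitoring bias (~0.58σ√dt/ν) is
kept well below the KS resolution by the step choice.

## Synthetic fixtures and what they show

The four-strand β-sheet fixture mirrors the topology of the A2 core that
resists unfolding: spatial strand order β1-β4-β5-β6, chain C-terminus on
the short-lived β6 edge, explicit carbonyl-O/amide-H pseudo-atom beads
forming a native H-bond ladder across each interface (d_ref = 2.4 Å), and
a "cleavage-site" bead buried in the middle of the β4-analog strand.
Cross-interface native-well depths are graded (β1β4 : β4β5 : β5β6 =
1.7 : 1.0 : 0.55) to emulate the graded mechanical resistance of the
native sheet, in which the short β6 edge strand unzips first and the
β1β4 core last.  Under strong C-terminal pulling the fixture reproduces
the sequential unzipping order (β5β6 → β4β5 → β1β4 half-drop times) in
≥ 90% of seeded replicas, and mean exposure times decrease strictly with
force.  These are statements about the model class — breakable
native-topology potentials under drag-coupled tension — not about A2's
sequence-specific energetics, glycosylation, or absolute rates; matching
measured unfolding kinetics would require a transferable force field and
orders-of-magnitude longer runs.

Study conditions used by the scaled-down simulation stages (chosen once as
desk-scale conditions): toy pulling at 250/450/700 pN (600 pN for the
unzipping-order statistic, 20 replicas), 25 000–30 000 steps of 6 fs at
300 K with γ = 0.3 amu/fs; dumbbell tumbling at 2 × 10⁹ and 10¹⁰ s⁻¹ at
T = 0; rotational TCF scan of the three-blob construct at 5 × 10⁹ and
5 × 10¹⁰ s⁻¹, T = 0, runs of 1.5 sweep times with 18 fs steps.

## Numerical notes and limitations

* Torsion gradients follow the standard four-site formulas; all force
  routines are validated against central finite differences in the tests.
* Excluded volume is a truncated (σ/r)¹² repulsion between pairs ≥ 3
  residues apart carrying no explicit term; the force is discontinuous at
  the σ cutoff, which is immaterial under damped dynamics at these
  stiffnesses.
* Angle forces floor sin θ at 10⁻⁶ to avoid the collinear singularity;
  collinear triples are transient under noise.
* Distance comparisons for cutoffs/criteria are strict (<); ties are
  measure-zero in floating point.
* Equilibrium-length defaults for assembled junction bonds come from the
  assembled geometry; overriding d₀ introduces deliberate pre-tension.
* The Couette coupling is one-way; hydrodynamic inter-bead correlations,
  walls and finite-box images are not modelled.  The default 800 × 200 ×
  200 Å box is reporting metadata and sets the shear reference plane only.
* Trajectories are deterministic in (model, parameters, seed); all
  samplers take explicit seeds and use independent generator streams.
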