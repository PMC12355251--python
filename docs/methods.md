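# Methods

`hingeflex` analyses how point variants of a hinged multidomain protein
reshape its interdomain dynamics and solution flexibility.  Everything is
exercised on a synthetic hinged-protein model whose statistics are known
in closed form, so every stage of the pipeline can be validated without
molecular-dynamics or scattering data.

## The synthetic hinge model

The toy protein consists of three rigid bead "domains" (default 30 beads
of radius 1.9 Å, sampled once per seed inside an 8 Å blob) connected by
two short hinge segments.  Domain II sits at the origin; domains I and
III ride on two arms of length 30 Å whose in-plane orientation angles are
the system's two degrees of freedom.  The interdomain angle θ — measured
at domain II's centre of mass between the domain-I and domain-III
centres — equals the difference of the arm angles, so a built structure
realises its state's rest angle *exactly* (blob templates are zero-mean).

Rest angles default to 122° for the open state (the compact single-state
angle of the three-domain reference geometry) and 75° for the closed
state, a hub angle chosen once as plausibly compact; hinge stiffnesses
default to κ = 8 kcal/mol/rad² per hinge, which at 310 K gives per-arm
angular fluctuations of ~16° — wide enough to populate distinct basins,
narrow enough that θ rarely folds over the 0°/180° boundaries.

**Dynamics.**  Each arm angle evolves as an independent overdamped
(Brownian) harmonic oscillator integrated with Euler–Maruyama:

    a_{t+1} = a_t − (dt/γ) κ (a_t − a₀) + sqrt(2 k_B T dt/γ) ξ_t

with k_B = 0.0019872 kcal/mol/K throughout.  This is an exact discrete
Ornstein–Uhlenbeck process whose stationary law is Normal(a₀, k_B T/κ)
up to a discretisation factor 1/(1 − βκ/2) with β = dt/γ; the default
mobility β = 1/(100 κ_max) keeps that bias below 0.5% and lets the
stiffest hinge relax over ~100 steps.  Equipartition tests use
β = 1/(25 κ) and 50,000 frames, pooling both hinges, so the Monte-Carlo
error on the sampled variance (~3% by the OU sampling formula
sqrt(2 τ_int/N)) sits far inside the 10% test band; those sizes were
fixed from the error formula, not tuned.

**Variants.**  A `VariantPerturbation` scales hinge stiffnesses, shifts
rest angles, and/or edits residue charges.  The default 13-system panel
(wild type plus 12 named variants) assigns each variant a perturbation
chosen once to mirror its qualitative character — e.g. a charge inversion
of an exposed domain-I lysine analogue, a global 2.5× stiffening, an
opening shift of hinge I–II.  These are synthetic stand-ins: they test
that the pipeline *propagates* generative parameters into its report
surfaces, not that the toy reproduces any real protein's numbers.

**What the generator does not emulate.**  Domains are rigid (no internal
fluctuations, so per-residue RMSF structure inside a domain is flat);
motion is in-plane; there is no solvent, no side-chain chemistry, no
anharmonicity, and SAXS profiles use uniform bead form factors with no
hydration shell or excluded-volume terms.  Passing tests therefore
demonstrate correctness of the estimators and the faithfulness of
parameter propagation — not force-field-level realism.

## Trajectory metrics

* **Superposition** is least-squares rigid (Kabsch); trajectory-scale
  paths use a batched SVD formulation.  RMSD series superpose each frame
  on a chosen selection and measure on another (per-domain RMSD = measure
  on one domain's Cα).
* **RMSF** concatenates replicas after discarding a burn-in (default:
  first 20% of frames), aligns every frame onto the mean structure by a
  fixed two-pass iteration (align → mean → re-align), and reports
  per-residue root-mean-square deviation from the mean.  In the study
  pipeline the superposition is fitted on the hub domain's Cα: with
  equal-mass rigid domains a whole-molecule fit redistributes a swinging
  arm's motion across all regions, whereas a rigid-core fit attributes
  each arm's swing to its own residues — the property the region-wise
  verdict matrix needs.  `rmsf_per_residue` defaults to fitting on all
  analysed atoms; `align_selection` selects the core.
* **Region verdicts** compare variant and WT RMSF region by region with
  a 1 Å threshold: `x` when some residue rises and some falls by at
  least the threshold, `up`/`down` when the regional mean crosses it,
  `~` otherwise.  Symbols are serialised as ASCII (`~`, `x`, `up`,
  `down`).
* **θ** uses Cα centres with equal weights by default (mass weighting is
  a switch).

## Equilibration diagnostics

Coordinate PCA is an SVD of the centred frame matrix (optionally after
mean-structure alignment).  The cosine content of the i-th PC projection
over its first t_f frames is evaluated with time rescaled to [0, 1] and
frequency k = i + 1 (0-based PC indexing):

    cc = 2 (Σ_t cos((i+1)π t/t_f) p(t))² / (t_f Σ_t p(t)²)

as a plain Riemann sum, clipped to [0, 1] against round-off.  The
integral form written without the time normalisation is not scale-free;
rescaling t to the unit interval restores the original diagnostic's
invariance to segment length and units.  A segment is flagged
not-equilibrated when any of the first n components (default 2) exceeds
the customary 0.7 criterion; the progressive scan recomputes the PCA on
each prefix and reports the trend between the two shortest segments.

## Free-energy surfaces and distribution comparison

2-D histograms over the (R_g, θ) collective variables are normalised to
unit mass; compared systems share one binning (default 40×40 over the
pooled data range).  The free energy is the Boltzmann inversion
F = −k_B T ln ρ + F₀ at T = 310 K with F₀ fixing min F = 0; empty bins
are masked (infinite free energy), never set to zero.

Jensen–Shannon divergence uses base-2 logarithms so the range [0, 1] is
exact (identical → 0, disjoint supports → 1), with the 0·log 0 ≡ 0
convention keeping JS(P, P) = 0 without pseudo-counts; a pseudo-count
mode exists for sparse data.  System-by-system JS matrices are clustered
with average linkage; trees are exportable as Newick.

## Charge-weighted SASA estimator

Per-residue solvent-accessible surface area uses the Shrake–Rupley
rolling-probe construction (probe 1.4 Å, 960 sphere points by default,
hydrogens excluded, Bondi-style vdW radii replaceable per structure —
coarse beads carry their own radii).  The binding estimator for a domain
D is

    α = Σ_{r ∈ D} q_r ⟨SASA_r⟩

over whole-residue areas, with formal side-chain charges (+1 LYS/ARG,
−1 ASP/GLU, 0 otherwise — histidine neutral as its majority state at
pH 7, terminal charges ignored because the sum is residue-wise).
Exposed positive residues favour binding to a phosphate backbone and
exposed negative residues disfavour it, so α is a cheap electrostatic
complementarity proxy; it is exactly linear in the charges, and
difference tables report pooled SDs sqrt(SD_v² + SD_wt²).

## SAXS flexibility suite

* **Forward model**: the Debye equation
  I(q) = Σ_ij f_i f_j sin(q r_ij)/(q r_ij) with uniform f = 1 for bead
  models (form factors injectable); I(0) = (Σf)².
* **Guinier analysis** fits ln I vs q² on a low-q window iterated
  self-consistently until q_max ≤ 1/R_g (≤ 20 iterations), returning
  I(0) and R_g; a non-decaying profile is a fit error.
* **Dimensionless Kratky**: (qR_g)² I/I(0) vs qR_g.  An ideal globular
  (Guinier) scatterer peaks at qR_g = √3 with height 3/e ≈ 1.1; flexible
  mixtures plateau above that level.  Coarse grids and still-rising
  transforms at qR_g = 3 produce warnings.
* **P(r)**: pair distances histogrammed with weights f_i f_j (self-pairs
  excluded so P(0) = 0); D_max is the largest pair distance.  R_g from
  P(r) uses the exact (Σf)² normalisation — dividing by the pair mass
  alone would bias R_g² by a factor N/(N−1), visible already at 50
  beads.
* **Conformer pools** rotate domain I about a random axis through the
  hinge-I–II pivot Cα and domain III about the hinge-II–III pivot,
  angles uniform in ±range, rejecting conformers with interdomain Cα
  contacts under 3.5 Å.  Desk-scale pools default to 200 members.
* **Multistate fitting** scores each n-member subset by σ-weighted
  non-negative least squares with a free global scale;
  χ² = (1/M) Σ_q ((I_exp − c Σ w_k I_k)/σ)², and both χ and χ² are
  reported.  Enumeration is exhaustive while C(N, n) ≤ 2·10⁵ (n ≤ 3 on
  200 members) and switches to greedy add-and-swap refinement beyond.
  Pool profiles are linearly interpolated onto the experimental grid;
  σ is never interpolated.  Equal-χ ties break on member indices.

  Weight recovery on noise-free mixtures is exact to solver tolerance.
  With noise the inversion is ill-conditioned: smooth Debye curves are
  nearly collinear, so with a 2% noise floor many subsets of a dense
  pool fit equally well and *member identity* is not recoverable — only
  the weight structure is.  The noisy-recovery tests therefore fit the
  true components on a detector-resolution grid (1000 points to
  q = 0.6 Å⁻¹), where error propagation puts per-weight errors near
  0.01.
* **Domain displacement** superposes two conformers on domain II and
  reports, for domains I and III, the axis-angle magnitude of the
  optimal domain rotation and the centre-of-mass displacement; any
  global rigid motion cancels by construction.

## Study orchestration

`run_study` enumerates variant × state × replica (open before closed; 13
variants × 2 states × 1 replica = 26 systems by default), then per
system: build → Langevin trajectory (default 2000 frames) →
cosine-content scan → burn-in discard → RMSD/R_g/θ series → SASA/α
(SASA strided, default every 20th frame).  Cross-system surfaces:
RMSF verdict matrices per state, shared-binning FES, JS matrices with
dendrograms, the α panel, and multistate fits for a selected variant
subset against synthetic mixture profiles (default weights
0.08/0.77/0.15 over compact/median/extended pool members, 2% noise).

Seeds derive deterministically from the study seed per (state, replica)
and are deliberately shared across variants (common random numbers):
variant-vs-WT comparisons are paired, so a charge-only variant
reproduces WT geometry exactly and mechanical effects are not
confounded with noise realisations.  System failures are recorded and
skipped, never fatal to the study.  Default problem sizes (2000-frame
trajectories, 60-member pools in the SAXS branch, strided SASA) keep a
full 26-system study in the minutes range on one core while leaving
every estimator inside its validated statistical regime.

## Numerical conventions

* k_B = 0.0019872 kcal/mol/K; default temperature 310 K.
* Histogram bins half-open [lo, hi), last bin closed (NumPy).
* PDB coordinates round-trip at the format's 10⁻³ Å precision.
* Degenerate inputs raise typed errors (`FormatError`,
  `StructureError`, `ParameterError`) rather than returning NaNs.
* All stochastic components take explicit integer seeds; same seed ⇒
  bit-identical output.

## Known limitations

Rigid domains mean intra-domain RMSF carries no signal; the hinge model
is planar; the χ score and pool sampler are documented simplifications
of production multistate-fitting tools, so fitted ensembles of real
experimental curves should be read comparatively, not absolutely; and
the SASA engine excludes hydrogens by design, so all-atom inputs with
hydrogens are measured on their heavy atoms only.
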