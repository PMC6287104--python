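# Methods

## Electrostatic model

The solute is a rigid set of atoms with point partial charges q_i (e) and van
der Waals radii r_i (Å). Its potential u(x), in dimensionless kT/e units,
satisfies the linearized Poisson–Boltzmann equation

    div( eps(x) grad u ) − eps_s κ² a(x) u = −4π l₀ Σ_i q_i δ(x − x_i)

* eps(x) = eps_protein at lattice nodes strictly inside the union of atom
  spheres, eps_solvent outside. The dielectric boundary is the raw van der
  Waals union — no solvent-excluded-surface reconstruction. The probe radius
  enters only the ion-accessibility map a(x), which switches screening off
  inside atom spheres inflated by the probe.
* κ is the inverse Debye length of a univalent salt,
  κ² = 8π l_B n with l_B = l₀/eps_s the Bjerrum length and
  n = N_A·I·10⁻²⁷ Å⁻³ the salt number density (I in mol/L). At 0.15 M,
  310 K and eps 78 this gives κ⁻¹ ≈ 8.0 Å.
* l₀ = e²/(4π ε₀ kT) is the vacuum Coulomb scale length; the packaged
  constants are 332.0636 kcal·mol⁻¹·Å·e⁻² and k_B = 0.0019872
  kcal·mol⁻¹·K⁻¹, so the linearization is valid in the |u| ≲ 1 regime that
  the comparison skin (3–7 Å off the surface) largely occupies.

### Discretization and solver

Standard flux-conserving 7-point finite differences on a cubic lattice:
face dielectrics are harmonic means of the adjacent node values; each point
charge is spread onto its 8 surrounding nodes with trilinear weights; the
6 faces carry Dirichlet values from superposed single-sphere Debye–Hückel
terms, q l₀ exp(−κ(d−r)) / (eps_s d (1+κr)), which is why the solver enforces
a ≥ 10 Å margin between every atom sphere and every face (the multi-sphere
DH superposition is accurate at that range). The linear system is solved by
red-black successive over-relaxation with ω = 2/(1 + sin(π/n)), terminating
when the ∞-norm residual of the h²-scaled stencil equations falls below
`convergence_tol` (default 1e-6) relative to the ∞-norm of the source term.
Non-convergence within `max_iterations` raises, reporting the final residual.

No correction is applied for the singular self-energy beyond trilinear
spreading: the discretization error concentrates within a few lattice cells
of each charge, and skins never sample inside the molecule. Verified
behaviour (see the test suite): ≤ 3% deviation from the analytic Coulomb
potential at r = 10 Å on a uniform-dielectric zero-salt 65³/0.5 Å grid, and a
fitted exp decay length of r·u(r) within 5% of the analytic Debye length in
salted uniform solution; the error at a fixed probe point shrinks when the
spacing is halved.

### Parameters (defaults)

| parameter | default | units | note |
|---|---|---|---|
| grid_points_per_side | 353 | – | production protein-scale grid |
| spacing | 0.33 | Å | grid resolution |
| ionic_strength | 0.15 | mol/L | univalent salt |
| eps_protein / eps_solvent | 2 / 78 | – | piecewise dielectric |
| temperature | 310 | K | sets the kT/e unit |
| probe_radius | 1.4 | Å | ion-exclusion (Stern) layer only |
| sigma / delta | 3 / 4 | Å | skin stand-off and thickness |

Tests and the acceptance script run at 25³–65³ with spacings 0.5–0.75 Å; toy
molecules are a few Å across, so these grids keep the same margin-to-size
ratios as the production configuration does for a full HLA ectodomain.

## Skin comparison

A node p belongs to a molecule's skin iff σ ≤ d(p) < σ+δ, with
d(p) = min_i (|p − x_i| − r_i). The half-open interval makes masks partition
cleanly under σ sweeps. Two molecules are compared over the boolean AND of
their skins; both potentials must live on one shared lattice, which is
arranged by superposing structure B onto structure A (Kabsch, least-squares
rigid transform over paired atoms — Cα atoms matched by residue index by
default, explicit pairs for toys) *before* solving. Solving after
superposition avoids grid resampling and its interpolation error entirely.

Similarity is the Hodgkin index SI = 2Σab/(Σa²+Σb²), sensitive to both sign
and magnitude. It is reported as the electrostatic similarity distance, the
monotone rescaling of SI onto [0, 2] anchored at the conventional points:
ESD = 1 − SI, so identity → 0, no correlation → 1, anticorrelation → 2.
Comparing two fields that are both identically zero on the mask is an error,
not SI = 0: the index is undefined there and a silent default would mask
solver failures.

Skin geometry uses σ = 3 Å, δ = 4 Å by default. The package's stability
suite shows the pairwise ESD rank order over a 6-molecule toy panel is
essentially invariant (Spearman ρ ≥ 0.9, observed worst ≈ 0.99) for every
σ, δ ∈ {1..5} Å, and that excluding a skin sub-region where the two fields
are near-identical moves the ESD by < 0.05.

## EMS-3D scoring

Donor and recipient typings are two-field allele names per locus (A, B, C,
DRB1, DQ, DP); DQB1/DPB1 names fold onto DQ/DP — HLA-DQ and -DP are scored
as single gene products keyed by the β-chain name, with α/β heterodimer
pairing out of scope. Names are normalized (optional "HLA-" prefix, case,
expression suffixes); anything not at exactly two-field resolution is
rejected. A donor allele is a mismatch when absent from the recipient's
alleles at the same locus; a homozygous donor mismatch is recorded once.

The EMS-3D of a mismatch is the minimum ESD over its comparator set:
all recipient class I alleles for class I (interlocus — a donor HLA-A
molecule resembling any recipient class I molecule, including HLA-C, is
deemed less immunogenic), same-locus recipient alleles for class II
(intralocus). A class II mismatch with no recipient allele typed at that
locus is an error (undefined comparison set), not a silent zero. Locus
totals sum the EMS-3D of a pair's one or two mismatches at that locus.

## Association models

`fit_logistic` fits DSA ~ intercept + EMS-3D (+ covariates) by maximum
likelihood (Newton/IRLS via statsmodels behind the module surface), with
Wald confidence intervals; odds ratios are reported per 0.1-unit EMS-3D
increase. Per-recipient random effects are deliberately omitted; a
cluster-robust (per-pair) covariance option substitutes. Constant outcomes,
perfect separation and non-convergence raise named errors. Quartile odds
ratios come from 2×2 tables against the first quartile, ties at cut points
assigned to the lower quartile for determinism, with a Haldane–Anscombe 0.5
continuity correction (flagged in the output) when a cell is empty.
Predicted-probability curves are inverse-logit transforms of the linear
predictor with pointwise delta-method (Wald) bands — a choice, as profile
bands would also be defensible. Binned observed rates report
events/count per half-open bin with percent rounded half-away-from-zero.

## Synthetic fixtures and what they do (not) show

Toy molecules are ~10-atom charge patterns (monopoles, charge-swapped twins,
dipole orientations, a quadrupole) decorating one fixed neutral 6-atom ring,
so all variants share a single frame and van der Waals surface: superposition
is exact and skin intersections equal each skin. Simulated cohorts draw two
alleles per locus per subject from a configurable pool (with replacement, so
homozygosity arises naturally), score mismatches through the real scoring
path, and draw DSA ~ Bernoulli(expit(β₀ + β₁·EMS-3D)) with defaults
β₀ = −2, β₁ = 8 — an event rate and effect steepness comparable to the
locus-level odds ratios the method is used to estimate. MFI is log-normal
around outcome-dependent medians (6000 for responders, 300 for
non-responders), clipped to the consistent side of the 2000 threshold; only
threshold behaviour is contractual. Lymphocyte dose is recorded as a
covariate (normal, mean 200×10⁶ cells) but carries no effect in the
generator's truth.

Passing these suites demonstrates internal correctness of the solver,
similarity formalism, scoring rules and inference — not that real HLA
molecules behave like 10-atom toys. In particular the fixtures have no
conformational variation, no protonation ambiguity, no allele-frequency or
linkage structure, and ESD magnitudes far wider than the 0–0.8 range seen
across real HLA panels. One seeded generator is passed explicitly through
every stochastic call; rerunning any stage with the same seed reproduces
output byte for byte.

## Numerical choices and edge cases

* Geometry equality between grids/masks is exact-dims plus 1e-9 on origin
  and spacing; mismatches raise rather than resample.
* Empty skins, empty skin intersections and zero-norm field comparisons
  raise; ESD matrices validate symmetry (1e-12), zero diagonal and [0, 2]
  bounds at construction, and reject NaN before clustering.
* Complete-linkage clustering and leaf ordering use scipy's deterministic
  agglomeration; Newick branch lengths are merge-height differences so every
  root-to-leaf path equals the final merge height.
* Kabsch superposition requires ≥ 3 non-collinear pairs (rank check at
  1e-6 of the coordinate span) and fixes the reflection sign, so the
  returned rotation always has determinant +1.
* PQR parsing accepts the 10- and 11-field whitespace dialects and reports
  the first malformed line by number; DX I/O follows the APBS OpenDX dialect
  and rejects non-regular or miscounted grids.

## Known limitations

* Linearized PB only; strongly charged surfaces where |u| ≫ 1 inside the
  skin would need the nonlinear equation.
* Van der Waals dielectric boundary (no SES/spline smoothing) and no
  multigrid/focusing: production 353³ solves work but take minutes, not
  seconds.
* Protonation states, homology modelling and model-quality validation are
  upstream concerns; structures (or PQR charge assignments) are accepted as
  given, with the packaged PARSE-like table as a convenience for plain PDB
  input.
* HLA-DQ/-DP α/β heterodimer pairing is not modelled; scores key on the
  β-chain allele name.
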