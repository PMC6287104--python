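# ems3d

Quantifying how *electrostatically different* two protein surfaces are — and
turning that difference into a clinical mismatch score for transplantation.

HLA (human leukocyte antigen) molecules are the main immunological barrier
between a transplant donor and recipient. Whether a recipient mounts a
donor-specific antibody (DSA) response against a mismatched donor HLA depends
less on how many sequence positions differ than on how different the molecular
*surface* looks to B-cell receptors. This package implements a structure-based
immunogenicity metric built entirely from continuum electrostatics:

1. **Potential.** The electrostatic potential φ of each molecule is computed on
   a cubic lattice by finite-difference solution of the linearized
   Poisson–Boltzmann equation,
   ∇·(ε∇φ) − ε_s κ² φ = −4π l₀ Σᵢ qᵢ δ(x−xᵢ),
   with a piecewise dielectric (ε_protein inside the van der Waals surface,
   ε_solvent outside), Debye screening κ in ion-accessible solvent, and
   potentials in dimensionless kT/e units.
2. **Skin comparison.** Two superposed molecules are compared over the
   intersection of their *skins* — lattice points at distance σ to σ+δ above
   each van der Waals surface — with the Hodgkin similarity index
   SI = 2Σ(φ_a φ_b) / (Σφ_a² + Σφ_b²) ∈ [−1, 1],
   reported as the electrostatic similarity distance ESD ∈ [0, 2]
   (0 = identity, 1 = no correlation, 2 = anticorrelation).
3. **EMS-3D.** For each mismatched donor allele, the three-dimensional
   electrostatic mismatch score is the *minimum* ESD against the recipient's
   own alleles — all class I alleles for a class I mismatch (interlocus), the
   same locus only for class II (intralocus). A donor allele that "looks like"
   anything the recipient's immune system already tolerates scores low.
4. **Association.** Logistic regression links EMS-3D (continuous, odds ratios
   per 0.1 unit; quartile splits for illustration) to binary DSA outcomes
   called from single-antigen-bead MFI at thresholds 2000 and 8000.

The package is aimed at structural immunologists and transplant
bioinformaticians; every stage is exercised end to end on built-in synthetic
fixtures (toy charge patterns with analytic screened-Coulomb oracles, and
simulated donor–recipient cohorts with known logistic coefficients).

## Worked example

```python
import numpy as np
from ems3d import SolverConfig, SkinParams, solve_lpb, compare_pair, fit_logistic
from ems3d.pbgrid import GridGeometry
from ems3d.synthetic import CohortSpec, make_toy_panel, simulate_cohort

# 1-2. solve two toy molecules on one shared frame and compare their skins
config = SolverConfig(grid_points_per_side=49, spacing=0.6)
panel = make_toy_panel(4, seed=1)
geometry = GridGeometry.centered(panel[0].geometric_center, 49, 0.6)
grids = [solve_lpb(m, config, geometry) for m in panel]
res = compare_pair(panel[0], grids[0], panel[2], grids[2], SkinParams())
print(f"SI = {res.si:.3f}, ESD = {res.esd:.3f} over {res.n_points} skin nodes")

# 3-4. simulate a cohort whose DSA risk follows expit(-2 + 8 * EMS-3D) and refit
pool = [f"A*{i+1:02d}:01" for i in range(4)]
esd = {("A*01:01","A*02:01"): 0.10, ("A*01:01","A*03:01"): 0.25,
       ("A*01:01","A*04:01"): 0.45, ("A*02:01","A*03:01"): 0.60,
       ("A*02:01","A*04:01"): 0.75, ("A*03:01","A*04:01"): 0.80}
spec = CohortSpec(n_pairs=2000, allele_pool={"A": pool}, beta0=-2.0, beta1=8.0, seed=1)
_, _, outcomes = simulate_cohort(spec, esd)
print(fit_logistic(outcomes).summary())
```

prints

```
SI = 0.395, ESD = 0.605 over 17328 skin nodes
Logistic regression of dsa_2000 (1975 records, log-likelihood -873.009)
        term       coef        se   OR/0.1U              95% CI
       const    -1.7842    0.1079
       ems3d     7.5544    0.3555     2.129 [  1.985,   2.282]
```

The first line compares a monopole toy molecule with an axial-dipole variant:
partially similar fields, ESD between identity (0) and no correlation (1).
The fit recovers the simulated slope (truth 8, here 7.55 ± 0.36): each 0.1-unit
increase in EMS-3D roughly doubles the odds of a DSA response in this cohort.

A command-line interface mirrors the library:
`ems3d solve`, `ems3d skin-compare`, `ems3d matrix`, `ems3d ems3d`,
`ems3d associate`, `ems3d simulate` and `ems3d run` (full pipeline with a
reproducibility manifest). Production solver settings (353³ grid at 0.33 Å,
0.15 M salt, ε 2/78, 310 K, probe 1.4 Å, σ 3 Å, δ 4 Å) ship as
`src/ems3d/data/production.cfg`; the desk-scale test configuration as `desk.cfg`.

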