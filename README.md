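# tsadesign

Computational enzyme redesign guided by transition-state analogues (TSAs).

Improving an enzyme's turnover requires stabilizing its transition state —
a structure that is almost never known. TSAs are stable inhibitors that
mimic the transition state's geometry and charge; for the benchmark system
here, *E. coli* β-glucuronidase (GUS) hydrolyzing *p*-nitrophenyl
glucuronide (pNP-GLU), the TSA is 1,5-glucarolactone. `tsadesign` builds on
the observation that cheap molecular-mechanics interaction energies (IE)
computed against the substrate and against the TSA track the Michaelis-
Menten parameters:

```
ln K_M        =  IE_S / (RT)_S        + c1
ln(kcat/K_M)  = -IE_TSA / (RT)_TSA    + c2
ln kcat       = -IE_TSA/(RT)_TSA + IE_S/(RT)_S + c3
```

where IE = E(complex) − E(enzyme) − E(ligand) after a single restrained
minimization, and the effective (RT) constants (for GUS/pNP-GLU, (RT)_S =
386.7 kJ/mol and (RT)_TSA = 15.3 kJ/mol) are recovered by ordinary least
squares on measured variants. Minimizing IE_S designs for K_M, minimizing
IE_TSA designs for catalytic efficiency, and a weighted combination designs
for k_cat.

The package provides, for whoever wants to run or study this workflow at
desk scale:

- **forcefield + solvation** (`energy`, `optimize`): CHARMM-style bonded
  terms, Lennard-Jones/Coulomb, a Still-form generalized-Born polar term
  with fixed Born radii, a deterministic Shrake-Rupley accessible-area
  nonpolar term, flat-bottom NOE catalytic restraints, analytic gradients,
  steepest-descent minimization, interaction and binding energies.
- **redesign engine** (`redesign`, `rotamers`): stochastic trajectories that
  mutate design positions, perturb backbone dihedrals, re-pack side chains
  from a rotamer library, and accept moves greedily then by the Metropolis
  criterion at a constant annealing temperature (7268 K — calibrated so a
  41.9 kJ/mol objective increase is accepted ~50% of the time), under
  feasibility constraints (IE_S < 0, IE_TSA < 0, alignment-derived permitted
  amino acids, at most two glycines across the design positions).
- **sequence constraints** (`alignments`): permitted amino-acid sets from
  family/superfamily alignment column profiles (observed at least once in
  the family, or in ≥5% of ungapped superfamily rows).
- **kinetics correlation** (`kinetics`): Eyring-Polanyi rates, the three
  OLS fits above, and mutant-vs-wild-type Δln predictions.
- **library analysis** (`library`): exact-fraction frequency tables over
  mutant libraries, representative mutations (≥15% in a library and ≥10
  percentage points above the others), and cross-library enrichment.
- **fixtures** (`synth`, `datasets`): deterministic toy enzyme-ligand
  complexes (the TSA ligand is a flattened, re-charged copy of the
  substrate), synthetic kinetics drawn exactly from the correlating model,
  a synthetic rotamer mini-library, and plain-text transcriptions of the
  benchmark's published restraints, permitted sets and top-10 mutant
  libraries.

## Worked example

```python
from tsadesign import interaction_energy, fit_ln_km
from tsadesign.synth import (ToyComplexSpec, SyntheticKineticsSpec,
                             generate_toy_complex, generate_synthetic_kinetics)

substrate, tsa, restraints = generate_toy_complex(ToyComplexSpec(seed=7))
print(interaction_energy(substrate, restraints, max_steps=40))  # -10.902
print(interaction_energy(tsa, restraints, max_steps=40))        # -11.109

ie, kin = generate_synthetic_kinetics(
    SyntheticKineticsSpec(n_variants=100, noise_sd_ln=0.2, seed=42))
fit = fit_ln_km(ie["ie_s"], kin["km_mM"])
print(round(fit.effective_rt, 1), round(fit.r_squared, 3))      # 369.5 0.97
```

Both interaction energies are negative — the toy complex binds both ligands
favourably, the analogue slightly tighter — and the K_M fit recovers the
(RT)_S = 386.7 kJ/mol used by the generator to within noise. The
`examples/` directory has one short narrative script per capability
(interaction energies, a redesign trajectory, the kinetics fits, library
analysis), each printing the numbers it computes and what they mean. A thin
CLI (`tsadesign energy|redesign|constraints|correlate|analyze-library|fixtures`)
wraps the same functions for shell use.

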