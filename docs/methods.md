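# Methods

## The model

`tsadesign` treats enzyme redesign as the minimization of a molecular-
mechanics interaction energy (IE) between an enzyme and one of two bound
ligands: the substrate, or a transition-state analogue (TSA) standing in
for the unknown transition state. The working assumptions are the standard
ones for this class of method: solute entropy changes on binding are small,
binding involves no induced fit (so IE, evaluated at the complex geometry,
approximates the binding free-energy difference), and the reaction
equilibrium after the rate-limiting step strongly favours product release.
Under those assumptions ln K_M is linear in IE_S, ln(kcat/K_M) is linear in
−IE_TSA, and ln kcat follows the weighted combination
−IE_TSA/(RT)_TSA + IE_S/(RT)_S, with empirical (RT) scale factors fitted by
ordinary least squares on measured variants.

A note on the (RT) constants and their "temperatures": the self-consistent
conversion is T = (RT)/R with R = 8.3145×10⁻³ kJ/(mol·K), i.e. 15.3 kJ/mol
↔ 1840 K and 386.7 kJ/mol ↔ 4.65×10⁴ K. Published prose for this benchmark
pairs the two temperatures the other way around; we implement the
self-consistent conversion and flag the pairing here rather than silently
"correcting" anything. These effective temperatures are regression scale
factors, not thermodynamic temperatures.

## Potential energy function

All energies are kJ/mol, distances Å, charges elementary charges. Inputs in
kcal/mol are converted at 4.184 kJ/kcal at the I/O layer.

- **Bonded**: harmonic bond/angle/Urey-Bradley/improper terms use
  E = k(x − x0)² with the ½ absorbed into k (CHARMM convention); the
  periodic dihedral is E = k_φ(1 + cos(nφ − δ)). Torsion derivatives follow
  the Blondel-Karplus formulation and are finite-difference checked in the
  tests.
- **Nonbonded**: Lennard-Jones in the rmin convention with geometric-mean
  well depths and additive rmin halves; Coulomb with
  K_e = 1389.354 kJ·Å/(mol·e²). 1-2 and 1-3 pairs are excluded; 1-4 pairs
  interact at full strength (a documented simplification). No cutoffs or
  neighbor lists: systems are desk-scale and the brute-force pair sum keeps
  oracle equivalence exact.
- **Polar solvation**: the Still pairwise generalized-Born form
  f_GB = sqrt(r² + a_i a_j exp(−r²/(4 a_i a_j))) with *fixed, user-supplied*
  Born radii, interior dielectric 1 and exterior 80, self-terms included and
  no exclusions. Fixed radii keep the term analytic and differentiable; the
  cost is that radii do not respond to burial changes.
- **Nonpolar solvation**: Σ_i σ_i·SASA_i with default
  σ = 0.0226 kJ/(mol·Å²) and SASA from a deterministic Shrake-Rupley scheme
  (256 golden-spiral sphere points per atom, probe 1.4 Å). Coordinates are
  first canonicalized to a principal-axes frame (axis signs fixed by
  coordinate skewness, right-handed completion), which makes the sampled
  area exactly invariant under global rotation/translation for generic
  geometries; perfectly symmetric configurations can fall outside that
  guarantee. Because the exposed/buried classification of a fixed finite
  point set is piecewise constant in the coordinates, the ASA term carries
  zero force; the minimizer's line search still monitors it through the
  total energy.
- **NOE restraints**: flat-bottom wells, zero in [d_min, d_max], harmonic
  walls with k_min below and k_max above (k_min ≤ k_max: catalytic contacts
  tolerate approach better than separation). The packaged fixture holds the
  four benchmark active-site contacts (windows 1.7-1.8 Å and 2.5-2.6 Å,
  constants 75/100 kJ/(mol·Å²)).

## Minimization, IE and BE

The minimizer is steepest descent with an Armijo backtracking line search
(initial step 0.01 Å, halving, c = 10⁻⁴, default gradient tolerance
0.1 kJ/(mol·Å), default 500 steps). It is deterministic and never accepts
an energy increase.

IE minimizes the complex once (restraints active) and subtracts single-point
energies of the enzyme and ligand parts *at the complex geometry*;
restraint energy belongs to the complex only, since the restraints couple
atoms across the two molecules. BE instead minimizes all three systems
independently, with the subsystem minimizations started from the relaxed
complex geometry. Consequently BE ≥ IE up to minimizer tolerance: the
separated parts can only lower the subtracted terms by relaxing, which
penalizes binding. ("Single-step minimization" is read as one minimization
run; `max_steps=1` is available for the literal reading.)

## Redesign trajectories

Each trajectory holds a pair of complexes sharing the enzyme (substrate-
bound and TSA-bound) and iterates propose → relax → evaluate → accept:

- **Proposals** (an open design choice, documented here rather than taken
  from any source): with probability 0.5, mutate one uniformly chosen
  design position to a uniformly chosen permitted amino acid and re-pack
  that side chain with its best rotamer; otherwise perturb the backbone
  φ/ψ dihedrals in the design window (positions ±1) by uniform draws within
  ±2° — applied independently per complex — and re-pack the current side
  chains at all design positions.
- **Rotamer packing** enumerates exhaustively up to 10,000 combinations and
  falls back to greedy position-by-position (seeded random order) above
  that; ties break toward alphabetical amino acid, then lowest rotamer
  index.
- **Relaxation** uses a per-iteration budget of `relax_steps` minimizer
  steps (default 30) rather than full convergence — a cost/accuracy
  trade-off chosen for desk-scale systems.
- **Feasibility**: IE_S < 0, IE_TSA < 0, all residues in their permitted
  sets, and at most `glycine_cap` (default 2) glycines across the design
  positions; infeasible proposals are rejected outright.
- **Acceptance**: strictly-improving only for the first
  `sa_start_iteration` iterations (default 100), then Metropolis at
  constant T (default 7268 K, where a 41.9 kJ/mol objective increase is
  accepted with probability ~0.500). As T → 0 the Metropolis phase reduces
  to greedy descent.
- **Aggregation**: independent trajectories (seeds = base seed + index)
  each report their best feasible state; multi-trajectory IE estimates are
  arithmetic means over trajectory bests (default 25 trajectories for IE
  estimation, 50 for design), with empty trajectories excluded and counted.

## Sequence constraints

Permitted sets per design position are the union of two inclusive rules:
observed at least once in the family alignment column, or at a frequency of
at least 5% among ungapped rows of the superfamily alignment column
(gap characters excluded from both the counts and the denominator;
ambiguity codes ignored with a logged count — no fractional distribution
scheme is applied). The alignment-column → structure-residue mapping is
explicit user input. The glycine cap is a separate global constraint.

## Library analysis

Frequencies are exact rationals (`fractions.Fraction`) so inclusive
boundary comparisons like 3/10 − 2/10 ≥ 1/10 behave exactly; decimal
thresholds are converted to rationals before comparison. A mutation is
*representative* of a library when its frequency there is ≥ 15% and exceeds
the maximum over the comparison libraries by ≥ 10 percentage points (both
inclusive; the strictest reading of "more frequent than the other
libraries" — a mean-comparison variant is available behind a flag).
Wild-type residues are never reported as mutations. Cross-group enrichment
uses two exposed thresholds (default: ≥ 10% in every library of group A,
≤ 5% in every library of group B); no published numeric values exist for
this rule, so the defaults are parameters, not claims.

## Synthetic data

`generate_toy_complex` builds a 2-10 residue zig-zag peptide with pseudo
side chains from the synthetic rotamer library and a small ring ligand
(2-10 atoms) placed ~4.5 Å from the mid-chain Cα, with one NOE restraint at
the built contact distance. The TSA complex shares the enzyme; its ligand
is the substrate ring flattened along z (half extent) with charge shifted
toward the first ring atom — mimicking how a lactone TSA differs from its
sugar substrate (planar ring, partial positive anomeric carbon) without
claiming chemical realism. Charge patterns: neutral, complementary
(attractive) or repulsive. Every generator output is a pure function of its
parameters and seed; the same seed gives byte-identical PDB output.

The synthetic rotamer library covers all 20 amino acids with two mirrored
rotamers each: linear pseudo side chains of 0-3 atoms (glycine has none),
a distinct golden-angle azimuthal twist per amino acid, and physically
motivated terminal partial charges (acidic −0.40/−0.45, basic +0.40/+0.45,
polar ≈ −0.1, apolar ~0). It is synthetic by construction — a stand-in with
the same file interface as a real backbone-dependent library, which remains
pluggable input.

`generate_synthetic_kinetics` draws IE_S, IE_TSA uniformly from
[−1600, −100] kJ/mol (the energy range the design libraries span) and
generates K_M, kcat/K_M and kcat *exactly* from the correlating equations
with chosen (RT) constants, intercepts and optional Gaussian ln-scale
noise. Passing tests on these data show the fits invert the model
correctly; they do not show that real kinetics obey the model — that
evidence has to come from measured variants.

## Problem sizes and limitations

Tests and examples run on toy complexes of ≤ ~30 atoms, trajectories of
tens of iterations with `relax_steps` ≈ 8, and 16-mutant enumerable design
spaces — sizes chosen so every stochastic result can be checked against an
exhaustive oracle. Known limitations: fixed Born radii (no burial
response); no 1-4 scaling; piecewise-constant SASA (no nonpolar forces);
steepest descent only (no quasi-Newton); the toy generator's geometry is
schematic, so absolute energies are not comparable to any published table —
only orderings, signs and the calibrated Metropolis/regression constants
carry over.
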