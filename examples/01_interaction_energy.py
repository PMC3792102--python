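"""Evaluate the interaction energy of a small enzyme-ligand complex.

Builds a deterministic toy complex (a short peptide with pseudo side chains
plus a charged ring ligand), evaluates the full energy decomposition, and
computes the interaction energy IE = E(complex) - E(enzyme) - E(ligand)
after a single minimization with the catalytic restraint active.
"""

from tsadesign import interaction_energy, total_energy
from tsadesign.synth import ToyComplexSpec, generate_toy_complex

substrate, tsa, restraints = generate_toy_complex(ToyComplexSpec(seed=7))

print("Energy decomposition of the substrate complex (kJ/mol):")
for term, value in total_energy(substrate, restraints).as_dict().items():
    print(f"  {term:>14s}  {value:10.3f}")

ie_s = interaction_energy(substrate, restraints, max_steps=40)
ie_tsa = interaction_energy(tsa, restraints, max_steps=40)
print(f"\nIE with the substrate:                 {ie_s:8.3f} kJ/mol")
print(f"IE with the transition-state analogue: {ie_tsa:8.3f} kJ/mol")
print("\nBoth are negative (favourable binding); the analogue binds slightly")
print("tighter because the flattened, recharged ring packs the same pocket.")
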