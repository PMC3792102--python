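"""Run a short stochastic redesign trajectory on a toy design space.

One design position is allowed to mutate among three amino acids; the
trajectory alternates mutations and backbone perturbations, relaxes each
candidate, and keeps the best feasible state under the K_M objective
(minimize the substrate interaction energy, with IE < 0 constraints and the
glycine cap).
"""

from tsadesign import RedesignConfig, run_trajectory
from tsadesign.synth import (
    ToyComplexSpec,
    generate_toy_complex,
    synthetic_rotamer_library,
)

substrate, tsa, restraints = generate_toy_complex(ToyComplexSpec(seed=3))
library = synthetic_rotamer_library()

config = RedesignConfig(
    design_positions=[2],
    permitted={2: {"S", "A", "G"}},   # wild type at position 2 is serine
    iterations=12,
    sa_start_iteration=4,
    temperature=7268.0,
    objective="KM",
    relax_steps=8,
    include_solvation=False,
    seed=0,
)

result = run_trajectory(substrate, tsa, config, library, restraints, restraints)
best = result.best_state
print(f"best assignment:  {best.assignment}")
print(f"IE_S = {best.ie_s:.3f} kJ/mol, IE_TSA = {best.ie_tsa:.3f} kJ/mol")
print(f"objective (IE_S): {best.objective_value:.3f} kJ/mol")
print("best-objective trace (monotone non-increasing):")
print("  " + " ".join(f"{v:.1f}" for v in result.best_trace))
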