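"""Energy minimization and interaction/binding-energy evaluation.

``interaction_energy`` follows the single-minimization protocol: relax the
complex once, then subtract the energies of the enzyme and ligand parts
evaluated *at the complex coordinates*. ``binding_energy`` instead minimizes
each of the three systems independently. NOE restraints couple enzyme and
ligand atoms and are therefore attributed to complex-state evaluations only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .energy import total_energy, total_energy_and_gradient
from .system import EnergyBreakdown, MolecularSystem, NOERestraint


class DivergenceError(RuntimeError):
    """Non-finite energy encountered during minimization."""


def minimize(
    system: MolecularSystem,
    restraints: Sequence[NOERestraint] = (),
    max_steps: int = 500,
    grad_tol: float = 0.1,
    include_solvation: bool = True,
    initial_step: float = 0.01,
    armijo_c: float = 1e-4,
) -> tuple[MolecularSystem, EnergyBreakdown]:
    """Steepest descent with a backtracking (Armijo) line search.

    Deterministic; never accepts an energy increase. Stops when the gradient
    norm drops below ``grad_tol`` kJ/(mol·Å), the line search stalls, or
    ``max_steps`` is exhausted.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    current = system
    energy, grad = total_energy_and_gradient(
        current, restraints, include_solvation=include_solvation
    )
    if not np.isfinite(energy.total):
        raise DivergenceError("non-finite starting energy")

    for _ in range(max_steps):
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= grad_tol:
            break
        direction = -grad / gnorm
        step = initial_step
        accepted = False
        # Armijo condition on the full energy (ASA term included even though
        # it carries no force: it is piecewise constant).
        slope = float(np.sum(grad * direction))
        for _bt in range(40):
            trial = current.with_coords(current.coords + step * direction)
            trial_energy, trial_grad = total_energy_and_gradient(
                trial, restraints, include_solvation=include_solvation
            )
            if not np.isfinite(trial_energy.total):
                step *= 0.5
                continue
            if trial_energy.total <= energy.total + armijo_c * step * slope:
                current, energy, grad = trial, trial_energy, trial_grad
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return current, energy


def interaction_energy_relaxed(
    complex_system: MolecularSystem,
    restraints: Sequence[NOERestraint] = (),
    max_steps: int = 500,
    grad_tol: float = 0.1,
    include_solvation: bool = True,
) -> tuple[MolecularSystem, float]:
    """As :func:`interaction_energy`, additionally returning the minimized
    complex (used by redesign trajectories to evolve coordinates)."""
    enzyme_idx = complex_system.atom_indices("enzyme")
    ligand_idx = complex_system.atom_indices("ligand")
    relaxed, e_complex = minimize(
        complex_system, restraints, max_steps=max_steps, grad_tol=grad_tol,
        include_solvation=include_solvation,
    )
    e_enzyme = total_energy(
        relaxed.subsystem(enzyme_idx), (), include_solvation=include_solvation
    )
    e_ligand = total_energy(
        relaxed.subsystem(ligand_idx), (), include_solvation=include_solvation
    )
    return relaxed, e_complex.total - e_enzyme.total - e_ligand.total


def interaction_energy(
    complex_system: MolecularSystem,
    restraints: Sequence[NOERestraint] = (),
    max_steps: int = 500,
    grad_tol: float = 0.1,
    include_solvation: bool = True,
) -> float:
    """IE = E(complex) - E(enzyme @ complex coords) - E(ligand @ complex coords).

    The complex is minimized once (restraints active); the subtracted parts
    are single-point evaluations at the minimized complex geometry, without
    restraints (the restraints couple enzyme and ligand atoms and are
    undefined for the separated parts).
    """
    _, ie = interaction_energy_relaxed(
        complex_system, restraints, max_steps=max_steps, grad_tol=grad_tol,
        include_solvation=include_solvation,
    )
    return ie


def binding_energy(
    complex_system: MolecularSystem,
    restraints: Sequence[NOERestraint] = (),
    max_steps: int = 500,
    grad_tol: float = 0.1,
    include_solvation: bool = True,
) -> float:
    """BE = E_min(complex) - E_min(enzyme) - E_min(ligand), with each term
    from an independent minimization of that subsystem.

    The subsystem minimizations start from the relaxed complex geometry, so
    each separated part can only lower its energy relative to its in-complex
    single-point value (hence BE <= IE up to minimizer tolerance).
    """
    enzyme_idx = complex_system.atom_indices("enzyme")
    ligand_idx = complex_system.atom_indices("ligand")
    relaxed, e_complex = minimize(
        complex_system, restraints, max_steps=max_steps, grad_tol=grad_tol,
        include_solvation=include_solvation,
    )
    _, e_enzyme = minimize(
        relaxed.subsystem(enzyme_idx), (), max_steps=max_steps,
        grad_tol=grad_tol, include_solvation=include_solvation,
    )
    _, e_ligand = minimize(
        relaxed.subsystem(ligand_idx), (), max_steps=max_steps,
        grad_tol=grad_tol, include_solvation=include_solvation,
    )
    return e_complex.total - e_enzyme.total - e_ligand.total
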