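"""Stochastic active-site redesign with simulated annealing.

Each trajectory iterates a propose / relax / evaluate / accept loop over a
pair of complexes that share the enzyme: one with the substrate bound, one
with the transition-state analogue (TSA). A proposal either mutates one
design position (re-packing its side chain with the best rotamer of the new
amino acid) or perturbs the backbone around the design positions and
re-packs the current side chains. After relaxation, the substrate and TSA
interaction energies (IE_S, IE_TSA) are evaluated and combined into the
design objective:

    KM            -> IE_S
    KCAT_OVER_KM  -> IE_TSA
    KCAT          -> IE_TSA/rt_tsa - IE_S/rt_s

all minimized. Feasible candidates must bind both ligands favourably
(IE_S < 0 and IE_TSA < 0), respect the per-position permitted amino-acid
sets, and carry at most ``glycine_cap`` glycines over the design positions.
Acceptance is greedy for the first ``sa_start_iteration`` iterations and
Metropolis at constant temperature thereafter. Independent trajectories are
aggregated by averaging their best interaction energies.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .alignments import glycine_count
from .constants import AA3_TO_AA1, R_GAS
from .energy import total_energy
from .optimize import interaction_energy_relaxed
from .rotamers import Rotamer, RotamerLibrary, place_rotamer
from .system import MolecularSystem, NOERestraint, SelectionError

logger = logging.getLogger(__name__)

ObjectiveName = Literal["KM", "KCAT_OVER_KM", "KCAT"]


class ConstraintError(ValueError):
    """Empty permitted-set/library intersection at a design position."""


class ConfigurationError(ValueError):
    """Missing or invalid redesign configuration values."""


class AggregationError(ValueError):
    """No usable trajectories to aggregate."""


@dataclass
class RedesignConfig:
    """Design positions, constraints, annealing schedule and objective.

    ``temperature`` is the constant simulated-annealing temperature in K;
    with the default 7268 K an objective increase of 41.9 kJ/mol is accepted
    about half of the time. ``rt_s``/``rt_tsa`` are the effective RT scale
    factors (kJ/mol) required by the KCAT objective.
    """

    design_positions: list[int]
    permitted: dict[int, set[str]]
    chain: str = "A"
    glycine_cap: int = 2
    n_trajectories: int = 25
    iterations: int = 5000
    sa_start_iteration: int = 100
    temperature: float = 7268.0
    objective: ObjectiveName = "KM"
    rt_s: float | None = None
    rt_tsa: float | None = None
    seed: int = 0
    backbone_magnitude: float = 2.0  # degrees
    mutation_probability: float = 0.5
    relax_steps: int = 30
    include_solvation: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.iterations < 0:
            raise ConfigurationError("iterations must be >= 0")
        for pos in self.design_positions:
            if not self.permitted.get(pos):
                raise ConstraintError(f"empty permitted set at position {pos}")
        if self.objective == "KCAT" and not (
            self.rt_s and self.rt_tsa and self.rt_s > 0 and self.rt_tsa > 0
        ):
            raise ConfigurationError("KCAT objective requires positive rt_s and rt_tsa")


@dataclass
class MutantState:
    """A candidate sequence with its interaction energies and feasibility."""

    assignment: dict[int, str]
    ie_s: float
    ie_tsa: float
    objective_value: float
    feasible: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class TrajectoryResult:
    """Outcome of one redesign trajectory."""

    best_state: MutantState | None
    best_trace: list[float]
    seed: int

    @property
    def found_feasible(self) -> bool:
        return self.best_state is not None


def metropolis_acceptance(delta_e: float, temperature: float) -> float:
    """min(1, exp(-dE / (R T))) with R = 8.3145e-3 kJ/(mol·K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if delta_e <= 0:
        return 1.0
    return math.exp(-delta_e / (R_GAS * temperature))


def objective_value(
    ie_s: float,
    ie_tsa: float,
    objective: ObjectiveName,
    rt_s: float | None = None,
    rt_tsa: float | None = None,
) -> float:
    """Design objective (minimized): the IE that the chosen kinetic
    parameter correlates with."""
    if objective == "KM":
        return ie_s
    if objective == "KCAT_OVER_KM":
        return ie_tsa
    if objective == "KCAT":
        if not (rt_s and rt_tsa and rt_s > 0 and rt_tsa > 0):
            raise ConfigurationError("KCAT objective requires positive rt_s and rt_tsa")
        return ie_tsa / rt_tsa - ie_s / rt_s
    raise ConfigurationError(f"unknown objective {objective!r}")


def check_feasibility(
    assignment: Mapping[int, str],
    ie_s: float,
    ie_tsa: float,
    config: RedesignConfig,
) -> tuple[bool, list[str]]:
    """Feasibility with reason codes: favourable binding of both ligands,
    permitted amino acids only, glycine cap respected."""
    reasons: list[str] = []
    if not ie_s < 0:
        reasons.append("ie_s_nonnegative")
    if not ie_tsa < 0:
        reasons.append("ie_tsa_nonnegative")
    if glycine_count(assignment, config.design_positions) > config.glycine_cap:
        reasons.append("glycine_cap")
    for pos in config.design_positions:
        if assignment[pos].upper() not in config.permitted[pos]:
            reasons.append("not_permitted")
            break
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# backbone perturbation


def _rotate_about_axis(
    coords: np.ndarray, indices: Sequence[int], origin: np.ndarray,
    axis: np.ndarray, angle: float,
) -> np.ndarray:
    """Rodrigues rotation of ``indices`` about (origin, axis) by ``angle``."""
    u = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    out = coords.copy()
    p = coords[indices] - origin
    out[indices] = (
        origin
        + p * c
        + np.cross(u, p) * s
        + np.outer(p @ u, u) * (1.0 - c)
    )
    return out


def perturb_backbone(
    system: MolecularSystem,
    chain: str,
    window: Sequence[int],
    magnitude: float,
    rng: np.random.Generator,
) -> MolecularSystem:
    """Rotate the phi/psi dihedrals of the window residues by uniform draws
    in ±``magnitude`` degrees, propagating rigidly downstream (increasing
    residue number). Pure dihedral rotations: bond lengths and bond angles
    are untouched."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    window = sorted(window)
    chain_res = sorted({
        a.residue_id for a in system.atoms
        if a.chain == chain and a.molecule_tag != "ligand"
    })
    for r in window:
        if r not in chain_res:
            raise SelectionError(f"window residue {r} not in chain {chain}")
    coords = system.coords.copy()
    for res in window:
        i_n = system.select_atom(chain, res, "N")
        i_ca = system.select_atom(chain, res, "CA")
        i_c = system.select_atom(chain, res, "C")
        # atoms downstream of the rotated bond, same chain, protein only
        later = [
            i for i, a in enumerate(system.atoms)
            if a.chain == chain and a.molecule_tag != "ligand" and a.residue_id > res
        ]
        this_res = system.residue_atom_indices(chain, res)

        phi = math.radians(rng.uniform(-magnitude, magnitude))
        moving_phi = [i for i in this_res if i not in (i_n, i_ca)] + later
        if moving_phi and phi != 0.0:
            coords = _rotate_about_axis(
                coords, moving_phi, coords[i_n], coords[i_ca] - coords[i_n], phi
            )

        psi = math.radians(rng.uniform(-magnitude, magnitude))
        moving_psi = [
            i for i in this_res if system.atoms[i].name == "O"
        ] + later
        if moving_psi and psi != 0.0:
            coords = _rotate_about_axis(
                coords, moving_psi, coords[i_ca], coords[i_c] - coords[i_ca], psi
            )
    return system.with_coords(coords)


# ---------------------------------------------------------------------------
# rotamer assignment


def _allowed_rotamers(
    library: RotamerLibrary, permitted: set[str]
) -> list[tuple[str, int, Rotamer]]:
    """Rotamers whose one-letter type is permitted, in deterministic order
    (amino acid alphabetical, then library index)."""
    out: list[tuple[str, int, Rotamer]] = []
    for res3 in sorted(library.by_residue):
        aa1 = AA3_TO_AA1.get(res3)
        if aa1 is None or aa1 not in permitted:
            continue
        for idx, rot in enumerate(library.by_residue[res3]):
            out.append((aa1, idx, rot))
    return out


def assign_rotamers(
    system: MolecularSystem,
    positions: Sequence[int],
    library: RotamerLibrary,
    permitted: Mapping[int, set[str]],
    restraints: Sequence[NOERestraint] = (),
    chain: str = "A",
    exhaustive_limit: int = 10_000,
    rng: np.random.Generator | None = None,
    include_solvation: bool = True,
) -> tuple[MolecularSystem, dict[int, str]]:
    """Pick one rotamer per design position minimizing the total energy.

    Exhaustive enumeration when the combination count is at most
    ``exhaustive_limit``; otherwise greedy position-by-position in seeded
    random order. Ties break toward the earlier candidate in deterministic
    order (alphabetical amino acid, then lowest rotamer index).
    """
    choices: dict[int, list[tuple[str, int, Rotamer]]] = {}
    for pos in positions:
        allowed = _allowed_rotamers(library, {a.upper() for a in permitted[pos]})
        if not allowed:
            raise ConstraintError(
                f"position {pos}: permitted set has no rotamers in the library"
            )
        choices[pos] = allowed

    n_combos = math.prod(len(choices[p]) for p in positions)

    def energy_of(sys_: MolecularSystem) -> float:
        return total_energy(sys_, restraints, include_solvation=include_solvation).total

    if n_combos <= exhaustive_limit:
        best: tuple[float, MolecularSystem, dict[int, str]] | None = None
        for combo in itertools.product(*(choices[p] for p in positions)):
            trial = system
            assignment: dict[int, str] = {}
            for pos, (aa1, _idx, rot) in zip(positions, combo):
                trial = place_rotamer(trial, chain, pos, rot)
                assignment[pos] = aa1
            e = energy_of(trial)
            if best is None or e < best[0]:
                best = (e, trial, assignment)
        assert best is not None
        return best[1], best[2]

    # greedy fallback, seeded random position order
    order = list(positions)
    if rng is not None:
        order = [positions[i] for i in rng.permutation(len(positions))]
    current = system
    assignment = {}
    for pos in order:
        best_local: tuple[float, MolecularSystem, str] | None = None
        for aa1, _idx, rot in choices[pos]:
            trial = place_rotamer(current, chain, pos, rot)
            e = energy_of(trial)
            if best_local is None or e < best_local[0]:
                best_local = (e, trial, aa1)
        assert best_local is not None
        current, assignment[pos] = best_local[1], best_local[2]
    return current, assignment


# ---------------------------------------------------------------------------
# trajectories


def _wildtype_assignment(
    system: MolecularSystem, chain: str, positions: Sequence[int]
) -> dict[int, str]:
    out: dict[int, str] = {}
    for pos in positions:
        idx = system.residue_atom_indices(chain, pos)
        if not idx:
            raise SelectionError(f"design position {pos} absent from chain {chain}")
        res3 = system.atoms[idx[0]].residue_name
        out[pos] = AA3_TO_AA1.get(res3, "X")
    return out


def _evaluate(
    sub: MolecularSystem,
    tsa: MolecularSystem,
    restraints_sub: Sequence[NOERestraint],
    restraints_tsa: Sequence[NOERestraint],
    config: RedesignConfig,
) -> tuple[MolecularSystem, MolecularSystem, float, float]:
    sub_rel, ie_s = interaction_energy_relaxed(
        sub, restraints_sub, max_steps=config.relax_steps,
        include_solvation=config.include_solvation,
    )
    tsa_rel, ie_tsa = interaction_energy_relaxed(
        tsa, restraints_tsa, max_steps=config.relax_steps,
        include_solvation=config.include_solvation,
    )
    return sub_rel, tsa_rel, ie_s, ie_tsa


def run_trajectory(
    enzyme_substrate: MolecularSystem,
    enzyme_tsa: MolecularSystem,
    config: RedesignConfig,
    library: RotamerLibrary,
    restraints_substrate: Sequence[NOERestraint] = (),
    restraints_tsa: Sequence[NOERestraint] = (),
    seed: int | None = None,
) -> TrajectoryResult:
    """One redesign trajectory; deterministic for a fixed seed.

    Proposals mutate one design position (probability
    ``mutation_probability``) or perturb the backbone around the design
    window and re-pack the current side chains. Infeasible proposals are
    rejected outright; acceptance on the objective is greedy before
    ``sa_start_iteration`` and Metropolis at constant temperature after.
    Returns an empty result (``best_state is None``) if no feasible state is
    ever seen.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    chain = config.chain
    positions = config.design_positions

    assignment = _wildtype_assignment(enzyme_substrate, chain, positions)
    sub, tsa, ie_s, ie_tsa = _evaluate(
        enzyme_substrate, enzyme_tsa, restraints_substrate, restraints_tsa, config
    )
    feasible, reasons = check_feasibility(assignment, ie_s, ie_tsa, config)
    current_obj = objective_value(ie_s, ie_tsa, config.objective, config.rt_s, config.rt_tsa)
    best: MutantState | None = None
    if feasible:
        best = MutantState(dict(assignment), ie_s, ie_tsa, current_obj, True)
    trace: list[float] = []
    current_feasible = feasible

    for iteration in range(config.iterations):
        mutate = rng.random() < config.mutation_probability
        prop_assignment = dict(assignment)
        try:
            if mutate:
                pos = positions[int(rng.integers(len(positions)))]
                aa_options = sorted(config.permitted[pos])
                new_aa = aa_options[int(rng.integers(len(aa_options)))]
                prop_assignment[pos] = new_aa
                if glycine_count(prop_assignment, positions) > config.glycine_cap:
                    trace.append(best.objective_value if best else math.inf)
                    continue
                prop_sub, _ = assign_rotamers(
                    sub, [pos], library, {pos: {new_aa}}, restraints_substrate,
                    chain=chain, include_solvation=config.include_solvation,
                )
                prop_tsa, _ = assign_rotamers(
                    tsa, [pos], library, {pos: {new_aa}}, restraints_tsa,
                    chain=chain, include_solvation=config.include_solvation,
                )
            else:
                window_lo = min(positions) - 1
                window_hi = max(positions) + 1
                chain_res = {
                    a.residue_id for a in sub.atoms
                    if a.chain == chain and a.molecule_tag != "ligand"
                }
                window = [r for r in range(window_lo, window_hi + 1) if r in chain_res]
                prop_sub = perturb_backbone(sub, chain, window, config.backbone_magnitude, rng)
                prop_tsa = perturb_backbone(tsa, chain, window, config.backbone_magnitude, rng)
                prop_sub, _ = assign_rotamers(
                    prop_sub, positions, library,
                    {p: {prop_assignment[p]} for p in positions},
                    restraints_substrate, chain=chain,
                    include_solvation=config.include_solvation,
                )
                prop_tsa, _ = assign_rotamers(
                    prop_tsa, positions, library,
                    {p: {prop_assignment[p]} for p in positions},
                    restraints_tsa, chain=chain,
                    include_solvation=config.include_solvation,
                )
            prop_sub, prop_tsa, prop_ie_s, prop_ie_tsa = _evaluate(
                prop_sub, prop_tsa, restraints_substrate, restraints_tsa, config
            )
        except (ValueError, RuntimeError) as exc:  # degenerate proposal
            logger.debug("iteration %d: proposal failed (%s)", iteration, exc)
            trace.append(best.objective_value if best else math.inf)
            continue

        prop_feasible, _reasons = check_feasibility(
            prop_assignment, prop_ie_s, prop_ie_tsa, config
        )
        if not prop_feasible:
            trace.append(best.objective_value if best else math.inf)
            continue
        prop_obj = objective_value(
            prop_ie_s, prop_ie_tsa, config.objective, config.rt_s, config.rt_tsa
        )

        if not current_feasible:
            accept = True
        elif iteration < config.sa_start_iteration:
            accept = prop_obj < current_obj
        else:
            accept = rng.random() < metropolis_acceptance(
                prop_obj - current_obj, config.temperature
            )
        if accept:
            assignment, sub, tsa = prop_assignment, prop_sub, prop_tsa
            ie_s, ie_tsa, current_obj = prop_ie_s, prop_ie_tsa, prop_obj
            current_feasible = True
            if best is None or prop_obj < best.objective_value:
                best = MutantState(dict(assignment), ie_s, ie_tsa, prop_obj, True)
        trace.append(best.objective_value if best else math.inf)

    return TrajectoryResult(best_state=best, best_trace=trace, seed=seed)


def run_redesign(
    enzyme_substrate: MolecularSystem,
    enzyme_tsa: MolecularSystem,
    config: RedesignConfig,
    library: RotamerLibrary,
    restraints_substrate: Sequence[NOERestraint] = (),
    restraints_tsa: Sequence[NOERestraint] = (),
) -> list[TrajectoryResult]:
    """Run ``config.n_trajectories`` trajectories with seeds
    ``config.seed + index``."""
    return [
        run_trajectory(
            enzyme_substrate, enzyme_tsa, config, library,
            restraints_substrate, restraints_tsa, seed=config.seed + i,
        )
        for i in range(config.n_trajectories)
    ]


def aggregate_best_ie(
    results: Sequence[TrajectoryResult], which: Literal["ie_s", "ie_tsa"]
) -> tuple[float, int]:
    """Mean of the chosen interaction energy over trajectory-best states.

    Returns (mean, number of excluded empty trajectories).
    """
    values = [
        getattr(r.best_state, which) for r in results if r.best_state is not None
    ]
    n_empty = len(results) - len(values)
    if not values:
        raise AggregationError("no trajectory produced a feasible state")
    return float(np.mean(values)), n_empty
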