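"""File formats: PDB subset, parameter files, restraint lists, run configs.

The PDB dialect covers ATOM/HETATM/TER/END records with the standard
fixed-width columns; HETATM atoms are tagged as ligand, ATOM as enzyme.
Coordinates are preserved to the format's 3 decimals; occupancy/B-factor are
written as 1.00/0.00. A missing chain identifier defaults to 'A' with a
warning.

The parameter file is a line-oriented key-value text format:

    PARAM <residue_name> <atom_name> <charge> <lj_epsilon> <lj_rmin_half> \
          <born_radius> <vdw_radius> <sasa_coefficient>
    BOND <i> <j> <k_b> <r0>
    ANGLE <i> <j> <k> <k_theta> <theta0>
    UB <i> <k> <k_ub> <s0>
    DIHEDRAL <i> <j> <k> <l> <k_phi> <n> <delta>
    IMPROPER <i> <j> <k> <l> <k_psi> <psi0>

with 1-based atom serials matching the accompanying PDB, energies in kJ/mol
(harmonic convention E = k(x-x0)^2 with the 1/2 absorbed into k; 1-2 and 1-3
nonbonded pairs are excluded automatically, 1-4 pairs interact at full
strength). Floats are written with ``repr`` so read(write(x)) == x exactly.

Restraint files hold one flat-bottom restraint per line:

    chainA resA atomA chainB resB atomB d_min d_max k_min k_max
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .redesign import RedesignConfig
from .system import Atom, BondedTopology, MolecularSystem, NOERestraint

logger = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """Malformed PDB record (reported with its line number)."""


class ParameterFileError(ValueError):
    """Malformed parameter-file line."""


@dataclass
class ParameterSet:
    """Per-(residue, atom) nonbonded/solvation parameters plus bonded terms."""

    atom_params: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    topology: BondedTopology = field(default_factory=BondedTopology)

    def lookup(self, residue_name: str, atom_name: str) -> dict[str, float]:
        try:
            return self.atom_params[(residue_name, atom_name)]
        except KeyError:
            raise ParameterFileError(
                f"no parameters for ({residue_name}, {atom_name})"
            ) from None


ATOM_PARAM_FIELDS = (
    "charge", "lj_epsilon", "lj_rmin_half", "born_radius", "vdw_radius",
    "sasa_coefficient",
)


def read_parameters(path: str | Path) -> ParameterSet:
    ps = ParameterSet()
    topo = ps.topology
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            kind = parts[0]
            if kind == "PARAM":
                res, name = parts[1], parts[2]
                values = [float(v) for v in parts[3:9]]
                if len(values) != 6:
                    raise ValueError("need 6 numeric fields")
                ps.atom_params[(res, name)] = dict(zip(ATOM_PARAM_FIELDS, values))
            elif kind == "BOND":
                topo.bonds.append((int(parts[1]) - 1, int(parts[2]) - 1,
                                   float(parts[3]), float(parts[4])))
            elif kind == "ANGLE":
                topo.angles.append((int(parts[1]) - 1, int(parts[2]) - 1,
                                    int(parts[3]) - 1, float(parts[4]), float(parts[5])))
            elif kind == "UB":
                topo.urey_bradley.append((int(parts[1]) - 1, int(parts[2]) - 1,
                                          float(parts[3]), float(parts[4])))
            elif kind == "DIHEDRAL":
                topo.dihedrals.append((int(parts[1]) - 1, int(parts[2]) - 1,
                                       int(parts[3]) - 1, int(parts[4]) - 1,
                                       float(parts[5]), int(parts[6]), float(parts[7])))
            elif kind == "IMPROPER":
                topo.impropers.append((int(parts[1]) - 1, int(parts[2]) - 1,
                                       int(parts[3]) - 1, int(parts[4]) - 1,
                                       float(parts[5]), float(parts[6])))
            else:
                raise ValueError(f"unknown record {kind!r}")
        except (IndexError, ValueError) as exc:
            raise ParameterFileError(f"line {lineno}: {raw!r} ({exc})") from exc
    return ps


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    lines = ["# PARAM res atom charge eps rmin_half born vdw sasa; indices 1-based"]
    for (res, name), vals in params.atom_params.items():
        nums = " ".join(repr(vals[f]) for f in ATOM_PARAM_FIELDS)
        lines.append(f"PARAM {res} {name} {nums}")
    t = params.topology
    for i, j, k, r0 in t.bonds:
        lines.append(f"BOND {i + 1} {j + 1} {k!r} {r0!r}")
    for i, j, kk, kt, t0 in t.angles:
        lines.append(f"ANGLE {i + 1} {j + 1} {kk + 1} {kt!r} {t0!r}")
    for i, k, kub, s0 in t.urey_bradley:
        lines.append(f"UB {i + 1} {k + 1} {kub!r} {s0!r}")
    for i, j, kk, l, kp, n, d in t.dihedrals:
        lines.append(f"DIHEDRAL {i + 1} {j + 1} {kk + 1} {l + 1} {kp!r} {n} {d!r}")
    for i, j, kk, l, kp, p0 in t.impropers:
        lines.append(f"IMPROPER {i + 1} {j + 1} {kk + 1} {l + 1} {kp!r} {p0!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def parameters_from_system(system: MolecularSystem) -> ParameterSet:
    """Extract a parameter set from an in-memory system so that
    ``read_pdb(pdb, params)`` reconstructs its energetics.

    Atom parameters are keyed by (residue_name, atom_name); raises if two
    atoms sharing a key carry different parameters. The bonded topology is
    copied with 0-based indices matching the system's atom order.
    """
    ps = ParameterSet(topology=system.topology)
    for atom in system.atoms:
        key = (atom.residue_name, atom.name)
        values = {f: getattr(atom, f) for f in ATOM_PARAM_FIELDS}
        if key in ps.atom_params and ps.atom_params[key] != values:
            raise ParameterFileError(
                f"inconsistent parameters for {key}: cannot key by "
                "(residue_name, atom_name)"
            )
        ps.atom_params[key] = values
    return ps


# ---------------------------------------------------------------------------
# PDB


def write_pdb(system: MolecularSystem, path: str | Path) -> None:
    lines: list[str] = []
    prev_chain: str | None = None
    for i, atom in enumerate(system.atoms):
        if prev_chain is not None and atom.chain != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain
        record = "HETATM" if atom.molecule_tag == "ligand" else "ATOM  "
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = system.coords[i]
        lines.append(
            f"{record}{i + 1:5d} {name:<4s} {atom.residue_name:<3s} "
            f"{atom.chain:1s}{atom.residue_id:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(
    path: str | Path,
    params: ParameterSet | None = None,
) -> MolecularSystem:
    """Read the ATOM/HETATM/TER/END subset into a MolecularSystem.

    HETATM atoms are tagged ``ligand``, ATOM atoms ``enzyme``. If ``params``
    is given, per-atom parameters are looked up by (residue_name, atom_name)
    and the bonded topology is taken from the parameter set; otherwise atoms
    carry neutral default parameters and no bonded terms.
    """
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    defaulted_chain = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        record = raw[:6]
        if record in ("TER   ", "END   ") or raw.strip() in ("TER", "END"):
            continue
        if record not in ("ATOM  ", "HETATM"):
            continue  # subset reader: other record types are ignored
        try:
            serial = int(raw[6:11])
            name = raw[12:16].strip()
            res_name = raw[17:20].strip()
            chain = raw[21].strip()
            res_id = int(raw[22:26])
            xyz = [float(raw[30:38]), float(raw[38:46]), float(raw[46:54])]
            element = raw[76:78].strip() or name[:1]
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"line {lineno}: malformed record {raw!r}") from exc
        if not chain:
            chain = "A"
            defaulted_chain = True
        tag = "ligand" if record == "HETATM" else "enzyme"
        kwargs: dict[str, float] = {}
        if params is not None:
            kwargs = dict(params.lookup(res_name, name))
        atoms.append(Atom(
            atom_id=serial, name=name, element=element, residue_id=res_id,
            residue_name=res_name, chain=chain, molecule_tag=tag, **kwargs,
        ))
        coords.append(xyz)
    if defaulted_chain:
        logger.warning("%s: missing chain identifier, defaulted to 'A'", path)
    topo = params.topology if params is not None else BondedTopology()
    return MolecularSystem(atoms, np.array(coords).reshape(-1, 3), topo)


# ---------------------------------------------------------------------------
# restraints


def read_restraints(path: str | Path) -> list[NOERestraint]:
    """One restraint per line:
    chainA resA atomA chainB resB atomB d_min d_max k_min k_max."""
    out: list[NOERestraint] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 10:
            raise PDBParseError(f"line {lineno}: expected 10 fields, got {len(parts)}")
        try:
            out.append(NOERestraint(
                chain_a=parts[0], residue_a=int(parts[1]), atom_a=parts[2],
                chain_b=parts[3], residue_b=int(parts[4]), atom_b=parts[5],
                d_min=float(parts[6]), d_max=float(parts[7]),
                k_min=float(parts[8]), k_max=float(parts[9]),
            ))
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: {raw!r} ({exc})") from exc
    return out


def write_restraints(restraints: Sequence[NOERestraint], path: str | Path) -> None:
    lines = ["# chainA resA atomA chainB resB atomB d_min d_max k_min k_max"]
    for r in restraints:
        lines.append(
            f"{r.chain_a} {r.residue_a} {r.atom_a} {r.chain_b} {r.residue_b} "
            f"{r.atom_b} {r.d_min!r} {r.d_max!r} {r.k_min!r} {r.k_max!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run config


def read_config(path: str | Path) -> RedesignConfig:
    """Read a YAML run config mirroring RedesignConfig field-for-field.

    ``permitted`` maps positions to strings of one-letter codes, e.g.
    ``{162: "ASG"}``.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ParameterFileError(f"{path}: config must be a mapping")
    permitted = {
        int(pos): {c.upper() for c in str(letters)}
        for pos, letters in data.pop("permitted", {}).items()
    }
    data["permitted"] = permitted
    data["design_positions"] = [int(p) for p in data["design_positions"]]
    return RedesignConfig(**data)


def write_config(config: RedesignConfig, path: str | Path) -> None:
    data = {
        "design_positions": list(config.design_positions),
        "permitted": {
            pos: "".join(sorted(aas)) for pos, aas in config.permitted.items()
        },
        "chain": config.chain,
        "glycine_cap": config.glycine_cap,
        "n_trajectories": config.n_trajectories,
        "iterations": config.iterations,
        "sa_start_iteration": config.sa_start_iteration,
        "temperature": config.temperature,
        "objective": config.objective,
        "rt_s": config.rt_s,
        "rt_tsa": config.rt_tsa,
        "seed": config.seed,
        "backbone_magnitude": config.backbone_magnitude,
        "mutation_probability": config.mutation_probability,
        "relax_steps": config.relax_steps,
        "include_solvation": config.include_solvation,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
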