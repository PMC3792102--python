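"""Deterministic synthetic fixtures: toy complexes, rotamers, kinetics.

Everything here is a desk-scale stand-in built from scratch: a short
zig-zag peptide "enzyme" with pseudo side chains, a small ring "ligand", and
a flattened, re-charged copy of that ligand playing the transition-state
analogue (mimicking the planar ring and anomeric partial positive charge
that distinguish a glycosidase TSA from its substrate). All generators are
pure functions of their spec, so the same seed reproduces byte-identical
output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .constants import AA1_TO_AA3, DEFAULT_SASA_COEFFICIENT
from .rotamers import (
    DEFAULT_SIDECHAIN_PARAMS,
    Rotamer,
    RotamerLibrary,
    place_rotamer,
)
from .system import Atom, BondedTopology, MolecularSystem, NOERestraint

ChargePattern = Literal["neutral", "complementary", "repulsive"]


class ValidationError(ValueError):
    """A synthetic-fixture spec is outside its allowed bounds."""


@dataclass
class ToyComplexSpec:
    """Recipe for a small enzyme-ligand pair.

    ``charge_pattern`` controls enzyme/ligand charge signs: ``neutral`` (all
    zero), ``complementary`` (opposite signs, attractive) or ``repulsive``
    (same sign). ``lj_epsilon``/``sasa_coefficient`` apply to every atom.
    """

    n_enzyme_residues: int = 3
    ligand_n_atoms: int = 4
    charge_pattern: ChargePattern = "complementary"
    seed: int = 0
    residue_types: list[str] = field(default_factory=list)  # 1-letter codes
    lj_epsilon: float = 0.25
    sasa_coefficient: float = DEFAULT_SASA_COEFFICIENT
    ligand_distance: float = 4.5  # Å from the mid-chain CA

    def __post_init__(self) -> None:
        if not (2 <= self.n_enzyme_residues <= 10):
            raise ValidationError("n_enzyme_residues must be in [2, 10]")
        if not (2 <= self.ligand_n_atoms <= 10):
            raise ValidationError("ligand_n_atoms must be in [2, 10]")
        if self.charge_pattern not in ("neutral", "complementary", "repulsive"):
            raise ValidationError(f"bad charge_pattern {self.charge_pattern!r}")
        if self.residue_types and len(self.residue_types) != self.n_enzyme_residues:
            raise ValidationError("residue_types length must match n_enzyme_residues")


@dataclass
class SyntheticKineticsSpec:
    """Recipe for kinetics tables drawn exactly from the correlating model."""

    n_variants: int = 50
    rt_s: float = 386.7
    rt_tsa: float = 15.3
    intercepts: tuple[float, float] = (2.0, -1.0)
    noise_sd_ln: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 3:
            raise ValidationError("n_variants must be >= 3")
        if self.noise_sd_ln < 0:
            raise ValidationError("noise_sd_ln must be >= 0")


# ---------------------------------------------------------------------------
# synthetic rotamer library


#: pseudo side-chain length per amino acid (glycine has none)
_SIDECHAIN_SIZE = {
    "G": 0, "A": 1, "S": 1, "C": 1, "T": 1, "V": 1, "P": 1,
    "D": 2, "N": 2, "L": 2, "I": 2, "M": 2, "E": 2, "Q": 2, "H": 2,
    "F": 3, "Y": 3, "W": 3, "K": 3, "R": 3,
}
#: partial charge on the terminal pseudo-atom (acidic/basic strong, polar weak)
_TERMINAL_CHARGE = {
    "D": -0.45, "E": -0.40, "K": 0.45, "R": 0.40, "H": 0.15,
    "S": -0.10, "T": -0.10, "N": -0.12, "Q": -0.12, "Y": -0.08,
    "C": 0.05, "M": 0.05, "W": -0.05, "F": -0.03,
}
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def synthetic_rotamer_library() -> RotamerLibrary:
    """Two pseudo-rotamers for each of the 20 amino acids.

    Side chains are linear runs of SC1..SCn atoms in the backbone local
    frame; the two rotamers mirror each other through the backbone plane.
    Each amino acid gets a distinct geometry (a golden-angle azimuthal twist
    indexed by its alphabetical rank) and a physically motivated terminal
    partial charge, so different sequences produce genuinely different
    energies. Deterministic: no randomness is involved.
    """
    rotamers: list[Rotamer] = []
    for idx, (aa1, size) in enumerate(sorted(_SIDECHAIN_SIZE.items())):
        res3 = AA1_TO_AA3[aa1]
        twist = _GOLDEN_ANGLE * idx
        for mirror, prob in ((1.0, 0.5), (-1.0, 0.5)):
            names = [f"SC{k + 1}" for k in range(size)]
            coords = []
            for k in range(size):
                coords.append([
                    0.3 + 0.1 * k + 0.25 * math.cos(twist),
                    0.4 + 0.3 * k + 0.25 * math.sin(twist),
                    mirror * (1.5 + 1.3 * k) * (1.0 + 0.01 * idx),
                ])
            charges = [0.0] * size
            if size and aa1 in _TERMINAL_CHARGE:
                charges[-1] = _TERMINAL_CHARGE[aa1]
            rotamers.append(Rotamer(
                res3, names, np.array(coords).reshape(-1, 3), prob, charges
            ))
    return RotamerLibrary(rotamers)


# ---------------------------------------------------------------------------
# toy complexes


_BACKBONE_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.2, 1.0, 0.1]),
    "C": np.array([2.5, 0.5, -0.2]),
    "O": np.array([2.9, -0.6, -0.4]),
}
_RESIDUE_SPACING = 3.6
_DEFAULT_RESIDUES = ["A", "S", "V", "L", "N", "T", "C", "M", "I", "Q"]


def _charges_for(pattern: ChargePattern, rng: np.random.Generator) -> tuple[float, float]:
    """(enzyme CA charge, ligand per-atom charge)."""
    if pattern == "neutral":
        return 0.0, 0.0
    magnitude = 0.25 + 0.1 * rng.random()
    if pattern == "complementary":
        return magnitude, -magnitude
    return magnitude, magnitude


def generate_toy_complex(
    spec: ToyComplexSpec,
    library: RotamerLibrary | None = None,
) -> tuple[MolecularSystem, MolecularSystem, list[NOERestraint]]:
    """Build (substrate complex, TSA complex, restraints).

    The two complexes share the enzyme; the TSA ligand is the substrate
    ligand with its ring flattened (z-extent halved) and charge shifted
    toward the first ring atom (the "anomeric" carbon analogue). One NOE
    restraint ties a mid-chain CA to that atom at its built distance.
    """
    rng = np.random.default_rng(spec.seed)
    library = library or synthetic_rotamer_library()
    q_enzyme, q_ligand = _charges_for(spec.charge_pattern, rng)

    atom_params = dict(DEFAULT_SIDECHAIN_PARAMS)
    atom_params["lj_epsilon"] = spec.lj_epsilon
    atom_params["sasa_coefficient"] = spec.sasa_coefficient

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    topo = BondedTopology()
    residues = spec.residue_types or [
        _DEFAULT_RESIDUES[i % len(_DEFAULT_RESIDUES)]
        for i in range(spec.n_enzyme_residues)
    ]

    index_of: dict[tuple[int, str], int] = {}
    for r in range(spec.n_enzyme_residues):
        base = np.array([r * _RESIDUE_SPACING, 0.0, 0.0])
        zig = np.array([0.0, 0.0, 0.35 * (-1.0) ** r])
        for name, offset in _BACKBONE_OFFSETS.items():
            idx = len(atoms)
            index_of[(r + 1, name)] = idx
            atoms.append(Atom(
                atom_id=idx + 1, name=name, element=name[:1],
                residue_id=r + 1, residue_name="GLY", chain="A",
                molecule_tag="enzyme",
                charge=q_enzyme if name == "CA" else 0.0,
                **atom_params,
            ))
            coords.append(base + offset + zig)

    def bond(i: int, j: int, k: float = 250.0) -> None:
        r0 = float(np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])))
        topo.bonds.append((i, j, k, r0))

    for r in range(1, spec.n_enzyme_residues + 1):
        bond(index_of[(r, "N")], index_of[(r, "CA")])
        bond(index_of[(r, "CA")], index_of[(r, "C")])
        bond(index_of[(r, "C")], index_of[(r, "O")])
        if r < spec.n_enzyme_residues:
            bond(index_of[(r, "C")], index_of[(r + 1, "N")])

    coords_arr = np.array(coords)
    enzyme = MolecularSystem(atoms, coords_arr, topo)

    # dress the backbone with wild-type side chains
    for r, aa1 in enumerate(residues, start=1):
        rot = library.rotamers_for(AA1_TO_AA3[aa1])[0]
        enzyme = place_rotamer(enzyme, "A", r, rot, sidechain_params=atom_params)

    # ligand ring below the mid-chain CA
    mid = (spec.n_enzyme_residues + 1) // 2
    i_mid_ca = enzyme.select_atom("A", mid, "CA")
    center = enzyme.coords[i_mid_ca] + np.array([0.3, -spec.ligand_distance, 0.2])
    n_lig = spec.ligand_n_atoms
    ring_radius = 0.8 + 0.08 * n_lig
    lig_coords = []
    for k in range(n_lig):
        angle = 2.0 * math.pi * k / n_lig
        lig_coords.append(center + np.array([
            ring_radius * math.cos(angle),
            0.35 * math.sin(2.0 * angle),
            ring_radius * math.sin(angle),
        ]))

    def build_complex(lig_xyz: list[np.ndarray], lig_charges: list[float]) -> MolecularSystem:
        all_atoms = [replace(a) for a in enzyme.atoms]
        all_coords = list(enzyme.coords)
        topo2 = BondedTopology(
            bonds=list(enzyme.topology.bonds),
            angles=list(enzyme.topology.angles),
            urey_bradley=list(enzyme.topology.urey_bradley),
            dihedrals=list(enzyme.topology.dihedrals),
            impropers=list(enzyme.topology.impropers),
        )
        first = len(all_atoms)
        for k, (xyz, q) in enumerate(zip(lig_xyz, lig_charges)):
            all_atoms.append(Atom(
                atom_id=first + k + 1, name=f"L{k + 1}", element="C",
                residue_id=1, residue_name="LIG", chain="L",
                molecule_tag="ligand", charge=q, **atom_params,
            ))
            all_coords.append(xyz)
        for k in range(n_lig):
            i, j = first + k, first + (k + 1) % n_lig
            if n_lig == 2 and k == 1:
                break
            r0 = float(np.linalg.norm(all_coords[i] - all_coords[j]))
            topo2.bonds.append((i, j, 250.0, r0))
        return MolecularSystem(all_atoms, np.array(all_coords), topo2)

    substrate = build_complex(lig_coords, [q_ligand] * n_lig)

    # TSA: flattened ring, charge shifted to the anomeric-carbon analogue
    tsa_xyz = []
    for xyz in lig_coords:
        flat = xyz.copy()
        flat[2] = center[2] + 0.5 * (xyz[2] - center[2])
        tsa_xyz.append(flat)
    tsa_charges = [q_ligand] * n_lig
    shift = 0.15 if spec.charge_pattern != "neutral" else 0.0
    tsa_charges[0] = q_ligand + shift
    if n_lig > 1:
        tsa_charges[1] = q_ligand - shift
    tsa = build_complex(tsa_xyz, tsa_charges)

    d_noe = float(np.linalg.norm(substrate.coords[i_mid_ca] - lig_coords[0]))
    restraints = [NOERestraint(
        chain_a="A", residue_a=mid, atom_a="CA",
        chain_b="L", residue_b=1, atom_b="L1",
        d_min=round(d_noe - 0.1, 3), d_max=round(d_noe + 0.1, 3),
        k_min=75.0, k_max=100.0,
    )]
    return substrate, tsa, restraints


# ---------------------------------------------------------------------------
# synthetic kinetics


def generate_synthetic_kinetics(
    spec: SyntheticKineticsSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (IE table, kinetics table) exactly from the correlating model.

    IE_S and IE_TSA are uniform on [-1600, -100] kJ/mol (the energy range the
    design libraries span); then, with independent Gaussian ln-scale noise,

        ln K_M       =  IE_S / rt_s   + c1 + eps1
        ln(kcat/K_M) = -IE_TSA/rt_tsa + c2 + eps2
        kcat         =  (kcat/K_M) * K_M.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants
    ie_s = rng.uniform(-1600.0, -100.0, size=n)
    ie_tsa = rng.uniform(-1600.0, -100.0, size=n)
    c1, c2 = spec.intercepts
    noise1 = rng.normal(0.0, spec.noise_sd_ln, size=n) if spec.noise_sd_ln else np.zeros(n)
    noise2 = rng.normal(0.0, spec.noise_sd_ln, size=n) if spec.noise_sd_ln else np.zeros(n)
    ln_km = ie_s / spec.rt_s + c1 + noise1
    ln_eff = -ie_tsa / spec.rt_tsa + c2 + noise2
    km = np.exp(ln_km)
    eff = np.exp(ln_eff)
    kcat = eff * km
    ids = [f"variant_{i:03d}" for i in range(n)]
    ie_table = pd.DataFrame({"variant_id": ids, "ie_s": ie_s, "ie_tsa": ie_tsa})
    kin_table = pd.DataFrame({
        "variant_id": ids, "km_mM": km, "kcat_per_s": kcat, "kcat_over_km": eff,
    })
    return ie_table, kin_table
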