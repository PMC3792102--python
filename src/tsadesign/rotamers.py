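"""Side-chain rotamers: local-frame geometry, placement, and library I/O.

A rotamer stores side-chain atom positions in a local frame defined by the
backbone N/CA/C atoms of its residue (origin at CA, x toward N, z normal to
the N-CA-C plane). Placing a rotamer maps those coordinates rigidly through
the frame of the target residue, so the rotamer's internal geometry is
preserved exactly.

The library text format is line-oriented::

    ROT <residue_type_3letter> <n_atoms> <probability>
    <atom_name> <x> <y> <z> [<charge>]
    ... (n_atoms lines)

The packaged mini-library is synthetic: pseudo side chains of 0-3 atoms per
amino acid, two rotamers each — a pluggable stand-in with the same interface
as a real backbone-dependent library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import AA3_TO_AA1
from .system import Atom, BondedTopology, MolecularSystem

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: generic nonbonded parameters for synthetic side-chain pseudo-atoms
DEFAULT_SIDECHAIN_PARAMS = {
    "lj_epsilon": 0.30,
    "lj_rmin_half": 1.8,
    "born_radius": 1.7,
    "vdw_radius": 1.7,
    "sasa_coefficient": 0.0226,
}
SIDECHAIN_BOND_K = 300.0  # kJ/(mol·Å²), toy attachment bonds


class StructureError(ValueError):
    """A residue is missing a backbone frame atom (N, CA or C)."""


class LibraryFormatError(ValueError):
    """Malformed rotamer-library file."""


@dataclass
class Rotamer:
    """One discrete side-chain conformation in the backbone local frame."""

    residue_type: str  # 3-letter code
    atom_names: list[str]
    local_coords: np.ndarray  # (n_atoms, 3)
    probability: float = 1.0
    charges: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.local_coords = np.asarray(self.local_coords, dtype=float).reshape(-1, 3)
        if len(self.local_coords) != len(self.atom_names):
            raise LibraryFormatError("rotamer atom count mismatch")
        if not (0.0 < self.probability <= 1.0 + 1e-6):
            raise LibraryFormatError(f"rotamer probability {self.probability} outside (0, 1]")
        if not self.charges:
            self.charges = [0.0] * len(self.atom_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


class RotamerLibrary:
    """Rotamers grouped by residue type (3-letter codes)."""

    def __init__(self, rotamers: list[Rotamer]):
        self.by_residue: dict[str, list[Rotamer]] = {}
        for rot in rotamers:
            self.by_residue.setdefault(rot.residue_type, []).append(rot)
        for res, rots in self.by_residue.items():
            total = sum(r.probability for r in rots)
            if total > 1.0 + 1e-6:
                raise LibraryFormatError(
                    f"{res}: rotamer probabilities sum to {total:.4f} > 1"
                )

    def residue_types(self) -> set[str]:
        return set(self.by_residue)

    def rotamers_for(self, residue_type: str) -> list[Rotamer]:
        try:
            return self.by_residue[residue_type]
        except KeyError:
            raise LibraryFormatError(f"no rotamers for residue {residue_type}") from None

    def one_letter_types(self) -> set[str]:
        return {AA3_TO_AA1[r] for r in self.by_residue if r in AA3_TO_AA1}


def read_rotamer_library(path: str | Path) -> RotamerLibrary:
    rotamers: list[Rotamer] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] != "ROT" or len(parts) != 4:
            raise LibraryFormatError(f"line {i}: expected 'ROT <res> <n> <p>', got {line!r}")
        res, n_atoms, prob = parts[1], int(parts[2]), float(parts[3])
        names, coords, charges = [], [], []
        for _ in range(n_atoms):
            if i >= len(lines):
                raise LibraryFormatError(f"line {i}: truncated rotamer block for {res}")
            fields = lines[i].split()
            i += 1
            if len(fields) not in (4, 5):
                raise LibraryFormatError(f"line {i}: expected 'name x y z [q]'")
            names.append(fields[0])
            coords.append([float(v) for v in fields[1:4]])
            charges.append(float(fields[4]) if len(fields) == 5 else 0.0)
        rotamers.append(Rotamer(res, names, np.array(coords).reshape(-1, 3),
                                prob, charges))
    return RotamerLibrary(rotamers)


def write_rotamer_library(library: RotamerLibrary, path: str | Path) -> None:
    out = ["# rotamer library: ROT <res3> <n_atoms> <probability>; atom lines: name x y z q"]
    for res in sorted(library.by_residue):
        for rot in library.by_residue[res]:
            out.append(f"ROT {res} {rot.n_atoms} {rot.probability:.6f}")
            for name, xyz, q in zip(rot.atom_names, rot.local_coords, rot.charges):
                out.append(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} {q:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# frames and placement


def backbone_frame(
    system: MolecularSystem, chain: str, residue_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (origin, rotation matrix) of the residue's N/CA/C local frame.

    Origin at CA; x toward N; z along x × (C - CA); y completes the
    right-handed frame. Columns of the matrix are the frame axes.
    """
    try:
        i_n = system.select_atom(chain, residue_id, "N")
        i_ca = system.select_atom(chain, residue_id, "CA")
        i_c = system.select_atom(chain, residue_id, "C")
    except Exception as exc:
        raise StructureError(
            f"residue {chain}/{residue_id} missing backbone frame atom: {exc}"
        ) from exc
    ca = system.coords[i_ca]
    xv = system.coords[i_n] - ca
    nx = np.linalg.norm(xv)
    if nx == 0.0:
        raise StructureError(f"degenerate frame at {chain}/{residue_id}")
    xh = xv / nx
    cv = system.coords[i_c] - ca
    zv = np.cross(xh, cv)
    nz = np.linalg.norm(zv)
    if nz == 0.0:
        raise StructureError(f"collinear backbone at {chain}/{residue_id}")
    zh = zv / nz
    yh = np.cross(zh, xh)
    return ca, np.column_stack([xh, yh, zh])


def place_rotamer(
    system: MolecularSystem,
    chain: str,
    residue_id: int,
    rotamer: Rotamer,
    sidechain_params: dict | None = None,
) -> MolecularSystem:
    """Replace the residue's side chain with ``rotamer``, rigidly mapped
    through the backbone frame. Backbone atoms are untouched; the residue is
    renamed to the rotamer's type; side-chain atoms are attached by a linear
    chain of harmonic bonds (CA - SC1 - SC2 - ...) whose rest lengths equal
    the placed geometry, so placement is at bonded equilibrium."""
    params = dict(DEFAULT_SIDECHAIN_PARAMS)
    if sidechain_params:
        params.update(sidechain_params)
    origin, rot_mat = backbone_frame(system, chain, residue_id)
    placed = origin + rotamer.local_coords @ rot_mat.T

    res_idx = system.residue_atom_indices(chain, residue_id)
    if not res_idx:
        raise StructureError(f"no atoms in residue {chain}/{residue_id}")
    backbone_idx = [i for i in res_idx if system.atoms[i].name in BACKBONE_ATOMS]
    sidechain_old = [i for i in res_idx if system.atoms[i].name not in BACKBONE_ATOMS]

    # Keep everything except the old side chain; insert new atoms after the
    # residue's last backbone atom.
    kept = [i for i in range(system.n_atoms) if i not in set(sidechain_old)]
    insert_after = max(backbone_idx)
    insert_pos = kept.index(insert_after) + 1
    index_map = {}
    new_atoms: list[Atom] = []
    new_coords: list[np.ndarray] = []
    for new_i, old_i in enumerate(kept[:insert_pos]):
        index_map[old_i] = new_i
        new_atoms.append(replace(system.atoms[old_i]))
        new_coords.append(system.coords[old_i])
    sc_start = insert_pos
    for k, (name, xyz, q) in enumerate(zip(rotamer.atom_names, placed, rotamer.charges)):
        new_atoms.append(Atom(
            atom_id=0, name=name, element=name[:1],
            residue_id=residue_id, residue_name=rotamer.residue_type,
            chain=chain, molecule_tag=system.atoms[backbone_idx[0]].molecule_tag,
            charge=q, **params,
        ))
        new_coords.append(xyz)
    for offset, old_i in enumerate(kept[insert_pos:]):
        index_map[old_i] = sc_start + rotamer.n_atoms + offset
        new_atoms.append(replace(system.atoms[old_i]))
        new_coords.append(system.coords[old_i])

    # rename the backbone atoms of the mutated residue and renumber atom_ids
    for i, atom in enumerate(new_atoms):
        atom.atom_id = i + 1
        if atom.chain == chain and atom.residue_id == residue_id:
            atom.residue_name = rotamer.residue_type

    def remap(term: tuple, n_idx: int) -> tuple | None:
        idx = term[:n_idx]
        if all(i in index_map for i in idx):
            return tuple(index_map[i] for i in idx) + term[n_idx:]
        return None

    topo = system.topology
    new_topo = BondedTopology(
        bonds=[t for t in (remap(b, 2) for b in topo.bonds) if t],
        angles=[t for t in (remap(a, 3) for a in topo.angles) if t],
        urey_bradley=[t for t in (remap(u, 2) for u in topo.urey_bradley) if t],
        dihedrals=[t for t in (remap(d, 4) for d in topo.dihedrals) if t],
        impropers=[t for t in (remap(im, 4) for im in topo.impropers) if t],
    )
    coords_arr = np.array(new_coords)
    anchor = index_map[system.select_atom(chain, residue_id, "CA")]
    prev = anchor
    for k in range(rotamer.n_atoms):
        cur = sc_start + k
        r0 = float(np.linalg.norm(coords_arr[cur] - coords_arr[prev]))
        new_topo.bonds.append((prev, cur, SIDECHAIN_BOND_K, r0))
        prev = cur

    extra = frozenset(
        (index_map[i], index_map[j])
        for i, j in system.extra_exclusions
        if i in index_map and j in index_map
    )
    return MolecularSystem(new_atoms, coords_arr, new_topo, extra)
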