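"""Molecular system containers: atoms, bonded topology, restraints.

A :class:`MolecularSystem` holds everything a force-field evaluation needs:
per-atom nonbonded/solvation parameters, coordinates in Å, the bonded
topology, and the nonbonded exclusion list (1-2 and 1-3 pairs are always
excluded; 1-4 pairs interact at full strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

MoleculeTag = Literal["enzyme", "ligand", "other"]


class TopologyError(ValueError):
    """A bonded-term index does not refer to an existing atom."""


class GeometryError(ValueError):
    """Degenerate geometry (zero-length vector) in an angle or dihedral."""


class RestraintError(ValueError):
    """A restraint selector does not resolve to exactly one atom."""


class SelectionError(ValueError):
    """A molecule-tag or residue selection matched nothing."""


class ParameterError(ValueError):
    """An atom parameter violates its physical bounds."""


@dataclass
class Atom:
    """One atom with its nonbonded and implicit-solvation parameters.

    ``charge`` is in elementary charges; ``lj_epsilon`` (well depth, kJ/mol)
    and ``lj_rmin_half`` (half the pair-minimum distance, Å) follow the
    rmin-based Lennard-Jones convention; ``born_radius`` feeds the pairwise
    generalized-Born polar term and ``vdw_radius``/``sasa_coefficient`` the
    accessible-area nonpolar term.
    """

    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str = "A"
    molecule_tag: MoleculeTag = "other"
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 1.0
    born_radius: float = 1.5
    sasa_coefficient: float = 0.0226
    vdw_radius: float = 1.7

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ParameterError(f"atom {self.name}: lj_epsilon must be >= 0")
        for attr in ("lj_rmin_half", "born_radius", "vdw_radius"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"atom {self.name}: {attr} must be > 0")
        if self.molecule_tag not in ("enzyme", "ligand", "other"):
            raise ParameterError(f"atom {self.name}: bad molecule_tag {self.molecule_tag!r}")


@dataclass
class BondedTopology:
    """Bonded force-field terms, stored as index tuples plus parameters.

    Harmonic terms use the convention E = k (x - x0)^2 with the 1/2 absorbed
    into k; the periodic dihedral is E = k (1 + cos(n phi - delta)).
    """

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    urey_bradley: list[tuple[int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int, float, float]] = field(default_factory=list)

    def validate(self, n_atoms: int) -> None:
        def chk(indices: Iterable[int], kind: str) -> None:
            for i in indices:
                if not (0 <= i < n_atoms):
                    raise TopologyError(f"{kind} index {i} out of range (n_atoms={n_atoms})")

        seen_pairs: set[tuple[int, int]] = set()
        for i, j, _k, _r0 in self.bonds:
            chk((i, j), "bond")
            pair = (min(i, j), max(i, j))
            if pair in seen_pairs:
                raise TopologyError(f"duplicate bond pair {pair}")
            seen_pairs.add(pair)
        for i, j, k, _kt, _t0 in self.angles:
            chk((i, j, k), "angle")
        for i, k, _kub, _s0 in self.urey_bradley:
            chk((i, k), "urey_bradley")
        for i, j, k, l, _kp, n, _d in self.dihedrals:
            chk((i, j, k, l), "dihedral")
            if n < 1:
                raise TopologyError(f"dihedral multiplicity must be >= 1, got {n}")
        for i, j, k, l, _kp, _p0 in self.impropers:
            chk((i, j, k, l), "improper")

    def bonded_pairs(self) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
        """Return (1-2 pairs, 1-3 pairs) as sorted index tuples."""
        adjacency: dict[int, set[int]] = {}
        pairs12: set[tuple[int, int]] = set()
        for i, j, _k, _r0 in self.bonds:
            adjacency.setdefault(i, set()).add(j)
            adjacency.setdefault(j, set()).add(i)
            pairs12.add((min(i, j), max(i, j)))
        pairs13: set[tuple[int, int]] = set()
        for j, neighbours in adjacency.items():
            ns = sorted(neighbours)
            for a in range(len(ns)):
                for b in range(a + 1, len(ns)):
                    pair = (ns[a], ns[b])
                    if pair not in pairs12:
                        pairs13.add(pair)
        return pairs12, pairs13


@dataclass
class NOERestraint:
    """Flat-bottom distance restraint with asymmetric harmonic walls.

    Zero inside [d_min, d_max]; k_min walls the short side and k_max the long
    side (k_min <= k_max: catalytic contacts survive small distances but must
    not drift apart). Atom selectors are (chain, residue_id, atom_name).
    """

    chain_a: str
    residue_a: int
    atom_a: str
    chain_b: str
    residue_b: int
    atom_b: str
    d_min: float
    d_max: float
    k_min: float
    k_max: float

    def __post_init__(self) -> None:
        if self.d_min > self.d_max:
            raise RestraintError(f"d_min {self.d_min} > d_max {self.d_max}")
        if self.k_min > self.k_max:
            raise RestraintError(f"k_min {self.k_min} > k_max {self.k_max}")


ENERGY_COMPONENTS = (
    "bond", "angle", "urey_bradley", "dihedral", "improper",
    "vdw", "electrostatic", "gb_polar", "asa_nonpolar", "noe",
)


@dataclass
class EnergyBreakdown:
    """Per-term energy decomposition, kJ/mol; ``total`` is the component sum."""

    bond: float = 0.0
    angle: float = 0.0
    urey_bradley: float = 0.0
    dihedral: float = 0.0
    improper: float = 0.0
    vdw: float = 0.0
    electrostatic: float = 0.0
    gb_polar: float = 0.0
    asa_nonpolar: float = 0.0
    noe: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(getattr(self, c) for c in ENERGY_COMPONENTS))

    def as_dict(self) -> dict[str, float]:
        d = {c: float(getattr(self, c)) for c in ENERGY_COMPONENTS}
        d["total"] = self.total
        return d


@dataclass
class MolecularSystem:
    """Atoms + coordinates + topology + nonbonded exclusions."""

    atoms: list[Atom]
    coords: np.ndarray
    topology: BondedTopology = field(default_factory=BondedTopology)
    extra_exclusions: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) != len(self.atoms):
            raise ValueError(
                f"coords rows ({len(self.coords)}) != atoms ({len(self.atoms)})"
            )
        self.topology.validate(len(self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def exclusions(self) -> frozenset[tuple[int, int]]:
        """All excluded nonbonded pairs: 1-2, 1-3, plus any extra pairs."""
        pairs12, pairs13 = self.topology.bonded_pairs()
        extra = {(min(i, j), max(i, j)) for i, j in self.extra_exclusions}
        return frozenset(pairs12 | pairs13 | extra)

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        return replace(self, coords=np.array(coords, dtype=float))

    def select_atom(self, chain: str, residue_id: int, atom_name: str) -> int:
        """Resolve a (chain, residue, atom-name) selector to a unique index."""
        hits = [
            i for i, a in enumerate(self.atoms)
            if a.chain == chain and a.residue_id == residue_id and a.name == atom_name
        ]
        if len(hits) != 1:
            raise RestraintError(
                f"selector ({chain}, {residue_id}, {atom_name}) matched "
                f"{len(hits)} atoms, expected exactly 1"
            )
        return hits[0]

    def atom_indices(self, molecule_tag: str) -> np.ndarray:
        idx = np.array(
            [i for i, a in enumerate(self.atoms) if a.molecule_tag == molecule_tag],
            dtype=int,
        )
        if idx.size == 0:
            raise SelectionError(f"no atoms tagged {molecule_tag!r}")
        return idx

    def residue_atom_indices(self, chain: str, residue_id: int) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if a.chain == chain and a.residue_id == residue_id
        ]

    def subsystem(self, indices: Sequence[int]) -> "MolecularSystem":
        """Extract the atoms at ``indices`` with remapped topology/exclusions.

        Bonded terms and exclusions are kept only when every participating
        atom survives the cut.
        """
        indices = list(indices)
        index_map = {old: new for new, old in enumerate(indices)}

        def keep(term: tuple, n_idx: int) -> tuple | None:
            idx = term[:n_idx]
            if all(i in index_map for i in idx):
                return tuple(index_map[i] for i in idx) + term[n_idx:]
            return None

        topo = BondedTopology(
            bonds=[t for t in (keep(b, 2) for b in self.topology.bonds) if t],
            angles=[t for t in (keep(a, 3) for a in self.topology.angles) if t],
            urey_bradley=[t for t in (keep(u, 2) for u in self.topology.urey_bradley) if t],
            dihedrals=[t for t in (keep(d, 4) for d in self.topology.dihedrals) if t],
            impropers=[t for t in (keep(im, 4) for im in self.topology.impropers) if t],
        )
        extra = frozenset(
            (index_map[i], index_map[j])
            for i, j in self.extra_exclusions
            if i in index_map and j in index_map
        )
        return MolecularSystem(
            atoms=[replace(self.atoms[i]) for i in indices],
            coords=self.coords[indices].copy(),
            topology=topo,
            extra_exclusions=extra,
        )
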