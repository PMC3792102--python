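"""Loaders for the packaged fixtures.

The packaged data are plain-text transcriptions of the benchmark system's
published inputs and outputs: the four catalytic-contact NOE restraints, the
per-position permitted amino-acid sets for the nine design positions of
E. coli beta-glucuronidase, and the six top-10 design libraries (K_M,
kcat/K_M and kcat objectives, for each of the pNP-GLU and pNP-GAL
substrates). The rotamer fixture is a synthetic mini-library.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .alignments import read_permitted_sets
from .library import DesignLibrary, parse_library_table
from .pdbio import read_restraints
from .rotamers import RotamerLibrary, read_rotamer_library
from .system import NOERestraint

_OBJECTIVE_SLUGS = {"KM": "km", "KCAT_OVER_KM": "kcat_over_km", "KCAT": "kcat"}


def _data_path(name: str) -> Path:
    return Path(resources.files("tsadesign").joinpath("data", name))  # type: ignore[arg-type]


def catalytic_restraints() -> list[NOERestraint]:
    """The four active-site NOE restraints (chain A enzyme, chain L ligand)."""
    return read_restraints(_data_path("catalytic_restraints.txt"))


def permitted_mutations() -> dict[int, set[str]]:
    """Alignment-derived permitted amino acids per design position."""
    return read_permitted_sets(_data_path("permitted_mutations.txt"))


def design_positions() -> list[int]:
    """The nine active-site design positions."""
    return sorted(permitted_mutations())


def design_library(substrate: str, objective: str) -> DesignLibrary:
    """One top-10 library: substrate in {pnp_glu, pnp_gal}, objective in
    {KM, KCAT_OVER_KM, KCAT}."""
    slug = _OBJECTIVE_SLUGS[objective]
    return parse_library_table(_data_path(f"top_mutants_{substrate}_{slug}.tsv"))


def design_libraries(substrate: str) -> dict[str, DesignLibrary]:
    """All three objective libraries for one substrate, keyed by objective."""
    return {obj: design_library(substrate, obj) for obj in _OBJECTIVE_SLUGS}


def rotamer_fixture_library() -> RotamerLibrary:
    """The packaged synthetic rotamer mini-library (2 per amino acid)."""
    return read_rotamer_library(_data_path("rotamers_synthetic.txt"))
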