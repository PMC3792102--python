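"""Sequence constraints from multiple-sequence-alignment profiles.

Permitted amino-acid sets at each design position are derived from two
alignments: a narrow family alignment (an amino acid observed at least once
is permitted) and a broad superfamily alignment (permitted if observed in at
least 5% of ungapped rows). The union of the two rules gives the permitted
set. A separate glycine cap bounds the total number of glycines across all
design positions of a candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import AlignIO

from .constants import STANDARD_AA1

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
AMBIGUOUS_AA = frozenset("BJOUXZ")


class AlignmentFormatError(ValueError):
    """Ragged alignment or out-of-range column."""


@dataclass
class ColumnProfile:
    """Amino-acid counts for one alignment column, gaps excluded."""

    counts: dict[str, int]
    n_ungapped: int
    n_sequences: int

    def frequency(self, amino_acid: str) -> float:
        if self.n_ungapped == 0:
            return 0.0
        return self.counts.get(amino_acid.upper(), 0) / self.n_ungapped


@dataclass
class PermittedSetRule:
    """Inclusive thresholds: >= min_count_family observations in the family
    alignment OR >= min_freq_superfamily frequency among ungapped superfamily
    rows."""

    min_count_family: int = 1
    min_freq_superfamily: float = 0.05

    def __post_init__(self) -> None:
        if self.min_count_family < 1:
            raise ValueError("min_count_family must be >= 1")
        if not (0.0 < self.min_freq_superfamily <= 1.0):
            raise ValueError("min_freq_superfamily must be in (0, 1]")


def read_alignment(path: str | Path) -> list[str]:
    """Read an aligned FASTA into a list of equal-length strings."""
    alignment = AlignIO.read(str(path), "fasta")
    return [str(rec.seq) for rec in alignment]


def column_profile(sequences: Sequence[str], column: int) -> ColumnProfile:
    """Count amino acids in one alignment column.

    Gaps ('-', '.') are excluded from the counts and the frequency
    denominator; letters are uppercased; ambiguity codes (B, J, O, U, X, Z)
    are ignored with a logged count.
    """
    if not sequences:
        return ColumnProfile({}, 0, 0)
    length = len(sequences[0])
    for i, seq in enumerate(sequences):
        if len(seq) != length:
            raise AlignmentFormatError(
                f"ragged alignment: sequence {i} has length {len(seq)} != {length}"
            )
    if not (0 <= column < length):
        raise AlignmentFormatError(f"column {column} out of range [0, {length})")

    counts: dict[str, int] = {}
    n_ungapped = 0
    n_ambiguous = 0
    for seq in sequences:
        letter = seq[column].upper()
        if letter in GAP_CHARS:
            continue
        if letter in AMBIGUOUS_AA or letter not in STANDARD_AA1:
            n_ambiguous += 1
            continue
        counts[letter] = counts.get(letter, 0) + 1
        n_ungapped += 1
    if n_ambiguous:
        logger.info("column %d: ignored %d ambiguous residue codes", column, n_ambiguous)
    return ColumnProfile(counts, n_ungapped, len(sequences))


def permitted_amino_acids(
    profile_family: ColumnProfile,
    profile_superfamily: ColumnProfile,
    rule: PermittedSetRule = PermittedSetRule(),
) -> set[str]:
    """Union of family-count and superfamily-frequency rules (inclusive)."""
    permitted = {
        aa for aa, c in profile_family.counts.items() if c >= rule.min_count_family
    }
    if profile_superfamily.n_ungapped > 0:
        permitted |= {
            aa
            for aa in profile_superfamily.counts
            if profile_superfamily.frequency(aa) >= rule.min_freq_superfamily
        }
    if not permitted:
        logger.warning("permitted set is empty for this position")
    return permitted


def glycine_count(
    assignment: Mapping[int, str], design_positions: Sequence[int]
) -> int:
    """Number of design positions assigned glycine."""
    return sum(1 for p in design_positions if assignment[p].upper() == "G")


# -- permitted-set file format: "position: A, C, F" ------------------------


def read_permitted_sets(path: str | Path) -> dict[int, set[str]]:
    permitted: dict[int, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            pos_str, aas = line.split(":", 1)
            position = int(pos_str)
            residues = {a.strip().upper() for a in aas.split(",") if a.strip()}
        except ValueError as exc:
            raise AlignmentFormatError(f"line {lineno}: {raw!r}") from exc
        bad = residues - STANDARD_AA1
        if bad:
            raise AlignmentFormatError(f"line {lineno}: non-standard codes {sorted(bad)}")
        permitted[position] = residues
    return permitted


def write_permitted_sets(permitted: Mapping[int, set[str]], path: str | Path) -> None:
    lines = [
        f"{pos}: {', '.join(sorted(aas))}" for pos, aas in sorted(permitted.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_column_map(path: str | Path) -> dict[int, int]:
    """Read a TSV of alignment-column (0-based) -> structure residue_id."""
    mapping: dict[int, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            col, res = line.split("\t")
            mapping[int(col)] = int(res)
        except ValueError as exc:
            raise AlignmentFormatError(f"line {lineno}: {raw!r}") from exc
    return mapping
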