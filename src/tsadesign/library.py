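"""Mutant-library frequency analysis: representative and enriched mutations.

A design library is an ordered set of top-ranked mutant sequences over the
design positions, each with its objective energy. Frequency tables give the
per-position amino-acid composition of a library (or of pooled libraries);
the representativeness rule flags a (position, amino acid) mutation as
characteristic of one library when it is both common there (>= 15% by
default) and markedly more common than in the comparison libraries (>= 10
percentage points above the maximum over the others by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Literal, Sequence

from .constants import STANDARD_AA1

Objective = Literal["KM", "KCAT_OVER_KM", "KCAT"]


class LibraryParseError(ValueError):
    """Malformed library TSV."""


class LibrarySchemaError(ValueError):
    """Libraries being compared do not share the same design positions."""


@dataclass
class DesignLibrary:
    """Ranked mutant sequences over an ordered list of design positions."""

    name: str
    objective: Objective
    positions: list[int]
    mutants: list[tuple[int, float, str]]  # (rank, energy kJ/mol, sequence)
    wildtype: str
    wildtype_energy: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.positions)
        if len(self.wildtype) != n:
            raise LibraryParseError(
                f"{self.name}: wildtype length {len(self.wildtype)} != {n} positions"
            )
        ranks = [r for r, _e, _s in self.mutants]
        if len(set(ranks)) != len(ranks):
            raise LibraryParseError(f"{self.name}: duplicate ranks")
        for rank, _energy, seq in self.mutants:
            if len(seq) != n:
                raise LibraryParseError(
                    f"{self.name} rank {rank}: sequence length {len(seq)} != {n}"
                )

    @property
    def n_mutants(self) -> int:
        return len(self.mutants)

    def sequences(self) -> list[str]:
        return [seq for _r, _e, seq in self.mutants]


@dataclass
class FrequencyTable:
    """Exact per-position amino-acid fractions over n_mutants sequences."""

    positions: list[int]
    fractions: dict[tuple[int, str], Fraction]
    n_mutants: int

    def frequency(self, position: int, amino_acid: str) -> Fraction:
        return self.fractions.get((position, amino_acid.upper()), Fraction(0))


@dataclass
class RepresentativenessRule:
    """A mutation represents a library if its frequency there is at least
    ``min_frequency`` and exceeds the other libraries' frequency by at least
    ``margin`` (both inclusive). ``comparison`` selects whether the margin is
    taken against the max or the mean over the other libraries."""

    min_frequency: float = 0.15
    margin: float = 0.10
    comparison: Literal["max", "mean"] = "max"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_frequency <= 1.0):
            raise ValueError("min_frequency must be in (0, 1]")
        if self.margin < 0.0:
            raise ValueError("margin must be >= 0")


def _as_fraction(threshold: float) -> Fraction:
    """Exact rational view of a decimal threshold (0.15 -> 3/20), so that
    inclusive boundary comparisons like 3/10 - 2/10 >= 1/10 hold exactly."""
    return Fraction(threshold).limit_denominator(10**6)


def frequency_table(
    libraries: DesignLibrary | Sequence[DesignLibrary],
) -> FrequencyTable:
    """Per-position amino-acid fractions; a sequence of libraries is pooled
    by concatenating their mutant lists."""
    if isinstance(libraries, DesignLibrary):
        libraries = [libraries]
    if not libraries:
        raise ValueError("no libraries given")
    positions = libraries[0].positions
    for lib in libraries[1:]:
        if lib.positions != positions:
            raise LibrarySchemaError(f"{lib.name}: position mismatch when pooling")
    sequences = [seq for lib in libraries for seq in lib.sequences()]
    if not sequences:
        raise ValueError("empty library")
    n = len(sequences)
    fractions: dict[tuple[int, str], Fraction] = {}
    for col, pos in enumerate(positions):
        for seq in sequences:
            key = (pos, seq[col].upper())
            fractions[key] = fractions.get(key, Fraction(0)) + Fraction(1, n)
    return FrequencyTable(list(positions), fractions, n)


def representative_mutations(
    target: DesignLibrary,
    others: Sequence[DesignLibrary],
    rule: RepresentativenessRule = RepresentativenessRule(),
) -> set[tuple[int, str]]:
    """Mutations (position, amino acid) characteristic of ``target``.

    Wild-type residues are excluded: a representative *mutation* must differ
    from the wild-type residue at its position.
    """
    for lib in others:
        if lib.positions != target.positions:
            raise LibrarySchemaError(f"{lib.name}: position mismatch")
    ft_target = frequency_table(target)
    ft_others = [frequency_table(lib) for lib in others]
    wt = {pos: target.wildtype[i].upper() for i, pos in enumerate(target.positions)}
    min_freq = _as_fraction(rule.min_frequency)
    margin = _as_fraction(rule.margin)

    out: set[tuple[int, str]] = set()
    for (pos, aa), freq in ft_target.fractions.items():
        if aa == wt[pos]:
            continue
        if freq < min_freq:
            continue
        other_freqs = [ft.frequency(pos, aa) for ft in ft_others]
        if not other_freqs:
            reference = Fraction(0)
        elif rule.comparison == "max":
            reference = max(other_freqs)
        else:
            reference = sum(other_freqs, Fraction(0)) / len(other_freqs)
        if freq - reference >= margin:
            out.add((pos, aa))
    return out


def enriched_in_group_absent_in_group(
    group_a: Sequence[DesignLibrary],
    group_b: Sequence[DesignLibrary],
    present_threshold: float = 0.10,
    absent_threshold: float = 0.05,
) -> set[tuple[int, str]]:
    """Mutations at frequency >= present_threshold in *every* library of
    group A and <= absent_threshold in *every* library of group B."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    positions = group_a[0].positions
    for lib in list(group_a) + list(group_b):
        if lib.positions != positions:
            raise LibrarySchemaError(f"{lib.name}: position mismatch")
    tables_a = [frequency_table(lib) for lib in group_a]
    tables_b = [frequency_table(lib) for lib in group_b]
    wt = {pos: group_a[0].wildtype[i].upper() for i, pos in enumerate(positions)}
    present = _as_fraction(present_threshold)
    absent = _as_fraction(absent_threshold)

    candidates = {key for ft in tables_a for key in ft.fractions}
    out: set[tuple[int, str]] = set()
    for pos, aa in candidates:
        if aa == wt[pos]:
            continue
        if all(ft.frequency(pos, aa) >= present for ft in tables_a) and all(
            ft.frequency(pos, aa) <= absent for ft in tables_b
        ):
            out.add((pos, aa))
    return out


# ---------------------------------------------------------------------------
# TSV format: header lines then one mutant per row
#
#   # name: <name>
#   # objective: <KM|KCAT_OVER_KM|KCAT>
#   # positions: 162 163 ...
#   rank  energy  aa_162  aa_163 ...
#   WT    -489.4  H  D  ...
#   1     -1548.7 Q  D  ...


def parse_library_table(path: str | Path) -> DesignLibrary:
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    rows: list[tuple[str, float, str]] = []
    positions: list[int] = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            try:
                key, value = line.lstrip("# ").split(":", 1)
                meta[key.strip()] = value.strip()
            except ValueError:
                raise LibraryParseError(f"line {lineno}: bad header {line!r}")
            continue
        fields = line.split("\t")
        if fields[0] == "rank":
            try:
                positions = [int(f) for f in fields[2:]]
            except ValueError as exc:
                raise LibraryParseError(f"line {lineno}: bad position header") from exc
            continue
        if not positions:
            raise LibraryParseError(f"line {lineno}: data before column header")
        if len(fields) != 2 + len(positions):
            raise LibraryParseError(
                f"line {lineno}: expected {2 + len(positions)} fields, got {len(fields)}"
            )
        seq = "".join(f.strip().upper() for f in fields[2:])
        bad = set(seq) - STANDARD_AA1
        if bad:
            raise LibraryParseError(f"line {lineno}: non-standard residues {sorted(bad)}")
        try:
            rows.append((fields[0].strip(), float(fields[1]), seq))
        except ValueError as exc:
            raise LibraryParseError(f"line {lineno}: bad energy {fields[1]!r}") from exc

    wildtype_rows = [r for r in rows if r[0] == "WT"]
    if len(wildtype_rows) != 1:
        raise LibraryParseError(f"expected exactly one WT row, got {len(wildtype_rows)}")
    mutants = [(int(r), e, s) for r, e, s in rows if r != "WT"]
    return DesignLibrary(
        name=meta.get("name", Path(path).stem),
        objective=meta.get("objective", "KM"),  # type: ignore[arg-type]
        positions=positions,
        mutants=mutants,
        wildtype=wildtype_rows[0][2],
        wildtype_energy=wildtype_rows[0][1],
    )


def _fmt(energy: float) -> str:
    text = repr(energy)
    return text


def write_library_table(library: DesignLibrary, path: str | Path) -> None:
    lines = [
        f"# name: {library.name}",
        f"# objective: {library.objective}",
        "rank\tenergy\t" + "\t".join(str(p) for p in library.positions),
        f"WT\t{_fmt(library.wildtype_energy)}\t" + "\t".join(library.wildtype),
    ]
    for rank, energy, seq in library.mutants:
        lines.append(f"{rank}\t{_fmt(energy)}\t" + "\t".join(seq))
    Path(path).write_text("\n".join(lines) + "\n")
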