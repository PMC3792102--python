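"""Design-library frequencies, representativeness and enrichment rules."""

from fractions import Fraction

import pytest

from tsadesign import datasets
from tsadesign.library import (
    DesignLibrary,
    LibrarySchemaError,
    RepresentativenessRule,
    enriched_in_group_absent_in_group,
    frequency_table,
    parse_library_table,
    representative_mutations,
    write_library_table,
)

POSITIONS = [1, 2]
WT = "HW"


def lib(name, seqs, objective="KM"):
    return DesignLibrary(
        name=name, objective=objective, positions=POSITIONS,
        mutants=[(i + 1, -float(i), s) for i, s in enumerate(seqs)],
        wildtype=WT,
    )


class TestFrequencyTable:
    def test_single_mutant_library_is_all_one(self):
        table = frequency_table(lib("x", ["AG"]))
        assert table.frequency(1, "A") == 1
        assert table.frequency(2, "G") == 1

    def test_fractions_sum_to_one_per_position(self):
        table = frequency_table(lib("x", ["AG", "AW", "SW", "HG"]))
        for pos in POSITIONS:
            total = sum(
                frac for (p, _aa), frac in table.fractions.items() if p == pos
            )
            assert total == Fraction(1)

    def test_pooling_concatenates(self):
        pooled = frequency_table([lib("a", ["AG"]), lib("b", ["SG", "SW"])])
        assert pooled.n_mutants == 3
        assert pooled.frequency(1, "S") == Fraction(2, 3)

    def test_pooled_serine_frequencies_match_published_counts(self):
        """Pooling each substrate's three top-10 libraries, serine at design
        position 162 appears 4/30 times for the native-like substrate and
        11/30 for the galactoside target."""
        glu = frequency_table(list(datasets.design_libraries("pnp_glu").values()))
        gal = frequency_table(list(datasets.design_libraries("pnp_gal").values()))
        assert glu.frequency(162, "S") == Fraction(4, 30)
        assert gal.frequency(162, "S") == Fraction(11, 30)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            frequency_table(lib("x", []))


class TestRepresentativeMutations:
    def test_clearly_dominant_mutation_included(self):
        target = lib("t", ["AG", "AG", "AW", "HG", "AW", "AG", "AG", "AG", "AW", "AG"])
        other = lib("o", ["HG"] * 9 + ["AG"])  # A at 10% in the other library
        hits = representative_mutations(target, [other])
        assert (1, "A") in hits

    def test_margin_below_threshold_excluded(self):
        target = lib("t", ["AG", "AW", "HG", "HG", "HG", "HG", "HG", "HG", "HG", "HG"])
        other = lib("o", ["AG", "HG", "HG", "HG", "HG", "HG", "HG", "HG", "HG", "HG"])
        # target freq(A) = 0.2, other = 0.1 -> margin 0.1 (inclusive, kept);
        # tighten the rule and it drops out
        assert (1, "A") in representative_mutations(target, [other])
        assert (1, "A") not in representative_mutations(
            target, [other], RepresentativenessRule(margin=0.15))

    def test_wildtype_residue_never_reported(self):
        target = lib("t", ["HG"] * 10)  # H is the WT residue at position 1
        hits = representative_mutations(target, [lib("o", ["AG"] * 10)])
        assert all(aa != "H" for pos, aa in hits if pos == 1)

    def test_known_tryptophan_to_arginine_case(self):
        """W549R is found 60% of the time in the efficiency-optimized
        galactoside library but only 20% in the other two: representative."""
        libs = datasets.design_libraries("pnp_gal")
        hits = representative_mutations(
            libs["KCAT_OVER_KM"], [libs["KM"], libs["KCAT"]])
        assert (549, "R") in hits

    def test_order_invariance(self):
        seqs = ["AG", "AW", "SG", "AG", "HG", "AG", "AW", "AG", "SG", "AG"]
        shuffled = list(reversed(seqs))
        others = [lib("o", ["HG"] * 10)]
        assert representative_mutations(lib("t", seqs), others) == (
            representative_mutations(lib("t2", shuffled), others))

    def test_monotone_shrinkage(self):
        target = lib("t", ["AG", "AG", "AW", "SG", "SG", "HG", "HG", "HG", "AW", "SG"])
        others = [lib("o", ["HG"] * 10), lib("p", ["AG"] + ["HG"] * 9)]
        loose = representative_mutations(
            target, others, RepresentativenessRule(0.15, 0.10))
        tighter_freq = representative_mutations(
            target, others, RepresentativenessRule(0.30, 0.10))
        tighter_margin = representative_mutations(
            target, others, RepresentativenessRule(0.15, 0.25))
        assert tighter_freq <= loose and tighter_margin <= loose

    def test_max_vs_mean_comparison_modes(self):
        target = lib("t", ["AG"] * 3 + ["HG"] * 7)         # A at 30%
        others = [lib("o", ["AG"] * 2 + ["HG"] * 8),        # A at 20%
                  lib("p", ["HG"] * 10)]                    # A at 0%
        # margin vs max: 0.30 - 0.20 = 0.10 < 0.15 -> excluded
        # margin vs mean: 0.30 - 0.10 = 0.20 >= 0.15 -> included
        vs_max = representative_mutations(
            target, others, RepresentativenessRule(0.15, 0.15, "max"))
        vs_mean = representative_mutations(
            target, others, RepresentativenessRule(0.15, 0.15, "mean"))
        assert (1, "A") in vs_mean and (1, "A") not in vs_max

    def test_position_mismatch_rejected(self):
        bad = DesignLibrary("b", "KM", [3, 4], [(1, 0.0, "AG")], "HW")
        with pytest.raises(LibrarySchemaError):
            representative_mutations(lib("t", ["AG"]), [bad])

    def test_brute_force_scan_equivalence(self):
        """The rule output equals an exhaustive scan over every
        (position, amino acid) pair on the packaged fixtures."""
        for substrate in ("pnp_glu", "pnp_gal"):
            libs = list(datasets.design_libraries(substrate).values())
            for i, target in enumerate(libs):
                others = [l for j, l in enumerate(libs) if j != i]
                got = representative_mutations(target, others)
                expected = set()
                ft = frequency_table(target)
                fts = [frequency_table(o) for o in others]
                wt = dict(zip(target.positions, target.wildtype))
                for pos in target.positions:
                    for aa in "ACDEFGHIKLMNPQRSTVWY":
                        if aa == wt[pos]:
                            continue
                        f = ft.frequency(pos, aa)
                        fo = max(t.frequency(pos, aa) for t in fts)
                        if f >= Fraction(15, 100) and f - fo >= Fraction(10, 100):
                            expected.add((pos, aa))
                assert got == expected, (substrate, target.name)


class TestEnrichment:
    def test_present_everywhere_absent_everywhere(self):
        group_a = [lib("a1", ["AG"] * 5 + ["HG"] * 5), lib("a2", ["AG"] * 10)]
        group_b = [lib("b1", ["HG"] * 10), lib("b2", ["HW"] * 10)]
        hits = enriched_in_group_absent_in_group(group_a, group_b)
        assert (1, "A") in hits

    def test_presence_in_one_b_library_excludes(self):
        group_a = [lib("a1", ["AG"] * 5 + ["HG"] * 5)]
        group_b = [lib("b1", ["AG"] * 5 + ["HG"] * 5)]
        assert (1, "A") not in enriched_in_group_absent_in_group(group_a, group_b)

    def test_brute_force_scan_on_fixtures(self):
        """Defaults applied to galactoside-vs-glucuronide fixtures equal an
        exhaustive (position, aa) scan."""
        gal = list(datasets.design_libraries("pnp_gal").values())
        glu = list(datasets.design_libraries("pnp_glu").values())
        got = enriched_in_group_absent_in_group(gal, glu)
        tables_a = [frequency_table(l) for l in gal]
        tables_b = [frequency_table(l) for l in glu]
        wt = dict(zip(gal[0].positions, gal[0].wildtype))
        expected = set()
        for pos in gal[0].positions:
            for aa in "ACDEFGHIKLMNPQRSTVWY":
                if aa == wt[pos]:
                    continue
                if all(t.frequency(pos, aa) >= Fraction(10, 100) for t in tables_a) \
                        and all(t.frequency(pos, aa) <= Fraction(5, 100)
                                for t in tables_b):
                    expected.add((pos, aa))
        assert got == expected


class TestTableIO:
    def test_glucuronide_fixture_contents(self):
        km = datasets.design_library("pnp_glu", "KM")
        assert km.wildtype == "HDFVGLGWN"
        assert km.wildtype_energy == pytest.approx(-489.4)
        assert km.n_mutants == 10
        assert km.positions == [162, 163, 164, 355, 356, 361, 362, 549, 550]

    def test_galactoside_efficiency_wildtype_energy_positive(self):
        eff = datasets.design_library("pnp_gal", "KCAT_OVER_KM")
        assert eff.wildtype_energy == pytest.approx(90.1)

    def test_round_trip_is_identity(self, tmp_path):
        original = datasets.design_library("pnp_glu", "KCAT")
        path = tmp_path / "lib.tsv"
        write_library_table(original, path)
        back = parse_library_table(path)
        assert back.mutants == original.mutants
        assert back.wildtype == original.wildtype
        assert back.positions == original.positions
        assert back.objective == original.objective

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("rank\tenergy\t1\t2\n1\tnot_a_number\tA\tG\n")
        from tsadesign.library import LibraryParseError
        with pytest.raises(LibraryParseError, match="line 2"):
            parse_library_table(path)
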