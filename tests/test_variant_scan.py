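"""Diagnostic SNP discovery, heterozygosity profiling and panel voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesamarker.core_io import Alignment, SequenceRecord
from mesamarker.variant_scan import (
    alignment_to_matrix,
    classify_individual,
    expand_iupac,
    find_diagnostic_snps,
    heterozygosity_profile,
)

from conftest import IUPAC_SETS, brute_force_diagnostic, make_matrix, random_matrix


class TestExpandIupac:
    @pytest.mark.parametrize("code,alleles,zygosity", [
        ("S", {"G", "C"}, "heterozygous"),
        ("A", {"A"}, "homozygous"),
        ("K", {"G", "T"}, "heterozygous"),
        ("B", {"C", "G", "T"}, "heterozygous"),
        (".", set(), "missing"),
    ])
    def test_expansion_and_zygosity(self, code, alleles, zygosity):
        call = expand_iupac(code)
        assert set(call.alleles) == alleles
        assert call.zygosity == zygosity

    def test_full_standard_table(self):
        for code, alleles in IUPAC_SETS.items():
            assert set(expand_iupac(code).alleles) == alleles

    def test_n_flagged_uninformative(self):
        call = expand_iupac("N")
        assert call.zygosity == "heterozygous" and call.uninformative

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            expand_iupac("Z")


class TestAlignmentToMatrix:
    @staticmethod
    def _aln(seqs, groups):
        return Alignment([
            SequenceRecord(id=f"s{i}", residues=s, group=g)
            for i, (s, g) in enumerate(zip(seqs, groups))
        ])

    def test_polymorphic_column_detected(self):
        m = alignment_to_matrix(self._aln(["AC", "AG"], ["high", "low"]))
        assert m.positions == [2]
        assert m.calls == [["C", "G"]]

    def test_identical_alignment_yields_empty_matrix(self):
        m = alignment_to_matrix(self._aln(["ACGT", "ACGT"], ["high", "low"]))
        assert m.positions == []

    def test_heterozygous_column_is_polymorphic(self):
        # a column that is all 'S' still segregates two alleles
        m = alignment_to_matrix(self._aln(["AS", "AS"], ["high", "low"]))
        assert m.positions == [2]

    def test_protein_alignment_rejected(self):
        aln = Alignment([
            SequenceRecord(id="a", residues="MK", moltype="protein"),
            SequenceRecord(id="b", residues="MR", moltype="protein"),
        ])
        with pytest.raises(ValueError):
            alignment_to_matrix(aln)

    def test_fixture_planting_round_trip(self, table2):
        """Sequences built by planting fixture calls on a constant background
        collapse back to the fixture, cell by cell."""
        length = 400
        background = "A" * length
        records = []
        for j, ind in enumerate(table2.individuals):
            seq = list(background)
            for i, pos in enumerate(table2.positions):
                seq[pos - 1] = table2.calls[i][j]
            records.append(SequenceRecord(id=ind.id, residues="".join(seq),
                                          species_code=ind.species_code, group=ind.group))
        m = alignment_to_matrix(Alignment(records))
        assert m.positions == table2.positions
        assert m.calls == table2.calls


class TestHeterozygosityProfile:
    def test_low_group_has_no_heterozygous_calls(self, table2):
        prof = heterozygosity_profile(table2, group="low")
        assert prof["total"] == 0
        assert all(c == 0 for c in prof["per_position"].values())

    def test_med_heterozygous_at_every_position(self, table2):
        prof = heterozygosity_profile(table2, species="med")
        assert prof["het_positions"] == set(table2.positions)

    def test_high_group_excluding_med_het_positions(self, table2):
        """Recomputed from the printed calls: without B. medwediewii the high
        group shows heterozygous sites at three of the six positions."""
        per_species = [heterozygosity_profile(table2, species=sp)["het_positions"]
                       for sp in ("ale", "len", "bg")]
        assert set.union(*per_species) == {160, 189, 304}

    def test_homozygous_matrix_all_zero(self):
        m = make_matrix({1: "ACGT", 9: "TTAA"}, "hhll")
        prof = heterozygosity_profile(m, group="high")
        assert prof["total"] == 0 and prof["het_positions"] == set()

    def test_unknown_subset_rejected(self, table2):
        with pytest.raises(ValueError):
            heterozygosity_profile(table2, species="nope")


class TestFindDiagnosticSnps:
    def test_fixture_reproduces_six_markers(self, table2):
        markers = find_diagnostic_snps(table2, "high", theta=0.9,
                                       require_contrast_fixed=True)
        assert [(m.position, m.diagnostic_allele) for m in markers] == [
            (160, "C"), (189, "A"), (262, "T"), (298, "G"), (304, "G"), (336, "A"),
        ]
        assert all(m.carrier_count_contrast == 0 for m in markers)

    def test_fixture_carrier_counts(self, table2):
        # frozen from the brute-force oracle run on the expanded table
        markers = find_diagnostic_snps(table2, "high", theta=0.9,
                                       require_contrast_fixed=True)
        counts = {m.position: m.carrier_count_target for m in markers}
        assert counts == {160: 20, 189: 19, 262: 19, 298: 18, 304: 19, 336: 20}

    def test_fixture_theta_one_keeps_fully_penetrant_positions(self, table2):
        markers = find_diagnostic_snps(table2, "high", theta=1.0,
                                       require_contrast_fixed=True)
        assert [m.position for m in markers] == [160, 336]

    def test_no_marker_when_groups_share_fixed_base(self):
        m = make_matrix({1: "AAAA", 7: "CCCC"}, "hhll")
        assert find_diagnostic_snps(m, "high", 0.9, True) == []

    def test_heterozygous_carrier_counts_as_carrying(self):
        # S carries C against a G-fixed contrast
        m = make_matrix({3: "SCGG"}, "hhll")
        (marker,) = find_diagnostic_snps(m, "high", 1.0, True)
        assert marker.diagnostic_allele == "C"
        assert marker.penetrance == 1.0

    def test_missing_calls_shrink_denominator(self):
        m = make_matrix({3: "C.GG"}, "hhll")
        (marker,) = find_diagnostic_snps(m, "high", 1.0, True)
        assert marker.n_target == 1 and marker.penetrance == 1.0

    def test_contrast_n_does_not_defeat_absence(self):
        # N in the contrast group is uninformative, not a universal carrier
        m = make_matrix({3: "CCNG"}, "hhll")
        (marker,) = find_diagnostic_snps(m, "high", 1.0, True)
        assert marker.diagnostic_allele == "C"
        assert marker.n_contrast == 1

    def test_symmetry_under_group_relabeling_when_fixed(self):
        m = make_matrix({3: "CCGG"}, "hhll")
        (hi,) = find_diagnostic_snps(m, "high", 1.0, True)
        (lo,) = find_diagnostic_snps(m, "low", 1.0, True)
        assert (hi.diagnostic_allele, lo.diagnostic_allele) == ("C", "G")

    def test_empty_group_rejected(self):
        m = make_matrix({3: "CC"}, "hh")
        with pytest.raises(ValueError):
            find_diagnostic_snps(m, "high", 0.9, True)

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            m = random_matrix(rng)
            theta = float(rng.choice([0.5, 0.75, 0.9, 1.0]))
            fixed = bool(rng.integers(2))
            got = {mk.position: mk.diagnostic_allele
                   for mk in find_diagnostic_snps(m, "high", theta, fixed)}
            assert got == brute_force_diagnostic(m, "high", theta, fixed)

    def test_theta_monotonicity_on_fixture(self, table2):
        counts = [
            len(find_diagnostic_snps(table2, "high", th, True))
            for th in (0.5, 0.7, 0.9, 0.95, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_theta_monotonicity_property(self, data):
        seed = data.draw(st.integers(0, 10_000))
        m = random_matrix(np.random.default_rng(seed))
        counts = [len(find_diagnostic_snps(m, "high", th, False))
                  for th in (0.2, 0.5, 0.8, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestClassifyIndividual:
    @pytest.fixture()
    def panel(self, table2):
        return find_diagnostic_snps(table2, "high", 0.9, True)

    def test_med_column_votes_target(self, panel):
        calls = dict(zip([160, 189, 262, 298, 304, 336], "SRWRKR"))
        res = classify_individual(panel, calls, "med_x")
        assert (res.votes_for_target, res.verdict) == (6, "target")

    def test_pen_column_votes_contrast(self, panel):
        calls = dict(zip([160, 189, 262, 298, 304, 336], "GGAATG"))
        res = classify_individual(panel, calls, "pen_x")
        assert (res.votes_for_target, res.verdict) == (0, "contrast")

    def test_low_coverage_is_ambiguous(self, panel):
        res = classify_individual(panel, {160: "C", 189: "A"})
        assert res.verdict == "ambiguous"

    def test_tie_is_ambiguous(self, panel):
        calls = {160: "C", 189: "A", 262: "A", 298: "A"}
        res = classify_individual(panel, calls)
        assert res.votes_for_target == 2 and res.verdict == "ambiguous"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            classify_individual([], {1: "A"})

    def test_no_covered_position_rejected(self, panel):
        with pytest.raises(ValueError):
            classify_individual(panel, {999: "A"})
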