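"""Mature-peptide calling: parsing, filters, combination, selection."""

import numpy as np
import pandas as pd
import pytest

from espdisc.peptide_calls import (
    MasterProteinEntry,
    PeptideIsoform,
    assign_truncations,
    call_mature_peptides,
    combine_isoforms,
    filter_confidence,
    filter_odd_dehydro,
    final_filter,
    parse_master_table,
    parse_modifications,
    parse_peptide_table,
    select_candidate_mature,
)


def iso(backbone, masters, abundance=1e6, psms=1, mods=(), confidence="High"):
    return PeptideIsoform(
        backbone=backbone,
        modifications=tuple(mods),
        abundance=abundance,
        psm_count=psms,
        confidence=confidence,
        master_accessions=tuple(masters),
    )


def master(acc, confidence="High", psms=5, has_stop=True):
    return MasterProteinEntry(acc, confidence, psms, has_stop)


class TestParsing:
    def test_single_exclusive_row(self):
        df = pd.DataFrame(
            [
                {
                    "Sequence": "GLLDTFK",
                    "Modifications": "",
                    "Abundance": "1e6",
                    "# PSMs": "4",
                    "Confidence": "High",
                    "Master Protein Accessions": "P1",
                }
            ]
        )
        (p,) = parse_peptide_table(df)
        assert p.backbone == "GLLDTFK" and p.is_exclusive and p.psm_count == 4

    def test_modification_dialect(self):
        assert parse_modifications("2xDehydro [C]; 1xDeamidated [N]") == (
            ("Dehydro", "C", 2),
            ("Deamidated", "N", 1),
        )

    def test_multi_accession_cell_not_exclusive(self):
        df = pd.DataFrame(
            [{"Sequence": "AA", "Modifications": "", "Abundance": "1",
              "# PSMs": "1", "Confidence": "High",
              "Master Protein Accessions": "P1; P2"}]
        )
        (p,) = parse_peptide_table(df)
        assert p.master_accessions == ("P1", "P2") and not p.is_exclusive

    def test_missing_column_named(self):
        df = pd.DataFrame([{"Sequence": "AA"}])
        with pytest.raises(ValueError, match="Abundance"):
            parse_peptide_table(df)

    def test_non_numeric_abundance_is_row_level_error(self):
        df = pd.DataFrame(
            [{"Sequence": "AA", "Modifications": "", "Abundance": "oops",
              "# PSMs": "1", "Confidence": "High",
              "Master Protein Accessions": "P1"}]
        )
        with pytest.raises(ValueError, match="row 0"):
            parse_peptide_table(df)

    def test_master_table_requires_stop_information(self):
        df = pd.DataFrame([{"Accession": "P1", "FDR Confidence": "High", "# PSMs": "3"}])
        with pytest.raises(ValueError, match="has_stop"):
            parse_master_table(df)
        (m,) = parse_master_table(df, has_stop={"P1": True})
        assert m.has_stop


class TestConfidenceFilter:
    def test_peptide_stranded_by_removed_master_disappears(self):
        isoforms = [iso("AAA", ["P2"])]
        masters = [master("P1"), master("P2", confidence="Low")]
        kept, kept_masters = filter_confidence(isoforms, masters)
        assert kept == [] and [m.accession for m in kept_masters] == ["P1"]

    def test_shared_peptide_becomes_exclusive(self):
        isoforms = [iso("AAA", ["P1", "P2"])]
        masters = [master("P1"), master("P2", confidence="Low")]
        (kept,), _ = filter_confidence(isoforms, masters)
        assert kept.master_accessions == ("P1",) and kept.is_exclusive

    def test_all_high_is_identity(self):
        isoforms = [iso("AAA", ["P1"])]
        masters = [master("P1")]
        assert filter_confidence(isoforms, masters) == (isoforms, masters)


class TestDehydroFilter:
    @pytest.mark.parametrize(
        "mods,kept",
        [
            ((("Dehydro", "C", 2),), True),
            ((("Dehydro", "C", 1),), False),
            ((), True),
            ((("Dehydro", "C", 1), ("Dehydro", "C", 2)), False),
            ((("Deamidated", "N", 1),), True),
        ],
    )
    def test_odd_cys_dehydro_removed(self, mods, kept):
        result = filter_odd_dehydro([iso("AAA", ["P1"], mods=mods)])
        assert bool(result) is kept

    def test_filter_order_invariance_with_confidence(self):
        isoforms = [
            iso("AAA", ["P1"], mods=(("Dehydro", "C", 1),)),
            iso("CCC", ["P2"]),
        ]
        masters = [master("P1"), master("P2", confidence="Medium")]
        a = filter_odd_dehydro(filter_confidence(isoforms, masters)[0])
        b, _ = filter_confidence(filter_odd_dehydro(isoforms), masters)
        assert a == b


class TestCombine:
    def test_additivity(self):
        combined = combine_isoforms(
            [iso("AAA", ["P1"], abundance=3e5, psms=2), iso("AAA", ["P1"], abundance=7e5, psms=3)]
        )
        assert len(combined) == 1
        assert combined[0].abundance == pytest.approx(1e6)
        assert combined[0].psm_count == 5

    def test_different_master_sets_stay_separate(self):
        combined = combine_isoforms([iso("AAA", ["P1"]), iso("AAA", ["P1", "P2"])])
        assert len(combined) == 2

    def test_single_isoform_unchanged(self):
        one = [iso("AAA", ["P1"])]
        assert combine_isoforms(one) == one

    def test_psm_conservation(self):
        rng = np.random.default_rng(0)
        isoforms = [
            iso(f"PEP{rng.integers(3)}", [f"P{rng.integers(2)}"], psms=int(rng.integers(1, 5)))
            for _ in range(30)
        ]
        combined = combine_isoforms(isoforms)
        assert sum(i.psm_count for i in combined) == sum(i.psm_count for i in isoforms)


class TestSelection:
    def test_max_abundance_wins(self):
        calls = select_candidate_mature(
            [master("P1")],
            [iso("AAAA", ["P1"], abundance=9e5), iso("BBBB", ["P1"], abundance=4e5)],
        )
        assert [c.backbone for c in calls] == ["AAAA"]

    def test_tie_broken_by_length_then_lexicographic(self):
        long33, short20 = "L" * 33, "S" * 20
        calls = select_candidate_mature(
            [master("P1")],
            [iso(short20, ["P1"], abundance=5e5), iso(long33, ["P1"], abundance=5e5)],
        )
        assert calls[0].backbone == long33
        calls = select_candidate_mature(
            [master("P1")],
            [iso("BBB", ["P1"], abundance=5e5), iso("AAA", ["P1"], abundance=5e5)],
        )
        assert calls[0].backbone == "AAA"

    def test_only_shared_peptides_yields_no_call(self):
        assert select_candidate_mature([master("P1")], [iso("AAA", ["P1", "P2"])]) == []


class TestFinalFilter:
    def test_low_psm_single_master_removed(self):
        calls = select_candidate_mature([master("P1", psms=2)], [iso("AAA", ["P1"])])
        assert final_filter(calls, [master("P1", psms=2)]) == []

    def test_conjunctive_semantics_removes_split_evidence(self):
        # one master passes the PSM bar, a different one the stop bar:
        # removed under the conjunctive reading, kept under "independent"
        from espdisc.peptide_calls import MaturePeptideCall

        masters = [master("M1", psms=1), master("M2", psms=5, has_stop=False)]
        call = MaturePeptideCall("AAA", ("M1", "M2"), 1.0, 6)
        assert final_filter([call], masters, semantics="conjunctive") == []
        assert final_filter([call], masters, semantics="independent") == [call]

    def test_passing_master_keeps_call(self):
        masters = [master("P1", psms=4)]
        call = select_candidate_mature(masters, [iso("AAA", ["P1"])])
        assert final_filter(call, masters) == call

    def test_unknown_master_is_an_error(self):
        from espdisc.peptide_calls import MaturePeptideCall

        with pytest.raises(ValueError, match="ghost"):
            final_filter([MaturePeptideCall("AAA", ("ghost",), 1.0, 3)], [master("P1")])

    def test_unknown_semantics_rejected(self):
        with pytest.raises(ValueError):
            final_filter([], [], semantics="nonsense")


class TestTruncations:
    def test_substring_counts_nonsubstring_unplaced(self):
        mature = "GLLDTFKNLALNAAKSAGVSVLNSLSCKLSKTC"
        combined = [
            iso(mature, ["P1"], abundance=1e6),
            iso("LLDTFKNL", ["P1"], abundance=1e5),
            iso("WWWWW", ["P1"], abundance=1e4),
        ]
        call = select_candidate_mature([master("P1")], combined)[0]
        call = assign_truncations(call, combined)
        assert call.truncated_forms == ["LLDTFKNL"]
        assert call.unplaced == ["WWWWW"]

    def test_ladder_count_matches_fixture(self, population):
        calls = call_mature_peptides(
            parse_peptide_table(population.peptide_table),
            parse_master_table(population.master_table),
        )
        truth = population.truth["calls"]
        assert len(calls) == len(population.precursors)
        for call in calls:
            expected = truth[call.master_accessions[0]]
            assert call.backbone == expected["mature"]
            assert call.n_truncated == expected["n_truncated"]

    def test_abundance_and_length_dominance(self, population):
        """Every surviving call out-weighs and out-spans its truncations."""
        calls = call_mature_peptides(
            parse_peptide_table(population.peptide_table),
            parse_master_table(population.master_table),
        )
        combined = combine_isoforms(
            filter_odd_dehydro(parse_peptide_table(population.peptide_table))
        )
        by_key = {(i.backbone, i.master_accessions): i.abundance for i in combined}
        for call in calls:
            for trunc in call.truncated_forms:
                t_ab = by_key[(trunc, call.master_accessions)]
                assert call.abundance > t_ab
                assert len(call.backbone) > len(trunc)
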