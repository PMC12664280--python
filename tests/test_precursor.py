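"""Precursor matching, extraction and structural annotation."""

import numpy as np
import pytest

from espdisc import catalog, seqset
from espdisc.precursor import (
    annotate_precursor,
    classify_source,
    detect_rana_box,
    extract_candidates,
    filter_mature_length,
    infer_processing_site,
    match_full_length,
    name_orphans,
    select_orf_variant,
    split_by_signal,
    PrecursorAnnotation,
)
from espdisc.sigpred import SignalPrediction, heuristic_predict


def make_set(mapping, name="SPS", has_stop=True):
    ps = seqset.ProteinSet(name=name)
    for pid, seq in mapping.items():
        ps.add(seqset.ProteinRecord(id=pid, sequence=seq, has_stop=has_stop))
    return ps


class TestMatching:
    def test_simple_occurrence(self):
        (m,) = match_full_length([("q", "ACD")], make_set({"s": "WWACDY"}))
        assert (m.start, m.end, m.subject_id) == (3, 5, "s")

    def test_one_mismatch_is_no_match(self):
        assert match_full_length([("q", "ACE")], make_set({"s": "WWACDY"})) == []

    def test_overlapping_occurrences_all_reported(self):
        ms = match_full_length([("q", "AA")], make_set({"s": "AAAA"}))
        assert [(m.start, m.end) for m in ms] == [(1, 2), (2, 3), (3, 4)]

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            match_full_length([("q", "")], make_set({"s": "AAAA"}))

    def test_validated_mature_peptide_found_in_its_master(self):
        # synthetic precursor packaging the validated brevinin-2GRa mature
        entry = next(e for e in catalog.DEMO_CATALOG if e.name == "brevinin-2GRa")
        precursor_seq = (
            "MFTLKKSLLLLFFLGTISLSLC" + "EQERDADEDDGGEMTEEEVKR" + entry.mature
        )
        sps = make_set({"TRINITY_DN0_c1_g1_i14.p1": precursor_seq, "other": "M" + "G" * 40})
        matches = match_full_length([(entry.name, entry.mature)], sps)
        assert len(matches) == 1
        assert "TRINITY_DN0_c1_g1_i14.p1" in matches[0].subject_id

    def test_equivalence_with_brute_force_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            subjects = {
                f"s{i}": "".join(rng.choice(list("AB"), size=rng.integers(5, 13)))
                for i in range(4)
            }
            query = "".join(rng.choice(list("AB"), size=rng.integers(1, 5)))
            got = {
                (m.subject_id, m.start, m.end)
                for m in match_full_length([("q", query)], make_set(subjects))
            }
            expected = {
                (sid, i + 1, i + len(query))
                for sid, s in subjects.items()
                for i in range(len(s) - len(query) + 1)
                if s[i : i + len(query)] == query
            }
            assert got == expected


class TestCandidateExtraction:
    def test_length_boundary_is_strict(self):
        osps = make_set({"a": "M" * 249, "b": "M" * 250}, name="OSPS")
        kept = extract_candidates(osps, matched_ids=[])
        assert [r.id for r in kept.records] == ["a"]

    def test_no_stop_removed(self):
        osps = make_set({"a": "M" * 80}, name="OSPS", has_stop=False)
        assert len(extract_candidates(osps, [])) == 0

    def test_matched_ids_excluded(self):
        osps = make_set({"a": "M" * 80, "b": "C" * 80}, name="OSPS")
        kept = extract_candidates(osps, ["a"])
        assert [r.id for r in kept.records] == ["b"]


class TestSignalSplit:
    def test_partition_restores_input(self):
        seq = "A" * 70
        signal, inter = split_by_signal(seq, SignalPrediction("x", True, 22, 0.9))
        assert len(signal) == 22 and len(inter) == 48 and signal + inter == seq

    def test_leu_cys_junction_convention(self):
        """The cleavage dipeptide spans the signal's last two residues."""
        seq = "MFTLKKSLLLLFFLGTISLSLC" + "DEDEDEKR" + "GLLSGILGAGKHIVSGLSGL"
        pred = heuristic_predict(seq)
        signal, inter = split_by_signal(seq, pred)
        assert signal.endswith("LC") and inter.startswith("D")

    def test_negative_prediction_is_error(self):
        with pytest.raises(ValueError):
            split_by_signal("A" * 30, SignalPrediction("x", False, 0, 0.1))

    def test_unplaced_cleavage_is_error(self):
        with pytest.raises(ValueError):
            split_by_signal("A" * 30, SignalPrediction("x", True, 0, 0.9))


class TestProcessingSite:
    def test_dibasic_site_before_hint(self):
        inter = "EEANEE" + "KR" + "GLLDTFKNLA"
        ps = infer_processing_site(inter, mature_hint="GLLDTFKNLA")
        assert ps.site == "KR" and ps.mature_start == 9
        assert ps.propiece_span == (1, 8)

    def test_hint_dominates_over_earlier_site(self):
        inter = "EEKR" + "AAAA" + "KR" + "GLLDTF"
        ps = infer_processing_site(inter, mature_hint="GLLDTF")
        assert ps.mature_start == len(inter) - 6 + 1 and ps.site == "KR"

    def test_no_basic_residues_flags_unprocessed(self):
        ps = infer_processing_site("QQQQNNNN")
        assert ps.unprocessed and ps.mature_start == 1 and ps.propiece_span is None

    def test_scan_prefers_kr_over_kk(self):
        inter = "EE" + "KK" + "AAAA" + "KR" + "GLDTFNAL"
        ps = infer_processing_site(inter)
        assert ps.site == "KR"

    def test_single_arg_only_as_fallback(self):
        inter = "EEER" + "GLDTFNALQ"
        ps = infer_processing_site(inter)
        assert ps.site == "R" and ps.mature_start == 5

    def test_downstream_length_window_respected(self):
        # the only dibasic site leaves a 2-residue mature: not a valid site
        ps = infer_processing_site("EEEEKRGG")
        assert ps.site != "KR" or ps.unprocessed


class TestRanaBox:
    @pytest.mark.parametrize(
        "mature,expected",
        [
            ("FLPLLAGLAANFLPKLFCKITKKC", (18, 24)),
            ("IAVNIPFKVHFRCKAAFC", (13, 18)),
            ("GLGGGGGG", None),
            ("GGGGGGGGC", None),  # single Cys: no loop
        ],
    )
    def test_hand_counted_positions(self, mature, expected):
        assert detect_rana_box(mature) == expected

    def test_all_catalog_matures_carry_a_rana_box(self):
        for entry in catalog.DEMO_CATALOG:
            box = detect_rana_box(entry.mature)
            assert box is not None, entry.name
            c1, c2 = box
            assert entry.mature[c1 - 1] == "C" and entry.mature[c2 - 1] == "C"
            assert 3 <= c2 - c1 - 1 <= 8


class TestMatureLengthFilter:
    @staticmethod
    def ann(*mature_spans):
        return PrecursorAnnotation(
            protein_id="p",
            signal_span=(1, 20),
            propiece_span=None,
            processing_site="",
            mature_spans=list(mature_spans),
            residual_span=None,
            has_stop=True,
        )

    def test_boundary_cases(self):
        kept = filter_mature_length(
            [self.ann((21, 121)), self.ann((21, 120)), self.ann((21, 140), (141, 220))]
        )
        # 101 aa removed; 100 aa kept; (120, 80) kept via the 80-aa mature
        assert [a.mature_spans for a in kept] == [[(21, 120)], [(21, 140), (141, 220)]]


class TestStartSiteChoice:
    preds = {
        "P": SignalPrediction("P", False, 0, 0.1),
        "P_ORF1": SignalPrediction("P_ORF1", True, 20, 0.9),
        "P_ORF2": SignalPrediction("P_ORF2", True, 18, 0.9),
    }

    def test_motif_match_wins(self):
        series = [("P", "MA" + "X" * 60), ("P_ORF1", "MFT" + "A" * 50), ("P_ORF2", "MAL" + "A" * 40)]
        assert select_orf_variant(series, self.preds, "MFT")[0] == "P_ORF1"

    def test_longest_secretory_without_motif(self):
        series = [("P_ORF1", "MFT" + "A" * 65), ("P_ORF2", "MAL" + "A" * 48)]
        assert select_orf_variant(series, self.preds)[0] == "P_ORF1"

    def test_single_positive(self):
        series = [("P", "MA" + "A" * 30), ("P_ORF1", "MFT" + "A" * 25)]
        assert select_orf_variant(series, self.preds)[0] == "P_ORF1"

    def test_no_secretory_member_is_error(self):
        with pytest.raises(ValueError):
            select_orf_variant([("P", "MA" + "A" * 30)], self.preds)


class TestSourceClassification:
    og = ["AAAACDEF", "GGGGCDEF"]
    od = ["MMMMCDEF"]
    of = ["WWWWCDEF"]

    @staticmethod
    def similar_if_shared_suffix(query, subjects):
        return any(s[-4:] == query[-4:] for s in subjects)

    def test_exact_tiers(self):
        assert classify_source("AAAACDEF", self.og, self.od, self.of) == "OG"
        assert classify_source("MMMMCDEF", [], self.od, self.of) == "OD"
        assert classify_source("WWWWCDEF", [], [], self.of) == "OF"

    def test_similarity_suffix_with_tier_priority(self):
        assert (
            classify_source("KKKKCDEF", self.og, self.od, self.of, self.similar_if_shared_suffix)
            == "OGP"
        )
        assert (
            classify_source("KKKKCDEF", [], [], self.of, self.similar_if_shared_suffix)
            == "OFP"
        )

    def test_no_hit_is_orphan(self):
        assert classify_source("KKKKNNNN", self.og, self.od, self.of, self.similar_if_shared_suffix) == "Orphan"

    def test_empty_catalogs_warn_and_orphan(self):
        assert classify_source("AAAA", [], [], []) == "Orphan"

    def test_orphan_naming_is_sequential_and_sorted(self):
        assert name_orphans(["b", "a", "c"]) == {
            "a": "odorranain-X1",
            "b": "odorranain-X2",
            "c": "odorranain-X3",
        }
        assert name_orphans([]) == {}


class TestAnnotationPartition:
    def test_spans_tile_simulated_precursors(self, population, predictor):
        """signal+propiece+mature tile every simulated precursor exactly."""
        for prec in population.precursors:
            record = seqset.ProteinRecord(
                id=prec.protein_id, sequence=prec.true_protein, has_stop=True
            )
            ann = annotate_precursor(record, predictor(record.id, record.sequence))
            spans = [ann.signal_span]
            if ann.propiece_span:
                spans.append(ann.propiece_span)
            spans.extend(ann.mature_spans)
            if ann.residual_span:
                spans.append(ann.residual_span)
            covered = []
            for start, end in spans:
                covered.extend(range(start, end + 1))
            assert covered == list(range(1, len(prec.true_protein) + 1))

    def test_ground_truth_recovery(self, population, predictor):
        hits = 0
        for prec in population.precursors:
            record = seqset.ProteinRecord(
                id=prec.protein_id, sequence=prec.true_protein, has_stop=True
            )
            ann = annotate_precursor(record, predictor(record.id, record.sequence))
            if (
                ann.signal_span == prec.signal_span
                and ann.propiece_span == prec.propiece_span
                and ann.mature_spans == [prec.mature_span]
                and ann.rana_box == prec.rana_box
            ):
                hits += 1
        assert hits / len(population.precursors) >= 0.95
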