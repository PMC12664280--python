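"""End-to-end orchestration: transcript-level sets, peptide calls, matching,
annotation and the in-repo homology passes, with a JSON counts report.

The stages mirror the discovery workflow: (green) build FPS/OSPS/SPS from
the predicted proteins and the abundance table; (blue) call mature peptides
from the peptide/master tables; (yellow) match called matures into the SPS,
extract unmatched short candidates from the OSPS, annotate precursor
structure (choosing the start site within each truncation series) and
classify provenance against reference catalogs.  Outputs are byte-stable
for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import catalog, homology, io, peptide_calls, precursor, seqset, sigpred

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the workflow; defaults are the standard values."""

    proteins: str = "proteins.fasta"
    abundance: str = "abundance.tsv"
    peptides: Optional[str] = "peptides.tsv"
    masters: Optional[str] = "masters.tsv"
    out_dir: str = "out"
    predictor: str = "heuristic"          # "heuristic" | "signalp5_file"
    signalp_file: Optional[str] = None
    min_len: int = 20
    min_reads: float = 1.0
    candidate_max_len: int = 250
    mature_max_len: int = 100
    psm_min: int = 3
    short_query_cutoff: int = 30
    final_filter_semantics: str = "conjunctive"
    start_motif: str = "MFT"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_len", "candidate_max_len", "mature_max_len", "psm_min", "short_query_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _make_predictor(config: PipelineConfig):
    if config.predictor == "heuristic":
        return sigpred.HeuristicPredictor()
    if config.predictor == "signalp5_file":
        if not config.signalp_file:
            raise ValueError("predictor 'signalp5_file' requires signalp_file")
        return sigpred.SignalP5TablePredictor.from_path(config.signalp_file)
    raise ValueError(f"unknown predictor: {config.predictor!r}")


def _similarity_predicate(searcher: homology.LocalSearch):
    def similar(query: str, subjects) -> bool:
        hits = searcher.search("q", query, [(f"s{i}", s) for i, s in enumerate(subjects)])
        return any(h.percent_identity < 100.0 or h.alignment_length < len(query) for h in hits)

    return similar


def run_pipeline(config: PipelineConfig, base_dir=".") -> dict:
    """Execute all stages and write FASTA/TSV/JSON outputs under ``out_dir``.

    Returns the counts report.  Missing peptide tables degrade gracefully to
    transcript-level-only mode, noted in the report.
    """
    base = Path(base_dir)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    # --- transcript level -------------------------------------------------
    proteins = io.read_protein_fasta(base / config.proteins)
    abundance = io.read_abundance(base / config.abundance)
    predictor = _make_predictor(config)

    fps = seqset.build_fps(proteins, abundance, config.min_reads, config.min_len)
    osps = seqset.build_osps(fps, predictor, config.min_len)
    sps = seqset.build_sps(fps, osps)
    io.write_fasta(fps.fasta_items(), out / "fps.fasta")
    io.write_fasta(osps.fasta_items(), out / "osps.fasta")
    io.write_fasta(sps.fasta_items(), out / "sps.fasta")

    secretory_in_fps = sum(
        1 for rec in fps.records if predictor(rec.id, rec.sequence).is_secretory
    )
    osps_nonredundant = seqset.count_nonredundant_secretory(osps)
    report.update(
        fps_size=len(fps),
        secretory_in_fps=secretory_in_fps,
        osps_size=len(osps),
        osps_nonredundant=osps_nonredundant,
        sps_size=len(sps),
        novel_osps=len(sps) - len(fps),
        sps_increase_percent=(
            seqset.percent_increase(len(fps), len(sps)) if len(fps) else None
        ),
        secretory_increase_percent=(
            seqset.percent_increase(secretory_in_fps, osps_nonredundant)
            if secretory_in_fps
            else None
        ),
    )
    report["stages"].append("transcript-level sets")

    # --- protein level ----------------------------------------------------
    calls: list[peptide_calls.MaturePeptideCall] = []
    peptide_path = base / config.peptides if config.peptides else None
    master_path = base / config.masters if config.masters else None
    if peptide_path and master_path and peptide_path.exists() and master_path.exists():
        isoforms = peptide_calls.parse_peptide_table(peptide_path)
        masters = peptide_calls.parse_master_table(master_path)
        calls = peptide_calls.call_mature_peptides(
            isoforms,
            masters,
            semantics=config.final_filter_semantics,
            min_psms=config.psm_min,
        )
        peptide_calls.write_call_report(calls, out / "mature_peptides.tsv")
        report["n_mature_calls"] = len(calls)
        report["n_truncated_total"] = sum(c.n_truncated for c in calls)
        report["stages"].append("mature-peptide calls")
    else:
        report["n_mature_calls"] = 0
        report["stages"].append("transcript-level-only mode (no peptide table)")

    # --- integration ------------------------------------------------------
    queries = [(c.master_accessions[0], c.backbone) for c in calls]
    queries += [(e.name, e.mature) for e in catalog.DEMO_CATALOG]
    matches = precursor.match_full_length(queries, sps) if queries else []
    matched_subjects = sorted({m.subject_id for m in matches})
    report["n_matched_subjects"] = len(matched_subjects)

    candidates = precursor.extract_candidates(
        osps, matched_subjects, config.candidate_max_len
    )
    report["n_candidates"] = len(candidates)

    # homology passes on still-unmatched candidates (in-repo search)
    searcher = homology.LocalSearch()
    splits = []
    for rec in candidates.records:
        pred = predictor(rec.id, rec.sequence)
        if not pred.is_secretory or pred.cleavage_after == 0:
            continue
        signal, intermediate = precursor.split_by_signal(rec.sequence, pred)
        splits.append(homology.QuerySplit(rec.id, signal, intermediate))
    matched_signals = []
    by_id = {rec.id: rec for rec in sps.records}
    for sid in matched_subjects:
        rec = by_id.get(sid)
        if rec is None:
            continue
        pred = predictor(rec.id, rec.sequence)
        if pred.is_secretory and pred.cleavage_after:
            matched_signals.append((rec.id, rec.sequence[: pred.cleavage_after]))
    hits, unhit = homology.two_pass_search(
        splits, {"reference": catalog.demo_fasta_items()}, matched_signals, searcher
    )
    report["n_candidate_hits"] = len(hits)
    report["n_candidate_unhit"] = len(unhit)

    # --- annotation -------------------------------------------------------
    mature_by_master = {c.master_accessions[0]: c.backbone for c in calls}
    series: dict[str, list[tuple[str, str]]] = {}
    for rec in osps.records:
        series.setdefault(seqset.parent_of(rec.id), []).append((rec.id, rec.sequence))

    annotate_ids = {seqset.parent_of(sid) for sid in matched_subjects}
    annotate_ids |= {seqset.parent_of(qid) for qid in hits}
    annotations = []
    for parent in sorted(annotate_ids):
        members = series.get(parent)
        if not members:
            continue
        predictions = {sid: predictor(sid, seq) for sid, seq in members}
        try:
            chosen_id, chosen_seq = precursor.select_orf_variant(
                members, predictions, config.start_motif or None
            )
        except ValueError:
            continue
        rec = seqset.ProteinRecord(id=chosen_id, sequence=chosen_seq, has_stop=True)
        hint = next(
            (mature_by_master[sid] for sid, _ in members if sid in mature_by_master),
            None,
        )
        annotations.append(
            precursor.annotate_precursor(
                rec,
                predictions[chosen_id],
                mature_hints=[hint] if hint else None,
            )
        )
    kept = precursor.filter_mature_length(annotations, config.mature_max_len)

    og_catalog = catalog.demo_mature_sequences()
    similar = _similarity_predicate(searcher)
    orphans = []
    for ann in kept:
        first = ann.mature_spans[0]
        mature_seq = None
        rec_seq = next((seq for sid, seq in series.get(seqset.parent_of(ann.protein_id), []) if sid == ann.protein_id), None)
        if rec_seq:
            mature_seq = rec_seq[first[0] - 1 : first[1]]
        if mature_seq:
            ann.source_class = precursor.classify_source(mature_seq, og_catalog, [], [], similar)
            if ann.source_class == "Orphan":
                orphans.append(ann.protein_id)
    for pid, name in precursor.name_orphans(orphans).items():
        for ann in kept:
            if ann.protein_id == pid:
                ann.subfamily = name

    precursor.write_annotations_gff3(kept, out / "annotations.gff3")
    pd.DataFrame(precursor.annotation_summary_rows(kept)).to_csv(
        out / "annotations.tsv", sep="\t", index=False
    )
    report["n_annotated"] = len(annotations)
    report["n_annotated_kept"] = len(kept)
    report["n_orphans"] = len(orphans)
    report["stages"].append("annotation")

    # internal consistency of the census arithmetic
    assert report["sps_size"] == report["fps_size"] + report["novel_osps"]

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
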