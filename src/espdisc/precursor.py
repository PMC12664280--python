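"""Precursor extraction and structural annotation of secretory peptides.

A frog-skin-type secretory precursor reads, N- to C-terminus:

    signal peptide -> (acidic) propiece -> basic processing site
    -> mature peptide(s) -> optional residual piece -> stop codon

This module turns that architecture into coordinates.  Mature peptides
observed by MS (or catalogued previously) are located in the search protein
set by exact full-length substring matching; unmatched short stop-codon
candidates are pulled from the optimized set; each precursor is then split
at the predicted signal cleavage, its processing site inferred (Lys-Arg and
other single/paired basic residues), its C-terminal Cys-(X)n-Cys "Rana box"
detected, and the whole structure reported with 1-based inclusive spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .seqset import ProteinRecord, ProteinSet
from .sigpred import SignalPrediction

logger = logging.getLogger(__name__)

SOURCE_CLASSES = ("OG", "OGP", "OD", "ODP", "OF", "OFP", "Orphan")

Span = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class MatchResult:
    """An exact full-length occurrence of a query inside a subject protein."""

    query_id: str
    subject_id: str
    start: int  # 1-based
    end: int    # inclusive


@dataclass
class PrecursorAnnotation:
    """Structural spans of one precursor protein (1-based, inclusive)."""

    protein_id: str
    signal_span: Span
    propiece_span: Optional[Span]
    processing_site: str
    mature_spans: list[Span]
    residual_span: Optional[Span]
    has_stop: bool
    rana_box: Optional[tuple[int, int]] = None  # Cys positions within mature 1
    family: str = ""
    subfamily: str = ""
    source_class: str = ""
    unprocessed: bool = False

    def mature_lengths(self) -> list[int]:
        return [end - start + 1 for start, end in self.mature_spans]


# --------------------------------------------------------------------------
# matching and candidate extraction


def match_full_length(
    queries: Sequence[tuple[str, str]],
    sps: ProteinSet,
) -> list[MatchResult]:
    """Find every exact occurrence of each query in the set's proteins.

    A "match" is the full-length query with 100% identity to a contiguous
    subsequence of a subject; all occurrences are reported, including
    overlapping ones within the same subject.  Empty queries are an error.
    """
    results: list[MatchResult] = []
    for query_id, query in queries:
        if not query:
            raise ValueError(f"empty query sequence: {query_id!r}")
        for rec in sps.records:
            start = rec.sequence.find(query)
            while start != -1:
                results.append(
                    MatchResult(query_id, rec.id, start + 1, start + len(query))
                )
                start = rec.sequence.find(query, start + 1)
    return results


def extract_candidates(
    osps: ProteinSet,
    matched_ids: Iterable[str],
    max_len: int = 250,
) -> ProteinSet:
    """Select unmatched short stop-codon-bearing sequences from the OSPS.

    Retained iff the record translation reached a stop codon, is shorter
    than *max_len* residues (strict), and its id was not already matched in
    the search set.
    """
    matched = set(matched_ids)
    out = ProteinSet(name="candidates", header_delimiter="|")
    for rec in osps.records:
        if rec.has_stop and len(rec.sequence) < max_len and rec.id not in matched:
            out.add(rec)
    return out


# --------------------------------------------------------------------------
# structural annotation


def split_by_signal(
    sequence: str, prediction: SignalPrediction
) -> tuple[str, str]:
    """Partition a precursor into (signal peptide, intermediate sequence).

    The intermediate sequence is everything remaining after signal removal:
    propiece, mature peptide(s), and any residual piece.  Concatenating the
    two parts restores the input.
    """
    if not prediction.is_secretory:
        raise ValueError("cannot split a non-secretory protein at its signal")
    ca = prediction.cleavage_after
    if ca == 0:
        raise ValueError("secretory prediction without a placed cleavage site")
    if ca >= len(sequence):
        raise ValueError("cleavage site at or beyond the end of the sequence")
    return sequence[:ca], sequence[ca:]


@dataclass(frozen=True)
class ProcessingSite:
    """Outcome of processing-site inference on an intermediate sequence.

    ``propiece_span`` covers residue 1 of the intermediate up to and
    including the basic site residues (so spans tile); ``mature_start`` is
    1-based within the intermediate.  ``unprocessed`` flags intermediates
    with no basic site and no hint: the whole intermediate is then treated
    as mature.
    """

    propiece_span: Optional[Span]
    site: str
    mature_start: int
    unprocessed: bool = False


_DIBASIC = ("KR", "RR", "KK")


def infer_processing_site(
    intermediate: str,
    mature_hint: Optional[str] = None,
    min_mature: int = 3,
    max_mature: int = 100,
) -> ProcessingSite:
    """Locate the propiece/mature boundary in an intermediate sequence.

    If *mature_hint* occurs in the intermediate, the mature start is forced
    to its first occurrence and the site is the one or two basic residues
    (K/R) immediately preceding it (empty string if none).  Otherwise the
    sequence is scanned left to right for a dibasic site -- KR preferred
    over RR/KK -- whose downstream segment is *min_mature*..*max_mature*
    residues; a single Arg is accepted only if no dibasic site qualifies.
    With neither hint nor basic site the intermediate is flagged
    "unprocessed" and treated as entirely mature.
    """
    if not intermediate:
        raise ValueError("empty intermediate sequence")
    n = len(intermediate)

    if mature_hint:
        pos = intermediate.find(mature_hint)
        if pos != -1:
            site = ""
            i = pos - 1
            while i >= 0 and intermediate[i] in "KR" and len(site) < 2:
                site = intermediate[i] + site
                i -= 1
            propiece = (1, pos) if pos >= 1 else None
            return ProcessingSite(propiece, site, pos + 1)

    def _downstream_ok(mature_start0: int) -> bool:
        return min_mature <= n - mature_start0 <= max_mature

    preferred: Optional[int] = None  # 0-based index of dibasic start
    fallback: Optional[int] = None
    for i in range(n - 1):
        pair = intermediate[i : i + 2]
        if pair in _DIBASIC and _downstream_ok(i + 2):
            if pair == "KR":
                preferred = i
                break
            if fallback is None:
                fallback = i
    idx = preferred if preferred is not None else fallback
    if idx is not None:
        return ProcessingSite((1, idx + 2), intermediate[idx : idx + 2], idx + 3)

    for i in range(n):
        if intermediate[i] == "R" and _downstream_ok(i + 1):
            return ProcessingSite((1, i + 1), "R", i + 2)

    return ProcessingSite(None, "", 1, unprocessed=True)


def detect_rana_box(mature: str) -> Optional[tuple[int, int]]:
    """Detect the C-terminal Cys-(X)n-Cys disulfide loop ("Rana box").

    The second Cys must sit within the last three residues; the first is the
    nearest upstream Cys separated by 3-8 intervening residues.  Returns
    1-based Cys positions or ``None``.
    """
    n = len(mature)
    cys2 = None
    for i in range(n, 0, -1):
        if mature[i - 1] == "C" and n - i <= 2:
            cys2 = i
            break
    if cys2 is None:
        return None
    for cys1 in range(cys2 - 1, 0, -1):
        if mature[cys1 - 1] == "C" and 3 <= cys2 - cys1 - 1 <= 8:
            return (cys1, cys2)
    return None


def filter_mature_length(
    annotations: Sequence[PrecursorAnnotation], max_mature: int = 100
) -> list[PrecursorAnnotation]:
    """Keep precursors with at least one mature peptide of <= *max_mature* aa.

    "Exceeded" is strict: a single 100-residue mature peptide survives, a
    101-residue one does not.
    """
    return [
        ann
        for ann in annotations
        if any(length <= max_mature for length in ann.mature_lengths())
    ]


def select_orf_variant(
    series: Sequence[tuple[str, str]],
    predictions: Mapping[str, SignalPrediction],
    start_motif: Optional[str] = None,
) -> tuple[str, str]:
    """Choose the start site of a precursor from its truncation series.

    *series* lists ``(id, sequence)`` for the full-length protein and its
    ORF-shift variants.  Among the secretory members: if *start_motif* is
    given (e.g. ``"MFT"``, the conserved frog-skin signal start), prefer the
    member whose first three residues equal it, longest first; otherwise the
    longest secretory member (the most upstream plausible start).  Ties
    resolve to the earliest series entry, so the choice is deterministic.
    """
    secretory = [
        (sid, seq)
        for sid, seq in series
        if sid in predictions and predictions[sid].is_secretory
    ]
    if not secretory:
        raise ValueError("no secretory member in the truncation series")
    if start_motif:
        matching = [item for item in secretory if item[1][:3] == start_motif]
        if matching:
            return max(matching, key=lambda item: len(item[1]))
    return max(secretory, key=lambda item: len(item[1]))


def annotate_precursor(
    record: ProteinRecord,
    prediction: SignalPrediction,
    mature_hints: Optional[Sequence[str]] = None,
    family: str = "",
    subfamily: str = "",
) -> PrecursorAnnotation:
    """Build the full structural annotation of one precursor.

    Without hints a single mature peptide is assumed, spanning from the
    inferred processing site to the C-terminus.  With hints (1-3 mature
    sequences in N->C order) each is placed in turn, rescanning the segment
    after the previous mature peptide; trailing residues after the last
    mature peptide become the residual piece.
    """
    signal, intermediate = split_by_signal(record.sequence, prediction)
    offset = len(signal)
    hints = [h for h in (mature_hints or []) if h]

    mature_spans: list[Span] = []
    propiece_span: Optional[Span] = None
    site = ""
    unprocessed = False
    residual_span: Optional[Span] = None

    if not hints:
        ps = infer_processing_site(intermediate)
        site, unprocessed = ps.site, ps.unprocessed
        if ps.propiece_span:
            propiece_span = (offset + ps.propiece_span[0], offset + ps.propiece_span[1])
        mature_spans.append((offset + ps.mature_start, len(record.sequence)))
    else:
        segment = intermediate
        seg_offset = offset
        for k, hint in enumerate(hints[:3]):
            ps = infer_processing_site(segment, mature_hint=hint)
            start_abs = seg_offset + ps.mature_start
            if hint in segment:
                end_abs = start_abs + len(hint) - 1
            else:  # hint absent: fall back to scan semantics for the rest
                end_abs = len(record.sequence)
            if k == 0:
                site, unprocessed = ps.site, ps.unprocessed
                if ps.propiece_span:
                    propiece_span = (
                        seg_offset + ps.propiece_span[0],
                        seg_offset + ps.propiece_span[1],
                    )
            mature_spans.append((start_abs, end_abs))
            if end_abs >= len(record.sequence):
                segment = ""
                break
            segment = record.sequence[end_abs:]
            seg_offset = end_abs
        if mature_spans and mature_spans[-1][1] < len(record.sequence):
            residual_span = (mature_spans[-1][1] + 1, len(record.sequence))

    first_mature = record.sequence[mature_spans[0][0] - 1 : mature_spans[0][1]]
    return PrecursorAnnotation(
        protein_id=record.id,
        signal_span=(1, offset),
        propiece_span=propiece_span,
        processing_site=site,
        mature_spans=mature_spans,
        residual_span=residual_span,
        has_stop=record.has_stop,
        rana_box=detect_rana_box(first_mature),
        family=family,
        subfamily=subfamily,
        unprocessed=unprocessed,
    )


# --------------------------------------------------------------------------
# provenance classification and naming

SimilarityPredicate = Callable[[str, Sequence[str]], bool]


def classify_source(
    mature: str,
    catalog_og: Sequence[str],
    catalog_odorrana: Sequence[str],
    catalog_anura: Sequence[str],
    similar: Optional[SimilarityPredicate] = None,
) -> str:
    """Assign a provenance class to a mature peptide.

    Exact full-sequence identity in the species / genus / order catalogs
    yields OG / OD / OF.  Similar-but-not-identical hits yield the "P"
    suffixed class of the highest-priority tier (OG > OD > OF).  No hit at
    all: Orphan.  Empty catalogs degrade to Orphan with a warning.
    """
    tiers = (
        ("OG", list(catalog_og)),
        ("OD", list(catalog_odorrana)),
        ("OF", list(catalog_anura)),
    )
    if not any(entries for _, entries in tiers):
        logger.warning("all reference catalogs are empty; classifying as Orphan")
        return "Orphan"
    for label, entries in tiers:
        if mature in entries:
            return label
    if similar is not None:
        for label, entries in tiers:
            inexact = [e for e in entries if e != mature]
            if inexact and similar(mature, inexact):
                return label + "P"
    return "Orphan"


def name_orphans(orphan_ids: Sequence[str], prefix: str = "odorranain-X") -> dict[str, str]:
    """Assign sequential subfamily names to orphan peptides.

    Input order is made deterministic by sorting on protein id; names run
    ``odorranain-X1``, ``-X2``, ...
    """
    return {pid: f"{prefix}{i}" for i, pid in enumerate(sorted(orphan_ids), 1)}


# --------------------------------------------------------------------------
# output


def annotation_summary_rows(annotations: Iterable[PrecursorAnnotation]) -> list[dict]:
    def fmt(span: Optional[Span]) -> str:
        return f"{span[0]}-{span[1]}" if span else ""

    rows = []
    for ann in annotations:
        rows.append(
            {
                "protein_id": ann.protein_id,
                "signal": fmt(ann.signal_span),
                "propiece": fmt(ann.propiece_span),
                "site": ann.processing_site,
                "mature": ";".join(fmt(s) for s in ann.mature_spans),
                "residual": fmt(ann.residual_span),
                "rana_box": fmt(ann.rana_box) if ann.rana_box else "",
                "has_stop": ann.has_stop,
                "family": ann.family,
                "subfamily": ann.subfamily,
                "source": ann.source_class,
            }
        )
    return rows


def write_annotations_gff3(annotations: Iterable[PrecursorAnnotation], path) -> None:
    """Write precursor features (signal_peptide, propeptide, mature_peptide,
    residual) as GFF3 against protein coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            rows: list[tuple[str, Span]] = [("signal_peptide", ann.signal_span)]
            if ann.propiece_span:
                rows.append(("propeptide", ann.propiece_span))
            rows.extend(("mature_peptide", span) for span in ann.mature_spans)
            if ann.residual_span:
                rows.append(("residual", ann.residual_span))
            for feature, (start, end) in rows:
                fh.write(
                    "\t".join(
                        (
                            ann.protein_id,
                            "espdisc",
                            feature,
                            str(start),
                            str(end),
                            ".",
                            ".",
                            ".",
                            f"ID={ann.protein_id}.{feature}.{start}",
                        )
                    )
                    + "\n"
                )
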