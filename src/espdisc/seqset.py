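"""Protein-set construction for secretory-protein rescue.

Transcriptome assemblers followed by ORF callers (TransDecoder-style) tend to
pick the longest open reading frame, which can place the start codon upstream
of the true one, inside the 5'-UTR.  The resulting N-terminally elongated
protein hides its signal peptide from sequence-based predictors.  This module
implements the protein-set bookkeeping used to rescue such false negatives:

* ``build_fps`` -- the filtered protein set (FPS): expression filter, length
  filter, then exact-sequence deduplication with comma-joined headers.
* ``generate_orf_variants`` -- the truncation series: one suffix per internal
  methionine ("ORF_shift" variants, ``<parent>_ORF1``, ``_ORF2``, ... ordered
  N-terminus to C-terminus).
* ``build_osps`` -- the optimized secretory protein set (OSPS): for every FPS
  protein whose full-length form or any truncation is predicted secretory,
  the full-length parent plus every positive truncation, pipe-joined headers.
* ``build_sps`` -- the search protein set (SPS): FPS union OSPS, deduplicated,
  suitable as an MS/MS search database.
* ``count_nonredundant_secretory`` / ``percent_increase`` / ``percent_share``
  -- the census statistics reported for such sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: The 20 canonical residues accepted in curated protein sets.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ORF_SUFFIX = re.compile(r"_ORF(\d+)$")
_TRANSDECODER_ID = re.compile(r"(.+?)\.p\d+(?:_ORF\d+)?$")


@dataclass
class ProteinRecord:
    """One predicted protein.

    A trailing ``*`` (stop marker emitted by ORF callers) is stripped from
    ``sequence`` and recorded as ``has_stop=True``.  The parent transcript id
    is derived from TransDecoder-style headers (``TRINITY_DN0_c1_g1_i24.p1``
    -> ``TRINITY_DN0_c1_g1_i24``) unless given explicitly.
    """

    id: str
    sequence: str
    has_stop: bool = False
    parent_transcript_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if self.sequence.endswith("*"):
            self.sequence = self.sequence[:-1]
            self.has_stop = True
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        if not self.parent_transcript_id:
            m = _TRANSDECODER_ID.match(self.id)
            self.parent_transcript_id = m.group(1) if m else self.id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfVariant:
    """A methionine-anchored suffix of a parent protein.

    ``sequence == parent.sequence[start_offset:]`` and starts with ``M``;
    ``start_offset >= 1`` (the first residue never yields a variant).
    """

    parent_id: str
    orf_index: int
    start_offset: int
    sequence: str

    @property
    def variant_id(self) -> str:
        return f"{self.parent_id}_ORF{self.orf_index}"


@dataclass
class ProteinSet:
    """A deduplicated collection of proteins with header provenance.

    ``header_groups`` maps each canonical sequence to the ordered list of
    original headers that carried it (first-seen order, so FASTA output is
    byte-stable).  ``records`` holds one representative record per sequence.
    """

    name: str
    records: list[ProteinRecord] = field(default_factory=list)
    header_groups: dict[str, list[str]] = field(default_factory=dict)
    header_delimiter: str = ","

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.header_groups

    def add(self, record: ProteinRecord) -> None:
        """Add a record, collapsing onto an existing identical sequence."""
        group = self.header_groups.get(record.sequence)
        if group is None:
            self.records.append(record)
            self.header_groups[record.sequence] = [record.id]
        elif record.id not in group:
            group.append(record.id)

    def sequences(self) -> set[str]:
        return set(self.header_groups)

    def fasta_items(self) -> Iterable[tuple[str, str]]:
        """Yield ``(consolidated_header, sequence)`` pairs in stable order."""
        for rec in self.records:
            yield self.header_delimiter.join(self.header_groups[rec.sequence]), rec.sequence

    def all_headers(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            out.extend(self.header_groups[rec.sequence])
        return out


class AbundanceTable:
    """Per-transcript read counts (and optional TPM) used for filtering.

    Missing transcripts are treated as zero reads.  Negative values are
    rejected at construction.
    """

    def __init__(self, table: Mapping[str, tuple[float, float]]):
        for tid, (count, tpm) in table.items():
            if count < 0 or tpm < 0:
                raise ValueError(f"negative abundance for transcript {tid!r}")
        self._table = dict(table)

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "AbundanceTable":
        return cls({tid: (c, 0.0) for tid, c in counts.items()})

    def read_count(self, transcript_id: str) -> float:
        return self._table.get(transcript_id, (0.0, 0.0))[0]

    def tpm(self, transcript_id: str) -> float:
        return self._table.get(transcript_id, (0.0, 0.0))[1]

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()


# --------------------------------------------------------------------------
# set construction


def build_fps(
    proteins: Sequence[ProteinRecord],
    abundance: AbundanceTable,
    min_reads: float = 1.0,
    min_len: int = 20,
) -> ProteinSet:
    """Build the filtered protein set through three sequential filters.

    1. expression: drop proteins whose transcript has read count < *min_reads*
       (counts may be fractional; the comparison is strict);
    2. length: drop sequences shorter than *min_len* residues;
    3. deduplication: collapse 100%-identical sequences, consolidating
       headers with comma delimiters.

    Raises ``ValueError`` for duplicate ids carrying different sequences
    (ambiguous input) and for sequences outside the 20-letter alphabet.
    """
    seen: dict[str, str] = {}
    for rec in proteins:
        prev = seen.get(rec.id)
        if prev is not None and prev != rec.sequence:
            raise ValueError(f"duplicate id {rec.id!r} with different sequences")
        seen[rec.id] = rec.sequence
        bad = set(rec.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {rec.id!r} contains non-standard residues: {sorted(bad)}"
            )

    expressed = [r for r in proteins if abundance.read_count(r.parent_transcript_id) >= min_reads]
    long_enough = [r for r in expressed if len(r.sequence) >= min_len]

    fps = ProteinSet(name="FPS", header_delimiter=",")
    for rec in long_enough:
        fps.add(rec)
    return fps


def generate_orf_variants(protein: ProteinRecord, min_len: int = 20) -> list[OrfVariant]:
    """Generate the methionine-truncation series of a protein.

    Every internal Met (1-based position >= 2) whose suffix is at least
    *min_len* residues yields one variant; variants are ordered N->C and
    indexed 1, 2, ... so that a higher index means more N-terminal sequence
    removed.  The initiator Met never generates a variant.
    """
    seq = protein.sequence
    variants: list[OrfVariant] = []
    for offset in range(1, len(seq)):
        if seq[offset] == "M" and len(seq) - offset >= min_len:
            variants.append(
                OrfVariant(
                    parent_id=protein.id,
                    orf_index=len(variants) + 1,
                    start_offset=offset,
                    sequence=seq[offset:],
                )
            )
    return variants


Predictor = Callable[[str, str], "object"]


def build_osps(
    fps: ProteinSet,
    predictor: Predictor,
    min_len: int = 20,
) -> ProteinSet:
    """Build the optimized secretory protein set.

    The predictor (``predictor(sequence_id, sequence) -> SignalPrediction``)
    is applied to each FPS protein and to every one of its ORF-shift
    variants.  If any member of a series is positive, the OSPS receives the
    full-length parent sequence plus every positive truncated variant.
    Duplicates are collapsed with pipe-joined headers.  A predictor failure
    on a sequence is logged and treated as a negative call.
    """

    def _predict(sid: str, seq: str) -> bool:
        try:
            return bool(predictor(sid, seq).is_secretory)
        except Exception:  # noqa: BLE001 - predictor contract: failure == negative
            logger.warning("signal predictor failed on %s; treating as negative", sid)
            return False

    osps = ProteinSet(name="OSPS", header_delimiter="|")
    for rec in fps.records:
        variants = generate_orf_variants(rec, min_len=min_len)
        parent_positive = _predict(rec.id, rec.sequence)
        positive_variants = [v for v in variants if _predict(v.variant_id, v.sequence)]
        if parent_positive or positive_variants:
            osps.add(
                ProteinRecord(
                    id=rec.id,
                    sequence=rec.sequence,
                    has_stop=rec.has_stop,
                    parent_transcript_id=rec.parent_transcript_id,
                )
            )
            for v in positive_variants:
                osps.add(
                    ProteinRecord(
                        id=v.variant_id,
                        sequence=v.sequence,
                        has_stop=rec.has_stop,
                        parent_transcript_id=rec.parent_transcript_id,
                    )
                )
    return osps


def build_sps(fps: ProteinSet, osps: ProteinSet) -> ProteinSet:
    """Merge FPS and OSPS into the search protein set, collapsing duplicates.

    ``len(sps) == len(fps) + |OSPS sequences not already in FPS|``; header
    groups are merged preserving provenance (FPS groups first, then OSPS
    headers appended in their own first-seen order).
    """
    sps = ProteinSet(name="SPS", header_delimiter=",")
    for source in (fps, osps):
        for rec in source.records:
            for header in source.header_groups[rec.sequence]:
                sps.add(
                    ProteinRecord(
                        id=header,
                        sequence=rec.sequence,
                        has_stop=rec.has_stop,
                        parent_transcript_id=rec.parent_transcript_id,
                    )
                )
    return sps


# --------------------------------------------------------------------------
# census statistics


def parent_of(header: str) -> str:
    """Strip a ``_ORF<k>`` suffix, returning the parent protein id.

    Raises ``ValueError`` for malformed variant suffixes such as ``_ORF``
    without a numeral or ``_ORF1x``.
    """
    m = _ORF_SUFFIX.search(header)
    if m:
        return header[: m.start()]
    if re.search(r"_ORF(?!\d+$)", header):
        raise ValueError(f"malformed ORF-variant header: {header!r}")
    return header


def count_nonredundant_secretory(pset: ProteinSet) -> int:
    """Count distinct parent proteins with at least one entry in *pset*.

    A parent with several positive truncation variants counts once (each
    truncation series collapses to its parent id).
    """
    parents = {parent_of(h) for h in pset.all_headers()}
    return len(parents)


def _round_half_up_1dp(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_increase(before: int, after: int) -> float:
    """Relative increase ``100 * (after - before) / before``, one decimal.

    Rounded half-up, matching how such census percentages are conventionally
    printed.  *before* must be positive.
    """
    if before <= 0:
        raise ValueError("percent_increase requires before > 0")
    if after < 0:
        raise ValueError("percent_increase requires after >= 0")
    return _round_half_up_1dp(Decimal(after - before) * 100 / Decimal(before))


def percent_share(part: int, total: int) -> float:
    """``100 * part / total`` rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("percent_share requires total > 0")
    return _round_half_up_1dp(Decimal(part) * 100 / Decimal(total))
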