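"""Phylogeny input preparation for frog-skin peptide precursors.

Mature-peptide regions of these precursors are hypervariable, so trees are
built from four nucleotide regions whose conservation differs: (r1) up to
45 nt of 5'-UTR plus the signal-peptide CDS, (r2) the propiece CDS, (r3)
the mature-peptide CDS, and (r4) the stop codon plus up to 45 nt of 3'-UTR.
Each region is aligned and trimmed externally (MAFFT E-INS-i / automated
trimming are the recorded defaults); this module owns only the
deterministic parts: slicing the regions out of a transcript, concatenating
externally aligned blocks into a supermatrix with a partition table, and
the taxa-naming scheme ``F<family>S<subfamily>-P<peptide>-<name>`` with
``_k`` suffixes for duplicate mature peptides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .precursor import PrecursorAnnotation

STOP_CODONS = ("TAA", "TAG", "TGA")

GAP = "-"  # missing-taxon fill uses the gap character, not "?"


@dataclass(frozen=True)
class RegionSet:
    """The four nucleotide regions of one precursor transcript."""

    taxon_name: str
    r1: str  # <=45 nt 5'-UTR + signal CDS
    r2: str  # propiece CDS ("" when the precursor has no propiece)
    r3: str  # mature-peptide CDS
    r4: str  # stop codon + <=45 nt 3'-UTR

    def __post_init__(self) -> None:
        if self.r2 and len(self.r2) % 3:
            raise ValueError("propiece CDS length must be divisible by 3")
        if len(self.r3) % 3:
            raise ValueError("mature CDS length must be divisible by 3")
        if self.r4[:3] not in STOP_CODONS:
            raise ValueError(f"r4 must begin with a stop codon, got {self.r4[:3]!r}")


def _aa_to_nt(cds_start: int, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map a 1-based inclusive aa span onto 1-based transcript coordinates."""
    return cds_start + 3 * (aa_start - 1), cds_start + 3 * aa_end - 1


def extract_regions(
    transcript: str,
    annotation: PrecursorAnnotation,
    cds_start: int,
    taxon_name: str = "",
    utr_cap: int = 45,
) -> RegionSet:
    """Slice the four phylogeny regions out of a transcript.

    *cds_start* is the 1-based transcript position of the first CDS
    nucleotide (amino acid k occupies nucleotides ``cds_start + 3(k-1)`` to
    ``cds_start + 3k - 1``).  UTR takes are capped at *utr_cap* nt and never
    padded.  Raises if the codon following the CDS is not a stop codon.
    """
    n_aa = (
        annotation.residual_span[1]
        if annotation.residual_span
        else annotation.mature_spans[-1][1]
    )
    stop_start0 = cds_start - 1 + 3 * n_aa
    if stop_start0 + 3 > len(transcript):
        raise ValueError("transcript too short to contain the CDS and stop codon")
    stop = transcript[stop_start0 : stop_start0 + 3]
    if stop not in STOP_CODONS:
        raise ValueError(
            f"expected a stop codon after the CDS, found {stop!r} at {stop_start0 + 1}"
        )

    utr5_take = min(utr_cap, cds_start - 1)
    sig_nt = _aa_to_nt(cds_start, annotation.signal_span[0], annotation.signal_span[1])
    r1 = transcript[cds_start - 1 - utr5_take : cds_start - 1] + transcript[
        sig_nt[0] - 1 : sig_nt[1]
    ]

    if annotation.propiece_span:
        pro_nt = _aa_to_nt(cds_start, *annotation.propiece_span)
        r2 = transcript[pro_nt[0] - 1 : pro_nt[1]]
    else:
        r2 = ""

    mat_nt = _aa_to_nt(
        cds_start, annotation.mature_spans[0][0], annotation.mature_spans[-1][1]
    )
    r3 = transcript[mat_nt[0] - 1 : mat_nt[1]]

    utr3_take = min(utr_cap, len(transcript) - (stop_start0 + 3))
    r4 = transcript[stop_start0 : stop_start0 + 3 + utr3_take]

    return RegionSet(taxon_name or annotation.protein_id, r1, r2, r3, r4)


# --------------------------------------------------------------------------
# supermatrix assembly

Block = Sequence[tuple[str, str]] | Mapping[str, str]


def _as_pairs(block: Block) -> list[tuple[str, str]]:
    if isinstance(block, Mapping):
        return list(block.items())
    return list(block)


def concatenate_supermatrix(
    blocks: Mapping[str, Block],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-region aligned blocks into one supermatrix.

    *blocks* maps region name -> aligned rows (taxon, sequence), in the
    region order to concatenate.  Within a block all rows must share one
    width and taxa must be unique.  A taxon missing from a block is filled
    with gaps across that block's width.  Returns the merged rows (taxon ->
    concatenated sequence, first-seen taxon order) and a partition table of
    1-based inclusive column intervals per region.
    """
    taxa: list[str] = []
    widths: dict[str, int] = {}
    per_region: dict[str, dict[str, str]] = {}
    for region, block in blocks.items():
        pairs = _as_pairs(block)
        rows: dict[str, str] = {}
        for taxon, seq in pairs:
            if taxon in rows:
                raise ValueError(f"duplicate taxon {taxon!r} in block {region!r}")
            rows[taxon] = seq
            if taxon not in taxa:
                taxa.append(taxon)
        if rows:
            lengths = {len(s) for s in rows.values()}
            if len(lengths) > 1:
                raise ValueError(f"unequal row lengths in block {region!r}")
            widths[region] = lengths.pop()
        else:
            widths[region] = 0
        per_region[region] = rows

    merged = {
        taxon: "".join(
            per_region[region].get(taxon, GAP * widths[region]) for region in blocks
        )
        for taxon in taxa
    }
    partitions: list[tuple[str, int, int]] = []
    cursor = 1
    for region in blocks:
        width = widths[region]
        partitions.append((region, cursor, cursor + width - 1))
        cursor += width
    return merged, partitions


def partition_table_text(partitions: Sequence[tuple[str, int, int]]) -> str:
    """RAxML-style partition lines: ``DNA, r1 = 1-120``."""
    return "\n".join(f"DNA, {name} = {start}-{end}" for name, start, end in partitions) + "\n"


# --------------------------------------------------------------------------
# taxa naming

_WHITESPACE = re.compile(r"\s+")


def make_taxon_name(
    family_id: int,
    subfamily_id: int,
    peptide_id: int,
    peptide_name: str,
    duplicate_index: Optional[int] = None,
) -> str:
    """Build a tree taxon label ``F<f>S<s>-P<p>-<name>[_k]``.

    Duplicates (identical mature peptides) carry ``_2``, ``_3``, ...;
    whitespace in the peptide name is sanitized to ``-``.
    """
    if family_id < 1 or subfamily_id < 1 or peptide_id < 1:
        raise ValueError("family, subfamily and peptide ids must be positive")
    name = _WHITESPACE.sub("-", peptide_name.strip())
    label = f"F{family_id}S{subfamily_id}-P{peptide_id}-{name}"
    if duplicate_index is not None:
        label += f"_{duplicate_index}"
    return label
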