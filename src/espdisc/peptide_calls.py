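"""Mature-peptide calling from tandem-MS peptide/PSM export tables.

Skin-secretion peptidomics detects each secreted peptide as a cloud of
isoforms: the full mature peptide plus ragged truncation products, each with
optional modifications (notably the -1.008 Da "dehydro" on disulfide-engaged
cysteines).  Given a Proteome Discoverer-style peptide export and the
matching master-protein table, this module

1. drops masters with Medium/Low FDR confidence (and peptides stranded by
   that removal), recomputing peptide exclusivity afterwards;
2. drops peptides carrying an odd number of Cys dehydro modifications (an
   intact disulfide contributes exactly two);
3. combines isoforms sharing (backbone, master set), accumulating abundance
   and PSM counts;
4. selects, per master protein, the most abundant exclusive peptide as the
   candidate mature peptide (ties: longer backbone, then lexicographic);
5. applies the final filter requiring at least one master with >= 3 PSMs and
   a stop codon;
6. assigns the remaining backbones of each master as truncated forms
   (proper contiguous substrings of the mature backbone) or "unplaced".

Matching is purely textual; Ile and Leu are treated as distinct characters
even though MS cannot distinguish them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

CONFIDENCE_LEVELS = ("High", "Medium", "Low")

#: Default column mapping for PD-style peptide exports.
PEPTIDE_COLUMNS = {
    "sequence": "Sequence",
    "modifications": "Modifications",
    "abundance": "Abundance",
    "psms": "# PSMs",
    "confidence": "Confidence",
    "masters": "Master Protein Accessions",
}

#: Default column mapping for PD-style master-protein exports.
MASTER_COLUMNS = {
    "accession": "Accession",
    "confidence": "FDR Confidence",
    "psms": "# PSMs",
    "has_stop": "Has Stop",
}

_MODIFICATION = re.compile(r"(\d+)x([A-Za-z0-9_+-]+)\s*\[([^\]]+)\]")


@dataclass(frozen=True)
class PeptideIsoform:
    backbone: str
    modifications: tuple[tuple[str, str, int], ...]  # (name, target, count)
    abundance: float
    psm_count: int
    confidence: str
    master_accessions: tuple[str, ...]

    @property
    def is_exclusive(self) -> bool:
        return len(self.master_accessions) == 1

    def dehydro_cys_count(self) -> int:
        return sum(
            count
            for name, target, count in self.modifications
            if name.lower() == "dehydro" and target.upper().startswith("C")
        )


@dataclass(frozen=True)
class MasterProteinEntry:
    accession: str
    fdr_confidence: str
    psm_total: int
    has_stop: bool


@dataclass
class MaturePeptideCall:
    backbone: str
    master_accessions: tuple[str, ...]
    abundance: float
    psm_total: int
    truncated_forms: list[str] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    @property
    def n_truncated(self) -> int:
        return len(self.truncated_forms)


# --------------------------------------------------------------------------
# parsing


def parse_modifications(cell: str) -> tuple[tuple[str, str, int], ...]:
    """Parse a PD modification string like ``"2xDehydro [C]; 1xDeamidated [N]"``."""
    if not cell or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    mods = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        m = _MODIFICATION.fullmatch(part)
        if m is None:
            raise ValueError(f"unparseable modification field: {part!r}")
        mods.append((m.group(2), m.group(3), int(m.group(1))))
    return tuple(mods)


def _as_dataframe(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, mapping: Mapping[str, str]) -> None:
    missing = [col for col in mapping.values() if col not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")


def parse_peptide_table(
    source: pd.DataFrame | str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[PeptideIsoform]:
    """Read a tab-separated PD-style peptide export into isoforms.

    Multi-accession cells are split on ``;``.  Non-numeric abundances raise a
    row-level error naming the offending row.
    """
    cols = dict(PEPTIDE_COLUMNS, **(columns or {}))
    df = _as_dataframe(source)
    _require(df, cols)
    isoforms: list[PeptideIsoform] = []
    for idx, row in df.iterrows():
        try:
            abundance = float(row[cols["abundance"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric abundance in row {idx}: {row[cols['abundance']]!r}"
            ) from exc
        if abundance < 0:
            raise ValueError(f"negative abundance in row {idx}")
        masters = tuple(
            acc.strip() for acc in str(row[cols["masters"]]).split(";") if acc.strip()
        )
        isoforms.append(
            PeptideIsoform(
                backbone=str(row[cols["sequence"]]).strip().upper(),
                modifications=parse_modifications(row[cols["modifications"]]),
                abundance=abundance,
                psm_count=int(float(row[cols["psms"]])),
                confidence=str(row[cols["confidence"]]).strip(),
                master_accessions=masters,
            )
        )
    return isoforms


def parse_master_table(
    source: pd.DataFrame | str | Path,
    has_stop: Mapping[str, bool] | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[MasterProteinEntry]:
    """Read a master-protein table; ``has_stop`` may come from a column or
    be supplied as a mapping keyed by accession (the mapping wins)."""
    cols = dict(MASTER_COLUMNS, **(columns or {}))
    df = _as_dataframe(source)
    _require(df, {k: v for k, v in cols.items() if k != "has_stop"})
    stop_col = cols["has_stop"] if cols["has_stop"] in df.columns else None
    if stop_col is None and has_stop is None:
        raise ValueError(
            f"master table lacks a {cols['has_stop']!r} column and no has_stop "
            "mapping was provided"
        )
    masters = []
    for idx, row in df.iterrows():
        acc = str(row[cols["accession"]]).strip()
        if has_stop is not None and acc in has_stop:
            stop = bool(has_stop[acc])
        elif stop_col is not None:
            stop = str(row[stop_col]).strip().lower() in ("true", "1", "yes")
        else:
            raise ValueError(f"no stop-codon status for master {acc!r} (row {idx})")
        masters.append(
            MasterProteinEntry(
                accession=acc,
                fdr_confidence=str(row[cols["confidence"]]).strip(),
                psm_total=int(float(row[cols["psms"]])),
                has_stop=stop,
            )
        )
    return masters


# --------------------------------------------------------------------------
# filtering and combination


def filter_confidence(
    isoforms: Sequence[PeptideIsoform],
    masters: Sequence[MasterProteinEntry],
) -> tuple[list[PeptideIsoform], list[MasterProteinEntry]]:
    """Remove Medium/Low-confidence masters and the peptides they strand.

    Peptides whose only masters were removed disappear; peptides that also
    map to surviving masters are kept with a pruned accession list, which can
    make a formerly shared peptide exclusive.
    """
    kept_masters = [m for m in masters if m.fdr_confidence == "High"]
    kept_ids = {m.accession for m in kept_masters}
    out: list[PeptideIsoform] = []
    for iso in isoforms:
        remaining = tuple(a for a in iso.master_accessions if a in kept_ids)
        if remaining:
            out.append(replace(iso, master_accessions=remaining))
    return out, kept_masters


def filter_odd_dehydro(isoforms: Sequence[PeptideIsoform]) -> list[PeptideIsoform]:
    """Drop isoforms with an odd total of Cys dehydro modifications.

    An intact disulfide contributes exactly two dehydro-Cys; an odd count is
    chemically implausible for a disulfide-looped peptide and marks an
    unreliable identification.  Zero is even and kept.
    """
    return [iso for iso in isoforms if iso.dehydro_cys_count() % 2 == 0]


def combine_isoforms(isoforms: Sequence[PeptideIsoform]) -> list[PeptideIsoform]:
    """Group isoforms by (backbone, master set); sum abundance and PSMs.

    Modification lists are concatenated for reporting.  Group order follows
    first appearance, keeping downstream output deterministic.
    """
    grouped: dict[tuple[str, frozenset[str]], PeptideIsoform] = {}
    order: list[tuple[str, frozenset[str]]] = []
    for iso in isoforms:
        key = (iso.backbone, frozenset(iso.master_accessions))
        if key not in grouped:
            grouped[key] = iso
            order.append(key)
        else:
            prev = grouped[key]
            grouped[key] = replace(
                prev,
                abundance=prev.abundance + iso.abundance,
                psm_count=prev.psm_count + iso.psm_count,
                modifications=prev.modifications + iso.modifications,
            )
    return [grouped[k] for k in order]


def select_candidate_mature(
    masters: Sequence[MasterProteinEntry],
    combined: Sequence[PeptideIsoform],
) -> list[MaturePeptideCall]:
    """Per master protein, pick the most abundant exclusive peptide.

    Ties are broken by greater backbone length, then lexicographically
    smallest backbone, so the choice is deterministic.  Masters without any
    exclusive peptide yield no call.
    """
    calls: list[MaturePeptideCall] = []
    for master in masters:
        candidates = [
            iso
            for iso in combined
            if iso.master_accessions == (master.accession,)
        ]
        if not candidates:
            continue
        best = sorted(
            candidates,
            key=lambda iso: (-iso.abundance, -len(iso.backbone), iso.backbone),
        )[0]
        calls.append(
            MaturePeptideCall(
                backbone=best.backbone,
                master_accessions=(master.accession,),
                abundance=best.abundance,
                psm_total=best.psm_count,
            )
        )
    return calls


def final_filter(
    calls: Sequence[MaturePeptideCall],
    masters: Sequence[MasterProteinEntry],
    semantics: str = "conjunctive",
    min_psms: int = 3,
) -> list[MaturePeptideCall]:
    """Remove candidates whose precursor proteins all fail the evidence bar.

    Under the default ``"conjunctive"`` semantics a call survives iff at
    least one of its masters has >= *min_psms* PSMs *and* a stop codon
    (removal when every master fails "PSMs < 3 or no stop").  The
    alternative ``"independent"`` semantics lets one master satisfy the PSM
    bar and a different one the stop-codon bar.
    """
    if semantics not in ("conjunctive", "independent"):
        raise ValueError(f"unknown final_filter semantics: {semantics!r}")
    by_acc = {m.accession: m for m in masters}
    out = []
    for call in calls:
        try:
            ms = [by_acc[a] for a in call.master_accessions]
        except KeyError as exc:
            raise ValueError(
                f"call {call.backbone!r} references unknown master {exc.args[0]!r}"
            ) from exc
        if semantics == "conjunctive":
            keep = any(m.psm_total >= min_psms and m.has_stop for m in ms)
        else:
            keep = any(m.psm_total >= min_psms for m in ms) and any(m.has_stop for m in ms)
        if keep:
            out.append(call)
    return out


def assign_truncations(
    call: MaturePeptideCall,
    combined: Sequence[PeptideIsoform],
) -> MaturePeptideCall:
    """Attach the master's other backbones as truncations or "unplaced".

    A truncation is a proper contiguous substring of the mature backbone;
    observed peptides of the same master that are not substrings are
    reported separately and never counted.
    """
    masters = set(call.master_accessions)
    for iso in combined:
        if iso.backbone == call.backbone:
            continue
        if not masters & set(iso.master_accessions):
            continue
        if iso.backbone in call.backbone:
            if iso.backbone not in call.truncated_forms:
                call.truncated_forms.append(iso.backbone)
        elif iso.backbone not in call.unplaced:
            call.unplaced.append(iso.backbone)
    return call


# --------------------------------------------------------------------------
# orchestration


def call_mature_peptides(
    isoforms: Sequence[PeptideIsoform],
    masters: Sequence[MasterProteinEntry],
    semantics: str = "conjunctive",
    min_psms: int = 3,
) -> list[MaturePeptideCall]:
    """Run the full mature-peptide workflow (filters 1-6 of the module doc)."""
    isoforms, masters = filter_confidence(isoforms, masters)
    isoforms = filter_odd_dehydro(isoforms)
    combined = combine_isoforms(isoforms)
    calls = select_candidate_mature(masters, combined)
    calls = final_filter(calls, masters, semantics=semantics, min_psms=min_psms)
    return [assign_truncations(call, combined) for call in calls]


def write_call_report(calls: Iterable[MaturePeptideCall], path) -> None:
    """Emit a tab-separated mature-peptide report.

    Columns: backbone, masters (``;``-joined), accumulated abundance, PSM
    total, number of truncated forms.
    """
    rows = [
        {
            "Mature peptide": c.backbone,
            "Master proteins": ";".join(c.master_accessions),
            "Abundance": c.abundance,
            "# PSMs": c.psm_total,
            "# Truncated": c.n_truncated,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["Mature peptide", "Master proteins", "Abundance", "# PSMs", "# Truncated"],
    ).to_csv(path, sep="\t", index=False)
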