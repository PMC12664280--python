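"""FASTA and table I/O built on Biopython and pandas."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqset import AbundanceTable, ProteinRecord


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; a trailing ``*`` marks a reached stop codon."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(items: Iterable[tuple[str, str]], path) -> None:
    """Write (header, sequence) pairs, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=header, description="") for header, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_abundance(path) -> AbundanceTable:
    """Read a 2- or 3-column tab-separated abundance table.

    Columns: transcript_id, read_count[, tpm]; a header row starting with
    ``transcript_id`` is tolerated.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] == "transcript_id":
        df = df.iloc[1:]
    table = {}
    for row in df.itertuples(index=False):
        tid = str(row[0])
        count = float(row[1])
        tpm = float(row[2]) if len(row) > 2 and not pd.isna(row[2]) else 0.0
        table[tid] = (count, tpm)
    return AbundanceTable(table)


def write_abundance(table: AbundanceTable, path) -> None:
    lines = ["transcript_id\tread_count\ttpm"]
    lines += [f"{tid}\t{c:g}\t{t:g}" for tid, (c, t) in table.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
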