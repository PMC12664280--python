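"""Synthetic frog-skin precursor transcripts and peptide tables.

The generator emulates the canonical frog-skin secretory precursor and the
failure mode the pipeline exists to repair.  Each synthetic transcript
carries:

* a 5'-UTR which, with configurable probability, contains an upstream
  in-frame ATG -- the situation in which a longest-ORF caller starts
  translation too early and the elongated protein hides its signal peptide;
* a signal peptide beginning Met-Phe-Thr with an n-region charge, a
  hydrophobic h-region, and a Leu-Cys cleavage junction, constructed to
  satisfy the built-in heuristic predictor at the true start and to fail it
  from the upstream start (the generator and the predictor are co-designed:
  together they form the test harness, not a biological claim);
* an acidic propiece (>= 40% Asp/Glu) terminating in the Lys-Arg
  processing site;
* a 20-46 residue mature peptide ending in a C-terminal Rana box
  (Cys-(X)4-7-Cys);
* a stop codon and 3'-UTR.

``make_peptide_table`` then emulates a DDA peptidomics export: per
precursor, the mature peptide at top abundance with a geometrically
decaying ladder of truncated forms, two dehydro-Cys modifications on
Rana-box peptides, one odd-dehydro decoy, a low-confidence master and a
shared (non-exclusive) peptide, so every downstream filter has work to do.

Codons are drawn uniformly over synonymous codons; there is no codon-usage
model, no MS noise model, and no missingness -- string-level ground truth
is the point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import write_abundance, write_fasta
from .seqset import AbundanceTable, ProteinRecord
from .sigpred import heuristic_predict

# amino acid -> synonymous codons, sorted for determinism
CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    CODONS.setdefault(_aa, ())
    CODONS[_aa] = CODONS[_aa] + (_codon,)
STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))
_SENSE_NON_ATG: tuple[str, ...] = tuple(
    sorted(c for c in standard_dna_table.forward_table if c != "ATG")
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Mature length 20-46 aa and a 4-7 residue Rana-box loop reflect the
    validated frog-skin peptides; the 0.5 upstream-ATG probability makes
    the rescued and directly-recognized subpopulations comparably sized.
    """

    upstream_atg_prob: float = 0.5
    extension_len_range: tuple[int, int] = (6, 14)    # aa translated from the false start
    utr5_codons_range: tuple[int, int] = (4, 20)      # scrubbed codons upstream of any start
    utr3_len_range: tuple[int, int] = (30, 90)        # nt
    h_run_range: tuple[int, int] = (6, 8)
    filler_range: tuple[int, int] = (3, 6)
    propiece_len_range: tuple[int, int] = (10, 18)
    propiece_acidity: float = 0.55
    min_propiece_acid_fraction: float = 0.40
    mature_len_range: tuple[int, int] = (20, 46)
    rana_gap_range: tuple[int, int] = (4, 7)
    max_retries: int = 50


DEFAULT_CONFIG = SimConfig()

_HYDRO_RUN_ALPHABET = "LFIV"
_FILLER_ALPHABET = "STGNQ"
_PROPIECE_OTHER = "SNQGAT"
_MATURE_CORE = "GLKASVNTIFM"
_MATURE_FIRST = "GLFVI"
_RANA_GAP_ALPHABET = "KLASGITNF"
_EXTENSION_ALPHABET = "STNQEDGH"  # non-hydrophobic: the elongated form must fail the h-region rule


@dataclass
class SyntheticPrecursor:
    """One synthetic precursor with full ground truth.

    ``annotated_protein`` is what a longest-ORF caller would report (the
    N-terminally elongated form when ``has_upstream_atg``); ``true_protein``
    starts at the real signal-peptide Met.  Spans are 1-based inclusive in
    true-protein coordinates.
    """

    transcript_id: str
    protein_id: str
    seed: int
    has_upstream_atg: bool
    extension_len: int           # 0 when there is no upstream ATG
    true_protein: str
    annotated_protein: str
    signal_len: int
    propiece_len: int
    mature: str
    rana_box: tuple[int, int]    # Cys positions within the mature peptide
    transcript: str
    utr5_len: int
    cds_start: int               # 1-based nt start of the annotated protein
    true_cds_start: int          # 1-based nt start of the true protein

    @property
    def signal_span(self) -> tuple[int, int]:
        return (1, self.signal_len)

    @property
    def propiece_span(self) -> tuple[int, int]:
        return (self.signal_len + 1, self.signal_len + self.propiece_len)

    @property
    def mature_span(self) -> tuple[int, int]:
        start = self.signal_len + self.propiece_len + 1
        return (start, start + len(self.mature) - 1)


def _draw(rng: np.random.Generator, alphabet: str, k: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=k))


def _encode(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        CODONS[aa][rng.integers(0, len(CODONS[aa]))] for aa in protein
    )


def _build_signal(rng: np.random.Generator, cfg: SimConfig) -> str:
    # Met-Phe-Thr start, Lys charge at position 5, hydrophobic core from
    # position 7, non-hydrophobic filler, Leu-Cys cleavage junction.
    x4 = "LIS"[rng.integers(0, 3)]
    x6 = "ST"[rng.integers(0, 2)]
    h_run = _draw(rng, _HYDRO_RUN_ALPHABET, int(rng.integers(*cfg.h_run_range, endpoint=True)))
    filler = _draw(rng, _FILLER_ALPHABET, int(rng.integers(*cfg.filler_range, endpoint=True)))
    return "MFT" + x4 + "K" + x6 + h_run + filler + "LC"


def _build_propiece(rng: np.random.Generator, cfg: SimConfig) -> str:
    length = int(rng.integers(*cfg.propiece_len_range, endpoint=True))
    core_len = length - 2  # the terminal Lys-Arg is fixed
    for _ in range(cfg.max_retries):
        core = "".join(
            "DE"[rng.integers(0, 2)]
            if rng.random() < cfg.propiece_acidity
            else _PROPIECE_OTHER[rng.integers(0, len(_PROPIECE_OTHER))]
            for _ in range(core_len)
        )
        acid_fraction = sum(c in "DE" for c in core) / length
        if acid_fraction >= cfg.min_propiece_acid_fraction:
            return core + "KR"
    raise RuntimeError("could not satisfy propiece acidity within the retry budget")


def _build_mature(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, tuple[int, int]]:
    length = int(rng.integers(*cfg.mature_len_range, endpoint=True))
    gap = int(rng.integers(*cfg.rana_gap_range, endpoint=True))
    core_len = length - gap - 2
    core = _MATURE_FIRST[rng.integers(0, len(_MATURE_FIRST))] + _draw(
        rng, _MATURE_CORE, core_len - 1
    )
    mature = core + "C" + _draw(rng, _RANA_GAP_ALPHABET, gap) + "C"
    return mature, (core_len + 1, length)


def make_precursor(
    seed: int,
    config: SimConfig = DEFAULT_CONFIG,
    transcript_id: str = "TRINITY_DN0_c0_g1_i1",
    protein_suffix: str = ".p1",
) -> SyntheticPrecursor:
    """Generate one precursor, deterministically for a given seed.

    Postconditions (asserted, with bounded retries): the heuristic predictor
    is positive on the true-start protein with cleavage exactly at the
    signal end, and negative on the elongated protein whenever an upstream
    in-frame ATG is present.
    """
    rng = np.random.default_rng(seed)
    for _ in range(config.max_retries):
        signal = _build_signal(rng, config)
        propiece = _build_propiece(rng, config)
        mature, rana_box = _build_mature(rng, config)
        true_protein = signal + propiece + mature

        pred = heuristic_predict(true_protein)
        if not (pred.is_secretory and pred.cleavage_after == len(signal)):
            continue

        has_upstream = bool(rng.random() < config.upstream_atg_prob)
        if has_upstream:
            ext_len = int(rng.integers(*config.extension_len_range, endpoint=True))
            extension = "M" + _draw(rng, _EXTENSION_ALPHABET, ext_len - 1)
            annotated = extension + true_protein
            if heuristic_predict(annotated).is_secretory:
                continue
        else:
            ext_len = 0
            annotated = true_protein

        utr5_codons = int(rng.integers(*config.utr5_codons_range, endpoint=True))
        pre = "".join(
            _SENSE_NON_ATG[rng.integers(0, len(_SENSE_NON_ATG))]
            for _ in range(utr5_codons)
        )
        cds = _encode(rng, annotated)
        stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        utr3 = _draw(rng, "ACGT", int(rng.integers(*config.utr3_len_range, endpoint=True)))
        transcript = pre + cds + stop + utr3

        cds_start = len(pre) + 1
        return SyntheticPrecursor(
            transcript_id=transcript_id,
            protein_id=transcript_id + protein_suffix,
            seed=seed,
            has_upstream_atg=has_upstream,
            extension_len=ext_len,
            true_protein=true_protein,
            annotated_protein=annotated,
            signal_len=len(signal),
            propiece_len=len(propiece),
            mature=mature,
            rana_box=rana_box,
            transcript=transcript,
            utr5_len=len(pre) + 3 * ext_len,
            cds_start=cds_start,
            true_cds_start=cds_start + 3 * ext_len,
        )
    raise RuntimeError(f"generator constraints unsatisfiable for seed {seed}")


# --------------------------------------------------------------------------
# peptide tables


def master_accession(precursor: SyntheticPrecursor) -> str:
    """The search-database entry the mature peptide resolves to.

    For an elongated precursor that is the first ORF-shift variant (the true
    start is the first internal Met); otherwise the annotated protein.
    """
    if precursor.has_upstream_atg:
        return precursor.protein_id + "_ORF1"
    return precursor.protein_id


def make_peptide_table(
    precursors: Sequence[SyntheticPrecursor],
    seed: int,
    ladder_depth: int = 4,
    decay: float = 0.5,
    include_decoy: bool = True,
    include_low_confidence: bool = True,
    include_shared: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict]]:
    """Emulate a DDA peptide export with known ground truth.

    Per precursor: the mature backbone at top abundance (>= 3 PSMs,
    ``2xDehydro [C]`` for the Rana-box cysteines, occasionally split into
    two isoforms to exercise combination) and *ladder_depth* N-terminal
    truncations at geometrically decaying abundance.  Adds one odd-dehydro
    decoy, one Low-confidence master with an exclusive peptide, and one
    peptide shared between two masters.  Returns (peptide table, master
    table, truth) where truth maps master accession to the expected call.
    """
    if not 0 < decay < 1:
        raise ValueError("decay must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pep_rows: list[dict] = []
    truth: dict[str, dict] = {}
    psm_by_master: dict[str, int] = {}

    def add_row(seq, mods, abundance, psms, confidence, masters):
        pep_rows.append(
            {
                "Sequence": seq,
                "Modifications": mods,
                "Abundance": f"{abundance:.1f}",
                "# PSMs": psms,
                "Confidence": confidence,
                "Master Protein Accessions": "; ".join(masters),
            }
        )
        for acc in masters:
            psm_by_master[acc] = psm_by_master.get(acc, 0) + psms

    for prec in precursors:
        acc = master_accession(prec)
        base = float(10 ** rng.uniform(6, 8))
        mature_psms = int(rng.integers(3, 13))
        mods = "2xDehydro [C]"
        if rng.random() < 0.3:  # split the mature peptide into two isoforms
            a1 = base * 0.6
            add_row(prec.mature, mods, a1, max(mature_psms - 1, 1), "High", [acc])
            add_row(
                prec.mature,
                mods + "; 1xDeamidated [N]",
                base - a1,
                1,
                "High",
                [acc],
            )
            mature_psms = max(mature_psms - 1, 1) + 1
        else:
            add_row(prec.mature, mods, base, mature_psms, "High", [acc])
        for i in range(1, ladder_depth + 1):
            add_row(
                prec.mature[i:],
                mods,
                base * decay**i,
                int(rng.integers(1, 4)),
                "High",
                [acc],
            )
        truth[acc] = {
            "mature": prec.mature,
            "n_truncated": ladder_depth,
            "abundance": base,
            "psm_total": mature_psms,
        }

    if include_decoy and precursors:
        acc = master_accession(precursors[0])
        # huge abundance but an odd dehydro count: must be filtered out
        add_row(precursors[0].mature[:-1], "1xDehydro [C]", 1e9, 2, "High", [acc])
    if include_shared and len(precursors) >= 2:
        accs = [master_accession(p) for p in precursors[:2]]
        add_row("GLWSNFKQGMGK", "", 5e8, 4, "High", accs)

    master_rows = [
        {
            "Accession": master_accession(p),
            "FDR Confidence": "High",
            "# PSMs": psm_by_master.get(master_accession(p), 0),
            "Has Stop": "TRUE",
        }
        for p in precursors
    ]
    if include_low_confidence:
        add_row("SSNNGGQQSSNNGG", "", 2e7, 5, "High", ["LOWCONF_1"])
        master_rows.append(
            {
                "Accession": "LOWCONF_1",
                "FDR Confidence": "Low",
                "# PSMs": psm_by_master.get("LOWCONF_1", 0),
                "Has Stop": "TRUE",
            }
        )
    peptide_df = pd.DataFrame(
        pep_rows,
        columns=[
            "Sequence",
            "Modifications",
            "Abundance",
            "# PSMs",
            "Confidence",
            "Master Protein Accessions",
        ],
    )
    master_df = pd.DataFrame(
        master_rows, columns=["Accession", "FDR Confidence", "# PSMs", "Has Stop"]
    )
    return peptide_df, master_df, truth


# --------------------------------------------------------------------------
# whole populations


@dataclass
class Population:
    """Everything the end-to-end pipeline needs, with ground truth."""

    seed: int
    precursors: list[SyntheticPrecursor]
    background: list[ProteinRecord]
    abundance: AbundanceTable
    peptide_table: pd.DataFrame
    master_table: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def protein_records(self) -> list[ProteinRecord]:
        records = [
            ProteinRecord(
                id=p.protein_id,
                sequence=p.annotated_protein,
                has_stop=True,
                parent_transcript_id=p.transcript_id,
            )
            for p in self.precursors
        ]
        records.extend(self.background)
        return records

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [(r.id, r.sequence + ("*" if r.has_stop else "")) for r in self.protein_records()],
            out / "proteins.fasta",
        )
        write_fasta(
            [(p.transcript_id, p.transcript) for p in self.precursors],
            out / "transcripts.fasta",
        )
        write_abundance(self.abundance, out / "abundance.tsv")
        self.peptide_table.to_csv(out / "peptides.tsv", sep="\t", index=False)
        self.master_table.to_csv(out / "masters.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def make_population(
    n: int,
    seed: int,
    config: SimConfig = DEFAULT_CONFIG,
    n_background: Optional[int] = None,
    low_abundance_fraction: float = 0.1,
    ladder_depth: int = 4,
    decay: float = 0.5,
    outdir=None,
) -> Population:
    """Generate *n* precursors plus non-secretory background proteins.

    Background proteins never start with Met, so they are guaranteed
    negatives for the heuristic; a *low_abundance_fraction* of them sit
    below one read to exercise the expression filter.  When *outdir* is
    given, all pipeline input files plus ``truth.json`` are written there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
    precursors = [
        make_precursor(sub_seeds[i], config, transcript_id=f"TRINITY_DN{i}_c0_g1_i1")
        for i in range(n)
    ]

    n_bg = n // 2 if n_background is None else n_background
    background: list[ProteinRecord] = []
    counts: dict[str, float] = {}
    for i in range(n_bg):
        length = int(rng.integers(30, 200))
        seq = _draw(rng, "ACDEFGHIKLNPQRSTVWY", 1) + _draw(
            rng, "ACDEFGHIKLMNPQRSTVWY", length - 1
        )
        if seq[0] == "M":  # unreachable with the first-residue alphabet; belt and braces
            seq = "G" + seq[1:]
        tid = f"TRINITY_DN{n + i}_c0_g1_i1"
        background.append(
            ProteinRecord(id=tid + ".p1", sequence=seq, has_stop=True, parent_transcript_id=tid)
        )
        low = rng.random() < low_abundance_fraction
        counts[tid] = float(rng.uniform(0.1, 0.9)) if low else float(10 ** rng.uniform(0.5, 3))
    for p in precursors:
        counts[p.transcript_id] = float(10 ** rng.uniform(0.5, 3))
    abundance = AbundanceTable({tid: (c, c / 10.0) for tid, c in counts.items()})

    table_seed = int(rng.integers(0, 2**31 - 1))
    peptide_df, master_df, call_truth = make_peptide_table(
        precursors, table_seed, ladder_depth=ladder_depth, decay=decay
    )

    truth = {
        "seed": seed,
        "n": n,
        "precursors": [
            {
                "transcript_id": p.transcript_id,
                "protein_id": p.protein_id,
                "master_accession": master_accession(p),
                "has_upstream_atg": p.has_upstream_atg,
                "extension_len": p.extension_len,
                "signal_len": p.signal_len,
                "propiece_len": p.propiece_len,
                "mature": p.mature,
                "rana_box": list(p.rana_box),
                "cds_start": p.cds_start,
                "true_cds_start": p.true_cds_start,
            }
            for p in precursors
        ],
        "calls": call_truth,
    }
    population = Population(
        seed=seed,
        precursors=precursors,
        background=background,
        abundance=abundance,
        peptide_table=peptide_df,
        master_table=master_df,
        truth=truth,
    )
    if outdir is not None:
        population.write(outdir)
    return population
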