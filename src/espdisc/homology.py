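"""Two-pass homology-search policy with an in-repo local-alignment fallback.

Short secreted peptides defeat default protein-BLAST settings, so the search
policy is length-dependent: queries of 30 residues or fewer use a permissive
short-query parameter set (E-value 1, 65% identity floor, ungapped bitscore
floor and sensitivity flags), longer queries a stricter sensitive set
(E-value 1e-3).  The external aligner (a DIAMOND/BLASTP-compatible engine)
is driven through command emission and 12-column tabular parsing only; for
desk-scale work and testing, ``naive_local_align`` provides a Smith-Waterman
local aligner with affine gaps, and ``two_pass_search`` runs the full
two-pass policy in-process:

  pass 1: intermediate sequences against the reference databases;
  pass 2: signal peptides of still-unhit queries against the signal
          peptides of pass-1 successes and of already-matched proteins --
          the "fish out" pass that recovers family members whose mature
          region has diverged beyond recognition.

In-repo search mode uses a raw-score threshold as a stand-in for an E-value
cutoff; its statistics are deliberately simpler than an external engine's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

SHORT_QUERY_MAX = 30

SHORT_EXTRA_FLAGS = (
    "--short-query-ungapped-bitscore",
    "15",
    "--gapped-filter-evalue",
    "0",
    "--shape-mask",
    "1111",
    "--block-size",
    "3",
)
LONG_EXTRA_FLAGS = ("--more-sensitive",)


@dataclass(frozen=True)
class ParamSet:
    """Aligner parameters; flags are emitted in a fixed order."""

    evalue: float
    min_identity: Optional[float]
    extra_flags: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")

    def evalue_str(self) -> str:
        if self.evalue == 1:
            return "1"
        if self.evalue == 1e-3:
            return "1e-3"
        return f"{self.evalue:g}"

    def flag_list(self) -> list[str]:
        flags = ["--evalue", self.evalue_str()]
        if self.min_identity is not None:
            flags += ["--id", f"{self.min_identity:g}"]
        flags += list(self.extra_flags)
        return flags


SHORT_PARAMS = ParamSet(evalue=1.0, min_identity=65.0, extra_flags=SHORT_EXTRA_FLAGS)
LONG_PARAMS = ParamSet(evalue=1e-3, min_identity=None, extra_flags=LONG_EXTRA_FLAGS)


def choose_params(query_length: int) -> ParamSet:
    """Length-dependent parameter policy; the boundary at 30 aa is inclusive
    for the short set."""
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    return SHORT_PARAMS if query_length <= SHORT_QUERY_MAX else LONG_PARAMS


def emit_search_command(
    db_path: str,
    query_path: str,
    params: ParamSet,
    out_path: str,
    program: str = "diamond blastp",
) -> str:
    """Deterministic external-aligner command requesting 12-column tabular
    output; the parameter flags are embedded verbatim."""
    if not db_path or not query_path or not out_path:
        raise ValueError("db, query and output paths must be non-empty")
    parts = [
        program,
        "--db",
        db_path,
        "--query",
        query_path,
        *params.flag_list(),
        "--outfmt",
        "6",
        "--out",
        out_path,
    ]
    return " ".join(parts)


# --------------------------------------------------------------------------
# tabular results


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity outside [0, 100]")


def parse_tabular_hits(text: str) -> list[HomologyHit]:
    """Parse 12-column tab-separated alignment output (the BLAST tabular
    standard: query, subject, %id, length, mismatches, gap opens, qstart,
    qend, sstart, send, evalue, bitscore)."""
    hits: list[HomologyHit] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"expected 12 columns at line {lineno}, found {len(fields)}"
            )
        hits.append(
            HomologyHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                query_span=(int(fields[6]), int(fields[7])),
                subject_span=(int(fields[8]), int(fields[9])),
            )
        )
    return hits


def top_hits(hits: Sequence[HomologyHit]) -> dict[str, HomologyHit]:
    """Best hit per query: maximal bitscore, ties broken by subject id."""
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if (
            cur is None
            or hit.bitscore > cur.bitscore
            or (hit.bitscore == cur.bitscore and hit.subject_id < cur.subject_id)
        ):
            best[hit.query_id] = hit
    return best


# --------------------------------------------------------------------------
# in-repo local alignment


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    percent_identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


def _default_matrix():
    return substitution_matrices.load("BLOSUM62")


def naive_local_align(
    q: str,
    s: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Optional[LocalAlignment]:
    """Smith-Waterman local alignment with affine gaps (Gotoh recurrences).

    A gap of length k costs ``gap_open + k * gap_extend``.  Identity is
    matching columns over all alignment columns, in percent.  Returns
    ``None`` when no alignment scores above zero.
    """
    if not q or not s:
        raise ValueError("naive_local_align requires non-empty sequences")
    mat = matrix if matrix is not None else _default_matrix()
    m, n = len(q), len(s)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (along s)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (along q)

    best, best_cell = 0.0, None
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + mat[q[i - 1], s[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_cell = H[i][j], (i, j)
    if best <= 0 or best_cell is None:
        return None

    # traceback
    i, j = best_cell
    state = "H"
    matches = columns = 0
    q_end, s_end = i, j
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + mat[q[i - 1], s[j - 1]]
            if H[i][j] == diag:
                matches += q[i - 1] == s[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
        else:  # F
            columns += 1
            if F[i][j] == H[i - 1][j] - gap_open - gap_extend:
                state = "H"
            i -= 1
    return LocalAlignment(
        score=best,
        percent_identity=100.0 * matches / columns,
        query_span=(i + 1, q_end),
        subject_span=(j + 1, s_end),
    )


# --------------------------------------------------------------------------
# two-pass search


@dataclass(frozen=True)
class QuerySplit:
    """A candidate precursor split at its signal cleavage site."""

    id: str
    signal: str
    intermediate: str


class LocalSearch:
    """In-repo FASTA-vs-FASTA search built on :func:`naive_local_align`.

    Acceptance follows the length-dependent parameter policy with a raw
    alignment-score floor standing in for the E-value cutoff: short queries
    must reach ``short_min_score`` and the short set's identity floor, long
    queries ``long_min_score``.
    """

    def __init__(
        self,
        matrix=None,
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
        short_min_score: float = 15.0,
        long_min_score: float = 40.0,
    ):
        self.matrix = matrix if matrix is not None else _default_matrix()
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.short_min_score = short_min_score
        self.long_min_score = long_min_score

    def search(
        self, query_id: str, query: str, db: Sequence[tuple[str, str]]
    ) -> list[HomologyHit]:
        params = choose_params(len(query))
        min_score = (
            self.short_min_score if params is SHORT_PARAMS else self.long_min_score
        )
        hits: list[HomologyHit] = []
        for subject_id, subject in db:
            aln = naive_local_align(
                query, subject, self.matrix, self.gap_open, self.gap_extend
            )
            if aln is None or aln.score < min_score:
                continue
            if (
                params.min_identity is not None
                and aln.percent_identity < params.min_identity
            ):
                continue
            hits.append(
                HomologyHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    percent_identity=round(aln.percent_identity, 1),
                    alignment_length=aln.query_span[1] - aln.query_span[0] + 1,
                    evalue=0.0,  # score-threshold surrogate; no E-value model
                    bitscore=aln.score,
                    query_span=aln.query_span,
                    subject_span=aln.subject_span,
                )
            )
        return hits


def two_pass_search(
    candidates: Sequence[QuerySplit],
    reference_dbs: Mapping[str, Sequence[tuple[str, str]]],
    sps_signal_db: Sequence[tuple[str, str]],
    searcher: Optional[LocalSearch] = None,
) -> tuple[dict[str, list[HomologyHit]], list[str]]:
    """Run the two-pass policy in-process.

    Pass 1 queries every candidate's intermediate sequence against each
    reference database.  Candidates with zero hits proceed to pass 2, where
    their signal peptides are searched against a database assembled from
    *sps_signal_db* (signal peptides of proteins already matched in the
    search set) plus the signal peptides of pass-1 successes.  Returns the
    merged per-candidate hit lists and the ids still unhit after both
    passes.
    """
    searcher = searcher or LocalSearch()
    hits: dict[str, list[HomologyHit]] = {}
    pass1_successes: list[QuerySplit] = []
    unhit_after_1: list[QuerySplit] = []
    for cand in candidates:
        found: list[HomologyHit] = []
        for db in reference_dbs.values():
            found.extend(searcher.search(cand.id, cand.intermediate, db))
        if found:
            hits[cand.id] = found
            pass1_successes.append(cand)
        else:
            unhit_after_1.append(cand)

    signal_db = list(sps_signal_db) + [
        (c.id, c.signal) for c in pass1_successes if c.signal
    ]
    unhit: list[str] = []
    for cand in unhit_after_1:
        if not cand.signal:
            logger.warning("candidate %s has an empty signal peptide; skipped in pass 2", cand.id)
            unhit.append(cand.id)
            continue
        found = searcher.search(cand.id, cand.signal, signal_db) if signal_db else []
        if found:
            hits[cand.id] = found
        else:
            unhit.append(cand.id)
    return hits, unhit
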