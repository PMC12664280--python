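"""Signal-peptide prediction: external-output parsing and a built-in heuristic.

Real pipelines run a neural-network predictor (SignalP) on every candidate
protein.  This module supplies (a) a parser for the SignalP-5 short tabular
output so such runs can be plugged in, and (b) ``heuristic_predict``, a small
deterministic window-based rule set that captures the textbook architecture
of a eukaryotic signal peptide (charged n-region, hydrophobic h-region,
cleavage motif within the first ~40 residues).  The heuristic is intentionally
simple: it exists so that synthetic precursors can be constructed to sit on
either side of it, making the whole pipeline testable without external
binaries.  It is a test oracle for the workflow, not a reimplementation of a
neural predictor.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Residues counted as hydrophobic for the h-region rule.
HYDROPHOBIC = frozenset("ACFILMVW")

_CS_POS = re.compile(r"CS pos:\s*(\d+)-(\d+)")


@dataclass(frozen=True)
class SignalPrediction:
    """Outcome of a signal-peptide call on one sequence.

    ``cleavage_after`` is the 1-based residue index after which the signal
    peptidase cuts; it is 0 whenever ``is_secretory`` is false.
    """

    sequence_id: str
    is_secretory: bool
    cleavage_after: int
    likelihood: float

    def __post_init__(self) -> None:
        if not self.is_secretory and self.cleavage_after != 0:
            raise ValueError("non-secretory prediction must have cleavage_after == 0")
        if not 0.0 <= self.likelihood <= 1.0:
            raise ValueError("likelihood must be a fraction in [0, 1]")


# --------------------------------------------------------------------------
# SignalP 5 short-format parser


def parse_signalp5(text: str) -> list[SignalPrediction]:
    """Parse SignalP-5 short tabular output.

    Comment lines start with ``#``.  Data columns: ID, Prediction,
    SP(Sec/SPI) probability, OTHER probability, and (for secretory rows) a
    cleavage-site field like ``CS pos: 22-23. Pr: 0.97``.  Rows predicted
    ``SP(Sec/SPI)`` become positive calls with ``cleavage_after`` taken from
    the first number of the CS field; ``OTHER`` rows are negative.  A
    secretory row without a parseable CS position is kept positive with
    ``cleavage_after=0`` and a warning; anything else raises with the line
    number.
    """
    predictions: list[SignalPrediction] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"unparseable SignalP row at line {lineno}: {raw!r}")
        seq_id, prediction, sp_prob_s = fields[0], fields[1], fields[2]
        try:
            sp_prob = float(sp_prob_s)
        except ValueError as exc:
            raise ValueError(f"bad probability at line {lineno}: {raw!r}") from exc
        if prediction == "SP(Sec/SPI)":
            m = _CS_POS.search(line)
            if m:
                cleavage = int(m.group(1))
            else:
                logger.warning(
                    "secretory row without CS position at line %d (%s)", lineno, seq_id
                )
                cleavage = 0
            predictions.append(SignalPrediction(seq_id, True, cleavage, sp_prob))
        elif prediction == "OTHER":
            predictions.append(SignalPrediction(seq_id, False, 0, sp_prob))
        else:
            raise ValueError(
                f"unknown prediction {prediction!r} at line {lineno}: {raw!r}"
            )
    return predictions


# --------------------------------------------------------------------------
# built-in heuristic


@dataclass(frozen=True)
class HeuristicParams:
    """Tunable windows of the heuristic signal-peptide rule.

    Defaults reflect typical eukaryotic signal peptides: a charged residue
    early in the n-region, a hydrophobic core of at least six residues
    beginning within the first dozen positions, and a cleavage site no deeper
    than residue 40.
    """

    min_length: int = 15
    charge_window_end: int = 6      # K/R required within residues 2..6
    h_run_min: int = 6              # minimum hydrophobic run length
    h_start_min: int = 2            # 1-based window for the run start
    h_start_max: int = 12
    cleavage_max: int = 40          # deepest allowed motif start
    tail_margin: int = 5            # motif start <= len - tail_margin
    positive_likelihood: float = 0.9
    negative_likelihood: float = 0.1


DEFAULT_HEURISTIC = HeuristicParams()


def heuristic_predict(
    sequence: str,
    sequence_id: str = "",
    params: HeuristicParams = DEFAULT_HEURISTIC,
) -> SignalPrediction:
    """Deterministic rule-based signal-peptide call.

    Positive iff all of:

    a. residue 1 is Met;
    b. at least one of K/R occurs within residues 2..6 (n-region charge);
    c. a run of >= 6 consecutive hydrophobic residues (A,C,F,I,L,M,V,W)
       starts within residues 2..12 (h-region); the run is extended
       maximally to locate its end;
    d. a cleavage motif is found with its first residue in positions
       (h-end + 1) .. min(len - 5, 40): the first occurrence of X-C (any
       residue then Cys) or A-X-A, cleaving after the motif's second
       residue.

    Sequences shorter than 15 residues are negative with likelihood 0 (too
    short to host a signal peptide).  The call is a pure function of the
    sequence.
    """
    seq = sequence
    n = len(seq)

    def negative(likelihood: float) -> SignalPrediction:
        return SignalPrediction(sequence_id, False, 0, likelihood)

    if n < params.min_length:
        return negative(0.0)
    if seq[0] != "M":
        return negative(params.negative_likelihood)
    if not any(c in "KR" for c in seq[1 : params.charge_window_end]):
        return negative(params.negative_likelihood)

    h_end = 0  # 1-based index of the last residue of the hydrophobic run
    for start0 in range(params.h_start_min - 1, params.h_start_max):
        window = seq[start0 : start0 + params.h_run_min]
        if len(window) == params.h_run_min and all(c in HYDROPHOBIC for c in window):
            end0 = start0 + params.h_run_min
            while end0 < n and seq[end0] in HYDROPHOBIC:
                end0 += 1
            h_end = end0
            break
    if h_end == 0:
        return negative(params.negative_likelihood)

    last_start = min(n - params.tail_margin, params.cleavage_max)
    for pos1 in range(h_end + 1, last_start + 1):
        i = pos1 - 1
        if seq[i + 1] == "C":  # X-C: cleave after the Cys
            return SignalPrediction(sequence_id, True, pos1 + 1, params.positive_likelihood)
        if seq[i] == "A" and i + 2 < n and seq[i + 2] == "A":  # A-X-A
            return SignalPrediction(sequence_id, True, pos1 + 1, params.positive_likelihood)
    return negative(params.negative_likelihood)


# --------------------------------------------------------------------------
# predictor objects usable by seqset.build_osps


class HeuristicPredictor:
    """Callable wrapper around :func:`heuristic_predict`."""

    def __init__(self, params: HeuristicParams = DEFAULT_HEURISTIC):
        self.params = params

    def __call__(self, sequence_id: str, sequence: str) -> SignalPrediction:
        return heuristic_predict(sequence, sequence_id, self.params)


class SignalP5TablePredictor:
    """Predictor backed by a parsed SignalP-5 output table.

    Sequences absent from the table are treated as negative with a warning,
    matching the pipeline contract that a predictor failure never aborts set
    construction.
    """

    def __init__(self, predictions: Iterable[SignalPrediction]):
        self._by_id: Mapping[str, SignalPrediction] = {
            p.sequence_id: p for p in predictions
        }

    @classmethod
    def from_text(cls, text: str) -> "SignalP5TablePredictor":
        return cls(parse_signalp5(text))

    @classmethod
    def from_path(cls, path) -> "SignalP5TablePredictor":
        with open(path, encoding="utf-8") as fh:
            return cls.from_text(fh.read())

    def __call__(self, sequence_id: str, sequence: str) -> SignalPrediction:
        pred = self._by_id.get(sequence_id)
        if pred is None:
            logger.warning("no SignalP row for %s; treating as negative", sequence_id)
            return SignalPrediction(sequence_id, False, 0, 0.0)
        return pred
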