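# Methods

## The precursor model

`espdisc` assumes the canonical architecture of a secreted peptide
precursor, N→C:

    signal peptide → (acidic) propiece → basic processing site →
    mature peptide(s) → optional second site → optional residual piece → stop

For frog-skin (FSAP-family) precursors the conserved features are a
Met-Phe-Thr signal start, a Leu-Cys signal cleavage junction, an acidic
propiece ending in Lys-Arg, a hypervariable 20–46 aa mature peptide, and a
C-terminal Cys-(X)<sub>n</sub>-Cys disulfide loop (Rana box).  All spans are
reported 1-based inclusive; the Rana-box positions are relative to the
mature peptide.  The cleavage "dipeptide" naming convention is the two
residues flanking the scissile bond: a Leu-Cys site means the signal's last
two residues are L,C (the propiece, not the mature peptide, follows the
Cys).

## Start-site rescue

Longest-ORF callers can start translation at an upstream in-frame ATG in
the 5′-UTR.  The elongated protein displaces the hydrophobic h-region out
of the N-terminal window that signal-peptide predictors evaluate, producing
a false negative.  The rescue is purely combinatorial: every internal Met
(position ≥ 2) whose suffix is ≥ 20 aa defines a truncation variant
(`_ORF1`, `_ORF2`, … with increasing N-terminal removal); the predictor is
re-run on the whole series.  The OSPS keeps, per secretory series, the
full-length parent plus every positive variant — this composition makes the
set sizes self-consistent: |OSPS| = non-redundant series count + variants
new to the FPS, which is also why |SPS| − |FPS| equals the number of
rescued variant sequences.  Reported percentages are rounded half-up to one
decimal.

## The heuristic signal predictor

The built-in predictor is a deterministic, window-based caricature of a
eukaryotic signal peptide, chosen so synthetic fixtures can be constructed
on either side of it.  Positive iff: (a) residue 1 is Met; (b) ≥ 1 K/R in
residues 2–6; (c) a run of ≥ 6 hydrophobic residues (A,C,F,I,L,M,V,W)
starting within residues 2–12; (d) a cleavage motif — first X-C or A-X-A —
starting between the end of that run and residue min(len−5, 40), cleaving
after the motif's second residue.  Sequences under 15 aa are negative with
likelihood 0; positives carry likelihood 0.9, negatives 0.1.  The 40-residue
cap keeps the motif search out of the mature region; the 2–12 start window
is what the upstream-start failure mode exploits.  This is a test oracle
and workflow stand-in, not a reimplementation of a neural predictor; real
runs should use the SignalP-5 tabular adapter (organism group and
probability cutoff are properties of the external run, not hard-coded
here).

## Mature-peptide calling

Filters operate in a fixed order (confidence → dehydro parity → isoform
combination → selection → final filter), though the first two commute.
Decisions that needed fixing where the workflow description is ambiguous:

* **Exclusivity is recomputed after confidence filtering** — a peptide
  shared with a Low-confidence master becomes exclusive once that master is
  dropped, mirroring how search engines regroup filtered results.
* **Call abundance is the accumulated (summed) isoform abundance**, not the
  maximal single isoform.
* **Final filter semantics**: "removed when all precursor proteins had
  fewer than 3 PSMs or lacked a stop codon" is read conjunctively — a call
  survives iff at least one master has ≥ 3 PSMs *and* a stop codon.  The
  alternative reading (one master passes each bar independently) is
  available via `final_filter_semantics: independent`.
* **Ties** in abundance break by greater length, then lexicographically —
  not biologically motivated, purely for determinism.
* **Ile/Leu are distinct characters**; matching is textual even though MS
  cannot distinguish them.
* An intact disulfide contributes exactly two dehydro-Cys (−1.008 Da each),
  so an odd per-peptide count marks an unreliable identification; zero is
  even and kept.

## Processing-site inference

With a mature-peptide hint (an MS-validated backbone), the mature start is
forced to the hint's first occurrence and the site is whatever 1–2 basic
residues precede it.  Without a hint, the intermediate is scanned left to
right for a dibasic site (KR preferred over RR/KK) whose downstream segment
is 3–100 aa; a single Arg is accepted only as a fallback; with no basic
site the precursor is flagged "unprocessed" and treated as entirely mature.
The propiece span includes the basic residues so that
signal + propiece + mature (+ residual) tile the precursor exactly — the
partition is asserted in tests.  These rules are an explicit, reproducible
approximation of expert manual annotation (e.g. recognizing acidic
propieces); they are not a convertase model.

## Homology policy

Parameter choice is a pure function of query length with the boundary at 30
aa inclusive for the short set (E-value 1, identity ≥ 65%, ungapped
bitscore floor 15, gapped-filter/shape-mask/block-size flags) and the
sensitive set (E-value 1e-3) above it.  External engines are driven only
through command emission and 12-column tabular parsing; "top hit" is max
bitscore per query with subject-id tie-breaks.  The in-repo search mode is
a hand-written Smith–Waterman with affine gaps (BLOSUM62, gap = 11 + k·1,
the matrix loaded from Biopython) whose acceptance rule substitutes a raw
score floor (15 short / 40 long) for an E-value cutoff — deliberately
simpler statistics, labeled as such, and validated against exhaustive
alignment enumeration on short sequences.  Pass 2 of the two-pass search
queries the signal peptides of still-unhit candidates against the signal
peptides of pass-1 successes and already-matched proteins, recovering
family members whose mature region has diverged beyond recognition; "unhit"
means zero reported rows.

## Synthetic data: what it does and does not emulate

`simulate.make_precursor` draws a signal peptide satisfying heuristic rules
(a)–(d) exactly at the true start ("MFT" + charge + hydrophobic run +
filler + "LC"), an acidic propiece (≥ 40% D/E, sampled at 55% acidity)
ending in KR with no other basic residues, and a mature peptide of 20–46 aa
ending in a Rana box with a 4–7 residue loop.  With probability 0.5 the
transcript carries an upstream in-frame ATG whose 6–14 aa extension is
drawn from non-hydrophobic residues, guaranteeing the elongated protein
fails rule (c); the generator asserts both predictor postconditions and
retries within a bounded budget.  Codons are uniform over synonymous
codons; upstream UTR codons exclude ATG so the annotated start is
well-defined.  Peptide tables carry a geometric truncation ladder
(default depth 4, decay 0.5), an odd-dehydro decoy, a Low-confidence master
and a shared peptide.

Because generator and predictor are co-designed, passing tests demonstrate
that the *workflow* (rescue, set arithmetic, calling, annotation) is
correct — they say nothing about real-data predictor accuracy, MS noise,
missingness, chimeric transcripts, or I/L ambiguity, none of which are
modeled.  Population sizes used in tests and in the acceptance script
(40 and 200 precursors, plus half as many non-secretory background
proteins, ~10% below one read) keep whole-suite runtimes in seconds while
leaving every filter with work to do.

## Phylogeny preparation

Region slicing is exact arithmetic on 1-based coordinates: r1 takes at most
45 nt of 5′-UTR (never padded) plus the signal CDS; r4 takes the stop codon
(validated as TAA/TAG/TGA) plus at most 45 nt of 3′-UTR.  Alignment and
trimming are delegated to external tools (MAFFT E-INS-i, automated
trimming, 1000 ultrafast bootstrap replicates are the recorded defaults);
the package owns per-region trimming-then-concatenation bookkeeping, gap
filling (`-`, not `?`) for taxa missing from a block, and RAxML-style
partition tables.

## Known limitations

* The heuristic predictor's rules are intentionally crude; OSPS composition
  on real data depends on the external predictor supplied.
* Provenance classes beyond the species tier need user-supplied catalogs;
  the bundled catalog covers only the 16 protein-level-validated mature
  peptides.
* The in-repo homology search has no E-value model and is quadratic per
  pair; it is for desk-scale candidate triage and testing, not database
  scans.
* Multi-mature precursors (2–3 mature peptides) are supported via repeated
  hint placement; scan-mode (hint-free) annotation assumes a single mature
  peptide ending at the C-terminus.
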