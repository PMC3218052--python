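# Methods

This note documents the models, conventions, parameter defaults and design
choices behind `shortprot`, and what the test suite does and does not
establish about behavior on real proteomes.

## Problem setting

The positive class is the short-lived protein: PSI (Protein Stability
Index) < 2.0, roughly a half-life under 30 minutes. Labels come either
from a user-supplied two-column PSI table (strict `psi < cutoff`
inequality; the cutoff is a parameter, default 2.0) or from the synthetic
generator's class of origin. Sequences are used exactly as provided: the
initiator methionine is never stripped, so "N-terminal residue" means
position 1 of the input. Coordinates are 0-based half-open internally and
rendered 1-based inclusive in human-readable output.

## Feature encoding

The 776-slot schema is a frozen registry (`seqio.build_schema`); both
feature modules emit exactly the registered names, once each, in order.

**k-mer blocks.** Di-peptide, class-dyad and class-triplet counts use
overlapping windows normalized by L−1 and L−2. A block whose window does
not fit the sequence (L < k) is all-zero. The distribution descriptor
reports, per class, the 1-based position of the 1st, 25%, 50%, 75% and
100% occurrence as a percentage of L; the k% occurrence is occurrence
number ⌈k·n_class⌉ clamped to ≥ 1; an absent class contributes five zeros.
Transitions are unordered class pairs, (n_xy + n_yx)/(L−1).

**Physicochemical.** Hydrophobicity is the GRAVY (mean Kyte–Doolittle
hydropathy). The isoelectric point uses the standard
Henderson–Hasselbalch charge model with the EMBOSS pKa set (N-term 8.6,
C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1), solved by
bisection on pH ∈ [0, 14] to |charge| < 1e-4. Both scales are module-level
constants a caller can monkeypatch or fork; they are the community
defaults, not tuned values.

**PEST.** Candidate segments are maximal stretches between positively
charged residues (R/K/H; termini also bound segments) of length ≥ 12
containing ≥ 1 P, ≥ 1 D/E and ≥ 1 S/T. The score is
0.55·DEPST − 0.5·HI, where DEPST is the mass percent of D/E/P/S/T in the
segment corrected by one equivalent each of (D|E), P and (S|T) (average
residue masses; preference D over E and S over T when both occur), and HI
is the mole-fraction-weighted Kyte–Doolittle hydropathy linearly rescaled
to 0–90 (10·KD + 45). Segments scoring ≥ +5 are "potential" PEST regions.
The exact one-equivalent bookkeeping of the original tool is
under-documented; the convention above is fixed, documented, and checked
in tests by independent hand evaluation. The four features are region
count, max length, score of the top-scoring region, and the relative
midpoint (midpoint/L) of the top-scoring region — the last collapses a
per-region quantity to one slot so the vector stays fixed-width.

**Low complexity (SEG-style).** Per-window Shannon entropy (bits),
window 12. Windows with H ≤ 2.2 seed regions; each seed extends over the
maximal contiguous run of windows with H ≤ 2.5; overlapping regions merge.
This is the classic two-threshold segmentation without the original's
final optimization pass; on the fixtures used in tests the calls coincide
with the brute-force entropy table by construction.

**Heuristic predictor stand-ins.** The original pipeline consumed external
predictors. Each capability here has (a) a deterministic in-process
heuristic and (b) a file-reader backend for real tool output, both meeting
the same output contract:

- *Signal peptide*: an 8-residue window with mean KD ≥ 1.6 (h-region)
  starting after a 1–12 residue n-region containing ≥ 1 K/R and no D/E.
  Readers: SignalP short format (trailing Y/N).
- *Transmembrane*: positions covered by any 19-residue window with mean
  KD ≥ 1.6; maximal runs ≥ 19 become regions. Readers: TMHMM-style
  `id TMhelix start end` lines (1-based inclusive).
- *Secondary structure*: per-residue Chou–Fasman propensity argmax →
  helix/sheet/coil fractions. Readers: PSIPRED `.ss2` / `.horiz`.
- *Disorder*: TOP-IDP per-residue propensity smoothed over a 21-residue
  window; positions > 0 form candidates; regions ≥ 30 residues reported.
  Readers: IUPred per-residue scores, threshold 0.5.
- *PTM sites*: sequon/context rules — [S/T]P or RxxS/T (phospho-S/T), Y
  with ≥ 2 D/E within ±5 (phospho-Y), WxxW (C-glyc), N-{P}-[S/T] (N-glyc),
  S/T with ≥ 2 P within ±5 (O-glyc). Reader: `id pos kind` tables.
- *Destruction box*: the four family scores count RxxL-core matches with
  documented context rules (geminin RxxLxx[DE]; cyclin A RxxL with N at
  +8; cyclin B RxxLG; securin bare RxxL). The original family blocks are
  unpublished, so these are explicit stand-ins; a reader backend accepts
  the original tool's per-family scores.

These heuristics are simplifications of the tools they stand in for; they
capture the hydropathy/propensity logic but none of the trained-model
accuracy. Feature slots remain meaningful and deterministic either way.

**Length normalization.** Counts and lengths of region-derived features
(PEST count/max, LCR features, disorder count/lengths, TM length, D-box
counts, PTM counts) are divided by sequence length ("content"); fractions,
existence flags and scores are left untouched. The per-slot flag lives in
the schema.

## Feature selection

F-value is the Golub signal-to-noise statistic |μ⁺−μ⁻|/(s⁺+s⁻) with
sample (n−1) standard deviations; when both classes are constant it is 0
for equal means, else a documented cap (1e6). The pipeline order is
correlation pruning → F ≥ 0.1 → ANOVA p ≤ 0.001 (two-group one-way ANOVA,
numerically the pooled t-test). Pruning is a greedy pass in descending-F
order (ties broken by schema order): a surviving feature drops every
not-yet-dropped feature with Pearson r ≥ 0.5 (positive correlations only)
at correlation p < 0.001. Constant columns have undefined correlations and
are never pruned on that step. The source formulation of both the F-value
and the propensity score was reconstructed from the cited statistic and
the surrounding interpretation ("> 1 means enriched"); the propensity
score is the class mean of the min-max-scaled feature divided by its
global mean, with constant features defined to score 1.

If a training split leaves no survivor (it can happen under shuffled-label
controls, where ~0.8 features are expected to pass p ≤ 0.001 by chance),
the top 10 features by F are kept so the downstream SVM stays defined.
This fallback never triggers when planted signal is present.

## Classification protocol

Per repeat: ⌊0.8·n_pos⌋ positives plus an equal number of negatives train
(balanced); all remaining samples test. Selection, scaling and model
fitting all happen inside the training split — the shuffled-label control
in the acceptance suite verifies the absence of leakage (held-out AUC
centered on 0.5). Min-max scaling is fitted on training data and applied
with clipping to [0, 1] at prediction time. The SVM grid is the libsvm
convention (C ∈ 2^{−5,−3,…,15}, γ ∈ 2^{−15,−13,…,3}), scored by mean
stratified 10-fold CV accuracy, ties broken toward smaller C then smaller
γ. Summaries report both mean-of-ratios across repeats (the layout used
for the headline numbers) and metrics recomputed from mean confusion
counts; the two differ by ~0.01 on typical runs. AUC integrates the ROC
trapezoidally over all score thresholds; MCC is defined as 0 when a
marginal is empty.

## Synthetic generator

The generator defines the study conditions for all desk-scale runs:
510 short-lived / 4328 long-lived by default, signal-peptide cassettes in
45% vs 3% of the classes (the published enrichment), TM cassettes in 35%
vs 10% (the source reports strong TM enrichment without printing rates;
these are plausible proteome-scale values fixed once), hydrophobic
log-odds shift +0.5 in short-lived and acidic (D/E) shift +0.5 in
long-lived backgrounds (raising hydrophobic content from ~30% to ~40% —
a strong, clearly separable effect), and log-normal lengths (median 450
short / 350 long, σ = 0.45, floor 60 — short-lived proteins here skew
secreted/membrane-bound and longer). Residues are i.i.d. within class;
cassettes (M + basic n-region + 10–15 residue L/I/V/F h-region + polar
c-region for SP; 19–25 residue L/I/V/F stretches for TM) overwrite
residues in place and are recorded as truth annotations. PSI values are
drawn log-normally per class, truncated at the 2.0 boundary, purely to
exercise label-table round-trips.

What the generator does **not** emulate: homology/family structure,
residue autocorrelation beyond planted cassettes, realistic degron usage
(KEN/D-box/PEST occur only at background rates), any N-end-rule signal,
and label noise. Consequences: (1) classifier metrics on synthetic data
(AUC ≈ 0.99 at defaults) are far above what real half-life data supports
— the synthetic signals are strong and clean by design, so passing tests
demonstrate pipeline correctness and signal recovery, not real-world
accuracy; (2) the N-end baseline is uninformative-to-anticorrelated on
synthetic data (SP cassettes start with stabilizing M), so only the
directional SVM-vs-baseline comparison is meaningful.

## Numerical and interface choices

- Feature tables are TSV with a 17-significant-digit float format, making
  write→read round-trips bit-exact for IEEE doubles.
- FASTA handling is lenient by default (records with B/J/O/U/X/Z/\*
  skipped with a logged count); `--strict` turns violations into errors.
- Degenerate inputs: length-1 sequences produce finite vectors with
  all-zero k-mer/region blocks; single-class truth yields NaN SE or SP
  with a warning; fraction = 1.0 splits are rejected.
- Desk-scale problem sizes used by the acceptance suite and script —
  100 short / 400 long, 3 repeats — were chosen as the smallest study
  where per-split selection, balanced resampling and the leakage control
  are all exercised with stable statistics.
- The redundancy filter of real datasets (20%-identity BLAST clustering)
  is out of scope; `seqio.cluster_by_identity` is an explicit
  not-implemented hook with guidance.

## Known limitations

- Heuristic backends are not substitutes for trained predictors; for real
  analyses, run the external tools and use the reader backends.
- The D-box family rules are approximations; treat the four family slots
  as RxxL-context counts unless a reader supplies real scores.
- The 11-feature reduced set is a fixed projection; its membership was
  derived on data this package does not ship, so on synthetic proteomes
  the full-vector pipeline is the meaningful mode.
- Single-sequence isoelectric points ignore folded-state pKa shifts, as
  all sequence-only methods do.
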