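# Methods

## Problem and model

`quadpre` predicts the quaternary-structure attribute of a protein chain —
how many polypeptide subunits form the assembly — among six states encoded
by their subunit counts c ∈ {1, 2, 3, 4, 6, 8} (monomer, dimer, trimer,
tetramer, hexamer, octamer; pentamers and heptamers are excluded as a
modelling decision because curated benchmarks contain too few of them to
train on). The predictor is a hybrid: every chain is encoded as a fixed
632-dimensional vector built from seven blocks, and a one-vs-rest ensemble
of six soft-margin RBF support-vector machines classifies the vector.

### Feature blocks (632 = 123 + 203 + 217 + 23 + 30 + 30 + 6)

**Sequence block (123).** Length; the 20-residue composition vector; 18
group counts over four residue groupings (five R groups, five electronic
groups, three hydrophobicity groups, five exchange groups); first- and
second-order composition moment vectors
CMV_x^k = Σ_{j∈positions(x)} j^k / Π_{d=0..k}(L−d) with 1-based positions
(40); mean isoelectric point; autocorrelation
A_n = (1/(L−n)) Σ a_i a_{i+n} of the Fauchère–Pliska (FH, lags 1–10),
Eisenberg (EH, lags 1–6) and Kyte–Doolittle hydropathy (HP, lags 1–9)
scales; cumulative-FH autocorrelation over prefix sums (lags 1–6); summed
FH and EH hydrophobicity; and the five R-group and five electronic-group
composition percentages. The full block needs L ≥ 11 (the longest
autocorrelation lag); shorter inputs raise rather than silently pad.

Scale values are the published literature values (Fauchère–Pliska 1983
octanol scale, Eisenberg 1984 consensus scale, Kyte–Doolittle 1982
hydropathy, Lehninger free-amino-acid pI). They and all grouping tables
are overridable from a YAML config, so alternative tabulations can be
dropped in without code changes. Two grouping details were genuinely open
and are fixed here by documented choice: the classical electronic grouping
names only 19 residues, so cysteine is folded into the neutral set
(GHWS→GHWSC) to keep each grouping a partition of the 20 residues (and the
five percentages summing to 1); the classical six exchange groups are
collapsed to five by folding the aromatics FYW into the ILMV hydrophobic
set, so the four groupings give exactly 18 counts.

**Profile blocks (203 PSSM + 217 secondary structure + 23 RSA).** These
consume externally produced per-residue profiles: a PSI-BLAST position-
specific scoring matrix, a PSIPRED-style 3-state (H/E/C) prediction with
optional per-state probabilities, and per-residue relative solvent
accessibility clipped into [0, 1]. The block *widths* and determinism are
the contract; the aggregate recipes are this package's own versioned
defaults (`RECIPE_VERSION` in `profile_features.py`), pinned by golden
tests so any change is deliberate:

* PSSM (203): per-column mean/min/max/std (80); per-column means over the
  first and last quarter of positions (40); per-residue-type self-scores
  (20); per-column fraction of positive scores (20); per-column mean
  centred sigmoid (20); global mean/max/min (3); per-column lag-1
  autocorrelation (20).
* Secondary structure (217 = 90 + 127): state contents, confidence
  aggregates, positional summaries, 10-window contents and confidences,
  and transition frequencies (90); segment statistics, segment-length
  histograms, helix/strand collocation pattern counts (all words of
  length 2–4 over the non-coil segment labels), windowed segment starts,
  inter-segment gaps and span summaries (127).
* RSA (23): mean RSA per residue type (20) and per secondary-structure
  state (3); absent types/states contribute 0 so vectors stay finite.

**Similarity block (30).** For each of the six classes, the five most
similar reference sequences (by E-value, ascending) each contribute the
*E-value index*: the negated base-10 exponent of the E-value's scientific
notation, mantissa discarded (3.2e-5 → 5), so stronger hits score higher.
E-values of exactly 0 (tool underflow) are capped at 200; missing hits pad
with 0; self-hits are removed before ranking. Both constants are config
values in `blast_features.py`.

**Motif blocks (30 + 6).** Gapped set motifs (each position a set of
allowed residues and/or gap) are preprocessed: a run of more than five
consecutive gap-only positions is deleted and splits the motif in two
(recursively, left to right), and fragments with fewer than five
residue-bearing positions are discarded. Sequences are scored against
motifs by Smith–Waterman local alignment whose every move cost comes from
the motif's penalty function: for set motifs, +1 for an allowed residue,
−1 for a disallowed residue, 0 for a gap the position allows and −1/3
otherwise; for probability motifs, each move against column i scores the
column's probability of the aligned symbol, with gap moves reading the
column's gap probability. One documented consequence of positive gap
scores: an alignment may open or extend through profitable gap columns,
so the DP applies the same zero-floor recurrence on the first row.
Per class, the five highest set-motif scores (descending, ties kept in
motif index order, missing scores padded with 0) give 30 features, and
the single probability motif per class gives 6 more.

### Fold-exclusion scheme

Similarity and motif features for a sequence are only ever computed
against reference folds other than the sequence's own, so cross-validation
never leaks a record into its own feature construction. The partition is
stratified and class-covering: members of each class are shuffled
(seeded) and dealt one per fold, the remainder greedily to the least
loaded fold; fold sizes differ by at most one and every fold contains
every class. A class with fewer members than folds is an error under the
default strict policy (`allow_missing_class=True` relaxes it). Motifs and
hit tables carry their source folds; using one against a sequence from a
source fold raises `LeakageError`.

### Classifier

Features are standardized per column with training-fold statistics (RBF
kernels need commensurable scales; the block units are wildly different).
One C-SVC per class (class vs rest), RBF kernel K(x, x′) =
exp(−γ‖x−x′‖²). Per-class decision values pass through a Platt-style
sigmoid (logistic regression on the decision value) so "predicted class =
highest probability" is well defined; the sigmoid is monotone, so
rankings — and hence every AUC — are identical to the raw decision
values, which remain available. Exact ties in the predicted class go to
the smaller subunit count. Defaults are C = 1 and γ = 1/632 (the
1/n_features heuristic for standardized inputs); hyperparameters are
otherwise chosen by an exhaustive grid search over
C ∈ {0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50, 100} and
γ ∈ {0.0025, 0.005, …, 10.24} (10 × 13 = 130 points), scored by
cross-validated class-averaged one-vs-rest AUC with ties broken toward
smaller C then smaller γ.

### Evaluation

The 6×6 confusion matrix (rows = true class, class order 1, 2, 3, 4, 6, 8)
is reduced one-vs-rest per class to TP/FP/FN/TN, giving ACC, TPR, FPR,
SPC = 1 − FPR, PPV and MCC with the standard formulas. Zero denominators
return the sentinel 0 with an explicit flag instead of NaN. The report
carries per-class values, their unweighted six-class means, and the
multiclass accuracy trace/N — two deliberately distinct accuracy notions
(mean one-vs-rest ACC is typically far higher than trace/N on unbalanced
data; both are always labelled). AUC is the rank-based Mann–Whitney area
with ties counted half. Display rounding is 1 decimal for percentages and
3 for MCC/AUC; raw values are retained.

## Synthetic data

The generator fabricates every input the pipeline consumes, with
independent signal knobs per feature channel (all in [0, 1]): composition
bias toward a class-specific preferred residue subset; a planted
class-specific motif embedded at a random position and mutated per
residue with probability 1 − conservation; surrogate profiles (PSSM =
scaled one-hot of the sequence plus integer noise; secondary structure
sampled from class-tilted segment propensities; RSA from a class-shifted
beta distribution); and hit tables whose same-class hits receive
E-value exponents in [20, 60] with probability equal to the hit signal
(otherwise [0, 5], as for other-class hits). Per-fold-complement motif
files are derived from the planted consensus, never from the excluded
fold. Defaults are 100 sequences per class, lengths 30–60, composition
bias 0.5, motif length 8 at conservation 0.9, profile signal 0.8, hit
signal 0.9, 10 folds — strong but not degenerate signal in every channel.
With every knob at 0 the classes are exchangeable and cross-validated AUC
sits at chance.

The surrogate profiles exercise parsing, widths, determinism and signal
flow only; they do not imitate the output statistics of real profile
predictors, and sequences are i.i.d. draws rather than evolutionarily
related families. Passing tests on synthetic data therefore demonstrate
that the machinery is correct and leak-free, not that any particular
accuracy will be achieved on real proteins — real-data accuracy depends
on the external profile/motif/search tools and the benchmark.

## Numerical and design choices

* Residue normalization: B→N, Z→Q, U→C, J→L; any other letter becomes the
  placeholder X, which is excluded from composition counts and scores 0
  on every scale in positional features. Sequences empty after
  normalization are rejected.
* Alignment scores and feature formulas are checked against independent
  brute-force oracles (explicit path enumeration for the local aligner;
  quadratic-time loops for the autocorrelations and moment vectors) to
  1e-10 in the test suite.
* Cross-validation fits the scaler, the machines and the calibrators on
  training folds only; each record is predicted exactly once by a model
  that never saw its fold.
* Under label permutation, cross-validated AUC is checked to be within
  3 standard errors of 0.5. This holds at the default study size (600
  records); well below ~30 records per class the CV estimator of AUC is
  known to be pessimistically biased under the null, so the chance
  property is asserted at adequate n.
* Problem sizes in the reproduction script: 100/class for the CV runs,
  4/class for the 130-point grid-evaluation count, the full 1040-record
  class profile for the fold contract, exhaustive sequences of length ≤ 6
  over a 3-letter sub-alphabet for the alignment oracle, 200 random
  sequences for the formula oracles.

## Known limitations

* The 203/217 profile recipes are fixed-width engineering defaults; no
  claim is made that they enumerate the same individual features as any
  previously published encoding of the same widths.
* No invocation of external tools (profile search, secondary-structure
  or accessibility prediction, motif discovery): the package consumes
  their outputs, or surrogates, only.
* The worked-example evaluation reproduces a published benchmark table
  from its printed confusion matrix; two cells of that table round
  differently in the source (tetramer one-vs-rest ACC 86.9% vs printed
  87.0%; hexamer PPV 45.7% vs printed 45.8%). The package asserts the
  recomputed values.
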