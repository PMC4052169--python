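# quadpre

Sequence-based prediction of protein **quaternary-structure attributes**:
given a protein chain, how many subunits form the assembly — monomer,
dimer, trimer, tetramer, hexamer or octamer (c ∈ {1, 2, 3, 4, 6, 8})?

Experimental determination of oligomeric state is slow and expensive, and
most sequence-based predictors only separate two states (e.g. homodimer
vs not). `quadpre` is a hybrid six-state predictor: each chain is encoded
as a 632-dimensional feature vector

| block | width | content |
|---|---|---|
| sequence | 123 | length, composition, residue-group counts, composition moment vectors, mean pI, hydrophobicity autocorrelations and sums, group percentages |
| PSSM | 203 | aggregates of the position-specific scoring matrix |
| secondary structure | 217 | state contents/confidences + segment and helix/strand collocation descriptors |
| RSA | 23 | mean relative solvent accessibility per residue type and per state |
| similarity | 30 | E-value indices (−⌊log₁₀ E⌋) of the 5 best hits per class |
| gapped motifs | 30 | top-5 Smith–Waterman scores per class against set motifs |
| probability motifs | 6 | Smith–Waterman score per class against probability motifs |

and classified by one-vs-rest soft-margin SVMs with the RBF kernel
K(xᵢ, xⱼ) = exp(−γ‖xᵢ−xⱼ‖²), with Platt-calibrated per-class
probabilities, (C, γ) grid search scored by cross-validated mean
one-vs-rest AUC, and class-covering n-fold cross-validation. Similarity
and motif features obey a *fold-exclusion scheme* — they are computed
only from reference folds other than the query's own, so CV never leaks.
The evaluation module implements the one-vs-rest reductions, ACC / TPR /
FPR / SPC / PPV / MCC, and rank-based ROC AUC.

External profile and search tools are **not** invoked: the package parses
their output formats (PSI-BLAST ASCII PSSM, PSIPRED `.ss2`, RSA tables,
tabular hit files, simple motif dialects) and ships a synthetic generator
that fabricates all of them with planted, tunable class signal so the
whole pipeline is testable offline.

## Worked example

The evaluation module reproduces a published six-class benchmark table
from its printed 6×6 prediction matrix, shipped with the package:

```bash
quadpre evaluate --confusion src/quadpre/data/example_confusion.tsv
```

prints

```
metric  monomer dimer   trimer  tetramer        hexamer octamer average
ACC     63.0%   63.8%   92.8%   86.9%   93.3%   90.6%   81.7%
TPR     77.9%   30.8%   24.5%   18.1%   23.9%   39.3%   35.7%
SPC     54.9%   79.8%   96.5%   99.0%   98.0%   93.8%   87.0%
PPV     48.4%   42.3%   27.1%   75.7%   45.7%   28.2%   44.6%
MCC     0.316   0.116   0.220   0.328   0.299   0.284   0.260
multiclass ACC  45.2%
```

Each column is the one-vs-rest reduction for that class; the average
column is the unweighted six-class mean. Note the two accuracy notions:
mean one-vs-rest ACC (81.7%) and multiclass accuracy trace/N (45.2%) —
both are always reported and labelled. Per-class AUC additionally appears
whenever held-out scores are available (confusion matrices alone don't
carry ranking information).

A full synthetic round trip:

```bash
quadpre simulate --n-per-class 20 --seed 1 --out bundle/
quadpre extract-features --bundle bundle/ --out features.tsv   # 120 x 632
quadpre cv --bundle bundle/ --seed 1 --out report.json
quadpre gridsearch --bundle bundle/ --seed 1 --out grid.json   # 130 points
```

Library use mirrors the CLI:

```python
import quadpre as q

ds = q.generate_dataset(q.SyntheticSpec(seed=1, n_per_class=20))
X, y, ids = q.featurize_dataset(ds.records, ds.profiles,
                                ds.motif_library, ds.hit_tables, ds.folds)
cm, scores = q.cross_validate(X, y, ds.folds, ids)
print(q.per_class_report(cm, scores).format_table())
```

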