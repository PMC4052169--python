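"""Feature assembly and the one-vs-rest RBF SVM classifier.

The full feature vector is 632-wide with a fixed block order:

    seq(123) | pssm(203) | ss(217) | rsa(23) | blast(30) | glam2(30) | gibbs(6)

Missing optional inputs (profiles, hit tables, motif libraries) pad
their block with zeros and are recorded in a provenance flag set, so the
width is invariant.

Classification is C-SVC with an RBF kernel K(x, x') = exp(-g ||x-x'||^2)
in a one-vs-rest reduction: one binary machine per oligomeric class,
each trained on features standardized with training-set statistics.
Per-class decision values are passed through a Platt-style sigmoid
(logistic regression on the decision value) so "highest probability"
is well defined; raw decision values remain available and give
identical rankings.  Ties in the predicted class are broken toward the
smaller subunit count.

Hyperparameters are selected by a grid search over the default grids

    C in {0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50, 100}
    g in {0.0025, 0.005, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64,
          1.28, 2.56, 5.12, 10.24}

scored by cross-validated class-averaged one-vs-rest AUC, ties broken
toward smaller C then smaller gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import blast_features, motif_features, profile_features, seq_features
from .core_io import (FoldAssignment, OLIGOMER_CLASSES, ProteinRecord,
                      SSPrediction, validate_class)
from .evaluation import roc_auc
from .motif_features import MotifLibrary

BLOCK_WIDTHS: Dict[str, int] = {
    "seq": seq_features.SEQ_BLOCK_WIDTH,
    "pssm": profile_features.PSSM_BLOCK_WIDTH,
    "ss": profile_features.SS_BLOCK_WIDTH,
    "rsa": profile_features.RSA_BLOCK_WIDTH,
    "blast": blast_features.BLAST_BLOCK_WIDTH,
    "glam2": motif_features.GLAM2_BLOCK_WIDTH,
    "gibbs": motif_features.GIBBS_BLOCK_WIDTH,
}
FEATURE_WIDTH = sum(BLOCK_WIDTHS.values())
assert FEATURE_WIDTH == 632

DEFAULT_C_GRID: Tuple[float, ...] = (0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50, 100)
DEFAULT_GAMMA_GRID: Tuple[float, ...] = (
    0.0025, 0.005, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.28, 2.56,
    5.12, 10.24)

#: Library defaults used when no grid search has been run: C = 1 and the
#: 1/n_features heuristic for the RBF width on standardized inputs.
DEFAULT_C = 1.0
DEFAULT_GAMMA = 1.0 / FEATURE_WIDTH


@dataclass(frozen=True)
class ProfileSet:
    """Optional per-record profiles consumed by the profile blocks."""

    pssm: Optional[np.ndarray] = None
    ss: Optional[SSPrediction] = None
    rsa: Optional[np.ndarray] = None


def feature_names() -> List[str]:
    names = seq_features.seq_feature_names()
    names += profile_features.profile_feature_names()
    for cls in OLIGOMER_CLASSES:
        names += [f"blast_c{cls}_r{r}" for r in range(1, 6)]
    for cls in OLIGOMER_CLASSES:
        names += [f"glam2_c{cls}_r{r}" for r in range(1, 6)]
    names += [f"gibbs_c{cls}" for cls in OLIGOMER_CLASSES]
    assert len(names) == FEATURE_WIDTH
    return names


def assemble_features(
    record: ProteinRecord,
    profiles: Optional[ProfileSet] = None,
    motif_library: Optional[MotifLibrary] = None,
    hit_tables: Optional[Mapping[int, object]] = None,
    fold_assignment: Optional[FoldAssignment] = None,
) -> Tuple[np.ndarray, frozenset]:
    """Assemble the 632-wide vector for one record.

    Returns the vector and the set of block names that were padded with
    zeros because their input was missing.  Motif and similarity blocks
    require a fold assignment (fold-exclusion scheme).
    """
    padded = set()
    parts = [seq_features.sequence_feature_block(record)]

    pssm = profiles.pssm if profiles else None
    ss = profiles.ss if profiles else None
    rsa = profiles.rsa if profiles else None
    if pssm is not None:
        parts.append(profile_features.pssm_feature_block(pssm, record.sequence))
    else:
        padded.add("pssm")
        parts.append(np.zeros(BLOCK_WIDTHS["pssm"]))
    if ss is not None:
        parts.append(profile_features.ss_feature_block(ss))
    else:
        padded.add("ss")
        parts.append(np.zeros(BLOCK_WIDTHS["ss"]))
    if rsa is not None and ss is not None:
        parts.append(profile_features.rsa_feature_block(record.sequence, rsa, ss))
    else:
        padded.add("rsa")
        parts.append(np.zeros(BLOCK_WIDTHS["rsa"]))

    fold = fold_assignment.fold_of(record.id) if fold_assignment else None
    if hit_tables is not None:
        if fold is None:
            raise ValueError("similarity features require a fold assignment")
        parts.append(blast_features.blast_feature_block(record, fold, hit_tables))
    else:
        padded.add("blast")
        parts.append(np.zeros(BLOCK_WIDTHS["blast"]))
    if motif_library is not None:
        if fold is None:
            raise ValueError("motif features require a fold assignment")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parts.append(motif_features.glam2_feature_block(
                record.sequence, fold, motif_library))
            parts.append(motif_features.gibbs_feature_block(
                record.sequence, fold, motif_library))
    else:
        padded.update({"glam2", "gibbs"})
        parts.append(np.zeros(BLOCK_WIDTHS["glam2"]))
        parts.append(np.zeros(BLOCK_WIDTHS["gibbs"]))

    x = np.concatenate(parts)
    assert x.size == FEATURE_WIDTH
    if not np.isfinite(x).all():
        raise ValueError(f"non-finite features for record {record.id!r}")
    return x, frozenset(padded)


def featurize_dataset(
    records: Sequence[ProteinRecord],
    profiles: Optional[Mapping[str, ProfileSet]] = None,
    motif_library: Optional[MotifLibrary] = None,
    hit_tables: Optional[Mapping[str, Mapping[int, object]]] = None,
    fold_assignment: Optional[FoldAssignment] = None,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Assemble the (n, 632) feature matrix for a whole dataset.

    Returns the matrix, the label array (0 for unlabelled records) and
    the record ids in row order.
    """
    rows, labels, ids = [], [], []
    for r in records:
        x, _ = assemble_features(
            r,
            profiles=profiles.get(r.id) if profiles else None,
            motif_library=motif_library,
            hit_tables=hit_tables.get(r.id) if hit_tables else None,
            fold_assignment=fold_assignment,
        )
        rows.append(x)
        labels.append(r.label if r.label is not None else 0)
        ids.append(r.id)
    return np.vstack(rows), np.asarray(labels), ids


# ---------------------------------------------------------------------------
# one-vs-rest SVM

@dataclass
class SVMModel:
    """One binary RBF machine per class, plus standardization and calibration."""

    C: float
    gamma: float
    seed: int
    scaler: StandardScaler
    machines: Dict[int, SVC]
    calibrators: Dict[int, LogisticRegression]
    classes: Tuple[int, ...] = OLIGOMER_CLASSES
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return int(self.scaler.mean_.shape[0])

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 6) raw one-vs-rest decision values; absent classes score -inf."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} does not match model "
                f"({self.n_features})")
        Xs = self.scaler.transform(X)
        out = np.full((X.shape[0], len(self.classes)), -np.inf)
        for k, cls in enumerate(self.classes):
            if cls in self.machines:
                out[:, k] = self.machines[cls].decision_function(Xs)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 6) Platt-calibrated per-class probabilities (not normalized)."""
        scores = self.decision_scores(X)
        out = np.zeros_like(scores)
        for k, cls in enumerate(self.classes):
            if cls in self.calibrators:
                d = scores[:, k]
                finite = np.isfinite(d)
                if finite.any():
                    out[finite, k] = self.calibrators[cls].predict_proba(
                        d[finite, None])[:, 1]
        return out


def train_ovr(X: np.ndarray, y: Sequence[int], C: float = DEFAULT_C,
              gamma: float = DEFAULT_GAMMA, seed: int = 0) -> SVMModel:
    """Train one-vs-rest C-SVC machines on standardized features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray([validate_class(c) for c in y])
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    present = sorted(set(int(c) for c in y))
    if len(present) < 2:
        raise ValueError("training requires at least two classes")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    machines: Dict[int, SVC] = {}
    calibrators: Dict[int, LogisticRegression] = {}
    for cls in present:
        binary = (y == cls).astype(int)
        svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
        svc.fit(Xs, binary)
        machines[cls] = svc
        d = svc.decision_function(Xs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            cal = LogisticRegression(max_iter=1000)
            cal.fit(d[:, None], binary)
        calibrators[cls] = cal
    return SVMModel(C=C, gamma=gamma, seed=seed, scaler=scaler,
                    machines=machines, calibrators=calibrators,
                    metadata={"n_train": int(X.shape[0]),
                              "classes_present": present})


def predict(model: SVMModel, x: np.ndarray) -> Tuple[int, np.ndarray]:
    """Predicted class (highest calibrated probability) and the 6 scores.

    Exact ties are broken toward the smaller subunit count.
    """
    probs = model.predict_proba(np.atleast_2d(x))[0]
    k = int(np.argmax(probs))  # argmax returns the first (smallest-class) max
    return model.classes[k], probs


def save_model(model: SVMModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> SVMModel:
    return joblib.load(path)


def write_feature_tsv(path, X: np.ndarray, y: Sequence[int],
                      ids: Sequence[str]) -> None:
    """Write a feature matrix as TSV with all 632 named columns."""
    names = feature_names()
    with open(path, "w") as fh:
        fh.write("id\tlabel\t" + "\t".join(names) + "\n")
        for rid, label, row in zip(ids, y, X):
            vals = "\t".join(f"{v:.10g}" for v in row)
            fh.write(f"{rid}\t{int(label)}\t{vals}\n")


def read_feature_tsv(path) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    ids: List[str] = []
    labels: List[int] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != FEATURE_WIDTH + 2:
            raise ValueError(f"feature TSV must have {FEATURE_WIDTH} columns")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            labels.append(int(parts[1]))
            rows.append([float(v) for v in parts[2:]])
    return np.asarray(rows), np.asarray(labels), ids


# ---------------------------------------------------------------------------
# cross-validation and grid search

def _fold_array(folds: FoldAssignment, record_ids: Sequence[str]) -> np.ndarray:
    return np.array([folds.fold_of(rid) for rid in record_ids])


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    folds: FoldAssignment,
    record_ids: Sequence[str],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> Tuple[np.ndarray, Dict[int, Tuple[np.ndarray, np.ndarray]]]:
    """n-fold cross-validation with held-out predictions for every record.

    Returns the 6x6 confusion matrix (rows = true class) and, per class,
    the held-out decision scores with their one-vs-rest truth labels for
    ROC analysis.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([validate_class(c) for c in y])
    fold_of = _fold_array(folds, record_ids)
    if set(np.unique(fold_of)) != set(range(1, folds.n_folds + 1)):
        raise ValueError("records do not cover all folds")

    cm = np.zeros((6, 6), dtype=int)
    scores_acc: Dict[int, List[float]] = {c: [] for c in OLIGOMER_CLASSES}
    labels_acc: Dict[int, List[bool]] = {c: [] for c in OLIGOMER_CLASSES}
    class_index = {c: k for k, c in enumerate(OLIGOMER_CLASSES)}

    for fold in range(1, folds.n_folds + 1):
        test = fold_of == fold
        model = train_ovr(X[~test], y[~test], C=C, gamma=gamma, seed=seed)
        probs = model.predict_proba(X[test])
        dec = model.decision_scores(X[test])
        pred = [model.classes[k] for k in np.argmax(probs, axis=1)]
        for yt, yp in zip(y[test], pred):
            cm[class_index[yt], class_index[yp]] += 1
        for k, cls in enumerate(OLIGOMER_CLASSES):
            d = dec[:, k]
            keep = np.isfinite(d)
            scores_acc[cls].extend(d[keep])
            labels_acc[cls].extend((y[test][keep] == cls))

    score_lists = {c: (np.array(scores_acc[c]), np.array(labels_acc[c]))
                   for c in OLIGOMER_CLASSES if len(scores_acc[c])}
    return cm, score_lists


def mean_ovr_auc(score_lists: Mapping[int, Tuple[np.ndarray, np.ndarray]]) -> float:
    """Unweighted mean of the per-class one-vs-rest AUCs."""
    aucs = []
    for cls in sorted(score_lists):
        scores, labels = score_lists[cls]
        if labels.any() and not labels.all():
            aucs.append(roc_auc(scores, labels))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


@dataclass(frozen=True)
class GridSpec:
    C_values: Tuple[float, ...] = DEFAULT_C_GRID
    gamma_values: Tuple[float, ...] = DEFAULT_GAMMA_GRID

    def __post_init__(self) -> None:
        if not self.C_values or not self.gamma_values:
            raise ValueError("grids must be non-empty")


@dataclass
class GridResult:
    C: float
    gamma: float
    mean_auc: float
    n_evaluations: int
    log: List[Tuple[float, float, float]]  # (C, gamma, mean AUC)


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    folds: FoldAssignment,
    record_ids: Sequence[str],
    grid: GridSpec = GridSpec(),
    seed: int = 0,
) -> GridResult:
    """Exhaustive (C, gamma) search scored by CV class-averaged AUC.

    Every grid point is evaluated and logged; the maximizer is returned
    with ties broken toward smaller C, then smaller gamma.
    """
    log: List[Tuple[float, float, float]] = []
    best: Optional[Tuple[float, float, float]] = None
    for C in sorted(grid.C_values):
        for gamma in sorted(grid.gamma_values):
            _, score_lists = cross_validate(
                X, y, folds, record_ids, C=C, gamma=gamma, seed=seed)
            auc = mean_ovr_auc(score_lists)
            log.append((C, gamma, auc))
            if best is None or auc > best[2]:
                best = (C, gamma, auc)
    assert best is not None
    return GridResult(C=best[0], gamma=best[1], mean_auc=best[2],
                      n_evaluations=len(log), log=log)
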