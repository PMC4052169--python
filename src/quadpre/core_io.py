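"""Dataset model, file formats, and class-covering fold partition.

The package works on six oligomeric states — monomer, dimer, trimer,
tetramer, hexamer and octamer, encoded by their subunit counts
``{1, 2, 3, 4, 6, 8}`` (pentamers and heptamers are not admissible).
Besides the raw sequences it consumes per-sequence profiles produced by
external tools:

* PSSM — the PSI-BLAST ``-Q`` ASCII matrix (three header lines, then one
  row per residue: index, residue, 20 integer scores).
* Secondary structure — the PSIPRED ``.ss2`` layout (index, residue,
  state in H/E/C, and three per-state probabilities in C, H, E order).
* RSA — a two-column TSV of residue index and relative solvent
  accessibility; values are clipped into [0, 1] on ingest.
* Similarity hits — a tab-separated table with ``qseqid``, ``sseqid``
  and ``evalue`` columns (positions configurable).

The fold partition implements stratified, class-covering n-fold
assignment: fold sizes differ by at most one and every fold contains at
least one member of every class, which the motif and similarity feature
schemes rely on.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import STANDARD_AAS

logger = logging.getLogger(__name__)

OLIGOMER_CLASSES: Tuple[int, ...] = (1, 2, 3, 4, 6, 8)
CLASS_NAMES: Dict[int, str] = {
    1: "monomer", 2: "dimer", 3: "trimer",
    4: "tetramer", 6: "hexamer", 8: "octamer",
}

#: Column order of PSSM files (PSI-BLAST convention).
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Placeholder for residues outside the 20 standard letters.  It is kept
#: in positional features with zero-valued scale contributions but is
#: excluded from composition counts.
PLACEHOLDER = "X"

_ALIASES = {"B": "N", "Z": "Q", "U": "C", "J": "L"}


class LeakageError(RuntimeError):
    """Raised when a feature would be computed from the record's own fold."""


def validate_class(c: int) -> int:
    if c not in OLIGOMER_CLASSES:
        raise ValueError(
            f"invalid oligomer class {c!r}: admissible subunit counts are "
            f"{OLIGOMER_CLASSES} (pentamer and heptamer are excluded)")
    return int(c)


def normalize_sequence(raw: str) -> str:
    """Normalize a raw sequence string.

    Uppercases, strips whitespace and non-letter characters, maps the
    ambiguity/rare letters B->N, Z->Q, U->C, J->L, and replaces any other
    non-standard letter with the neutral placeholder ``X``.
    """
    out = []
    for ch in raw.upper():
        if not ch.isalpha():
            continue
        ch = _ALIASES.get(ch, ch)
        out.append(ch if ch in STANDARD_AAS else PLACEHOLDER)
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein chain with an optional oligomeric-state label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_AAS) - {PLACEHOLDER}
        if bad:
            raise ValueError(
                f"record {self.id!r}: unnormalized letters {sorted(bad)}; "
                "pass the sequence through normalize_sequence() first")
        if self.label is not None:
            validate_class(self.label)

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> List[ProteinRecord]:
    """Read a FASTA file into normalized :class:`ProteinRecord` objects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[ProteinRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq))
        if not seq:
            raise ValueError(
                f"{path}: record {entry.id!r} has an empty sequence after normalization")
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(entries, str(Path(path)), "fasta-2line")


def read_labels(path: str | Path) -> Dict[str, int]:
    """Read a two-column TSV of record id and subunit count."""
    labels: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, c = line.split("\t")[:2]
            labels[rid] = validate_class(int(c))
    return labels


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid in labels:
            fh.write(f"{rid}\t{labels[rid]}\n")


# ---------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class SSPrediction:
    """Three-state secondary-structure prediction (H/E/C)."""

    states: str
    confidence: Optional[np.ndarray] = None  # (L, 3) columns H, E, C

    def __post_init__(self) -> None:
        bad = set(self.states) - set("HEC")
        if bad:
            raise ValueError(f"unknown secondary-structure state(s) {sorted(bad)}")
        if self.confidence is not None:
            conf = np.asarray(self.confidence, dtype=float)
            if conf.shape != (len(self.states), 3):
                raise ValueError("confidence must be (L, 3)")
            if (conf < 0).any() or (conf > 1).any():
                raise ValueError("confidences must lie in [0, 1]")
            object.__setattr__(self, "confidence", conf)

    def __len__(self) -> int:
        return len(self.states)


def read_pssm(path: str | Path, expected_length: int) -> np.ndarray:
    """Read a PSI-BLAST ASCII PSSM into an (L, 20) float array.

    Columns follow :data:`PSSM_AA_ORDER`.  Only the first 20 score
    columns of each row are used.
    """
    rows: List[List[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):  # skip 3 header lines
        parts = line.split()
        if not parts:
            continue
        if not parts[0].isdigit():
            break  # trailing footer (lambda/K statistics)
        if len(parts) < 22:
            raise ValueError(f"{path}:{lineno}: malformed PSSM row (needs 20 scores)")
        try:
            rows.append([float(x) for x in parts[2:22]])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric score in PSSM row") from None
    matrix = np.asarray(rows, dtype=float)
    if matrix.shape[0] != expected_length:
        raise ValueError(
            f"{path}: PSSM has {matrix.shape[0]} rows, expected {expected_length}")
    if not np.isfinite(matrix).all():
        raise ValueError(f"{path}: non-finite PSSM values")
    return matrix


def write_pssm(matrix: np.ndarray, sequence: str, path: str | Path) -> None:
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(PSSM_AA_ORDER) + "\n")
        for i, row in enumerate(matrix):
            scores = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i + 1:5d} {sequence[i]} {scores}\n")


def read_ss2(path: str | Path, expected_length: int) -> SSPrediction:
    """Read a PSIPRED ``.ss2`` file (probabilities in C, H, E column order)."""
    states: List[str] = []
    conf: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed .ss2 row")
            state = parts[2]
            if state not in "HEC" or len(state) != 1:
                raise ValueError(
                    f"{path}:{lineno}: unknown state {state!r} (only H/E/C accepted)")
            states.append(state)
            if len(parts) >= 6:
                p_c, p_h, p_e = (float(parts[3]), float(parts[4]), float(parts[5]))
                conf.append([p_h, p_e, p_c])  # reorder to H, E, C
    if len(states) != expected_length:
        raise ValueError(
            f"{path}: {len(states)} rows, expected {expected_length}")
    confidence = np.asarray(conf) if len(conf) == len(states) and conf else None
    return SSPrediction(states="".join(states), confidence=confidence)


def write_ss2(ss: SSPrediction, sequence: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, state in enumerate(ss.states):
            if ss.confidence is not None:
                p_h, p_e, p_c = ss.confidence[i]
            else:
                p_h, p_e, p_c = [float(state == s) for s in "HEC"]
            fh.write(f"{i + 1:4d} {sequence[i]} {state}   "
                     f"{p_c:.3f} {p_h:.3f} {p_e:.3f}\n")


def read_rsa(path: str | Path, expected_length: int) -> np.ndarray:
    """Read the two-column RSA TSV; out-of-range values clipped with a warning."""
    values: List[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            values.append(float(parts[1]))
    if len(values) != expected_length:
        raise ValueError(f"{path}: {len(values)} rows, expected {expected_length}")
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        warnings.warn(f"{path}: RSA values outside [0, 1] clipped", stacklevel=2)
        arr = np.clip(arr, 0.0, 1.0)
    return arr


def write_rsa(rsa: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(rsa, dtype=float)):
            fh.write(f"{i + 1}\t{v:.4f}\n")


# ---------------------------------------------------------------------------
# similarity hit tables

@dataclass(frozen=True)
class BlastHit:
    subject_id: str
    subject_class: int
    evalue: float
    subject_fold: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.evalue) or self.evalue < 0:
            raise ValueError(f"E-value must be finite and >= 0, got {self.evalue!r}")
        validate_class(self.subject_class)


@dataclass(frozen=True)
class BlastHitTable:
    """Hits for one query, sorted ascending by E-value."""

    query_id: str
    hits: Tuple[BlastHit, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.hits, key=lambda h: h.evalue))
        object.__setattr__(self, "hits", ordered)


def read_blast_tab(
    path: str | Path,
    class_map: Mapping[str, int],
    *,
    fold_map: Optional[Mapping[str, int]] = None,
    qseqid_col: int = 0,
    sseqid_col: int = 1,
    evalue_col: int = 2,
) -> Dict[str, BlastHitTable]:
    """Read a tabular hit file into per-query tables.

    Hits to subjects absent from ``class_map`` are dropped with a
    warning; negative E-values are an error.
    """
    per_query: Dict[str, List[BlastHit]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            qid, sid = parts[qseqid_col], parts[sseqid_col]
            evalue = float(parts[evalue_col])
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value {evalue}")
            if sid not in class_map:
                dropped += 1
                continue
            fold = fold_map.get(sid) if fold_map is not None else None
            per_query.setdefault(qid, []).append(
                BlastHit(subject_id=sid, subject_class=class_map[sid],
                         evalue=evalue, subject_fold=fold))
    if dropped:
        warnings.warn(
            f"{path}: dropped {dropped} hit(s) to subjects with unknown class",
            stacklevel=2)
    return {qid: BlastHitTable(query_id=qid, hits=tuple(hits))
            for qid, hits in per_query.items()}


# ---------------------------------------------------------------------------
# fold partition

@dataclass(frozen=True)
class FoldAssignment:
    """A class-covering n-fold partition of a labelled dataset."""

    n_folds: int
    assignment: Dict[str, int]  # record id -> fold in 1..n_folds
    rosters: Dict[Tuple[int, int], Tuple[str, ...]]  # (fold, class) -> ids

    def fold_of(self, record_id: str) -> int:
        return self.assignment[record_id]

    def fold_sizes(self) -> List[int]:
        sizes = [0] * self.n_folds
        for fold in self.assignment.values():
            sizes[fold - 1] += 1
        return sizes

    def members(self, fold: int) -> List[str]:
        return [rid for rid, f in self.assignment.items() if f == fold]

    def roster(self, fold: int, cls: int) -> Tuple[str, ...]:
        return self.rosters.get((fold, cls), ())


def partition_folds(
    records: Sequence[ProteinRecord],
    n_folds: int = 10,
    seed: int = 0,
    *,
    allow_missing_class: bool = False,
) -> FoldAssignment:
    """Partition labelled records into ``n_folds`` class-covering folds.

    Members of each class are shuffled (seeded) and one is dealt to every
    fold so each fold covers every class; the remainder is dealt greedily
    to the least-loaded fold, so fold sizes differ by at most one.  Under
    the default strict policy a class with fewer members than folds is an
    error; with ``allow_missing_class`` it covers as many folds as it can.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if any(r.label is None for r in records):
        raise ValueError("all records must be labelled for fold partitioning")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")

    rng = np.random.default_rng(seed)
    by_class: Dict[int, List[str]] = {}
    for r in sorted(records, key=lambda r: r.id):
        by_class.setdefault(int(r.label), []).append(r.id)

    assignment: Dict[str, int] = {}
    loads = np.zeros(n_folds, dtype=int)
    leftovers: List[str] = []

    for cls in sorted(by_class):
        members = list(by_class[cls])
        rng.shuffle(members)
        if len(members) < n_folds:
            if not allow_missing_class:
                raise ValueError(
                    f"class {cls} has {len(members)} member(s), fewer than "
                    f"{n_folds} folds; every fold must contain every class "
                    "(pass allow_missing_class=True to relax)")
            folds = list(rng.permutation(n_folds)[: len(members)] + 1)
        else:
            folds = list(range(1, n_folds + 1))
        for rid, fold in zip(members, folds):
            assignment[rid] = fold
            loads[fold - 1] += 1
        leftovers.extend(members[len(folds):])

    rng.shuffle(leftovers)
    for rid in leftovers:
        fold = int(np.argmin(loads)) + 1  # least-loaded, lowest index on ties
        assignment[rid] = fold
        loads[fold - 1] += 1

    rosters: Dict[Tuple[int, int], List[str]] = {}
    label_of = {r.id: int(r.label) for r in records}
    for rid in sorted(assignment):
        rosters.setdefault((assignment[rid], label_of[rid]), []).append(rid)

    fa = FoldAssignment(
        n_folds=n_folds,
        assignment=assignment,
        rosters={k: tuple(v) for k, v in rosters.items()},
    )
    sizes = fa.fold_sizes()
    assert max(sizes) - min(sizes) <= 1, "fold sizes must differ by at most one"
    return fa


def write_folds(fa: FoldAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_folds={fa.n_folds}\n")
        for rid in sorted(fa.assignment):
            fh.write(f"{rid}\t{fa.assignment[rid]}\n")


def read_folds(path: str | Path, labels: Mapping[str, int]) -> FoldAssignment:
    assignment: Dict[str, int] = {}
    n_folds = 10
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "n_folds=" in line:
                    n_folds = int(line.split("n_folds=")[1])
                continue
            if not line:
                continue
            rid, fold = line.split("\t")
            assignment[rid] = int(fold)
    rosters: Dict[Tuple[int, int], List[str]] = {}
    for rid in sorted(assignment):
        rosters.setdefault((assignment[rid], labels[rid]), []).append(rid)
    return FoldAssignment(n_folds=n_folds, assignment=assignment,
                          rosters={k: tuple(v) for k, v in rosters.items()})
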