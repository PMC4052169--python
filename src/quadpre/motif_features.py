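"""Gapped-motif scoring: preprocessing, penalty functions and local alignment.

Two motif representations are supported:

* :class:`GLAM2Motif` — an ordered list of positions, each a non-empty
  set of allowed symbols (the 20 standard residues and/or the gap
  character ``-``).
* :class:`GIBBSMotif` — an ungapped-width motif of per-position
  probability columns over the 21-letter alphabet (20 residues + gap).

Raw gapped motifs are cleaned before use: a run of more than five
consecutive gap-only positions is deleted and splits the motif in two
(applied recursively left to right), and a motif left with fewer than
five residue-bearing positions is discarded.

Scoring uses Smith-Waterman local alignment in which *all* move costs
come from the motif's penalty function.  For a set motif the
substitution score is +1 when the residue is allowed at the position and
-1 when it is not; a gap move against a position scores 0 when the
position itself allows a gap and -1/3 otherwise.  For a probability
motif, every move against column i scores that column's probability for
the aligned symbol, with gap moves scoring the column's gap probability.
Cell values are floored at zero, so scores are always >= 0.

Per-sequence features follow a fold-exclusion scheme: a sequence in fold
i is only ever scored against motifs built from the other folds.  The
block is 30 GLAM2 values (per class, the five highest motif scores in
descending order, padded with 0) plus 6 GIBBS values (one motif per
class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union
import warnings

import numpy as np

from .core_io import LeakageError, OLIGOMER_CLASSES, validate_class
from .scales import STANDARD_AAS

GAP = "-"

#: Alphabet of probability-motif columns: 20 residues then the gap.
GIBBS_ALPHABET = "ARNDCQEGHILKMFPSTWYV" + GAP

GLAM2_BLOCK_WIDTH = 30
GIBBS_BLOCK_WIDTH = 6
PAD_SCORE = 0.0

_MAX_GAP_RUN = 5
_MIN_AA_POSITIONS = 5


@dataclass(frozen=True)
class GLAM2Motif:
    """Position-set motif; each position is a set of allowed symbols."""

    positions: Tuple[FrozenSet[str], ...]
    source_class: Optional[int] = None
    source_folds: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("motif must have at least one position")
        pos = tuple(frozenset(p) for p in self.positions)
        allowed = set(STANDARD_AAS) | {GAP}
        for p in pos:
            if not p:
                raise ValueError("motif position sets must be non-empty")
            bad = p - allowed
            if bad:
                raise ValueError(f"invalid motif symbols {sorted(bad)}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "source_folds", frozenset(self.source_folds))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_aa_positions(self) -> int:
        return sum(1 for p in self.positions if p - {GAP})


@dataclass(frozen=True)
class GIBBSMotif:
    """Probability motif: (n, 21) column-stochastic matrix over residues + gap."""

    matrix: np.ndarray
    source_class: Optional[int] = None
    source_folds: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 21 or m.shape[0] < 1:
            raise ValueError("GIBBS motif matrix must be (n, 21) with n >= 1")
        if (m < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each motif column must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "source_folds", frozenset(self.source_folds))

    def __len__(self) -> int:
        return int(self.matrix.shape[0])


Motif = Union[GLAM2Motif, GIBBSMotif]


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_glam2(motif: GLAM2Motif) -> List[GLAM2Motif]:
    """Apply the gap-run split and minimum-residue rules.

    Runs of more than five consecutive gap-only positions are removed
    and split the motif (left to right, recursively); fragments with
    fewer than five residue-bearing positions are dropped.  The result
    may be empty.
    """
    def split(positions: Sequence[FrozenSet[str]]) -> List[Tuple[FrozenSet[str], ...]]:
        run_start = None
        for i, p in enumerate(positions):
            if p == frozenset({GAP}):
                if run_start is None:
                    run_start = i
                if i - run_start + 1 > _MAX_GAP_RUN:
                    # extend the run to its full length, then split around it
                    j = i
                    while j < len(positions) and positions[j] == frozenset({GAP}):
                        j += 1
                    left = tuple(positions[:run_start])
                    rest = split(positions[j:])
                    return ([left] if left else []) + rest
            else:
                run_start = None
        return [tuple(positions)] if positions else []

    out = []
    for positions in split(motif.positions):
        frag = GLAM2Motif(positions=positions, source_class=motif.source_class,
                          source_folds=motif.source_folds) if positions else None
        if frag is not None and frag.n_aa_positions >= _MIN_AA_POSITIONS:
            out.append(frag)
    return out


# ---------------------------------------------------------------------------
# penalty functions

def glam2_penalty(position: FrozenSet[str], symbol: str) -> float:
    """Set-motif penalty: +1 allowed residue, -1 disallowed residue,
    0 for a gap the position allows, -1/3 for a gap it does not."""
    if symbol == GAP:
        return 0.0 if GAP in position else -1.0 / 3.0
    if symbol not in STANDARD_AAS:
        raise ValueError(f"invalid symbol {symbol!r}")
    return 1.0 if symbol in position else -1.0


_GIBBS_INDEX = {ch: i for i, ch in enumerate(GIBBS_ALPHABET)}


def gibbs_penalty(column: np.ndarray, symbol: str) -> float:
    """Probability-motif penalty: the column's probability of the symbol
    (the gap symbol reads the column's gap probability)."""
    try:
        return float(column[_GIBBS_INDEX[symbol]])
    except KeyError:
        raise ValueError(f"symbol {symbol!r} outside the motif alphabet") from None


# ---------------------------------------------------------------------------
# Smith-Waterman

def sw_align(seq: str, motif: Motif) -> float:
    """Best local-alignment score of a sequence against a motif.

    Dynamic programming over sequence positions i and motif positions j
    with zero cell floor; diagonal moves score the penalty function of
    (position j, residue i) and both gap directions score the penalty of
    (position j, gap).
    """
    if not seq:
        raise ValueError("empty sequence")
    L, n = len(seq), len(motif)
    if isinstance(motif, GLAM2Motif):
        sub = np.empty((L, n))
        gap_cost = np.empty(n)
        for j, pos in enumerate(motif.positions):
            gap_cost[j] = glam2_penalty(pos, GAP)
            for i, ch in enumerate(seq):
                sub[i, j] = glam2_penalty(pos, ch) if ch in STANDARD_AAS else -1.0
    else:
        m = motif.matrix
        # placeholder residues outside the alphabet read probability 0
        sub = np.empty((L, n))
        for i, ch in enumerate(seq):
            sub[i] = m[:, _GIBBS_INDEX[ch]] if ch in _GIBBS_INDEX else 0.0
        gap_cost = m[:, _GIBBS_INDEX[GAP]]

    H = np.zeros((L + 1, n + 1))
    best = 0.0
    # row 0 follows the same recurrence/floor: a local alignment may open
    # with gap moves when the motif's gap scores make that profitable
    # (possible for probability motifs, never for set motifs)
    for j in range(1, n + 1):
        H[0, j] = max(0.0, H[0, j - 1] + gap_cost[j - 1])
        best = max(best, H[0, j])
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            g = gap_cost[j - 1]
            v = max(0.0,
                    H[i - 1, j - 1] + sub[i - 1, j - 1],
                    H[i, j - 1] + g,
                    H[i - 1, j] + g)
            H[i, j] = v
            if v > best:
                best = v
    return best


# ---------------------------------------------------------------------------
# motif files

def write_glam2_motifs(motifs: Sequence[GLAM2Motif], path: str | Path) -> None:
    """One motif per stanza; one line per position listing its symbols."""
    with open(path, "w") as fh:
        for k, motif in enumerate(motifs):
            fh.write(f">motif{k + 1}\n")
            for pos in motif.positions:
                fh.write("".join(sorted(pos)) + "\n")


def read_glam2_motifs(path: str | Path, *, source_class: Optional[int] = None,
                      source_folds: Sequence[int] = ()) -> List[GLAM2Motif]:
    motifs: List[GLAM2Motif] = []
    positions: List[FrozenSet[str]] = []

    def flush() -> None:
        if positions:
            motifs.append(GLAM2Motif(positions=tuple(positions),
                                     source_class=source_class,
                                     source_folds=frozenset(source_folds)))
            positions.clear()

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                continue
            positions.append(frozenset(line))
    flush()
    return motifs


def write_gibbs_motif(motif: GIBBSMotif, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: " + " ".join(GIBBS_ALPHABET) + "\n")
        for row in motif.matrix:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_gibbs_motif(path: str | Path, *, source_class: Optional[int] = None,
                     source_folds: Sequence[int] = ()) -> GIBBSMotif:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(x) for x in line.split()])
    m = np.asarray(rows, dtype=float)
    m = m / m.sum(axis=1, keepdims=True)  # renormalize rounded probabilities
    return GIBBSMotif(matrix=m, source_class=source_class,
                      source_folds=frozenset(source_folds))


# ---------------------------------------------------------------------------
# library and feature blocks

@dataclass
class MotifLibrary:
    """Per-fold motif sets under the fold-exclusion scheme.

    ``glam2[(fold, cls)]`` holds the motifs usable for sequences *in*
    ``fold`` (i.e. built from all other folds); likewise ``gibbs``.
    """

    n_folds: int
    glam2: Dict[Tuple[int, int], List[GLAM2Motif]] = field(default_factory=dict)
    gibbs: Dict[Tuple[int, int], GIBBSMotif] = field(default_factory=dict)

    def _check(self, motif: Motif, fold: int) -> None:
        if fold in motif.source_folds:
            raise LeakageError(
                f"motif built from fold {fold} used for a fold-{fold} sequence")

    def glam2_for(self, fold: int, cls: int) -> List[GLAM2Motif]:
        motifs = self.glam2.get((fold, cls), [])
        for m in motifs:
            self._check(m, fold)
        return motifs

    def gibbs_for(self, fold: int, cls: int) -> Optional[GIBBSMotif]:
        motif = self.gibbs.get((fold, cls))
        if motif is not None:
            self._check(motif, fold)
        return motif

    @classmethod
    def from_directory(cls, directory: str | Path, n_folds: int = 10) -> "MotifLibrary":
        """Load ``fold{i}_class{c}.glam2.txt`` / ``.gibbs.txt`` files."""
        directory = Path(directory)
        lib = cls(n_folds=n_folds)
        for fold in range(1, n_folds + 1):
            others = frozenset(range(1, n_folds + 1)) - {fold}
            for c in OLIGOMER_CLASSES:
                gpath = directory / f"fold{fold}_class{c}.glam2.txt"
                if gpath.exists():
                    lib.glam2[(fold, c)] = read_glam2_motifs(
                        gpath, source_class=c, source_folds=others)
                bpath = directory / f"fold{fold}_class{c}.gibbs.txt"
                if bpath.exists():
                    lib.gibbs[(fold, c)] = read_gibbs_motif(
                        bpath, source_class=c, source_folds=others)
        return lib

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (fold, c), motifs in sorted(self.glam2.items()):
            write_glam2_motifs(motifs, directory / f"fold{fold}_class{c}.glam2.txt")
        for (fold, c), motif in sorted(self.gibbs.items()):
            write_gibbs_motif(motif, directory / f"fold{fold}_class{c}.gibbs.txt")


def glam2_feature_block(seq: str, fold_of_seq: int, library: MotifLibrary) -> np.ndarray:
    """Per class, the five highest motif alignment scores, descending (30)."""
    out = np.full(GLAM2_BLOCK_WIDTH, PAD_SCORE)
    for k, cls in enumerate(OLIGOMER_CLASSES):
        motifs = library.glam2_for(fold_of_seq, cls)
        if not motifs:
            warnings.warn(f"no gapped motifs for class {cls}; block padded",
                          stacklevel=2)
            continue
        scores = [sw_align(seq, m) for m in motifs]
        # stable sort descending: ties keep motif index order
        top = sorted(scores, key=lambda s: -s)[:5]
        out[5 * k: 5 * k + len(top)] = top
    return out


def gibbs_feature_block(seq: str, fold_of_seq: int, library: MotifLibrary) -> np.ndarray:
    """Alignment score against each class's probability motif (6)."""
    out = np.full(GIBBS_BLOCK_WIDTH, PAD_SCORE)
    for k, cls in enumerate(OLIGOMER_CLASSES):
        motif = library.gibbs_for(fold_of_seq, cls)
        if motif is None:
            warnings.warn(f"no probability motif for class {cls}; padded",
                          stacklevel=2)
            continue
        out[k] = sw_align(seq, motif)
    return out
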