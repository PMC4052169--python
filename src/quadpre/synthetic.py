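"""Synthetic class-labelled datasets with planted, recoverable signal.

The generator fabricates everything the pipeline consumes — labelled
sequences, surrogate PSSM / secondary-structure / RSA profiles,
per-fold motif libraries, and per-query similarity hit tables — with a
tunable amount of class signal in every feature block:

* composition bias: each class draws residues from a mixture of the
  uniform background and a class-specific preferred residue subset;
* a planted class motif embedded at a random position, mutated
  per-residue with probability 1 - conservation;
* surrogate profiles: PSSM = scaled one-hot of the sequence plus
  integer noise; secondary structure sampled from class-tilted segment
  propensities; RSA from a class-shifted beta distribution;
* hit tables in which same-class reference sequences receive far
  smaller E-values with probability equal to the hit signal;
* per-fold-complement GLAM2/GIBBS motif files derived from the planted
  motifs, never from the excluded fold.

With every signal knob at zero the six classes are exchangeable and
cross-validated AUC sits at chance.  The surrogate profiles exercise
parsing, widths and signal flow only — they make no attempt to imitate
the output statistics of the real external predictors, so results on
synthetic data say nothing about accuracy on real proteins.

Everything is driven by a single mandatory seed and is byte-identical
across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from .core_io import (BlastHit, BlastHitTable, FoldAssignment, OLIGOMER_CLASSES,
                      PSSM_AA_ORDER, ProteinRecord, SSPrediction, partition_folds,
                      read_blast_tab, read_fasta, read_folds, read_labels,
                      read_pssm, read_rsa, read_ss2, write_fasta, write_folds,
                      write_labels, write_pssm, write_rsa, write_ss2)
from .model import ProfileSet
from .motif_features import GAP, GIBBS_ALPHABET, GIBBSMotif, GLAM2Motif, MotifLibrary
from .scales import STANDARD_AAS

#: Class-specific preferred residues for the composition bias.
CLASS_PREFERRED: Dict[int, str] = {
    1: "AVLG", 2: "KRHE", 3: "STNQ", 4: "FYWM", 6: "DEPG", 8: "CILV",
}

#: Class-specific (H, E, C) secondary-structure propensities at full signal.
_CLASS_SS: Dict[int, Tuple[float, float, float]] = {
    1: (0.70, 0.10, 0.20), 2: (0.10, 0.70, 0.20), 3: (0.50, 0.30, 0.20),
    4: (0.60, 0.20, 0.20), 6: (0.20, 0.60, 0.20), 8: (0.35, 0.45, 0.20),
}
_BASE_SS = (0.30, 0.20, 0.50)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``n_per_class`` may be a single count or a per-class mapping (e.g.
    to mimic an unbalanced benchmark).  All signal strengths live in
    [0, 1]; zero everywhere yields label-exchangeable data.
    """

    seed: int
    n_per_class: Union[int, Mapping[int, int]] = 100
    length_range: Tuple[int, int] = (30, 60)
    composition_bias: float = 0.5
    motif_length: int = 8
    motif_conservation: float = 0.9
    profile_signal: float = 0.8
    profile_noise: float = 0.3
    hit_signal: float = 0.9
    n_glam2_per_class: int = 2
    n_folds: int = 10

    def __post_init__(self) -> None:
        for name in ("composition_bias", "motif_conservation",
                     "profile_signal", "profile_noise", "hit_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.length_range[0] < 30:
            raise ValueError("minimum sequence length is 30")
        if self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length range")
        if self.motif_length < 5:
            raise ValueError("planted motifs need at least 5 positions")

    def class_counts(self) -> Dict[int, int]:
        if isinstance(self.n_per_class, int):
            return {c: self.n_per_class for c in OLIGOMER_CLASSES}
        counts = dict(self.n_per_class)
        if set(counts) != set(OLIGOMER_CLASSES):
            raise ValueError("per-class counts must cover all six classes")
        return counts


@dataclass
class SyntheticDataset:
    records: List[ProteinRecord]
    profiles: Dict[str, ProfileSet]
    motif_library: MotifLibrary
    hit_tables: Dict[str, Dict[int, BlastHitTable]]
    folds: FoldAssignment
    truth: Dict[str, int]
    consensus: Dict[int, str] = field(default_factory=dict)


def _composition_weights(cls: int, bias: float) -> np.ndarray:
    w = np.full(20, (1.0 - bias) / 20.0)
    pref = CLASS_PREFERRED[cls]
    for aa in pref:
        w[STANDARD_AAS.index(aa)] += bias / len(pref)
    return w / w.sum()


def _sample_sequence(rng: np.random.Generator, cls: int, L: int,
                     spec: SyntheticSpec, consensus: str) -> str:
    aas = np.array(list(STANDARD_AAS))
    weights = _composition_weights(cls, spec.composition_bias)
    seq = list(rng.choice(aas, size=L, p=weights))
    start = int(rng.integers(0, L - len(consensus) + 1))
    for k, ch in enumerate(consensus):
        if rng.random() < spec.motif_conservation:
            seq[start + k] = ch
        # otherwise the background draw stands (fully mutated at zero signal)
    return "".join(seq)


def _surrogate_pssm(rng: np.random.Generator, seq: str,
                    spec: SyntheticSpec) -> np.ndarray:
    L = len(seq)
    onehot = np.zeros((L, 20))
    for i, ch in enumerate(seq):
        if ch in PSSM_AA_ORDER:
            onehot[i, PSSM_AA_ORDER.index(ch)] = 1.0
    noise = rng.normal(0.0, 1.0 + 4.0 * spec.profile_noise, size=(L, 20))
    return np.rint(7.0 * onehot - 2.0 + noise)


def _surrogate_ss(rng: np.random.Generator, cls: int, L: int,
                  spec: SyntheticSpec) -> SSPrediction:
    s = spec.profile_signal
    probs = np.array([(1 - s) * b + s * c
                      for b, c in zip(_BASE_SS, _CLASS_SS[cls])])
    probs /= probs.sum()
    states: List[str] = []
    while len(states) < L:
        state = "HEC"[int(rng.choice(3, p=probs))]
        if states and states[-1] == state:
            continue
        run = 2 + int(rng.geometric(0.35))
        states.extend(state * min(run, L - len(states)))
    conf = np.zeros((L, 3))
    for i, state in enumerate(states):
        p_true = round(float(rng.uniform(0.60, 0.95)), 3)
        p_other = round((1.0 - p_true) / 2.0, 3)
        p_last = round(1.0 - p_true - p_other, 3)
        k = "HEC".index(state)
        rest = [j for j in range(3) if j != k]
        conf[i, k] = p_true
        conf[i, rest[0]] = p_other
        conf[i, rest[1]] = p_last
    return SSPrediction(states="".join(states), confidence=conf)


def _surrogate_rsa(rng: np.random.Generator, cls: int, L: int,
                   spec: SyntheticSpec) -> np.ndarray:
    k = list(OLIGOMER_CLASSES).index(cls)
    mean = 0.25 + spec.profile_signal * 0.07 * k
    a, b = mean * 10.0, (1.0 - mean) * 10.0
    return np.clip(np.round(rng.beta(a, b, size=L), 4), 0.0, 1.0)


def _build_motif_library(rng: np.random.Generator, spec: SyntheticSpec,
                         consensus: Dict[int, str]) -> MotifLibrary:
    lib = MotifLibrary(n_folds=spec.n_folds)
    letters = list(STANDARD_AAS)
    for fold in range(1, spec.n_folds + 1):
        others = frozenset(range(1, spec.n_folds + 1)) - {fold}
        for cls in OLIGOMER_CLASSES:
            cons = consensus[cls]
            motifs = []
            for m in range(spec.n_glam2_per_class):
                positions = []
                for ch in cons:
                    pos = {ch}
                    # degenerate variants broaden later motifs slightly
                    if m > 0 and rng.random() < 1.0 - spec.motif_conservation:
                        pos.add(str(rng.choice(letters)))
                    positions.append(frozenset(pos))
                motifs.append(GLAM2Motif(positions=tuple(positions),
                                         source_class=cls, source_folds=others))
            lib.glam2[(fold, cls)] = motifs
            cons_prob = 0.05 + 0.9 * spec.motif_conservation
            matrix = np.full((len(cons), 21), (1.0 - cons_prob) / 20.0)
            for i, ch in enumerate(cons):
                matrix[i, GIBBS_ALPHABET.index(ch)] += cons_prob - (1.0 - cons_prob) / 20.0
                matrix[i] /= matrix[i].sum()
            lib.gibbs[(fold, cls)] = GIBBSMotif(matrix=matrix, source_class=cls,
                                                source_folds=others)
    return lib


def _hit_tables_for(rng: np.random.Generator, record: ProteinRecord,
                    folds: FoldAssignment, spec: SyntheticSpec
                    ) -> Dict[int, BlastHitTable]:
    fold = folds.fold_of(record.id)
    tables: Dict[int, BlastHitTable] = {}
    for cls in OLIGOMER_CLASSES:
        pool: List[str] = []
        for k in range(1, spec.n_folds + 1):
            if k != fold:
                pool.extend(folds.roster(k, cls))
        pool = [p for p in pool if p != record.id]
        n_hits = min(5, len(pool))
        subjects = (rng.choice(np.array(pool), size=n_hits, replace=False)
                    if n_hits else [])
        hits = []
        for sid in subjects:
            strong = (cls == record.label) and (rng.random() < spec.hit_signal)
            expo = int(rng.integers(20, 61)) if strong else int(rng.integers(0, 6))
            mantissa = round(float(rng.uniform(1.0, 9.49)), 2)
            evalue = float(f"{mantissa:.2f}e-{expo:02d}")
            hits.append(BlastHit(subject_id=str(sid), subject_class=cls,
                                 evalue=evalue, subject_fold=folds.fold_of(str(sid))))
        tables[cls] = BlastHitTable(query_id=record.id, hits=tuple(hits))
    return tables


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a fully reproducible labelled dataset with all inputs."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.class_counts()

    consensus = {
        cls: "".join(rng.choice(list(STANDARD_AAS), size=spec.motif_length))
        for cls in OLIGOMER_CLASSES
    }

    records: List[ProteinRecord] = []
    for cls in OLIGOMER_CLASSES:
        for k in range(counts[cls]):
            L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = _sample_sequence(rng, cls, L, spec, consensus[cls])
            records.append(ProteinRecord(id=f"c{cls}_{k:04d}", sequence=seq,
                                         label=cls))

    fold_seed = int(rng.integers(2 ** 31))
    folds = partition_folds(records, n_folds=spec.n_folds, seed=fold_seed)

    profiles: Dict[str, ProfileSet] = {}
    for r in records:
        profiles[r.id] = ProfileSet(
            pssm=_surrogate_pssm(rng, r.sequence, spec),
            ss=_surrogate_ss(rng, r.label, r.length, spec),
            rsa=_surrogate_rsa(rng, r.label, r.length, spec),
        )

    motif_library = _build_motif_library(rng, spec, consensus)

    hit_tables = {r.id: _hit_tables_for(rng, r, folds, spec) for r in records}

    truth = {r.id: int(r.label) for r in records}
    return SyntheticDataset(records=records, profiles=profiles,
                            motif_library=motif_library, hit_tables=hit_tables,
                            folds=folds, truth=truth, consensus=consensus)


# ---------------------------------------------------------------------------
# fixture bundles on disk

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(dataset: SyntheticDataset, directory: str | Path
                         ) -> Dict[str, str]:
    """Write the dataset in the on-disk dialects the readers consume.

    Returns the manifest (relative path -> sha256), which is also
    written to ``manifest.json``.
    """
    directory = Path(directory)
    for sub in ("pssm", "ss", "rsa", "hits", "motifs"):
        (directory / sub).mkdir(parents=True, exist_ok=True)

    write_fasta(dataset.records, directory / "sequences.fasta")
    write_labels(dataset.truth, directory / "labels.tsv")
    write_folds(dataset.folds, directory / "folds.tsv")
    for r in dataset.records:
        prof = dataset.profiles[r.id]
        write_pssm(prof.pssm, r.sequence, directory / "pssm" / f"{r.id}.pssm")
        write_ss2(prof.ss, r.sequence, directory / "ss" / f"{r.id}.ss2")
        write_rsa(prof.rsa, directory / "rsa" / f"{r.id}.rsa")
        with open(directory / "hits" / f"{r.id}.tsv", "w") as fh:
            for cls in OLIGOMER_CLASSES:
                for hit in dataset.hit_tables[r.id][cls].hits:
                    fh.write(f"{r.id}\t{hit.subject_id}\t{hit.evalue:.2e}\n")
    dataset.motif_library.write(directory / "motifs")

    manifest: Dict[str, str] = {}
    for path in sorted(directory.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(directory))] = _sha256(path)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def verify_manifest(directory: str | Path) -> None:
    """Raise if any bundled file's checksum differs from the manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    for rel, digest in manifest.items():
        path = directory / rel
        if not path.exists():
            raise ValueError(f"manifest references missing file {rel}")
        if _sha256(path) != digest:
            raise ValueError(f"checksum mismatch for {rel}")


def read_fixture_bundle(directory: str | Path) -> SyntheticDataset:
    """Read a bundle back; inverse of :func:`write_fixture_bundle`."""
    directory = Path(directory)
    truth = read_labels(directory / "labels.tsv")
    raw = read_fasta(directory / "sequences.fasta")
    records = [ProteinRecord(id=r.id, sequence=r.sequence, label=truth[r.id])
               for r in raw]
    folds = read_folds(directory / "folds.tsv", truth)
    profiles: Dict[str, ProfileSet] = {}
    hit_tables: Dict[str, Dict[int, BlastHitTable]] = {}
    for r in records:
        profiles[r.id] = ProfileSet(
            pssm=read_pssm(directory / "pssm" / f"{r.id}.pssm", r.length),
            ss=read_ss2(directory / "ss" / f"{r.id}.ss2", r.length),
            rsa=read_rsa(directory / "rsa" / f"{r.id}.rsa", r.length),
        )
        tables = read_blast_tab(directory / "hits" / f"{r.id}.tsv", truth,
                                fold_map=folds.assignment)
        table = tables.get(r.id, BlastHitTable(query_id=r.id, hits=()))
        per_class: Dict[int, BlastHitTable] = {}
        for cls in OLIGOMER_CLASSES:
            hits = tuple(h for h in table.hits if h.subject_class == cls)
            per_class[cls] = BlastHitTable(query_id=r.id, hits=hits)
        hit_tables[r.id] = per_class
    motif_library = MotifLibrary.from_directory(directory / "motifs",
                                                n_folds=folds.n_folds)
    return SyntheticDataset(records=records, profiles=profiles,
                            motif_library=motif_library, hit_tables=hit_tables,
                            folds=folds, truth=truth)
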