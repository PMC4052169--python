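"""Features computed from the primary sequence alone (123 values).

Layout of the block, in fixed order:

====================  =====  =========================================
sub-block             width  content
====================  =====  =========================================
length                1      sequence length L
composition           20     fraction of each standard residue
group_counts          18     residue counts per group over the four
                             groupings (R 5, electronic 5,
                             hydrophobicity 3, exchange 5)
cmv                   40     composition moment vector, orders 1 and 2
mean_pi               1      mean isoelectric point
autocorr              25     scale autocorrelation: FH lags 1-10,
                             EH lags 1-6, HP lags 1-9
cum_autocorr          6      cumulative FH autocorrelation, lags 1-6
hsum                  2      summed FH and EH hydrophobicity
rgroup_pct            5      R-group composition percentages
egroup_pct            5      electronic-group composition percentages
====================  =====  =========================================

Composition-type features count only the 20 standard residues; the
placeholder ``X`` contributes zero to every scale so it is neutral in
positional features.  The composition moment vector of order k for
residue type x is

    CMV_x^k = sum_{j in positions(x)} j^k / prod_{d=0..k} (L - d)

with 1-based positions, so order k needs L >= k + 1.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .core_io import ProteinRecord
from .scales import DEFAULT_SCALES, PhysicoScales, STANDARD_AAS

SEQ_BLOCK_WIDTH = 123

#: (scale, lag range) pairs of the autocorrelation sub-block.
AUTOCORR_SPEC = (("FH", range(1, 11)), ("EH", range(1, 7)), ("HP", range(1, 10)))

CUM_AUTOCORR_LAGS = range(1, 7)


def _scale_values(seq: str, table) -> np.ndarray:
    """Per-residue scale values; non-standard placeholders score 0."""
    return np.array([table.get(ch, 0.0) for ch in seq], dtype=float)


def _standard_mask(seq: str) -> np.ndarray:
    return np.array([ch in STANDARD_AAS for ch in seq], dtype=bool)


def composition_vector(seq: str) -> np.ndarray:
    """Fractions of the 20 standard residues among counted residues."""
    if not seq:
        raise ValueError("empty sequence")
    n_std = int(_standard_mask(seq).sum())
    counts = np.array([seq.count(aa) for aa in STANDARD_AAS], dtype=float)
    return counts / n_std if n_std else counts


def group_counts(seq: str, scales: PhysicoScales = DEFAULT_SCALES) -> np.ndarray:
    """Raw residue counts per group: 18 integers over the four groupings."""
    if not seq:
        raise ValueError("empty sequence")
    out: List[float] = []
    for _, groups in scales.all_groupings():
        for _, members in groups:
            out.append(sum(seq.count(aa) for aa in members))
    counts = np.array(out, dtype=float)
    assert counts.size == 18
    return counts


def composition_moment_vector(seq: str, order: int) -> np.ndarray:
    """CMV of the given order (1 or 2) over the 20 standard residues."""
    if order not in (1, 2):
        raise ValueError("only orders 1 and 2 are defined")
    L = len(seq)
    if L < order + 1:
        raise ValueError(f"sequence of length {L} too short for CMV order {order}")
    denom = 1.0
    for d in range(order + 1):
        denom *= (L - d)
    positions = np.arange(1, L + 1, dtype=float) ** order
    out = np.zeros(20)
    for k, aa in enumerate(STANDARD_AAS):
        mask = np.array([ch == aa for ch in seq])
        out[k] = positions[mask].sum() / denom
    return out


def mean_isoelectric_point(seq: str, scales: PhysicoScales = DEFAULT_SCALES) -> float:
    """Arithmetic mean of the free-amino-acid pI over counted residues."""
    mask = _standard_mask(seq)
    if not mask.any():
        raise ValueError("no standard residues")
    vals = _scale_values(seq, scales.pi)
    return float(vals[mask].mean())


def autocorrelation(seq: str, scale: str, lag: int,
                    scales: PhysicoScales = DEFAULT_SCALES) -> float:
    """Scale autocorrelation A_n = 1/(L-n) * sum_i a_i * a_{i+n}."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    L = len(seq)
    if L <= lag:
        raise ValueError(f"lag {lag} requires sequence length > {lag}, got {L}")
    a = _scale_values(seq, scales.scale(scale))
    return float(np.dot(a[:-lag], a[lag:]) / (L - lag))


def cumulative_autocorrelation(seq: str, lag: int,
                               scales: PhysicoScales = DEFAULT_SCALES) -> float:
    """Cumulative FH autocorrelation using prefix sums:

    A_n = sum_{i=1..L-n} S_i * S_{i+n} / (L - n),  S_i = sum_{j<=i} a_j.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    L = len(seq)
    if L <= lag:
        raise ValueError(f"lag {lag} requires sequence length > {lag}, got {L}")
    prefix = np.cumsum(_scale_values(seq, scales.fh))
    i = np.arange(L - lag)
    return float(np.dot(prefix[i], prefix[i + lag]) / (L - lag))


def hydrophobicity_sum(seq: str, scale: str,
                       scales: PhysicoScales = DEFAULT_SCALES) -> float:
    """Plain sum of the FH or EH scale over residues."""
    if scale not in ("FH", "EH"):
        raise ValueError("hydrophobicity sums are defined for FH and EH")
    if not seq:
        raise ValueError("empty sequence")
    return float(_scale_values(seq, scales.scale(scale)).sum())


def group_percentages(seq: str, grouping: str,
                      scales: PhysicoScales = DEFAULT_SCALES) -> np.ndarray:
    """Composition percentage of each of the 5 R or electronic groups."""
    groups = {"R": scales.r_groups, "electronic": scales.electronic_groups}[grouping]
    n_std = int(_standard_mask(seq).sum())
    counts = np.array(
        [sum(seq.count(aa) for aa in members) for _, members in groups], dtype=float)
    return counts / n_std if n_std else counts


def seq_feature_names(scales: PhysicoScales = DEFAULT_SCALES) -> List[str]:
    names = ["length"]
    names += [f"comp_{aa}" for aa in STANDARD_AAS]
    for gname, groups in scales.all_groupings():
        names += [f"count_{gname}_{sub}" for sub, _ in groups]
    for order in (1, 2):
        names += [f"cmv{order}_{aa}" for aa in STANDARD_AAS]
    names += ["mean_pi"]
    for scale, lags in AUTOCORR_SPEC:
        names += [f"ac_{scale}_{n}" for n in lags]
    names += [f"cumac_FH_{n}" for n in CUM_AUTOCORR_LAGS]
    names += ["hsum_FH", "hsum_EH"]
    names += [f"rgroup_pct_{sub}" for sub, _ in scales.r_groups]
    names += [f"egroup_pct_{sub}" for sub, _ in scales.electronic_groups]
    assert len(names) == SEQ_BLOCK_WIDTH
    return names


def sequence_feature_block(record: ProteinRecord | str,
                           scales: PhysicoScales = DEFAULT_SCALES) -> np.ndarray:
    """Assemble the full 123-wide sequence feature block."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    parts = [
        np.array([float(len(seq))]),
        composition_vector(seq),
        group_counts(seq, scales),
        composition_moment_vector(seq, 1),
        composition_moment_vector(seq, 2),
        np.array([mean_isoelectric_point(seq, scales)]),
        np.array([autocorrelation(seq, scale, n, scales)
                  for scale, lags in AUTOCORR_SPEC for n in lags]),
        np.array([cumulative_autocorrelation(seq, n, scales)
                  for n in CUM_AUTOCORR_LAGS]),
        np.array([hydrophobicity_sum(seq, "FH", scales),
                  hydrophobicity_sum(seq, "EH", scales)]),
        group_percentages(seq, "R", scales),
        group_percentages(seq, "electronic", scales),
    ]
    block = np.concatenate(parts)
    assert block.size == SEQ_BLOCK_WIDTH, block.size
    assert np.isfinite(block).all()
    return block
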