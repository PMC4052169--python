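"""Similarity features from per-class hit tables (30 values).

For a query sequence, the five most similar reference sequences of each
oligomeric class (searched against reference folds other than the
query's own) contribute one feature each: the E-value index, i.e. the
negated base-10 exponent of the E-value in scientific notation, so
better hits give larger values.  ``3.2e-5`` maps to 5, ``1e-30`` to 30,
anything >= 1 to <= 0, and a reported E-value of exactly 0 maps to a cap
of 200.  Classes with fewer than five hits are padded with 0.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional

import numpy as np

from .core_io import BlastHitTable, LeakageError, OLIGOMER_CLASSES, ProteinRecord

BLAST_BLOCK_WIDTH = 30

#: Feature value for an E-value reported as exactly 0 (tool underflow).
ZERO_EVALUE_CAP = 200.0

#: Feature value for a missing hit.
PAD_VALUE = 0.0


def evalue_index(evalue: float) -> float:
    """Negated base-10 exponent of the E-value's scientific notation.

    The mantissa is discarded: ``evalue_index(3.2e-5) == 5``.
    """
    if evalue < 0 or not math.isfinite(evalue):
        raise ValueError(f"E-value must be finite and >= 0, got {evalue!r}")
    if evalue == 0:
        return ZERO_EVALUE_CAP
    return float(-math.floor(math.log10(evalue)))


def blast_feature_block(
    query: ProteinRecord | str,
    fold_of_query: int,
    tables: Mapping[int, BlastHitTable],
) -> np.ndarray:
    """Per class, E-value indices of the five best hits (30 values).

    Self-hits are excluded; a hit annotated with the query's own fold is
    a leakage error.
    """
    query_id = query.id if isinstance(query, ProteinRecord) else str(query)
    out = np.full(BLAST_BLOCK_WIDTH, PAD_VALUE)
    for k, cls in enumerate(OLIGOMER_CLASSES):
        table = tables.get(cls)
        if table is None:
            continue
        rank = 0
        seen = set()
        for hit in table.hits:  # already ascending by E-value
            if hit.subject_id == query_id:
                continue
            if hit.subject_fold is not None and hit.subject_fold == fold_of_query:
                raise LeakageError(
                    f"hit table for query {query_id!r} references subject "
                    f"{hit.subject_id!r} from the query's own fold {fold_of_query}")
            if hit.subject_class != cls:
                continue
            if hit.subject_id in seen:
                continue
            seen.add(hit.subject_id)
            out[5 * k + rank] = evalue_index(hit.evalue)
            rank += 1
            if rank == 5:
                break
    return out
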