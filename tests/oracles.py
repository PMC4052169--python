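"""Independent brute-force oracles used to pin the optimized implementations.

Everything here is deliberately naive: explicit loops and explicit
enumeration, sharing no code with the package internals they check.
"""

from __future__ import annotations

import math
from typing import List, Sequence

from quadpre.motif_features import (GAP, GIBBSMotif, GLAM2Motif,
                                    gibbs_penalty, glam2_penalty)


def brute_cmv(seq: str, aa: str, order: int) -> float:
    denom = 1.0
    L = len(seq)
    for d in range(order + 1):
        denom *= (L - d)
    total = 0.0
    for j, ch in enumerate(seq, start=1):
        if ch == aa:
            total += j ** order
    return total / denom


def brute_autocorr(seq: str, table, lag: int) -> float:
    L = len(seq)
    total = 0.0
    for i in range(L - lag):
        total += table.get(seq[i], 0.0) * table.get(seq[i + lag], 0.0)
    return total / (L - lag)


def brute_cumulative_autocorr(seq: str, table, lag: int) -> float:
    L = len(seq)
    vals = [table.get(ch, 0.0) for ch in seq]
    total = 0.0
    for i in range(1, L - lag + 1):
        left = sum(vals[:i])
        right = sum(vals[:i + lag])
        total += left * right
    return total / (L - lag)


def brute_mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    den = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den


def brute_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney pair counting: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _move_scores(seq: str, motif):
    """Substitution and per-column gap costs under the motif's penalties."""
    if isinstance(motif, GLAM2Motif):
        sub = [[glam2_penalty(pos, ch) for pos in motif.positions] for ch in seq]
        gap = [glam2_penalty(pos, GAP) for pos in motif.positions]
    else:
        sub = [[gibbs_penalty(motif.matrix[j], ch) for j in range(len(motif))]
               for ch in seq]
        gap = [gibbs_penalty(motif.matrix[j], GAP) for j in range(len(motif))]
    return sub, gap


def enumerate_local_score(seq: str, motif) -> float:
    """Best local-alignment score by explicit enumeration of all paths.

    A local alignment is a monotone path of diagonal / motif-advance /
    sequence-advance moves starting anywhere; each move against motif
    column j contributes the substitution penalty (diagonal) or the
    column's gap penalty (either single advance).  The best score over
    every path prefix, floored at 0, must equal the DP result.
    """
    L, n = len(seq), len(motif)
    sub, gap = _move_scores(seq, motif)
    best = 0.0

    def dfs(i: int, j: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < L and j < n:
            dfs(i + 1, j + 1, score + sub[i][j])
        if j < n:
            dfs(i, j + 1, score + gap[j])
        if i < L and j >= 1:
            # sequence advances while sitting at motif column j
            dfs(i + 1, j, score + gap[j - 1])

    for i0 in range(L + 1):
        for j0 in range(n + 1):
            dfs(i0, j0, 0.0)
    return best
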