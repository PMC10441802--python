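"""Weighted averaging of per-model similarity matrices.

The consensus matrix C = sum_m w_m S^m is the elementwise convex
combination of the models' similarity matrices, weighted by the
normalised CIVI weights.  It is a posterior similarity matrix over the
model ensemble: C_ij is the model-averaged probability that points i and
j share a cluster.
"""

from __future__ import annotations

import numpy as np

from .civi import ModelWeights
from .core import SimilarityMatrix

#: Weights summing to 1 within this tolerance are renormalised; beyond it
#: the input is rejected (protects the unit-diagonal invariant of C).
WEIGHT_SUM_TOL = 1e-6


def consensus_matrix(sims: list[SimilarityMatrix], weights: ModelWeights) -> SimilarityMatrix:
    """Elementwise weighted average of similarity matrices.

    Requires as many weights as matrices, all matrices over the same N,
    and weights summing to 1 (within :data:`WEIGHT_SUM_TOL`).
    """
    if len(sims) == 0:
        raise ValueError("need at least one similarity matrix")
    w = np.asarray(weights.normalised, dtype=float)
    if w.size != len(sims):
        raise ValueError(f"{len(sims)} similarity matrices but {w.size} weights")
    n = sims[0].n_points
    for s in sims:
        if s.n_points != n:
            raise ValueError("similarity matrices disagree on N")
    total = w.sum()
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"weights sum to {total:.8g}, not 1")
    w = w / total
    c = np.zeros((n, n))
    for wm, s in zip(w, sims):
        c += wm * s.values
    np.clip(c, 0.0, 1.0, out=c)
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 1.0)
    return SimilarityMatrix(c)
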