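"""External evaluation of ensemble solutions against ground truth.

The benchmark metric is the Hubert-Arabie Adjusted Rand Index: pairwise
agreement between two partitions, chance-corrected so random labellings
score 0 in expectation and identical partitions (up to relabelling)
score 1.  The high-certainty subset restricts evaluation to points whose
final allocation probability clears a threshold, isolating the part of
the sample for which the ensemble claims low model-based uncertainty.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .ssmf import EnsembleResult


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie ARI between two partitions of the same points."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def high_certainty_subset(
    result: EnsembleResult, threshold: float = 0.8
) -> tuple[np.ndarray, float]:
    """Indices with max allocation probability strictly above ``threshold``.

    Returns the index array and the proportion of points retained.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    max_prob = result.allocations.values.max(axis=1)
    idx = np.flatnonzero(max_prob > threshold)
    n = result.allocations.n_points
    if idx.size == 0:
        warnings.warn("no point exceeds the certainty threshold", RuntimeWarning)
    return idx, idx.size / n
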