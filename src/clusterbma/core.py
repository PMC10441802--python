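"""Domain containers and the allocation-to-similarity transformation.

The two central objects of the ensemble are the cluster *allocation
matrix* ``A`` (N observations x K clusters, rows on the probability
simplex) and the pairwise *similarity matrix* ``S`` (N x N co-assignment
probabilities).  A hard clusterer produces a binary allocation matrix; a
soft clusterer (e.g. a Gaussian mixture) produces probabilistic rows.
Every model's solution, whatever its number of clusters or labelling,
maps onto a similarity matrix ``S = A A^T`` (diagonal set to 1), which is
the common quantity averaged across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tolerance within which allocation rows must sum to 1.  Rows inside the
#: tolerance are renormalised; rows outside it are rejected as malformed.
ROW_SUM_TOL = 1e-8

#: Symmetry tolerance for similarity/consensus matrices.
SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class AllocationMatrix:
    """N x K matrix of cluster membership probabilities for one model.

    Rows lie on the probability simplex.  ``model_id`` identifies the
    producing algorithm (or the ensemble itself for averaged output).
    """

    values: np.ndarray
    model_id: str = "model"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("allocation matrix must be a non-empty 2-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("allocation matrix contains non-finite entries")
        if values.min() < -ROW_SUM_TOL or values.max() > 1 + ROW_SUM_TOL:
            raise ValueError("allocation probabilities must lie in [0, 1]")
        row_sums = values.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"allocation rows must sum to 1 (row {bad} sums to {row_sums[bad]:.6g})"
            )
        values = np.clip(values, 0.0, 1.0)
        values = values / values.sum(axis=1, keepdims=True)
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    @property
    def is_hard(self) -> bool:
        """True when every row is a vertex of the simplex (binary allocation)."""
        return bool(np.all(np.isin(self.values, (0.0, 1.0))))

    def hard_labels(self) -> np.ndarray:
        """1-based cluster labels by highest membership (ties to lowest index)."""
        return np.argmax(self.values, axis=1) + 1


@dataclass(frozen=True)
class SimilarityMatrix:
    """N x N matrix of pairwise co-assignment probabilities.

    Symmetric, entries in [0, 1], unit diagonal.  Holds both a single
    model's similarity matrix and the weighted consensus across models.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.all(np.isfinite(values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.max(np.abs(values - values.T)) > SYMMETRY_TOL:
            raise ValueError("similarity matrix must be symmetric")
        if values.min() < -SYMMETRY_TOL or values.max() > 1 + SYMMETRY_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")
        values = np.clip(0.5 * (values + values.T), 0.0, 1.0)
        if not np.all(np.diag(values) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LabeledDataset:
    """Synthetic feature matrix with ground-truth cluster labels.

    ``separation`` records the pairwise separation index the generator
    targeted; ``sizes`` the planted per-cluster counts.
    """

    features: np.ndarray
    labels: np.ndarray
    separation: float
    sizes: tuple[int, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isfinite(features)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if features.shape[0] != labels.shape[0]:
            raise ValueError("features and labels disagree on N")
        k = len(self.sizes)
        counts = np.bincount(labels, minlength=k + 1)[1:]
        if labels.min() < 1 or labels.max() > k or tuple(counts) != tuple(self.sizes):
            raise ValueError("labels must be 1..K with counts matching `sizes`")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)

    @property
    def n_points(self) -> int:
        return self.features.shape[0]

    @property
    def n_dims(self) -> int:
        return self.features.shape[1]


def allocation_to_similarity(alloc: AllocationMatrix) -> SimilarityMatrix:
    """Similarity matrix ``S = A A^T`` with the diagonal forced to 1.

    Off-diagonal entry ``s_ij`` is the inner product of allocation rows i
    and j: the probability that i and j are co-assigned under the model.
    For hard allocations this is exactly the 0/1 co-membership indicator.
    """
    a = alloc.values
    s = a @ a.T
    np.fill_diagonal(s, 1.0)
    # numerical guard: inner products of simplex rows are already in [0,1]
    np.clip(s, 0.0, 1.0, out=s)
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s)


def crisp_projection(alloc: AllocationMatrix) -> AllocationMatrix:
    """Harden a soft allocation: each point to its highest-probability cluster.

    Ties are broken to the lowest cluster index (deterministic).
    """
    idx = np.argmax(alloc.values, axis=1)
    hard = np.zeros_like(alloc.values)
    hard[np.arange(alloc.n_points), idx] = 1.0
    return AllocationMatrix(hard, model_id=alloc.model_id)


def labels_to_allocation(labels, k: int, model_id: str = "model") -> AllocationMatrix:
    """Hard N x k allocation matrix from 1-based integer labels."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    hard = np.zeros((labels.size, k))
    hard[np.arange(labels.size), labels - 1] = 1.0
    return AllocationMatrix(hard, model_id=model_id)
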