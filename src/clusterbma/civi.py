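"""Clustering internal validation indices (CIVIs) and model weights.

A CIVI scores the quality of a clustering without reference to ground
truth — compactness, separation, inter-cluster density.  Here CIVI scores
stand in for the marginal likelihood of each candidate model: normalising
them across models (directly for maximise-type indices, reciprocally for
minimise-type) gives weights that, under equal model priors 1/M,
approximate posterior model probabilities and drive the weighted average
of similarity matrices.

Two indices are first-class: the Calinski-Harabasz index (ratio of
between- to within-cluster sums of squares, to be maximised) and S_Dbw
(intra-cluster variance plus inter-cluster density, to be minimised).
The registry is pluggable so other indices can be added with a declared
direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .core import AllocationMatrix, crisp_projection

Direction = Literal["maximise", "minimise"]


def _split_by_label(features: np.ndarray, labels: np.ndarray):
    uniq = np.unique(labels)
    return uniq, [features[labels == u] for u in uniq]


def _check_partition(features: np.ndarray, labels: np.ndarray) -> None:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on N")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 non-empty clusters")


def calinski_harabasz(features: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: [BGSS/(K-1)] / [WGSS/(N-K)].

    BGSS = sum_k n_k ||c_k - c̄||² (between-cluster sum of squares about
    the grand mean), WGSS = sum_k sum_{x in k} ||x - c_k||².  Higher is
    better: compact, well-separated clusters.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _check_partition(features, labels)
    n = features.shape[0]
    uniq, groups = _split_by_label(features, labels)
    k = uniq.size
    if n <= k:
        raise ValueError("need N > K for the Calinski-Harabasz index")
    grand = features.mean(axis=0)
    bgss = sum(g.shape[0] * float(np.sum((g.mean(axis=0) - grand) ** 2)) for g in groups)
    wgss = sum(float(np.sum((g - g.mean(axis=0)) ** 2)) for g in groups)
    if wgss == 0.0:
        raise ValueError("within-cluster sum of squares is zero; CH undefined")
    return (bgss / (k - 1)) / (wgss / (n - k))


def ch_pairwise_centroid(features: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise-centroid variant of Calinski-Harabasz.

    Numerator sum_k sum_{j != k} n_k d²(c_j, c_k) / (K-1) instead of the
    standard BGSS about the grand mean; denominator as in
    :func:`calinski_harabasz`.  Provided for completeness; the standard
    form is the default everywhere else in the package.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _check_partition(features, labels)
    n = features.shape[0]
    uniq, groups = _split_by_label(features, labels)
    k = uniq.size
    if n <= k:
        raise ValueError("need N > K")
    centroids = np.array([g.mean(axis=0) for g in groups])
    sizes = np.array([g.shape[0] for g in groups], dtype=float)
    d2 = np.sum((centroids[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
    num = float(np.sum(sizes[:, None] * d2) - np.sum(sizes * np.diag(d2)))
    wgss = sum(float(np.sum((g - g.mean(axis=0)) ** 2)) for g in groups)
    if wgss == 0.0:
        raise ValueError("within-cluster sum of squares is zero")
    return (num / (k - 1)) / (wgss / (n - k))


def s_dbw(features: np.ndarray, labels: np.ndarray) -> float:
    """S_Dbw index: Scat(K) + Dens_bw(K); lower is better.

    Scat(K) = (1/K) sum_k ||sigma(C_k)|| / ||sigma(D)|| measures mean
    intra-cluster variance relative to the dataset variance, where
    sigma(.) is the per-dimension (population) variance vector.

    Dens_bw(K) averages, over ordered cluster pairs (k, j), the number of
    points of C_k ∪ C_j within a threshold distance of the midpoint
    between the two centres, relative to the larger of the densities at
    the two centres themselves.  The threshold is the mean cluster
    variance norm (1/K) sum_k ||sigma(C_k)||.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _check_partition(features, labels)
    uniq, groups = _split_by_label(features, labels)
    k = uniq.size
    sigma_d = float(np.linalg.norm(features.var(axis=0)))
    if sigma_d == 0.0:
        raise ValueError("zero dataset variance; S_Dbw undefined")
    sigma_norms = np.array([float(np.linalg.norm(g.var(axis=0))) for g in groups])
    scat = float(np.mean(sigma_norms / sigma_d))

    threshold = float(np.mean(sigma_norms))
    centroids = [g.mean(axis=0) for g in groups]

    def n_within(points: np.ndarray, centre: np.ndarray) -> int:
        d = np.linalg.norm(points - centre, axis=1)
        return int(np.sum(d <= threshold))

    dens = 0.0
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            union = np.vstack([groups[a], groups[b]])
            mid = 0.5 * (centroids[a] + centroids[b])
            numer = n_within(union, mid)
            denom = max(n_within(groups[a], centroids[a]), n_within(groups[b], centroids[b]))
            if denom == 0:
                # degenerate: no point within threshold of either centre
                dens += float(numer)
            else:
                dens += numer / denom
    dens_bw = dens / (k * (k - 1))
    return scat + dens_bw


@dataclass(frozen=True)
class CiviSpec:
    """Named validation index plus the direction in which it improves."""

    name: str
    direction: Direction

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise KeyError(
                f"unknown validation index {self.name!r}; registered: {sorted(_REGISTRY)}"
            )
        if self.direction not in ("maximise", "minimise"):
            raise ValueError("direction must be 'maximise' or 'minimise'")


_REGISTRY: dict[str, tuple[Callable[[np.ndarray, np.ndarray], float], Direction]] = {}


def register_index(
    name: str, func: Callable[[np.ndarray, np.ndarray], float], direction: Direction
) -> None:
    """Register a validation index under ``name`` with its direction."""
    if direction not in ("maximise", "minimise"):
        raise ValueError("direction must be 'maximise' or 'minimise'")
    _REGISTRY[name] = (func, direction)


def get_index(name: str) -> CiviSpec:
    """Spec for a registered index, with its canonical direction."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown validation index {name!r}; registered: {sorted(_REGISTRY)}")
    return CiviSpec(name, _REGISTRY[name][1])


def _sklearn_silhouette(features, labels):
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(features, labels))


def _sklearn_davies_bouldin(features, labels):
    from sklearn.metrics import davies_bouldin_score

    return float(davies_bouldin_score(features, labels))


register_index("calinski_harabasz", calinski_harabasz, "maximise")
register_index("ch_pairwise_centroid", ch_pairwise_centroid, "maximise")
register_index("s_dbw", s_dbw, "minimise")
register_index("silhouette", _sklearn_silhouette, "maximise")
register_index("davies_bouldin", _sklearn_davies_bouldin, "minimise")


def compute_civi(spec: CiviSpec, features: np.ndarray, alloc: AllocationMatrix) -> float:
    """Score one model's allocation with the named index.

    Soft allocations are crisp-projected first (each point to its
    highest-probability cluster), so indices defined on partitions apply
    uniformly to hard and soft models.
    """
    if spec.name not in _REGISTRY:
        raise KeyError(f"unknown validation index {spec.name!r}")
    func, _ = _REGISTRY[spec.name]
    labels = crisp_projection(alloc).hard_labels()
    return float(func(np.asarray(features, dtype=float), labels))


@dataclass(frozen=True)
class ModelWeights:
    """Raw CIVI scores and the normalised weights derived from them.

    With equal model priors the normalised weight of a model is its
    approximate posterior model probability.
    """

    model_ids: tuple[str, ...]
    raw_scores: np.ndarray
    normalised: np.ndarray
    index: str = ""
    direction: Direction = "maximise"

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_scores, dtype=float)
        norm = np.asarray(self.normalised, dtype=float)
        if len(self.model_ids) != raw.size or raw.size != norm.size:
            raise ValueError("model_ids, raw_scores and normalised must align")
        if abs(norm.sum() - 1.0) > 1e-10:
            raise ValueError("normalised weights must sum to 1")
        if norm.min() < 0:
            raise ValueError("normalised weights must be non-negative")
        object.__setattr__(self, "model_ids", tuple(self.model_ids))
        object.__setattr__(self, "raw_scores", raw)
        object.__setattr__(self, "normalised", norm)

    def as_dict(self) -> dict:
        return {
            mid: {
                "raw": float(r),
                "normalised": float(w),
                "index": self.index,
                "direction": self.direction,
            }
            for mid, r, w in zip(self.model_ids, self.raw_scores, self.normalised)
        }


def normalise_weights(
    raw, direction: Direction, model_ids=None, index: str = ""
) -> ModelWeights:
    """Normalised model weights from raw CIVI scores.

    maximise: w_m = W_m / sum(W);  minimise: w_m = (1/W_m) / sum(1/W).
    Either way the weights sum to 1 and, under equal priors, approximate
    posterior model probabilities.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw scores must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw scores must be finite")
    if model_ids is None:
        model_ids = tuple(f"model_{i + 1}" for i in range(raw.size))
    if direction == "maximise":
        if np.any(raw < 0):
            raise ValueError("negative raw score under maximise; cannot normalise")
        total = raw.sum()
        if total == 0:
            raise ValueError("all raw scores are zero; weights undefined")
        norm = raw / total
    elif direction == "minimise":
        if np.any(raw <= 0):
            raise ValueError("non-positive raw score under minimise; reciprocal undefined")
        inv = 1.0 / raw
        norm = inv / inv.sum()
    else:
        raise ValueError("direction must be 'maximise' or 'minimise'")
    return ModelWeights(tuple(model_ids), raw, norm, index=index, direction=direction)
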