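"""Uniform adapters turning base clustering algorithms into allocation matrices.

The ensemble is agnostic to where its input solutions come from; these
adapters run ten standard algorithms with a fixed cluster count ``k`` and
return every result as an :class:`~clusterbma.core.AllocationMatrix` —
binary rows for hard algorithms, probabilistic rows for the soft ones
(Gaussian mixture, fuzzy c-means).

Backends: scikit-learn and scipy provide hierarchical (average/Ward)
linkage, k-means, spectral clustering, affinity propagation and Gaussian
mixtures.  PAM (k-medoids), fuzzy c-means, a 1 x k self-organising map
and divisive (DIANA-style) clustering are implemented here directly;
the DIANA adapter approximates classical divisive analysis by repeatedly
2-means-splitting the cluster with the largest diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import AffinityPropagation, KMeans, SpectralClustering
from sklearn.mixture import GaussianMixture

from .core import AllocationMatrix, labels_to_allocation

#: Algorithms producing binary allocations.
HARD_ALGORITHMS = (
    "hc_average",
    "hc_ward",
    "diana",
    "kmeans",
    "pam",
    "affinity_propagation",
    "spectral",
    "som",
)
#: Algorithms producing probabilistic allocations.
SOFT_ALGORITHMS = ("gmm", "fuzzy_cmeans")

#: The nine-algorithm benchmark panel (hc_ward is the tenth adapter,
#: used in the case-study-style pipeline rather than the benchmark).
BENCHMARK_PANEL = (
    "hc_average",
    "diana",
    "kmeans",
    "pam",
    "affinity_propagation",
    "spectral",
    "gmm",
    "som",
    "fuzzy_cmeans",
)


@dataclass(frozen=True)
class ClustererSpec:
    """One base-model request: algorithm name, cluster count, seed."""

    algorithm: str
    k: int
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in HARD_ALGORITHMS + SOFT_ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"known: {HARD_ALGORITHMS + SOFT_ALGORITHMS}"
            )
        if self.k < 2:
            raise ValueError("k must be at least 2")


def _hierarchical(features: np.ndarray, k: int, method: str) -> np.ndarray:
    z = linkage(features, method=method)
    return fcluster(z, t=k, criterion="maxclust")


def _kmeans_labels(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    # backend defaults (single k-means++ start), per the panel's
    # default-settings policy
    km = KMeans(n_clusters=k, random_state=seed)
    return km.fit_predict(features) + 1


def _pam(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Partitioning Around Medoids via alternating (Voronoi) iteration.

    Greedy BUILD initialisation on the full distance matrix, then
    alternate point-to-medoid assignment with per-cluster medoid updates
    until the medoid set is stable.
    """
    d = squareform(pdist(features))
    n = d.shape[0]
    # BUILD: first medoid minimises total distance, later ones maximise gain
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[medoids[0]].copy()
    for _ in range(k - 1):
        gain = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        m = int(np.argmax(gain))
        medoids.append(m)
        nearest = np.minimum(nearest, d[m])
    medoids = np.array(medoids)
    for _ in range(100):
        assign = np.argmin(d[medoids], axis=0)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            sub = d[np.ix_(members, members)]
            new_medoids[c] = members[int(np.argmin(sub.sum(axis=1)))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(d[medoids], axis=0) + 1


def _diana(features: np.ndarray, k: int) -> np.ndarray:
    """Divisive clustering: split the widest cluster with 2-means until k."""
    n = features.shape[0]
    labels = np.ones(n, dtype=int)
    while labels.max() < k:
        diameters = {}
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if members.size < 2:
                diameters[c] = 0.0
                continue
            diameters[c] = float(pdist(features[members]).max())
        target = max(diameters, key=diameters.get)
        members = np.flatnonzero(labels == target)
        if members.size < 2:
            warnings.warn("cannot split a singleton cluster further", RuntimeWarning)
            break
        split = KMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(
            features[members]
        )
        labels[members[split == 1]] = labels.max() + 1
    return labels


def _affinity_propagation(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Affinity propagation agglomerated down to k clusters.

    AP chooses its own number of exemplars; the exemplar centres are then
    merged by average-linkage hierarchical clustering into k groups.
    """
    ap = AffinityPropagation(damping=0.9, max_iter=200, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap_labels = ap.fit_predict(features)
    centres = ap.cluster_centers_
    if centres is None or len(centres) == 0 or np.any(ap_labels < 0):
        warnings.warn("affinity propagation failed to converge; falling back to k-means",
                      RuntimeWarning)
        return _kmeans_labels(features, k, seed)
    n_exemplars = centres.shape[0]
    if n_exemplars <= k:
        if n_exemplars < k:
            warnings.warn(
                f"affinity propagation produced {n_exemplars} < k={k} exemplars",
                RuntimeWarning,
            )
        return ap_labels + 1
    z = linkage(centres, method="average")
    merged = fcluster(z, t=k, criterion="maxclust")
    return merged[ap_labels]


def _spectral(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    sc = SpectralClustering(
        n_clusters=k,
        affinity="nearest_neighbors",
        n_neighbors=10,
        assign_labels="kmeans",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sc.fit_predict(features) + 1


def _gmm(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    gm = GaussianMixture(n_components=k, covariance_type="full", random_state=seed)
    gm.fit(features)
    return gm.predict_proba(features)


def _som(features: np.ndarray, k: int, seed: int, n_epochs: int = 30) -> np.ndarray:
    """Batch self-organising map on a 1 x k grid; one node per cluster.

    Nodes are initialised along the first principal axis and trained with
    a Gaussian neighbourhood whose radius shrinks from k/2 to 0.3 over
    the epochs; each point is then assigned to its best-matching node.
    """
    x = np.asarray(features, dtype=float)
    mean = x.mean(axis=0)
    centred = x - mean
    # deterministic principal-axis initialisation
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    pos = np.linspace(-1.0, 1.0, k)
    scale = np.std(centred @ axis)
    nodes = mean + np.outer(pos * scale, axis)
    grid = np.arange(k, dtype=float)
    for epoch in range(n_epochs):
        radius = (k / 2.0) * (0.3 / (k / 2.0)) ** (epoch / max(n_epochs - 1, 1))
        bmu = np.argmin(cdist(x, nodes), axis=1)
        h = np.exp(-((grid[None, :] - grid[bmu][:, None]) ** 2) / (2.0 * radius**2))
        weight_sum = h.sum(axis=0)
        updated = (h.T @ x) / np.maximum(weight_sum[:, None], 1e-12)
        nodes = np.where(weight_sum[:, None] > 1e-12, updated, nodes)
    bmu = np.argmin(cdist(x, nodes), axis=1)
    if np.unique(bmu).size < k:
        warnings.warn("self-organising map left empty nodes", RuntimeWarning)
    return bmu + 1


def _fuzzy_cmeans(
    features: np.ndarray, k: int, seed: int, m: float = 2.0,
    max_iter: int = 300, tol: float = 1e-5,
) -> np.ndarray:
    """Fuzzy c-means memberships (fuzzifier m=2)."""
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(k), size=n)
    exponent = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        um = u**m
        centres = (um.T @ x) / np.maximum(um.sum(axis=0)[:, None], 1e-12)
        d = np.maximum(cdist(x, centres), 1e-12)
        inv = d ** (-exponent)
        new_u = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    return u


def run_clusterer(spec: ClustererSpec, features: np.ndarray) -> AllocationMatrix:
    """Run one base algorithm and return its allocation matrix.

    Hard algorithms return binary allocations with exactly ``spec.k``
    columns (empty columns permitted, with a warning, when the backend
    cannot populate all k clusters); soft algorithms return membership
    probabilities.  Deterministic given ``spec.seed``.
    """
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    if x.shape[0] <= spec.k:
        raise ValueError("need more observations than clusters")
    alg, k, seed = spec.algorithm, spec.k, spec.seed

    if alg == "hc_average":
        labels = _hierarchical(x, k, "average")
    elif alg == "hc_ward":
        labels = _hierarchical(x, k, "ward")
    elif alg == "diana":
        labels = _diana(x, k)
    elif alg == "kmeans":
        labels = _kmeans_labels(x, k, seed)
    elif alg == "pam":
        labels = _pam(x, k, seed)
    elif alg == "affinity_propagation":
        labels = _affinity_propagation(x, k, seed)
    elif alg == "spectral":
        labels = _spectral(x, k, seed)
    elif alg == "som":
        labels = _som(x, k, seed)
    elif alg == "gmm":
        return AllocationMatrix(_gmm(x, k, seed), model_id=alg)
    elif alg == "fuzzy_cmeans":
        return AllocationMatrix(_fuzzy_cmeans(x, k, seed), model_id=alg)
    else:  # unreachable thanks to ClustererSpec validation
        raise ValueError(f"unknown algorithm {alg!r}")

    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < k:
        warnings.warn(
            f"{alg} produced {np.unique(labels).size} non-empty clusters (k={k})",
            RuntimeWarning,
        )
    return labels_to_allocation(labels, k, model_id=alg)
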