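"""Labelled Gaussian cluster generator with a controllable separation index.

Cluster separation is parameterised by a quantile-based projection index
in (-1, 1): project two clusters onto the direction that best separates
them and compare the gap between the clusters' outer alpha/2 quantiles
with the span they jointly cover,

    J = (q_L(B) - q_U(A)) / (q_U(B) - q_L(A)),

where A is the cluster with the smaller projected mean and q_L, q_U are
the alpha/2 and 1-alpha/2 sample quantiles of the projections.  J near 1
means a wide empty gap; negative J means the alpha-trimmed supports
overlap.

The generator plants spherical unit-variance Gaussian clusters at the
vertices of a regular simplex (all pairwise separations equal) scaled so
the theoretical index between any pair equals the requested ``sep_val``.
For unit-variance 1-D projections the index has the closed form
J = (delta - 2z) / (delta + 2z) with z the normal 1-alpha/2 quantile, so
the required centre distance is delta = 2z (1 + J) / (1 - J).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import LabeledDataset

#: Default quantile level of the separation index.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SimSpec:
    """Generation settings: K clusters x points_per_cluster in n_dims."""

    n_clusters: int
    points_per_cluster: int
    n_dims: int
    sep_val: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if self.points_per_cluster < 1:
            raise ValueError("points_per_cluster must be at least 1")
        if self.n_dims < 1:
            raise ValueError("n_dims must be at least 1")
        if not (-1.0 < self.sep_val < 1.0):
            raise ValueError("sep_val must lie in (-1, 1)")


def delta_for_separation(sep_val: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Centre distance giving theoretical index ``sep_val`` for unit-variance pairs."""
    if not (-1.0 < sep_val < 1.0):
        raise ValueError("sep_val must lie in (-1, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return 2.0 * z * (1.0 + sep_val) / (1.0 - sep_val)


def separation_for_delta(delta: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Inverse of :func:`delta_for_separation`."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return (delta - 2.0 * z) / (delta + 2.0 * z)


def _best_direction(a: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    """Direction maximising the normal-theory separation index.

    Uses sample moments: maximise (d.w - z(s_a + s_b)) / (d.w + z(s_a + s_b))
    with s = sqrt(w' Sigma w).  The mean-difference direction (exact
    optimum for equal spherical covariances) seeds a quasi-Newton polish
    that handles unequal covariances.
    """
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    d = mean_b - mean_a
    if np.linalg.norm(d) < 1e-12:
        d = np.ones_like(d)
    cov_a = np.atleast_2d(np.cov(a, rowvar=False))
    cov_b = np.atleast_2d(np.cov(b, rowvar=False))

    def neg_index(w: np.ndarray) -> float:
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            return 1.0
        w = w / nw
        gap = float(np.dot(mean_b - mean_a, w))
        spread = z * (
            np.sqrt(max(float(w @ cov_a @ w), 1e-300))
            + np.sqrt(max(float(w @ cov_b @ w), 1e-300))
        )
        return -(abs(gap) - spread) / (abs(gap) + spread)

    w0 = d / np.linalg.norm(d)
    res = optimize.minimize(neg_index, w0, method="Nelder-Mead" if d.size <= 2 else "BFGS")
    w = res.x if res.success and neg_index(res.x) <= neg_index(w0) else w0
    return w / np.linalg.norm(w)


def separation_index(
    features_a: np.ndarray, features_b: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> float:
    """Empirical quantile separation index between two clusters.

    Symmetric in its arguments; in (-1, 1).  Positive values indicate a
    gap between the alpha-trimmed projected supports, negative values
    overlap.
    """
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5)")
    a = np.atleast_2d(np.asarray(features_a, dtype=float))
    b = np.atleast_2d(np.asarray(features_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both clusters must be non-empty")
    w = _best_direction(a, b, alpha)
    pa, pb = a @ w, b @ w
    if pa.mean() > pb.mean():  # orient so b sits to the right
        pa, pb = pb, pa
    lo, hi = alpha / 2.0, 1.0 - alpha / 2.0
    qla, qua = np.quantile(pa, [lo, hi])
    qlb, qub = np.quantile(pb, [lo, hi])
    span = qub - qla
    if span <= 1e-12:
        raise ValueError("degenerate projection: clusters have no spread")
    return float((qlb - qua) / span)


def _simplex_vertices(k: int) -> np.ndarray:
    """k points in (k-1) dims, unit pairwise distance, centred at the origin."""
    m = np.eye(k) - 1.0 / k
    u, s, _ = np.linalg.svd(m)
    coords = u[:, : k - 1] * s[: k - 1]  # pairwise distance sqrt(2)
    return coords / np.sqrt(2.0)


def generate_clusters(spec: SimSpec, alpha: float = DEFAULT_ALPHA) -> LabeledDataset:
    """Sample spherical unit-variance Gaussian clusters at separation ``sep_val``.

    Centres sit at the vertices of a regular simplex embedded in the
    first ``n_clusters - 1`` coordinates, scaled so the theoretical
    pairwise separation index equals ``sep_val``; the remaining
    dimensions carry pure noise.  Reproducible given ``spec.seed``.
    """
    k = spec.n_clusters
    if spec.n_dims < k - 1:
        raise ValueError(
            f"n_dims={spec.n_dims} too small to embed a {k}-cluster simplex "
            f"(needs at least {k - 1})"
        )
    delta = delta_for_separation(spec.sep_val, alpha)
    vertices = _simplex_vertices(k) * delta
    centres = np.zeros((k, spec.n_dims))
    centres[:, : k - 1] = vertices

    rng = np.random.default_rng(spec.seed)
    n_pc = spec.points_per_cluster
    features = np.empty((k * n_pc, spec.n_dims))
    labels = np.empty(k * n_pc, dtype=int)
    for c in range(k):
        block = slice(c * n_pc, (c + 1) * n_pc)
        features[block] = centres[c] + rng.standard_normal((n_pc, spec.n_dims))
        labels[block] = c + 1
    return LabeledDataset(
        features=features,
        labels=labels,
        separation=spec.sep_val,
        sizes=(n_pc,) * k,
        meta={
            "n_clusters": k,
            "points_per_cluster": n_pc,
            "n_dims": spec.n_dims,
            "sep_val": spec.sep_val,
            "seed": spec.seed,
            "alpha": alpha,
            "centre_distance": delta,
        },
    )
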