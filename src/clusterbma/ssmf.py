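"""Symmetric simplex matrix factorisation (SSMF) of the consensus matrix.

The consensus matrix C is factorised as C ~ A A^T where the rows of the
N x K_BMA matrix A lie on the probability simplex, so A is directly a
matrix of probabilistic cluster allocations.  The solver minimises the
off-diagonal squared residual

    F(A) = sum_{i != j} (C_ij - (A A^T)_ij)^2 + lambda * sum_i (1 - ||a_i||^2)

    F(A) = sum_{i != j} (C_ij - (A A^T)_ij)^2 + lambda * ||A||_F^2

by projected gradient descent with an adaptive step size and Euclidean
projection of every row onto the simplex after each step.  The diagonal
of C is excluded from the fit because it is 1 by construction and carries
no co-assignment information.

Redundant clusters empty because exactly fitting a consensus with fewer
than K_BMA blocks requires co-clustered rows to share a single simplex
vertex: splitting a block across two columns breaks the within-block
residual, so surplus columns drain to (near) zero mass and are pruned
afterwards.  Per-point allocation uncertainty is 1 minus the row maximum
of A: the probability that the hardened allocation is not the point's
true cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .civi import ModelWeights
from .core import AllocationMatrix, SimilarityMatrix


@dataclass(frozen=True)
class SsmfConfig:
    """Solver settings for the factorisation.

    ``k_bma`` is the target number of averaged clusters; ``l2_lambda``
    the strength of the L2 regulariser; ``n_restarts``
    random initialisations are screened for ``pilot_iters`` iterations
    and the best is run to convergence.
    """

    k_bma: int
    max_iter: int = 5000
    step_size: float = 1e-3
    l2_lambda: float = 0.01
    tol: float = 1e-8
    seed: int = 0
    n_restarts: int = 5
    pilot_iters: int = 50
    mass_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.k_bma < 2:
            raise ValueError("k_bma must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")
        if not (0.0 <= self.mass_threshold < 1.0):
            raise ValueError("mass_threshold must lie in [0, 1)")


@dataclass(frozen=True)
class SsmfFit:
    """Converged factorisation plus solver diagnostics."""

    allocation: AllocationMatrix
    objective_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


@dataclass(frozen=True)
class EnsembleResult:
    """Full output bundle of the averaging pipeline."""

    allocations: AllocationMatrix
    uncertainty: np.ndarray
    weights: ModelWeights
    consensus: SimilarityMatrix
    surviving_clusters: int
    objective_trace: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        u = np.asarray(self.uncertainty, dtype=float)
        expected = 1.0 - self.allocations.values.max(axis=1)
        if u.shape != (self.allocations.n_points,) or np.max(np.abs(u - expected)) > 1e-10:
            raise ValueError("uncertainty must equal 1 - max allocation probability")
        if self.surviving_clusters > self.allocations.n_clusters:
            raise ValueError("surviving_clusters cannot exceed allocated columns")
        object.__setattr__(self, "uncertainty", u)

    def hard_labels(self) -> np.ndarray:
        return self.allocations.hard_labels()


def project_rows_to_simplex(a: np.ndarray) -> np.ndarray:
    """Euclidean projection of every row onto the probability simplex."""
    n, k = a.shape
    srt = np.sort(a, axis=1)[:, ::-1]
    css = np.cumsum(srt, axis=1) - 1.0
    idx = np.arange(1, k + 1)
    cond = srt - css / idx > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last True per row
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(a - theta[:, None], 0.0)


def _objective_terms(c: np.ndarray, c2_offdiag: float, a: np.ndarray, lam: float):
    """Objective and gradient sharing the single O(N^2 K) product C @ A."""
    p = c @ a
    g = a.T @ a
    r = np.einsum("ij,ij->i", a, a)
    # ||C - AA^T||_F^2 restricted to off-diagonal entries:
    #   ||C||^2 - 2<C, AA^T> + ||A^T A||^2  minus the diagonal part
    cross = float(np.einsum("ij,ij->", p, a))
    quad = float(np.sum(g * g))
    # diagonal of C@A includes C_ii * a_i = a_i; <C,AA^T> over diagonal = sum r_i
    data = c2_offdiag + 2.0 * float(r.sum()) - 2.0 * cross + quad - float(np.sum(r * r))
    obj = data + lam * float(r.sum())
    grad = 4.0 * (a @ g - p) + 4.0 * (1.0 - r)[:, None] * a + 2.0 * lam * a
    return obj, grad


def _objective_only(c: np.ndarray, c2_offdiag: float, a: np.ndarray, lam: float) -> float:
    p = c @ a
    g = a.T @ a
    r = np.einsum("ij,ij->i", a, a)
    cross = float(np.einsum("ij,ij->", p, a))
    quad = float(np.sum(g * g))
    data = c2_offdiag + 2.0 * float(r.sum()) - 2.0 * cross + quad - float(np.sum(r * r))
    return data + lam * float(r.sum())


def _descend(
    c: np.ndarray,
    c2_offdiag: float,
    a: np.ndarray,
    lam: float,
    step: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[float], bool, float]:
    """Monotone projected gradient descent from ``a``; returns best iterate."""
    obj, grad = _objective_terms(c, c2_offdiag, a, lam)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        decreased = False
        for _bt in range(40):
            cand = project_rows_to_simplex(a - step * grad)
            cand_obj = _objective_only(c, c2_offdiag, cand, lam)
            if cand_obj <= obj:
                decreased = True
                break
            step *= 0.5
        if not decreased or not np.isfinite(cand_obj):
            converged = True  # no descent direction at machine precision
            break
        rel = (obj - cand_obj) / max(abs(obj), 1e-12)
        a, obj = cand, cand_obj
        trace.append(obj)
        _, grad = _objective_terms(c, c2_offdiag, a, lam)
        step *= 1.6  # try a longer step next round
        if rel < tol:
            converged = True
            break
    return a, trace, converged, step


def factorise(consensus: SimilarityMatrix, config: SsmfConfig) -> SsmfFit:
    """Factorise a consensus matrix into simplex-row allocations.

    ``n_restarts`` Dirichlet(1) initialisations are each descended for
    ``pilot_iters`` iterations; the one with the lowest objective is then
    run to convergence (relative objective change below ``tol`` or
    ``max_iter`` iterations).  Deterministic given ``config.seed``.
    """
    c = consensus.values
    n = consensus.n_points
    if config.k_bma > n:
        raise ValueError("k_bma cannot exceed the number of observations")
    c2_offdiag = float(np.sum(c * c)) - float(np.sum(np.diag(c) ** 2))
    rng = np.random.default_rng(config.seed)
    lam = config.l2_lambda

    starts = [
        rng.dirichlet(np.ones(config.k_bma), size=n) for _ in range(config.n_restarts)
    ]
    if config.n_restarts == 1:
        best_a, pilot_trace, step = starts[0], [], config.step_size
    else:
        pilot_budget = min(config.pilot_iters, config.max_iter)
        best_a, pilot_trace, step, best_obj = None, [], config.step_size, np.inf
        for a0 in starts:
            a, tr, _, stp = _descend(
                c, c2_offdiag, a0, lam, config.step_size, pilot_budget, config.tol
            )
            if tr[-1] < best_obj:
                best_obj, best_a, pilot_trace, step = tr[-1], a, tr, stp

    a, tail, converged, _ = _descend(
        c, c2_offdiag, best_a, lam, step, config.max_iter, config.tol
    )
    trace = np.asarray(pilot_trace + tail[1:] if pilot_trace else tail)
    if not converged:
        warnings.warn(
            f"SSMF did not reach tol={config.tol:g} within max_iter={config.max_iter}; "
            "returning the best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    alloc = AllocationMatrix(a, model_id="clusterBMA")
    return SsmfFit(alloc, trace, converged, n_iter=len(trace) - 1)


def ssmf_factorise(consensus: SimilarityMatrix, config: SsmfConfig) -> AllocationMatrix:
    """Allocation matrix from :func:`factorise` (diagnostics dropped)."""
    return factorise(consensus, config).allocation


def prune_empty_clusters(
    alloc: AllocationMatrix, mass_threshold: float = 0.01
) -> AllocationMatrix:
    """Drop columns whose total mass is at most ``mass_threshold * N``.

    The regulariser empties redundant columns rather than deleting them;
    this removes those near-zero columns and renormalises the rows.  The
    surviving cluster count is the returned matrix's ``n_clusters``.
    """
    if not (0.0 <= mass_threshold < 1.0):
        raise ValueError("mass_threshold must lie in [0, 1)")
    values = alloc.values
    col_mass = values.sum(axis=0)
    keep = col_mass > mass_threshold * alloc.n_points
    if not np.any(keep):
        raise ValueError("all columns fall below the mass threshold")
    if np.all(keep):
        return alloc
    kept = values[:, keep]
    row_sums = kept.sum(axis=1, keepdims=True)
    # a row can lose (almost) all mass only in pathological inputs
    degenerate = row_sums[:, 0] < 1e-12
    if np.any(degenerate):
        kept[degenerate] = 1.0 / kept.shape[1]
        row_sums = kept.sum(axis=1, keepdims=True)
    return AllocationMatrix(kept / row_sums, model_id=alloc.model_id)


def allocation_uncertainty(alloc: AllocationMatrix) -> np.ndarray:
    """Per-point uncertainty 1 - max_k A_ik, in [0, 1 - 1/K]."""
    return 1.0 - alloc.values.max(axis=1)


def choose_k_bma(input_ks, strategy: str = "max_k", increment: int = 1) -> int:
    """Heuristic choice of the averaged cluster count K_BMA.

    ``max_k`` takes the largest K among the input models; ``max_k_plus``
    adds ``increment`` on top, leaving room for sub-cluster structure
    that differs across models (the regulariser empties unused columns).
    """
    ks = list(input_ks)
    if not ks:
        raise ValueError("need at least one input K")
    if strategy == "max_k":
        return int(max(ks))
    if strategy == "max_k_plus":
        return int(max(ks)) + int(increment)
    raise ValueError(f"unknown strategy {strategy!r}")
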