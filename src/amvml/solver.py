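"""Adaptive multi-view multi-label learning (AMVML).

The model jointly learns

* a row-stochastic disease affinity graph ``SD`` (q x q) as a consensus of m
  disease similarity views,
* a row-stochastic miRNA affinity graph ``SM`` (p x p) as a consensus of n
  miRNA similarity views, and
* a real-valued prediction matrix ``F`` (q x p) that propagates the known
  binary associations ``Y`` over both graphs,

by minimizing

    Omega(SD, SM, F) =  sum_v wD_v ||SD - AD_v||_F^2 + 2a Tr(F' L_SD F)
                      + sum_u wM_u ||SM - AM_u||_F^2 + 2b Tr(F L_SM F')
                      + ||F - Y||_F^2

subject to every row of SD and SM lying on the probability simplex, where
``L_S = D_S - (S' + S)/2`` is the (symmetric, PSD) graph Laplacian of an
affinity matrix S.  View weights are not free parameters: they are set
inversely proportional to each view's Frobenius distance from the learned
consensus (self-conducted weight learning), so unreliable views are
down-weighted automatically.

The optimization alternates exact coordinate minimizers — a per-row Euclidean
projection onto the simplex for SD and SM, and a Sylvester equation for F —
so the objective decreases monotonically within each inner loop; the outer
loop re-estimates the view weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_sylvester
from scipy.spatial.distance import cdist

from .containers import AssociationMatrix, SimilarityView
from .errors import NumericalError

__all__ = [
    "AMVMLConfig",
    "AMVMLState",
    "laplacian",
    "simplex_project",
    "project_rows_to_simplex",
    "update_SD",
    "update_SM",
    "update_F",
    "update_weights",
    "objective",
    "fit_amvml",
]

WEIGHT_EPS = 1e-10  # guard when a learned graph coincides with a view


@dataclass(frozen=True)
class AMVMLConfig:
    """Hyper-parameters and stopping rules of the solver.

    ``alpha`` and ``beta`` trade the label-consistency (graph-regularization)
    terms against the view-fitting and label-fitting terms; both default to
    1e-4, the best-performing setting in cross-validation.  The inner loop
    alternates the SD/SM/F updates until the relative objective change drops
    below ``inner_tol``; the outer loop re-estimates view weights until the
    largest relative weight change drops below ``outer_tol``.
    """

    alpha: float = 1e-4
    beta: float = 1e-4
    inner_tol: float = 1e-6
    outer_tol: float = 1e-4
    max_inner: int = 50
    max_outer: int = 10
    normalized_laplacian: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.inner_tol <= 0 or self.outer_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_inner < 1 or self.max_outer < 1:
            raise ValueError("iteration caps must be at least 1")


@dataclass
class AMVMLState:
    """Result of a fit: learned affinities, predictions, weights and trace.

    ``objective_trace`` holds one list of objective values per outer
    iteration (one value per inner iteration); within each list the values
    are non-increasing.
    """

    SD: np.ndarray
    SM: np.ndarray
    F: np.ndarray
    wD: np.ndarray
    wM: np.ndarray
    objective_trace: list[list[float]] = field(default_factory=list)
    converged: bool = False

    @property
    def flat_trace(self) -> list[float]:
        return [v for block in self.objective_trace for v in block]


def laplacian(S: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Graph Laplacian ``L = D - (S' + S)/2`` of a (possibly asymmetric) affinity.

    ``D`` is diagonal with ``D_ii = sum_j (S_ij + S_ji)/2``, so ``L`` is
    symmetric with zero row sums and positive semi-definite for non-negative
    S.  With ``normalized=True`` the symmetric normalization
    ``D^-1/2 L D^-1/2`` is returned (isolated nodes kept at zero).
    """
    S = np.asarray(S, dtype=float)
    W = 0.5 * (S + S.T)
    d = W.sum(axis=1)
    L = np.diag(d) - W
    if normalized:
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        L = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    return L


def simplex_project(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex.

    Exact O(k log k) sorting algorithm for
    ``argmin { ||x - v||^2 : x >= 0, sum(x) = 1 }``.
    """
    v = np.asarray(v, dtype=float)
    return project_rows_to_simplex(v[None, :])[0]


def project_rows_to_simplex(M: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto the probability simplex."""
    M = np.asarray(M, dtype=float)
    n_rows, k = M.shape
    u = -np.sort(-M, axis=1)  # descending
    css = np.cumsum(u, axis=1)
    idx = np.arange(1, k + 1)
    cond = u * idx > (css - 1.0)
    # rho: last index (0-based) where the condition holds; it holds at 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = (css[np.arange(n_rows), rho] - 1.0) / (rho + 1.0)
    return np.maximum(M - theta[:, None], 0.0)


def _weighted_view_sum(views: Sequence[SimilarityView], w: np.ndarray) -> np.ndarray:
    if len(views) != len(w):
        raise ValueError(f"{len(views)} views but {len(w)} weights")
    shapes = {v.matrix.shape for v in views}
    if len(shapes) != 1:
        raise ValueError(f"views have mismatched shapes: {shapes}")
    out = np.zeros(views[0].matrix.shape)
    for wv, view in zip(w, views):
        out += wv * view.matrix
    return out


def update_SD(
    views_D: Sequence[SimilarityView],
    wD: np.ndarray,
    F: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Closed-form update of the disease affinity graph.

    Row i of SD is the simplex projection of the weighted view average
    shifted by the label-consistency penalty:
    ``(sum_v wD_v AD_v[i] - (alpha/2) z_i) / sum_v wD_v`` with
    ``z_ij = ||F_i - F_j||^2`` over rows of F (disease profiles).
    """
    wD = np.asarray(wD, dtype=float)
    acc = _weighted_view_sum(views_D, wD)
    if acc.shape[0] != F.shape[0]:
        raise ValueError(
            f"disease views are {acc.shape[0]}x{acc.shape[0]} but F has {F.shape[0]} rows"
        )
    wsum = wD.sum()
    target = acc
    if alpha != 0:
        Z = cdist(F, F, "sqeuclidean")
        target = acc - 0.5 * alpha * Z
    return project_rows_to_simplex(target / wsum)


def update_SM(
    views_M: Sequence[SimilarityView],
    wM: np.ndarray,
    F: np.ndarray,
    beta: float,
) -> np.ndarray:
    """Closed-form update of the miRNA affinity graph.

    The miRNA problem is the exact transpose of the disease problem: profiles
    are the *columns* of F.
    """
    return update_SD(views_M, wM, np.asarray(F).T, beta)


def update_F(
    SD: np.ndarray,
    SM: np.ndarray,
    Y: np.ndarray,
    alpha: float,
    beta: float,
    *,
    normalized_laplacian: bool = False,
) -> np.ndarray:
    """Solve the Sylvester equation ``(alpha L_SD + I) F + F (beta L_SM) = Y``.

    The left Laplacian couples diseases (rows of F), the right one miRNAs
    (columns).  The solution is unique because ``alpha L_SD + I`` is positive
    definite and ``beta L_SM`` positive semi-definite, so no eigenvalue sum
    vanishes.  With ``alpha == beta == 0`` the equation reduces to ``F = Y``
    and Y is returned exactly.
    """
    SD = np.asarray(SD, dtype=float)
    SM = np.asarray(SM, dtype=float)
    Y = np.asarray(Y, dtype=float)
    q, p = Y.shape
    if SD.shape != (q, q) or SM.shape != (p, p):
        raise ValueError(
            f"shape mismatch: Y is {q}x{p}, SD {SD.shape}, SM {SM.shape}"
        )
    if alpha == 0 and beta == 0:
        return Y.copy()
    A = alpha * laplacian(SD, normalized_laplacian) + np.eye(q)
    B = beta * laplacian(SM, normalized_laplacian)
    return solve_sylvester(A, B, Y)


def update_weights(S: np.ndarray, views: Sequence[SimilarityView]) -> np.ndarray:
    """Self-conducted view weights: ``w_v = 1 / (2 ||S - A_v||_F)``.

    Views closer to the learned consensus receive larger weight; a small
    guard keeps the weight finite when a view coincides with the consensus.
    """
    S = np.asarray(S, dtype=float)
    dists = np.array([np.linalg.norm(S - v.matrix) for v in views])
    return 1.0 / (2.0 * np.maximum(dists, WEIGHT_EPS))


def objective(
    SD: np.ndarray,
    SM: np.ndarray,
    F: np.ndarray,
    Y: np.ndarray,
    views_D: Sequence[SimilarityView],
    views_M: Sequence[SimilarityView],
    wD: np.ndarray,
    wM: np.ndarray,
    alpha: float,
    beta: float,
    *,
    normalized_laplacian: bool = False,
) -> float:
    """Value of the AMVML objective Omega at the given point."""
    Y = np.asarray(Y, dtype=float)
    val = float(np.linalg.norm(F - Y) ** 2)
    for w, view in zip(np.asarray(wD, dtype=float), views_D):
        val += w * np.linalg.norm(SD - view.matrix) ** 2
    for w, view in zip(np.asarray(wM, dtype=float), views_M):
        val += w * np.linalg.norm(SM - view.matrix) ** 2
    L_SD = laplacian(SD, normalized_laplacian)
    L_SM = laplacian(SM, normalized_laplacian)
    val += 2.0 * alpha * float(np.sum(F * (L_SD @ F)))
    val += 2.0 * beta * float(np.sum(F * (F @ L_SM)))
    return val


def _check_finite(name: str, arr: np.ndarray, outer: int, inner: int) -> None:
    if not np.isfinite(arr).all():
        raise NumericalError(
            f"non-finite values in {name} at outer iteration {outer}, "
            f"inner iteration {inner}"
        )


def fit_amvml(
    views_D: Sequence[SimilarityView],
    views_M: Sequence[SimilarityView],
    Y: AssociationMatrix | np.ndarray,
    config: AMVMLConfig = AMVMLConfig(),
) -> AMVMLState:
    """Run the full alternating optimization and return the learned state.

    View weights start uniform (1/m and 1/n) and F starts at Y.  Each inner
    iteration updates SD, then SM, then F with their exact coordinate
    minimizers (F solves the Sylvester equation of the objective's
    first-order condition, ``(2 alpha L_SD + I) F + F (2 beta L_SM) = Y``),
    so the recorded objective values are non-increasing within every inner
    loop.  After inner convergence the view weights are re-estimated; the
    procedure stops when they stabilize.
    """
    if isinstance(Y, AssociationMatrix):
        Ymat = Y.matrix.astype(float)
    else:
        Ymat = np.asarray(Y, dtype=float)
    if not views_D or not views_M:
        raise ValueError("need at least one similarity view per space")
    q, p = Ymat.shape
    for v in views_D:
        if v.matrix.shape != (q, q):
            raise ValueError(f"disease view {v.name!r} is {v.matrix.shape}, expected {(q, q)}")
    for v in views_M:
        if v.matrix.shape != (p, p):
            raise ValueError(f"miRNA view {v.name!r} is {v.matrix.shape}, expected {(p, p)}")

    m, n = len(views_D), len(views_M)
    wD = np.full(m, 1.0 / m)
    wM = np.full(n, 1.0 / n)
    F = Ymat.copy()
    SD = SM = None
    trace: list[list[float]] = []
    converged = False

    for outer in range(config.max_outer):
        block: list[float] = []
        prev = None
        for inner in range(config.max_inner):
            SD = update_SD(views_D, wD, F, config.alpha)
            SM = update_SM(views_M, wM, F, config.beta)
            # factor 2: the objective carries 2*alpha and 2*beta on its
            # graph-regularization terms, so the exact F-minimizer doubles
            # the coefficients in the Sylvester equation
            F = update_F(
                SD,
                SM,
                Ymat,
                2.0 * config.alpha,
                2.0 * config.beta,
                normalized_laplacian=config.normalized_laplacian,
            )
            _check_finite("SD", SD, outer, inner)
            _check_finite("SM", SM, outer, inner)
            _check_finite("F", F, outer, inner)
            omega = objective(
                SD, SM, F, Ymat, views_D, views_M, wD, wM,
                config.alpha, config.beta,
                normalized_laplacian=config.normalized_laplacian,
            )
            block.append(omega)
            if prev is not None and abs(prev - omega) / max(prev, 1e-12) < config.inner_tol:
                break
            prev = omega
        trace.append(block)
        new_wD = update_weights(SD, views_D)
        new_wM = update_weights(SM, views_M)
        rel = max(
            float(np.max(np.abs(new_wD - wD) / np.maximum(wD, WEIGHT_EPS))),
            float(np.max(np.abs(new_wM - wM) / np.maximum(wM, WEIGHT_EPS))),
        )
        wD, wM = new_wD, new_wM
        if rel < config.outer_tol:
            converged = True
            break

    return AMVMLState(
        SD=SD, SM=SM, F=F, wD=wD, wM=wM, objective_trace=trace, converged=converged
    )
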