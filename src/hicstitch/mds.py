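"""Weighted, penalized metric MDS in three dimensions.

The objective minimized is, over unordered pairs ``i < j``::

    sum_{D_ij finite} w_ij * (||x_i - x_j|| - D_ij)**2
        - lambda * sum_{D_ij infinite} ||x_i - x_j||**2

subject to a centered configuration.  The first term is handled by SMACOF
majorization; the concave penalty term is majorized by its tangent plane,
so the combined update keeps the guaranteed monotone descent of SMACOF.
Infinite target distances mark pairs with no observed contacts, which the
penalty pushes apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .distances import make_weights

__all__ = [
    "Configuration3D",
    "MDSConfig",
    "MDSResult",
    "stress_value",
    "solve_mds",
    "classical_mds",
    "default_lambda",
]


@dataclass(frozen=True)
class Configuration3D:
    """An ``n x 3`` coordinate set with per-point bin labels."""

    coords: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        labels = np.asarray(self.labels)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be n x 3")
        if labels.shape != (coords.shape[0],):
            raise ValueError("labels must align with coords rows")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", labels)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def centered(self) -> "Configuration3D":
        return Configuration3D(self.coords - self.coords.mean(axis=0), self.labels)

    def is_centered(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.coords.mean(axis=0)) <= tol))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.coords, columns=["x", "y", "z"])
        frame.insert(0, "label", self.labels)
        return frame


@dataclass(frozen=True)
class MDSConfig:
    """Settings for :func:`solve_mds`.

    ``lambda_`` of ``None`` selects a data-driven default that keeps the
    penalty term small relative to the weighted stress (see
    :func:`default_lambda`).  ``n_restarts`` random initializations are run
    in addition to the primary ``init``; the lowest-stress solution wins,
    ties broken by the lowest restart index.  ``n_restarts=None`` means
    "decide per context": plain :func:`solve_mds` uses 0, while the
    stage-2 positioning step enables restarts for small sampled problems.
    """

    weight_scheme: str = "inverse"
    lambda_: float | None = None
    max_iter: int = 2000
    rel_tol: float = 1e-7
    init: str = "classical"
    seed: int = 0
    n_restarts: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.init not in ("classical", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass(frozen=True)
class MDSResult:
    config: Configuration3D
    stress: float
    n_iter: int
    converged: bool
    stress_history: np.ndarray = field(repr=False, default=None)


def stress_value(
    X: np.ndarray | Configuration3D,
    D: np.ndarray,
    W: np.ndarray,
    lambda_: float = 0.0,
) -> float:
    """Evaluate the weighted, penalized stress criterion over pairs i < j."""
    coords = X.coords if isinstance(X, Configuration3D) else np.asarray(X, float)
    D = np.asarray(D, dtype=float)
    dist = cdist(coords, coords)
    iu = np.triu_indices(D.shape[0], k=1)
    d, target, w = dist[iu], D[iu], np.asarray(W, float)[iu]
    finite = np.isfinite(target)
    fit = float((w[finite] * (d[finite] - target[finite]) ** 2).sum())
    penalty = float((d[~finite] ** 2).sum())
    return fit - lambda_ * penalty


def default_lambda(D: np.ndarray, W: np.ndarray) -> float:
    """Penalty coefficient that cannot dominate the weighted stress.

    ``0.01 * mean(w_ij * D_ij**2)`` over finite off-diagonal pairs, divided
    by ``(#infinite pairs + 1)``.
    """
    D = np.asarray(D, dtype=float)
    iu = np.triu_indices(D.shape[0], k=1)
    target, w = D[iu], np.asarray(W, float)[iu]
    finite = np.isfinite(target)
    n_inf = int((~finite).sum())
    if n_inf == 0:
        return 0.0
    mean_wd2 = float((w[finite] * target[finite] ** 2).mean()) if finite.any() else 1.0
    return 0.01 * mean_wd2 / (n_inf + 1)


def classical_mds(D: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Classical (Torgerson) scaling; infinite entries are imputed with the
    maximum finite distance."""
    D = np.asarray(D, dtype=float).copy()
    finite = np.isfinite(D)
    if not finite.all():
        D[~finite] = D[finite].max() if finite.any() else 1.0
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(vals)
    if X.shape[1] < n_components:
        X = np.hstack([X, np.zeros((n, n_components - X.shape[1]))])
    return X - X.mean(axis=0)


def _check_connected(D: np.ndarray) -> None:
    finite = np.isfinite(D) & ~np.eye(D.shape[0], dtype=bool)
    n_comp, labels = connected_components(sp.csr_matrix(finite), directed=False)
    if n_comp > 1:
        members = [list(np.flatnonzero(labels == c)[:6]) for c in range(n_comp)]
        raise ValueError(
            f"finite-distance graph has {n_comp} disconnected components "
            f"(leading members: {members}); use pseudocount distances or "
            "penalty mode with lambda > 0 to couple them"
        )


def _smacof(D, W, lambda_, X0, max_iter, rel_tol):
    """Monotone majorization descent on the penalized stress from X0."""
    n = D.shape[0]
    finite = np.isfinite(D)
    np.fill_diagonal(finite, False)
    Wf = np.where(finite, W, 0.0)
    V = np.diag(Wf.sum(axis=1)) - Wf
    A = None
    if lambda_ > 0 and not finite.all():
        infinite = ~finite & ~np.eye(n, dtype=bool)
        Ai = infinite.astype(float)
        A = np.diag(Ai.sum(axis=1)) - Ai
    Vp = np.linalg.pinv(V, hermitian=True)

    X = X0 - X0.mean(axis=0)
    history = [stress_value(X, D, W, lambda_)]
    converged = False
    for _ in range(max_iter):
        dist = cdist(X, X)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, D / dist, 0.0)
        ratio[~finite] = 0.0
        Bmat = -Wf * ratio
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        target = Bmat @ X
        if A is not None:
            target = target + lambda_ * (A @ X)
        X = Vp @ target
        X -= X.mean(axis=0)
        history.append(stress_value(X, D, W, lambda_))
        prev, cur = history[-2], history[-1]
        if prev - cur < rel_tol * (abs(prev) + 1e-12):
            converged = True
            break
    return X, np.array(history), converged


def solve_mds(D: np.ndarray, config: MDSConfig | None = None) -> MDSResult:
    """Embed a target distance matrix in 3D.

    Weights are derived from ``D`` via the configured scheme; pairs with
    infinite target distance enter the penalty term only.  The
    finite-distance graph must be connected unless a positive penalty is in
    effect.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = MDSConfig()
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if n == 1:
        cfg = Configuration3D(np.zeros((1, 3)), np.arange(1))
        return MDSResult(cfg, 0.0, 0, True, np.zeros(1))

    W = make_weights(D, config.weight_scheme)
    lambda_ = config.lambda_ if config.lambda_ is not None else default_lambda(D, W)
    if lambda_ == 0:
        _check_connected(D)

    rng = np.random.default_rng(config.seed)
    finite = np.isfinite(D)
    scale = D[finite & (D > 0)].mean() if (finite & (D > 0)).any() else 1.0

    inits: list[np.ndarray] = []
    if config.init == "classical":
        inits.append(classical_mds(D))
    else:
        inits.append(rng.normal(scale=scale, size=(n, 3)))
    for _ in range(config.n_restarts or 0):
        inits.append(rng.normal(scale=scale, size=(n, 3)))

    best: MDSResult | None = None
    for X0 in inits:
        X, history, converged = _smacof(
            D, W, lambda_, X0, config.max_iter, config.rel_tol
        )
        result = MDSResult(
            Configuration3D(X, np.arange(n)),
            float(history[-1]),
            len(history) - 1,
            converged,
            history,
        )
        if best is None or result.stress < best.stress:
            best = result
    return best
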