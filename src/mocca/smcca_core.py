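"""Single-component sparse multiple CCA solver.

Given S standardized assays X_1..X_S sharing n samples, one component of
sparse multiple CCA maximizes the sum of pairwise cross-covariances

    sum_{i<j} w_i' X_i' X_j w_j    s.t.  ||w_i||_2 <= 1,  ||w_i||_1 <= c_i,

by block coordinate ascent: holding the other assays' weights fixed, the
optimal w_i for the linear objective g_i = sum_{j != i} X_i' X_j w_j over
the (L2, L1) constraint set is a soft-thresholded, L2-normalized copy of
g_i, with the threshold found by bisection so the L1 bound holds with
equality when active.  Each block update solves its subproblem exactly, so
the objective ascends monotonically.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PenalizedProblem",
    "ComponentFit",
    "soft_threshold",
    "l1_project",
    "update_weight",
    "objective",
    "fit_single_component",
]

_DEGENERATE_TOL = 1e-12


def soft_threshold(x: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise sign(x) * max(|x| - delta, 0)."""
    if delta < 0:
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def l1_project(x: np.ndarray, c: float, tol: float = 1e-12, max_bisect: int = 200) -> np.ndarray:
    """Map x to the unit-L2 vector u maximizing u'x subject to ||u||_1 <= c.

    u = S(x, delta) / ||S(x, delta)||_2 with delta = 0 when the normalized
    input already satisfies the L1 bound, else the delta > 0 (bisection on
    [0, max|x|], tolerance ``tol`` on ||u||_1 - c) at which the bound holds
    with equality.  Requires 1 <= c <= sqrt(len(x)) (below 1 the problem is
    infeasible for a unit-L2 vector; above sqrt(p) the bound never binds).
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("cannot project the zero vector")
    if not (1.0 - 1e-12 <= c <= math.sqrt(p) + 1e-9):
        raise ValueError(f"c={c} outside [1, sqrt(p)={math.sqrt(p):.4g}]")
    u = x / norm
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, float(np.abs(x).max())
    for _ in range(max_bisect):
        delta = 0.5 * (lo + hi)
        s = soft_threshold(x, delta)
        s_norm = np.linalg.norm(s)
        l1 = np.abs(s).sum() / s_norm if s_norm > 0 else 1.0
        if abs(l1 - c) <= tol:
            break
        if l1 > c:
            lo = delta
        else:
            hi = delta
    s = soft_threshold(x, delta)
    return s / np.linalg.norm(s)


@dataclasses.dataclass
class PenalizedProblem:
    """One sparse multiple CCA component problem.

    ``assays`` are standardized numpy matrices sharing n samples in the same
    order; ``penalties`` are the per-assay L1 bounds c_i in [1, sqrt(p_i)].
    """

    assays: Sequence[np.ndarray]
    penalties: Sequence[float]
    init: str = "svd"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assays = [np.asarray(x, dtype=float) for x in self.assays]
        if len(self.assays) < 2:
            raise ValueError("need at least two assays")
        n = self.assays[0].shape[0]
        for i, x in enumerate(self.assays):
            if x.ndim != 2 or x.shape[0] != n:
                raise ValueError(f"assay {i} does not share the sample dimension n={n}")
            if not np.isfinite(x).all():
                raise ValueError(f"assay {i} contains non-finite values")
        self.penalties = [float(c) for c in self.penalties]
        if len(self.penalties) != len(self.assays):
            raise ValueError("one penalty per assay required")
        for c, x in zip(self.penalties, self.assays):
            if not (1.0 - 1e-12 <= c <= math.sqrt(x.shape[1]) + 1e-9):
                raise ValueError(
                    f"penalty {c} outside [1, sqrt(p)={math.sqrt(x.shape[1]):.4g}]"
                )
        if self.init not in ("svd", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclasses.dataclass
class ComponentFit:
    """One fitted component: per-assay weights, canonical variables, and the
    objective trajectory recorded after every block update."""

    weights: list[np.ndarray]
    cvs: list[np.ndarray]
    objective_trajectory: list[float]
    iterations: int
    converged: bool
    degenerate: bool = False


def objective(assays: Sequence[np.ndarray], weights: Sequence[np.ndarray]) -> float:
    """Sum over assay pairs i<j of w_i' X_i' X_j w_j."""
    cvs = [x @ w for x, w in zip(assays, weights)]
    total = 0.0
    for i in range(len(cvs)):
        for j in range(i + 1, len(cvs)):
            total += float(cvs[i] @ cvs[j])
    return total


def _cross_products(assays: Sequence[np.ndarray]) -> dict[tuple[int, int], np.ndarray]:
    cache: dict[tuple[int, int], np.ndarray] = {}
    for i in range(len(assays)):
        for j in range(len(assays)):
            if i != j and (j, i) not in cache:
                cache[(i, j)] = assays[i].T @ assays[j]
    return cache


def _gradient(
    assays: Sequence[np.ndarray],
    weights: Sequence[np.ndarray],
    i: int,
    cache: dict[tuple[int, int], np.ndarray] | None,
) -> np.ndarray:
    g = np.zeros(assays[i].shape[1])
    for j in range(len(assays)):
        if j == i:
            continue
        if cache is not None:
            cij = cache[(i, j)] if (i, j) in cache else cache[(j, i)].T
            g += cij @ weights[j]
        else:
            g += assays[i].T @ (assays[j] @ weights[j])
    return g


def update_weight(
    problem: PenalizedProblem,
    i: int,
    weights: Sequence[np.ndarray],
    cache: dict[tuple[int, int], np.ndarray] | None = None,
) -> tuple[np.ndarray, bool]:
    """Exact block update for assay i given the other assays' weights.

    Returns (w_i, degenerate).  A (near-)zero gradient — assay i orthogonal
    to every other assay's current canonical variable — is flagged
    degenerate and yields a zero weight vector.
    """
    g = _gradient(problem.assays, weights, i, cache)
    scale = max(np.linalg.norm(a, ord="fro") for a in problem.assays)
    if np.linalg.norm(g) <= _DEGENERATE_TOL * max(scale, 1.0):
        return np.zeros_like(g), True
    return l1_project(g, problem.penalties[i]), False


def _initial_weights(problem: PenalizedProblem) -> list[np.ndarray]:
    if problem.init == "svd":
        ws = []
        for x in problem.assays:
            # leading right singular vector, deterministic sign
            _, _, vt = np.linalg.svd(x, full_matrices=False)
            v = vt[0]
            k = int(np.argmax(np.abs(v)))
            ws.append(v if v[k] >= 0 else -v)
        return ws
    rng = np.random.default_rng(problem.seed)
    ws = []
    for x in problem.assays:
        w = rng.standard_normal(x.shape[1])
        ws.append(w / np.linalg.norm(w))
    return ws


def _fix_sign(weights: list[np.ndarray], cvs: list[np.ndarray]) -> None:
    """Make the first nonzero entry of assay 1's weight vector positive.

    Negating every assay's weights jointly leaves the objective unchanged,
    so this is a pure reporting convention."""
    w0 = weights[0]
    nz = np.flatnonzero(w0)
    if nz.size and w0[nz[0]] < 0:
        for arr in (*weights, *cvs):
            arr *= -1.0


def fit_single_component(
    problem: PenalizedProblem,
    convergence_tol: float = 1e-6,
    max_iter: int = 100,
    cache_cross_products: bool = True,
) -> ComponentFit:
    """Block coordinate ascent to a single sparse multiple CCA component.

    Initialization is the leading right singular vector of each assay
    (``init="svd"``, deterministic) or a seeded unit Gaussian
    (``init="random"``).  Sweeps cycle i = 1..S until the largest relative
    L1 change of any weight vector falls below ``convergence_tol`` or
    ``max_iter`` sweeps elapse; non-convergence returns the last iterate
    with ``converged=False`` and a warning.
    """
    assays = problem.assays
    cache = _cross_products(assays) if cache_cross_products else None
    weights = _initial_weights(problem)
    trajectory = [objective(assays, weights)]
    converged = False
    degenerate = False
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        old = [w.copy() for w in weights]
        for i in range(len(assays)):
            w_new, deg = update_weight(problem, i, weights, cache)
            weights[i] = w_new
            degenerate = degenerate or deg
            trajectory.append(objective(assays, weights))
        if degenerate:
            break
        change = 0.0
        for w_old, w_new in zip(old, weights):
            denom = np.abs(w_old).sum()
            delta = np.abs(w_new - w_old).sum()
            change = max(change, delta / denom if denom > 0 else delta)
        if change < convergence_tol:
            converged = True
            break
    if not converged and not degenerate:
        warnings.warn(
            f"sparse multiple CCA component did not converge in {max_iter} sweeps "
            f"(last relative L1 change {change:.2e})",
            RuntimeWarning,
        )
    cvs = [x @ w for x, w in zip(assays, weights)]
    _fix_sign(weights, cvs)
    return ComponentFit(
        weights=weights,
        cvs=cvs,
        objective_trajectory=trajectory,
        iterations=iterations,
        converged=converged or degenerate,
        degenerate=degenerate,
    )
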