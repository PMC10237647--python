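"""Sparse multiple CCA with Gram-Schmidt deflation (SMCCA-GS).

Components are extracted sequentially: after each component, every assay is
deflated by its own just-extracted canonical variable before the next
component is fitted.  Two deflation modes exist:

* ``projection`` (default): each assay column is replaced by its residual
  after least-squares projection onto the new CV.  Columns of the deflated
  matrix are then exactly orthogonal to all earlier CVs, so within-assay
  CVs are uncorrelated by construction.
* ``rank_one``: subtract the outer product CV * w' from the current matrix
  (the cumulative reading of the classical deflation formula).  This does
  not guarantee orthogonality — on data with correlated features successive
  CVs can remain substantially correlated, which is exactly the pathology
  the projection mode is there to remove.

The user-facing estimator is :class:`SMCCAGS`, scikit-learn style: ``fit``
takes a list of samples x features matrices (one per assay), fitted
attributes carry trailing underscores, and ``transform`` applies trained
weights to new cohorts.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import numbers
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dataio import RunConfig
from .smcca_core import ComponentFit, PenalizedProblem, fit_single_component

logger = logging.getLogger(__name__)

__all__ = ["SMCCAGS", "deflate", "fit_smcca_gs", "transform_assay", "FitResult"]


def deflate(
    current: np.ndarray, new_cv: np.ndarray, new_w: np.ndarray, mode: str = "projection"
) -> np.ndarray:
    """Remove an extracted component's contribution from an assay matrix.

    ``projection``: residualize every column on ``new_cv`` (orthogonal
    projector I - cv cv'/||cv||^2 applied on the left).  ``rank_one``:
    subtract the outer product ``new_cv @ new_w'``.
    """
    current = np.asarray(current, dtype=float)
    cv = np.asarray(new_cv, dtype=float)
    w = np.asarray(new_w, dtype=float)
    if cv.shape[0] != current.shape[0] or w.shape[0] != current.shape[1]:
        raise ValueError("deflation vector lengths do not match the matrix")
    if mode == "projection":
        nrm2 = float(cv @ cv)
        if nrm2 == 0:
            raise ValueError("cannot project onto a zero-norm canonical variable")
        return current - np.outer(cv, cv @ current) / nrm2
    if mode == "rank_one":
        return current - np.outer(cv, w)
    raise ValueError(f"unknown deflation mode {mode!r}")


class SMCCAGS(BaseEstimator):
    """Sparse multiple canonical correlation analysis with Gram-Schmidt deflation.

    Parameters
    ----------
    n_components : int
        Number of canonical variables to extract per assay.
    penalties : "default", float, or sequence of float
        Per-assay L1 bounds c_i in [1, sqrt(p_i)] controlling weight
        sparsity; ``"default"`` uses 0.5 * sqrt(p_i).
    deflation : {"projection", "rank_one"}
        Between-component deflation mode (see module docstring).
    init : {"svd", "random"}
        Weight initialization for each component's block ascent.
    standardize : bool
        Center/scale each feature (n-1 denominator) before fitting; the
        training constants are stored for transform.  Set False only for
        pre-standardized input.
    tol, max_iter :
        Convergence tolerance (relative L1 weight change) and sweep cap for
        each component.
    cv_space : {"deflated", "original"}
        Whether reported CVs are computed against the matrices the
        component was fitted to (default) or the original standardized
        matrices.
    random_state : int or None
        Seed for ``init="random"``.

    Attributes
    ----------
    weights_ : list of ndarray, each (p_i, K)
        Canonical weight vectors per assay, in the original feature space.
    cvs_ : list of ndarray, each (n, K)
        Canonical variables per assay.
    penalties_ : ndarray (S,)
        Resolved L1 bounds.
    means_, sds_ : list of ndarray
        Training standardization constants per assay.
    component_fits_ : list of ComponentFit
        Solver metadata (objective trajectories, iterations, convergence).
    n_components_ : int
        Components actually extracted (may be fewer than requested if a
        degenerate, all-zero component stopped extraction early).
    """

    def __init__(
        self,
        n_components: int = 1,
        penalties="default",
        deflation: str = "projection",
        init: str = "svd",
        standardize: bool = True,
        tol: float = 1e-6,
        max_iter: int = 100,
        cv_space: str = "deflated",
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.penalties = penalties
        self.deflation = deflation
        self.init = init
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.cv_space = cv_space
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _validate_views(self, Xs) -> list[np.ndarray]:
        if isinstance(Xs, np.ndarray) and Xs.ndim == 2:
            raise ValueError(
                "SMCCAGS expects a list of assay matrices (one per assay), "
                "not a single 2-D array"
            )
        Xs = [np.asarray(x, dtype=float) for x in Xs]
        if len(Xs) < 2:
            raise ValueError("need at least two assays")
        n = Xs[0].shape[0]
        for i, x in enumerate(Xs):
            if x.ndim != 2 or x.shape[0] != n:
                raise ValueError(
                    f"assay {i} has shape {x.shape}; all assays must share the "
                    f"sample dimension n={n}"
                )
            if not np.isfinite(x).all():
                raise ValueError(f"assay {i} contains NaN or infinite values")
            if x.shape[1] < 1:
                raise ValueError(f"assay {i} has no features")
        return Xs

    def _resolve_penalties(self, Xs: Sequence[np.ndarray]) -> np.ndarray:
        if isinstance(self.penalties, str):
            if self.penalties != "default":
                raise ValueError(f"unknown penalties spec {self.penalties!r}")
            return np.array([max(1.0, 0.5 * math.sqrt(x.shape[1])) for x in Xs])
        if isinstance(self.penalties, numbers.Real):
            cs = np.full(len(Xs), float(self.penalties))
        else:
            cs = np.asarray([float(c) for c in self.penalties])
            if cs.shape[0] != len(Xs):
                raise ValueError("one penalty per assay required")
        for c, x in zip(cs, Xs):
            if not (1.0 <= c <= math.sqrt(x.shape[1]) + 1e-9):
                raise ValueError(
                    f"penalty {c} outside [1, sqrt(p)={math.sqrt(x.shape[1]):.4g}]"
                )
        return cs

    def _standardize_train(self, Xs: list[np.ndarray]) -> list[np.ndarray]:
        self.means_, self.sds_ = [], []
        out = []
        for i, x in enumerate(Xs):
            if self.standardize:
                mean = x.mean(axis=0)
                sd = x.std(axis=0, ddof=1)
                if (sd == 0).any():
                    bad = int(np.argmax(sd == 0))
                    raise ValueError(f"assay {i}: zero-variance feature at column {bad}")
                out.append((x - mean) / sd)
            else:
                mean = np.zeros(x.shape[1])
                sd = np.ones(x.shape[1])
                out.append(x.copy())
            self.means_.append(mean)
            self.sds_.append(sd)
        return out

    def fit(self, Xs, y=None):
        """Fit K components on a list of samples x features assay matrices."""
        if self.deflation not in ("projection", "rank_one"):
            raise ValueError(f"unknown deflation mode {self.deflation!r}")
        if self.cv_space not in ("deflated", "original"):
            raise ValueError(f"unknown cv_space {self.cv_space!r}")
        Xs = self._validate_views(Xs)
        Zs = self._standardize_train(Xs)
        originals = [z.copy() for z in Zs]
        self.penalties_ = self._resolve_penalties(Zs)
        S = len(Zs)
        K = int(self.n_components)
        weights = [[] for _ in range(S)]
        cvs = [[] for _ in range(S)]
        self.component_fits_: list[ComponentFit] = []
        current = Zs
        for k in range(K):
            problem = PenalizedProblem(
                assays=current,
                penalties=self.penalties_,
                init=self.init,
                seed=None if self.random_state is None else int(self.random_state) + k,
            )
            comp = fit_single_component(
                problem, convergence_tol=self.tol, max_iter=self.max_iter
            )
            if comp.degenerate or any(np.all(w == 0) for w in comp.weights):
                warnings.warn(
                    f"component {k + 1} is degenerate (all-zero weights); "
                    f"stopping after {k} component(s)",
                    RuntimeWarning,
                )
                break
            self.component_fits_.append(comp)
            for i in range(S):
                weights[i].append(comp.weights[i])
                if self.cv_space == "original":
                    cvs[i].append(originals[i] @ comp.weights[i])
                else:
                    cvs[i].append(comp.cvs[i])
            if k < K - 1:
                current = [
                    deflate(current[i], comp.cvs[i], comp.weights[i], self.deflation)
                    for i in range(S)
                ]
        self.n_components_ = len(self.component_fits_)
        if self.n_components_ == 0:
            raise ValueError("no non-degenerate component could be extracted")
        self.weights_ = [np.column_stack(w) for w in weights]
        self.cvs_ = [np.column_stack(c) for c in cvs]
        self.n_samples_ = Zs[0].shape[0]
        return self

    def transform(self, Xs, standardization: str = "target") -> list[np.ndarray]:
        """Apply the trained weights to (possibly new-cohort) assay matrices.

        ``standardization="target"`` (default) scales each assay by its own
        means/SDs; ``"source"`` replays the training constants.  Component 1
        of ``transform(training_data, standardization="source")`` reproduces
        the fitted CV1 exactly; later components differ because fitting
        computes them against deflated matrices.
        """
        check_is_fitted(self, "weights_")
        Xs = self._validate_views(Xs)
        if standardization not in ("target", "source"):
            raise ValueError(f"unknown standardization {standardization!r}")
        out = []
        for i, x in enumerate(Xs):
            if x.shape[1] != self.weights_[i].shape[0]:
                raise ValueError(
                    f"assay {i} has {x.shape[1]} features; weights expect "
                    f"{self.weights_[i].shape[0]} (intersect features first)"
                )
            if standardization == "target":
                mean = x.mean(axis=0)
                sd = x.std(axis=0, ddof=1)
                sd = np.where(sd == 0, 1.0, sd)
            else:
                mean, sd = self.means_[i], self.sds_[i]
            out.append(((x - mean) / sd) @ self.weights_[i])
        return out

    def fit_transform(self, Xs, y=None) -> list[np.ndarray]:
        return self.fit(Xs).cvs_

    def cv_correlation_matrix(self, assay_index: int = 0) -> np.ndarray:
        """K x K Pearson correlation matrix among one assay's fitted CVs."""
        check_is_fitted(self, "cvs_")
        cv = self.cvs_[assay_index]
        if cv.shape[1] == 1:
            return np.ones((1, 1))
        return np.corrcoef(cv, rowvar=False)


# ---------------------------------------------------------------------- #
# DataFrame-level wrappers


@dataclasses.dataclass
class FitResult:
    """Labelled fit artifacts for a set of named assays."""

    assay_names: list[str]
    weights: dict[str, pd.DataFrame]  # features x CV1..CVK
    cvs: dict[str, pd.DataFrame]  # samples x CV1..CVK
    penalties: dict[str, float]
    deflation_mode: str
    means: dict[str, pd.Series]
    sds: dict[str, pd.Series]
    components: list[dict]
    selection: dict[str, list[str]] | None = None

    @property
    def n_components(self) -> int:
        return next(iter(self.weights.values())).shape[1]


def _component_meta(fits: list[ComponentFit]) -> list[dict]:
    return [
        {
            "iterations": f.iterations,
            "converged": bool(f.converged),
            "degenerate": bool(f.degenerate),
            "objective_trajectory": [float(v) for v in f.objective_trajectory],
        }
        for f in fits
    ]


def result_from_estimator(
    est: SMCCAGS,
    assays: Sequence[pd.DataFrame],
    names: Sequence[str],
    selection: dict[str, list[str]] | None = None,
) -> FitResult:
    comp_cols = [f"CV{k + 1}" for k in range(est.n_components_)]
    weights, cvs, penalties, means, sds = {}, {}, {}, {}, {}
    for i, name in enumerate(names):
        weights[name] = pd.DataFrame(
            est.weights_[i], index=assays[i].columns, columns=comp_cols
        )
        cvs[name] = pd.DataFrame(est.cvs_[i], index=assays[i].index, columns=comp_cols)
        penalties[name] = float(est.penalties_[i])
        means[name] = pd.Series(est.means_[i], index=assays[i].columns)
        sds[name] = pd.Series(est.sds_[i], index=assays[i].columns)
    return FitResult(
        assay_names=list(names),
        weights=weights,
        cvs=cvs,
        penalties=penalties,
        deflation_mode=est.deflation,
        means=means,
        sds=sds,
        components=_component_meta(est.component_fits_),
        selection=selection,
    )


def fit_smcca_gs(
    assays: Sequence[pd.DataFrame],
    config: RunConfig,
    names: Sequence[str] | None = None,
) -> FitResult:
    """Fit SMCCA-GS on named, sample-aligned assay DataFrames."""
    names = list(names) if names is not None else [f"assay{i + 1}" for i in range(len(assays))]
    idx = assays[0].index
    for a in assays[1:]:
        if not a.index.equals(idx):
            raise ValueError("assays are not sample-aligned; run align_samples first")
    est = SMCCAGS(
        n_components=config.n_components,
        penalties=config.penalties,
        deflation=config.deflation_mode,
        init=config.init,
        tol=config.convergence_tol,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    est.fit([a.to_numpy(dtype=float) for a in assays])
    return result_from_estimator(est, assays, names)


def transform_assay(
    assay: pd.DataFrame,
    weights: pd.DataFrame,
    standardization: str = "target",
    source_means: pd.Series | None = None,
    source_sds: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply a trained weight matrix to a (feature-intersected) assay.

    With ``standardization="target"`` the assay is scaled by its own
    per-feature means/SDs; with ``"source"`` the provided training constants
    are replayed.
    """
    if list(assay.columns) != list(weights.index):
        raise ValueError("feature order mismatch; run intersect_features first")
    x = assay.to_numpy(dtype=float)
    if standardization == "target":
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
    elif standardization == "source":
        if source_means is None or source_sds is None:
            raise ValueError("source standardization requires stored means/sds")
        mean = source_means.loc[assay.columns].to_numpy(dtype=float)
        sd = source_sds.loc[assay.columns].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown standardization {standardization!r}")
    z = (x - mean) / sd
    return pd.DataFrame(
        z @ weights.to_numpy(dtype=float), index=assay.index, columns=weights.columns
    )
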