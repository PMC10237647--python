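"""Supervised sparse multiple CCA (SSMCCA).

Supervision enters as a per-assay feature-selection step before the
unsupervised SMCCA-GS fit: within each assay, features are ranked by the
absolute Pearson correlation of the feature with the outcome (for a binary
outcome coded 0/1 this is the point-biserial correlation) and the top
``ceil(quantile * p)`` are retained.  The selected submatrices are then
standardized and fitted with SMCCA-GS; reported weight matrices live in the
full original feature space with exact zeros for unselected features, so
transfer and downstream tooling need not know about the selection.

Unlike the classical two-assay supervised sparse CCA, any number of assays
(>= 2) is accepted.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import RunConfig
from .smcca_gs import SMCCAGS, FitResult, result_from_estimator

__all__ = ["SelectionMask", "supervised_select", "SSMCCA", "fit_ssmcca"]


@dataclasses.dataclass
class SelectionMask:
    """Outcome-guided selection result for one assay."""

    retained: list  # feature ids (DataFrame input) or column indices (ndarray)
    statistic: np.ndarray  # |corr(feature, outcome)| per original feature
    quantile: float


def _abs_outcome_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    if y_ss == 0:
        raise ValueError("outcome is constant; supervised selection undefined")
    xc = x - x.mean(axis=0)
    x_ss = (xc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.sqrt(x_ss * y_ss)
    return np.abs(np.nan_to_num(r, nan=0.0))  # constant features rank last


def supervised_select(
    assay, outcome, quantile: float = 0.8
) -> SelectionMask:
    """Rank features by |Pearson r| with the outcome; keep the top
    ceil(quantile * p), ties at the cut broken by feature identifier."""
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    is_frame = isinstance(assay, pd.DataFrame)
    x = assay.to_numpy(dtype=float) if is_frame else np.asarray(assay, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("outcome length does not match sample count")
    stat = _abs_outcome_correlation(x, y)
    p = x.shape[1]
    m = math.ceil(quantile * p)
    ids = list(assay.columns) if is_frame else list(range(p))
    order = sorted(range(p), key=lambda j: (-stat[j], ids[j]))
    keep = sorted(order[:m])  # original order preserved
    return SelectionMask(
        retained=[ids[j] for j in keep], statistic=stat, quantile=quantile
    )


class SSMCCA(SMCCAGS):
    """Supervised SMCCA-GS: outcome-guided feature selection, then the
    unsupervised fit on the retained features.

    Additional parameter ``selection_quantile`` (default 0.8) is the
    retained fraction of features per assay.  ``fit(Xs, y)`` requires the
    outcome; with ``selection_quantile=1`` the fit reduces exactly to the
    unsupervised estimator.

    Extra fitted attributes: ``selection_masks_`` (per-assay
    :class:`SelectionMask`) and ``selected_indices_`` (column indices kept).
    Reported ``weights_`` are in the full feature space with exact zeros on
    unselected features.
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
        selection_quantile: float = 0.8,
    ):
        super().__init__(
            n_components=n_components,
            penalties=penalties,
            deflation=deflation,
            init=init,
            standardize=standardize,
            tol=tol,
            max_iter=max_iter,
            cv_space=cv_space,
            random_state=random_state,
        )
        self.selection_quantile = selection_quantile

    def fit(self, Xs, y=None):
        if y is None:
            raise ValueError("SSMCCA.fit requires an outcome vector y")
        Xs = self._validate_views(Xs)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != Xs[0].shape[0]:
            raise ValueError("outcome length does not match sample count")
        self.selection_masks_ = [
            supervised_select(x, y, self.selection_quantile) for x in Xs
        ]
        self.selected_indices_ = [
            np.asarray(m.retained, dtype=int) for m in self.selection_masks_
        ]
        for i, idx in enumerate(self.selected_indices_):
            if idx.size < 2:
                raise ValueError(
                    f"assay {i} reduced to {idx.size} feature(s) by selection"
                )
        sub = [x[:, idx] for x, idx in zip(Xs, self.selected_indices_)]
        super().fit(sub)
        # scatter weights / standardization constants back to full feature space
        full_w, full_mean, full_sd = [], [], []
        for i, (x, idx) in enumerate(zip(Xs, self.selected_indices_)):
            p = x.shape[1]
            w = np.zeros((p, self.n_components_))
            w[idx] = self.weights_[i]
            full_w.append(w)
            mean = x.mean(axis=0) if self.standardize else np.zeros(p)
            sd = x.std(axis=0, ddof=1) if self.standardize else np.ones(p)
            sd = np.where(sd == 0, 1.0, sd)
            full_mean.append(mean)
            full_sd.append(sd)
        self.weights_ = full_w
        self.means_ = full_mean
        self.sds_ = full_sd
        return self


def fit_ssmcca(
    assays: Sequence[pd.DataFrame],
    outcome,
    config: RunConfig,
    names: Sequence[str] | None = None,
) -> FitResult:
    """Fit SSMCCA on named, sample-aligned assay DataFrames."""
    names = list(names) if names is not None else [f"assay{i + 1}" for i in range(len(assays))]
    idx = assays[0].index
    for a in assays[1:]:
        if not a.index.equals(idx):
            raise ValueError("assays are not sample-aligned; run align_samples first")
    if isinstance(outcome, pd.Series):
        outcome = outcome.loc[idx]
    est = SSMCCA(
        n_components=config.n_components,
        penalties=config.penalties,
        deflation=config.deflation_mode,
        init=config.init,
        tol=config.convergence_tol,
        max_iter=config.max_iter,
        random_state=config.seed,
        selection_quantile=config.selection_quantile,
    )
    est.fit([a.to_numpy(dtype=float) for a in assays], np.asarray(outcome, dtype=float))
    selection = {
        name: [assays[i].columns[j] for j in est.selected_indices_[i]]
        for i, name in enumerate(names)
    }
    return result_from_estimator(est, assays, names, selection=selection)
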