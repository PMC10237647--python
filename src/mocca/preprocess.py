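"""Feature transforms, greedy correlated-feature pruning, variance selection,
and PCA-IQR sample outlier flagging.

The transforms here are the standard pre-CCA cleanup for cohort omics data:
log + rank-based inverse normal transformation for skewed abundance
measures, per-feature standardization (stored constants support cross-cohort
transfer), removal of highly correlated features so the sparse solver does
not split weight mass across near-duplicates, and a simple per-sample
IQR-versus-PC1 outlier diagnostic.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "PruneReport",
    "OutlierReport",
    "log_inverse_normal",
    "inverse_normal",
    "standardize",
    "prune_correlated",
    "top_variance_select",
    "pca_iqr_outliers",
]


@dataclasses.dataclass
class PruneReport:
    """Record of a correlated-feature pruning pass.

    ``removed_ids`` is in removal order; after pruning no remaining pair has
    in-sample squared Pearson correlation >= ``threshold``.
    """

    removed_ids: list[str]
    threshold: float
    mode: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class OutlierReport:
    """Per-sample IQR / top-PC coordinates and the flagged sample set."""

    sample_ids: list[str]
    iqr: np.ndarray
    pc1: np.ndarray
    flagged: list[str]
    rule: str

    def to_dict(self) -> dict:
        return {
            "sample_ids": list(self.sample_ids),
            "iqr": [float(v) for v in self.iqr],
            "pc1": [float(v) for v in self.pc1],
            "flagged": list(self.flagged),
            "rule": self.rule,
        }


def inverse_normal(assay: pd.DataFrame) -> pd.DataFrame:
    """Rank-based inverse normal transform, per feature.

    Each feature's values are replaced by Phi^-1((rank - 0.5) / n), with
    average ranks for ties.  The 0.5 offset is symmetric and keeps the
    arguments away from 0 and 1.  A fully tied (constant) feature maps to
    all zeros.
    """
    values = assay.to_numpy(dtype=float)
    n = values.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, values) if values.size else values
    out = ndtri((ranks - 0.5) / n)
    return pd.DataFrame(out, index=assay.index, columns=assay.columns)


def log_inverse_normal(assay: pd.DataFrame) -> pd.DataFrame:
    """Log transform followed by rank-based inverse normal transform.

    Values must be strictly positive for the log step; the error names the
    first offending feature.  Because log is monotone the composite equals
    the inverse normal transform of the raw ranks, but the precondition is
    checked so that misuse on signed data fails loudly.
    """
    values = assay.to_numpy(dtype=float)
    bad = (values <= 0).any(axis=0)
    if bad.any():
        feat = assay.columns[int(np.argmax(bad))]
        raise ValueError(f"non-positive value in feature {feat!r}: log undefined")
    logged = pd.DataFrame(np.log(values), index=assay.index, columns=assay.columns)
    return inverse_normal(logged)


def standardize(assay: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center and scale each feature to mean 0, SD 1 (n-1 denominator).

    Returns the standardized frame plus the per-feature means and SDs, which
    are stored alongside fitted weights so a training cohort's scaling can be
    replayed on a target cohort.
    """
    mean = assay.mean(axis=0)
    sd = assay.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature(s): {list(zero.index)[:10]}")
    return (assay - mean) / sd, mean, sd


def _adjacency(values: np.ndarray, threshold: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns -> nan
        corr = np.corrcoef(values, rowvar=False)
    r2 = np.nan_to_num(corr, nan=0.0) ** 2
    adj = r2 >= threshold
    np.fill_diagonal(adj, False)
    return adj


def prune_correlated(
    assay: pd.DataFrame, threshold: float = 0.8, mode: str = "max_degree"
) -> tuple[pd.DataFrame, PruneReport]:
    """Greedily remove features until no pair has squared Pearson r >= threshold.

    Pairs at or above the threshold are "neighbors".  One feature is removed
    per iteration from among those with at least one remaining neighbor:

    * ``mode="max_degree"`` (default) removes the feature with the most
      neighbors — the choice that actually maximizes the retained feature
      count (on a hub-and-spokes correlation graph it removes the hub and
      keeps every leaf);
    * ``mode="printed"`` removes the feature with the *fewest* neighbors,
      the greedy variant that discards leaves one by one and keeps the hub.

    Ties on neighbor count resolve to the lexicographically smallest feature
    id, so the procedure is deterministic.
    """
    if mode not in ("printed", "max_degree"):
        raise ValueError(f"unknown mode {mode!r}")
    if assay.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    ids = list(assay.columns)
    adj = _adjacency(assay.to_numpy(dtype=float), threshold)
    alive = np.ones(len(ids), dtype=bool)
    removed: list[str] = []
    while True:
        degree = adj[np.ix_(alive, alive)].sum(axis=1)
        if degree.size == 0 or degree.max() == 0:
            break
        alive_idx = np.flatnonzero(alive)
        candidates = alive_idx[degree > 0]
        cand_deg = degree[degree > 0]
        best = cand_deg.max() if mode == "max_degree" else cand_deg.min()
        tied = candidates[cand_deg == best]
        victim = min(tied, key=lambda j: ids[j])
        alive[victim] = False
        removed.append(ids[victim])
    kept = [f for f, a in zip(ids, alive) if a]
    report = PruneReport(removed_ids=removed, threshold=threshold, mode=mode)
    return assay[kept], report


def top_variance_select(assay: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k features with the largest sample variance (original column
    order preserved; ties broken toward the earlier column)."""
    p = assay.shape[1]
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside [1, p={p}]")
    var = assay.var(axis=0, ddof=1).to_numpy()
    order = np.argsort(-var, kind="stable")[:k]
    keep = np.zeros(p, dtype=bool)
    keep[order] = True
    return assay.loc[:, keep]


def pca_iqr_outliers(
    assay: pd.DataFrame, fence_multiplier: float = 3.0
) -> OutlierReport:
    """Flag sample outliers on the IQR-versus-top-PC diagnostic.

    Each sample gets its within-sample interquartile range across features
    (x-axis) and its score on the first principal component of the
    standardized matrix (y-axis).  Samples whose IQR exceeds
    Q3 + fence_multiplier * IQR of the per-sample IQR distribution are
    flagged (a Tukey fence; the field practice is visual inspection of this
    plot, which a fixed fence operationalizes).
    """
    if assay.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    values = assay.to_numpy(dtype=float)
    q1, q3 = np.percentile(values, [25, 75], axis=1)
    sample_iqr = q3 - q1

    centered = values - values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = centered / sd
    # scores on the first right singular vector = PC1 of the standardized data
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pc1 = u[:, 0] * s[0]

    fq1, fq3 = np.percentile(sample_iqr, [25, 75])
    fence = fq3 + fence_multiplier * (fq3 - fq1)
    if math.isinf(fence_multiplier):
        flagged_mask = np.zeros(len(sample_iqr), dtype=bool)
    else:
        flagged_mask = sample_iqr > fence
    rule = f"IQR > Q3 + {fence_multiplier} * IQR(IQRs) = {fence:.6g}"
    return OutlierReport(
        sample_ids=list(assay.index),
        iqr=sample_iqr,
        pc1=pc1,
        flagged=[s_ for s_, f in zip(assay.index, flagged_mask) if f],
        rule=rule,
    )
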