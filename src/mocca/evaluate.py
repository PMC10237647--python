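"""Quantifying canonical-variable / phenotype relationships.

Variance explained is the workhorse: for a continuous outcome, ordinary
least squares R-squared; for a binary outcome, McFadden's pseudo-R-squared
1 - ll(full) / ll(null).  Two modes are provided:

* ``incremental`` (default): the gain of the predictor block beyond a
  covariate-only model, R2(covariates + predictors) - R2(covariates);
* ``marginal``: R2 of the predictors alone.

Also here: a per-assay PCA baseline, cumulative variance-explained curves
over the top 1..K components, covariate-adjusted Wald association tests,
and the seeded harness that compares two fitting procedures by the outcome
variance their first canonical variables explain across random restarts.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EvalResult",
    "MethodComparison",
    "variance_explained",
    "pc_baseline",
    "cumulative_r2_curve",
    "association_test",
    "compare_methods_over_seeds",
]


@dataclasses.dataclass
class EvalResult:
    r2: float
    family: str
    mode: str
    n: int
    n_predictors: int
    n_covariates: int
    warnings: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class MethodComparison:
    """Per-seed variance explained for two methods plus a paired test."""

    seeds: list[int]
    r2_a: np.ndarray
    r2_b: np.ndarray
    mean_difference: float  # mean(A) - mean(B)
    p_value: float
    test: str = "paired t-test"
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _drop_aliased(design: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Drop linearly dependent columns (pivoted QR), never the intercept."""
    if design.shape[1] == 0:
        return design, []
    rank = int(np.linalg.matrix_rank(design))
    if rank == design.shape[1]:
        return design, list(range(design.shape[1]))
    # greedy: keep columns that increase rank
    kept: list[int] = []
    for j in range(design.shape[1]):
        trial = design[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
    warnings.warn(
        f"design is rank-deficient; dropping {design.shape[1] - len(kept)} aliased column(s)",
        RuntimeWarning,
    )
    return design[:, kept], kept


def _ols_r2(y: np.ndarray, design: np.ndarray) -> float:
    """R2 of y on [1, design] via least squares."""
    X = np.column_stack([np.ones(len(y)), design]) if design.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("outcome is constant")
    return 1.0 - float(resid @ resid) / tss


def _logit_llf(y: np.ndarray, design: np.ndarray) -> tuple[float, bool]:
    """Maximized log-likelihood of a logistic model with intercept.

    Returns (llf, separated); perfect separation yields llf -> 0.
    """
    X = sm.add_constant(design, has_constant="add") if design.size else np.ones((len(y), 1))
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            llf = float(res.llf)
            if not res.mle_retvals.get("converged", True):
                fitted = res.predict(X)
                if np.all((fitted > 0.99) == (y > 0.5)):
                    separated = True
        except Exception:
            separated = True
            llf = 0.0
    if separated:
        llf = 0.0
    return llf, separated


def variance_explained(
    outcome,
    predictors,
    covariates=None,
    family: str = "linear",
    mode: str = "incremental",
) -> EvalResult:
    """Proportion of outcome variation explained by a predictor block.

    Linear family: OLS R-squared (incremental: R2 gain over the
    covariate-only model).  Logistic family: McFadden pseudo-R-squared,
    with the null model holding the covariates (incremental) or only the
    intercept (marginal).
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    if mode not in ("incremental", "marginal"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(outcome, dtype=float)
    P = _as_2d(predictors)
    C = _as_2d(covariates) if covariates is not None else np.empty((len(y), 0))
    if len(y) != P.shape[0] or len(y) != C.shape[0]:
        raise ValueError("outcome, predictors and covariates disagree on n")
    if len(y) <= P.shape[1] + C.shape[1] + 1:
        raise ValueError("too few samples for the requested design")
    warns: list[str] = []
    if mode == "marginal":
        C = np.empty((len(y), 0))
    full = np.column_stack([C, P]) if C.size else P
    full, _ = _drop_aliased(full)
    if family == "linear":
        r2_full = _ols_r2(y, full)
        r2_null = _ols_r2(y, C) if C.size else 0.0
        r2 = max(r2_full - r2_null, 0.0)
    else:
        y = np.asarray(outcome)
        levels = np.unique(y)
        if len(levels) != 2:
            raise ValueError("logistic family requires a binary outcome")
        y01 = (y == levels[1]).astype(float)
        ll_null_ref, _ = _logit_llf(y01, np.empty((len(y01), 0)))  # intercept-only
        ll_null, _ = _logit_llf(y01, C) if C.size else (ll_null_ref, False)
        ll_full, separated = _logit_llf(y01, full)
        if separated:
            warns.append("perfect separation: pseudo-R2 reported as 1")
            r2 = 1.0
        else:
            r2 = 1.0 - ll_full / ll_null if ll_null != 0 else 1.0
            r2 = float(np.clip(r2, 0.0, 1.0))
    return EvalResult(
        r2=float(r2),
        family=family,
        mode=mode,
        n=len(y),
        n_predictors=P.shape[1],
        n_covariates=C.shape[1] if mode == "incremental" else 0,
        warnings=warns,
    )


def pc_baseline(assay, k: int) -> np.ndarray:
    """First k principal-component scores of a standardized assay matrix.

    Components are ordered by decreasing variance; each loading vector's
    largest-magnitude entry is made positive, so signs are deterministic.
    """
    x = np.asarray(assay, dtype=float)
    n, p = x.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k={k} outside [1, min(n, p)={min(n, p)}]")
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            scores[:, j] *= -1
    return scores


def cumulative_r2_curve(
    outcome, components, covariates=None, family: str = "linear", mode: str = "incremental"
) -> np.ndarray:
    """Variance explained by the top 1..K components (refit per k).

    For the linear family the curve is monotone non-decreasing in k
    (nested designs).
    """
    comp = _as_2d(components)
    return np.array(
        [
            variance_explained(outcome, comp[:, : k + 1], covariates, family, mode).r2
            for k in range(comp.shape[1])
        ]
    )


def association_test(
    cv, outcome, covariates=None, family: str = "linear"
) -> tuple[float, float]:
    """Wald test of the canonical variable in a covariate-adjusted model.

    Returns (effect sign, two-sided p-value).  Significance thresholds
    (e.g. Bonferroni-corrected) are the caller's decision; replication
    conventionally also requires the same direction of effect.
    """
    y = np.asarray(outcome, dtype=float)
    v = np.asarray(cv, dtype=float).ravel()
    C = _as_2d(covariates) if covariates is not None else np.empty((len(y), 0))
    design = sm.add_constant(
        np.column_stack([C, v]) if C.size else v[:, None], has_constant="add"
    )
    if family == "linear":
        res = sm.OLS(y, design).fit()
    elif family == "logistic":
        levels = np.unique(y)
        if len(levels) != 2:
            raise ValueError("logistic family requires a binary outcome")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit((y == levels[1]).astype(float), design).fit(disp=0, maxiter=200)
    else:
        raise ValueError(f"unknown family {family!r}")
    coef = float(res.params[-1])
    pval = float(res.pvalues[-1])
    if np.isnan(pval):  # exact collinearity of cv and outcome
        pval = 0.0
    return float(np.sign(coef)), pval


def compare_methods_over_seeds(
    fitter_a: Callable[[int], np.ndarray],
    fitter_b: Callable[[int], np.ndarray],
    outcome,
    n_seeds: int = 100,
    covariates=None,
    family: str = "linear",
    mode: str = "marginal",
    base_seed: int = 0,
) -> MethodComparison:
    """Seeded head-to-head comparison of two CV-producing procedures.

    Each fitter is a callable ``seed -> CV1 vector`` (typically a randomly
    initialized fit).  For every seed both methods run, the outcome
    variance explained by each CV1 is recorded, and the per-seed
    differences are tested with a paired two-sided t-test.
    """
    if n_seeds < 2:
        raise ValueError("need at least two seeds")
    y = np.asarray(outcome, dtype=float)
    seeds = [base_seed + s for s in range(n_seeds)]
    r2_a = np.empty(n_seeds)
    r2_b = np.empty(n_seeds)
    for k, seed in enumerate(seeds):
        cv_a = np.asarray(fitter_a(seed), dtype=float).ravel()
        cv_b = np.asarray(fitter_b(seed), dtype=float).ravel()
        r2_a[k] = variance_explained(y, cv_a, covariates, family, mode).r2
        r2_b[k] = variance_explained(y, cv_b, covariates, family, mode).r2
    diffs = r2_a - r2_b
    if np.allclose(diffs, 0.0):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_rel(r2_a, r2_b).pvalue)
    return MethodComparison(
        seeds=seeds,
        r2_a=r2_a,
        r2_b=r2_b,
        mean_difference=float(diffs.mean()),
        p_value=p_value,
    )
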