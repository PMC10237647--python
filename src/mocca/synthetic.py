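"""Synthetic multi-omics data with planted shared sparse latent structure.

The generator emulates the situation the CCA machinery targets: S assays
measured on the same samples, each a noisy linear readout of a small set of
shared latent factors through assay-specific sparse loading matrices, plus
optional additive per-batch mean shifts (assay-specific technical
variation) and an outcome linearly linked to the latents.

Model, per assay i:

    X_i = F B_i' + batch shifts + E_i,   E_i ~ N(0, noise_sd_i^2)

where F = sqrt(n) * Z holds the latent factors scaled to unit sample
variance and Z has orthonormal columns (Z'Z = I).  The stored truth keeps
Z, the sparse loadings B_i (exactly round(sparsity * p_i) nonzeros per
factor, magnitudes set by ``loading_scale``), the outcome coefficients and
the batch labels, so recovery tests can score fitted weights and canonical
variables against the planted structure.

The continuous outcome is y = F @ gamma + eps with eps scaled so the
population R-squared of y on the factors equals ``outcome_r2``; the binary
outcome is a Bernoulli draw through a logistic link whose linear predictor
is scaled to the matching latent-scale signal fraction.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_multiomics", "generate_cohort_pair"]


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions for one synthetic multi-assay dataset.

    ``loading_scale`` may be a scalar or one value per factor (the per-factor
    SD of the nonzero loadings); ``noise_sd`` a scalar or one value per
    assay; ``outcome_coefs`` optional per-factor coefficients (default: all
    ones, every factor outcome-linked).
    """

    n: int = 300
    p: Sequence[int] = (400, 600)
    k_true: int = 1
    sparsity: float = 0.05
    loading_scale: object = 3.0
    noise_sd: object = 1.0
    n_batches: int = 1
    batch_sd: float = 0.0
    outcome_r2: float = 0.5
    outcome_coefs: Sequence[float] | None = None
    seed: int = 0
    n_cohorts: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if not 0 <= self.outcome_r2 < 1:
            raise ValueError("outcome_r2 must be in [0, 1)")
        if self.n < 2 or self.k_true < 1 or any(pi < 1 for pi in self.p):
            raise ValueError("invalid problem dimensions")
        if self.n_cohorts not in (1, 2):
            raise ValueError("n_cohorts must be 1 or 2")
        for pi in self.p:
            if round(self.sparsity * pi) < 1:
                raise ValueError(
                    f"sparsity {self.sparsity} yields zero nonzero loadings at p={pi}"
                )

    def loading_scales(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.loading_scale, dtype=float), (self.k_true,)
        ).copy()

    def noise_sds(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (len(self.p),)
        ).copy()

    def gamma(self) -> np.ndarray:
        if self.outcome_coefs is None:
            return np.ones(self.k_true)
        g = np.asarray(self.outcome_coefs, dtype=float)
        if g.shape != (self.k_true,):
            raise ValueError("outcome_coefs must have one entry per factor")
        return g


@dataclasses.dataclass
class SyntheticTruth:
    """Planted structure for recovery scoring."""

    latents: np.ndarray  # n x k, orthonormal columns (Z'Z = I)
    factors: np.ndarray  # n x k, sqrt(n) * latents (unit sample variance)
    loadings: list[np.ndarray]  # per assay, p_i x k, sparse
    outcome_coefs: np.ndarray
    batch_labels: list[np.ndarray]
    generator: str = "numpy.random.default_rng(PCG64)"


def _orthonormal_latents(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    z = rng.standard_normal((n, k))
    q, r = np.linalg.qr(z)
    return q * np.sign(np.diag(r))  # deterministic sign


def _sparse_loadings(
    rng: np.random.Generator, p: int, k: int, sparsity: float, scales: np.ndarray
) -> np.ndarray:
    b = np.zeros((p, k))
    m = round(sparsity * p)
    for j in range(k):
        support = rng.choice(p, size=m, replace=False)
        b[support, j] = scales[j] * rng.standard_normal(m)
    return b


def _one_cohort(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    loadings: list[np.ndarray],
    gamma: np.ndarray,
    cohort_tag: str = "",
) -> tuple[list[pd.DataFrame], pd.DataFrame, SyntheticTruth]:
    n, k = spec.n, spec.k_true
    z = _orthonormal_latents(rng, n, k)
    factors = np.sqrt(n) * z
    noise_sds = spec.noise_sds()
    sample_ids = [f"S{cohort_tag}{i + 1:05d}" for i in range(n)]
    assays: list[pd.DataFrame] = []
    batch_labels: list[np.ndarray] = []
    for i, p in enumerate(spec.p):
        x = factors @ loadings[i].T + noise_sds[i] * rng.standard_normal((n, p))
        labels = np.zeros(n, dtype=int)
        if spec.n_batches > 1 and spec.batch_sd > 0:
            labels = rng.integers(0, spec.n_batches, size=n)
            shifts = spec.batch_sd * rng.standard_normal((spec.n_batches, p))
            x = x + shifts[labels]
        batch_labels.append(labels)
        assays.append(
            pd.DataFrame(
                x,
                index=sample_ids,
                columns=[f"A{i + 1}_F{j + 1:05d}" for j in range(p)],
            )
        )

    signal = factors @ gamma
    var_signal = float(gamma @ gamma)  # factors have ~unit variance, orthogonal
    if spec.outcome_r2 > 0 and var_signal > 0:
        eps_sd = np.sqrt(var_signal * (1 - spec.outcome_r2) / spec.outcome_r2)
    else:
        eps_sd = 1.0
        signal = np.zeros(n)
    y = signal + eps_sd * rng.standard_normal(n)

    # binary outcome through a logistic link; the linear predictor is scaled
    # so the latent-scale signal fraction matches outcome_r2 against the
    # logistic residual variance pi^2/3
    if spec.outcome_r2 > 0 and var_signal > 0:
        target_var = (np.pi**2 / 3) * spec.outcome_r2 / (1 - spec.outcome_r2)
        eta = signal * np.sqrt(target_var / var_signal)
    else:
        eta = np.zeros(n)
    y_bin = rng.binomial(1, expit(eta)).astype(float)

    phenotypes = pd.DataFrame({"y": y, "y_bin": y_bin}, index=sample_ids)
    truth = SyntheticTruth(
        latents=z,
        factors=factors,
        loadings=loadings,
        outcome_coefs=gamma,
        batch_labels=batch_labels,
    )
    return assays, phenotypes, truth


def generate_multiomics(
    spec: SyntheticSpec,
) -> tuple[list[pd.DataFrame], pd.DataFrame, SyntheticTruth]:
    """Generate one cohort of multi-assay data plus phenotypes and truth.

    Identical specs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    scales = spec.loading_scales()
    loadings = [
        _sparse_loadings(rng, p, spec.k_true, spec.sparsity, scales) for p in spec.p
    ]
    return _one_cohort(spec, rng, loadings, spec.gamma())


def generate_cohort_pair(
    spec: SyntheticSpec,
) -> tuple[
    tuple[list[pd.DataFrame], pd.DataFrame, SyntheticTruth],
    tuple[list[pd.DataFrame], pd.DataFrame, SyntheticTruth],
]:
    """Two cohorts sharing true loadings and outcome coefficients, with
    independent samples, noise and batch draws (the transferability design)."""
    if spec.n_cohorts != 2:
        raise ValueError("spec.n_cohorts must be 2 for a cohort pair")
    rng = np.random.default_rng(spec.seed)
    scales = spec.loading_scales()
    loadings = [
        _sparse_loadings(rng, p, spec.k_true, spec.sparsity, scales) for p in spec.p
    ]
    gamma = spec.gamma()
    cohort_a = _one_cohort(spec, rng, loadings, gamma, cohort_tag="A")
    cohort_b = _one_cohort(spec, rng, loadings, gamma, cohort_tag="B")
    return cohort_a, cohort_b
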