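import numpy as np
import pandas as pd
import pytest

from mocca.synthetic import SyntheticSpec, generate_multiomics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_assay(rng) -> pd.DataFrame:
    """20 samples x 6 features, positive values (log-safe)."""
    values = np.exp(rng.standard_normal((20, 6)))
    return pd.DataFrame(
        values,
        index=[f"S{i:03d}" for i in range(20)],
        columns=[f"F{j}" for j in range(6)],
    )


@pytest.fixture(scope="session")
def planted_one_factor():
    """Single shared sparse factor across two assays, moderate size."""
    spec = SyntheticSpec(
        n=150, p=(80, 120), k_true=1, sparsity=0.1, loading_scale=3.0,
        noise_sd=1.0, outcome_r2=0.5, seed=42,
    )
    return generate_multiomics(spec), spec


@pytest.fixture(scope="session")
def planted_three_factor():
    """Three shared factors with distinct strengths (identifiable ordering)."""
    spec = SyntheticSpec(
        n=200, p=(150, 200), k_true=3, sparsity=0.1,
        loading_scale=(6.0, 4.0, 2.5), noise_sd=1.0, outcome_r2=0.5, seed=7,
    )
    return generate_multiomics(spec), spec
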