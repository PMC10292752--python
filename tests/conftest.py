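import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nmfmarker import ExpressionMatrix, SyntheticSpec, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples, TPM scale."""
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["GeneA", "GeneB", "GeneC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(frame, scale_tag="tpm")


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted two-group dataset with clear separation."""
    spec = SyntheticSpec(
        n_genes=200, n_samples=24, n_disease_samples=10,
        n_marker_genes=12, n_bystander_genes=30,
        marker_effect=3.0, noise_model="gamma", noise_scale=0.05, seed=3,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def separated_block_dataset():
    """Strong-separation fixture: all NMF runs agree on the partition."""
    spec = SyntheticSpec(
        n_genes=150, n_samples=24, n_disease_samples=10,
        n_marker_genes=10, n_bystander_genes=20,
        marker_effect=3.0, noise_model="gamma", noise_scale=0.05, seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
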