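import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from emat.preprocess import ExpressionMatrix
from emat.simulate import CohortSpec, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blobs_matrix(n_per_cluster, n_genes, K, separation, noise_sd=1.0, seed=0,
                      noise_seed=None):
    """Genes x samples matrix with K planted clusters; per-gene RMS
    between-centroid gap = separation * noise_sd.  ``noise_seed`` draws an
    independent cohort from the same centroids."""
    rng = np.random.default_rng(seed)
    centroids = rng.normal(0, separation * noise_sd / np.sqrt(2), size=(n_genes, K))
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
    cols, labels, data = [], [], []
    for k in range(K):
        for i in range(n_per_cluster):
            cols.append(f"c{k}_s{i}")
            labels.append(k + 1)
            data.append(centroids[:, k] + rng.normal(0, noise_sd, n_genes))
    values = pd.DataFrame(np.array(data).T, index=[f"g{j}" for j in range(n_genes)], columns=cols)
    m = ExpressionMatrix(values, scale="zscore")
    return m, pd.Series(labels, index=cols)


@pytest.fixture
def blobs():
    """4 well-separated planted blobs (separation >> noise)."""
    return make_blobs_matrix(n_per_cluster=25, n_genes=40, K=4, separation=8.0, seed=7)


@pytest.fixture(scope="session")
def planted_cohort():
    """Moderate-size cohort with cluster-driven hazards, reused read-only."""
    spec = CohortSpec(
        n_samples=300, n_genes=600, signature_size=100, separation=4.0,
        hazard_ratios=(1.0, 1.5, 2.0, 4.0), seed=42,
    )
    return generate_cohort(spec)
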