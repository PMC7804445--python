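import numpy as np
import pandas as pd
import pytest

from soilbiome import CountMatrix, make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def default_bundle():
    return make_fixture("default")


@pytest.fixture
def small_counts():
    """A tiny hand-written count matrix: 4 species x 4 samples, 2 groups."""
    df = pd.DataFrame(
        [[5, 3, 0, 1], [2, 2, 2, 2], [0, 0, 9, 7], [1, 4, 1, 0]],
        index=["spA", "spB", "spC", "spD"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix(df)


@pytest.fixture
def small_metadata():
    return pd.DataFrame(
        {"group": ["X", "X", "Y", "Y"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )


def random_count_matrix(rng, n_species=10, n_samples=8, zero_frac=0.3, mean=20.0):
    """Random zero-inflated matrix where every pair of samples shares taxa."""
    counts = rng.poisson(mean, size=(n_species, n_samples))
    mask = rng.random(counts.shape) < zero_frac
    counts = np.where(mask, 0, counts)
    counts[0, :] = rng.poisson(mean, n_samples) + 1  # guarantee a shared taxon
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"sp{i}" for i in range(n_species)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
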