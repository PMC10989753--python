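import numpy as np
import pandas as pd
import pytest

from qmd import FeatureTable, RelAbundanceTable, synth_pool


def make_feature_table(counts, groups=None, taxa=None, samples=None):
    """Build a FeatureTable from a plain nested list / array of counts."""
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=taxa, columns=samples)
    group_of = dict(zip(samples, groups)) if groups is not None else None
    return FeatureTable(counts=df, group_of=group_of)


def make_rel_table(rel, groups, taxa=None, samples=None):
    rel = np.asarray(rel, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(rel.shape[0])]
    samples = samples or [f"s{j}" for j in range(rel.shape[1])]
    df = pd.DataFrame(rel, index=taxa, columns=samples)
    return RelAbundanceTable(rel=df, group_of=dict(zip(samples, groups)))


@pytest.fixture
def six_sample_table():
    """5 taxa x 6 samples, 3 per group, every taxon detected everywhere."""
    rng = np.random.default_rng(7)
    counts = rng.integers(1, 200, size=(5, 6))
    return make_feature_table(counts, groups=["T", "T", "T", "C", "C", "C"])


@pytest.fixture(scope="session")
def small_pool():
    """A small but structured pool shared by the slower simulation tests."""
    return synth_pool(n_taxa=60, n_pool_samples=40, seed=2024)


@pytest.fixture(scope="session")
def dense_pool():
    """Sparsity-free pool: every taxon detected in every sample."""
    return synth_pool(n_taxa=40, n_pool_samples=30, sparsity=0.0, seed=2025)
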