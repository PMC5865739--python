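import numpy as np
import pytest

import svmcluster as sc


@pytest.fixture(scope="session")
def small_spec():
    """A miniature planted-signal cohort: 12 regions, 18 subjects, strong effect."""
    return sc.SyntheticSpec(
        n_group_a=8,
        n_group_b=10,
        n_regions=12,
        n_timepoints=60,
        planted_pairs=[(0, 1, 0.8, -0.4), (2, 3, 0.8, -0.4), (4, 5, 0.8, -0.4)],
        baseline_corr=0.1,
        noise_sd=0.1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return sc.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_ds(small_cohort):
    return sc.Dataset.from_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_split(small_ds):
    return sc.split_dataset(small_ds, (12, 2, 4), seed=42)


@pytest.fixture(scope="session")
def small_cluster(small_ds, small_split):
    cluster = sc.build_cluster(small_ds, small_split, n=12, d=8, k=31, seed=42)
    sc.member_accuracies(cluster, small_ds, small_split.validation_idx)
    return cluster


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
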