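"""Shared fixtures: null histograms and a small simulated cohort."""

import numpy as np
import pytest

from joindel.config import RunConfig
from joindel.likelihood import transform_histogram
from joindel.profile import InsertSizeHistogram


@pytest.fixture(scope="session")
def null_hist() -> InsertSizeHistogram:
    """Empirical null insert-size histogram, ~Normal(450, 15), n=20,000."""
    rng = np.random.default_rng(424242)
    inserts = np.rint(rng.normal(450, 15, size=20_000)).astype(int)
    return InsertSizeHistogram.from_insert_sizes(inserts)


@pytest.fixture(scope="session")
def window_hist(null_hist):
    return transform_histogram(null_hist, window_size=30)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-sample, 400 kb cohort with 6 deletions, profiled at 30x."""
    from joindel.simulate import (
        simulate_deletion_set,
        simulate_genotypes,
        simulate_profiles,
    )

    length = 400_000
    deletions = simulate_deletion_set(
        6, contig_length=length, len_range=(600, 5000), seed=7
    )
    cohort = simulate_genotypes(deletions, 4, seed=8)
    profiles = simulate_profiles(
        deletions, cohort, contig_length=length, coverage=30, seed=9
    )
    return deletions, cohort, profiles, length
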