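"""Shared fixtures: one small study-like cohort generated once per session."""

import pytest
from hypothesis import settings

from phagemosaic.synthetic_data import make_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

COHORT_LENGTH = 30_000
HOST_LENGTH = 12_000


@pytest.fixture(scope="session")
def cohort():
    """Six-genome cohort with every planted element class (seed 1)."""
    genomes, host, truth = make_cohort(scenario="cluster_j_like", seed=1,
                                       length=COHORT_LENGTH,
                                       host_length=HOST_LENGTH)
    return genomes, host, truth


@pytest.fixture(scope="session")
def cohort_by_id(cohort):
    genomes, host, truth = cohort
    return {g.id: g for g in genomes}, host, truth
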