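"""Shared fixtures: small simulated families and a tiny hand-written record set."""

from __future__ import annotations

import pytest

from isfamily.records_io import RecordSet
from isfamily.synthetic import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def small_family():
    """20-taxon default-condition family with two injected isoform pairs."""
    return simulate_family(SimulationConfig(seed=11, n_taxa=20, isoform_pairs=2))


@pytest.fixture(scope="session")
def small_records(small_family) -> RecordSet:
    return small_family[0]


@pytest.fixture(scope="session")
def small_truth(small_family):
    return small_family[1]


@pytest.fixture(scope="session")
def tiny_family():
    """8-taxon family, no isoforms: cheap input for expensive stages."""
    return simulate_family(SimulationConfig(seed=5, n_taxa=8, isoform_pairs=0))
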