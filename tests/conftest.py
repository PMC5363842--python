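"""Shared fixtures: a small noise-free synthetic genome, reused across tests."""

import pytest

from kzfptools.simulate import (
    GenomeConfig,
    simulate_annotations,
    simulate_sequences,
    simulate_signal,
)


@pytest.fixture(scope="session")
def clean_config():
    """Default study conditions at mutation rate 0 (noise-free sequences)."""
    return GenomeConfig(seed=7, mutation_rate=0.0)


@pytest.fixture(scope="session")
def clean_genome(clean_config):
    """(units, krab_hits, repeats, truth, genome records) at mutation rate 0."""
    units, krabs, repeats, truth = simulate_annotations(clean_config, seed=7)
    genome = simulate_sequences(clean_config, truth, seed=7)
    return units, krabs, repeats, truth, genome


@pytest.fixture(scope="session")
def clean_signal(clean_config, clean_genome):
    _, _, _, truth, _ = clean_genome
    return simulate_signal(clean_config, truth, seed=7)
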