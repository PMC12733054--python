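"""Shared fixtures: a small simulated cohort and its on-disk form."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from g2h.simulate import SimConfig, simulate_population, write_simulation

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_CONFIG = SimConfig(
    n_chrom=3,
    chrom_lengths_bp=(8_000_000, 6_000_000, 5_000_000),
    genetic_lengths_cM=(120.0, 100.0, 90.0),
    n_blocks_total=150,
    mean_snps_per_block=6.0,
    pop_size=6,
    error_rate=0.02,
    missing_rate=0.05,
    seed=42,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_population(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_sim")
    paths = write_simulation(small_sim, str(out))
    return paths
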