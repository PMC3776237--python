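"""Shared fixtures: small simulated datasets with known truth."""

from __future__ import annotations

import pytest

from msimpute.sim import SimConfig, simulate_panel
from msimpute.types import build_region
from msimpute.phasing import make_window


CLEAN = dict(
    ms_error_rate=0.0,
    ms_mutation_rate=0.0,
    recomb_rate=0.0,
    rounding_error_rate=0.0,
)


@pytest.fixture(scope="session")
def clean_sim():
    """Small error-free multi-breed dataset (closed world)."""
    cfg = SimConfig(
        n_breeds=4, n_founders=50, n_trios=25, markers=("MS1",),
        region_snps=40, window_snps=24, seed=101, **CLEAN,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def clean_window(clean_sim):
    region = build_region(clean_sim.ms_map[0], clean_sim.snp_map)
    return make_window(region, 24)


@pytest.fixture(scope="session")
def noisy_sim():
    """Dataset with realistic MS error, mutation and recombination."""
    cfg = SimConfig(
        n_breeds=4, n_founders=50, n_trios=25, markers=("MS1",),
        region_snps=40, window_snps=24, seed=202,
    )
    return simulate_panel(cfg)
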