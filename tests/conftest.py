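"""Shared fixtures: small synthetic populations reused across test modules."""

import numpy as np
import pytest

from froskd import (
    QuantConfig,
    SimulationConfig,
    estimate_autofluorescence,
    simulate_population,
)


@pytest.fixture(scope="session")
def clean_saturated():
    """Noise-free, fully saturated population: every array carries 512 molecules."""
    cfg = SimulationConfig(
        n_cells=12,
        conc_law="fixed",
        conc_low=12000.0,   # ~20x Kd: occupancy rounds to exactly 2 x repeats
        replicated_dot_fraction=0.0,
        noise=False,
        seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def clean_midrange():
    """Noise-free population near Kd with known per-cell ground truth."""
    cfg = SimulationConfig(
        n_cells=16,
        conc_law="log-uniform",
        conc_low=200.0,
        conc_high=1200.0,
        replicated_dot_fraction=0.0,
        noise=False,
        seed=7,
    )
    return simulate_population(cfg)


def matched_quant(population) -> QuantConfig:
    cfg = population.config
    af = estimate_autofluorescence(
        [f.control for f in population.fields], [f.mask for f in population.fields]
    )
    return QuantConfig(dof=cfg.dof, pixel_size=cfg.pixel_size, autofluorescence_level=af)


@pytest.fixture(scope="session")
def quant_clean_saturated(clean_saturated):
    return matched_quant(clean_saturated)


@pytest.fixture(scope="session")
def quant_clean_midrange(clean_midrange):
    return matched_quant(clean_midrange)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
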