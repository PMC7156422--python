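"""Shared fixtures: small synthetic maps with planted, known structure."""

import numpy as np
import pytest

from hicreprog import sim
from hicreprog.contacts import ContactMatrix, ice_normalize, make_bins


def matrix_from_values(values: np.ndarray, resolution: int = 100_000) -> ContactMatrix:
    """Wrap a dense symmetric array as a single-chromosome ContactMatrix."""
    n = values.shape[0]
    bins = make_bins({"chr1": n * resolution}, resolution)
    return ContactMatrix(bins=bins, values=values.astype(float), resolution=resolution)


def uniform_matrix(n: int, value: float = 1.0, resolution: int = 100_000) -> ContactMatrix:
    vals = np.full((n, n), value)
    np.fill_diagonal(vals, 0.0)
    return matrix_from_values(vals, resolution)


@pytest.fixture(scope="session")
def plaid_map():
    """Depth-1e6 map with a planted 25-bin alternating compartment plaid."""
    e = sim.alternating_compartments(500, 25)
    params = sim.SimParams(
        n_bins=500,
        bin_size=100_000,
        decay_exponent=-1.0,
        compartment_vector=e,
        plaid_strength=0.5,
        depth=1e6,
        seed=3,
    )
    m, truth = sim.simulate_contact_map(params)
    return m, truth


@pytest.fixture(scope="session")
def tad_map():
    """Depth-2e6 map with planted 15-bin TADs (beta = 4) covering bins 10-460."""
    tads = tuple(
        (s, s + 15, 4.0) for s in range(10, 460, 15) if s + 15 <= 475
    )
    params = sim.SimParams(
        n_bins=500,
        bin_size=100_000,
        decay_exponent=-1.0,
        tad_intervals=tads,
        depth=2e6,
        seed=5,
    )
    m, truth = sim.simulate_contact_map(params)
    return m, truth


@pytest.fixture(scope="session")
def tad_map_iced(tad_map):
    m, truth = tad_map
    return ice_normalize(m), truth
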