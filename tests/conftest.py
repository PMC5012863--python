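import numpy as np
import pandas as pd
import pytest

from virtualtms import (
    Connectome,
    SimulationConfig,
    SyntheticConnectomeSpec,
    assign_frequencies,
    generate_connectome,
    node_strength,
    normalize_connectome,
)


@pytest.fixture
def tiny_conn():
    """3-region connectome with known weights AB=1, AC=2, BC=0."""
    w = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    return Connectome(w, ("A", "B", "C"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _random_symmetric(n, rng, density=1.0):
    w = rng.random((n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = mask & mask.T
        w = np.where(mask, w, 0.0)
        np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def random_conn(rng):
    w = _random_symmetric(6, rng)
    return Connectome(w, tuple("abcdef"))


@pytest.fixture(scope="session")
def toy16():
    """Small synthetic network with hub r000 and sensory r008."""
    spec = SyntheticConnectomeSpec(
        n_regions=16, n_modules=2, hub_ids=("r000",), sensory_ids=("r008",), seed=42
    )
    conn = normalize_connectome(generate_connectome(spec))
    omega = assign_frequencies(node_strength(conn))
    return conn, omega


@pytest.fixture
def fast_cfg():
    """Short simulation for unit tests of the machinery, not the science."""
    return SimulationConfig(
        coupling=0.07, dt=0.1, duration=120.0, transient=30.0,
        sampling_interval=2.0, seed=7,
    )
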