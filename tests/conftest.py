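"""Shared fixtures.

The heavyweight fixtures (the 20 000-record benchmark dataset and the
toy-profile surrogate trained on it) are session-scoped so the capability,
novelty and ranking checks share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import pepanneal as pa

#: The fixed benchmark: one landscape with default couplings, observation
#: noise of 0.5 score units and a pinned seed; 20 000 records split 80/10/10.
BENCHMARK_SEED = 2025
BENCHMARK_N = 20000


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def benchmark_landscape():
    return pa.make_landscape(seed=BENCHMARK_SEED, noise_sigma=0.5)


@pytest.fixture(scope="session")
def benchmark_splits(benchmark_landscape):
    table = pa.generate_dataset(benchmark_landscape, BENCHMARK_N, seed=BENCHMARK_SEED)
    return pa.split_table(table, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_surrogate(benchmark_splits):
    """Toy-profile LSTM trained on the benchmark (the expensive fixture)."""
    train, val, _ = benchmark_splits
    return pa.train_surrogate(train, val, pa.TOY_PROFILE)
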