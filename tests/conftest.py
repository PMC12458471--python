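"""Shared fixtures: a tiny synthetic world and a trained toy model.

Everything is generated programmatically at fixed seeds; nothing is read
from disk.
"""

import numpy as np
import pytest

import vectorhab as vh
from vectorhab.synthetic import WorldParams


@pytest.fixture(scope="session")
def tiny_world():
    """A 6x8 grid, ~4 months of days: enough for seq_len <= 10 tests."""
    params = WorldParams(n_lat=6, n_lon=8, n_days=120)
    return vh.generate_world(params, seed=11)


@pytest.fixture(scope="session")
def tiny_features(tiny_world):
    return tiny_world.features


@pytest.fixture(scope="session")
def tiny_records(tiny_world):
    presences = vh.sample_presences(tiny_world, 120, rng_seed=7, min_prior_days=10)
    absences = vh.generate_pseudo_absences(
        presences, tiny_world.grid, vh.count_absences(120, 0.2), rng_seed=8
    )
    return presences + absences


@pytest.fixture(scope="session")
def separable_data():
    """Linearly separable toy set: presences at high synthetic temperature."""
    rng = np.random.default_rng(0)
    n = 200
    X_pos = rng.normal(25.0, 2.0, size=(n, 4))
    X_neg = rng.normal(5.0, 2.0, size=(n, 4))
    X = np.vstack([X_pos, X_neg])
    y = np.r_[np.ones(n), np.zeros(n)]
    order = rng.permutation(2 * n)
    return X[order], y[order]


@pytest.fixture(scope="session")
def series_fixtures():
    return vh.make_series_fixtures()


def brute_force_diameter(series, mass=0.95):
    """Independent exhaustive scan over all (start, length) circular windows."""
    s = np.asarray(series, dtype=float)
    n = s.size
    total = s.sum()
    target = mass * total
    for length in range(1, n + 1):
        for start in range(n):
            idx = np.arange(start, start + length) % n
            if s[idx].sum() >= target - 1e-12 * total:
                return length, start + 1
    return n, 1


def exhaustive_scan_diameter(series, mass=0.95):
    """Exhaustive per-start scan: for every start day, the minimal window
    length reaching the mass target; global minimum with earliest-start
    tie-break. Covers the same (start, length) space as the double loop."""
    s = np.asarray(series, dtype=float)
    n = s.size
    total = s.sum()
    target = mass * total - 1e-12 * total
    best_len, best_start = n + 1, None
    for start in range(n):
        cum = np.cumsum(np.roll(s, -start))
        length = int(np.argmax(cum >= target)) + 1
        if length < best_len:
            best_len, best_start = length, start + 1
    return best_len, best_start
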