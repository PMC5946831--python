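"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive second implementations (exhaustive
path enumeration, recursive alignment, direct collapse) kept independent
of the package's own algorithms.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

from squigglecall import sim

BASES = "ACGT"
BLANK = 4


def collapse_path(path) -> str:
    """Independent CTC collapse: drop consecutive repeats, then blanks."""
    out = []
    prev = -1
    for s in path:
        if s != prev and s != BLANK:
            out.append(BASES[s])
        prev = s
    return "".join(out)


@lru_cache(maxsize=None)
def _all_paths(T: int) -> np.ndarray:
    return np.array(list(itertools.product(range(5), repeat=T)), dtype=int)


@lru_cache(maxsize=None)
def _collapse_table(T: int) -> tuple:
    return tuple(collapse_path(p) for p in _all_paths(T))


def posterior_by_sequence(probs: np.ndarray) -> dict[str, float]:
    """Exact posterior over collapsed sequences by enumerating all 5^T paths."""
    T = probs.shape[0]
    paths = _all_paths(T)
    masses = np.prod(probs[np.arange(T), paths], axis=1)
    acc: dict[str, float] = {}
    for seq, mass in zip(_collapse_table(T), masses):
        acc[seq] = acc.get(seq, 0.0) + float(mass)
    return acc


def brute_force_ctc(probs: np.ndarray, label: str) -> float:
    """Total path mass collapsing to ``label``: the CTC likelihood."""
    return posterior_by_sequence(probs).get(label, 0.0)


def random_prob_matrix(rng: np.random.Generator, T: int) -> np.ndarray:
    return rng.dirichlet(np.ones(5), size=T)


def reference_lstm_step(x_t, h_prev, c_prev, W_x, W_h, b, H):
    """Plain (un-normalized) LSTM step with the (f, i, o, g) gate order."""
    gates = h_prev @ W_h + x_t @ W_x + b

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    f, i, o, g = (gates[:, :H], gates[:, H:2 * H],
                  gates[:, 2 * H:3 * H], gates[:, 3 * H:])
    c_t = sig(f) * c_prev + sig(i) * np.tanh(g)
    h_t = sig(o) * np.tanh(c_t)
    return h_t, c_t


@pytest.fixture(scope="session")
def k1_model() -> sim.PoreModel:
    return sim.generate_pore_model(1, seed=11)


@pytest.fixture(scope="session")
def k5_model() -> sim.PoreModel:
    return sim.generate_pore_model(5, seed=3)
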