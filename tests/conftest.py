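"""Shared fixtures and the power-iteration fixation oracle.

The oracle iterates x <- M x from the boundary-pinned initial vector until
the update is below tolerance; it is deliberately independent of the direct
linear solves it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

import tempofix as tf


def power_iteration_fixation(
    M: np.ndarray,
    zero_states: np.ndarray,
    one_states: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 5_000_000,
) -> np.ndarray:
    """Brute-force fixation probabilities by value iteration."""
    x = np.zeros(M.shape[0])
    x[one_states] = 1.0
    for _ in range(max_iter):
        xn = M @ x
        xn[zero_states] = 0.0
        xn[one_states] = 1.0
        if np.max(np.abs(xn - x)) < tol:
            return xn
        x = xn
    raise RuntimeError("power iteration did not converge")


@pytest.fixture(scope="session")
def graphs3():
    return tf.enumerate_connected_graphs(3)


@pytest.fixture(scope="session")
def graphs4():
    return tf.enumerate_connected_graphs(4)


@pytest.fixture(scope="session")
def graphs6():
    return tf.enumerate_connected_graphs(6)


@pytest.fixture(scope="session")
def star_complete_4():
    return tf.make_star(4), tf.make_complete(4)
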