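"""Shared fixtures: reference model instances and a uniform unicycle builder."""

import numpy as np
import pytest

from topoclock import ModelParams, build_generator, steady_state


def make_unicycle(n: int, forward: float, backward: float) -> np.ndarray:
    """Generator of a single ring of n states with uniform rates.

    The uniform unicycle is the most coherent oscillator: its spectrum has
    the circulant closed form and it saturates both thermodynamic bounds.
    """
    W = np.zeros((n, n))
    for i in range(n):
        W[(i + 1) % n, i] += forward
        W[(i - 1) % n, i] += backward
    np.fill_diagonal(W, -W.sum(axis=0))
    return W


@pytest.fixture(scope="session")
def edge_params() -> ModelParams:
    """The edge-localized working point (mu=1, rho=2, gamma_tot=1, 6x6)."""
    return ModelParams(mu=1.0, rho=2.0, gamma_tot=1.0)


@pytest.fixture(scope="session")
def edge_generator(edge_params):
    return build_generator(edge_params)


@pytest.fixture(scope="session")
def edge_steady_state(edge_generator):
    return steady_state(edge_generator)
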