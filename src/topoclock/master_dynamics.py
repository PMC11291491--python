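"""Master-equation analysis: generator, steady state, spectrum, coherence.

The probability distribution ``p(t)`` over lattice states evolves by
``dp/dt = W p`` with the generator ``W`` in column convention: ``W[i, j]`` is
the rate of the transition j -> i for ``i != j`` and each diagonal entry is
minus the total exit rate of its column, so columns sum to zero and
probability is conserved.

Oscillatory relaxation is dominated by the first non-zero eigenvalue
``lambda_1 = -lambda_R + i*lambda_I`` (smallest |Re| among the non-zero
eigenvalues).  Its imaginary part sets the oscillation period
``T = 2*pi/lambda_I`` and the ratio ``R = lambda_I/lambda_R`` is the
coherence: up to a factor 2*pi, the number of oscillations completed before
stochastic dephasing damps them out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_model import ModelParams, Transition, build_transitions, enumerate_states

__all__ = [
    "RateMatrix",
    "SpectralSummary",
    "rate_matrix",
    "build_generator",
    "steady_state",
    "first_nonzero_eigenvalue",
    "coherence_and_period",
    "evolve",
    "spectrum_to_frame",
    "steady_state_to_frame",
]

#: Relative tolerance (times the rate scale) used to identify the zero
#: eigenvalue and to verify generator/steady-state residuals.
ZERO_EIG_RTOL = 1e-9

RateMatrix = np.ndarray


@dataclass
class SpectralSummary:
    """Spectrum of a generator and its slowest oscillatory mode.

    ``lambda_R >= 0`` and ``lambda_I >= 0`` parametrize the first non-zero
    eigenvalue as ``lambda_1 = -lambda_R + i*lambda_I``.
    """

    eigenvalues: np.ndarray
    lambda_R: float
    lambda_I: float

    @property
    def lambda_1(self) -> complex:
        return complex(-self.lambda_R, self.lambda_I)

    @property
    def coherence(self) -> float:
        """R = lambda_I / lambda_R; zero for a non-oscillatory mode."""
        if self.lambda_R <= 0:
            raise ValueError("lambda_R must be positive (no relaxation otherwise)")
        return self.lambda_I / self.lambda_R

    @property
    def period(self) -> float:
        """Oscillation period 2*pi/lambda_I; infinite when lambda_I = 0."""
        if self.lambda_I == 0.0:
            return float("inf")
        return 2.0 * np.pi / self.lambda_I


def rate_matrix(transitions: Sequence[Transition], n_states: int) -> RateMatrix:
    """Dense generator ``W`` with ``W[i, j]`` the rate j -> i.

    Duplicate (source, target) pairs have their rates summed (with a
    warning); diagonal entries close each column to zero.
    """
    W = np.zeros((n_states, n_states))
    seen: set[tuple[int, int]] = set()
    duplicates = 0
    for t in transitions:
        if not (0 <= t.source < n_states and 0 <= t.target < n_states):
            raise ValueError(f"transition {t} references an invalid state index")
        if t.source == t.target:
            raise ValueError(f"self-loop transition at state {t.source}")
        if t.rate <= 0:
            raise ValueError(f"non-positive rate in transition {t}")
        key = (t.source, t.target)
        if key in seen:
            duplicates += 1
        seen.add(key)
        W[t.target, t.source] += t.rate
    if duplicates:
        warnings.warn(f"{duplicates} duplicate transitions had their rates summed")
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(W, -W.sum(axis=0))
    return W


def build_generator(params: ModelParams) -> RateMatrix:
    """Generator of the topological lattice model for ``params``."""
    return rate_matrix(build_transitions(params), params.n_states)


def _rate_scale(W: RateMatrix) -> float:
    return float(np.max(np.abs(np.diag(W)))) or 1.0


def steady_state(W: RateMatrix) -> np.ndarray:
    """Unique normalized null vector of an irreducible generator.

    Solves ``W p = 0`` with the normalization row sum(p) = 1 substituted for
    the last (redundant) equation.  Raises on a reducible graph, naming the
    disconnected components.
    """
    n = W.shape[0]
    adjacency = csr_matrix((np.abs(W) > 0).astype(np.int8))
    n_comp, labels = connected_components(adjacency, directed=True, connection="strong")
    if n_comp > 1:
        members = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(
            f"generator is reducible: {n_comp} strongly connected components "
            f"with state indices {members}"
        )
    A = W.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    p = np.linalg.solve(A, b)
    scale = _rate_scale(W)
    residual = np.max(np.abs(W @ p))
    if residual > 1e-10 * scale:
        raise np.linalg.LinAlgError(
            f"steady-state residual {residual:.3e} exceeds tolerance"
        )
    if p.min() < -1e-12:
        raise np.linalg.LinAlgError("steady state has a significantly negative entry")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def first_nonzero_eigenvalue(
    W: RateMatrix, eigenvalues: np.ndarray | None = None
) -> SpectralSummary:
    """Slowest non-zero mode of the generator.

    Excludes the (numerically) zero eigenvalue, then selects the eigenvalue
    with the smallest |Re|; ties are broken in favor of the largest imaginary
    part (the oscillatory member), and of a conjugate pair the member with
    ``Im >= 0`` is reported.
    """
    if eigenvalues is None:
        eigenvalues = np.linalg.eigvals(W)
    scale = _rate_scale(W)
    tol = ZERO_EIG_RTOL * scale
    nonzero = eigenvalues[
        (np.abs(eigenvalues.real) >= tol) | (np.abs(eigenvalues.imag) >= tol)
    ]
    if nonzero.size == 0:
        raise ValueError("degenerate input: all eigenvalues are numerically zero")
    # smallest |Re| first, then largest |Im| (the oscillatory mode), then Im >= 0
    order = np.lexsort((-nonzero.imag, -np.abs(nonzero.imag), np.abs(nonzero.real)))
    lam = nonzero[order[0]]
    return SpectralSummary(
        eigenvalues=eigenvalues,
        lambda_R=float(max(-lam.real, 0.0)),
        lambda_I=float(abs(lam.imag)) if abs(lam.imag) >= tol else 0.0,
    )


def coherence_and_period(spec: SpectralSummary) -> tuple[float, float]:
    """Coherence ``R = lambda_I/lambda_R`` and period ``T = 2*pi/lambda_I``.

    A purely relaxational mode (``lambda_I = 0``) has coherence 0 and an
    undefined period, reported as ``inf``.
    """
    if spec.lambda_R <= 0:
        raise ValueError("lambda_R must be positive (no relaxation otherwise)")
    if spec.lambda_I == 0.0:
        return 0.0, float("inf")
    return spec.coherence, spec.period


def evolve(W: RateMatrix, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Probability distributions ``exp(W t) p0`` at the requested times."""
    times = np.asarray(times, dtype=float)
    out = np.empty((times.size, p0.size))
    for k, t in enumerate(times):
        out[k] = scipy.linalg.expm(W * t) @ p0
    return out


# ---------------------------------------------------------------------------
# serialization


def spectrum_to_frame(eigenvalues: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-eigenvalues.real)
    return pd.DataFrame(
        {
            "index": np.arange(eigenvalues.size),
            "re": eigenvalues.real[order],
            "im": eigenvalues.imag[order],
        }
    )


def steady_state_to_frame(p: np.ndarray, params: ModelParams) -> pd.DataFrame:
    states = enumerate_states(params.nx, params.ny)
    return pd.DataFrame(
        {
            "x": [s.x for s in states],
            "y": [s.y for s in states],
            "s": [s.s for s in states],
            "probability": p,
        }
    )
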