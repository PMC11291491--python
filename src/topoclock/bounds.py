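"""Thermodynamic bounds: cycle-affinity coherence bound and spectral ellipse.

Two conjectured bounds constrain any master-equation oscillator in terms of
its cycles.  For a cycle ``kappa`` with ``N_kappa`` states and affinity
``A_kappa`` (the log-product of forward/backward rate ratios around it), the
coherence obeys

    R <= max_kappa cot(pi / N_kappa) * tanh(A_kappa / (2 N_kappa)),

saturated by a unicyclic network with uniform rates.  The full spectrum of a
generator rescaled so that ``min_i W_ii = -1`` is conjectured to lie inside
the ellipse centered at -1 with semi-axes ``(1, tanh(A_C / (2 N_C)))``, where
``A_C / N_C`` is the maximum affinity per state over all cycles; the uniform
unicycle sits exactly on that ellipse.

For the topological lattice model every transition has forward/backward ratio
``e^mu``, so the affinity per state of *any* cycle is at most mu and the bound
maximization reduces to maximizing the cycle length.  The maximizer is the
global counterclockwise boundary cycle constructed here, which on the 6x6
lattice alternates 24 external hops with 28 internal priming steps
(``N_kappa = 52``).  The 28 internal-step source states are the slow
bottleneck of the edge current and carry the high steady-state probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    INTERNAL_PREV,
    EXTERNAL_STEP,
    INTERNAL_NEXT,
    LatticeState,
    ModelParams,
    derive_rates,
    state_index,
)
from .master_dynamics import RateMatrix

__all__ = [
    "CycleSpec",
    "EllipseBound",
    "boundary_cycle",
    "cycle_affinity",
    "coherence_bound",
    "rescale_generator",
    "spectral_ellipse_check",
    "ellipse_points",
]

#: Tolerance on the normalized ellipse-membership form.
ELLIPSE_TOL = 1e-8


@dataclass(frozen=True)
class CycleSpec:
    """A closed cycle: ordered states, length and affinity (k_B*T units)."""

    states: tuple[LatticeState, ...]
    affinity: float

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def affinity_per_state(self) -> float:
        return self.affinity / self.n

    def indices(self, nx: int, ny: int) -> list[int]:
        return [state_index(s, nx, ny) for s in self.states]


@dataclass(frozen=True)
class EllipseBound:
    """Spectral ellipse centered at -w0 with semi-axes (w0, w0*tanh(A/2N))."""

    w0: float
    affinity_per_state: float

    @property
    def semi_minor(self) -> float:
        return self.w0 * math.tanh(self.affinity_per_state / 2.0)

    def membership(self, eigenvalues: np.ndarray) -> np.ndarray:
        """Quadratic-form value; <= 1 means inside or on the ellipse."""
        x = (np.asarray(eigenvalues).real + self.w0) / self.w0
        b = self.semi_minor
        with np.errstate(divide="ignore", invalid="ignore"):
            y2 = np.where(
                b > 0,
                (np.asarray(eigenvalues).imag / b) ** 2,
                np.where(np.abs(np.asarray(eigenvalues).imag) > 0, np.inf, 0.0),
            )
        return x**2 + y2


def boundary_cycle(params: ModelParams) -> CycleSpec:
    """The unique forward counterclockwise cycle around the lattice boundary.

    Constructed by the deterministic fast-path walk: from each state take the
    external forward hop in the primed direction if it stays on the lattice,
    otherwise the internal forward step.  Starting from a boundary state this
    closes into the cycle that alternates external hops with the internal
    re-priming steps forced at the boundary (one per non-corner boundary
    position, two per corner).  Every step has forward/backward rate ratio
    ``e^mu``, so the affinity per state is exactly mu.
    """
    nx, ny = params.nx, params.ny
    rates = derive_rates(params)
    start = LatticeState(0, 0, "S")  # corner state on the cycle for any size
    states: list[LatticeState] = []
    affinity = 0.0
    current = start
    for _ in range(16 * (nx + 1) * (ny + 1) + 1):
        states.append(current)
        dx, dy = EXTERNAL_STEP[current.s]
        tx, ty = current.x + dx, current.y + dy
        if 0 <= tx <= nx and 0 <= ty <= ny:
            # external hop lands in the internal state prev(s)
            nxt = LatticeState(tx, ty, INTERNAL_PREV[current.s])
            affinity += math.log(rates.gamma_ex / rates.gamma_ex_rev)
        else:
            nxt = LatticeState(current.x, current.y, INTERNAL_NEXT[current.s])
            affinity += math.log(rates.gamma_in / rates.gamma_in_rev)
        if nxt == start:
            return CycleSpec(states=tuple(states), affinity=affinity)
        current = nxt
    raise RuntimeError("boundary walk failed to close (should be impossible)")




def cycle_affinity(W: RateMatrix, indices: list[int]) -> float:
    """Affinity ``ln prod_i W[k_{i+1}, k_i] / W[k_i, k_{i+1}]`` of a cycle.

    ``indices`` lists the states in cycle order; the edge from the last back
    to the first closes the loop.  Raises if a step of the cycle is not a
    bidirectional edge of the graph.
    """
    total = 0.0
    n = len(indices)
    for a in range(n):
        i, j = indices[a], indices[(a + 1) % n]
        fwd, back = W[j, i], W[i, j]
        if fwd <= 0 or back <= 0:
            raise ValueError(f"cycle step {i} -> {j} is not a bidirectional edge")
        total += math.log(fwd / back)
    return total


def coherence_bound(n_kappa: int, affinity: float) -> float:
    """Upper bound ``cot(pi/N) * tanh(A / (2N))`` on the coherence."""
    if n_kappa < 3:
        raise ValueError("a cycle needs at least 3 states")
    return math.tanh(affinity / (2.0 * n_kappa)) / math.tan(math.pi / n_kappa)


def rescale_generator(W: RateMatrix) -> tuple[RateMatrix, float]:
    """Rescale so that ``min_i W_ii = -1`` (equivalently max_i |W_ii| = 1).

    Returns the rescaled matrix and the scale factor applied.  Coherence is a
    ratio of eigenvalue parts and is invariant under this rescaling.
    """
    w0 = float(np.max(np.abs(np.diag(W))))
    if w0 <= 0:
        raise ValueError("generator has a zero diagonal; cannot rescale")
    return W / w0, 1.0 / w0


def spectral_ellipse_check(
    W: RateMatrix, affinity_per_state: float, eigenvalues: np.ndarray | None = None
) -> pd.DataFrame:
    """Test every eigenvalue of the rescaled generator against the ellipse.

    The generator is rescaled so ``min_i W_ii = -1`` (w0 = 1) and each
    eigenvalue is checked against the closed ellipse with semi-axes
    ``(1, tanh(A/2N))`` centered at -1.  Returns a table with the rescaled
    eigenvalue, the inside flag (within ``ELLIPSE_TOL``) and the signed
    distance ``m - 1`` of the membership form.
    """
    Wr, _ = rescale_generator(W)
    if eigenvalues is None:
        eigenvalues = np.linalg.eigvals(Wr)
    else:
        _, factor = rescale_generator(W)
        eigenvalues = np.asarray(eigenvalues) * factor
    bound = EllipseBound(w0=1.0, affinity_per_state=affinity_per_state)
    m = bound.membership(eigenvalues)
    return pd.DataFrame(
        {
            "re": eigenvalues.real,
            "im": eigenvalues.imag,
            "inside": m <= 1.0 + ELLIPSE_TOL,
            "signed_distance": m - 1.0,
        }
    )


def ellipse_points(affinity_per_state: float, w0: float = 1.0, n: int = 512) -> np.ndarray:
    """Parametric polyline ``g(x)`` of the bounding ellipse for plotting."""
    x = np.linspace(0.0, 1.0, n, endpoint=True)
    b = math.tanh(affinity_per_state / 2.0)
    return w0 * (-1.0 + np.cos(2 * np.pi * x) + 1j * b * np.sin(2 * np.pi * x))
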