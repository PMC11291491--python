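"""State space and transition graph of the topological lattice oscillator.

The model describes a single KaiC hexamer as a continuous-time Markov chain on
a two-dimensional lattice of phosphorylation counts.  A configuration is
``(x, y)_s`` where ``x`` counts phosphorylated T-sites (0..Nx), ``y`` counts
phosphorylated S-sites (0..Ny) and the internal compass state
``s in {N, E, S, W}`` labels which (de)phosphorylation step the molecule is
primed for next.

Two families of transitions connect the states:

* *external* transitions change the phosphorylation level by one step in the
  compass direction ``s`` (E: x+1, N: y+1, W: x-1, S: y-1) at rate
  ``gamma_ex`` (reverse ``gamma_ex_rev``);
* *internal* transitions re-prime the molecule by cycling the compass state
  E -> N -> W -> S -> E at rate ``gamma_in`` (reverse ``gamma_in_rev``),
  representing conformational changes, KaiA/KaiB interaction and nucleotide
  exchange at fixed phosphorylation level.

The four rates derive from three physical parameters: the thermodynamic force
``mu`` (in units of k_B*T, with k_B*T = 1 throughout) biasing every forward
transition, the timescale ratio ``rho = ln(gamma_ex / gamma_in)`` and the
overall rate scale ``gamma_tot``.  ``rho > 0`` is the topological regime in
which the steady state localizes on the lattice boundary and a chiral edge
current emerges.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPASS",
    "INTERNAL_NEXT",
    "INTERNAL_PREV",
    "EXTERNAL_STEP",
    "ModelParams",
    "RateSet",
    "LatticeState",
    "Transition",
    "derive_rates",
    "enumerate_states",
    "state_index",
    "build_transitions",
    "is_boundary",
    "boundary_mask",
    "transitions_to_frame",
    "write_transitions",
    "read_params",
    "write_params",
]

#: Compass states in their canonical (serialization) order.
COMPASS: tuple[str, ...] = ("N", "E", "S", "W")

#: Forward internal cycle E -> N -> W -> S -> E (counterclockwise priming).
INTERNAL_NEXT: dict[str, str] = {"E": "N", "N": "W", "W": "S", "S": "E"}
INTERNAL_PREV: dict[str, str] = {v: k for k, v in INTERNAL_NEXT.items()}

#: Unit lattice displacement of the external hop primed by each compass state.
EXTERNAL_STEP: dict[str, tuple[int, int]] = {
    "E": (1, 0),
    "N": (0, 1),
    "W": (-1, 0),
    "S": (0, -1),
}

# exp() overflows IEEE doubles just above 709; reject before that point so the
# failure mode is an explicit message rather than inf rates.
_EXP_LIMIT = 700.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the topological lattice model.

    Parameters
    ----------
    mu : float
        Thermodynamic force per transition in units of k_B*T.  ``mu = 0`` is
        detailed balance; positive ``mu`` biases the forward direction of
        every transition by ``e^mu``.
    rho : float
        Log-ratio of external to internal rates, ``ln(gamma_ex/gamma_in)``.
        ``rho > 0`` is the topological regime.
    gamma_tot : float
        Total rate scale; the four microscopic rates sum to this value.
    nx, ny : int
        Maximum T- and S-phosphorylation counts.  A KaiC hexamer has
        ``nx = ny = 6`` (six monomers, one T- and one S-site each).
    """

    mu: float
    rho: float
    gamma_tot: float = 1.0
    nx: int = 6
    ny: int = 6

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.rho)):
            raise ValueError("mu and rho must be finite reals")
        if not (math.isfinite(self.gamma_tot) and self.gamma_tot > 0):
            raise ValueError("gamma_tot must be a positive finite real")
        if int(self.nx) != self.nx or int(self.ny) != self.ny:
            raise ValueError("nx and ny must be integers")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")

    @property
    def n_states(self) -> int:
        return 4 * (self.nx + 1) * (self.ny + 1)


@dataclass(frozen=True)
class RateSet:
    """The four microscopic rates derived from (mu, rho, gamma_tot)."""

    gamma_ex: float
    gamma_ex_rev: float
    gamma_in: float
    gamma_in_rev: float

    def as_dict(self) -> dict[str, float]:
        return {
            "gamma_ex": self.gamma_ex,
            "gamma_ex_rev": self.gamma_ex_rev,
            "gamma_in": self.gamma_in,
            "gamma_in_rev": self.gamma_in_rev,
        }


class LatticeState(NamedTuple):
    """One configuration ``(x, y)_s`` of the lattice model."""

    x: int
    y: int
    s: str


@dataclass(frozen=True)
class Transition:
    """A directed transition between state indices with a positive rate."""

    source: int
    target: int
    rate: float
    kind: str  # internal_fwd | internal_rev | external_fwd | external_rev


def derive_rates(params: ModelParams) -> RateSet:
    """Derive the four transition rates from ``(mu, rho, gamma_tot)``.

    The defining relations are ``gamma_ex/gamma_ex_rev = gamma_in/gamma_in_rev
    = e^mu``, ``gamma_ex/gamma_in = gamma_ex_rev/gamma_in_rev = e^rho`` and
    ``gamma_ex + gamma_ex_rev + gamma_in + gamma_in_rev = gamma_tot``, whose
    unique solution is ``gamma_in_rev = gamma_tot / ((1+e^mu)(1+e^rho))`` with
    the other three rates scaled up by ``e^mu``, ``e^rho`` and ``e^(mu+rho)``.
    """
    if abs(params.mu) + abs(params.rho) > _EXP_LIMIT:
        raise ValueError(
            f"|mu| + |rho| = {abs(params.mu) + abs(params.rho):g} exceeds the "
            f"floating-point overflow limit ({_EXP_LIMIT:g}) for e^(mu+rho)"
        )
    emu = math.exp(params.mu)
    erho = math.exp(params.rho)
    gamma_in_rev = params.gamma_tot / ((1.0 + emu) * (1.0 + erho))
    rates = RateSet(
        gamma_ex=gamma_in_rev * emu * erho,
        gamma_ex_rev=gamma_in_rev * erho,
        gamma_in=gamma_in_rev * emu,
        gamma_in_rev=gamma_in_rev,
    )
    if not all(math.isfinite(r) and r > 0 for r in rates.as_dict().values()):
        raise ValueError(
            f"derived rates are not representable for mu={params.mu}, rho={params.rho}"
        )
    return rates


def enumerate_states(nx: int, ny: int) -> list[LatticeState]:
    """All ``4*(nx+1)*(ny+1)`` states in lexicographic (x, y, s) order.

    The compass coordinate uses the fixed order ``(N, E, S, W)`` so the
    enumeration (and therefore every serialized index) is stable across runs.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    return [
        LatticeState(x, y, s)
        for x in range(nx + 1)
        for y in range(ny + 1)
        for s in COMPASS
    ]


def state_index(state: LatticeState, nx: int, ny: int) -> int:
    """Index of ``state`` in the :func:`enumerate_states` ordering."""
    if not (0 <= state.x <= nx and 0 <= state.y <= ny):
        raise ValueError(f"state {state} outside lattice [0,{nx}]x[0,{ny}]")
    return (state.x * (ny + 1) + state.y) * 4 + COMPASS.index(state.s)


def is_boundary(state: LatticeState, nx: int, ny: int) -> bool:
    """Whether a state sits on the geometric boundary of the lattice."""
    return state.x in (0, nx) or state.y in (0, ny)


def boundary_mask(nx: int, ny: int) -> np.ndarray:
    """Boolean per-state mask of boundary membership, in enumeration order."""
    return np.array([is_boundary(s, nx, ny) for s in enumerate_states(nx, ny)])


def build_transitions(params: ModelParams) -> list[Transition]:
    """All directed transitions of the lattice model.

    Internal transitions cycle the compass state within each ``(x, y)``:
    forward E -> N -> W -> S -> E at ``gamma_in`` and the reverse at
    ``gamma_in_rev``.  An external forward transition moves one lattice step in
    the primed direction ``s`` and lands in the internal state ``prev(s)`` —
    the state whose forward internal step re-primes the move just made — at
    rate ``gamma_ex``; its reverse runs at ``gamma_ex_rev``.  This landing
    convention makes external plaquette loops clockwise and internal loops
    counterclockwise.  External hops that would leave the lattice are absent
    together with their reverses, so the graph stays reversible and ``mu = 0``
    is a true equilibrium.
    """
    rates = derive_rates(params)
    nx, ny = params.nx, params.ny
    transitions: list[Transition] = []
    for state in enumerate_states(nx, ny):
        i = state_index(state, nx, ny)
        # internal forward and reverse within the plaquette (x, y)
        fwd = LatticeState(state.x, state.y, INTERNAL_NEXT[state.s])
        rev = LatticeState(state.x, state.y, INTERNAL_PREV[state.s])
        transitions.append(
            Transition(i, state_index(fwd, nx, ny), rates.gamma_in, "internal_fwd")
        )
        transitions.append(
            Transition(i, state_index(rev, nx, ny), rates.gamma_in_rev, "internal_rev")
        )
        # external hop in the primed direction, if it stays on the lattice
        dx, dy = EXTERNAL_STEP[state.s]
        tx, ty = state.x + dx, state.y + dy
        if 0 <= tx <= nx and 0 <= ty <= ny:
            target = LatticeState(tx, ty, INTERNAL_PREV[state.s])
            j = state_index(target, nx, ny)
            transitions.append(Transition(i, j, rates.gamma_ex, "external_fwd"))
            transitions.append(Transition(j, i, rates.gamma_ex_rev, "external_rev"))
    return transitions


# ---------------------------------------------------------------------------
# serialization


def transitions_to_frame(transitions: Iterable[Transition]) -> pd.DataFrame:
    """Transition list as a 4-column table (source, target, rate, kind)."""
    return pd.DataFrame(
        [(t.source, t.target, t.rate, t.kind) for t in transitions],
        columns=["source_index", "target_index", "rate", "kind"],
    )


def write_transitions(transitions: Iterable[Transition], path) -> None:
    transitions_to_frame(transitions).to_csv(path, index=False, sep="\t")


def read_params(path) -> ModelParams:
    """Read model parameters from a flat JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    known = {"mu", "rho", "gamma_tot", "nx", "ny"}
    extra = set(raw) - known
    if extra:
        warnings.warn(f"ignoring unknown config keys: {sorted(extra)}")
    return ModelParams(**{k: raw[k] for k in known if k in raw})


def write_params(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "mu": params.mu,
                "rho": params.rho,
                "gamma_tot": params.gamma_tot,
                "nx": params.nx,
                "ny": params.ny,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
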