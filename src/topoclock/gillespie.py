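"""Stochastic trajectory simulation of the lattice model (Gillespie algorithm).

Exact continuous-time sampling: in each step the waiting time is exponential
with the current state's total exit rate, and the next state is drawn with
probability proportional to the outgoing rates.  The steady-state occupancy
estimate is the fraction of *time* (not visits) spent in each state, which
converges to the algebraic steady state as the trajectory grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ModelParams, Transition, build_transitions, enumerate_states

__all__ = [
    "Trajectory",
    "simulate",
    "simulate_chain",
    "occupancy",
    "total_variation",
    "winding_loops",
    "trajectory_to_frame",
]


@dataclass
class Trajectory:
    """A sampled path: visited state indices and their entry times.

    ``states[k]`` is entered at ``times[k]``; the recorded duration ends at
    the entry time of the final state, so the last entry carries no dwell
    and occupancy estimates use the first ``len(states) - 1`` dwells.
    """

    states: np.ndarray
    times: np.ndarray
    seed: int | None
    n_states: int

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @property
    def n_steps(self) -> int:
        return self.states.size - 1


def _transition_tables(
    transitions: list[Transition], n_states: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state exit rates, padded target table and cumulative probabilities."""
    targets: list[list[int]] = [[] for _ in range(n_states)]
    rates: list[list[float]] = [[] for _ in range(n_states)]
    for t in transitions:
        targets[t.source].append(t.target)
        rates[t.source].append(t.rate)
    max_deg = max(len(ts) for ts in targets)
    target_tab = np.zeros((n_states, max_deg), dtype=np.int64)
    cum_tab = np.ones((n_states, max_deg))
    exit_rates = np.zeros(n_states)
    for i in range(n_states):
        r = np.array(rates[i])
        if r.size == 0 or r.sum() <= 0:
            raise ValueError(f"state {i} is absorbing (zero exit rate)")
        exit_rates[i] = r.sum()
        cum = np.cumsum(r) / r.sum()
        target_tab[i, : r.size] = targets[i]
        cum_tab[i, : r.size] = cum
        cum_tab[i, r.size:] = 1.0
        target_tab[i, r.size:] = targets[i][-1]
    return exit_rates, target_tab, cum_tab


def simulate_chain(
    transitions: list[Transition],
    n_states: int,
    n_steps: int,
    seed: int | None = None,
    initial_state: int | None = None,
) -> Trajectory:
    """Sample a trajectory of ``n_steps`` reactions of an arbitrary chain.

    The initial condition is uniform over all states (seed-controlled) unless
    ``initial_state`` is given.  Identical seeds give identical trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_states
    exit_rates, target_tab, cum_tab = _transition_tables(transitions, n)

    state = (
        int(rng.integers(n)) if initial_state is None else int(initial_state)
    )
    if not 0 <= state < n:
        raise ValueError(f"initial state {state} out of range")
    states = np.empty(n_steps + 1, dtype=np.int64)
    dwells = np.empty(n_steps)
    states[0] = state
    block = 1 << 16
    pos = block  # force an initial draw
    u_exp = u_choice = None
    for k in range(n_steps):
        if pos >= block:
            u_exp = rng.exponential(size=block)
            u_choice = rng.random(size=block)
            pos = 0
        dwells[k] = u_exp[pos] / exit_rates[state]
        state = int(
            target_tab[state, np.searchsorted(cum_tab[state], u_choice[pos], side="right")]
        )
        pos += 1
        states[k + 1] = state
    times = np.concatenate(([0.0], np.cumsum(dwells)))
    return Trajectory(states=states, times=times, seed=seed, n_states=n)


def simulate(
    params: ModelParams,
    n_steps: int,
    seed: int | None = None,
    initial_state: int | None = None,
) -> Trajectory:
    """Sample a trajectory of the topological lattice model."""
    return simulate_chain(
        build_transitions(params), params.n_states, n_steps, seed, initial_state
    )


def occupancy(traj: Trajectory) -> np.ndarray:
    """Time-weighted state occupancy; sums to 1."""
    if traj.duration <= 0:
        raise ValueError("trajectory has zero duration")
    dwells = np.diff(traj.times)
    occ = np.zeros(traj.n_states)
    np.add.at(occ, traj.states[:-1], dwells)
    return occ / occ.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two distributions."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def winding_loops(
    traj: Trajectory, params: ModelParams, min_radius: float = 2.0
) -> tuple[int, int]:
    """Counts of positive (counterclockwise) and negative loops around the
    lattice center.

    Tracks the unwrapped polar angle of ``(x - nx/2, y - ny/2)`` along the
    trajectory and counts a loop only when a full 2*pi excursion from the
    last counted level completes, so diffusive re-crossings of a single level
    do not register.  Lattice positions within ``min_radius`` of the center
    are excluded from the angle series: a hop past the center flips the angle
    by ~pi with an arbitrary sign, which would otherwise register as spurious
    half-loops.  In the topological regime the edge current makes the
    positive count dominate.
    """
    states = enumerate_states(params.nx, params.ny)
    xs = np.array([s.x for s in states], dtype=float)[traj.states]
    ys = np.array([s.y for s in states], dtype=float)[traj.states]
    cx, cy = params.nx / 2.0, params.ny / 2.0
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    ok = r >= max(min_radius, 1e-9)
    if not ok.any():
        return 0, 0
    ang = np.arctan2(dy[ok], dx[ok])
    unwrapped = np.unwrap(ang)
    q = (unwrapped - unwrapped[0]) / (2.0 * np.pi)
    # hysteresis counting needs only the points where q crosses an integer
    levels = np.floor(q).astype(int)
    events = np.flatnonzero(np.diff(levels) != 0) + 1
    pos = neg = 0
    ref = 0.0
    for v in q[events]:
        while v - ref >= 1.0:
            pos += 1
            ref += 1.0
        while v - ref <= -1.0:
            neg += 1
            ref -= 1.0
    return pos, neg


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame({"time": traj.times, "state_index": traj.states})
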