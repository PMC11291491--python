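"""Comparison oscillators: an MWC-type ring and a bilayer lattice model.

Both serve as baselines for the coherence of the topological lattice model
and expose the same generator interface so every analysis operation (spectrum,
coherence, entropy production, bounds) applies unchanged.  They are
reconstructions built from the structural descriptions of the originals:
the published definitions are not reproduced in full detail here, so all
quantitative comparisons against them are property-based (bounds and
orderings), never exact values.

**MWC-type model.**  A KaiC hexamer with concerted (all-or-none)
conformational state: the molecule is either in the phosphorylation-prone
conformation (n = 0..6 phosphorylated monomers, phosphorylating upward) or in
the dephosphorylation-prone conformation (dephosphorylating downward), with
conformational switches at the fully phosphorylated and fully
dephosphorylated ends.  This is a unicyclic network of 2*(n_sites+1) = 14
states.  Parameters: a rate scale ``gamma``, a conformational energy ``E``
(k_B*T) that tilts the landscape (each conformation is strained in
proportion to how far its phosphorylation level is from its preferred end),
and a chemical driving ``eta`` (k_B*T) of which each of the 12 chemical
steps dissipates ``eta/2``.  The switches are energetically balanced, so the
cycle affinity is ``6*eta`` and the maximum affinity per state is
``(3/7)*eta``; at ``eta = 0`` every cycle is balanced and the model is at
equilibrium.

**Bilayer lattice model.**  Two congruent (nx+1) x (ny+1) phosphorylation
lattices for free and KaiB-bound KaiC.  The free layer phosphorylates (x+1
and y+1 moves at ``gamma_ex`` forward, ``gamma_ex_rev`` reverse), the bound
layer dephosphorylates (x-1 and y-1 moves), and vertical layer switches run
at the internal rates with the bias split across the anti-diagonal: KaiB
binding is forward-favored (``gamma_in`` against ``gamma_in_rev``) on the
upper-right half ``x + y > (nx+ny)/2`` and unbinding forward-favored on the
lower-left half.  Every edge has forward/backward ratio ``e^mu``, so mu = 0
is detailed balance and the maximum affinity per state is mu, attained on
the longest forward cycle (up through one layer, down the other:
``2*(nx+ny) + 2`` states).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ModelParams, derive_rates
from .master_dynamics import (
    RateMatrix,
    coherence_and_period,
    first_nonzero_eigenvalue,
)
from .bounds import boundary_cycle, coherence_bound

__all__ = [
    "MWCParams",
    "BilayerParams",
    "build_mwc",
    "mwc_cycle_indices",
    "build_bilayer",
    "bilayer_max_cycle",
    "model_bound",
    "sample_and_compare",
    "bound_curves",
]


@dataclass(frozen=True)
class MWCParams:
    """MWC-ring parameters: rate scale, conformational energy, driving."""

    gamma: float
    energy: float
    eta: float
    n_sites: int = 6

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def n_states(self) -> int:
        return 2 * (self.n_sites + 1)


@dataclass(frozen=True)
class BilayerParams:
    """Bilayer-lattice parameters, sharing the (mu, rho) parametrization."""

    mu: float
    rho: float
    gamma_tot: float = 1.0
    nx: int = 6
    ny: int = 6

    @property
    def n_states(self) -> int:
        return 2 * (self.nx + 1) * (self.ny + 1)


def mwc_cycle_indices(params: MWCParams) -> list[int]:
    """State indices of the single cycle in ring order.

    States 0..n_sites are the phosphorylating conformation at levels
    0..n_sites; states n_sites+1..2*n_sites+1 are the dephosphorylating
    conformation at levels n_sites..0.
    """
    n = params.n_sites
    return list(range(2 * n + 2))


def build_mwc(params: MWCParams) -> RateMatrix:
    """Generator of the 2*(n_sites+1)-state MWC-type ring."""
    n = params.n_sites
    n_states = params.n_states
    # state energies: conformation A prefers low, B prefers high phosphorylation
    energies = np.empty(n_states)
    energies[: n + 1] = params.energy * np.arange(n + 1) / n
    energies[n + 1 :] = params.energy * (n - np.arange(n, -1, -1)) / n
    # ring order: A0 .. A6, B6 .. B0, back to A0
    W = np.zeros((n_states, n_states))
    ring = mwc_cycle_indices(params)
    for a in range(n_states):
        i, j = ring[a], ring[(a + 1) % n_states]
        dE = energies[j] - energies[i]
        # chemical steps carry driving eta/2; the two switches are balanced
        drive = 0.0 if a in (n, 2 * n + 1) else params.eta / 2.0
        W[j, i] += params.gamma * math.exp((drive - dE) / 2.0)
        W[i, j] += params.gamma * math.exp((-drive + dE) / 2.0)
    np.fill_diagonal(W, -W.sum(axis=0))
    return W


def build_bilayer(params: BilayerParams) -> RateMatrix:
    """Generator of the two-layer phosphorylation lattice."""
    rates = derive_rates(
        ModelParams(params.mu, params.rho, params.gamma_tot, params.nx, params.ny)
    )
    nx, ny = params.nx, params.ny
    n_cells = (nx + 1) * (ny + 1)

    def idx(layer: int, x: int, y: int) -> int:
        return layer * n_cells + x * (ny + 1) + y

    W = np.zeros((params.n_states, params.n_states))
    for x in range(nx + 1):
        for y in range(ny + 1):
            # layer 0 (free KaiC) phosphorylates forward
            for dx, dy in ((1, 0), (0, 1)):
                tx, ty = x + dx, y + dy
                if tx <= nx and ty <= ny:
                    W[idx(0, tx, ty), idx(0, x, y)] += rates.gamma_ex
                    W[idx(0, x, y), idx(0, tx, ty)] += rates.gamma_ex_rev
            # layer 1 (KaiB-bound) dephosphorylates forward
            for dx, dy in ((-1, 0), (0, -1)):
                tx, ty = x + dx, y + dy
                if tx >= 0 and ty >= 0:
                    W[idx(1, tx, ty), idx(1, x, y)] += rates.gamma_ex
                    W[idx(1, x, y), idx(1, tx, ty)] += rates.gamma_ex_rev
            # layer switches: binding forward-favored on the upper-right half
            upper_right = (x + y) > (nx + ny) / 2.0
            bind, unbind = (
                (rates.gamma_in, rates.gamma_in_rev)
                if upper_right
                else (rates.gamma_in_rev, rates.gamma_in)
            )
            W[idx(1, x, y), idx(0, x, y)] += bind
            W[idx(0, x, y), idx(1, x, y)] += unbind
    np.fill_diagonal(W, -W.sum(axis=0))
    return W


def bilayer_max_cycle(params: BilayerParams) -> tuple[int, float]:
    """(N, affinity) of the longest uniformly forward cycle of the bilayer.

    Up one layer from (0,0) to (nx,ny), bind, down the other, unbind:
    ``2*(nx+ny) + 2`` states, every step with ratio e^mu.
    """
    n = 2 * (params.nx + params.ny) + 2
    return n, n * params.mu


def model_bound(model: str, force_per_state: float, nx: int = 6, ny: int = 6) -> float:
    """Cycle-affinity coherence bound for one of the three models.

    ``force_per_state`` is the thermodynamic force per state A/N (equal to mu
    for the lattice models and to (3/7)*eta for the MWC ring).
    """
    if model == "topological":
        n = boundary_cycle(ModelParams(mu=1.0, rho=1.0, nx=nx, ny=ny)).n
    elif model == "bilayer":
        n, _ = bilayer_max_cycle(BilayerParams(mu=1.0, rho=1.0, nx=nx, ny=ny))
    elif model == "mwc":
        n = MWCParams(gamma=1.0, energy=1.0, eta=1.0).n_states
    elif model == "unicycle28":
        n = 28
    else:
        raise ValueError(f"unknown model {model!r}")
    return coherence_bound(n, n * force_per_state)


def sample_and_compare(n_samples: int, seed: int | None = None) -> pd.DataFrame:
    """Random-parameter coherence comparison of the three models.

    Samples ``mu ~ U[0, 10]`` and ``rho ~ U[0, 7]`` for the topological and
    bilayer models and ``gamma ~ U[3, 7]``, ``E ~ U[5, 15]``,
    ``eta ~ U[0, 70/3]`` for the MWC ring (so its force per state
    ``(3/7)*eta`` covers the same [0, 10] range).  Returns one row per sample
    with the model name, raw parameters, thermodynamic force per state, and
    coherence.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_samples):
        mu, rho = rng.uniform(0.0, 10.0), rng.uniform(0.0, 7.0)
        mu_b, rho_b = rng.uniform(0.0, 10.0), rng.uniform(0.0, 7.0)
        gamma = rng.uniform(3.0, 7.0)
        energy = rng.uniform(5.0, 15.0)
        eta = rng.uniform(0.0, 70.0 / 3.0)

        from .master_dynamics import build_generator

        for model, W, force, parlist in (
            (
                "topological",
                build_generator(ModelParams(mu=mu, rho=rho)),
                mu,
                {"mu": mu, "rho": rho},
            ),
            (
                "bilayer",
                build_bilayer(BilayerParams(mu=mu_b, rho=rho_b)),
                mu_b,
                {"mu": mu_b, "rho": rho_b},
            ),
            (
                "mwc",
                build_mwc(MWCParams(gamma=gamma, energy=energy, eta=eta)),
                3.0 * eta / 7.0,
                {"gamma": gamma, "energy": energy, "eta": eta},
            ),
        ):
            spec = first_nonzero_eigenvalue(W)
            R, _ = coherence_and_period(spec)
            rows.append({"model": model, "force_per_state": force, "coherence": R, **parlist})
    return pd.DataFrame(rows)


def bound_curves(force_grid: np.ndarray) -> pd.DataFrame:
    """Coherence-bound curves of all models over a force-per-state grid."""
    rows = []
    for model in ("topological", "bilayer", "mwc", "unicycle28"):
        for f in np.asarray(force_grid, dtype=float):
            rows.append(
                {"model": model, "force_per_state": f, "bound": model_bound(model, f)}
            )
    return pd.DataFrame(rows)
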