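"""Non-equilibrium thermodynamics: entropy production and cost-precision.

The free-energy cost of maintaining the oscillation is quantified by the
entropy production per period,

    Delta_S = (T/2) * sum_ij (p_j W_ij - p_i W_ji) * ln(p_j W_ij / (p_i W_ji)),

in units of k_B (with rates measured in units of gamma_tot, Delta_S per period
is invariant under rescaling the overall timescale).  Each summand is the net
probability flux on an edge times its thermodynamic force, so Delta_S >= 0
with equality exactly at detailed balance (mu = 0).

Assigning each edge's summand to the lattice boundary (both endpoint states
with x in {0, nx} or y in {0, ny}) or to the bulk splits Delta_S into edge and
bulk parts.  In the topological regime the steady state localizes onto the
boundary as the driving mu grows, so the bulk part — which normally dominates,
O(N^2) edges against O(N) — falls while the edge part rises, producing a
regime where stronger driving dissipates *less* per cycle while coherence
still rises.  The ratio Delta_S / R measures the cost of precision; its global
minimum over (mu, rho) identifies the most efficient oscillator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ModelParams, boundary_mask, build_transitions
from .master_dynamics import (
    RateMatrix,
    build_generator,
    coherence_and_period,
    first_nonzero_eigenvalue,
    rate_matrix,
    steady_state,
)

__all__ = [
    "EntropyDecomposition",
    "entropy_production_rate",
    "entropy_production_per_period",
    "decompose_entropy",
    "scan_phase_diagram",
    "find_cost_precision_optimum",
    "grid",
]

#: Below this (relative to the rate scale) the entropy production rate of a
#: non-oscillating chain is treated as exactly zero.
_EQUILIBRIUM_RTOL = 1e-12


@dataclass(frozen=True)
class EntropyDecomposition:
    """Entropy production per period split into edge and bulk parts (k_B)."""

    delta_S: float
    delta_S_edge: float
    delta_S_bulk: float


def _pairwise_terms(W: RateMatrix, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-ordered-pair entropy terms and the off-diagonal adjacency mask.

    Raises if the graph has a one-way edge (W_ij > 0 with W_ji = 0), for
    which the entropy production is ill-defined.
    """
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    adj = (W > 0) & off
    if not np.array_equal(adj, adj.T):
        i, j = np.argwhere(adj & ~adj.T)[0]
        raise ValueError(
            f"one-way edge {j} -> {i}: entropy production is undefined "
            "for a graph that is not reversible"
        )
    flux = W * p[np.newaxis, :]  # flux[i, j] = p_j W_ij
    terms = np.zeros_like(W)
    both = adj & (flux > 0) & (flux.T > 0)
    terms[both] = (flux[both] - flux.T[both]) * np.log(flux[both] / flux.T[both])
    # pairs where one steady-state flux vanishes (p = 0 on an endpoint)
    # contribute 0 by the convention 0*log(0) = 0
    return terms, adj


def entropy_production_rate(W: RateMatrix, p: np.ndarray) -> float:
    """Steady-state entropy production rate, in k_B per unit time."""
    terms, _ = _pairwise_terms(W, p)
    return float(terms.sum()) / 2.0


def entropy_production_per_period(W: RateMatrix, p: np.ndarray, period: float) -> float:
    """Entropy production per oscillation period (k_B).

    At detailed balance the period is infinite but the rate is zero; that
    limit is reported as exactly 0.
    """
    rate = entropy_production_rate(W, p)
    scale = float(np.max(np.abs(np.diag(W))))
    if not np.isfinite(period):
        if rate <= _EQUILIBRIUM_RTOL * scale:
            return 0.0
        raise ValueError("infinite period with non-zero entropy production rate")
    return period * rate


def decompose_entropy(
    W: RateMatrix, p: np.ndarray, period: float, params: ModelParams
) -> EntropyDecomposition:
    """Split the entropy production per period into edge and bulk parts.

    An edge of the transition graph is assigned to the lattice boundary iff
    *both* endpoint states lie on it; everything else counts as bulk.  The two
    parts sum to the total by construction.
    """
    terms, _ = _pairwise_terms(W, p)
    on_edge = boundary_mask(params.nx, params.ny)
    pair_on_edge = on_edge[:, np.newaxis] & on_edge[np.newaxis, :]
    rate_edge = float(terms[pair_on_edge].sum()) / 2.0
    rate_bulk = float(terms[~pair_on_edge].sum()) / 2.0
    scale = float(np.max(np.abs(np.diag(W))))
    if not np.isfinite(period):
        if rate_edge + rate_bulk <= _EQUILIBRIUM_RTOL * scale:
            return EntropyDecomposition(0.0, 0.0, 0.0)
        raise ValueError("infinite period with non-zero entropy production rate")
    return EntropyDecomposition(
        delta_S=period * (rate_edge + rate_bulk),
        delta_S_edge=period * rate_edge,
        delta_S_bulk=period * rate_bulk,
    )


def grid(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive-of-endpoint arithmetic grid, robust to float step error."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def scan_phase_diagram(
    mu_grid: np.ndarray,
    rho_grid: np.ndarray,
    gamma_tot: float = 1.0,
    nx: int = 6,
    ny: int = 6,
    allow_trivial: bool = False,
) -> pd.DataFrame:
    """Coherence, entropy production and cost-precision over a (mu, rho) grid.

    Returns one row per grid cell with columns ``mu, rho, coherence, delta_S,
    delta_S_edge, delta_S_bulk, cost_precision``.  Cells with a purely
    relaxational slowest mode (lambda_I = 0, e.g. mu = 0) get coherence 0 and
    ``cost_precision = inf``.  Negative rho (the trivial regime) is rejected
    unless ``allow_trivial`` is set.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if not allow_trivial and np.any(rho_grid <= 0):
        raise ValueError(
            "rho <= 0 is the trivial regime; pass allow_trivial=True to scan it"
        )
    # the transition graph is fixed across the grid; only the four rates
    # change, so precompute the index structure once
    from .core_model import derive_rates

    template = ModelParams(mu=0.0, rho=0.0, gamma_tot=gamma_tot, nx=nx, ny=ny)
    trans = build_transitions(template)
    src = np.array([t.source for t in trans])
    tgt = np.array([t.target for t in trans])
    kind_names = ["external_fwd", "external_rev", "internal_fwd", "internal_rev"]
    kind_code = np.array([kind_names.index(t.kind) for t in trans])
    n = template.n_states
    rows = []
    for mu in mu_grid:
        for rho in rho_grid:
            params = ModelParams(mu=mu, rho=rho, gamma_tot=gamma_tot, nx=nx, ny=ny)
            r = derive_rates(params)
            per_kind = np.array(
                [r.gamma_ex, r.gamma_ex_rev, r.gamma_in, r.gamma_in_rev]
            )
            W = np.zeros((n, n))
            np.add.at(W, (tgt, src), per_kind[kind_code])
            np.fill_diagonal(W, -W.sum(axis=0))
            p = steady_state(W)
            spec = first_nonzero_eigenvalue(W)
            R, period = coherence_and_period(spec)
            dec = decompose_entropy(W, p, period, params)
            rows.append(
                (
                    mu,
                    rho,
                    R,
                    dec.delta_S,
                    dec.delta_S_edge,
                    dec.delta_S_bulk,
                    dec.delta_S / R if R > 0 else float("inf"),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mu",
            "rho",
            "coherence",
            "delta_S",
            "delta_S_edge",
            "delta_S_bulk",
            "cost_precision",
        ],
    )


def find_cost_precision_optimum(diagram: pd.DataFrame) -> tuple[float, float, float]:
    """(mu*, rho*, min) of Delta_S / R over a phase-diagram table.

    Non-finite cells (flagged non-oscillatory points) are excluded with a
    warning.
    """
    finite = np.isfinite(diagram["cost_precision"].to_numpy())
    if not finite.all():
        warnings.warn(
            f"excluding {int((~finite).sum())} non-finite cost-precision cells"
        )
    sub = diagram[finite]
    if sub.empty:
        raise ValueError("no finite cost-precision cells in the diagram")
    row = sub.loc[sub["cost_precision"].idxmin()]
    return float(row["mu"]), float(row["rho"]), float(row["cost_precision"])
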