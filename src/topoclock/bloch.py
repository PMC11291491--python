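"""Reciprocal-space analysis: Bloch bands, spectral gaps, and the Zak phase.

On the infinite (bulk) lattice the generator is translation-invariant with a
four-state unit cell (the compass states), so it block-diagonalizes into 4x4
Bloch matrices ``W(kx, ky)`` over the Brillouin zone ``[-pi, pi)^2``.
Internal transitions act within the unit cell; an external hop with unit
displacement ``d`` picks up the phase ``e^(-i k.d)``.  The four eigenvalue
branches form the band structure; the gaps

    Delta_I / Delta_R = min_k(top band) - max_k(second band)

of the imaginary/real parts measure the isolation of the slow oscillatory
band, and Delta_I is an accurate predictor of the coherence of the finite
lattice.

The topological invariant is the 2D Zak phase: the pair of Wilson-loop
(Berry) phases of the steady-state band — the band continuously connected to
the zero eigenvalue at k = 0 — along straight loops in kx and in ky.  Since
``W(k)`` is not normal, the loop uses biorthogonal left/right eigenvectors.
Each component is quantized to 0 (trivial regime, rho < 0) or pi (topological
regime, rho > 0); the transition at rho = 0 closes the band gap.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    COMPASS,
    EXTERNAL_STEP,
    INTERNAL_NEXT,
    INTERNAL_PREV,
    ModelParams,
    RateSet,
    derive_rates,
)

__all__ = [
    "BandStructure",
    "ZakPhase",
    "bloch_matrix",
    "band_structure",
    "band_gaps",
    "wilson_loop_phase",
    "zak_phase",
    "zak_phase_2d",
]

_IDX = {s: i for i, s in enumerate(COMPASS)}

#: Deviation from {0, pi} beyond which a Zak phase is considered unquantized.
ZAK_SNAP_TOL = 1e-3
#: Eigenvalue separation below which band tracking is declared ambiguous.
DEGENERACY_TOL = 1e-10


@dataclass
class BandStructure:
    """Four complex eigenvalue branches on a k-grid (units of the rate scale)."""

    kx: np.ndarray
    ky: np.ndarray
    eigenvalues: np.ndarray  # shape (n_kx, n_ky, 4), unsorted branches


@dataclass(frozen=True)
class ZakPhase:
    """One Wilson-loop component: raw phase, snapped value, and deviation."""

    direction: str
    raw: float
    snapped: float
    deviation: float


def bloch_matrix(
    rates: RateSet | ModelParams, kx: float, ky: float
) -> np.ndarray:
    """The 4x4 Bloch generator ``W(kx, ky)`` in compass order (N, E, S, W).

    At ``k = 0`` the columns sum to zero (the unit-cell generator); the
    diagonal is the k-independent total outflow ``-gamma_tot``.
    """
    if isinstance(rates, ModelParams):
        rates = derive_rates(rates)
    M = np.zeros((4, 4), dtype=complex)
    k = np.array([kx, ky])
    for s in COMPASS:
        i = _IDX[s]
        # internal cycle within the unit cell
        M[_IDX[INTERNAL_NEXT[s]], i] += rates.gamma_in
        M[_IDX[INTERNAL_PREV[s]], i] += rates.gamma_in_rev
        # external hop in direction s lands in prev(s) one cell over
        d = np.array(EXTERNAL_STEP[s])
        phase = cmath.exp(-1j * float(k @ d))
        M[_IDX[INTERNAL_PREV[s]], i] += rates.gamma_ex * phase
        # and its reverse comes back with the conjugate phase
        M[i, _IDX[INTERNAL_PREV[s]]] += rates.gamma_ex_rev / phase
    total = (
        rates.gamma_in + rates.gamma_in_rev + rates.gamma_ex + rates.gamma_ex_rev
    )
    M[np.diag_indices(4)] -= total
    return M


def _bloch_stack(rates: RateSet, kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
    """Vectorized stack of Bloch matrices over a k-grid, shape (nkx, nky, 4, 4)."""
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    M = np.zeros(KX.shape + (4, 4), dtype=complex)
    for s in COMPASS:
        i = _IDX[s]
        M[..., _IDX[INTERNAL_NEXT[s]], i] += rates.gamma_in
        M[..., _IDX[INTERNAL_PREV[s]], i] += rates.gamma_in_rev
        dx, dy = EXTERNAL_STEP[s]
        phase = np.exp(-1j * (KX * dx + KY * dy))
        M[..., _IDX[INTERNAL_PREV[s]], i] += rates.gamma_ex * phase
        M[..., i, _IDX[INTERNAL_PREV[s]]] += rates.gamma_ex_rev / phase
    total = (
        rates.gamma_in + rates.gamma_in_rev + rates.gamma_ex + rates.gamma_ex_rev
    )
    for a in range(4):
        M[..., a, a] -= total
    return M


def band_structure(params: ModelParams, n_k: int = 101) -> BandStructure:
    """Eigenvalue branches of ``W(k)`` on an ``n_k x n_k`` Brillouin-zone grid."""
    rates = derive_rates(params)
    kx = np.linspace(-np.pi, np.pi, n_k, endpoint=False)
    ky = np.linspace(-np.pi, np.pi, n_k, endpoint=False)
    eig = np.linalg.eigvals(_bloch_stack(rates, kx, ky))
    return BandStructure(kx=kx, ky=ky, eigenvalues=eig)


def band_gaps(bands: BandStructure) -> tuple[float, float]:
    """Spectral gaps ``(Delta_I, Delta_R)`` between the two topmost bands.

    For the imaginary and real parts separately, branch values are sorted
    pointwise in k (descending) and the gap is ``min_k(band 1) -
    max_k(band 2)``; a negative value means the bands overlap.
    """
    gaps = []
    for part in (bands.eigenvalues.imag, bands.eigenvalues.real):
        ordered = np.sort(part, axis=-1)[..., ::-1]
        gaps.append(float(ordered[..., 0].min() - ordered[..., 1].max()))
    return gaps[0], gaps[1]


def minimum_interband_distance(bands: BandStructure) -> float:
    """Smallest pointwise complex distance between any two branches.

    Goes to zero at the topological transition rho = 0, where the band gap
    closes.
    """
    eig = bands.eigenvalues
    dmin = np.inf
    for a in range(4):
        for b in range(a + 1, 4):
            dmin = min(dmin, float(np.abs(eig[..., a] - eig[..., b]).min()))
    return dmin


def _biorthogonal_bands(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues, right eigenvectors, and biorthogonal left rows of a stack.

    The left rows are the rows of ``V^-1``, so ``L[b] @ U[:, b] = 1`` exactly.
    """
    lam, V = np.linalg.eig(M)
    L = np.linalg.inv(V)
    return lam, V, L


def wilson_loop_phase(right: np.ndarray, left: np.ndarray) -> float:
    """Phase of the discretized biorthogonal Wilson loop.

    ``right[j]`` is the tracked band's right eigenvector at loop point j and
    ``left[j]`` the biorthogonal left row (``left[j] @ right[j] = 1``).  The
    product of consecutive overlaps ``left[j+1] @ right[j]`` around the closed
    loop is gauge invariant (per-point rescalings cancel telescopically); its
    argument is the Berry/Zak phase.
    """
    n = right.shape[0]
    prod = 1.0 + 0.0j
    for j in range(n):
        prod *= left[(j + 1) % n] @ right[j]
    if prod == 0:
        raise ValueError("Wilson loop product vanished; band tracking failed")
    return float(np.angle(prod))


def _tracked_band_indices(lam: np.ndarray, V: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Follow the steady-state band along a loop by biorthogonal overlap.

    The band is seeded at the first loop point with the eigenvalue of largest
    real part (continuously connected to the zero mode of the generator) and
    continued by maximal |left . right| overlap with the previous point.
    Raises if two candidate eigenvalues are numerically degenerate.
    """
    n_pts = lam.shape[0]
    idx = np.empty(n_pts, dtype=int)
    order = np.argsort(-lam[0].real)
    if abs(lam[0][order[0]] - lam[0][order[1]]) < DEGENERACY_TOL:
        raise ValueError("band degeneracy at the first loop point")
    idx[0] = order[0]
    for j in range(1, n_pts):
        overlaps = np.abs(L[j - 1, idx[j - 1], :] @ V[j])
        best = np.argsort(-overlaps)
        if overlaps[best[0]] - overlaps[best[1]] < DEGENERACY_TOL:
            raise ValueError(
                f"band tracking ambiguous at loop point {j} "
                f"(overlaps {overlaps[best[0]]:.3e} vs {overlaps[best[1]]:.3e})"
            )
        idx[j] = best[0]
    return idx


def zak_phase(
    params: ModelParams,
    direction: str,
    n_k: int = 400,
    fixed_values: tuple[float, ...] = (0.0, 2.0),
) -> ZakPhase:
    """One component of the 2D Zak phase of the steady-state band.

    Computes the biorthogonal Wilson loop along a straight closed k-line in
    ``direction`` ("x" or "y") with the transverse momentum held at each of
    ``fixed_values``; the results must agree (they are quantized) and their
    circular mean is reported.  The phase is reduced mod 2*pi and snapped to
    {0, pi}; the pre-snap deviation is part of the result.
    """
    if params.rho == 0:
        raise ValueError("rho = 0 sits on the topological transition (gap closed)")
    if direction not in ("x", "y"):
        raise ValueError("direction must be 'x' or 'y'")
    if n_k < 100:
        raise ValueError("n_k >= 100 required for a converged Wilson loop")
    rates = derive_rates(params)
    ks = np.linspace(-np.pi, np.pi, n_k, endpoint=False)
    phases = []
    for fixed in fixed_values:
        if direction == "x":
            M = _bloch_stack(rates, ks, np.array([fixed]))[:, 0]
        else:
            M = _bloch_stack(rates, np.array([fixed]), ks)[0, :]
        lam, V, L = _biorthogonal_bands(M)
        idx = _tracked_band_indices(lam, V, L)
        right = V[np.arange(n_k), :, idx]
        left = L[np.arange(n_k), idx, :]
        phases.append(wilson_loop_phase(right, left))
    # circular mean; quantization guarantees the individual loops agree
    mean = float(np.angle(np.mean(np.exp(1j * np.array(phases)))))
    raw = mean % (2.0 * math.pi)
    dist_to = {0.0: min(raw, 2.0 * math.pi - raw), math.pi: abs(raw - math.pi)}
    snapped = min(dist_to, key=dist_to.get)
    return ZakPhase(
        direction=direction, raw=raw, snapped=snapped, deviation=dist_to[snapped]
    )


def zak_phase_2d(params: ModelParams, n_k: int = 400) -> tuple[ZakPhase, ZakPhase]:
    """Both components (phi_x, phi_y) of the 2D Zak phase."""
    return zak_phase(params, "x", n_k), zak_phase(params, "y", n_k)


def bands_to_frame(bands: BandStructure) -> pd.DataFrame:
    """Band export: one row per (kx, ky, branch) with Re and Im parts."""
    nkx, nky = bands.kx.size, bands.ky.size
    KX, KY = np.meshgrid(bands.kx, bands.ky, indexing="ij")
    # pointwise descending sort of the imaginary part defines the band index
    order = np.argsort(-bands.eigenvalues.imag, axis=-1)
    eig = np.take_along_axis(bands.eigenvalues, order, axis=-1)
    rows = {
        "kx": np.repeat(KX.ravel(), 4),
        "ky": np.repeat(KY.ravel(), 4),
        "band_index": np.tile(np.arange(4), nkx * nky),
        "re": eig.real.ravel(),
        "im": eig.imag.ravel(),
    }
    return pd.DataFrame(rows)
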