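"""Entropy production, its edge/bulk split, and the cost-precision landscape."""

import math

import numpy as np
import pytest

from topoclock import (
    ModelParams,
    boundary_mask,
    build_generator,
    build_transitions,
    coherence_and_period,
    decompose_entropy,
    entropy_production_per_period,
    entropy_production_rate,
    find_cost_precision_optimum,
    first_nonzero_eigenvalue,
    grid,
    rate_matrix,
    scan_phase_diagram,
    steady_state,
)
from conftest import make_unicycle


def model_quantities(params):
    W = build_generator(params)
    p = steady_state(W)
    spec = first_nonzero_eigenvalue(W)
    R, T = coherence_and_period(spec)
    return W, p, spec, R, T


class TestEntropyProduction:
    def test_equilibrium_produces_no_entropy(self):
        params = ModelParams(mu=0.0, rho=3.0)
        W = build_generator(params)
        p = steady_state(W)
        assert entropy_production_per_period(W, p, float("inf")) == 0.0
        dec = decompose_entropy(W, p, float("inf"), params)
        assert dec.delta_S == dec.delta_S_edge == dec.delta_S_bulk == 0.0

    @pytest.mark.parametrize("n,a,b", [(12, 2.0, 0.5), (8, 1.0, 0.25)])
    def test_unicycle_closed_form(self, n, a, b):
        W = make_unicycle(n, a, b)
        p = steady_state(W)
        _, T = coherence_and_period(first_nonzero_eigenvalue(W))
        mu = math.log(a / b)
        assert entropy_production_per_period(W, p, T) == pytest.approx(
            2 * math.pi * mu / math.sin(2 * math.pi / n), rel=1e-9
        )

    @pytest.mark.parametrize("mu,rho", [(0.5, 1.0), (3.0, 2.0), (1.0, -1.0)])
    def test_driving_always_dissipates(self, mu, rho):
        params = ModelParams(mu=mu, rho=rho)
        W, p, _, _, T = model_quantities(params)
        assert entropy_production_per_period(W, p, T) > 0

    def test_one_way_edge_rejected(self):
        W = np.array([[-1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="one-way"):
            entropy_production_rate(W, np.array([0.5, 0.5]))

    def test_per_period_invariant_under_timescale_rescaling(self):
        vals = []
        for gamma_tot in (1.0, 10.0):
            params = ModelParams(mu=2.0, rho=3.0, gamma_tot=gamma_tot)
            W, p, _, _, T = model_quantities(params)
            vals.append(entropy_production_per_period(W, p, T))
        assert vals[0] == pytest.approx(vals[1], rel=1e-9)


class TestDecomposition:
    @pytest.mark.parametrize("mu,rho", [(1.0, 2.0), (4.0, 5.0), (2.5, 0.5)])
    def test_edge_plus_bulk_equals_total(self, mu, rho):
        params = ModelParams(mu=mu, rho=rho)
        W, p, _, _, T = model_quantities(params)
        dec = decompose_entropy(W, p, T, params)
        assert dec.delta_S == pytest.approx(
            dec.delta_S_edge + dec.delta_S_bulk, abs=1e-10 * max(dec.delta_S, 1.0)
        )
        assert dec.delta_S == pytest.approx(
            entropy_production_per_period(W, p, T), rel=1e-12
        )

    def test_bulk_entropy_decreases_with_driving_in_efficient_regime(self):
        # deep in the topological regime the steady state migrates to the
        # boundary as mu grows, draining the bulk dissipation
        bulk = []
        for mu in np.arange(2.0, 6.5, 0.5):
            params = ModelParams(mu=mu, rho=5.0)
            W, p, _, _, T = model_quantities(params)
            bulk.append(decompose_entropy(W, p, T, params).delta_S_bulk)
        assert np.all(np.diff(bulk) < 0)

    def test_efficient_regime_rising_coherence_falling_cost(self):
        Rs, dSs = [], []
        for mu in np.arange(2.0, 6.5, 0.5):
            params = ModelParams(mu=mu, rho=5.0)
            W, p, _, R, T = model_quantities(params)
            Rs.append(R)
            dSs.append(entropy_production_per_period(W, p, T))
        assert np.all(np.diff(Rs) > 0)
        assert np.all(np.diff(dSs) < 0)


class TestEdgeLocalization:
    def test_boundary_probability_increases_with_rho(self):
        mask = boundary_mask(6, 6)
        weights = []
        for rho in (0.5, 1.5, 3.0, 5.0):
            p = steady_state(build_generator(ModelParams(mu=1.0, rho=rho)))
            weights.append(p[mask].sum())
        assert np.all(np.diff(weights) > 0)

    def test_top28_states_robust_to_rate_perturbation(self):
        """Topological protection: +-10% independent rate noise leaves the
        high-probability bottleneck set unchanged."""
        params = ModelParams(mu=1.0, rho=3.0)
        transitions = build_transitions(params)
        p_clean = steady_state(build_generator(params))
        top_clean = set(np.argsort(-p_clean)[:28])
        rng = np.random.default_rng(20240731)
        factors = rng.uniform(0.9, 1.1, size=len(transitions))
        perturbed = [
            t.__class__(t.source, t.target, t.rate * f, t.kind)
            for t, f in zip(transitions, factors)
        ]
        p_noisy = steady_state(rate_matrix(perturbed, params.n_states))
        assert set(np.argsort(-p_noisy)[:28]) == top_clean


@pytest.fixture(scope="module")
def coarse_diagram():
    return scan_phase_diagram(grid(0.0, 10.0, 0.5), grid(0.5, 7.0, 0.5))


class TestPhaseDiagram:
    def test_columns_and_grid_shape(self, coarse_diagram):
        assert list(coarse_diagram.columns) == [
            "mu", "rho", "coherence", "delta_S", "delta_S_edge",
            "delta_S_bulk", "cost_precision",
        ]
        assert len(coarse_diagram) == 21 * 14

    def test_non_oscillatory_cells_flagged(self, coarse_diagram):
        mu0 = coarse_diagram[coarse_diagram.mu == 0.0]
        assert (mu0.coherence == 0.0).all()
        assert np.isinf(mu0.cost_precision).all()

    def test_coherence_monotone_along_both_axes(self, coarse_diagram):
        along_mu = coarse_diagram[coarse_diagram.rho == 3.0].sort_values("mu")
        assert np.all(np.diff(along_mu.coherence) > 0)
        along_rho = coarse_diagram[coarse_diagram.mu == 3.0].sort_values("rho")
        assert np.all(np.diff(along_rho.coherence) > 0)

    def test_optimum_is_interior(self, coarse_diagram):
        with pytest.warns(UserWarning, match="non-finite"):
            mu_star, rho_star, value = find_cost_precision_optimum(coarse_diagram)
        assert 0.0 < mu_star < 10.0
        assert 0.5 < rho_star < 7.0
        assert value > 0

    def test_optimum_invariant_under_timescale_rescaling(self):
        mu_grid, rho_grid = grid(5.0, 8.0, 0.5), grid(3.0, 5.0, 0.5)
        opt1 = find_cost_precision_optimum(scan_phase_diagram(mu_grid, rho_grid, 1.0))
        opt5 = find_cost_precision_optimum(scan_phase_diagram(mu_grid, rho_grid, 5.0))
        assert opt1[:2] == opt5[:2]
        assert opt1[2] == pytest.approx(opt5[2], rel=1e-9)

    def test_trivial_regime_requires_opt_in(self):
        with pytest.raises(ValueError, match="trivial"):
            scan_phase_diagram(grid(1.0, 2.0, 1.0), grid(-1.0, 1.0, 1.0))
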