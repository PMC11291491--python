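"""Generator algebra, steady states, spectra and the coherence observable."""

import math

import numpy as np
import pytest
import scipy.linalg

from topoclock import (
    LatticeState,
    ModelParams,
    Transition,
    build_generator,
    coherence_and_period,
    enumerate_states,
    evolve,
    first_nonzero_eigenvalue,
    rate_matrix,
    state_index,
    steady_state,
)
from conftest import make_unicycle


class TestRateMatrix:
    def test_two_state_toy_diagonal(self):
        W = rate_matrix([Transition(0, 1, 2.0, "x"), Transition(1, 0, 3.0, "x")], 2)
        assert W[1, 0] == 2.0 and W[0, 1] == 3.0
        assert W[0, 0] == -2.0 and W[1, 1] == -3.0

    def test_duplicate_transitions_summed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            W = rate_matrix(
                [
                    Transition(0, 1, 2.0, "x"),
                    Transition(0, 1, 1.0, "x"),
                    Transition(1, 0, 3.0, "x"),
                ],
                2,
            )
        assert W[1, 0] == 3.0

    @pytest.mark.parametrize(
        "params",
        [
            ModelParams(mu=1.0, rho=2.0),
            ModelParams(mu=-2.0, rho=-1.0, gamma_tot=7.0, nx=2, ny=3),
        ],
    )
    def test_columns_sum_to_zero(self, params):
        W = build_generator(params)
        assert np.abs(W.sum(axis=0)).max() < 1e-12 * params.gamma_tot

    def test_zero_eigenvalue_present(self, edge_generator):
        ev = np.linalg.eigvals(edge_generator)
        assert np.min(np.abs(ev)) < 1e-10


class TestSteadyState:
    def test_residual_and_normalization(self, edge_generator, edge_steady_state):
        p = edge_steady_state
        assert np.abs(edge_generator @ p).max() < 1e-10
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()

    def test_reducible_graph_names_components(self):
        # two disconnected 2-cycles
        transitions = [
            Transition(0, 1, 1.0, "x"),
            Transition(1, 0, 1.0, "x"),
            Transition(2, 3, 1.0, "x"),
            Transition(3, 2, 1.0, "x"),
        ]
        W = rate_matrix(transitions, 4)
        with pytest.raises(ValueError, match=r"reducible.*\[0, 1\].*\[2, 3\]"):
            steady_state(W)


class TestSpectrum:
    @pytest.mark.parametrize("n,a,b", [(8, 1.0, 0.2), (12, 2.0, 0.5), (28, 3.0, 1.0)])
    def test_unicycle_circulant_closed_form(self, n, a, b):
        W = make_unicycle(n, a, b)
        spec = first_nonzero_eigenvalue(W)
        theta = 2.0 * np.pi / n
        expected = a * (np.exp(1j * theta) - 1) + b * (np.exp(-1j * theta) - 1)
        assert spec.lambda_1.real == pytest.approx(expected.real, rel=1e-9)
        assert spec.lambda_1.imag == pytest.approx(expected.imag, rel=1e-9)

    def test_reversible_model_has_real_spectrum(self):
        spec = first_nonzero_eigenvalue(build_generator(ModelParams(mu=0.0, rho=2.0)))
        assert spec.lambda_I == 0.0
        assert np.abs(spec.eigenvalues.imag).max() < 1e-10

    def test_driven_topological_mode_is_complex(self, edge_generator):
        spec = first_nonzero_eigenvalue(edge_generator)
        assert spec.lambda_I > 0

    def test_conjugate_pair_selection_reports_positive_imag(self, edge_generator):
        assert first_nonzero_eigenvalue(edge_generator).lambda_I >= 0

    def test_stability_all_real_parts_nonpositive(self, edge_generator):
        ev = np.linalg.eigvals(edge_generator)
        assert ev.real.max() < 1e-10

    def test_degenerate_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            first_nonzero_eigenvalue(np.zeros((3, 3)))


class TestCoherence:
    @pytest.mark.parametrize("n,a,b", [(12, 2.0, 0.5), (52, 1.0, math.exp(-1.0))])
    def test_unicycle_coherence_closed_form(self, n, a, b):
        spec = first_nonzero_eigenvalue(make_unicycle(n, a, b))
        R, T = coherence_and_period(spec)
        mu = math.log(a / b)
        assert R == pytest.approx(math.tanh(mu / 2) / math.tan(math.pi / n), rel=1e-9)
        assert T == pytest.approx(
            2 * math.pi / ((a - b) * math.sin(2 * math.pi / n)), rel=1e-9
        )

    def test_non_oscillatory_mode_reports_zero_coherence(self):
        spec = first_nonzero_eigenvalue(build_generator(ModelParams(mu=0.0, rho=1.0)))
        R, T = coherence_and_period(spec)
        assert R == 0.0 and T == float("inf")

    def test_coherence_monotone_in_mu_at_fixed_rho(self):
        Rs = []
        for mu in np.linspace(0.5, 8.0, 6):
            spec = first_nonzero_eigenvalue(build_generator(ModelParams(mu=mu, rho=3.0)))
            Rs.append(coherence_and_period(spec)[0])
        assert np.all(np.diff(Rs) > 0)


class TestTimeEvolution:
    def test_probability_conserved_under_evolution(self, edge_generator):
        n = edge_generator.shape[0]
        p0 = np.zeros(n)
        p0[0] = 1.0
        for p in evolve(edge_generator, p0, [0.0, 10.0, 100.0]):
            assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_damped_oscillation_matches_spectral_rates(self):
        """Phosphorylation-level relaxation from a point initial condition
        decays at lambda_R with period 2*pi/lambda_I (within 2%)."""
        params = ModelParams(mu=2.0, rho=2.0)
        W = build_generator(params)
        spec = first_nonzero_eigenvalue(W)
        R, T = coherence_and_period(spec)
        p_s = steady_state(W)
        states = enumerate_states(params.nx, params.ny)
        phos = np.array([s.x + s.y for s in states], dtype=float)
        p0 = np.zeros(params.n_states)
        p0[state_index(LatticeState(0, 0, "E"), params.nx, params.ny)] = 1.0
        dt = T / 20.0
        propagator = scipy.linalg.expm(W * dt)
        signal = np.empty(240)
        v = p0
        for k in range(signal.size):
            signal[k] = phos @ v
            v = propagator @ v
        s = signal - phos @ p_s
        s = s[60:]  # discard the fast multi-mode transient (3 periods)
        # a single damped cosine obeys an order-2 linear recurrence; fit it
        # and read the mode off the characteristic roots
        A = np.column_stack([s[:-2], s[1:-1]])
        coef, *_ = np.linalg.lstsq(A, s[2:], rcond=None)
        roots = np.roots([1.0, -coef[1], -coef[0]])
        z = roots[roots.imag > 0][0]
        lam = np.log(z) / dt
        assert -lam.real == pytest.approx(spec.lambda_R, rel=0.02)
        assert lam.imag == pytest.approx(spec.lambda_I, rel=0.02)
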