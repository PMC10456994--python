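import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from certgeom import synth
from certgeom.certainty import (
    NoiseModel,
    certain_synapses,
    certain_with_noise_exact,
    min_certainty_margin,
    noisy_y_critical_scan,
    w_critical,
    y_critical,
    y_critical_all,
    y_critical_angle_form,
    y_critical_linear,
    y_critical_noisy_bounds,
    y_critical_nonorthogonal_bound,
)
from certgeom.geometry import (
    FeedforwardProblem,
    classify_dimensions,
    feedforward_problem,
    synapse_projections,
)
from conftest import random_orthonormal_problem


def geom_of(problem, m=0):
    labels = classify_dimensions(problem.y_target, problem.n_synapses)
    return synapse_projections(problem, labels, m), labels


def ball_sampling_y_cr(problem, m, W=1.0, grid=0.01, n=40000, seed=0):
    """Brute-force critical magnitude: largest response level with mixed signs
    among uniformly sampled exact solutions."""
    from certgeom.solution_space import sample_solutions

    labels = classify_dimensions(problem.y_target, problem.n_synapses)
    y_hat = problem.y_target / np.linalg.norm(problem.y_target)
    rng = np.random.default_rng(seed)
    largest = 0.0
    for s in np.arange(grid, W + grid / 2, grid):
        scaled = FeedforwardProblem(
            z=problem.z, y_target=s * y_hat, Z=problem.Z, Z_inv=problem.Z_inv,
            presyn_labels=problem.presyn_labels,
        )
        samples = sample_solutions(scaled, labels, W, n, rng)
        ws = np.array([x.weights[m] for x in samples])
        if np.any(ws > 1e-9) and np.any(ws < -1e-9):
            largest = s
    return largest


class TestYCritical:
    def test_one_of_each_45_degrees(self):
        # one constrained, one semiconstrained (orthogonal to the synapse),
        # one unconstrained dimension at theta = phi = 45 deg
        problem = synth.toy_one_of_each(np.pi / 4, np.pi / 4)
        g, _ = geom_of(problem)
        assert y_critical(g, 1.0) == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_ball_sampling_oracle_matches(self):
        problem = synth.toy_one_of_each(np.pi / 4, np.pi / 4)
        emp = ball_sampling_y_cr(problem, 0)
        assert abs(emp - 1 / np.sqrt(3)) <= 0.0101

    def test_zero_correlation_gives_W(self):
        # e_y = 0: the sign is never identifiable within the bound
        z = np.eye(3)[:2]
        problem = feedforward_problem(z, np.array([0.7, 0.0]))
        g, _ = geom_of(problem, m=1)  # column (0,1,0): semiconstrained only
        assert g.e_y == 0.0
        assert y_critical(g, 1.0) == pytest.approx(1.0)

    def test_fully_constrained_gives_zero(self):
        z = np.eye(3)[:2]
        problem = feedforward_problem(z, np.array([0.7, 0.1]))
        g, _ = geom_of(problem, m=0)
        assert g.e_sstar == 0.0 and g.e_u == 0.0
        assert y_critical(g, 1.0) == 0.0

    @pytest.mark.parametrize("psi", [0.3, 0.6, 1.2])
    def test_obtuse_chi_family(self, psi):
        # semiconstrained dimension acts as unconstrained: y_cr = W sin(psi)
        problem = synth.orthogonal_family(psi, 2.2)
        g, _ = geom_of(problem)
        assert y_critical(g, 1.0) == pytest.approx(np.sin(psi), abs=1e-12)

    @pytest.mark.parametrize("theta,gamma", [(0.4, 0.3), (0.9, 1.0), (0.7, 0.1)])
    def test_two_semiconstrained_toy(self, theta, gamma):
        problem = synth.toy_two_semiconstrained(theta, gamma)
        g, _ = geom_of(problem)
        expected = np.sqrt(
            np.sin(theta) ** 2 * np.cos(gamma) ** 2
            / (np.cos(theta) ** 2 + np.sin(theta) ** 2 * np.cos(gamma) ** 2)
        )
        assert y_critical(g, 1.0) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("theta,alpha", [(0.4, 0.2), (0.8, -0.5), (1.1, 0.6)])
    def test_two_constrained_toy(self, theta, alpha):
        problem = synth.toy_two_constrained(theta, alpha)
        g, _ = geom_of(problem)
        expected = np.sqrt(
            np.sin(theta) ** 2
            / (np.cos(theta) ** 2 * np.cos(alpha) ** 2 + np.sin(theta) ** 2)
        )
        assert y_critical(g, 1.0) == pytest.approx(expected, abs=1e-10)


class TestAlgebraicEquivalence:
    @given(st.integers(min_value=0, max_value=2000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_angle_form_equals_projection_form(self, seed):
        problem, labels = random_orthonormal_problem(seed, N=7, P=5, C=3)
        m = seed % 7
        g = synapse_projections(problem, labels, m)
        assert y_critical_angle_form(g, 1.0) == pytest.approx(
            y_critical(g, 1.0), abs=1e-10
        )

    @given(st.integers(min_value=0, max_value=2000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_linear_below_nonlinear(self, seed):
        problem, labels = random_orthonormal_problem(seed, N=6, P=5, C=2)
        for m in range(6):
            g = synapse_projections(problem, labels, m)
            lin = y_critical_linear(g, 1.0)
            non = y_critical(g, 1.0)
            assert lin <= non + 1e-12
            if g.e_sstar > 1e-9:
                assert lin < non

    def test_vectorized_matches_scalar(self):
        problem, labels = random_orthonormal_problem(12, N=9, P=6, C=3)
        vec = y_critical_all(problem, labels, 1.0)
        sca = [
            y_critical(synapse_projections(problem, labels, m), 1.0)
            for m in range(9)
        ]
        np.testing.assert_allclose(vec, sca, atol=1e-12)

    def test_monotonic_in_projections(self):
        # y_cr rises with adverse/unconstrained mass, falls with correlation
        from dataclasses import replace

        problem, labels = random_orthonormal_problem(0, N=6, P=5, C=2)
        g = synapse_projections(problem, labels, 0)
        base = y_critical(g, 1.0)
        assert y_critical(replace(g, e_sstar=g.e_sstar + 0.1), 1.0) > base
        assert y_critical(replace(g, e_u=g.e_u + 0.1), 1.0) > base
        assert y_critical(replace(g, e_y=g.e_y * 2.0), 1.0) < base


class TestWCritical:
    def test_fig2_equals_one(self, fig2):
        spec, patterns, _, _ = fig2
        results = certain_synapses(spec, patterns, NoiseModel(0.0, 1.0))
        x1 = next(r for r in results if r.presyn == 1)
        assert x1.W_cr == pytest.approx(1.0, abs=1e-12)

    def test_inverse_of_y_critical(self):
        problem, labels = random_orthonormal_problem(5, N=6, P=4, C=2)
        g = synapse_projections(problem, labels, 2)
        W = 0.8
        y_star = y_critical(g, W)
        assert w_critical(g, y_star) == pytest.approx(W, abs=1e-9)

    def test_linear_in_response_magnitude(self):
        problem, labels = random_orthonormal_problem(6, N=6, P=4, C=2)
        g = synapse_projections(problem, labels, 1)
        assert w_critical(g, 0.6) == pytest.approx(2 * w_critical(g, 0.3), abs=1e-9)

    def test_unbounded_when_fully_constrained(self):
        z = np.eye(3)[:2]
        problem = feedforward_problem(z, np.array([0.7, 0.1]))
        g, _ = geom_of(problem, m=0)
        assert w_critical(g, 0.5) == np.inf


class TestNoisyBounds:
    def test_zero_error_reduction(self):
        problem, labels = random_orthonormal_problem(9, N=6, P=5, C=2)
        g = synapse_projections(problem, labels, 3)
        lo, hi = y_critical_noisy_bounds(g, problem.y_target, NoiseModel(0.0, 1.0))
        assert lo == pytest.approx(y_critical(g, 1.0), abs=1e-9)
        assert hi == pytest.approx(y_critical(g, 1.0), abs=1e-9)

    def test_closed_form_no_transition_lower_bound(self):
        # e_y^2 = e_s*^2 = e_u^2 = 1/4, eps = 0.1: lower bound sqrt(2/3) + 0.1
        from certgeom.certainty import _bound_terms

        lo, hi = _bound_terms(0.25, 0.25, 0.25, 0.75, 1.0, 0.1)
        assert lo == pytest.approx(np.sqrt(2.0 / 3.0) + 0.1, abs=1e-12)
        assert hi >= lo

    def test_bounds_ordered_and_capped(self):
        problem, labels = random_orthonormal_problem(14, N=6, P=5, C=2)
        for m in range(6):
            g = synapse_projections(problem, labels, m)
            lo, hi = y_critical_noisy_bounds(g, problem.y_target, NoiseModel(0.2, 1.0))
            assert lo <= hi + 1e-12
            assert hi <= 1.0 + 1e-12

    @pytest.mark.parametrize("k", range(12))
    def test_sandwich_against_exact_oracle(self, k):
        """Lower bound <= exact noisy critical magnitude <= upper bound."""
        noise = NoiseModel(0.1, 1.0)
        problem = synth.transition_configuration(6, 5, 2, seed=700 + k)
        labels = classify_dimensions(problem.y_target, 6)
        m = k % 6
        g = synapse_projections(problem, labels, m)
        lo, hi = y_critical_noisy_bounds(g, problem.y_target, noise)
        exact = noisy_y_critical_scan(problem, labels, m, noise, tol=1e-3)
        assert lo - 2e-3 <= exact <= hi + 2e-3


class TestExactNoisyCertainty:
    def test_reduces_to_zero_error_condition(self):
        problem, labels = random_orthonormal_problem(3, N=6, P=5, C=2)
        noise = NoiseModel(0.0, 1.0)
        for m in range(3):
            res = certain_with_noise_exact(problem, labels, m, noise)
            g = synapse_projections(problem, labels, m)
            expected = np.linalg.norm(problem.y_target) > y_critical(g, 1.0)
            assert res.certain == expected
            if res.certain:
                assert res.predicted_sign == np.sign(g.e_y)

    def test_budget_covering_response_never_certain(self):
        problem, labels = random_orthonormal_problem(4, N=6, P=5, C=2)
        y_norm = np.linalg.norm(problem.y_target)
        res = certain_with_noise_exact(
            problem, labels, 0, NoiseModel(y_norm * 1.01, 1.0)
        )
        assert not res.certain

    def test_transition_flips_certainty(self):
        """A synapse certain under the no-transition analysis loses certainty
        once the budget can zero an adversely aligned small response."""
        from certgeom.synth import _complete_orthogonal

        y = np.array([0.06, 0.75, 0.0])
        labels = classify_dimensions(y, 4)
        # synapse direction: negative on the small constrained component,
        # positive on the large one -> zeroing the small component adds
        # adverse semiconstrained mass
        direction = np.array([-0.875171, 0.397303, 0.159384, 0.22544])
        direction /= np.linalg.norm(direction)
        Z = _complete_orthogonal(direction)  # rows orthonormal, Z[:,0] = direction
        problem2 = FeedforwardProblem(
            z=Z[:3], y_target=y, Z=Z, Z_inv=Z.T, presyn_labels=np.arange(4)
        )
        margin_lo, _ = min_certainty_margin(
            problem2, labels, 0, NoiseModel(0.04, 1.0)
        )
        margin_hi, _ = min_certainty_margin(
            problem2, labels, 0, NoiseModel(0.08, 1.0)
        )
        assert margin_lo > 0  # below the transition budget: still certain
        assert margin_hi <= 0  # budget covers the small response: uncertain


class TestNonorthogonalBound:
    def test_orthonormal_reduction_exact(self):
        problem, labels = random_orthonormal_problem(8, N=6, P=4, C=2)
        for m in range(4):
            g = synapse_projections(problem, labels, m)
            bound = y_critical_nonorthogonal_bound(problem, m, 1.0)
            assert bound == pytest.approx(min(y_critical(g, 1.0), 1.0), abs=1e-9)

    def test_fig2_unnormalized_rows_conservative(self, fig2):
        _, _, problem, labels = fig2
        bound = y_critical_nonorthogonal_bound(problem, 0, 1.0)
        # exact threshold for the first synapse at W = 1 is |y| = 1
        assert bound >= 1.0 - 1e-9
        # and the bound is confirmed conservative by sampling: no mixed signs
        # appear above it (the whole feasible range here)
        emp = ball_sampling_y_cr(problem, 0, W=1.0, grid=0.05, n=5000)
        assert emp <= bound + 1e-9

    def test_near_orthonormal_continuity(self):
        problem, labels = random_orthonormal_problem(10, N=5, P=3, C=2)
        rng = np.random.default_rng(0)
        z_pert = problem.z + 1e-3 * rng.standard_normal(problem.z.shape) / 10
        pert = feedforward_problem(z_pert, problem.y_target)
        g = synapse_projections(problem, labels, 1)
        exact = y_critical(g, 1.0)
        bound = y_critical_nonorthogonal_bound(pert, 1, 1.0)
        assert bound == pytest.approx(exact, rel=0.01, abs=0.01)


class TestCertainSynapses:
    def test_fig2_table(self, fig2):
        spec, patterns, _, _ = fig2
        results = certain_synapses(spec, patterns, NoiseModel(0.0, 1.0))
        by_presyn = {r.presyn: r for r in results}
        assert not by_presyn[1].certain          # x1 -> y ambiguous at W = 1
        assert by_presyn[2].certain              # x2 -> y always present
        assert by_presyn[2].predicted_sign == 1  # and excitatory

    @pytest.mark.parametrize("chi_deg,expected", [(30, False), (44, False),
                                                  (46, True), (80, True)])
    def test_self_synapse_condition(self, chi_deg, expected):
        spec, patterns, target = synth.self_synapse_network(np.radians(chi_deg))
        results = certain_synapses(spec, patterns, NoiseModel(0.0, 1.0))
        self_result = next(
            r for r in results if r.neuron == target and r.presyn == target
        )
        assert self_result.y_cr == pytest.approx(np.cos(np.radians(chi_deg)), abs=1e-9)
        assert self_result.certain == expected

    def test_all_zero_response_neuron(self):
        spec, patterns = synth.fig2_toy()
        patterns.y[:] = 0.0
        results = certain_synapses(spec, patterns, NoiseModel(0.0, 1.0))
        assert not any(r.certain for r in results)

    def test_weight_bound_below_response_norm(self):
        problem = synth.toy_one_of_each(0.4, 0.4, y2=0.9)
        from certgeom.config_io import NetworkSpec, PatternSet

        spec = NetworkSpec(n_input=3, n_driven=1, allow_self_synapse=False)
        patterns = PatternSet(x=problem.z, y=problem.y_target[:, None])
        results = certain_synapses(spec, patterns, NoiseModel(0.0, 0.5))
        assert all(not r.certain for r in results)
        assert any("no solutions" in r.note for r in results)

    def test_sign_correctness_on_sampled_solutions(self):
        """Whenever certain, every sampled exact solution carries the
        predicted sign."""
        from certgeom.solution_space import sample_solutions

        found_certain = 0
        for seed in range(6):
            problem, labels = random_orthonormal_problem(seed + 40, N=5, P=4, C=3)
            samples = sample_solutions(problem, labels, 1.0, 400, seed=seed)
            for m in range(5):
                g = synapse_projections(problem, labels, m)
                if np.linalg.norm(problem.y_target) > y_critical(g, 1.0):
                    found_certain += 1
                    signs = np.sign([s.weights[m] for s in samples])
                    assert np.all(signs == np.sign(g.e_y))
        assert found_certain > 0
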