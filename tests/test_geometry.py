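import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from certgeom import synth
from certgeom.config_io import NetworkSpec, PatternSet
from certgeom.geometry import (
    classify_dimensions,
    decompose_recurrent,
    extend_to_full_rank,
    feedforward_problem,
    normalize_rows,
    synapse_projections,
    target_problem,
)
from conftest import random_orthonormal_problem


class TestDecomposeRecurrent:
    def test_single_driven_all_to_all_is_feedforward(self):
        spec = NetworkSpec(n_input=3, n_driven=1, allow_self_synapse=False)
        x = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        patterns = PatternSet(x=x, y=np.array([[0.4], [0.0]]))
        (problem,) = decompose_recurrent(spec, patterns)
        np.testing.assert_array_equal(problem.z, x)
        np.testing.assert_array_equal(problem.presyn_labels, [1, 2, 3])

    def test_recurrent_spec_shapes(self):
        # 4 driven, 7 inputs, no self-synapses: each problem has 10 columns
        spec, patterns, _ = synth.recurrent_orthogonal_config(7, 4, 8, seed=0, C=3)
        problem = target_problem(spec, patterns, 0)
        assert problem.n_synapses == 10
        assert problem.n_patterns == 8
        # columns: 3 other driven neurons then 7 inputs
        np.testing.assert_array_equal(problem.presyn_labels[:3], [1, 2, 3])

    def test_mask_excludes_column(self):
        mask = np.array([[False, True, True, False]])  # drop input 3
        spec = NetworkSpec(n_input=3, n_driven=1, adjacency_mask=mask)
        patterns = PatternSet(x=np.eye(3)[:2], y=np.array([[1.0], [0.5]]))
        (problem,) = decompose_recurrent(spec, patterns)
        assert problem.n_synapses == 2
        np.testing.assert_array_equal(problem.presyn_labels, [1, 2])

    def test_too_many_patterns_raises(self):
        spec = NetworkSpec(n_input=2, n_driven=1, allow_self_synapse=False)
        patterns = PatternSet(x=np.vstack([np.eye(2), [[1.0, 2.0]]]),
                              y=np.ones((3, 1)))
        with pytest.raises(ValueError, match="underdetermined regime"):
            decompose_recurrent(spec, patterns)


class TestExtendToFullRank:
    def test_orthogonal_family_null_row(self):
        psi, chi = 0.6, 0.8
        z = synth.orthogonal_family(psi, chi).z
        Z, Z_inv = extend_to_full_rank(z)
        expected = np.array(
            [np.sin(psi) * np.sin(chi), -np.cos(psi) * np.sin(chi), np.cos(chi)]
        )
        # appended row spans the null space, fixed up to overall sign
        assert (
            np.allclose(Z[2], expected, atol=1e-12)
            or np.allclose(Z[2], -expected, atol=1e-12)
        )
        np.testing.assert_allclose(Z @ Z_inv, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(Z_inv, Z.T, atol=1e-12)  # orthogonal

    def test_square_case_returns_input(self):
        z = np.array([[2.0, 0.0], [1.0, 1.0]])
        Z, Z_inv = extend_to_full_rank(z)
        np.testing.assert_array_equal(Z, z)
        np.testing.assert_allclose(Z @ Z_inv, np.eye(2), atol=1e-12)

    def test_duplicated_row_raises(self):
        z = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="rank-deficient"):
            extend_to_full_rank(z)

    def test_sign_convention_reproducible(self):
        z = synth.random_configuration(7, 4, 2, seed=3).z
        Z1, _ = extend_to_full_rank(z)
        Z2, _ = extend_to_full_rank(z.copy())
        np.testing.assert_array_equal(Z1, Z2)


class TestClassifyDimensions:
    @pytest.mark.parametrize(
        "y,n,expected",
        [
            ((1.0, 0.0), 2, ["constrained", "semiconstrained"]),
            ((0.2, 0.7, 0.4), 3, ["constrained"] * 3),
            ((0.5, 0.0), 4,
             ["constrained", "semiconstrained", "unconstrained", "unconstrained"]),
        ],
    )
    def test_trichotomy(self, y, n, expected):
        labels = classify_dimensions(np.array(y), n)
        assert labels.labels == expected
        assert labels.n_constrained + labels.n_semiconstrained == len(y)
        assert labels.n_unconstrained == n - len(y)

    def test_negative_entry_raises(self):
        with pytest.raises(ValueError, match="noisy"):
            classify_dimensions(np.array([0.5, -0.1]), 3)


class TestSynapseProjections:
    def test_fig2_orthonormalized_values(self, fig2):
        _, _, problem, _ = fig2
        z_n, y_n = normalize_rows(problem.z, problem.y_target)
        problem_n = feedforward_problem(z_n, y_n)
        labels = classify_dimensions(y_n, 2)
        g = synapse_projections(problem_n, labels, 0)
        assert g.e_y == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert g.e_sstar**2 == pytest.approx(0.5, abs=1e-12)
        assert g.e_u == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_family_angles(self):
        # acute angles map directly onto the orientation angles
        psi, chi = 0.5, 0.7
        problem = synth.orthogonal_family(psi, chi)
        labels = classify_dimensions(problem.y_target, 3)
        g = synapse_projections(problem, labels, 0)
        assert np.cos(g.theta) == pytest.approx(np.cos(psi), abs=1e-12)
        assert np.sin(g.theta) * np.cos(g.phi) == pytest.approx(
            np.sin(psi) * np.cos(chi), abs=1e-12
        )
        assert np.sin(g.theta) * np.sin(g.phi) == pytest.approx(
            np.sin(psi) * np.sin(chi), abs=1e-12
        )

    def test_fully_constrained_direction(self):
        # synapse direction entirely inside the constrained subspace
        z = np.eye(3)[:2]
        problem = feedforward_problem(z, np.array([0.8, 0.1]))
        labels = classify_dimensions(problem.y_target, 3)
        g = synapse_projections(problem, labels, 0)
        assert g.e_u == pytest.approx(0.0, abs=1e-12)
        assert g.e_sstar == pytest.approx(0.0, abs=1e-12)
        assert g.theta == pytest.approx(0.0, abs=1e-7)

    def test_gamma_convention_empty_semiconstrained_projection(self):
        # synapse with zero semiconstrained component: gamma := pi/2
        z = np.eye(3)[:2]
        problem = feedforward_problem(z, np.array([0.5, 0.0]))
        labels = classify_dimensions(problem.y_target, 3)
        g = synapse_projections(problem, labels, 0)  # column (1,0,0): no semi part
        assert g.gamma == pytest.approx(np.pi / 2)

    def test_zero_response_rejected(self):
        problem = feedforward_problem(np.eye(2), np.zeros(2))
        labels = classify_dimensions(problem.y_target, 2)
        with pytest.raises(ValueError, match="uncertain for y = 0"):
            synapse_projections(problem, labels, 0)


class TestInvariants:
    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_basis_round_trip(self, seed):
        problem, _ = random_orthonormal_problem(seed)
        rng = np.random.default_rng(seed + 1)
        w = rng.standard_normal(problem.n_synapses)
        np.testing.assert_allclose(
            problem.from_eta(problem.to_eta(w)), w, atol=1e-10
        )

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_of_unity(self, seed):
        problem, labels = random_orthonormal_problem(seed)
        for m in range(problem.n_synapses):
            g = synapse_projections(problem, labels, m)
            total = (
                np.cos(g.theta) ** 2
                + np.sin(g.theta) ** 2 * np.cos(g.phi) ** 2
                + np.sin(g.theta) ** 2 * np.sin(g.phi) ** 2
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_unconstrained_subspace_shared_for_all_to_all(self):
        # with all-to-all connectivity every driven neuron sees the same
        # presynaptic patterns, so the unconstrained subspace orientation is
        # identical across driven neurons
        rng = np.random.default_rng(4)
        x = synth.random_orthogonal(4, rng)[:2]
        y = np.abs(rng.uniform(0.2, 0.8, (2, 2)))
        spec = NetworkSpec(n_input=4, n_driven=2, allow_self_synapse=True)
        patterns = PatternSet(x=x, y=y)
        p0, p1 = decompose_recurrent(spec, patterns)
        U0, U1 = p0.Z[2:], p1.Z[2:]
        # mutual projection is orthogonal: the row spaces coincide
        proj = U0 @ np.linalg.pinv(U1)
        np.testing.assert_allclose(
            U0, proj @ U1, atol=1e-8
        )
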