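import numpy as np
import pytest

from eegsync.icon import (
    BasisSpec,
    CouplingModel,
    build_design,
    coupling_strengths,
    edge_ranking_auc,
    estimate_derivative,
    infer_network,
    solve_inverse,
    synchronizability,
)
from eegsync.io import Recording


class TestDerivative:
    def test_linear_ramp_exact_everywhere(self):
        fs = 100.0
        x = np.arange(500) / fs  # x(t) = t
        np.testing.assert_allclose(estimate_derivative(x, fs), 1.0, atol=1e-9)

    def test_sinusoid_taylor_error_bound(self):
        fs, f = 256.0, 4.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * f * t)
        dx = estimate_derivative(x, fs)
        exact = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f) ** 3 / (6 * fs**2)
        interior = slice(1, -1)
        assert np.abs(dx[interior] - exact[interior]).max() < bound

    def test_constant_zero(self):
        assert np.all(estimate_derivative(np.full(10, 3.0), 10.0) == 0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            estimate_derivative(np.array([1.0, 2.0]), 10.0)


class TestBasis:
    def test_first_function_constant(self, rng):
        B = BasisSpec(5).evaluate(rng.uniform(-1, 1, 50))
        np.testing.assert_array_equal(B[:, 0], 1.0)
        assert B.shape == (50, 5)

    def test_phase_domain_alignment(self):
        """Scaled wrapped phase x = theta/pi maps so that the first
        harmonic pair spans sin/cos of theta itself."""
        theta = np.linspace(-np.pi, np.pi, 64, endpoint=False)
        B = BasisSpec(3).evaluate(theta / np.pi)
        # sin(2*pi*u) with u=(theta/pi+1)/2 equals sin(theta+pi) = -sin(theta)
        np.testing.assert_allclose(B[:, 1], -np.sin(theta), atol=1e-12)
        np.testing.assert_allclose(B[:, 2], -np.cos(theta), atol=1e-12)

    def test_r_validation(self):
        with pytest.raises(ValueError):
            BasisSpec(0)


class TestBuildDesign:
    def test_column_count_formula(self, rng):
        win = rng.uniform(-1, 1, size=(23, 600))
        prob = build_design(win, 0, BasisSpec(5), fs=256.0)
        assert prob.n_columns == 5 + 25 * 22 == 555
        assert len(prob.column_map) == 555

    def test_constant_basis_all_ones(self, rng):
        win = rng.uniform(-1, 1, size=(2, 20))
        prob = build_design(win, 0, BasisSpec(1), fs=10.0)
        assert prob.n_columns == 2
        np.testing.assert_array_equal(prob.A, 1.0)

    def test_entries_match_named_products(self, rng):
        basis = BasisSpec(2)
        win = rng.uniform(-1, 1, size=(3, 10))
        prob = build_design(win, 1, basis, fs=10.0)
        B = [basis.evaluate(win[j]) for j in range(3)]
        for c, key in enumerate(prob.column_map):
            if key[0] == "self":
                expected = B[1][:, key[1]]
            else:
                j, k, l = key
                expected = B[1][:, k] * B[j][:, l]
            np.testing.assert_allclose(prob.A[:, c], expected, atol=1e-12)

    def test_underdetermined_window_rejected(self, rng):
        win = rng.uniform(-1, 1, size=(23, 100))
        with pytest.raises(ValueError, match="longer window"):
            build_design(win, 0, BasisSpec(5), fs=256.0)


class TestSolveInverse:
    def test_consistent_system_zero_residual(self, rng):
        win = rng.uniform(-1, 1, size=(3, 200))
        prob = build_design(win, 0, BasisSpec(2), fs=100.0)
        z_true = rng.standard_normal(prob.n_columns)
        prob.y = prob.A @ z_true
        z = solve_inverse(prob)
        assert np.linalg.norm(prob.y - prob.A @ z) < 1e-8 * np.linalg.norm(prob.y)

    def test_orthonormal_columns_closed_form(self, rng):
        import types

        Q, _ = np.linalg.qr(rng.standard_normal((50, 10)))
        y = rng.standard_normal(50)
        prob = types.SimpleNamespace(A=Q, y=y)
        z = solve_inverse(prob)
        np.testing.assert_allclose(z, Q.T @ y, atol=1e-10)

    def test_beats_random_candidates(self, rng):
        import types

        A = rng.standard_normal((50, 10))
        y = rng.standard_normal(50)
        prob = types.SimpleNamespace(A=A, y=y)
        z = solve_inverse(prob)
        best = np.linalg.norm(y - A @ z)
        for _ in range(100):
            cand = z + rng.standard_normal(10)
            assert np.linalg.norm(y - A @ cand) >= best - 1e-12

    def test_nonfinite_rejected(self, rng):
        import types

        prob = types.SimpleNamespace(A=np.array([[np.nan]]), y=np.array([1.0]))
        with pytest.raises(ValueError, match="non-finite"):
            solve_inverse(prob)


class TestCouplingStrengths:
    def test_zero_coefficients(self, rng):
        win = rng.uniform(-1, 1, size=(3, 30))
        prob = build_design(win, 0, BasisSpec(2), fs=10.0)
        _, _, alpha_row = coupling_strengths(np.zeros(prob.n_columns), prob)
        assert np.all(alpha_row == 0)

    def test_single_block_entry(self, rng):
        win = rng.uniform(-1, 1, size=(3, 30))
        prob = build_design(win, 0, BasisSpec(2), fs=10.0)
        z = np.zeros(prob.n_columns)
        z[prob.column_map.index((1, 0, 1))] = 3.0
        _, _, alpha_row = coupling_strengths(z, prob)
        assert alpha_row[1] == pytest.approx(3.0)
        assert alpha_row[2] == 0.0

    def test_constant_source_products_fold_into_self(self, rng):
        """P_k(x_i) * 1 is indistinguishable from self dynamics; its
        coefficient moves to a_k and does not count as coupling."""
        win = rng.uniform(-1, 1, size=(3, 30))
        prob = build_design(win, 0, BasisSpec(2), fs=10.0)
        z = np.zeros(prob.n_columns)
        z[prob.column_map.index((1, 1, 0))] = 2.5
        a, b, alpha_row = coupling_strengths(z, prob)
        assert a[1] == pytest.approx(2.5)
        assert np.all(alpha_row == 0)
        assert np.all(b == 0)

    def test_matches_blockwise_frobenius(self, rng):
        win = rng.uniform(-1, 1, size=(4, 60))
        prob = build_design(win, 2, BasisSpec(3), fs=10.0)
        z = rng.standard_normal(prob.n_columns)
        _, b, alpha_row = coupling_strengths(z, prob)
        for j in range(4):
            expected = 0.0
            for c, key in enumerate(prob.column_map):
                # l=0 columns are canonicalized away into the self block
                if key[0] != "self" and key[0] == j and key[2] != 0:
                    expected += z[c] ** 2
            assert abs(alpha_row[j] - np.sqrt(expected)) < 1e-12
        assert alpha_row[2] == 0.0

    def test_length_mismatch(self, rng):
        win = rng.uniform(-1, 1, size=(3, 30))
        prob = build_design(win, 0, BasisSpec(2), fs=10.0)
        with pytest.raises(ValueError, match="length"):
            coupling_strengths(np.zeros(3), prob)


class TestExactRecovery:
    def test_noiseless_model_data_recovers_coefficients(self, rng):
        """Data generated inside the basis span with exact derivatives
        supplied reproduces the generating coefficients (in canonical
        form, which is the identifiable parameterization)."""
        basis = BasisSpec(3)
        n_ch = 3
        C = basis.r + basis.r**2 * (n_ch - 1)
        M = 2 * C
        states = rng.uniform(-1, 1, size=(n_ch, M))
        prob0 = build_design(states, 0, basis, y=np.zeros(M))
        z_true = rng.standard_normal(C)
        y = prob0.A @ z_true  # exact derivative under the generating model
        prob = build_design(states, 0, basis, y=y)
        z = solve_inverse(prob)
        a_hat, b_hat, alpha_hat = coupling_strengths(z, prob)
        a_true, b_true, alpha_true = coupling_strengths(z_true, prob)
        np.testing.assert_allclose(a_hat, a_true, atol=1e-6)
        np.testing.assert_allclose(b_hat, b_true, atol=1e-6)
        np.testing.assert_allclose(alpha_hat, alpha_true, atol=1e-6)


class TestInferNetwork:
    def test_coupled_vs_uncoupled_contrast(self, oscillator_pair):
        """The Kuramoto pair's edges dominate everything touching the
        uncoupled bystander.  A 3-term basis suffices for sin coupling
        (first harmonics only); the leaner block also keeps the noise
        floor of the root-sum-square strength low."""
        from eegsync.icon import average_coupling

        rec, gt = oscillator_pair
        models = infer_network(rec, window=20.0, wrap_phase=True, basis=BasisSpec(3))
        alpha = average_coupling(models)
        coupled = min(alpha[0, 1], alpha[1, 0])
        bystander = max(alpha[0, 2], alpha[1, 2], alpha[2, 0], alpha[2, 1])
        assert coupled > 3 * bystander
        # recovered strength matches K * sqrt(2) (two unit coefficients)
        assert alpha[0, 1] == pytest.approx(0.6 * np.sqrt(2), rel=0.2)

    def test_channel_order_invariance(self, oscillator_pair):
        rec, _ = oscillator_pair
        short = Recording(data=rec.data[:, : int(20 * rec.fs) + 1], fs=rec.fs, labels=rec.labels)
        m_fwd = infer_network(short, window=20.0, wrap_phase=True)
        m_rev = infer_network(
            short, window=20.0, wrap_phase=True, channel_order=[2, 1, 0]
        )
        np.testing.assert_array_equal(m_fwd[0].alpha, m_rev[0].alpha)

    def test_out_of_domain_warning(self, rng):
        rec = Recording(data=5.0 * rng.standard_normal((2, 300)), fs=10.0)
        with pytest.warns(UserWarning, match="basis domain"):
            infer_network(rec, window=20.0, basis=BasisSpec(2))


class TestSynchronizability:
    def _models(self, alphas):
        out = []
        for t, a in enumerate(alphas):
            n = a.shape[0]
            out.append(
                CouplingModel(a=np.zeros((n, 1)), b=np.zeros((n, n, 1, 1)), alpha=a, t_k=float(t))
            )
        return out

    def test_zero_network(self):
        models = self._models([np.zeros((4, 4))] * 3)
        sync = synchronizability(models)
        assert np.all(sync.lambda2 == 0) and np.all(sync.ema == 0)

    def test_beta_one_identity(self, rng):
        alphas = [np.abs(rng.random((4, 4))) for _ in range(5)]
        for a in alphas:
            np.fill_diagonal(a, 0.0)
        models = self._models(alphas)
        sync = synchronizability(models, beta=1.0)
        np.testing.assert_array_equal(sync.ema, sync.lambda2)

    def test_constant_series_fixed_point(self):
        a = np.ones((3, 3)) - np.eye(3)
        sync = synchronizability(self._models([a] * 10), beta=0.3)
        np.testing.assert_allclose(sync.ema, sync.lambda2[0], rtol=1e-12)

    def test_ema_bounded_by_raw_extremes(self, rng):
        alphas = []
        for _ in range(20):
            a = np.abs(rng.random((4, 4)))
            np.fill_diagonal(a, 0.0)
            alphas.append(a)
        sync = synchronizability(self._models(alphas), beta=0.2)
        assert np.all(sync.ema >= sync.lambda2.min() - 1e-12)
        assert np.all(sync.ema <= sync.lambda2.max() + 1e-12)

    def test_beta_validation(self):
        with pytest.raises(ValueError, match="beta"):
            synchronizability(self._models([np.zeros((2, 2))]), beta=0.0)

    def test_symmetrized_laplacian_value(self):
        """Directed strengths are averaged: a single directed edge of
        weight 2w behaves like an undirected edge of weight w."""
        a = np.zeros((2, 2))
        a[0, 1] = 2.0
        sync = synchronizability(self._models([a]))
        assert sync.lambda2[0] == pytest.approx(2.0)  # L eigenvalues 0, 2*w=2


class TestEdgeRankingAuc:
    def test_perfect_separation(self):
        K = np.zeros((3, 3))
        K[0, 1] = 1.0
        alpha = np.zeros((3, 3))
        alpha[0, 1] = 5.0
        alpha[1, 0] = 0.1
        assert edge_ranking_auc(alpha, K) == 1.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            edge_ranking_auc(np.zeros((3, 3)), np.zeros((3, 3)))
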