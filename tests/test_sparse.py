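import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.linear_model import Lasso

from snmda import (
    EntityIndex,
    ProfileSet,
    SparseConfig,
    interaction_profiles,
    reconstruct_similarity,
    solve_l1,
    sparse_neighbourhood,
)


def lasso_oracle(x, D, lam, nonneg=False):
    """Independent convex solver for ||Dw - x||^2 + lam ||w||_1."""
    model = Lasso(
        alpha=lam / (2 * len(x)), fit_intercept=False, positive=nonneg,
        tol=1e-14, max_iter=1_000_000,
    )
    return model.fit(D, x).coef_


def objective(w, x, D, lam):
    return float(np.sum((D @ w - x) ** 2) + lam * np.abs(w).sum())


class TestInteractionProfiles:
    def test_mirna_profiles_are_columns(self, fig2):
        ps = interaction_profiles(fig2, "mirna")
        assert list(ps.vectors[:, ps.index.index("M1")]) == [1, 1, 0, 1, 0]

    def test_disease_profiles_are_rows(self, fig2):
        ps = interaction_profiles(fig2, "disease")
        assert list(ps.vectors[:, ps.index.index("D1")]) == [1, 0, 1, 0, 0]

    def test_zero_column_gives_zero_profile(self):
        from snmda import AssociationMatrix

        A = AssociationMatrix(
            np.array([[1, 0], [1, 0]]), EntityIndex(["d1", "d2"]), EntityIndex(["m1", "m2"])
        )
        ps = interaction_profiles(A, "mirna")
        assert not ps.vectors[:, 1].any()


class TestSolveL1:
    def test_zero_target_gives_zero_coefficients(self):
        w = solve_l1(np.zeros(4), np.ones((4, 3)), lam=0.1)
        assert np.array_equal(w, np.zeros(3))

    def test_single_column_closed_form(self):
        # D = [x]: w* = 1 - lam / (2 ||x||^2), approaching 1 as lam -> 0
        x = np.array([1.0, 1.0, 0.0, 1.0])
        prev = 0.0
        for lam in (1.0, 0.1, 0.001):
            w = solve_l1(x, x[:, None], lam)
            expected = 1.0 - lam / (2 * np.dot(x, x))
            assert w[0] == pytest.approx(expected, abs=1e-8)
            assert w[0] > prev
            prev = w[0]

    @given(st.integers(0, 40))
    def test_objective_matches_convex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, k = int(rng.integers(3, 9)), int(rng.integers(2, 7))
        D = rng.normal(size=(m, k))
        x = rng.normal(size=m)
        lam = 0.1 * float(np.abs(D.T @ x).max()) + 1e-6
        nonneg = bool(seed % 2)
        w = solve_l1(x, D, lam, nonneg=nonneg)
        ref = lasso_oracle(x, D, lam, nonneg=nonneg)
        if nonneg:
            assert (w >= 0).all()
        assert objective(w, x, D, lam) <= objective(ref, x, D, lam) * (1 + 1e-6) + 1e-12

    def test_large_lam_gives_exact_zero(self):
        # KKT: lam >= 2 max|D'x| makes w = 0 optimal
        rng = np.random.default_rng(3)
        D = rng.normal(size=(6, 4))
        x = rng.normal(size=6)
        lam = 2.0 * float(np.abs(D.T @ x).max())
        assert np.array_equal(solve_l1(x, D, lam), np.zeros(4))

    @given(st.integers(0, 30))
    def test_increasing_lam_never_increases_l1_norm(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.normal(size=(8, 5))
        x = rng.normal(size=8)
        lam = 0.05 * float(np.abs(D.T @ x).max()) + 1e-9
        n1 = np.abs(solve_l1(x, D, lam)).sum()
        n2 = np.abs(solve_l1(x, D, 10 * lam)).sum()
        assert n2 <= n1 + 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        D = rng.normal(size=(10, 6))
        x = rng.normal(size=10)
        w1 = solve_l1(x, D, 0.05)
        w2 = solve_l1(x, D, 0.05)
        assert np.array_equal(w1, w2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            solve_l1(np.ones(3), np.ones((4, 2)), 0.1)
        with pytest.raises(ValueError):
            solve_l1(np.ones(3), np.ones((3, 2)), -1.0)


class TestSparseNeighbourhood:
    def test_thresholding(self):
        assert sparse_neighbourhood(np.array([0.4, 0.0, 0.2]), 0.25) == {0}

    def test_eps_zero_keeps_all_positive(self):
        assert sparse_neighbourhood(np.array([0.4, 0.0, 0.2]), 0.0) == {0, 2}

    def test_all_below_eps_gives_empty_set(self):
        assert sparse_neighbourhood(np.array([0.01, 0.0]), 0.05) == set()


class TestReconstructSimilarity:
    def test_identical_profiles_reconstruct_each_other(self):
        X = np.array([[1, 1], [1, 1], [0, 0]], dtype=float)
        ps = ProfileSet(X, EntityIndex(["a", "b"]), "mirna")
        res = reconstruct_similarity(ps)
        assert res.similarity.values[0, 1] > 0
        # the oracle agrees a single identical atom carries the mass
        ref = lasso_oracle(X[:, 0], X[:, [1]], 0.01 * 2.0)
        assert res.weights[0, 1] == pytest.approx(float(ref[0]), abs=1e-4)

    def test_orthogonal_profile_gets_zero_row(self):
        X = np.array([[1, 0], [0, 1]], dtype=float)
        ps = ProfileSet(X, EntityIndex(["a", "b"]), "mirna")
        res = reconstruct_similarity(ps)
        assert np.array_equal(res.similarity.values, np.zeros((2, 2)))

    def test_structural_postconditions_on_toy_network(self, fig2):
        res = reconstruct_similarity(interaction_profiles(fig2, "mirna"))
        assert np.array_equal(np.diag(res.weights), np.zeros(5))
        S = res.similarity.values
        assert np.array_equal(S, S.T)
        assert (S >= 0).all()

    def test_batch_solution_matches_per_sample_solver(self, fig2):
        ps = interaction_profiles(fig2, "disease")
        res = reconstruct_similarity(ps, SparseConfig(symmetrize=False))
        X = ps.vectors
        for i in range(X.shape[1]):
            cols = np.delete(np.arange(X.shape[1]), i)
            D = X[:, cols]
            lam = 0.01 * float(np.abs(D.T @ X[:, i]).max())
            w = np.clip(solve_l1(X[:, i], D, lam), 0.0, None)
            w[w <= 1e-4] = 0.0
            expected = np.zeros(X.shape[1])
            expected[cols] = w
            assert res.weights[i] == pytest.approx(expected, abs=1e-5)

    def test_all_zero_profile_logs_and_zeroes_row(self, caplog):
        X = np.array([[1, 0, 1], [1, 0, 0]], dtype=float)
        ps = ProfileSet(X, EntityIndex(["a", "b", "c"]), "mirna")
        with caplog.at_level("WARNING"):
            res = reconstruct_similarity(ps)
        assert "all-zero profile" in caplog.text
        assert not res.weights[1].any()

    def test_fewer_than_two_entities_rejected(self):
        ps = ProfileSet(np.ones((3, 1)), EntityIndex(["a"]), "mirna")
        with pytest.raises(ValueError):
            reconstruct_similarity(ps)

    def test_deterministic(self, fig2):
        r1 = reconstruct_similarity(interaction_profiles(fig2, "mirna"))
        r2 = reconstruct_similarity(interaction_profiles(fig2, "mirna"))
        assert np.array_equal(r1.weights, r2.weights)
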