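import numpy as np
import pytest
from hypothesis import given, strategies as st

import snmda.pipeline
from snmda import (
    AssociationMatrix,
    EntityIndex,
    PlantedNetworkSpec,
    degree_distribution,
    global_loocv,
    kfold_cv,
    local_loocv,
    make_snmda_scorer,
    planted_network,
    roc_auc,
    uniform_random_scorer,
)


def brute_force_auc(scores, labels):
    """O(P*N) pairwise-ordering fraction with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def small_planted():
    return planted_network(
        PlantedNetworkSpec(n_diseases=12, n_mirnas=14, n_blocks=3,
                           p_within=0.6, p_noise=0.05, prior_strength=0.8, seed=3)
    )


class TestRocAuc:
    def test_perfect_separation(self):
        auc, roc = roc_auc(np.array([0.9, 0.1]), np.array([1, 0]))
        assert auc == 1.0
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_full_ties_give_chance_level(self):
        auc, _ = roc_auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))
        assert auc == 0.5

    def test_interleaved_example(self):
        auc, _ = roc_auc(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 0, 1, 0]))
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(st.integers(0, 100))
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, roc = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        fpr, tpr = zip(*roc)
        assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tpr, tpr[1:]))


class TestDegreeDistribution:
    def test_toy_network_degrees(self, fig2):
        d_hist, m_hist = degree_distribution(fig2)
        assert dict(d_hist) == {2: 3, 3: 2}
        assert dict(m_hist) == {1: 1, 2: 1, 3: 3}

    def test_empty_network_all_zero(self):
        A = AssociationMatrix(np.zeros((2, 3), dtype=int),
                              EntityIndex(["d1", "d2"]), EntityIndex(["m1", "m2", "m3"]))
        d_hist, m_hist = degree_distribution(A)
        assert d_hist == [(0, 2)] and m_hist == [(0, 3)]

    @given(st.integers(0, 50))
    def test_handshake_identity(self, seed):
        rng = np.random.default_rng(seed)
        values = (rng.random((5, 7)) < 0.4).astype(int)
        A = AssociationMatrix(values, EntityIndex([f"d{i}" for i in range(5)]),
                              EntityIndex([f"m{j}" for j in range(7)]))
        d_hist, m_hist = degree_distribution(A)
        assert sum(d * c for d, c in d_hist) == sum(d * c for d, c in m_hist)


class TestLOOCV:
    def test_single_positive_rejected(self):
        A = AssociationMatrix(np.array([[1, 0], [0, 0]]),
                              EntityIndex(["d1", "d2"]), EntityIndex(["m1", "m2"]))
        with pytest.raises(ValueError):
            global_loocv(A, scorer=uniform_random_scorer(0))

    def test_random_scores_sit_at_chance(self):
        A, _, _ = small_planted()
        g = global_loocv(A, scorer=uniform_random_scorer(5))
        l = local_loocv(A, scorer=uniform_random_scorer(6))
        # null sd of the Mann-Whitney AUC at this size is ~0.05; allow 3 sigma
        assert abs(g.auc - 0.5) < 0.15
        assert abs(l.auc - 0.5) < 0.15

    def test_method_recovers_planted_structure(self):
        A, mfs, dss = small_planted()
        res = global_loocv(A, mfs, dss, fast=True)
        assert res.auc > 0.8
        assert res.mode == "global_loocv" and res.per_rep_auc == [res.auc]

    def test_local_is_not_easier_than_global(self):
        A, mfs, dss = small_planted()
        g = global_loocv(A, mfs, dss, fast=True)
        l = local_loocv(A, mfs, dss, fast=True)
        assert l.auc <= g.auc + 0.05

    def test_masking_reaches_the_reconstruction(self, monkeypatch):
        """Within each fold the held-out entry must be zero in the profile
        matrices the sparse reconstruction sees (full per-fold rerun)."""
        A, mfs, dss = planted_network(
            PlantedNetworkSpec(n_diseases=5, n_mirnas=6, n_blocks=2,
                               p_within=0.9, p_noise=0.1, seed=2)
        )
        seen = []
        original = snmda.pipeline.reconstruct_similarity

        def recording(profiles, config=None):
            seen.append((profiles.side, profiles.vectors.copy()))
            return original(profiles, config)

        monkeypatch.setattr(snmda.pipeline, "reconstruct_similarity", recording)
        global_loocv(A, mfs, dss, fast=False)
        positives = A.known_pairs()
        # first two calls are the full-data run; then one (mirna, disease)
        # pair of calls per fold, in the order of `positives`
        fold_calls = seen[2:]
        assert len(fold_calls) == 2 * len(positives)
        for k, (d, m) in enumerate(positives):
            side_m, vec_m = fold_calls[2 * k]
            side_d, vec_d = fold_calls[2 * k + 1]
            assert side_m == "mirna" and side_d == "disease"
            assert vec_m[d, m] == 0  # profile columns are A's columns
            assert vec_d[m, d] == 0

    def test_same_seed_reproduces_bitwise(self):
        A, mfs, dss = small_planted()
        r1 = global_loocv(A, mfs, dss, fast=True, seed=9)
        r2 = global_loocv(A, mfs, dss, fast=True, seed=9)
        assert r1.auc == r2.auc and r1.roc == r2.roc


class TestKFold:
    def test_k_below_two_rejected(self):
        A, _, _ = small_planted()
        with pytest.raises(ValueError):
            kfold_cv(A, scorer=uniform_random_scorer(0), k=1)

    def test_per_rep_length(self):
        A, mfs, dss = small_planted()
        res = kfold_cv(A, mfs, dss, fast=True, k=5, reps=3, seed=1)
        assert len(res.per_rep_auc) == 3
        assert res.auc == pytest.approx(np.mean(res.per_rep_auc))

    def test_leave_one_out_partition_degenerates_to_global(self):
        A, mfs, dss = small_planted()
        scorer = make_snmda_scorer(mfs, dss, fast=True, A_full=A)
        n_pos = A.n_associations
        g = global_loocv(A, scorer=scorer)
        kf = kfold_cv(A, scorer=scorer, k=n_pos, reps=1, seed=0)
        assert kf.auc == pytest.approx(g.auc, abs=1e-12)

    def test_seed_determinism(self):
        A, mfs, dss = small_planted()
        r1 = kfold_cv(A, mfs, dss, fast=True, k=4, reps=2, seed=11)
        r2 = kfold_cv(A, mfs, dss, fast=True, k=4, reps=2, seed=11)
        assert r1.per_rep_auc == r2.per_rep_auc
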