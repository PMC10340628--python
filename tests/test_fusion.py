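"""Fusion: mean pooling, GMM supervectors, early/joint/late strategies."""

import numpy as np
import pytest

from pdscreen.fusion import (DiagonalGMM, build_joint_model, early_fuse,
                             gmm_supervector, joint_forward, late_fuse,
                             mean_pool)
from pdscreen.nn.losses import softmax, softmax_cross_entropy


class TestMeanPool:
    def test_simple_average(self):
        np.testing.assert_allclose(mean_pool([[0, 2], [2, 0]]), [1, 1])

    def test_single_vector_identity(self):
        np.testing.assert_allclose(mean_pool([[3.0, -1.0]]), [3.0, -1.0])

    def test_matches_loop_sum(self, rng):
        X = rng.standard_normal((100, 7))
        total = np.zeros(7)
        for row in X:
            total += row
        np.testing.assert_allclose(mean_pool(X), total / 100, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_pool([])


class TestEarlyLateFuse:
    def test_concatenation_with_named_slices(self, rng):
        fv = early_fuse(rng.standard_normal(768), rng.standard_normal(192))
        assert fv.values.shape == (960,)
        assert fv.parts["speech"] == slice(0, 768)
        assert fv.parts["language"] == slice(768, 960)

    def test_zero_language_leaves_speech_slice_unchanged(self, rng):
        s = rng.standard_normal(10)
        fv = early_fuse(s, np.zeros(4))
        np.testing.assert_array_equal(fv.values[fv.parts["speech"]], s)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            early_fuse(np.array([np.inf]), np.zeros(2))

    def test_late_fusion_two_dimensional(self):
        fv = late_fuse(0.9, 0.3)
        np.testing.assert_allclose(fv.values, [0.9, 0.3])
        np.testing.assert_allclose(late_fuse(0.5, 0.5).values, [0.5, 0.5])

    def test_late_fusion_range_check(self):
        with pytest.raises(ValueError, match="outside"):
            late_fuse(1.2, 0.5)

    def test_separable_scores_perfectly_classified_downstream(self):
        from pdscreen.evaluation import svm_fit_predict

        rng = np.random.default_rng(0)
        pd_scores = np.column_stack([rng.uniform(0.7, 1.0, 20),
                                     rng.uniform(0.6, 1.0, 20)])
        hc_scores = np.column_stack([rng.uniform(0.0, 0.3, 20),
                                     rng.uniform(0.0, 0.4, 20)])
        X = np.vstack([pd_scores, hc_scores])
        y = np.array([1] * 20 + [0] * 20)
        scores, _ = svm_fit_predict(X, y, X, seed=0)
        assert (((scores >= 0.5).astype(int)) == y).all()


class TestGMMSupervector:
    def test_k1_closed_form(self, rng):
        X = rng.standard_normal((40, 3)) * [1.0, 2.0, 0.5] + [1.0, -1.0, 0.0]
        sv = gmm_supervector(X, K=1, seed=0)
        np.testing.assert_allclose(sv.values[:3], X.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(sv.values[3:], X.var(axis=0), atol=1e-6)

    def test_k8_d64_length(self, rng):
        sv = gmm_supervector(rng.standard_normal((100, 64)), K=8, seed=0)
        assert sv.values.shape == (2 * 8 * 64,)

    def test_too_few_embeddings_suggests_smaller_k(self, rng):
        with pytest.raises(ValueError, match="smaller K"):
            gmm_supervector(rng.standard_normal((3, 4)), K=8)

    def _two_blob_data(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((n // 2, 2))
        b = rng.standard_normal((n // 2, 2)) + 10.0
        return np.vstack([a, b])

    def test_k2_recovers_separated_means(self):
        X = self._two_blob_data()
        sv = gmm_supervector(X, K=2, seed=0)
        means = sv.values[:4].reshape(2, 2)
        np.testing.assert_allclose(means[0], [0, 0], atol=0.2)
        np.testing.assert_allclose(means[1], [10, 10], atol=0.2)

    def test_em_loglikelihood_monotone(self):
        gmm = DiagonalGMM(K=2, seed=0).fit(self._two_blob_data())
        ll = np.array(gmm.ll_history_)
        assert len(ll) >= 2
        assert np.all(np.diff(ll) >= -1e-8)

    def test_responsibilities_assign_points_to_near_component(self):
        X = self._two_blob_data()
        gmm = DiagonalGMM(K=2, seed=0).fit(X)
        resp = gmm.responsibilities(X)
        order = np.argsort(gmm.means_[:, 0])
        assign = np.argsort(order)[resp.argmax(axis=1)]
        truth = np.array([0] * 250 + [1] * 250)
        assert (assign == truth).mean() >= 0.99

    def test_supervector_invariant_to_input_order(self, rng):
        X = self._two_blob_data()
        perm = rng.permutation(len(X))
        a = gmm_supervector(X, K=2, seed=0).values
        b = gmm_supervector(X[perm], K=2, seed=0).values
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_matches_sklearn_gmm_on_separated_data(self):
        from sklearn.mixture import GaussianMixture

        X = self._two_blob_data()
        ours = gmm_supervector(X, K=2, seed=0)
        ref = GaussianMixture(n_components=2, covariance_type="diag",
                              random_state=1).fit(X)
        order = np.argsort(ref.means_[:, 0])
        np.testing.assert_allclose(ours.values[:4].reshape(2, 2),
                                   ref.means_[order], atol=0.05)
        np.testing.assert_allclose(ours.values[4:].reshape(2, 2),
                                   ref.covariances_[order], atol=0.2)


class TestJointFusion:
    def _setup(self, rng, sv_dim=6):
        model = build_joint_model(d=5, sv_dim=sv_dim, filters=4, dropout=0.0,
                                  seed=3)
        M = rng.standard_normal((7, 5))
        return model, M

    def test_zero_supervector_equals_text_only_head_slice(self, rng):
        model, M = self._setup(rng)
        probs = joint_forward(M, np.zeros(6), model)
        E = model.embed_batch([M], train=False)
        W = model.head.W.data
        logits = E @ W[: E.shape[1]] + model.head.b.data
        np.testing.assert_allclose(probs, softmax(logits)[0], atol=1e-6)

    def test_deterministic_across_calls(self, rng):
        model, M = self._setup(rng)
        sv = rng.standard_normal(6)
        p1 = joint_forward(M, sv, model)
        p2 = joint_forward(M.copy(), sv.copy(), model)
        np.testing.assert_array_equal(p1, p2)

    def test_dimension_mismatch_rejected(self, rng):
        model, M = self._setup(rng)
        with pytest.raises(ValueError, match="supervector"):
            joint_forward(M, np.zeros(5), model)

    def test_loss_gradient_reaches_text_filters(self, rng):
        model, M = self._setup(rng)
        sv = rng.standard_normal((1, 6))
        y = np.array([1])

        def loss():
            logits = model.forward_logits(([M], sv), train=False)
            return softmax_cross_entropy(logits, y)[0]

        logits = model.forward_logits(([M], sv), train=False)
        _, dl = softmax_cross_entropy(logits, y)
        for p in model.params():
            p.grad[...] = 0.0
        model.backward(dl)
        analytic = model.W[0].grad.copy()
        assert np.abs(analytic).max() > 0
        # finite-difference probe on one filter weight
        idx = np.unravel_index(np.abs(analytic).argmax(), analytic.shape)
        eps = 1e-3
        orig = model.W[0].data[idx]
        model.W[0].data[idx] = orig + eps
        fp = loss()
        model.W[0].data[idx] = orig - eps
        fm = loss()
        model.W[0].data[idx] = orig
        fd = (fp - fm) / (2 * eps)
        assert fd == pytest.approx(analytic[idx], rel=0.05, abs=1e-5)
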