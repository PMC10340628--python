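"""Fusion of speech and language representations.

Three strategies combine the two modalities at the speaker level:

* **early** — static feature concatenation: the mean-pooled speech embedding
  is joined with the language embedding into one vector for an SVM;
* **joint** — the per-speaker speech dynamics are encoded as a GMM
  supervector (stacked component means and diagonal covariances of a
  diagonal-covariance Gaussian mixture fitted to the speaker's chunk
  embeddings, K in {2, 4, 8}) and concatenated to the language embedding
  inside the text CNN just before its fully connected head, so the training
  loss back-propagates into the text filters;
* **late** — the two per-speaker decision scores form a 2-dimensional
  bi-modal vector classified by an SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .text import NgramCNN, NgramCNNConfig, EmbeddingMatrix
from .nn.losses import softmax


def mean_pool(chunk_embeddings) -> np.ndarray:
    """Arithmetic mean of a non-empty list of equal-length vectors."""
    embs = np.asarray(chunk_embeddings, dtype=np.float64)
    if embs.ndim != 2 or embs.shape[0] == 0:
        raise ValueError("mean_pool needs a non-empty list of equal-length vectors")
    return embs.mean(axis=0)


@dataclass
class FusionVector:
    values: np.ndarray
    parts: dict[str, slice] = field(default_factory=dict)


def early_fuse(speech_vec: np.ndarray, lang_vec: np.ndarray) -> FusionVector:
    """Concatenate [speech | language] with named slices.

    Per-part z-score standardization with training-fold statistics is applied
    downstream (see :func:`pdscreen.evaluation.run_experiment`), never here,
    so this function stays leak-free by construction.
    """
    s = np.asarray(speech_vec, dtype=np.float64).ravel()
    l = np.asarray(lang_vec, dtype=np.float64).ravel()
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(l))):
        raise ValueError("non-finite inputs to early_fuse")
    return FusionVector(
        values=np.concatenate([s, l]),
        parts={"speech": slice(0, len(s)), "language": slice(len(s), len(s) + len(l))},
    )


def late_fuse(speech_score: float, lang_score: float) -> FusionVector:
    """Bi-modal 2-vector of decision scores, each required to be in [0, 1]."""
    for name, v in (("speech", speech_score), ("language", lang_score)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} score {v} outside [0, 1]")
    return FusionVector(values=np.array([speech_score, lang_score]),
                        parts={"speech": slice(0, 1), "language": slice(1, 2)})


# ---------------------------------------------------------------------------
# Diagonal-covariance GMM + supervectors


@dataclass
class GMMSupervector:
    values: np.ndarray       # [mu_1..mu_K | diag(Sigma)_1..diag(Sigma)_K]
    K: int
    d: int
    speaker_id: str = ""

    def __post_init__(self):
        assert self.values.shape[0] == 2 * self.K * self.d


class DiagonalGMM:
    """Diagonal-covariance Gaussian mixture fitted by EM.

    K-means initialization (seeded), variance floor, and a log-likelihood
    history recorded every iteration; EM guarantees the history is
    non-decreasing and the fit asserts it.
    """

    def __init__(self, K: int, seed: int = 0, max_iter: int = 200,
                 tol: float = 1e-6, var_floor: float = 1e-6):
        self.K, self.seed = K, seed
        self.max_iter, self.tol, self.var_floor = max_iter, tol, var_floor
        self.means_ = None
        self.vars_ = None
        self.weights_ = None
        self.ll_history_: list[float] = []

    def _log_prob(self, X):
        # (n, K) per-component log densities
        n, d = X.shape
        diff2 = (X[:, None, :] - self.means_[None]) ** 2 / self.vars_[None]
        return (-0.5 * (diff2.sum(axis=2) + np.log(self.vars_).sum(axis=1)[None]
                        + d * np.log(2 * np.pi)))

    def _e_step(self, X):
        lp = self._log_prob(X) + np.log(self.weights_)[None]
        mx = lp.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(lp - mx).sum(axis=1))
        resp = np.exp(lp - lse[:, None])
        return resp, float(lse.mean())

    def fit(self, X: np.ndarray) -> "DiagonalGMM":
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        if n < self.K:
            raise ValueError(
                f"{n} embeddings < K={self.K} components; use a smaller K")
        km = KMeans(n_clusters=self.K, n_init=3, random_state=self.seed).fit(X)
        labels = km.labels_
        self.means_ = km.cluster_centers_.astype(np.float64)
        self.vars_ = np.empty((self.K, d))
        self.weights_ = np.empty(self.K)
        for k in range(self.K):
            mask = labels == k
            self.weights_[k] = max(mask.sum(), 1) / n
            self.vars_[k] = (X[mask].var(axis=0) if mask.any() else X.var(axis=0))
        self.weights_ /= self.weights_.sum()
        self.vars_ = np.maximum(self.vars_, self.var_floor)

        self.ll_history_ = []
        prev = -np.inf
        for _ in range(self.max_iter):
            resp, ll = self._e_step(X)
            self.ll_history_.append(ll)
            assert ll >= prev - 1e-8, "EM log-likelihood decreased"
            if ll - prev < self.tol:
                break
            prev = ll
            nk = resp.sum(axis=0) + 1e-12
            self.weights_ = nk / n
            self.means_ = (resp.T @ X) / nk[:, None]
            self.vars_ = np.maximum(
                (resp.T @ (X ** 2)) / nk[:, None] - self.means_ ** 2,
                self.var_floor)
        return self

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        resp, _ = self._e_step(np.asarray(X, dtype=np.float64))
        return resp

    def sorted_components(self):
        """Deterministic ordering: ascending by mean coordinates (lexicographic,
        first coordinate primary)."""
        order = np.lexsort(self.means_.T[::-1])
        return self.means_[order], self.vars_[order], self.weights_[order]


def gmm_supervector(chunk_embeddings: np.ndarray, K: int, seed: int = 0,
                    speaker_id: str = "") -> GMMSupervector:
    """Fit a per-speaker diagonal GMM and stack [means | diagonal covariances].

    Components are sorted by their mean vectors (first coordinate primary) so
    the supervector layout is stable across refits.  With ``K=1`` this
    reduces to the sample mean and population variance per dimension.
    """
    X = np.asarray(chunk_embeddings, dtype=np.float64)
    gmm = DiagonalGMM(K=K, seed=seed).fit(X)
    means, variances, _ = gmm.sorted_components()
    return GMMSupervector(values=np.concatenate([means.ravel(), variances.ravel()]),
                          K=K, d=X.shape[1], speaker_id=speaker_id)


# ---------------------------------------------------------------------------
# Joint fusion model


def build_joint_model(d: int, sv_dim: int, widths=(2, 3, 4), filters: int = 64,
                      dropout: float = 0.2, seed: int = 0) -> NgramCNN:
    """Text n-gram CNN with a supervector slot concatenated before the head."""
    return NgramCNN(NgramCNNConfig(d=d, widths=tuple(widths), filters=filters,
                                   dropout=dropout, sv_dim=sv_dim, seed=seed))


def joint_forward(M: EmbeddingMatrix | np.ndarray, sv: GMMSupervector | np.ndarray,
                  model: NgramCNN) -> np.ndarray:
    """Forward pass of the joint model on one speaker: 2-class probabilities."""
    X = M.M if isinstance(M, EmbeddingMatrix) else np.asarray(M)
    v = sv.values if isinstance(sv, GMMSupervector) else np.asarray(sv)
    if v.shape[0] != model.cfg.sv_dim:
        raise ValueError(
            f"supervector length {v.shape[0]} != model slot {model.cfg.sv_dim}")
    logits = model.forward_logits(([X], v[None, :]), train=False)
    return softmax(logits)[0]
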