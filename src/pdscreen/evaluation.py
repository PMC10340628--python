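"""Speaker-independent evaluation protocol.

All experiments share one protocol: stratified speaker-independent 10-fold
cross-validation.  Within each fold, every fitted quantity — feature
standardization, SVM grid search, GMM-free supervectors aside (those are
per-speaker), deep-model early stopping — sees training-fold speakers only;
test-fold speakers contribute nothing until scoring.  SVMs use a Gaussian
kernel with C in {0.001, ..., 100} and gamma in {0.0001, ..., 100} selected
by inner stratified 5-fold accuracy (ties to the smaller C, then smaller
gamma), and their decision values are mapped to [0, 1] probabilities by a
Platt-style logistic fit on training data.  Deep models train with Adam and
cross-entropy for up to 200 epochs with early-stopping patience 40, with
dropout {0.2, 0.4, 0.6} and L2 {0.0001, 0.005, 0.001} selectable by
validation loss.  Metrics are accuracy, sensitivity (PD recall), specificity
(HC recall) and F1 of the PD class, reported per fold and as mean ± standard
deviation, with PD as the positive class and the decision threshold at 0.5
(ties count as positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .audio import PD, MelConfig, mel_spectrogram, segment, standardize_recording_mels
from .cohort import Cohort, toy_embedder
from .fusion import early_fuse, gmm_supervector, build_joint_model, late_fuse, mean_pool
from .nn import Adam
from .nn.losses import softmax_cross_entropy
from .speech import (CNN1DLSTM, CNN1DLSTMConfig, LogMelProjectionEmbedder,
                     ResNet2D, ResNet2DConfig, chunk_embeddings)
from .text import NgramCNN, NgramCNNConfig, embed_transcript


# ---------------------------------------------------------------------------
# Fold planning


@dataclass
class FoldPlan:
    k: int
    assignments: dict[str, int]
    seed: int

    def fold_speakers(self, fold: int) -> tuple[list[str], list[str]]:
        train = sorted(s for s, f in self.assignments.items() if f != fold)
        test = sorted(s for s, f in self.assignments.items() if f == fold)
        return train, test


def speaker_folds(cohort_or_labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified partition of speakers into ``k`` folds.

    Speakers are shuffled within each class and dealt round-robin through a
    seed-permuted fold order, so fold sizes differ by at most one and each
    class spreads as evenly as possible across folds.
    """
    labels = (cohort_or_labels.labels if isinstance(cohort_or_labels, Cohort)
              else dict(cohort_or_labels))
    if len(labels) < k:
        raise ValueError(f"{len(labels)} speakers < {k} folds")
    rng = np.random.default_rng(seed)
    fold_order = rng.permutation(k)
    assignments: dict[str, int] = {}
    cursor = 0
    for lab in sorted(set(labels.values())):
        spks = sorted(s for s, l in labels.items() if l == lab)
        rng.shuffle(spks)
        for s in spks:
            assignments[s] = int(fold_order[cursor % k])
            cursor += 1
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# Configurations


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    early_stopping_patience: int = 40
    dropout_grid: tuple[float, ...] = (0.2, 0.4, 0.6)
    l2_grid: tuple[float, ...] = (0.0001, 0.005, 0.001)
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.early_stopping_patience >= self.epochs:
            raise ValueError("patience must be smaller than the epoch budget")
        if not self.dropout_grid or not self.l2_grid:
            raise ValueError("hyper-parameter grids must be non-empty")


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 5


# ---------------------------------------------------------------------------
# SVM with inner grid search


class _PlattSVM:
    """RBF SVM whose decision values are mapped to [0, 1] by a logistic fit
    on the training data (Platt-style calibration, train-fold only)."""

    def __init__(self, clf: SVC, a: float, b: float):
        self.clf, self.a, self.b = clf, a, b

    def scores(self, X) -> np.ndarray:
        d = self.clf.decision_function(np.asarray(X))
        return 1.0 / (1.0 + np.exp(-(self.a * d + self.b)))


def _fit_platt(decision: np.ndarray, y: np.ndarray, iters: int = 200):
    """Newton fit of P(y=1|d) = sigmoid(a*d + b) with slight target smoothing."""
    n1, n0 = int(y.sum()), int((1 - y).sum())
    t = np.where(y == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))
    a, b = 1.0, 0.0
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-(a * decision + b)))
        g = p - t
        ga, gb = (g * decision).sum(), g.sum()
        w = np.maximum(p * (1 - p), 1e-12)
        haa = (w * decision * decision).sum() + 1e-9
        hab = (w * decision).sum()
        hbb = w.sum() + 1e-9
        det = haa * hbb - hab * hab
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a, b = a - da, b - db
        if abs(da) + abs(db) < 1e-10:
            break
    return a, b


def _svm_fit(X_train, y_train, cfg: SVMConfig, seed: int):
    """Grid-search an RBF SVM on training data only; return calibrated model."""
    y_train = np.asarray(y_train)
    classes, counts = np.unique(y_train, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class training data")
    n_splits = int(min(cfg.inner_folds, counts.min()))
    best = None
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(skf.split(X_train, y_train))
        for C in cfg.C_grid:
            for gamma in cfg.gamma_grid:
                accs = []
                for tr, va in splits:
                    clf = SVC(kernel=cfg.kernel, C=C, gamma=gamma)
                    clf.fit(X_train[tr], y_train[tr])
                    accs.append((clf.predict(X_train[va]) == y_train[va]).mean())
                acc = float(np.mean(accs))
                if best is None or acc > best[0] + 1e-12:  # ties: smaller C then gamma
                    best = (acc, C, gamma)
        _, C, gamma = best
    else:  # too few samples for inner CV: middle-of-grid fallback
        C, gamma = 1.0, 0.01
    clf = SVC(kernel=cfg.kernel, C=C, gamma=gamma)
    clf.fit(X_train, y_train)
    a, b = _fit_platt(clf.decision_function(X_train), y_train)
    return _PlattSVM(clf, a, b), (C, gamma)


def svm_fit_predict(X_train, y_train, X_test, cfg: SVMConfig | None = None,
                    seed: int = 0):
    """Train an RBF SVM (inner 5-fold grid search on train only) and score test.

    Returns ``(scores, (C, gamma))`` where scores are Platt-calibrated
    class-1 probabilities in [0, 1].
    """
    cfg = cfg or SVMConfig()
    model, chosen = _svm_fit(np.asarray(X_train), y_train, cfg, seed)
    return model.scores(X_test), chosen


# ---------------------------------------------------------------------------
# Deep-model training


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without val-loss improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.bad = 0

    def update(self, loss: float, epoch: int) -> bool:
        if loss < self.best - 1e-12:
            self.best, self.best_epoch, self.bad = loss, epoch, 0
            return True
        self.bad += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.bad >= self.patience


class ArrayDataset:
    def __init__(self, X, y):
        self.X, self.y = X, np.asarray(y)

    def __len__(self):
        return len(self.y)

    def batch(self, idx):
        return self.X[idx]


class ListDataset:
    """Dataset over a list of variable-size items (embedding matrices)."""

    def __init__(self, items, y, svs=None):
        self.items, self.y = list(items), np.asarray(y)
        self.svs = svs

    def __len__(self):
        return len(self.y)

    def batch(self, idx):
        ms = [self.items[i] for i in idx]
        if self.svs is not None:
            return (ms, self.svs[idx])
        return ms


def _eval_loss(model, dataset, batch_size: int = 64) -> float:
    losses, counts = [], []
    for i in range(0, len(dataset), batch_size):
        idx = np.arange(i, min(i + batch_size, len(dataset)))
        logits = model.forward_logits(dataset.batch(idx), train=False)
        loss, _ = softmax_cross_entropy(logits, dataset.y[idx])
        losses.append(loss * len(idx))
        counts.append(len(idx))
    return float(np.sum(losses) / np.sum(counts))


def _fit_one(model, train_set, val_set, cfg: TrainConfig, l2: float):
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr, l2=l2)
    stopper = EarlyStopping(cfg.early_stopping_patience)
    best_state = model.get_state()
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(len(train_set))
        ep_losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i: i + cfg.batch_size]
            logits = model.forward_logits(train_set.batch(idx), train=True)
            loss, dlogits = softmax_cross_entropy(logits, train_set.y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_losses.append(loss)
        val_loss = _eval_loss(model, val_set)
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss, epoch):
            best_state = model.get_state()
        if stopper.should_stop:
            break
    model.set_state(best_state)
    history["stopped_epoch"] = epoch
    history["best_epoch"] = stopper.best_epoch
    history["best_val_loss"] = float(stopper.best)
    return history


def train_deep(model, train_set, val_set, cfg: TrainConfig | None = None):
    """Train with Adam + cross-entropy, early stopping on validation loss.

    Dropout and L2 are selected over ``cfg.dropout_grid`` x ``cfg.l2_grid``
    by best validation loss (grid order breaks ties); the returned model
    carries the best-validation checkpoint of the winning combination.
    """
    cfg = cfg or TrainConfig()
    if len(val_set) == 0:
        raise ValueError("empty validation set")
    best = None
    for dp in cfg.dropout_grid:
        for l2 in cfg.l2_grid:
            m = model.respawn(dropout=dp)
            hist = _fit_one(m, train_set, val_set, cfg, l2)
            if best is None or hist["best_val_loss"] < best[0] - 1e-12:
                best = (hist["best_val_loss"], m, hist, dp, l2)
    _, m, hist, dp, l2 = best
    hist["dropout"], hist["l2"] = dp, l2
    return m, hist


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, sensitivity (PD recall), specificity (HC recall), F1 (PD), in %.

    Scores at exactly the threshold count as positive.  Labels may be given
    as {0, 1} integers (1 = PD) or {"HC", "PD"} strings; both classes must be
    present, otherwise sensitivity or specificity is undefined and an error
    is raised.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1]")
    y = np.asarray([1 if (l == 1 or l == PD) else 0 for l in labels])
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute metrics")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return {
        "accuracy": 100.0 * (tp + tn) / len(y),
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "f1": 100.0 * f1,
    }


# ---------------------------------------------------------------------------
# Experiment driver


BRANCHES = (
    "speech_resnet2d", "speech_cnn1d", "speech_pretrained",
    "text_functionals", "text_ngram",
    "fusion_early", "fusion_joint", "fusion_late",
)

METRICS = ("accuracy", "sensitivity", "specificity", "f1")


@dataclass
class ExperimentConfig:
    branch: str
    n_folds: int = 10
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    val_fraction: float = 0.2
    max_chunks_per_speaker: int | None = None  # subsample chunks for deep speech
    stub_dim: int = 768
    gmm_k: int = 8
    text_d: int = 16
    text_filters: int = 64
    threshold: float = 0.5
    embedder: object | None = None  # WordEmbedder; defaults to the toy embedder


@dataclass
class FoldResult:
    fold: int
    train_speakers: list[str]
    test_speakers: list[str]
    scores: dict[str, float]
    metrics: dict[str, float]
    chosen: dict
    fit_log: dict


@dataclass
class CVReport:
    branch: str
    seed: int
    n_speakers: int
    folds: list[FoldResult]
    aggregate: dict[str, tuple[float, float]]
    labels: dict[str, str]

    def score_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            for spk, score in fr.scores.items():
                rows.append({"speaker_id": spk, "label": self.labels[spk],
                             "score": score, "fold": fr.fold})
        return pd.DataFrame(rows).sort_values("speaker_id").reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch, "seed": self.seed,
            "n_speakers": self.n_speakers,
            "aggregate": {m: {"mean": v[0], "std": v[1]}
                          for m, v in self.aggregate.items()},
            "folds": [asdict(f) for f in self.folds],
        }

    def save_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def _aggregate(folds: list[FoldResult]) -> dict[str, tuple[float, float]]:
    out = {}
    for m in METRICS:
        vals = np.array([f.metrics[m] for f in folds])
        out[m] = (float(vals.mean()), float(vals.std()))  # population std
    return out


def _derived_seed(seed: int, fold: int, tag: int) -> int:
    return (seed * 100003 + fold * 613 + tag * 31 + 17) % (2 ** 31)


def _val_split(train_spk: list[str], labels: dict[str, str], fraction: float,
               seed: int) -> tuple[list[str], list[str]]:
    """Stratified inner split of training speakers for early stopping."""
    rng = np.random.default_rng(seed)
    val: list[str] = []
    for lab in sorted(set(labels[s] for s in train_spk)):
        spks = sorted(s for s in train_spk if labels[s] == lab)
        rng.shuffle(spks)
        n_val = max(1, int(round(fraction * len(spks))))
        val.extend(spks[:n_val])
    val = sorted(val)
    fit = sorted(s for s in train_spk if s not in val)
    return fit, val


class _FeatureCache:
    """Per-speaker features computed lazily; none depend on other speakers."""

    def __init__(self, cohort: Cohort, cfg: ExperimentConfig):
        self.cohort = cohort
        self.cfg = cfg
        self.rec = {r.speaker_id: r for r in cohort.recordings}
        self.txt = {t.speaker_id: t for t in cohort.transcripts}
        self._mels = None
        self._raw = None
        self._stub = None
        self._mats = None
        self._functionals = None
        self._svs = None
        self._embedder = cfg.embedder or toy_embedder(d=cfg.text_d,
                                                      seed=cfg.seed)

    def _subsample(self, X):
        m = self.cfg.max_chunks_per_speaker
        if m is None or len(X) <= m:
            return X
        idx = np.linspace(0, len(X) - 1, m).round().astype(int)
        return X[idx]

    @property
    def mels(self) -> dict[str, np.ndarray]:
        if self._mels is None:
            self._mels = {}
            for spk, rec in self.rec.items():
                chunks = segment(rec)
                mels = [mel_spectrogram(c) for c in chunks]
                self._mels[spk] = self._subsample(standardize_recording_mels(mels))
        return self._mels

    @property
    def raw_chunks(self) -> dict[str, np.ndarray]:
        if self._raw is None:
            self._raw = {}
            for spk, rec in self.rec.items():
                X = np.stack([c.samples for c in segment(rec)])[:, None, :]
                self._raw[spk] = self._subsample(X.astype(np.float32))
        return self._raw

    @property
    def stub_embeddings(self) -> dict[str, np.ndarray]:
        if self._stub is None:
            emb = LogMelProjectionEmbedder(dim=self.cfg.stub_dim, seed=self.cfg.seed)
            self._stub = {spk: chunk_embeddings(rec, emb)
                          for spk, rec in self.rec.items()}
        return self._stub

    @property
    def matrices(self) -> dict[str, np.ndarray]:
        if self._mats is None:
            self._mats = {spk: embed_transcript(t, self._embedder).M
                          for spk, t in self.txt.items()}
        return self._mats

    @property
    def functionals(self) -> dict[str, np.ndarray]:
        if self._functionals is None:
            from .text import functional_vector
            self._functionals = {spk: functional_vector(M)
                                 for spk, M in self.matrices.items()}
        return self._functionals

    @property
    def supervectors(self) -> dict[str, np.ndarray]:
        if self._svs is None:
            self._svs = {
                spk: gmm_supervector(embs, K=self.cfg.gmm_k,
                                     seed=self.cfg.seed, speaker_id=spk).values
                for spk, embs in self.stub_embeddings.items()}
        return self._svs


def _labels01(labels: dict[str, str], speakers) -> np.ndarray:
    return np.array([1 if labels[s] == PD else 0 for s in speakers])


def _train_deep_fold(proto, feats: dict[str, np.ndarray], labels, fit_spk,
                     val_spk, tcfg: TrainConfig):
    def stack(spks):
        X = np.concatenate([feats[s] for s in spks])
        y = np.concatenate([[1 if labels[s] == PD else 0] * len(feats[s])
                            for s in spks])
        return ArrayDataset(X, y)

    return train_deep(proto, stack(fit_spk), stack(val_spk), tcfg)


def _chunk_speaker_scores(model, feats, speakers) -> dict[str, float]:
    return {s: float(model.predict_proba(feats[s])[:, 1].mean())
            for s in speakers}


def _train_text_fold(cache: _FeatureCache, labels, fit_spk, val_spk,
                     tcfg: TrainConfig, seed: int, sv_scaler=None):
    cfg = cache.cfg
    svs = None
    sv_dim = 0
    if sv_scaler is not None:
        svs = {s: sv_scaler.transform(cache.supervectors[s][None])[0]
               for s in cache.rec}
        sv_dim = len(next(iter(svs.values())))
    d = cache.matrices[next(iter(cache.matrices))].shape[1]
    proto = NgramCNN(NgramCNNConfig(d=d, filters=cfg.text_filters,
                                    sv_dim=sv_dim, seed=seed))

    def dataset(spks):
        ms = [cache.matrices[s] for s in spks]
        y = _labels01(labels, spks)
        if svs is not None:
            return ListDataset(ms, y, svs=np.stack([svs[s] for s in spks]))
        return ListDataset(ms, y)

    model, hist = train_deep(proto, dataset(fit_spk), dataset(val_spk), tcfg)

    def score(spks) -> dict[str, float]:
        ds = dataset(spks)
        probs = model.predict_proba(ds.batch(np.arange(len(spks))))
        return {s: float(p[1]) for s, p in zip(spks, probs)}

    def embed(spks) -> dict[str, np.ndarray]:
        E = model.embed_batch([cache.matrices[s] for s in spks], train=False)
        return {s: e for s, e in zip(spks, E)}

    return model, hist, score, embed


def run_experiment(cohort: Cohort, cfg: ExperimentConfig) -> CVReport:
    """Run one branch of the pipeline under speaker-independent k-fold CV."""
    if cfg.branch not in BRANCHES:
        raise ValueError(f"unknown branch {cfg.branch!r}; expected one of {BRANCHES}")
    labels = cohort.labels
    plan = speaker_folds(labels, k=cfg.n_folds, seed=cfg.seed)
    cache = _FeatureCache(cohort, cfg)
    folds: list[FoldResult] = []

    for fold in range(cfg.n_folds):
        train_spk, test_spk = plan.fold_speakers(fold)
        fseed = _derived_seed(cfg.seed, fold, 0)
        fit_log = {"standardizer_speakers": [], "grid_search_speakers": [],
                   "early_stopping_speakers": [], "gmm_speakers": {}}
        chosen: dict = {}

        def svm_on(vectors: dict[str, np.ndarray], tr=None):
            """Standardize on train, grid-search on train, score everyone."""
            tr_ = tr or train_spk
            scaler = StandardScaler().fit(np.stack([vectors[s] for s in tr_]))
            fit_log["standardizer_speakers"] = sorted(tr_)
            fit_log["grid_search_speakers"] = sorted(tr_)
            Xtr = scaler.transform(np.stack([vectors[s] for s in tr_]))
            model, params = _svm_fit(Xtr, _labels01(labels, tr_), cfg.svm, fseed)

            def score(spks) -> dict[str, float]:
                X = scaler.transform(np.stack([vectors[s] for s in spks]))
                return dict(zip(spks, model.scores(X)))

            return score, params, scaler

        if cfg.branch in ("speech_resnet2d", "speech_cnn1d"):
            fit_spk, val_spk = _val_split(train_spk, labels, cfg.val_fraction,
                                          _derived_seed(cfg.seed, fold, 1))
            fit_log["early_stopping_speakers"] = val_spk
            feats = (cache.mels if cfg.branch == "speech_resnet2d"
                     else cache.raw_chunks)
            if cfg.branch == "speech_resnet2d":
                proto = ResNet2D(ResNet2DConfig(seed=fseed))
            else:
                proto = CNN1DLSTM(CNN1DLSTMConfig(seed=fseed))
            tcfg = replace(cfg.train, seed=fseed)
            model, hist = _train_deep_fold(proto, feats, labels, fit_spk,
                                           val_spk, tcfg)
            scores = _chunk_speaker_scores(model, feats, test_spk)
            chosen = {"dropout": hist["dropout"], "l2": hist["l2"],
                      "stopped_epoch": hist["stopped_epoch"]}

        elif cfg.branch == "speech_pretrained":
            pooled = {s: mean_pool(e) for s, e in cache.stub_embeddings.items()}
            score, params, _ = svm_on(pooled)
            scores = score(test_spk)
            chosen = {"C": params[0], "gamma": params[1]}

        elif cfg.branch == "text_functionals":
            score, params, _ = svm_on(cache.functionals)
            scores = score(test_spk)
            chosen = {"C": params[0], "gamma": params[1]}

        elif cfg.branch == "text_ngram":
            fit_spk, val_spk = _val_split(train_spk, labels, cfg.val_fraction,
                                          _derived_seed(cfg.seed, fold, 1))
            fit_log["early_stopping_speakers"] = val_spk
            tcfg = replace(cfg.train, seed=fseed)
            _, hist, score, _ = _train_text_fold(cache, labels, fit_spk,
                                                 val_spk, tcfg, fseed)
            scores = score(test_spk)
            chosen = {"dropout": hist["dropout"], "l2": hist["l2"],
                      "stopped_epoch": hist["stopped_epoch"]}

        elif cfg.branch == "fusion_early":
            fit_spk, val_spk = _val_split(train_spk, labels, cfg.val_fraction,
                                          _derived_seed(cfg.seed, fold, 1))
            fit_log["early_stopping_speakers"] = val_spk
            tcfg = replace(cfg.train, seed=fseed)
            _, hist, _, embed = _train_text_fold(cache, labels, fit_spk,
                                                 val_spk, tcfg, fseed)
            lang = embed(sorted(labels))
            pooled = {s: mean_pool(e) for s, e in cache.stub_embeddings.items()}
            fused = {s: early_fuse(pooled[s], lang[s]).values
                     for s in sorted(labels)}
            score, params, _ = svm_on(fused)
            scores = score(test_spk)
            chosen = {"C": params[0], "gamma": params[1],
                      "text_dropout": hist["dropout"]}

        elif cfg.branch == "fusion_joint":
            fit_spk, val_spk = _val_split(train_spk, labels, cfg.val_fraction,
                                          _derived_seed(cfg.seed, fold, 1))
            fit_log["early_stopping_speakers"] = val_spk
            fit_log["gmm_speakers"] = {s: [s] for s in sorted(labels)}
            sv_scaler = StandardScaler().fit(
                np.stack([cache.supervectors[s] for s in train_spk]))
            fit_log["standardizer_speakers"] = sorted(train_spk)
            tcfg = replace(cfg.train, seed=fseed)
            _, hist, score, _ = _train_text_fold(cache, labels, fit_spk,
                                                 val_spk, tcfg, fseed,
                                                 sv_scaler=sv_scaler)
            scores = score(test_spk)
            chosen = {"dropout": hist["dropout"], "l2": hist["l2"],
                      "gmm_k": cfg.gmm_k, "stopped_epoch": hist["stopped_epoch"]}

        elif cfg.branch == "fusion_late":
            fit_spk, val_spk = _val_split(train_spk, labels, cfg.val_fraction,
                                          _derived_seed(cfg.seed, fold, 1))
            fit_log["early_stopping_speakers"] = val_spk
            tcfg = replace(cfg.train, seed=fseed)
            _, hist, t_score, _ = _train_text_fold(cache, labels, fit_spk,
                                                   val_spk, tcfg, fseed)
            pooled = {s: mean_pool(e) for s, e in cache.stub_embeddings.items()}
            s_score, s_params, _ = svm_on(pooled)
            sp, tx = s_score(sorted(labels)), t_score(sorted(labels))
            bimodal = {s: late_fuse(float(np.clip(sp[s], 0, 1)),
                                    float(np.clip(tx[s], 0, 1))).values
                       for s in sorted(labels)}
            score, params, _ = svm_on(bimodal)
            scores = score(test_spk)
            chosen = {"C": params[0], "gamma": params[1],
                      "speech_C": s_params[0], "speech_gamma": s_params[1]}

        metrics = compute_metrics([scores[s] for s in test_spk],
                                  [labels[s] for s in test_spk],
                                  threshold=cfg.threshold)
        folds.append(FoldResult(
            fold=fold, train_speakers=train_spk, test_speakers=test_spk,
            scores={s: float(scores[s]) for s in test_spk}, metrics=metrics,
            chosen=chosen, fit_log=fit_log))

    return CVReport(branch=cfg.branch, seed=cfg.seed, n_speakers=len(labels),
                    folds=folds, aggregate=_aggregate(folds), labels=labels)


def desk_scale_train_config(seed: int = 0) -> TrainConfig:
    """Reduced training regimen used for the end-to-end synthetic experiments.

    The full regimen (200 epochs, patience 40, 3x3 hyper-parameter grid) is
    the default; this preset trains the numpy models for up to 6 epochs with
    patience 3 at a single grid point, which the strongly separable synthetic
    cohorts saturate comfortably.
    """
    return TrainConfig(epochs=6, early_stopping_patience=3,
                       dropout_grid=(0.2,), l2_grid=(0.0001,), seed=seed)


def desk_scale_text_train_config(seed: int = 0) -> TrainConfig:
    """Reduced regimen for the (much cheaper) text and joint-fusion CNNs.

    A cohort of a few dozen speakers gives only one mini-batch per epoch, so
    the text models get a larger epoch budget than the speech CNNs; sixty
    epochs are still two orders of magnitude below the full regimen's cost.
    """
    return TrainConfig(epochs=60, early_stopping_patience=10,
                       dropout_grid=(0.2,), l2_grid=(0.0001,), seed=seed)
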