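"""Language encoders: embedding matrices, statistical functionals, n-gram CNN.

Each transliteration (the verbatim transcript of a spontaneous monologue) is
mapped to an embedding matrix ``M`` of shape ``n x d`` — one row per token —
through a pluggable word embedder.  Two representations are derived from it:

* a static functional vector stacking four per-dimension statistics
  (mean, standard deviation, skewness, kurtosis) into a ``4d`` vector, fed to
  an SVM downstream;
* a multi-kernel n-gram CNN: one-dimensional convolutions with kernels
  spanning the full embedding dimension and widths 2, 3 and 4 tokens (bi-,
  tri- and four-gram contexts), max pooling over positions per filter, and a
  fully connected softmax head on the concatenated per-filter maxima.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol

import numpy as np
from scipy import stats

from . import nn
from .nn.losses import softmax


@dataclass
class Transliteration:
    tokens: list[str]
    speaker_id: str
    label: str | None = None

    @property
    def n_words(self) -> int:
        return len(self.tokens)


_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return _PUNCT.sub(" ", text.lower()).split()


class WordEmbedder(Protocol):
    dim: int

    def vector(self, token: str) -> np.ndarray: ...


def oov_vector(token: str, dim: int, scale: float = 1.0) -> np.ndarray:
    """Deterministic pseudo-random vector for an out-of-vocabulary token.

    Seeded from a stable hash of the token so the same word maps to the same
    vector in every process.
    """
    seed = int.from_bytes(hashlib.md5(token.encode("utf-8")).digest()[:4], "little")
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal(dim)


class TableEmbedder:
    """Context-independent lookup table with deterministic OOV fallback."""

    def __init__(self, table: dict[str, np.ndarray], name: str = "table"):
        if not table:
            raise ValueError("empty embedding table")
        self.table = {t: np.asarray(v, dtype=np.float64) for t, v in table.items()}
        dims = {v.shape[0] for v in self.table.values()}
        if len(dims) != 1:
            raise ValueError("inconsistent embedding dimensions in table")
        self.dim = dims.pop()
        self.name = name

    @classmethod
    def from_word2vec_text(cls, path: str | Path, name: str | None = None
                           ) -> "TableEmbedder":
        """Load the word2vec text format (optional count/dim header line)."""
        table = {}
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().split()
            if len(first) != 2 or not first[1].lstrip("-").isdigit():
                table[first[0]] = np.array([float(v) for v in first[1:]])
            for line in fh:
                parts = line.split()
                if parts:
                    table[parts[0]] = np.array([float(v) for v in parts[1:]])
        return cls(table, name=name or Path(path).stem)

    def vector(self, token: str) -> np.ndarray:
        v = self.table.get(token)
        return v if v is not None else oov_vector(token, self.dim)


class ContextualToyEmbedder:
    """Deterministic toy context-dependent embedder (for tests and demos).

    A token's vector is its base (context-independent) vector blended with
    the average of its immediate neighbors' base vectors, mimicking how
    transformer embeddings shift with context.
    """

    def __init__(self, base: WordEmbedder, mix: float = 0.5):
        self.base = base
        self.mix = mix
        self.dim = base.dim

    def vector(self, token: str) -> np.ndarray:
        return self.base.vector(token)

    def matrix(self, tokens: list[str]) -> np.ndarray:
        base = np.stack([self.base.vector(t) for t in tokens])
        out = base.copy()
        for i in range(len(tokens)):
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < len(tokens)]
            if nbrs:
                out[i] = (1 - self.mix) * base[i] + self.mix * base[nbrs].mean(axis=0)
        return out


@dataclass
class EmbeddingMatrix:
    M: np.ndarray            # (n, d)
    embedder_name: str = ""
    speaker_id: str = ""
    label: str | None = None


def embed_transcript(t: Transliteration, embedder: WordEmbedder
                     ) -> EmbeddingMatrix:
    """Build the ``n x d`` embedding matrix, one row per token in order."""
    if not t.tokens:
        raise ValueError("empty token list")
    if hasattr(embedder, "matrix"):  # context-dependent path
        M = embedder.matrix(t.tokens)
    else:
        M = np.stack([embedder.vector(tok) for tok in t.tokens])
    return EmbeddingMatrix(M=M, embedder_name=getattr(embedder, "name", type(embedder).__name__),
                           speaker_id=t.speaker_id, label=t.label)


def functional_vector(M: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Stack per-dimension mean, population std, skewness and kurtosis (4d).

    Kurtosis is the raw (non-excess) fourth standardized moment.  Dimensions
    with zero variance get skewness 0 and kurtosis 0 so degenerate columns
    never propagate NaNs.
    """
    X = M.M if isinstance(M, EmbeddingMatrix) else np.asarray(M, dtype=np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population (ddof=0)
    nz = std > 1e-12
    skew = np.zeros_like(mean)
    kurt = np.zeros_like(mean)
    if X.shape[0] > 1 and nz.any():
        skew[nz] = stats.skew(X[:, nz], axis=0, bias=True)
        kurt[nz] = stats.kurtosis(X[:, nz], axis=0, fisher=False, bias=True)
    return np.concatenate([mean, std, skew, kurt])


# ---------------------------------------------------------------------------
# n-gram CNN


@dataclass(frozen=True)
class NgramCNNConfig:
    d: int
    widths: tuple[int, ...] = (2, 3, 4)
    filters: int = 64
    n_classes: int = 2
    dropout: float = 0.2
    sv_dim: int = 0          # joint fusion: supervector concatenated pre-head
    seed: int = 0

    @property
    def language_embedding_dim(self) -> int:
        return len(self.widths) * self.filters


class NgramCNN:
    """Multi-kernel n-gram CNN over embedding matrices.

    For each kernel width ``w`` the kernel spans the full embedding dimension
    (shape ``w x d``); a valid 1-D convolution over token positions gives
    ``n - w + 1`` activations per filter and max pooling keeps one value per
    filter.  The concatenated maxima form the language embedding; the head is
    a single fully connected layer with softmax.  When ``sv_dim > 0`` a fixed
    per-speaker supervector is concatenated to the language embedding just
    before the head (joint fusion); the supervector is an input, not a
    learned quantity, but the loss gradient reaches the convolution filters.

    Inputs shorter than the widest kernel are zero-row padded.
    """

    kind = "ngram_cnn"

    def __init__(self, cfg: NgramCNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.W = [nn.Param(nn.layers.he_init(rng, (cfg.filters, w * cfg.d), w * cfg.d),
                           f"ngram{w}.W") for w in cfg.widths]
        self.b = [nn.Param(np.zeros(cfg.filters), f"ngram{w}.b", is_weight=False)
                  for w in cfg.widths]
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.head = nn.Dense(cfg.language_embedding_dim + cfg.sv_dim,
                             cfg.n_classes, rng, name="head")

    # -- batching helpers ---------------------------------------------------

    def _pad_batch(self, Ms: list[np.ndarray]):
        d = self.cfg.d
        for M in Ms:
            if M.shape[1] != d:
                raise ValueError(f"embedding dim mismatch: model d={d}, "
                                 f"matrix d={M.shape[1]}")
        wmax = max(self.cfg.widths)
        lengths = np.array([max(M.shape[0], wmax) for M in Ms])
        N = lengths.max()
        X = np.zeros((len(Ms), N, d), dtype=np.float32)
        for i, M in enumerate(Ms):
            X[i, : M.shape[0]] = M
        return X, lengths

    def embed_batch(self, Ms: list[np.ndarray], train: bool = False):
        """Language embeddings ``(B, widths*filters)`` with argmax caches."""
        X, lengths = self._pad_batch(Ms)
        B, N, d = X.shape
        outs, caches = [], []
        for wi, w in enumerate(self.cfg.widths):
            P = N - w + 1
            win = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)
            win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, P, w * d)
            act = win @ self.W[wi].data.T + self.b[wi].data  # (B, P, F)
            valid = np.maximum(lengths - w + 1, 1)
            mask = np.arange(P)[None, :] >= valid[:, None]
            act = np.where(mask[:, :, None], -np.inf, act)
            arg = act.argmax(axis=1)                          # (B, F)
            outs.append(act.max(axis=1))
            caches.append((win, arg))
        self._caches = caches
        E = np.concatenate(outs, axis=1)
        return E

    def forward_logits(self, X, train: bool = False):
        """X: list of matrices, or tuple ``(list_of_matrices, sv_array)``."""
        if isinstance(X, tuple):
            Ms, svs = X
        else:
            Ms, svs = X, None
        E = self.embed_batch(Ms, train=train)
        if self.cfg.sv_dim:
            if svs is None or svs.shape[1] != self.cfg.sv_dim:
                raise ValueError(
                    f"expected supervectors of dim {self.cfg.sv_dim}")
            E = np.concatenate([E, svs.astype(E.dtype)], axis=1)
        elif svs is not None:
            raise ValueError("model was not built with a supervector slot")
        E = self.drop.forward(E, train=train)
        return self.head.forward(E, train=train)

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        g = self.drop.backward(g)
        F = self.cfg.filters
        for wi, _w in enumerate(self.cfg.widths):
            gw = g[:, wi * F: (wi + 1) * F]      # (B, F)
            win, arg = self._caches[wi]
            B = gw.shape[0]
            bi = np.repeat(np.arange(B), F)
            fi = np.tile(np.arange(F), B)
            rows = win[bi, arg.ravel()]           # (B*F, w*d)
            np.add.at(self.W[wi].grad, fi, gw.ravel()[:, None] * rows)
            self.b[wi].grad += gw.sum(axis=0)
        # gradient w.r.t. token embeddings is not needed (inputs are fixed)
        return None

    def params(self):
        out = []
        for W, b in zip(self.W, self.b):
            out += [W, b]
        return out + self.head.params()

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        if isinstance(X, tuple):
            Ms, svs = X
            chunks = [
                (Ms[i:i + batch_size], svs[i:i + batch_size])
                for i in range(0, len(Ms), batch_size)]
        else:
            chunks = [X[i:i + batch_size] for i in range(0, len(X), batch_size)]
        return np.concatenate(
            [softmax(self.forward_logits(c, train=False)) for c in chunks])

    def respawn(self, dropout: float | None = None) -> "NgramCNN":
        cfg = self.cfg if dropout is None else replace(self.cfg, dropout=dropout)
        return NgramCNN(cfg)

    def get_state(self):
        return [p.data.copy() for p in self.params()]

    def set_state(self, state):
        for p, s in zip(self.params(), state):
            p.data[...] = s


def build_ngram_cnn(cfg: NgramCNNConfig) -> NgramCNN:
    return NgramCNN(cfg)


def ngram_cnn_forward(M: EmbeddingMatrix | np.ndarray, model: NgramCNN):
    """Single-matrix forward: returns ``(language_embedding, probs)``."""
    X = M.M if isinstance(M, EmbeddingMatrix) else np.asarray(M)
    E = model.embed_batch([X], train=False)
    probs = softmax(model.forward_logits([X], train=False))
    return E[0], probs[0]


# ---------------------------------------------------------------------------
# Transcript I/O


def read_transcript(path: str | Path, speaker_id: str = "",
                    label: str | None = None) -> Transliteration:
    text = Path(path).read_text(encoding="utf-8")
    return Transliteration(tokens=tokenize(text),
                           speaker_id=speaker_id or Path(path).stem, label=label)


def read_transcripts_jsonl(path: str | Path) -> list[Transliteration]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append(Transliteration(tokens=tokenize(rec["text"]),
                                           speaker_id=rec["speaker_id"],
                                           label=rec.get("label")))
    return out
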