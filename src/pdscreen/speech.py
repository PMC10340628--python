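"""Speech encoders: 1D-CNN+LSTM, residual 2D-CNN, and a pluggable embedder.

Three per-chunk speech representations are provided:

* a 1-D CNN (16 then 32 channels, each followed by temporal max pooling of
  size 2) feeding two 64-cell LSTM layers and a fully connected 2-class head,
  applied to raw 500 ms waveform chunks;
* a residual 2-D CNN over 128 x 63 log-mel spectrograms — input convolution
  with 16 channels, three stages of two residual blocks with 16/32/64 feature
  maps, global average pooling per channel to a 64-dimensional chunk
  embedding, and a 2-class head;
* an adapter around any pretrained frame-level embedder: frame embeddings are
  mean-pooled over time into one fixed-length vector per recording or chunk.
  A deterministic stub embedder (a fixed random projection of log-mel frames)
  ships with the package so the full pipeline runs without downloads.

The module also exposes the textbook primitives (`conv1d_apply`,
`conv2d_apply`, `lstm_step`) as pure functions; the learned layers in
:mod:`pdscreen.nn` use the framework cross-correlation convention, while
`conv2d_apply` is the flipped-kernel convolution and is kept as the reference
definition.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np
from scipy.signal import convolve2d

from . import nn
from .audio import AudioRecording, Chunk, MelConfig, mel_spectrogram, segment
from .nn.losses import softmax


# ---------------------------------------------------------------------------
# Pure-function primitives


@dataclass
class Conv1DSpec:
    weights: np.ndarray  # (C_out, C_in, K)
    bias: np.ndarray     # (C_out,)


def conv1d_apply(x: np.ndarray, spec: Conv1DSpec) -> np.ndarray:
    """Valid cross-correlation of a ``(C_in, L)`` sequence with a filter bank.

    Output channel ``j`` is ``bias[j] + sum_k weights[j,k] (x) x[k]`` where
    ``(x)`` slides the kernel without flipping; output length is
    ``L - K + 1``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    W = np.asarray(spec.weights, dtype=np.float64)
    b = np.asarray(spec.bias, dtype=np.float64)
    c_out, c_in, K = W.shape
    if x.shape[0] != c_in:
        raise ValueError(f"expected {c_in} input channels, got {x.shape[0]}")
    L = x.shape[1]
    if L < K:
        raise ValueError(f"input length {L} shorter than kernel {K}")
    win = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)  # (C_in, L', K)
    return np.einsum("clk,jck->jl", win, W) + b[:, None]


def conv2d_apply(I: np.ndarray, H: np.ndarray) -> np.ndarray:
    """True 2-D convolution ``G[m,n] = sum_{j,k} H[j,k] I[m-j, n-k]`` (valid).

    The kernel is flipped relative to cross-correlation; restricted to the
    valid region so no padding assumptions enter.
    """
    I = np.asarray(I, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    if H.shape[0] > I.shape[0] or H.shape[1] > I.shape[1]:
        raise ValueError(f"kernel {H.shape} larger than image {I.shape}")
    return convolve2d(I, H, mode="valid")


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


@dataclass
class LSTMStepWeights:
    """One gate-weight matrix per gate, acting on ``[h_{t-1}, x_t]``."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray


def lstm_step(x_t: np.ndarray, state: LSTMState, weights: LSTMStepWeights
              ) -> LSTMState:
    """One LSTM cell update.

    f, i, o are logistic gates on ``[h_{t-1}, x_t]``; the cell state is
    ``c_t = f*c_{t-1} + i*c~`` and the hidden state ``h_t = o * tanh(c_t)``.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(state.h))
            and np.all(np.isfinite(state.c))):
        raise ValueError("non-finite inputs to lstm_step")
    z = np.concatenate([state.h, x_t])

    def sigma(v):
        return 1.0 / (1.0 + np.exp(-v))

    f = sigma(weights.W_f @ z + weights.b_f)
    i = sigma(weights.W_i @ z + weights.b_i)
    c_tilde = np.tanh(weights.W_c @ z + weights.b_c)
    o = sigma(weights.W_o @ z + weights.b_o)
    c = f * state.c + i * c_tilde
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


# ---------------------------------------------------------------------------
# Trainable models


@dataclass
class ChunkScore:
    speaker_id: str
    chunk_index: int
    score: float                      # class-1 (PD) probability
    embedding: np.ndarray | None = None


def speaker_score(chunk_scores: list[ChunkScore]) -> float:
    """Speaker-level decision score: the mean of the per-chunk scores."""
    if not chunk_scores:
        raise ValueError("no chunk scores for speaker")
    return float(np.mean([c.score for c in chunk_scores]))


class ClassifierModel:
    """Shared training/prediction surface for the numpy models."""

    net: nn.Sequential
    cfg: object

    def forward_logits(self, X, train: bool = False) -> np.ndarray:
        return self.net.forward(X, train=train)

    def backward(self, dlogits) -> None:
        self.net.backward(dlogits)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def predict_proba(self, X, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            out.append(softmax(self.forward_logits(X[i:i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def respawn(self, dropout: float | None = None) -> "ClassifierModel":
        """Fresh re-initialized copy (same seed), optionally new dropout."""
        cfg = self.cfg if dropout is None else replace(self.cfg, dropout=dropout)
        return type(self)(cfg)

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p.data[...] = s


@dataclass(frozen=True)
class CNN1DLSTMConfig:
    input_len: int = 4000
    conv_channels: tuple[int, int] = (16, 32)
    kernel_sizes: tuple[int, int] = (16, 8)
    strides: tuple[int, int] = (4, 4)
    pool: int = 2
    lstm_hidden: int = 64
    lstm_layers: int = 2
    n_classes: int = 2
    dropout: float = 0.2
    seed: int = 0


class CNN1DLSTM(ClassifierModel):
    """Raw-waveform chunk classifier: two strided 1-D convolutions (16 and 32
    channels), each followed by temporal max pooling of size 2, two 64-cell
    LSTM layers, and a fully connected 2-class head on the last hidden state.
    """

    kind = "cnn1d_lstm"

    def __init__(self, cfg: CNN1DLSTMConfig | None = None):
        self.cfg = cfg or CNN1DLSTMConfig()
        c = self.cfg
        rng = np.random.default_rng(c.seed)
        self.conv1 = nn.Conv1d(1, c.conv_channels[0], c.kernel_sizes[0], rng,
                               stride=c.strides[0], name="conv1")
        self.pool1 = nn.MaxPool1d(c.pool)
        self.conv2 = nn.Conv1d(c.conv_channels[0], c.conv_channels[1],
                               c.kernel_sizes[1], rng, stride=c.strides[1],
                               name="conv2")
        self.pool2 = nn.MaxPool1d(c.pool)
        self.relu1, self.relu2 = nn.ReLU(), nn.ReLU()
        self.lstms = [
            nn.LSTM(c.conv_channels[1] if i == 0 else c.lstm_hidden,
                    c.lstm_hidden, rng, name=f"lstm{i}")
            for i in range(c.lstm_layers)
        ]
        self.drop = nn.Dropout(c.dropout, rng)
        self.head = nn.Dense(c.lstm_hidden, c.n_classes, rng, name="head")

    @property
    def layer_inventory(self) -> list[str]:
        c = self.cfg
        inv = []
        for i, ch in enumerate(c.conv_channels):
            inv.append(f"conv1d({ch}ch)")
            inv.append(f"maxpool({c.pool})")
        inv += [f"lstm({c.lstm_hidden})" for _ in range(c.lstm_layers)]
        inv.append(f"dense({c.n_classes})")
        return inv

    def forward_logits(self, X, train: bool = False):
        x = self.relu1.forward(self.conv1.forward(X, train=train))
        x = self.pool1.forward(x)
        x = self.relu2.forward(self.conv2.forward(x, train=train))
        x = self.pool2.forward(x)
        x = np.ascontiguousarray(x.transpose(0, 2, 1))  # (B, T, C)
        for lstm in self.lstms:
            x = lstm.forward(x, train=train)
        self._T = x.shape[1]
        h_last = x[:, -1]
        h_last = self.drop.forward(h_last, train=train)
        return self.head.forward(h_last, train=train)

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        g = self.drop.backward(g)
        gseq = np.zeros((g.shape[0], self._T, g.shape[1]), dtype=g.dtype)
        gseq[:, -1] = g
        for lstm in reversed(self.lstms):
            gseq = lstm.backward(gseq)
        g = np.ascontiguousarray(gseq.transpose(0, 2, 1))
        g = self.pool2.backward(g)
        g = self.conv2.backward(self.relu2.backward(g))
        g = self.pool1.backward(g)
        self.conv1.backward(self.relu1.backward(g))

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        for lstm in self.lstms:
            out += lstm.params()
        return out + self.head.params()


@dataclass(frozen=True)
class ResNet2DConfig:
    n_mels: int = 128
    n_frames: int = 63
    stem_channels: int = 16
    stage_channels: tuple[int, int, int] = (16, 32, 64)
    blocks_per_stage: int = 2
    n_classes: int = 2
    dropout: float = 0.2
    batch_norm: bool = True
    bias: bool = False        # conv bias (off under batch norm, canonical)
    seed: int = 0

    @property
    def embedding_dim(self) -> int:
        return self.stage_channels[-1]


class ResNet2D(ClassifierModel):
    """Residual spectrogram encoder.

    Stem: 7x7 stride-2 convolution with 16 channels + 3x3 stride-2 max pool
    (the canonical residual-network stem).  Trunk: three stages of two
    residual blocks with 16, 32 and 64 feature maps (stages 2 and 3 enter
    with a stride-2 block whose skip path is a 1x1 projection).  Global
    average pooling per channel yields a 64-dimensional chunk embedding,
    followed by dropout and a fully connected 2-class head.
    """

    kind = "resnet2d"

    def __init__(self, cfg: ResNet2DConfig | None = None):
        self.cfg = cfg or ResNet2DConfig()
        c = self.cfg
        rng = np.random.default_rng(c.seed)
        bn = ([nn.BatchNorm2d(c.stem_channels, name="stem.bn")]
              if c.batch_norm else [])
        stem = [
            nn.Conv2d(1, c.stem_channels, 7, rng, stride=2, pad=3, bias=c.bias,
                      name="stem.conv"),
            *bn,
            nn.ReLU(),
            nn.MaxPool2d(3, 2, pad=1),
        ]
        blocks = []
        c_in = c.stem_channels
        for s, ch in enumerate(c.stage_channels):
            for b in range(c.blocks_per_stage):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(nn.ResidualBlock(
                    c_in, ch, rng, stride=stride, batch_norm=c.batch_norm,
                    bias=c.bias, name=f"s{s}b{b}"))
                c_in = ch
        self.encoder = nn.Sequential(*stem, *blocks, nn.GlobalAvgPool2d())
        self.blocks = blocks
        self.drop = nn.Dropout(c.dropout, rng)
        self.head = nn.Dense(c.embedding_dim, c.n_classes, rng,
                             bias=not (c.bias is False and not c.batch_norm),
                             name="head")
        self.net = nn.Sequential(self.encoder, self.drop, self.head)

    def _check_input(self, X):
        c = self.cfg
        if X.shape[2:] != (c.n_mels, c.n_frames):
            raise ValueError(
                f"expected input {c.n_mels}x{c.n_frames}, got "
                f"{X.shape[2]}x{X.shape[3]}")

    def forward_logits(self, X, train: bool = False):
        self._check_input(X)
        return self.net.forward(X, train=train)

    def embed(self, X) -> np.ndarray:
        """64-d chunk embeddings (encoder output before the head)."""
        self._check_input(X)
        return self.encoder.forward(X, train=False)


@dataclass(frozen=True)
class SpeechModelSpec:
    """Lightweight descriptor of a built speech model (for reports/CLI)."""

    kind: str
    embedding_dim: int | None
    n_params: int


def build_cnn1d_lstm(cfg: CNN1DLSTMConfig | None = None) -> CNN1DLSTM:
    return CNN1DLSTM(cfg)


def build_resnet2d(cfg: ResNet2DConfig | None = None) -> ResNet2D:
    return ResNet2D(cfg)


# ---------------------------------------------------------------------------
# Pretrained-embedder adapter


class PretrainedEmbedder(Protocol):
    """Contract for pluggable frame-level speech embedders."""

    dim: int

    def frame_embeddings(self, samples: np.ndarray, rate: int) -> np.ndarray:
        """Return a (T, dim) matrix of frame embeddings."""
        ...


class LogMelProjectionEmbedder:
    """Deterministic stand-in for a pretrained speech embedder (synthetic).

    Projects 128-band log-mel frames through a fixed, seed-determined random
    matrix followed by tanh.  It carries whatever class structure the mel
    frames carry, is bit-reproducible, and declares its dimension like a real
    self-supervised model adapter would (768 by default, matching the common
    transformer hidden size).
    """

    def __init__(self, dim: int = 768, seed: int = 0, n_mels: int = 128,
                 hop_length: int = 64):
        self.dim = dim
        self.seed = seed
        self.n_mels = n_mels
        self.hop_length = hop_length
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(0.0, 1.0 / np.sqrt(n_mels), size=(n_mels, dim))

    def frame_embeddings(self, samples: np.ndarray, rate: int) -> np.ndarray:
        chunk = Chunk(samples=np.asarray(samples, dtype=np.float64), rate=rate,
                      start_s=0.0, parent_speaker="")
        cfg = MelConfig(n_mels=self.n_mels, hop_length=self.hop_length)
        mel = mel_spectrogram(chunk, cfg, expected_samples=None)
        frames = mel.values.T  # (T, n_mels)
        frames = (frames - frames.mean()) / (frames.std() + 1e-8)
        return np.tanh(frames @ self._proj)


def pretrained_embed(recording: AudioRecording,
                     embedder: PretrainedEmbedder) -> np.ndarray:
    """Temporal mean of the embedder's frame embeddings: one vector per file."""
    frames = embedder.frame_embeddings(np.asarray(recording.samples), recording.rate)
    frames = np.asarray(frames)
    if frames.ndim != 2 or frames.shape[0] == 0:
        raise ValueError("embedder returned an empty frame sequence")
    return frames.mean(axis=0)


def chunk_embeddings(recording: AudioRecording, embedder: PretrainedEmbedder,
                     win_ms: float = 500.0, shift_ms: float = 250.0
                     ) -> np.ndarray:
    """Mean-pooled embedder vector per chunk: ``(n_chunks, dim)``."""
    chunks = segment(recording, win_ms=win_ms, shift_ms=shift_ms)
    return np.stack([
        pretrained_embed(
            AudioRecording(ch.samples, ch.rate, recording.speaker_id,
                           recording.label), embedder)
        for ch in chunks
    ])
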