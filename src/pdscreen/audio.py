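"""Audio preprocessing: loading, resampling, chunking, log-mel spectrograms.

The front end mirrors common dysarthric-speech pipelines: recordings are
peak-normalized and polyphase-resampled to 8 kHz, segmented into 500 ms chunks
with 250 ms shifts, and each chunk is mapped to a 128-band log-mel spectrogram
(STFT with a 512-sample Hann window and 64-sample hop, centered reflection
padding), giving a 128 x 63 matrix per chunk at the defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

PD, HC = "PD", "HC"


@dataclass
class AudioRecording:
    """A sampled waveform with speaker identity and class label."""

    samples: np.ndarray
    rate: int
    speaker_id: str
    label: str | None = None  # "PD", "HC" or None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Chunk:
    samples: np.ndarray
    rate: int
    start_s: float
    parent_speaker: str


@dataclass
class MelConfig:
    n_mels: int = 128
    win_length: int = 512       # 64 ms at 8 kHz
    hop_length: int = 64
    n_fft: int = 512
    fmin: float = 0.0
    fmax: float | None = None   # defaults to Nyquist
    log_floor: float = 1e-10
    log: bool = True
    center: bool = True


@dataclass
class MelSpectrogram:
    values: np.ndarray          # (n_mels, n_frames)
    n_mels: int
    frame_times: np.ndarray     # seconds per column
    source_chunk: Chunk | None = field(default=None, repr=False)


def preprocess(recording: AudioRecording, target_rate: int = 8000) -> AudioRecording:
    """Resample to ``target_rate`` and peak-normalize to [-1, 1].

    Upsampling is refused (the corpus convention is to move down to 8 kHz);
    an all-zero input is passed through without normalization.
    """
    if len(recording.samples) == 0:
        raise ValueError("empty recording")
    if target_rate > recording.rate:
        raise ValueError(
            f"upsampling not supported ({recording.rate} Hz -> {target_rate} Hz)")
    x = np.asarray(recording.samples, dtype=np.float64)
    if target_rate != recording.rate:
        g = np.gcd(int(target_rate), int(recording.rate))
        x = resample_poly(x, target_rate // g, recording.rate // g)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return AudioRecording(samples=x, rate=target_rate,
                          speaker_id=recording.speaker_id, label=recording.label)


def segment(recording: AudioRecording, win_ms: float = 500.0,
            shift_ms: float = 250.0) -> list[Chunk]:
    """Cut the recording into overlapping fixed-length chunks.

    Yields ``floor((L - W) / S) + 1`` chunks; a trailing remainder shorter
    than one window is dropped.
    """
    W = round(recording.rate * win_ms / 1000.0)
    S = round(recording.rate * shift_ms / 1000.0)
    L = len(recording.samples)
    if L < W:
        raise ValueError(
            f"recording shorter than one chunk ({L} samples < window {W})")
    n = (L - W) // S + 1
    return [
        Chunk(samples=recording.samples[i * S: i * S + W], rate=recording.rate,
              start_s=i * S / recording.rate, parent_speaker=recording.speaker_id)
        for i in range(n)
    ]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_center_frequencies(n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    """Center frequencies (Hz) of the triangular mel filters."""
    pts = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    return pts[1:-1]


def mel_filterbank(n_mels: int, n_fft: int, rate: int, fmin: float = 0.0,
                   fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank matrix of shape ``(n_mels, n_fft//2 + 1)``."""
    if fmax is None:
        fmax = rate / 2.0
    pts = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, ctr, hi = pts[i], pts[i + 1], pts[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _frame(x: np.ndarray, win: int, hop: int, center: bool) -> np.ndarray:
    if center:
        x = np.pad(x, win // 2, mode="reflect")
    n = (len(x) - win) // hop + 1
    return np.lib.stride_tricks.sliding_window_view(x, win)[:: hop][:n]


def mel_spectrogram(chunk: Chunk, cfg: MelConfig | None = None,
                    expected_samples: int | None = 4000) -> MelSpectrogram:
    """Log-mel spectrogram of one chunk (128 x 63 at the defaults).

    Deterministic for a fixed input and config.  With ``cfg.log`` disabled the
    linear mel power is returned, which scales quadratically with the waveform
    amplitude.
    """
    cfg = cfg or MelConfig()
    x = np.asarray(chunk.samples, dtype=np.float64)
    if expected_samples is not None and len(x) != expected_samples:
        raise ValueError(
            f"chunk length mismatch: expected {expected_samples} samples, "
            f"got {len(x)}")
    frames = _frame(x, cfg.win_length, cfg.hop_length, cfg.center)
    window = get_window("hann", cfg.win_length, fftbins=True)
    spec = np.fft.rfft(frames * window, n=cfg.n_fft, axis=1)
    power = np.abs(spec) ** 2  # (n_frames, n_fft//2+1)
    fb = mel_filterbank(cfg.n_mels, cfg.n_fft, chunk.rate, cfg.fmin,
                        cfg.fmax if cfg.fmax is not None else chunk.rate / 2.0)
    mel = power @ fb.T  # (n_frames, n_mels)
    values = np.log(np.maximum(mel, cfg.log_floor)).T if cfg.log else mel.T
    times = chunk.start_s + np.arange(values.shape[1]) * cfg.hop_length / chunk.rate
    return MelSpectrogram(values=values, n_mels=cfg.n_mels, frame_times=times,
                          source_chunk=chunk)


def standardize_recording_mels(mels: list[MelSpectrogram]) -> np.ndarray:
    """Stack one recording's chunk spectrograms, z-scored over all its frames.

    Returns an array of shape ``(n_chunks, 1, n_mels, n_frames)`` ready for
    the 2-D encoder.  Standardization statistics come from this recording
    only, so it leaks nothing across speakers or folds.
    """
    stack = np.stack([m.values for m in mels])
    mu = stack.mean()
    sd = stack.std()
    if sd == 0:
        sd = 1.0
    return ((stack - mu) / sd)[:, None, :, :].astype(np.float32)


# ---------------------------------------------------------------------------
# WAV + manifest I/O


def save_wav(path: str | Path, recording: AudioRecording) -> None:
    x = np.clip(np.asarray(recording.samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(str(path), recording.rate,
                  np.round(x * 32767.0).astype(np.int16))


def load_wav(path: str | Path, speaker_id: str = "", label: str | None = None
             ) -> AudioRecording:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioRecording(samples=data, rate=int(rate),
                          speaker_id=speaker_id or Path(path).stem, label=label)


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=["speaker_id", "wav_path", "transcript_path",
                                "label"]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if p.suffix == ".jsonl":
        with open(p) as fh:
            return pd.DataFrame([json.loads(line) for line in fh if line.strip()])
    return pd.read_csv(p)
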