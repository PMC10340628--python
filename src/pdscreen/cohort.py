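"""Synthetic cohort generator: paired recordings and transliterations.

The generator emulates a spontaneous-monologue corpus for a two-class
(PD vs. healthy-control) study so every pipeline stage can be exercised
without clinical data:

* **Audio** — a source–filter voice model: a glottal pulse train at a
  speaker-specific fundamental frequency (~120 Hz) driven through two vocal
  tract resonators, with cycle-to-cycle frequency perturbation (jitter),
  amplitude perturbation (shimmer), and additive aspiration noise.  The PD
  class receives elevated jitter/shimmer/noise — the classic acoustic
  signature of hypokinetic dysarthria — scaled by ``audio_effect``.
* **Text** — token sequences drawn from a mixture of two disjoint topic
  vocabularies with a Zipf-like within-topic distribution.  The class label
  shifts the topic mixture weight by ``text_effect`` (lambda), while the
  word-count distribution is shared between classes, so transcript *content*
  separates the classes but transcript *length* does not.

Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .audio import AudioRecording, save_wav, write_manifest, PD, HC
from .text import Transliteration, WordEmbedder, oov_vector


@dataclass(frozen=True)
class AudioEffect:
    """Extra perturbation applied to the PD class on top of the HC baseline."""

    jitter: float = 0.02       # cycle-length sd as fraction of the period
    shimmer: float = 0.10      # cycle-amplitude sd, relative
    noise_gain: float = 0.10   # aspiration-noise amplitude


HC_BASELINE = AudioEffect(jitter=0.005, shimmer=0.03, noise_gain=0.02)


@dataclass(frozen=True)
class CohortSpec:
    n_pd: int = 20
    n_hc: int = 20
    duration_s: float = 10.0
    rate: int = 8000
    audio_effect: AudioEffect | float = 1.0   # float scales the default deltas
    text_effect: float = 0.8                  # lambda in [0, 1]
    words_mean: float = 80.0
    words_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pd < 1 or self.n_hc < 1:
            raise ValueError("speaker counts must be >= 1")
        if not 0.0 <= self.text_effect <= 1.0:
            raise ValueError("text_effect (lambda) must be in [0, 1]")
        if self.duration_s < 1.0:
            raise ValueError("duration must be >= 1 s")

    def resolved_audio_effect(self) -> AudioEffect:
        e = self.audio_effect
        if isinstance(e, AudioEffect):
            return e
        return AudioEffect(jitter=0.02 * e, shimmer=0.10 * e, noise_gain=0.10 * e)


@dataclass
class Cohort:
    recordings: list[AudioRecording]
    transcripts: list[Transliteration]

    @property
    def speaker_ids(self) -> list[str]:
        return [r.speaker_id for r in self.recordings]

    @property
    def labels(self) -> dict[str, str]:
        return {r.speaker_id: r.label for r in self.recordings}


# ---------------------------------------------------------------------------
# Vocabulary


def _make_vocabulary(n_per_topic: int = 60, seed: int = 20240601
                     ) -> list[list[str]]:
    """Two disjoint topic vocabularies of pronounceable synthetic tokens."""
    rng = np.random.default_rng(seed)
    cons = list("bdfgklmnprstvz")
    vows = list("aeiou")
    seen: set[str] = set()
    topics: list[list[str]] = []
    for _ in range(2):
        topic: list[str] = []
        while len(topic) < n_per_topic:
            n_syll = int(rng.integers(2, 4))
            tok = "".join(cons[rng.integers(len(cons))] + vows[rng.integers(len(vows))]
                          for _ in range(n_syll))
            if tok not in seen:
                seen.add(tok)
                topic.append(tok)
        topics.append(topic)
    return topics


TOPIC_VOCABULARY: list[list[str]] = _make_vocabulary()


# ---------------------------------------------------------------------------
# Audio synthesis


def gen_recording(label: str, spec: CohortSpec, speaker_seed: int,
                  speaker_id: str = "") -> AudioRecording:
    """Synthesize one vowel-like recording with class-dependent perturbations."""
    rng = np.random.default_rng(speaker_seed)
    delta = spec.resolved_audio_effect()
    base = HC_BASELINE
    if label == PD:
        jitter = base.jitter + delta.jitter
        shimmer = base.shimmer + delta.shimmer
        noise_gain = base.noise_gain + delta.noise_gain
    else:
        jitter, shimmer, noise_gain = base.jitter, base.shimmer, base.noise_gain

    n = int(round(spec.duration_s * spec.rate))
    f0 = float(np.clip(rng.normal(120.0, 15.0), 90.0, 170.0))
    period = spec.rate / f0

    source = np.zeros(n)
    pos = 0.0
    while pos < n:
        idx = int(round(pos))
        if idx < n:
            amp = max(0.1, 1.0 + shimmer * rng.standard_normal())
            source[idx] = amp
        T = period * (1.0 + jitter * rng.standard_normal())
        pos += float(np.clip(T, 0.5 * period, 1.5 * period))

    aspiration = noise_gain * rng.standard_normal(n)
    x = source + aspiration
    # two formant resonators (second-order IIR)
    for fc, bw in ((600.0, 90.0), (1200.0, 110.0)):
        r = np.exp(-np.pi * bw / spec.rate)
        a = [1.0, -2.0 * r * np.cos(2.0 * np.pi * fc / spec.rate), r * r]
        x = lfilter([1.0], a, x)
    # slow loudness modulation, vaguely syllabic
    t = np.arange(n) / spec.rate
    x = x * (1.0 + 0.2 * np.sin(2.0 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi)))
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return AudioRecording(samples=x, rate=spec.rate,
                          speaker_id=speaker_id or f"spk{speaker_seed}", label=label)


def gen_transcript(label: str, spec: CohortSpec, speaker_seed: int,
                   speaker_id: str = "") -> Transliteration:
    """Draw a token sequence from the class-shifted topic mixture.

    The number of words is drawn from the shared (words_mean, words_sd)
    normal, independent of class; the topic mixture weight is
    ``0.5 + lambda/2`` for HC and ``0.5 - lambda/2`` for PD.
    """
    rng = np.random.default_rng(speaker_seed)
    n_words = max(5, int(round(rng.normal(spec.words_mean, spec.words_sd))))
    lam = spec.text_effect
    p_topic0 = 0.5 + lam / 2.0 if label == HC else 0.5 - lam / 2.0
    ranks = np.arange(len(TOPIC_VOCABULARY[0]))
    zipf = 1.0 / (ranks + 2.0)
    zipf /= zipf.sum()
    tokens = []
    for _ in range(n_words):
        topic = TOPIC_VOCABULARY[0 if rng.random() < p_topic0 else 1]
        tokens.append(topic[rng.choice(len(topic), p=zipf)])
    return Transliteration(tokens=tokens,
                           speaker_id=speaker_id or f"spk{speaker_seed}",
                           label=label)


def _speaker_seeds(spec: CohortSpec, n: int) -> np.ndarray:
    # two independent child seeds per speaker (audio, text), all < 2**31
    ss = np.random.SeedSequence(spec.seed)
    return ss.generate_state(2 * n, dtype=np.uint64) % (2 ** 31)


def gen_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate the aligned cohort; optionally write WAVs/transcripts/manifest."""
    n = spec.n_pd + spec.n_hc
    labels = [PD] * spec.n_pd + [HC] * spec.n_hc
    ids = ([f"PD{i:03d}" for i in range(spec.n_pd)]
           + [f"HC{i:03d}" for i in range(spec.n_hc)])
    seeds = _speaker_seeds(spec, n)
    recordings, transcripts = [], []
    for i, (sid, lab) in enumerate(zip(ids, labels)):
        recordings.append(gen_recording(lab, spec, int(seeds[2 * i]), sid))
        transcripts.append(gen_transcript(lab, spec, int(seeds[2 * i + 1]), sid))
    cohort = Cohort(recordings=recordings, transcripts=transcripts)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "wav").mkdir(parents=True, exist_ok=True)
        (out / "txt").mkdir(parents=True, exist_ok=True)
        rows = []
        for rec, tr in zip(recordings, transcripts):
            wav_path = out / "wav" / f"{rec.speaker_id}.wav"
            txt_path = out / "txt" / f"{rec.speaker_id}.txt"
            save_wav(wav_path, rec)
            txt_path.write_text(" ".join(tr.tokens), encoding="utf-8")
            rows.append({"speaker_id": rec.speaker_id, "wav_path": str(wav_path),
                         "transcript_path": str(txt_path), "label": rec.label})
        write_manifest(out / "manifest.csv", rows)
    return cohort


# ---------------------------------------------------------------------------
# Toy word embedder


class ToyEmbedder:
    """Deterministic unit-norm word embedder with topic-clustered vectors.

    Tokens of one topic vocabulary are generated around a shared random
    centroid, so both the statistical functionals and the n-gram CNN have
    genuine topical signal to find.  Unknown tokens fall back to the
    deterministic hash-seeded vector.
    """

    def __init__(self, vocab, d: int = 16, seed: int = 0, spread: float = 0.5):
        if d < 2:
            raise ValueError("embedding dimension must be >= 2")
        groups = vocab if vocab and isinstance(vocab[0], (list, tuple)) else [vocab]
        if not any(groups):
            raise ValueError("empty vocabulary")
        self.dim = d
        self.name = f"toy{d}"
        rng = np.random.default_rng(seed)
        self.table: dict[str, np.ndarray] = {}
        self.topic_of: dict[str, int] = {}
        for g, group in enumerate(groups):
            centroid = rng.standard_normal(d)
            centroid /= np.linalg.norm(centroid)
            for tok in group:
                v = centroid + spread * rng.standard_normal(d)
                self.table[tok] = v / np.linalg.norm(v)
                self.topic_of[tok] = g

    def vector(self, token: str) -> np.ndarray:
        v = self.table.get(token)
        if v is None:
            v = oov_vector(token, self.dim)
            v = v / np.linalg.norm(v)
        return v


def toy_embedder(vocab=None, d: int = 16, seed: int = 0) -> ToyEmbedder:
    """Build the deterministic toy embedder (defaults to the cohort vocabulary)."""
    return ToyEmbedder(vocab if vocab is not None else TOPIC_VOCABULARY,
                       d=d, seed=seed)
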