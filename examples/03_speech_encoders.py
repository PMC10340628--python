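"""The three speech representations on one synthetic recording.

1) 1D-CNN+LSTM scores raw 4000-sample chunks; 2) the residual 2-D CNN embeds
each 128x63 log-mel chunk into 64 dimensions; 3) the pretrained-embedder
adapter mean-pools frame embeddings into one vector per recording (here the
deterministic stub embedder stands in for a real self-supervised model).
Chunk scores average into one speaker-level decision score.
"""

import numpy as np

from pdscreen.audio import mel_spectrogram, segment, standardize_recording_mels
from pdscreen.cohort import CohortSpec, gen_recording
from pdscreen.speech import (ChunkScore, LogMelProjectionEmbedder,
                             build_cnn1d_lstm, build_resnet2d, pretrained_embed,
                             speaker_score)

rec = gen_recording("PD", CohortSpec(duration_s=5.0, seed=0), 7, "demo")
chunks = segment(rec)

m1 = build_cnn1d_lstm()
print("1D-CNN+LSTM layers:", " -> ".join(m1.layer_inventory),
      f"({m1.num_params()} params)")
raw = np.stack([c.samples for c in chunks])[:, None, :].astype(np.float32)
probs = m1.predict_proba(raw)
print(f"  untrained chunk PD-probabilities: mean {probs[:, 1].mean():.3f}")

m2 = build_resnet2d()
mels = standardize_recording_mels([mel_spectrogram(c) for c in chunks])
emb = m2.embed(mels)
print(f"2D residual CNN: {len(m2.blocks)} residual blocks -> "
      f"{emb.shape[1]}-d chunk embeddings ({m2.num_params()} params)")

scores = [ChunkScore(rec.speaker_id, i, float(p))
          for i, p in enumerate(m2.predict_proba(mels)[:, 1])]
print(f"speaker score from the untrained head (mean of {len(scores)} chunk "
      f"scores): {speaker_score(scores):.3f}")

stub = LogMelProjectionEmbedder(dim=768, seed=0)
v = pretrained_embed(rec, stub)
print(f"pretrained-adapter vector: {v.shape[0]}-d temporal mean of frames")
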