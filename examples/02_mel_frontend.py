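"""Audio front end: resample, chunk, and compute log-mel spectrograms.

A 10 s recording at 8 kHz yields 39 half-second chunks (250 ms shift), each
mapped to a 128-band x 63-frame log-mel matrix — the input of the 2-D
residual encoder.
"""

from pdscreen.audio import mel_spectrogram, preprocess, segment
from pdscreen.cohort import CohortSpec, gen_recording

spec = CohortSpec(duration_s=10.0, seed=0)
rec = gen_recording("PD", spec, speaker_seed=42, speaker_id="demo")
rec = preprocess(rec, target_rate=8000)
print(f"recording: {rec.duration_s:.1f} s at {rec.rate} Hz, "
      f"peak {abs(rec.samples).max():.2f}")

chunks = segment(rec, win_ms=500, shift_ms=250)
print(f"chunks: {len(chunks)} x {len(chunks[0].samples)} samples "
      f"(starts every {chunks[1].start_s - chunks[0].start_s:.2f} s)")

mel = mel_spectrogram(chunks[0])
print(f"log-mel per chunk: {mel.values.shape[0]} bands x "
      f"{mel.values.shape[1]} frames, range [{mel.values.min():.1f}, "
      f"{mel.values.max():.1f}] (natural log of mel power)")
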