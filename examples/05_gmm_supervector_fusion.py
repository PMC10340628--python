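"""GMM supervectors and the three fusion strategies.

A speaker's variable-length set of chunk embeddings becomes one fixed-length
supervector by stacking the means and diagonal covariances of a fitted
Gaussian mixture.  Early fusion concatenates static speech + language
vectors; joint fusion feeds the supervector into the text CNN before its
head; late fusion classifies the 2-d vector of decision scores.
"""

import numpy as np

from pdscreen.fusion import (build_joint_model, early_fuse, gmm_supervector,
                             joint_forward, late_fuse, mean_pool)

rng = np.random.default_rng(0)
# chunk embeddings drawn from two modes, as if voiced/unvoiced chunks differed
embs = np.vstack([rng.normal(0, 1, (30, 8)), rng.normal(4, 1, (30, 8))])

sv = gmm_supervector(embs, K=2, seed=0, speaker_id="demo")
print(f"supervector: 2*K*d = {sv.values.shape[0]} "
      f"(K={sv.K} components, d={sv.d})")
print(f"  component means ~ {sv.values[:8].round(2)} | {sv.values[8:16].round(2)}")

speech_vec = mean_pool(embs)
lang_vec = rng.standard_normal(12)
fused = early_fuse(speech_vec, lang_vec)
print(f"early fusion: {len(speech_vec)} + {len(lang_vec)} -> "
      f"{fused.values.shape[0]}-d, parts {dict(fused.parts)}")

joint = build_joint_model(d=6, sv_dim=sv.values.shape[0], filters=8, seed=1)
M = rng.standard_normal((9, 6))
probs = joint_forward(M, sv, joint)
print(f"joint fusion probabilities: HC {probs[0]:.3f}  PD {probs[1]:.3f}")

bimodal = late_fuse(0.91, 0.34)
print(f"late fusion bi-modal representation: {bimodal.values}")
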