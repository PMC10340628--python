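"""Language encoders on one synthetic transliteration.

The transcript becomes an n x d embedding matrix (one row per word).  The
static route stacks four statistical functionals into a 4d vector for an
SVM; the n-gram CNN route slides 2/3/4-word kernels over the matrix and
max-pools each filter, giving a language embedding and a class probability.
"""

import numpy as np

from pdscreen.cohort import CohortSpec, gen_transcript, toy_embedder
from pdscreen.text import (NgramCNNConfig, build_ngram_cnn, embed_transcript,
                           functional_vector, ngram_cnn_forward)

tr = gen_transcript("PD", CohortSpec(seed=0), speaker_seed=5, speaker_id="demo")
print(f"transcript: {tr.n_words} words, first five: {tr.tokens[:5]}")

emb = toy_embedder(d=16, seed=3)
M = embed_transcript(tr, emb)
print(f"embedding matrix M: {M.M.shape[0]} x {M.M.shape[1]}")

fv = functional_vector(M)
print(f"functional vector: length {fv.shape[0]} "
      f"(= 4 x {M.M.shape[1]}: mean | std | skewness | kurtosis)")

model = build_ngram_cnn(NgramCNNConfig(d=16, filters=64, seed=0))
E, probs = ngram_cnn_forward(M, model)
print(f"n-gram CNN: kernels {[tuple(W.data.shape) for W in model.W]} "
      f"-> language embedding {E.shape[0]}-d")
print(f"untrained class probabilities: HC {probs[0]:.3f}  PD {probs[1]:.3f}")
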