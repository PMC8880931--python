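"""The patient-pair NT-Xent loss on toy projections.

Two ECGs of one patient form a positive pair; every other ECG in the
batch is a negative. The loss is small when positives align and
negatives are orthogonal, log(2N-1) when the space is uninformative.
"""

import math

import numpy as np

from pclr.contrastive import LossConfig, batch_loss, cosine_similarity, pair_loss

print("cosine similarities:",
      cosine_similarity([1, 0], [1, 0]),
      cosine_similarity([1, 0], [0, 1]),
      cosine_similarity([1, 1], [-1, -1]))

# N = 2 patients, well-separated pairs, tau = 0.1
Z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
pairs = [(0, 1), (2, 3)]
cfg = LossConfig(temperature=0.1)
print(f"separated pairs:  l(0,1) = {pair_loss(0, 1, Z, cfg):.6f} "
      "(near zero: positives identical, negatives orthogonal)")

# uninformative projections: everything identical
Z_flat = np.ones((4, 2))
print(f"collapsed space:  l(0,1) = {pair_loss(0, 1, Z_flat, cfg):.4f} "
      f"= log(2N-1) = {math.log(3):.4f}")

print(f"batch loss (sum over patients): "
      f"{batch_loss(Z, pairs, cfg):.6f} separated, "
      f"{batch_loss(Z_flat, pairs, cfg):.4f} collapsed")
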