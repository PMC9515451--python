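"""The cluster-weighted cross-entropy (CWCE) loss in isolation.

Patches are embedded, z-scored, projected onto the principal components
explaining 95% of the variance, and grouped by k-means (k=10).  The loss
then averages cross-entropy per cluster before macro-averaging across the
clusters present in the batch, so a tissue type that dominates the batch
cannot dominate the gradient.
"""

import math

import numpy as np

from histocascade import PredictionBatch, cwce_loss

# worked example: cluster A holds one perfectly classified sample (CE 0),
# cluster B one sample with p(true) = e^-1 (CE 1)
probs = np.array([[1.0, 0.0], [math.exp(-1), 1 - math.exp(-1)]])
labels = np.array([[1.0, 0.0], [1.0, 0.0]])
clusters = np.array([0, 1])
print("macro CWCE over {CE=0, CE=1}:",
      cwce_loss(PredictionBatch(probs, labels, clusters)))  # -> 0.5

# the macro property: inflating cluster B to 99 copies changes nothing
probs_big = np.vstack([probs[:1], np.tile(probs[1], (99, 1))])
labels_big = np.tile([1.0, 0.0], (100, 1))
clusters_big = np.array([0] + [1] * 99)
print("same loss with 99 copies in cluster B:",
      cwce_loss(PredictionBatch(probs_big, labels_big, clusters_big)))
# A sample-weighted mean would drift to ~0.99; the macro average stays 0.5.
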