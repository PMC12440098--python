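"""The evaluation metrics on controlled inputs.

Jaccard neighborhood similarity compares kNN sets in an embedding versus
the original data space; the fold change of top correlations attributes
a topic to a modality; the supervised suite wraps the six standard
clustering scores.
"""

import numpy as np

from spamv import (
    fold_change_top_correlations,
    jaccard_similarity,
    supervised_scores,
)

rng = np.random.default_rng(0)
n = 200
data = rng.standard_normal((n, 30))

print("Jaccard neighborhood similarity (k=15):")
print(f"  embedding == data:        {jaccard_similarity(data, data, k=15):.3f}")
noisy = data + 0.3 * rng.standard_normal(data.shape)
print(f"  mildly noised embedding:  {jaccard_similarity(noisy, data, k=15):.3f}")
shuffled = data[rng.permutation(n)]
print(f"  unrelated embedding:      {jaccard_similarity(shuffled, data, k=15):.3f}")

topic = rng.standard_normal(n)
x1 = np.column_stack([topic + 0.5 * rng.standard_normal(n) for _ in range(10)])
x2 = rng.standard_normal((n, 10))
d = fold_change_top_correlations(topic, x1, x2)
print(f"\nfold change of top correlations (topic built from modality 1): {d:+.2f}")
print("  positive -> the topic tracks modality 1")

truth = np.repeat([0, 1, 2, 3], 50)
good = truth.copy()
good[:10] = 1  # a few mistakes
print("\nsupervised scores, slightly corrupted labels:")
print("  ", {k: round(v, 3) for k, v in supervised_scores(good, truth).items()})
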