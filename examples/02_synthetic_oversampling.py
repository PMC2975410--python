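"""Enlarge a tiny positive set with synthetic convex combinations.

Each synthetic example lies on the open segment between a positive and
one of its k nearest positive neighbors, so any halfspace containing the
positives contains every synthetic point — the enlargement adds no noise
a separating hyperplane could see.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform

from genepu import make_synthetic_examples, neighbor_count_for_amount
from genepu.oversample import synthetic_features

rng = np.random.default_rng(0)
positives = rng.normal(loc=[2.0, 2.0], scale=0.5, size=(12, 2))

amount = 400  # percent: a "<60 annotated genes" class is enlarged 4x
n = neighbor_count_for_amount(amount, k=10)
print(f"{amount}% enlargement with k=10 nearest neighbors -> combine each "
      f"positive with {n} randomly chosen neighbors")

dist = squareform(pdist(positives))
enlarged = make_synthetic_examples(range(len(positives)), dist, n=n, k=10, rng_seed=1)
print(f"|P| = {len(positives)} -> {enlarged.n_synthetic} synthetic examples "
      f"({enlarged.n_total} total positives)")

synth = synthetic_features(positives, enlarged)
# a hyperplane with all positives strictly on one side
w, b = np.array([1.0, 1.0]), -1.0
assert np.all(positives @ w + b > 0)
violations = int(np.sum(synth @ w + b <= 0))
print(f"hyperplane check: {violations} of {enlarged.n_synthetic} synthetic points "
      "cross a hyperplane that separates the positives (always 0 — convexity)")

c = enlarged.combinations[0]
print(f"first combination: {c.synthetic_id} = {c.alpha:.3f} * x[{c.parent_a}] "
      f"+ {1 - c.alpha:.3f} * x[{c.parent_b}]")
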