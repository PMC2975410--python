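"""Run the full three-stage pipeline and benchmark it against baselines.

Trains on a simulated PU dataset, prints the audit manifest highlights,
then compares negative-selection strategies over several seeds with the
PU protocol: F1 on a 20% holdout (held-out unlabeled scored as negative)
and ROC of the decision values against the hidden ground truth.
"""

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel

from genepu import SpeRneConfig, compare_strategies, predict_unknowns, run_spe_rne
from genepu.metrics import roc_auc
from genepu.simulate import simulate_pu_dataset

ds = simulate_pu_dataset(seed=1)  # the standard suite conditions
x = ds.features
kernel = rbf_kernel(x, gamma=1.0 / (x.shape[1] * x.var()))
res = run_spe_rne(ds.P, ds.U, kernel=kernel, config=SpeRneConfig(seed=1))

m = res.manifest
print(f"stage 1: |P| = {m['n_positives']} -> {m['n_synthetic']} synthetic positives "
      f"(enlargement {m['enlargement_times']}x, schedule for a '<60' class)")
print(f"stage 2: {m['n_initial_negatives']} initial negatives, {m['n_iterations']} "
      f"iterations, {m['n_representative_negatives']} representative negatives")
print(f"stage 3: grid-searched C = {m['best_params']['C']:g} "
      f"(cross-validated F1 {m['best_params']['cv_f1']:.3f})")

_, dec = predict_unknowns(res.model, kernel=res.kernel, query_indices=ds.U)
print(f"ROC on the hidden truth of all unlabeled genes: {roc_auc(ds.truth[ds.U], dec):.3f}")

print("\nstrategy benchmark (5 seeds; full suite uses 20):")
_, summary = compare_strategies(seeds=(1, 2, 3, 4, 5))
print(summary.to_string(index=False))
print("\nn_f1_zero counts seeds where a strategy recalls no positives "
      "(F1 undefined -> 0): the all-unlabeled-as-negative baseline collapses "
      "under class imbalance; the pipeline never does.")
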