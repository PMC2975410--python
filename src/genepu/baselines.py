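"""Baseline negative-selection strategies.

Three comparison methods that differ from the main pipeline only in how
they pick negative training examples:

- ``twoclass``: every unlabeled point is a negative (maximal training set,
  maximal class imbalance and false-negative noise);
- ``twoclassbal``: |P| unlabeled points sampled uniformly as negatives
  (balanced but tiny, prone to overfitting and high seed variance);
- ``psol_lite``: a greedy max-min-dispersion initial negative set followed
  by iterative SVM expansion of the negatives — a simplified two-step
  rendition of the PSoL scheme, not a faithful reimplementation of the
  original algorithm.

All three share the kernel plumbing and evaluation of the main pipeline,
so comparisons isolate the selection strategy.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .oversample import kernel_induced_distances
from .svm import TrainedModel, train_binary

__all__ = ["twoclass_train", "twoclassbal_train", "psol_lite_train", "greedy_dispersion_select"]

log = logging.getLogger(__name__)


def _fit(p, n, kernel, svm_params) -> TrainedModel:
    idx = np.concatenate([p, n])
    y = np.concatenate([np.ones(len(p), dtype=int), -np.ones(len(n), dtype=int)])
    params = {"C": 1.0}
    params.update(svm_params or {})
    return train_binary(y, kernel=kernel, train_indices=idx, **params)


def twoclass_train(p, u, kernel: np.ndarray, svm_params: dict | None = None) -> TrainedModel:
    """Train with all unlabeled points as negatives."""
    p = np.asarray(p, dtype=int)
    u = np.asarray(u, dtype=int)
    if p.size == 0:
        raise ValueError("positive set is empty")
    if np.intersect1d(p, u).size:
        raise ValueError("P and U must be disjoint")
    return _fit(p, u, kernel, svm_params)


def twoclassbal_train(
    p, u, kernel: np.ndarray, svm_params: dict | None = None, rng_seed=0
) -> TrainedModel:
    """Train with |P| uniformly sampled unlabeled points as negatives."""
    p = np.asarray(p, dtype=int)
    u = np.asarray(u, dtype=int)
    if len(u) < len(p):
        raise ValueError("unlabeled pool smaller than the positive set")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    neg = np.sort(rng.choice(u, size=len(p), replace=False))
    return _fit(p, neg, kernel, svm_params)


def greedy_dispersion_select(p, u, distances: np.ndarray, size: int) -> np.ndarray:
    """Greedy max-min selection of unlabeled points far from P and from
    each other.

    The first pick maximizes the distance to the positive set (distance to
    a set = minimum over its members); each later pick maximizes the
    minimum distance to P and to the points already selected.  A greedy
    approximation — the exact dispersion problem is NP-hard.
    """
    p = np.asarray(p, dtype=int)
    u = np.asarray(u, dtype=int)
    size = min(size, len(u))
    min_d = distances[np.ix_(u, p)].min(axis=1)  # distance to the positive set
    chosen: list[int] = []
    avail = np.ones(len(u), dtype=bool)
    for _ in range(size):
        cand = np.where(avail)[0]
        best = cand[np.lexsort((u[cand], -min_d[cand]))][0]
        chosen.append(u[best])
        avail[best] = False
        min_d = np.minimum(min_d, distances[u, u[best]])
    return np.sort(np.asarray(chosen, dtype=int))


def psol_lite_train(
    p,
    u,
    kernel: np.ndarray,
    svm_params: dict | None = None,
    expand_cap: int = 3,
    stop_ratio: float = 4.0,
    init_size: int | None = None,
) -> TrainedModel:
    """Simplified PSoL: dispersion-selected initial negatives, then
    iterative expansion of the negative set until few unlabeled remain.

    Unlike the representative-negative extraction of the main pipeline,
    the negative set only grows (no support-vector distillation, no
    validation-based selection); the final classifier is returned
    directly.  ``init_size`` defaults to |P| for a balanced start.
    """
    p = np.asarray(p, dtype=int)
    u = np.asarray(u, dtype=int)
    if p.size == 0:
        raise ValueError("positive set is empty")
    dist = kernel_induced_distances(kernel)
    n_init = len(p) if init_size is None else init_size
    negatives = greedy_dispersion_select(p, u, dist, n_init)
    remaining = np.setdiff1d(u, negatives)
    model = _fit(p, negatives, kernel, svm_params)
    while len(remaining) >= stop_ratio * len(p):
        dec = model.decision_function(kernel=kernel, query_indices=remaining)
        neg_mask = dec < 0
        cap = expand_cap * len(p)
        candidates = remaining[neg_mask]
        order = np.lexsort((candidates, dec[neg_mask]))
        new_neg = candidates[order[:cap]]
        if new_neg.size == 0:
            log.info("psol_lite: no new negatives predicted; stopping expansion")
            break
        negatives = np.union1d(negatives, new_neg)
        remaining = np.setdiff1d(remaining, new_neg)
        model = _fit(p, negatives, kernel, svm_params)
    return model
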