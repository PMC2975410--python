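"""Representative negative extraction (stage 2).

From the enlarged positive set P~ and the unlabeled pool U, a reliable
negative set is distilled in three steps: (1) a one-class SVM over all
training points flags the ~10% most peripheral points, and those falling
in U become the initial negatives; (2) a two-class SVM is retrained
iteratively, each round keeping only its negative support vectors plus up
to m*|P~| freshly predicted, most-confident negatives — the decision
boundary marches toward the positives while |U'| shrinks — stopping once
|U'| < stop_ratio * |P~|; (3) each iteration's classifier is scored by F1
on a held-out validation split and the negative set of the best one is
returned as the representative negatives RN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import confusion_counts, precision_recall_f1
from .svm import TrainedModel, train_binary, train_one_class

__all__ = [
    "ValidationSplit",
    "IterationRecord",
    "IterationTrace",
    "split_validation",
    "initial_negatives",
    "iterate_negatives",
    "select_representative_negatives",
]

log = logging.getLogger(__name__)

DEFAULT_M = 3
DEFAULT_STOP_RATIO = 4.0
DEFAULT_VALIDATION_FRACTION = 0.10
DEFAULT_OUTLIER_PERCENT = 10.0


@dataclass
class ValidationSplit:
    """Held-out validation indices (10% of P~ and of U) plus the rest."""

    v_pos: np.ndarray
    v_unl: np.ndarray
    train_pos: np.ndarray
    train_unl: np.ndarray

    def __post_init__(self) -> None:
        for name in ("v_pos", "v_unl", "train_pos", "train_unl"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))


@dataclass
class IterationRecord:
    iteration: int
    model: TrainedModel
    negatives: np.ndarray  # the set N_i the classifier was trained on
    n_pred: int  # |N_pred| chosen this round
    n_svs: int  # negative support vectors carried forward
    u_remaining: int  # |U'| at training time
    validation_f1: float = float("nan")

    def __post_init__(self) -> None:
        self.negatives = np.asarray(self.negatives, dtype=int)


@dataclass
class IterationTrace:
    records: list[IterationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "n_negatives": [len(r.negatives) for r in self.records],
                "n_pred": [r.n_pred for r in self.records],
                "n_svs": [r.n_svs for r in self.records],
                "u_remaining": [r.u_remaining for r in self.records],
                "validation_f1": [r.validation_f1 for r in self.records],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def split_validation(
    p_tilde,
    u,
    fraction: float = DEFAULT_VALIDATION_FRACTION,
    rng_seed=0,
) -> ValidationSplit:
    """Hold out ceil(fraction*|P~|) positives and ceil(fraction*|U|)
    unlabeled points, uniformly at random; deterministic under the seed."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    p_tilde = np.asarray(p_tilde, dtype=int)
    u = np.asarray(u, dtype=int)
    if len(p_tilde) < 2 or len(u) < 2:
        raise ValueError("need at least two positives and two unlabeled points")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n_vp = math.ceil(fraction * len(p_tilde))
    n_vu = math.ceil(fraction * len(u))
    if n_vp >= len(p_tilde) or n_vu >= len(u):
        raise ValueError("validation split would leave an empty training set")
    v_pos = rng.choice(p_tilde, size=n_vp, replace=False)
    v_unl = rng.choice(u, size=n_vu, replace=False)
    return ValidationSplit(
        v_pos=np.sort(v_pos),
        v_unl=np.sort(v_unl),
        train_pos=np.setdiff1d(p_tilde, v_pos),
        train_unl=np.setdiff1d(u, v_unl),
    )


def initial_negatives(
    p_train,
    u_train,
    kernel: np.ndarray,
    percent: float = DEFAULT_OUTLIER_PERCENT,
) -> np.ndarray:
    """One-class boundary over P~' ∪ U'; unlabeled points left outside
    become the initial negatives N1.

    The outlier fraction maps to the nu parameter (percent/100).  If the
    boundary degenerates and flags no unlabeled point, the fallback takes
    the percent·|U'| unlabeled points with the smallest mean similarity to
    the positives (logged).
    """
    p_train = np.asarray(p_train, dtype=int)
    u_train = np.asarray(u_train, dtype=int)
    all_idx = np.concatenate([p_train, u_train])
    model = train_one_class(nu=percent / 100.0, kernel=kernel, train_indices=all_idx)
    dec = model.decision_function(kernel=kernel, query_indices=u_train)
    n1 = u_train[dec < 0]
    if n1.size == 0:
        k = max(1, math.ceil(percent / 100.0 * len(u_train)))
        mean_sim = kernel[np.ix_(u_train, p_train)].mean(axis=1)
        order = np.lexsort((u_train, mean_sim))
        n1 = np.sort(u_train[order[:k]])
        log.warning(
            "one-class boundary flagged no unlabeled point; falling back to the "
            "%d least positive-similar unlabeled points", k,
        )
    return np.sort(n1)


def iterate_negatives(
    p_train,
    u_prime,
    n1,
    kernel: np.ndarray,
    m: int = DEFAULT_M,
    stop_ratio: float = DEFAULT_STOP_RATIO,
    svm_params: dict | None = None,
) -> IterationTrace:
    """Iterative retraining that moves the boundary toward the positives.

    ``u_prime`` must already exclude ``n1``.  Each round trains P~'(+1) vs
    N(-1), records the classifier and its training negatives, then forms
    the next negative set from the round's negative support vectors plus
    the up-to m*|P~'| unlabeled points with the most negative decision
    values among those predicted negative; those predicted points leave
    U'.  The loop runs while |U'| >= stop_ratio*|P~'| and also exits when
    no new negative is predicted.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    p_train = np.asarray(p_train, dtype=int)
    u_prime = np.asarray(u_prime, dtype=int)
    n_cur = np.asarray(n1, dtype=int)
    if np.intersect1d(n_cur, p_train).size:
        raise ValueError("initial negatives overlap the positive set")
    params = {"C": 1.0}
    params.update(svm_params or {})
    trace = IterationTrace()
    i = 1
    while len(u_prime) >= stop_ratio * len(p_train):
        train_idx = np.concatenate([p_train, n_cur])
        y = np.concatenate([np.ones(len(p_train), dtype=int), -np.ones(len(n_cur), dtype=int)])
        try:
            model = train_binary(y, kernel=kernel, train_indices=train_idx, **params)
        except Exception as exc:  # surface the partial trace with the failure
            raise RuntimeError(
                f"classifier training failed at iteration {i}: {exc}"
            ) from exc
        dec = model.decision_function(kernel=kernel, query_indices=u_prime)
        neg_mask = dec < 0
        cap = m * len(p_train)
        candidates = u_prime[neg_mask]
        cand_dec = dec[neg_mask]
        order = np.lexsort((candidates, cand_dec))  # most negative first
        n_pred = candidates[order[:cap]]
        n_svs = model.negative_support_indices()
        trace.records.append(
            IterationRecord(
                iteration=i,
                model=model,
                negatives=n_cur.copy(),
                n_pred=len(n_pred),
                n_svs=len(n_svs),
                u_remaining=len(u_prime),
            )
        )
        if n_pred.size == 0:
            log.info("no new negatives predicted at iteration %d; stopping", i)
            break
        n_cur = np.union1d(n_pred, n_svs)
        u_prime = np.setdiff1d(u_prime, n_pred)
        i += 1
    return trace


def select_representative_negatives(
    trace: IterationTrace,
    split: ValidationSplit,
    kernel: np.ndarray,
) -> np.ndarray:
    """Pick the negative set whose classifier maximizes validation F1.

    Held-out positives are labeled +1 and held-out unlabeled points -1
    (a biased but consistent selection signal).  Ties break toward the
    earliest iteration; if every classifier scores 0, the last iteration's
    set is returned with a warning.
    """
    if not trace.records:
        raise ValueError("iteration trace is empty")
    v_idx = np.concatenate([split.v_pos, split.v_unl])
    y_true = np.concatenate(
        [np.ones(len(split.v_pos), dtype=int), -np.ones(len(split.v_unl), dtype=int)]
    )
    for rec in trace.records:
        pred = rec.model.predict(kernel=kernel, query_indices=v_idx)
        _, _, f1 = precision_recall_f1(confusion_counts(y_true, pred))
        rec.validation_f1 = f1
    best_rec = max(trace.records, key=lambda r: (r.validation_f1, -r.iteration))
    if best_rec.validation_f1 == 0.0:
        log.warning("all validation F1 scores are 0; returning the last negative set")
        return trace.records[-1].negatives.copy()
    return best_rec.negatives.copy()
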