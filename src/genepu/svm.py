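"""Contract layer over the maximum-margin solver (libsvm via scikit-learn).

Provides binary and one-class training on precomputed kernels or explicit
features (RBF), decision values reconstructed from the stored dual
solution, retrieval of negative support vectors, and cross-validated grid
search over (C, g).

A ``TrainedModel`` is self-contained: its decision function is computable
from the stored support indices, dual coefficients and bias alone, which
lets the iterative negative-extraction loop score arbitrary kernel rows
without holding on to the fitted sklearn estimator.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC, OneClassSVM

from .metrics import confusion_counts, precision_recall_f1

__all__ = [
    "TrainedModel",
    "train_binary",
    "train_one_class",
    "grid_search_train",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

log = logging.getLogger(__name__)

#: Grid-search defaults: C in 2^-5 .. 2^15, g in 2^-15 .. 2^3, step 2^2.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class TrainedModel:
    """A fitted maximum-margin model, reproducible from its stored fields.

    ``train_indices`` maps positions within the training set back to the
    caller's (global) index space, so decision values on new points can be
    read off a full precomputed kernel.
    """

    mode: str  # "binary" | "one_class"
    kernel_mode: str  # "precomputed" | "rbf" | "linear"
    support_: np.ndarray  # positions of SVs within the training set
    dual_coef: np.ndarray  # y_i * alpha_i for each SV
    intercept: float
    params: dict = field(default_factory=dict)
    train_indices: np.ndarray | None = None  # global ids of training points
    train_labels: np.ndarray | None = None  # +/-1 labels of training points
    support_vectors: np.ndarray | None = None  # explicit features (rbf mode)

    @property
    def support_indices(self) -> np.ndarray:
        """Global indices of the support vectors."""
        if self.train_indices is None:
            return self.support_.copy()
        return np.asarray(self.train_indices)[self.support_]

    def negative_support_indices(self) -> np.ndarray:
        """Global indices of support vectors with label -1 (binary mode)."""
        if self.mode != "binary":
            raise ValueError("negative support vectors exist only in binary mode")
        neg = self.train_labels[self.support_] == -1
        return self.support_indices[neg]

    def decision_function(
        self,
        kernel: np.ndarray | None = None,
        query_indices: Sequence[int] | None = None,
        features: np.ndarray | None = None,
    ) -> np.ndarray:
        """f(x) = sum_i dual_i K(x, sv_i) + b for the requested points.

        Precomputed mode: pass the full square ``kernel`` plus global
        ``query_indices``.  RBF/linear mode: pass explicit ``features``.
        """
        if self.kernel_mode == "precomputed":
            if kernel is None or query_indices is None:
                raise ValueError("precomputed mode needs kernel and query_indices")
            rows = kernel[np.ix_(np.asarray(query_indices), self.support_indices)]
        else:
            if features is None:
                raise ValueError(f"{self.kernel_mode} mode needs explicit features")
            features = np.atleast_2d(np.asarray(features, dtype=float))
            if self.kernel_mode == "rbf":
                rows = rbf_kernel(features, self.support_vectors, gamma=self.params["gamma"])
            else:
                rows = features @ self.support_vectors.T
        return rows @ self.dual_coef + self.intercept

    def predict(self, **kw) -> np.ndarray:
        """Sign of the decision value; zero maps to -1."""
        return np.where(self.decision_function(**kw) > 0, 1, -1)

    def to_json(self) -> str:
        """Flat text serialization of the model record."""
        rec = {
            "mode": self.mode,
            "kernel_mode": self.kernel_mode,
            "support": self.support_.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "params": self.params,
            "train_indices": None
            if self.train_indices is None
            else np.asarray(self.train_indices).tolist(),
            "train_labels": None
            if self.train_labels is None
            else np.asarray(self.train_labels).tolist(),
            "support_vectors": None
            if self.support_vectors is None
            else np.asarray(self.support_vectors).tolist(),
        }
        return json.dumps(rec)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        rec = json.loads(text)
        return cls(
            mode=rec["mode"],
            kernel_mode=rec["kernel_mode"],
            support_=np.asarray(rec["support"], dtype=int),
            dual_coef=np.asarray(rec["dual_coef"], dtype=float),
            intercept=float(rec["intercept"]),
            params=rec["params"],
            train_indices=None
            if rec["train_indices"] is None
            else np.asarray(rec["train_indices"], dtype=int),
            train_labels=None
            if rec["train_labels"] is None
            else np.asarray(rec["train_labels"], dtype=int),
            support_vectors=None
            if rec["support_vectors"] is None
            else np.asarray(rec["support_vectors"], dtype=float),
        )


def _training_gram(
    kernel_mode: str,
    kernel: np.ndarray | None,
    features: np.ndarray | None,
    idx: np.ndarray,
    gamma: float | None,
):
    if kernel_mode == "precomputed":
        if kernel is None:
            raise ValueError("precomputed mode needs a kernel matrix")
        return kernel[np.ix_(idx, idx)], None
    if features is None:
        raise ValueError(f"{kernel_mode} mode needs explicit features")
    x = np.asarray(features, dtype=float)[idx]
    if kernel_mode == "rbf":
        return rbf_kernel(x, x, gamma=gamma), x
    if kernel_mode == "linear":
        return x @ x.T, x
    raise ValueError(f"unknown kernel mode {kernel_mode!r}")


def train_binary(
    labels: Sequence[int],
    C: float = 1.0,
    *,
    kernel: np.ndarray | None = None,
    features: np.ndarray | None = None,
    train_indices: Sequence[int] | None = None,
    kernel_mode: str = "precomputed",
    gamma: float | None = None,
    class_weight=None,
) -> TrainedModel:
    """Soft-margin binary SVM on a precomputed kernel or explicit features.

    ``labels`` aligns with ``train_indices`` (global positions into the
    kernel/feature matrix; defaults to 0..len(labels)-1).  Both classes
    must be present.
    """
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("binary training needs both +1 and -1 labels")
    idx = (
        np.arange(len(y)) if train_indices is None else np.asarray(train_indices, dtype=int)
    )
    gram, x = _training_gram(kernel_mode, kernel, features, idx, gamma)
    svc = SVC(
        kernel="precomputed",
        C=C,
        class_weight=class_weight,
        cache_size=256,
    )
    svc.fit(gram, y)
    return TrainedModel(
        mode="binary",
        kernel_mode=kernel_mode,
        support_=svc.support_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        params={"C": C, "gamma": gamma},
        train_indices=idx,
        train_labels=y,
        support_vectors=None if x is None else x[svc.support_],
    )


def train_one_class(
    nu: float,
    *,
    kernel: np.ndarray | None = None,
    features: np.ndarray | None = None,
    train_indices: Sequence[int] | None = None,
    kernel_mode: str = "precomputed",
    gamma: float | None = None,
) -> TrainedModel:
    """One-class SVM; roughly a ``nu`` fraction of training points score
    as outliers (negative decision value)."""
    if not 0 < nu < 1:
        raise ValueError("nu must lie in (0, 1)")
    if train_indices is None:
        n = len(kernel) if kernel is not None else len(features)
        idx = np.arange(n)
    else:
        idx = np.asarray(train_indices, dtype=int)
    gram, x = _training_gram(kernel_mode, kernel, features, idx, gamma)
    if np.allclose(gram, gram[0, 0]):
        raise ValueError("degenerate kernel: all entries equal")
    oc = OneClassSVM(kernel="precomputed", nu=nu)
    oc.fit(gram)
    return TrainedModel(
        mode="one_class",
        kernel_mode=kernel_mode,
        support_=oc.support_.copy(),
        dual_coef=oc.dual_coef_.ravel().copy(),
        intercept=float(oc.intercept_[0]),
        params={"nu": nu, "gamma": gamma},
        train_indices=idx,
        train_labels=None,
        support_vectors=None if x is None else x[oc.support_],
    )


def grid_search_train(
    labels: Sequence[int],
    *,
    kernel: np.ndarray | None = None,
    features: np.ndarray | None = None,
    train_indices: Sequence[int] | None = None,
    kernel_mode: str = "precomputed",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    synthetic_parents: dict[int, tuple[int, int]] | None = None,
) -> tuple[TrainedModel, dict, pd.DataFrame]:
    """Stratified-CV grid search maximizing F1; refit on all data.

    In precomputed mode the gamma grid is ignored (a single placeholder
    point is used).  A fold whose training part lacks a class, or whose
    F1 is undefined (no recalled positives), contributes F1 = 0.  Ties are
    broken toward smaller C, then smaller g, making the search invariant
    to grid ordering.

    ``synthetic_parents`` maps the global index of a synthetic
    convex-combination example to its parents' global indices.  When
    given, CV folds are formed over the original examples only, a
    synthetic joins a fold's training part only if both its parents train
    there, and synthetics are never scored as validation cases.  Without
    this, a synthetic lying between two training-fold parents leaks them
    into the validation fold and memorizing hyperparameters look perfect
    in CV — the standard pitfall of oversampling before splitting.
    """
    y = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not len(C_grid):
        raise ValueError("C grid must be nonempty")
    idx = (
        np.arange(len(y)) if train_indices is None else np.asarray(train_indices, dtype=int)
    )
    gammas: Sequence[float | None]
    if kernel_mode == "precomputed":
        gammas = [None]
    else:
        if not len(gamma_grid):
            raise ValueError("gamma grid must be nonempty")
        gammas = list(gamma_grid)

    syn = synthetic_parents or {}
    pos = np.arange(len(y))
    is_syn = np.isin(idx, list(syn)) if syn else np.zeros(len(y), dtype=bool)
    orig_pos = pos[~is_syn]
    y_orig = y[orig_pos]
    n_splits = min(folds, int(np.bincount((y_orig == 1).astype(int)).min()))
    if n_splits < folds:
        log.warning("reducing CV folds from %d to %d (small class)", folds, n_splits)
    if n_splits < 2:
        raise ValueError("too few members of a class for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=False)
    split_cache = []
    for tr_o, va_o in skf.split(np.zeros(len(orig_pos)), y_orig):
        tr = orig_pos[tr_o]
        if syn:
            tr_globals = set(idx[tr])
            syn_ok = [
                i
                for i in pos[is_syn]
                if syn[idx[i]][0] in tr_globals and syn[idx[i]][1] in tr_globals
            ]
            tr = np.sort(np.concatenate([tr, np.asarray(syn_ok, dtype=int)]))
        split_cache.append((tr, orig_pos[va_o]))

    rows = []
    for C, g in itertools.product(sorted(C_grid), sorted(gammas, key=lambda v: v or 0)):
        f1s = []
        for tr, va in split_cache:
            if len(np.unique(y[tr])) < 2:
                f1s.append(0.0)
                log.warning("fold lacks a class; scoring 0")
                continue
            model = train_binary(
                y[tr],
                C=C,
                kernel=kernel,
                features=features,
                train_indices=idx[tr],
                kernel_mode=kernel_mode,
                gamma=g,
            )
            if kernel_mode == "precomputed":
                pred = model.predict(kernel=kernel, query_indices=idx[va])
            else:
                pred = model.predict(features=np.asarray(features)[idx[va]])
            _, _, f1 = precision_recall_f1(confusion_counts(y[va], pred))
            f1s.append(f1)
        rows.append({"C": C, "gamma": g, "cv_f1": float(np.mean(f1s))})
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (-r["cv_f1"], r["C"], r["gamma"] or 0))
    final = train_binary(
        y,
        C=best["C"],
        kernel=kernel,
        features=features,
        train_indices=idx,
        kernel_mode=kernel_mode,
        gamma=best["gamma"],
    )
    best_params = {"C": best["C"], "gamma": best["gamma"], "cv_f1": best["cv_f1"]}
    return final, best_params, table
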