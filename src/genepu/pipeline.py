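"""End-to-end orchestration of the three-stage PU learning pipeline.

Stage 1 enlarges the positive set with synthetic convex combinations (the
amount set by the annotation-size schedule), stage 2 extracts the
representative negative set RN by iterative maximum-margin retraining, and
stage 3 grid-searches the final classifier on P~ ∪ RN.  A single top-level
seed determines every random choice, and the returned manifest records
every parameter and set size needed to re-run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics.pairwise import rbf_kernel

from . import baselines as _baselines
from .io_formats import KernelMatrix
from .metrics import confusion_counts, precision_recall_f1, roc_auc
from .negatives import (
    IterationTrace,
    ValidationSplit,
    initial_negatives,
    iterate_negatives,
    select_representative_negatives,
    split_validation,
)
from .oversample import (
    EnlargedPositives,
    extend_kernel_with_synthetics,
    kernel_induced_distances,
    make_synthetic_examples,
    neighbor_count_for_amount,
    synthetic_features,
)
from .simulate import STANDARD_SUITE, STANDARD_SUITE_SEEDS, simulate_pu_dataset
from .svm import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, TrainedModel, grid_search_train

__all__ = [
    "SpeRneConfig",
    "SpeRneResult",
    "enlargement_times",
    "run_spe_rne",
    "predict_unknowns",
    "collapse_synthetic_supports",
    "compare_strategies",
    "STRATEGIES",
]

log = logging.getLogger(__name__)

#: Enlargement schedule keyed by annotation-count upper bound (None = no
#: bound): classes with fewer than 60 positives are enlarged 4x, 60-100 2x,
#: 100-300 1x, and larger classes get no synthesis.
DEFAULT_SCHEDULE: tuple[tuple[int | None, int], ...] = (
    (60, 4),
    (100, 2),
    (300, 1),
    (None, 0),
)

STRATEGIES = ("spe_rne", "twoclass", "twoclassbal", "psol_lite")


@dataclass
class SpeRneConfig:
    """Tunable parameters of the pipeline (defaults are the method's)."""

    k_neighbors: int = 10
    m: int = 3
    stop_ratio: float = 4.0
    validation_fraction: float = 0.10
    one_class_percent: float = 10.0
    schedule: tuple = DEFAULT_SCHEDULE
    enlargement_times_override: int | None = None
    iteration_C: float = 1.0
    C_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    rbf_gamma: float | None = None  # features mode; None = 1/(d * var(X))
    exclude_synthetics_from_validation: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = [list(x) for x in self.schedule]
        d["C_grid"] = list(self.C_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        return d


@dataclass
class SpeRneResult:
    model: TrainedModel
    best_params: dict
    cv_table: pd.DataFrame
    trace: IterationTrace
    rn: np.ndarray
    enlarged: EnlargedPositives
    split: ValidationSplit
    manifest: dict
    kernel: np.ndarray  # training kernel incl. synthetic rows
    features_aug: np.ndarray | None  # augmented features (features mode)

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, sort_keys=True)


def enlargement_times(n_pos: int, schedule=DEFAULT_SCHEDULE) -> int:
    """Enlargement multiplier for a class with ``n_pos`` positives."""
    for bound, times in schedule:
        if bound is None or n_pos < bound:
            return times
    return 0


def run_spe_rne(
    p,
    u,
    kernel: KernelMatrix | np.ndarray | None = None,
    features: np.ndarray | None = None,
    config: SpeRneConfig | None = None,
) -> SpeRneResult:
    """Run all three stages and return the final model plus full audit state.

    Exactly one of ``kernel`` (precomputed similarity over all genes) or
    ``features`` (explicit vectors; an RBF kernel is built internally) must
    be given.  ``p`` and ``u`` are disjoint global index sets into the
    kernel/feature rows; rows outside ``p`` ∪ ``u`` are ignored by training
    but remain addressable for prediction.
    """
    cfg = config or SpeRneConfig()
    p = np.asarray(sorted(p), dtype=int)
    u = np.asarray(sorted(u), dtype=int)
    if p.size == 0 or u.size == 0:
        raise ValueError("both P and U must be nonempty")
    if np.intersect1d(p, u).size:
        raise ValueError("P and U must be disjoint")
    if (kernel is None) == (features is None):
        raise ValueError("pass exactly one of kernel or features")
    rng = np.random.default_rng(cfg.seed)

    # --- Stage 1: synthetic positive enlargement -------------------------
    times = (
        cfg.enlargement_times_override
        if cfg.enlargement_times_override is not None
        else enlargement_times(len(p), cfg.schedule)
    )
    n_neighbors = neighbor_count_for_amount(times * 100.0, cfg.k_neighbors)
    if features is not None:
        x = np.asarray(features, dtype=float)
        n_orig = len(x)
        dist = squareform(pdist(x))
        enlarged = (
            make_synthetic_examples(p, dist, n_neighbors, cfg.k_neighbors, rng)
            if n_neighbors > 0
            else EnlargedPositives(original_ids=p)
        )
        x_aug = np.vstack([x, synthetic_features(x, enlarged)])
        gamma0 = cfg.rbf_gamma if cfg.rbf_gamma is not None else 1.0 / (x.shape[1] * x.var())
        k_full = rbf_kernel(x_aug, gamma=gamma0)
        features_aug = x_aug
        kernel_mode = "rbf"
    else:
        k_base = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel, float)
        n_orig = len(k_base)
        dist = kernel_induced_distances(k_base)
        enlarged = (
            make_synthetic_examples(p, dist, n_neighbors, cfg.k_neighbors, rng)
            if n_neighbors > 0
            else EnlargedPositives(original_ids=p)
        )
        k_full = extend_kernel_with_synthetics(k_base, enlarged)
        features_aug = None
        gamma0 = None
        kernel_mode = "precomputed"
    syn_idx = np.arange(n_orig, n_orig + enlarged.n_synthetic)
    p_tilde = np.concatenate([p, syn_idx])

    # --- Stage 2: representative negative extraction ---------------------
    if cfg.exclude_synthetics_from_validation:
        split_src = split_validation(p, u, cfg.validation_fraction, rng)
        split = ValidationSplit(
            v_pos=split_src.v_pos,
            v_unl=split_src.v_unl,
            train_pos=np.concatenate([split_src.train_pos, syn_idx]),
            train_unl=split_src.train_unl,
        )
    else:
        split = split_validation(p_tilde, u, cfg.validation_fraction, rng)
    n1 = initial_negatives(split.train_pos, split.train_unl, k_full, cfg.one_class_percent)
    u_prime = np.setdiff1d(split.train_unl, n1)
    trace = iterate_negatives(
        split.train_pos,
        u_prime,
        n1,
        k_full,
        m=cfg.m,
        stop_ratio=cfg.stop_ratio,
        svm_params={"C": cfg.iteration_C},
    )
    if len(trace):
        rn = select_representative_negatives(trace, split, k_full)
    else:
        log.warning("iteration trace empty (|U'| already below the stop ratio); "
                    "using the initial negative set as RN")
        rn = n1.copy()

    # --- Stage 3: grid-searched final classifier -------------------------
    train_idx = np.concatenate([p_tilde, rn])
    y = np.concatenate([np.ones(len(p_tilde), dtype=int), -np.ones(len(rn), dtype=int)])
    syn_parents = {
        int(n_orig + r): (c.parent_a, c.parent_b)
        for r, c in enumerate(enlarged.combinations)
    }
    model, best_params, cv_table = grid_search_train(
        y,
        kernel=k_full if kernel_mode == "precomputed" else None,
        features=features_aug,
        train_indices=train_idx,
        kernel_mode=kernel_mode,
        C_grid=cfg.C_grid,
        gamma_grid=cfg.gamma_grid,
        folds=cfg.cv_folds,
        synthetic_parents=syn_parents,
    )

    manifest = {
        "config": cfg.to_dict(),
        "kernel_mode": kernel_mode,
        "rbf_gamma_stage12": gamma0,
        "n_genes": int(n_orig),
        "n_positives": int(len(p)),
        "n_unlabeled": int(len(u)),
        "enlargement_times": int(times),
        "n_neighbors_used": int(n_neighbors),
        "n_synthetic": int(enlarged.n_synthetic),
        "n_p_tilde": int(len(p_tilde)),
        "n_validation_pos": int(len(split.v_pos)),
        "n_validation_unl": int(len(split.v_unl)),
        "n_initial_negatives": int(len(n1)),
        "n_iterations": int(len(trace)),
        "iteration_negatives": [int(len(r.negatives)) for r in trace.records],
        "iteration_u_remaining": [int(r.u_remaining) for r in trace.records],
        "iteration_validation_f1": [float(r.validation_f1) for r in trace.records],
        "n_representative_negatives": int(len(rn)),
        "representative_negatives": [int(i) for i in rn],
        "best_params": {k: (None if v is None else float(v)) for k, v in best_params.items()},
    }
    return SpeRneResult(
        model=model,
        best_params=best_params,
        cv_table=cv_table,
        trace=trace,
        rn=rn,
        enlarged=enlarged,
        split=split,
        manifest=manifest,
        kernel=k_full,
        features_aug=features_aug,
    )


def predict_unknowns(
    model: TrainedModel,
    kernel: np.ndarray | None = None,
    query_indices=None,
    features: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and decision values for query genes.

    Precomputed mode needs the full kernel and global query indices (an
    index outside the kernel raises with the offending ids listed); RBF
    mode needs explicit feature rows.
    """
    if model.kernel_mode == "precomputed":
        if kernel is None or query_indices is None:
            raise ValueError("precomputed mode needs kernel and query_indices")
        q = np.asarray(query_indices, dtype=int)
        bad = q[(q < 0) | (q >= kernel.shape[0])]
        if bad.size:
            raise ValueError(f"query ids not covered by the kernel: {bad.tolist()}")
        dec = model.decision_function(kernel=kernel, query_indices=q)
    else:
        dec = model.decision_function(features=features)
    labels = np.where(dec > 0, 1, -1)
    return labels, dec


def collapse_synthetic_supports(
    model: TrainedModel, enlarged: EnlargedPositives, n_orig: int
) -> TrainedModel:
    """Re-express a precomputed-mode model over original kernel rows only.

    A synthetic support vector s = alpha*e + (1-alpha)*e' contributes
    dual * K(x, s) = dual*alpha*K(x, e) + dual*(1-alpha)*K(x, e') to the
    decision function, so its dual weight folds exactly onto its parents.
    The returned model scores any point of the original (unextended)
    kernel — the form saved to disk — and its decision values coincide
    with the input model's.  Support-vector bookkeeping (e.g. negative-SV
    retrieval) refers to the folded weights, so use the original model for
    anything beyond prediction.
    """
    if model.kernel_mode != "precomputed":
        return model
    coef: dict[int, float] = {}
    for pos, dual in zip(model.support_, model.dual_coef):
        g = int(model.train_indices[pos])
        if g < n_orig:
            coef[g] = coef.get(g, 0.0) + float(dual)
        else:
            c = enlarged.combinations[g - n_orig]
            coef[c.parent_a] = coef.get(c.parent_a, 0.0) + float(dual) * c.alpha
            coef[c.parent_b] = coef.get(c.parent_b, 0.0) + float(dual) * (1.0 - c.alpha)
    idx = np.array(sorted(coef), dtype=int)
    lab = {int(g): int(l) for g, l in zip(model.train_indices, model.train_labels)}
    return TrainedModel(
        mode=model.mode,
        kernel_mode="precomputed",
        support_=np.arange(len(idx)),
        dual_coef=np.array([coef[int(i)] for i in idx]),
        intercept=model.intercept,
        params=dict(model.params),
        train_indices=idx,
        train_labels=np.array([lab.get(int(i), 1) for i in idx], dtype=int),
    )


def _holdout_split(ds, fraction: float, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    p_hold = np.sort(rng.choice(ds.P, size=math.ceil(fraction * len(ds.P)), replace=False))
    u_hold = np.sort(rng.choice(ds.U, size=math.ceil(fraction * len(ds.U)), replace=False))
    return (
        np.setdiff1d(ds.P, p_hold),
        np.setdiff1d(ds.U, u_hold),
        p_hold,
        u_hold,
    )


def compare_strategies(
    strategies=STRATEGIES,
    seeds=STANDARD_SUITE_SEEDS,
    dataset_params: dict | None = None,
    config: SpeRneConfig | None = None,
    holdout_fraction: float = 0.20,
    svm_params: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark negative-selection strategies on simulated PU data.

    For each seed a PU dataset is drawn, 20% of the labeled positives and
    20% of the unlabeled pool are held out, each strategy trains on the
    rest, and two scores are recorded: F1 on the held-out split with
    held-out unlabeled points treated as negatives (the PU evaluation
    protocol), and the ROC score of the decision values against the hidden
    ground truth of the held-out points.  Returns (per-run rows, per-
    strategy summary with mean/variance of F1, mean ROC and the count of
    runs with F1 = 0 under the NaN-to-zero convention).

    All strategies, including the main pipeline, share one fixed-width RBF
    kernel over the features (precomputed mode), so the comparison
    isolates the negative-selection strategy.
    """
    params = dict(STANDARD_SUITE)
    params.update(dataset_params or {})
    base_cfg = config or SpeRneConfig()
    rows = []
    for seed in seeds:
        ds = simulate_pu_dataset(**params, seed=seed)
        rng = np.random.default_rng([seed, 7])
        p_tr, u_tr, p_hold, u_hold = _holdout_split(ds, holdout_fraction, rng)
        x = ds.features
        gamma = base_cfg.rbf_gamma if base_cfg.rbf_gamma is not None else 1.0 / (
            x.shape[1] * x.var()
        )
        k_shared = rbf_kernel(x, gamma=gamma)
        hold_idx = np.concatenate([p_hold, u_hold])
        y_eval = np.concatenate(
            [np.ones(len(p_hold), dtype=int), -np.ones(len(u_hold), dtype=int)]
        )
        for strategy in strategies:
            if strategy == "spe_rne":
                cfg = dataclasses.replace(base_cfg, seed=seed)
                res = run_spe_rne(p_tr, u_tr, kernel=k_shared, config=cfg)
                _, dec = predict_unknowns(res.model, kernel=res.kernel, query_indices=hold_idx)
            else:
                if strategy == "twoclass":
                    model = _baselines.twoclass_train(p_tr, u_tr, k_shared, svm_params)
                elif strategy == "twoclassbal":
                    model = _baselines.twoclassbal_train(
                        p_tr, u_tr, k_shared, svm_params, rng_seed=np.random.default_rng([seed, 11])
                    )
                elif strategy == "psol_lite":
                    model = _baselines.psol_lite_train(p_tr, u_tr, k_shared, svm_params)
                else:
                    raise ValueError(f"unknown strategy {strategy!r}")
                _, dec = predict_unknowns(model, kernel=k_shared, query_indices=hold_idx)
            pred = np.where(dec > 0, 1, -1)
            _, _, f1 = precision_recall_f1(confusion_counts(y_eval, pred))
            roc = roc_auc(ds.truth[hold_idx], dec)
            rows.append({"strategy": strategy, "seed": seed, "f1": f1, "roc": roc})
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("strategy", sort=False)
        .agg(
            mean_f1=("f1", "mean"),
            var_f1=("f1", lambda s: float(np.var(s))),
            mean_roc=("roc", "mean"),
            n_f1_zero=("f1", lambda s: int((s == 0).sum())),
            n_runs=("f1", "size"),
        )
        .reset_index()
    )
    return table, summary
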