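"""Synthetic data generators for positive-unlabeled experiments.

The PU generator emulates the structure the method assumes: a compact
cloud of positives of which only a few are labeled, and a multi-modal
negative class (three Gaussian components, reflecting that "not annotated
to this term" covers many unrelated functions) mixed with hidden positives
into the unlabeled pool.  Companion generators produce Erdős–Rényi
interaction graphs and expression matrices with missing entries so the
kernel-building and imputation stages are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .kernels import ExpressionMatrix, InteractionGraph

__all__ = [
    "SimulatedPUDataset",
    "simulate_pu_dataset",
    "simulate_interaction_graph",
    "simulate_expression_matrix",
    "STANDARD_SUITE",
    "STANDARD_SUITE_SEEDS",
]

#: The standard simulation suite: parameters used by the benchmark runs.
STANDARD_SUITE = dict(
    n_labeled_pos=20, n_hidden_pos=80, n_neg=900, d=10, separation=4.0, noise_sd=1.0
)
STANDARD_SUITE_SEEDS = tuple(range(1, 21))


@dataclass
class SimulatedPUDataset:
    """Features with hidden ground truth and a PU labeling.

    ``truth`` is +/-1 per row; ``P`` indexes the labeled positives (a
    subset of the true positives) and ``U`` everything else, i.e. all
    negatives plus the hidden positives.
    """

    features: np.ndarray
    truth: np.ndarray
    P: np.ndarray
    U: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        assert np.all(self.truth[self.P] == 1)
        assert len(self.P) + len(self.U) == len(self.truth)

    @property
    def hidden_positives(self) -> np.ndarray:
        return self.U[self.truth[self.U] == 1]


def simulate_pu_dataset(
    n_labeled_pos: int = STANDARD_SUITE["n_labeled_pos"],
    n_hidden_pos: int = STANDARD_SUITE["n_hidden_pos"],
    n_neg: int = STANDARD_SUITE["n_neg"],
    d: int = STANDARD_SUITE["d"],
    separation: float = STANDARD_SUITE["separation"],
    noise_sd: float = STANDARD_SUITE["noise_sd"],
    seed: int = 0,
    n_neg_components: int = 3,
) -> SimulatedPUDataset:
    """Draw a PU dataset of Gaussian clouds.

    Positives sit at the origin with isotropic noise ``noise_sd``;
    negatives are an equal-weight mixture of ``n_neg_components`` Gaussian
    components whose centers lie at distance ``separation`` from the
    positive center in random directions.  Row order is shuffled so the
    index carries no label information.  Deterministic under ``seed``.
    """
    if n_labeled_pos < 2:
        raise ValueError("need at least two labeled positives for downstream kNN")
    rng = np.random.default_rng(seed)
    n_pos = n_labeled_pos + n_hidden_pos
    centers = rng.normal(size=(n_neg_components, d))
    centers *= separation / np.linalg.norm(centers, axis=1, keepdims=True)
    x_pos = rng.normal(scale=noise_sd, size=(n_pos, d))
    comp = rng.integers(n_neg_components, size=n_neg)
    x_neg = centers[comp] + rng.normal(scale=noise_sd, size=(n_neg, d))
    x = np.vstack([x_pos, x_neg])
    truth = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    perm = rng.permutation(len(x))
    x, truth = x[perm], truth[perm]
    pos_idx = np.where(truth == 1)[0]
    labeled = np.sort(rng.choice(pos_idx, size=n_labeled_pos, replace=False))
    unlabeled = np.setdiff1d(np.arange(len(x)), labeled)
    return SimulatedPUDataset(features=x, truth=truth, P=labeled, U=unlabeled, seed=seed)


def simulate_interaction_graph(n: int, edge_prob: float, seed: int = 0) -> InteractionGraph:
    """Erdős–Rényi G(n, p) graph over synthetic gene ids g0000..."""
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    ids = [f"g{i:04d}" for i in range(n)]
    g = nx.gnp_random_graph(n, edge_prob, seed=seed)
    edges = {(ids[u], ids[v]) for u, v in g.edges()}
    return InteractionGraph(gene_ids=ids, edges=edges)


def simulate_expression_matrix(
    n: int, d: int, missing_rate: float, seed: int = 0
) -> ExpressionMatrix:
    """IID Gaussian expression with Bernoulli missingness.

    Rows that come out fully missing are re-masked so every gene keeps at
    least one observation (required by the imputer).
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n, d))
    mask = rng.random(size=(n, d)) < missing_rate
    for i in range(n):
        while mask[i].all():
            mask[i] = rng.random(d) < missing_rate
    values = values.copy()
    values[mask] = np.nan
    return ExpressionMatrix(
        gene_ids=[f"g{i:04d}" for i in range(n)],
        condition_ids=[f"c{j:03d}" for j in range(d)],
        values=values,
    )
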