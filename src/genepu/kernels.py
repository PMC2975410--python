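"""Per-source gene similarity kernels and their combination.

Three sources feed the integrated kernel: a Gaussian kernel on (imputed)
expression profiles, a diffusion kernel on the protein-interaction graph,
and any precomputed similarity matrix (e.g. pairwise sequence scores).
Each kernel is double-centered, then cosine-normalized to unit diagonal,
then the matrices are summed entrywise into the final "sum matrix" used by
the maximum-margin classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import squareform, pdist

from .io_formats import FormatError, KernelMatrix

__all__ = [
    "ExpressionMatrix",
    "InteractionGraph",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "knn_impute",
    "gaussian_kernel",
    "diffusion_kernel",
    "center_kernel",
    "normalize_kernel",
    "combine_kernels",
]

log = logging.getLogger(__name__)

#: Gaussian kernel width used for the expression kernel.
DEFAULT_GAMMA = 2.0
#: Diffusion constant of the interaction-graph kernel.
DEFAULT_BETA = 2.0
#: Neighbors used by the KNN imputer.
DEFAULT_IMPUTE_K = 10

_NORMALIZE_RIDGE = 1e-10


@dataclass
class ExpressionMatrix:
    """Genes x conditions expression levels with missing entries as NaN."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.condition_ids = list(self.condition_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise FormatError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        fully_missing = np.where(np.all(np.isnan(self.values), axis=1))[0]
        if fully_missing.size:
            raise FormatError(
                f"gene {self.gene_ids[fully_missing[0]]!r} has no observed values"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the entry is observed."""
        return ~np.isnan(self.values)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class InteractionGraph:
    """Undirected protein-interaction graph over an ordered gene list."""

    gene_ids: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        universe = set(self.gene_ids)
        canon: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a not in universe or b not in universe:
                raise FormatError(f"edge ({a!r}, {b!r}) outside the gene universe")
            if a == b:
                continue  # self-loops carry no diffusion information
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon

    def adjacency(self) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        a = np.zeros((len(self.gene_ids), len(self.gene_ids)))
        for u, v in self.edges:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        return a


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes-by-conditions TSV; empty cells or 'NA' mean missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionMatrix(
        gene_ids=[str(i) for i in df.index],
        condition_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.condition_ids)
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def read_edge_list(path, gene_ids=None) -> InteractionGraph:
    """Read a two-column undirected edge list; duplicates are collapsed."""
    edges: set[tuple[str, str]] = set()
    nodes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"edge list line {lineno} needs two columns")
            a, b = fields[0], fields[1]
            edges.add((a, b))
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    nodes.append(g)
    ids = list(gene_ids) if gene_ids is not None else nodes
    return InteractionGraph(gene_ids=ids, edges=edges)


def write_edge_list(graph: InteractionGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{b}\n")


def knn_impute(expr: ExpressionMatrix, k: int = DEFAULT_IMPUTE_K) -> ExpressionMatrix:
    """Fill missing expression entries by weighted k-nearest-neighbor rows.

    For a missing entry (i, j), candidate donors are the gene rows with
    column j observed.  Distance to a donor is the Euclidean distance over
    the co-observed columns, with the squared distance rescaled by the
    inverse fraction of co-observed columns so rows with few shared columns
    are not spuriously close.  The k nearest donors contribute a weighted
    mean with weights proportional to 1/distance (exact-duplicate donors,
    distance zero, take over with equal weights).  If no donor shares an
    observed column, the column mean is used.

    Observed entries are never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = expr.values
    obs = expr.mask
    n, d = x.shape
    out = x.copy()
    col_means = np.array(
        [np.nanmean(x[:, j]) if obs[:, j].any() else np.nan for j in range(d)]
    )
    # Scaled squared distances between all row pairs over co-observed columns.
    xz = np.where(obs, x, 0.0)
    obs_f = obs.astype(float)
    co = obs_f @ obs_f.T  # co-observed column counts
    sq = (
        (xz**2 @ obs_f.T) + (obs_f @ (xz**2).T) - 2.0 * (xz @ xz.T)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.sqrt(np.maximum(sq, 0.0) * d / co)
    dist[co == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    for i in range(n):
        missing_cols = np.where(~obs[i])[0]
        for j in missing_cols:
            donors = np.where(obs[:, j] & np.isfinite(dist[i]))[0]
            if donors.size == 0:
                out[i, j] = col_means[j]
                continue
            order = np.lexsort((donors, dist[i, donors]))
            chosen = donors[order[:k]]
            dd = dist[i, chosen]
            if np.any(dd == 0.0):
                out[i, j] = x[chosen[dd == 0.0], j].mean()
            else:
                w = 1.0 / dd
                out[i, j] = np.dot(w, x[chosen, j]) / w.sum()
            if np.isnan(out[i, j]):  # all k donors missing col j cannot happen
                out[i, j] = col_means[j]
    return ExpressionMatrix(
        gene_ids=expr.gene_ids, condition_ids=expr.condition_ids, values=out
    )


def gaussian_kernel(
    expr: ExpressionMatrix, gamma: float = DEFAULT_GAMMA, standardize: bool = False
) -> KernelMatrix:
    """K[i, j] = exp(-gamma * ||x_i - x_j||^2) on complete expression rows.

    ``standardize`` optionally z-scores each condition column first.
    """
    if expr.has_missing:
        raise ValueError("expression matrix has missing values; impute first")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = expr.values
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    sq = squareform(pdist(x, metric="sqeuclidean"))
    k = np.exp(-gamma * sq)
    return KernelMatrix(ids=expr.gene_ids, values=(k + k.T) / 2.0)


def diffusion_kernel(graph: InteractionGraph, beta: float = DEFAULT_BETA) -> KernelMatrix:
    """Matrix exponential exp(beta * H), H = A - D the negative Laplacian.

    Computed by dense symmetric eigendecomposition; the result is symmetric
    PSD and row-stochastic (each row sums to 1) because H annihilates the
    all-ones vector.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = graph.adjacency()
    h = a - np.diag(a.sum(axis=1))
    w, v = scipy.linalg.eigh(h)
    k = (v * np.exp(beta * w)) @ v.T
    return KernelMatrix(ids=graph.gene_ids, values=(k + k.T) / 2.0)


def center_kernel(km: KernelMatrix) -> KernelMatrix:
    """Double-center the kernel so all row and column sums are zero."""
    k = km.values
    row = k.mean(axis=1, keepdims=True)
    col = k.mean(axis=0, keepdims=True)
    grand = k.mean()
    return km.with_values(k - row - col + grand)


def normalize_kernel(km: KernelMatrix) -> KernelMatrix:
    """Cosine-normalize: K[i,j] / sqrt(K[i,i] K[j,j]); unit diagonal.

    Diagonal entries in (0, 1e-10] get a 1e-10 ridge before division;
    a nonpositive diagonal entry is an error naming the gene.
    """
    k = km.values.copy()
    diag = np.diag(k).copy()
    tiny = (diag > 0) & (diag <= _NORMALIZE_RIDGE)
    diag[tiny] += _NORMALIZE_RIDGE
    bad = np.where(diag <= 0)[0]
    if bad.size:
        raise ValueError(
            f"nonpositive kernel self-similarity for gene {km.ids[bad[0]]!r} "
            f"({diag[bad[0]]:.3g}); cannot normalize"
        )
    s = 1.0 / np.sqrt(diag)
    out = k * np.outer(s, s)
    np.fill_diagonal(out, 1.0)
    return km.with_values((out + out.T) / 2.0)


def combine_kernels(kernels: list[KernelMatrix]) -> KernelMatrix:
    """Center, then normalize, each kernel and sum them entrywise.

    Centering removes per-source mean effects and normalization equalizes
    the scale of the sources before the sum, so no single data source
    dominates the combined similarity.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    ids = kernels[0].ids
    for km in kernels[1:]:
        if km.ids != ids:
            bad = next(
                (i, a, b)
                for i, (a, b) in enumerate(zip(ids, km.ids))
                if a != b
            ) if len(km.ids) == len(ids) else (min(len(ids), len(km.ids)), None, None)
            raise ValueError(
                f"kernel id mismatch at position {bad[0]}: {bad[1]!r} vs {bad[2]!r}"
            )
    total = np.zeros_like(kernels[0].values)
    for km in kernels:
        total = total + normalize_kernel(center_kernel(km)).values
    return KernelMatrix(ids=list(ids), values=total)
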