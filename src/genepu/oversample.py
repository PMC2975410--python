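"""Synthetic positive oversampling (stage 1).

With only a handful of annotated genes per functional class, the positive
set is enlarged by convex combinations: for each labeled positive e, n of
its k nearest positive neighbors e' are chosen at random and a synthetic
point alpha*e + (1-alpha)*e' with alpha ~ Uniform(0,1) is added.  Any
synthetic point lies on the open segment between two positives, so any
halfspace containing all positives also contains every synthetic point —
the enlargement introduces no noise that a separating hyperplane could
see.

Synthetic points need never be materialized as features: for an
inner-product kernel, rows for a convex combination follow by bilinearity
(``extend_kernel_with_synthetics``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import KernelMatrix

__all__ = [
    "SyntheticCombination",
    "EnlargedPositives",
    "kernel_induced_distances",
    "neighbor_count_for_amount",
    "make_synthetic_examples",
    "synthetic_features",
    "extend_kernel_with_synthetics",
    "write_combination_manifest",
]

log = logging.getLogger(__name__)


@dataclass
class SyntheticCombination:
    """One synthetic positive: alpha * parent_a + (1 - alpha) * parent_b."""

    parent_a: int
    parent_b: int
    alpha: float
    synthetic_id: str

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.parent_a == self.parent_b:
            raise ValueError("parents must differ")


@dataclass
class EnlargedPositives:
    """The original positive set plus its synthetic combinations."""

    original_ids: np.ndarray
    combinations: list[SyntheticCombination] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.original_ids = np.asarray(self.original_ids, dtype=int)

    @property
    def n_synthetic(self) -> int:
        return len(self.combinations)

    @property
    def n_total(self) -> int:
        return len(self.original_ids) + self.n_synthetic


def kernel_induced_distances(km: KernelMatrix | np.ndarray, indices=None) -> np.ndarray:
    """Distances induced by a kernel: d(i,j) = sqrt(Kii + Kjj - 2Kij).

    For a kernel that is an inner product of feature vectors this equals
    the Euclidean distance in feature space.  Negative radicands from
    numerical noise are clipped to zero.
    """
    k = km.values if isinstance(km, KernelMatrix) else np.asarray(km, dtype=float)
    if indices is not None:
        k = k[np.ix_(indices, indices)]
    diag = np.diag(k)
    sq = diag[:, None] + diag[None, :] - 2.0 * k
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def neighbor_count_for_amount(amount_percent: float, k: int) -> int:
    """Number of neighbors combined per positive for a given enlargement.

    An enlargement of 100*n percent generates n synthetic examples per
    positive, one along each of n randomly chosen nearest neighbors, so
    n = round(amount/100) clamped to [0, k].  500% with k = 10 uses 5
    neighbors; 0% disables synthesis.
    """
    if amount_percent < 0:
        raise ValueError("enlargement amount must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = int(np.floor(amount_percent / 100.0 + 0.5))
    return min(n, k)


def make_synthetic_examples(
    positives: Sequence[int],
    distances: np.ndarray,
    n: int,
    k: int,
    rng_seed,
) -> EnlargedPositives:
    """Generate n synthetic combinations per positive from its k-NN.

    ``distances`` is a full square matrix indexable by the global positive
    indices (e.g. from ``kernel_induced_distances`` or explicit Euclidean
    distances).  Neighbors are searched within the positive set only; ties
    break by ascending index.  The n partners are drawn uniformly without
    replacement; if n exceeds the neighbors available after clamping k to
    |P|-1, partners cycle with replacement (logged).  alpha is drawn
    Uniform(0,1), rejecting exact endpoints.
    """
    p = np.asarray(sorted(positives), dtype=int)
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > k:
        raise ValueError(f"n={n} exceeds k={k}")
    if n == 0:
        return EnlargedPositives(original_ids=p)
    if len(p) < 2:
        raise ValueError("need at least two positives to synthesize")
    if k > len(p) - 1:
        log.warning("clamping k from %d to %d (|P|-1)", k, len(p) - 1)
        k = len(p) - 1
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    combos: list[SyntheticCombination] = []
    counter = 0
    for e in p:
        others = p[p != e]
        d = distances[e, others]
        order = np.lexsort((others, d))
        nn = others[order[:k]]
        if n <= len(nn):
            chosen = rng.choice(nn, size=n, replace=False)
        else:
            log.warning("cycling neighbors with replacement for positive %d", e)
            reps = int(np.ceil(n / len(nn)))
            chosen = np.tile(nn, reps)[:n]
        for e_prime in chosen:
            alpha = rng.uniform(0.0, 1.0)
            while alpha <= 0.0 or alpha >= 1.0:  # measure-zero guard
                alpha = rng.uniform(0.0, 1.0)
            combos.append(
                SyntheticCombination(
                    parent_a=int(e),
                    parent_b=int(e_prime),
                    alpha=float(alpha),
                    synthetic_id=f"syn{counter:05d}",
                )
            )
            counter += 1
    return EnlargedPositives(original_ids=p, combinations=combos)


def synthetic_features(features: np.ndarray, enlarged: EnlargedPositives) -> np.ndarray:
    """Materialize synthetic points as explicit feature rows."""
    x = np.asarray(features, dtype=float)
    if not enlarged.combinations:
        return np.empty((0, x.shape[1]))
    rows = [
        c.alpha * x[c.parent_a] + (1.0 - c.alpha) * x[c.parent_b]
        for c in enlarged.combinations
    ]
    return np.vstack(rows)


def extend_kernel_with_synthetics(
    kernel: KernelMatrix | np.ndarray,
    enlarged: EnlargedPositives,
    check_psd: bool = True,
) -> np.ndarray:
    """Append kernel rows/columns for each synthetic point by bilinearity.

    A synthetic point s = alpha*e + (1-alpha)*e' has
    K(s, x) = alpha*K(e, x) + (1-alpha)*K(e', x) for any x, and the
    synthetic-synthetic block follows by expanding both sides.  The
    originals occupy indices 0..n-1 and synthetics n..n+s-1 of the output.
    A non-PSD input (smallest eigenvalue < -1e-6) is reported as a warning
    because the bilinear extension is only meaningful for inner-product
    kernels; the computation proceeds regardless.
    """
    k = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel, dtype=float)
    n = k.shape[0]
    s = enlarged.n_synthetic
    if s == 0:
        return k.copy()
    if check_psd:
        lo = float(np.linalg.eigvalsh(k)[0])
        if lo < -1e-6:
            log.warning("input kernel is not PSD (min eigenvalue %.3g)", lo)
    # Each synthetic point is a sparse coefficient vector over the originals.
    coef = np.zeros((s, n))
    for r, c in enumerate(enlarged.combinations):
        coef[r, c.parent_a] += c.alpha
        coef[r, c.parent_b] += 1.0 - c.alpha
    k_os = k @ coef.T  # originals x synthetics
    k_ss = coef @ k_os  # synthetics x synthetics
    out = np.empty((n + s, n + s))
    out[:n, :n] = k
    out[:n, n:] = k_os
    out[n:, :n] = k_os.T
    out[n:, n:] = (k_ss + k_ss.T) / 2.0
    return out


def write_combination_manifest(enlarged: EnlargedPositives, path) -> None:
    """TSV manifest (synthetic_id, parent_a, parent_b, alpha) for audit."""
    with open(path, "w") as fh:
        fh.write("synthetic_id\tparent_a\tparent_b\talpha\n")
        for c in enlarged.combinations:
            fh.write(f"{c.synthetic_id}\t{c.parent_a}\t{c.parent_b}\t{c.alpha:.17g}\n")
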