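"""On-disk formats and annotation preprocessing.

Kernel/similarity matrices travel as TSV with a header row and a first
column that both list the gene identifiers in the same order.  Annotations
are two-column TSV (gene, term) plus a parent->child edge list describing
the term DAG; a thin GAF 2.x converter is provided.  Identifiers are
opaque, case-sensitive strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "KernelMatrix",
    "AnnotationSet",
    "TermGroup",
    "FormatError",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_annotations",
    "read_gaf",
    "write_annotations",
    "propagate_annotations",
    "group_terms_by_size",
    "GROUP_BOUNDARIES",
    "GROUP_LABELS",
]

#: Annotation-size group boundaries, half-open: [0,60), [60,100), [100,300), [300,inf).
GROUP_BOUNDARIES: tuple[int, ...] = (60, 100, 300)
GROUP_LABELS: tuple[str, ...] = ("<60", "60-100", "100-300", ">300")

_SYMMETRY_TOL = 1e-8


class FormatError(ValueError):
    """Raised for malformed on-disk artifacts."""


@dataclass
class KernelMatrix:
    """A square symmetric gene-by-gene similarity (kernel) matrix.

    Parameters
    ----------
    ids
        Ordered gene identifiers; must be unique.
    values
        Square real matrix aligned with ``ids``; symmetric within 1e-8.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise FormatError(
                f"kernel must be square with dimension {n}, got shape {self.values.shape}"
            )
        if len(set(self.ids)) != n:
            raise FormatError("gene identifiers must be unique")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise FormatError(f"kernel not symmetric (max asymmetry {asym:.3g})")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, gene: str) -> int:
        return self.ids.index(gene)

    def with_values(self, values: np.ndarray) -> "KernelMatrix":
        return KernelMatrix(ids=list(self.ids), values=values)


@dataclass
class AnnotationSet:
    """Gene -> term assignments together with the term DAG.

    ``dag`` holds (parent, child) edges; every annotated term must either
    appear in the DAG or be a root/isolated term (always satisfied, since a
    term absent from the DAG is treated as isolated).  The DAG must be
    acyclic.
    """

    assignments: set[tuple[str, str]]
    dag: set[tuple[str, str]]
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignments = set(self.assignments)
        self.dag = set(self.dag)
        if not self.gene_universe:
            self.gene_universe = sorted({g for g, _ in self.assignments})
        g = nx.DiGraph(list(self.dag))
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            u, v = cycle[0][0], cycle[0][1]
            raise FormatError(f"term DAG contains a cycle through edge ({u}, {v})")

    @property
    def terms(self) -> set[str]:
        return {t for _, t in self.assignments} | {t for e in self.dag for t in e}

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, t in self.assignments if t == term}


@dataclass
class TermGroup:
    """A term together with its annotation count and size-group label."""

    term: str
    positive_count: int
    group_label: str

    def __post_init__(self) -> None:
        if self.positive_count < 0:
            raise ValueError("positive_count must be non-negative")
        expected = label_for_count(self.positive_count)
        if self.group_label != expected:
            raise ValueError(
                f"group label {self.group_label!r} inconsistent with count "
                f"{self.positive_count} (expected {expected!r})"
            )


def label_for_count(
    count: int,
    boundaries: tuple[int, ...] = GROUP_BOUNDARIES,
    labels: tuple[str, ...] = GROUP_LABELS,
) -> str:
    """Map an annotation count to its half-open size group."""
    for b, lab in zip(boundaries, labels):
        if count < b:
            return lab
    return labels[-1]


def read_similarity_matrix(path) -> KernelMatrix:
    """Read a TSV similarity matrix; symmetry is enforced by (K + K.T)/2.

    The header row and first column must list identical identifiers in the
    same order.  Non-numeric cells raise a parse error naming the cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(row_ids) != len(col_ids):
        raise FormatError(
            f"matrix is not square: {len(row_ids)} rows vs {len(col_ids)} columns"
        )
    if row_ids != col_ids:
        bad = next(i for i, (r, c) in enumerate(zip(row_ids, col_ids)) if r != c)
        raise FormatError(
            f"row/column identifiers disagree at position {bad}: "
            f"{row_ids[bad]!r} vs {col_ids[bad]!r}"
        )
    try:
        values = df.astype(float).to_numpy()
    except ValueError:
        for i, rid in enumerate(row_ids):
            for j, cid in enumerate(col_ids):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell at row {rid!r}, column {cid!r}: "
                        f"{df.iat[i, j]!r}"
                    ) from None
        raise
    values = (values + values.T) / 2.0
    return KernelMatrix(ids=row_ids, values=values)


def write_similarity_matrix(km: KernelMatrix, path) -> None:
    """Write a kernel matrix as TSV with full float precision."""
    df = pd.DataFrame(km.values, index=km.ids, columns=km.ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_annotations(assign_path, dag_path, gene_universe=None) -> AnnotationSet:
    """Read gene->term pairs and a parent->child DAG edge list (both TSV)."""
    pairs = _read_two_cols(assign_path, "annotation")
    edges = _read_two_cols(dag_path, "dag") if dag_path is not None else set()
    return AnnotationSet(
        assignments=pairs,
        dag=edges,
        gene_universe=list(gene_universe) if gene_universe is not None else [],
    )


def read_gaf(path) -> set[tuple[str, str]]:
    """Extract (gene, term) pairs from a GAF 2.x file.

    Only the DB object symbol (column 2) and GO id (column 5) are used;
    comment lines starting with '!' are skipped.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"GAF line has fewer than 5 columns: {line!r}")
            pairs.add((fields[2], fields[4]))
    return pairs


def write_annotations(ann: AnnotationSet, assign_path, dag_path=None) -> None:
    with open(assign_path, "w") as fh:
        for g, t in sorted(ann.assignments):
            fh.write(f"{g}\t{t}\n")
    if dag_path is not None:
        with open(dag_path, "w") as fh:
            for p, c in sorted(ann.dag):
                fh.write(f"{p}\t{c}\n")


def _read_two_cols(path, what: str) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{what} line {lineno} needs two columns: {line!r}")
            pairs.add((fields[0], fields[1]))
    return pairs


def propagate_annotations(ann: AnnotationSet) -> AnnotationSet:
    """Up-propagate annotations along the term DAG (true-path rule).

    A gene annotated to a term becomes annotated to every ancestor of that
    term.  The operation is idempotent and only adds pairs.
    """
    g = nx.DiGraph(list(ann.dag))
    ancestors: dict[str, set[str]] = {}
    out = set(ann.assignments)
    for gene, term in ann.assignments:
        if term not in ancestors:
            ancestors[term] = nx.ancestors(g, term) if term in g else set()
        out.update((gene, anc) for anc in ancestors[term])
    return replace(ann, assignments=out)


def group_terms_by_size(
    ann: AnnotationSet,
    terms=None,
    boundaries: tuple[int, ...] = GROUP_BOUNDARIES,
    labels: tuple[str, ...] = GROUP_LABELS,
) -> list[TermGroup]:
    """Count annotated genes per term and assign size-group labels.

    Expects an already-propagated AnnotationSet so counts respect the
    true-path rule.  Boundaries are half-open so every count maps to
    exactly one group.
    """
    counts: dict[str, int] = {}
    for _, term in ann.assignments:
        counts[term] = counts.get(term, 0) + 1
    wanted = sorted(counts) if terms is None else list(terms)
    return [
        TermGroup(
            term=t,
            positive_count=counts.get(t, 0),
            group_label=label_for_count(counts.get(t, 0), boundaries, labels),
        )
        for t in wanted
    ]
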