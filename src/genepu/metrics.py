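"""Evaluation measures: precision/recall/F1 with the NaN-to-zero
convention, rank-based ROC score, and per-group aggregation.

When a classifier recalls no positives (TP = 0 with FP = 0 or FN arbitrary)
precision and/or recall are 0/0; the resulting F1 is undefined and, under
the convention used throughout this package, scored as 0 so that severely
imbalanced failures count against a method instead of being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "precision_recall_f1",
    "roc_auc",
    "aggregate_by_group",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    """Per-term scores plus per-group summary statistics.

    ``per_term`` columns: term, group, precision, recall, f1, roc.
    ``per_group`` columns: group, n, nan_count (F1 undefined before the
    zero substitution), mean_f1, var_f1, mean_roc.
    """

    per_term: pd.DataFrame
    per_group: pd.DataFrame

    def to_tsv(self, per_term_path, per_group_path=None) -> None:
        self.per_term.to_csv(per_term_path, sep="\t", index=False)
        if per_group_path is not None:
            self.per_group.to_csv(per_group_path, sep="\t", index=False)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/FN/TN for +/-1 labels."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (set(np.unique(yt)) <= {-1, 1} and set(np.unique(yp)) <= {-1, 1}):
        raise ValueError("labels must be +1 or -1")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
    )


def precision_recall_f1(
    c: ConfusionCounts, nan_to_zero: bool = True
) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 gives NaN,
    replaced by 0 when ``nan_to_zero`` (the default)."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    if np.isnan(p) or np.isnan(r) or (p + r) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * p * r / (p + r)
    if nan_to_zero:
        p = 0.0 if np.isnan(p) else p
        r = 0.0 if np.isnan(r) else r
        f1 = 0.0 if np.isnan(f1) else f1
    return p, r, f1


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve from real-valued scores.

    Computed as the normalized Mann-Whitney rank statistic; tied scores
    contribute 1/2.  Returns NaN when only one class is present.
    """
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("y_true and scores must align")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == -1))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks handle ties as 1/2 wins
    r_pos = ranks[yt == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aggregate_by_group(
    per_term: pd.DataFrame,
    groups=None,
    population_variance: bool = True,
) -> EvalReport:
    """Summarize per-term rows by annotation-size group.

    ``per_term`` must carry columns term, group, f1 and optionally roc and
    f1_was_nan (True where F1 was undefined before substitution).  Variance
    is the population variance (divide by n) by default.  ``groups``
    optionally fixes the group rows to emit; a listed group with no terms
    yields n=0 and NaN statistics.
    """
    df = per_term.copy()
    if "roc" not in df.columns:
        df["roc"] = np.nan
    if "f1_was_nan" not in df.columns:
        df["f1_was_nan"] = False
    ddof = 0 if population_variance else 1
    wanted = sorted(df["group"].unique()) if groups is None else list(groups)
    rows = []
    for group in wanted:
        sub = df[df["group"] == group]
        n = len(sub)
        rows.append(
            {
                "group": group,
                "n": n,
                "nan_count": int(sub["f1_was_nan"].sum()),
                "mean_f1": float(sub["f1"].mean()) if n else float("nan"),
                "var_f1": float(sub["f1"].var(ddof=ddof)) if n > ddof else (0.0 if n else float("nan")),
                "mean_roc": float(sub["roc"].mean()) if n else float("nan"),
            }
        )
    return EvalReport(per_term=df, per_group=pd.DataFrame(rows))
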