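"""Dual-score feature ranking: information gain ratio and Gini gain.

Continuous features are first discretized into equal-frequency bins
(default 4).  Each feature then gets two filter scores against the binary
class label:

* gain ratio  = (H(label) - H(label | feature)) / H(feature), in bits,
  defined as 0 when the feature has zero entropy;
* Gini gain   = Gini(label) - sum_v p(v) Gini(label | v).

Per-score rank positions are combined (mean of ranks by default) and the
top-k features (default k = 5) are selected.  Ties break by gain ratio
(descending), then by name, so the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class UndefinedScoreError(ValueError):
    """Raised when the label has a single class."""


@dataclass
class RankedFeatures:
    """Per-feature scores, combined ranks, and the selected subset."""

    scores: pd.DataFrame       # index: feature; columns: gain_ratio, gini, combined_rank
    selected: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["selected"] = out.index.isin(self.selected)
        return out.reset_index(names="feature")


def discretize_equal_frequency(values: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency (quantile) binning by rank blocks.

    Each value is assigned ``floor(min_rank * bins / n)`` where
    ``min_rank`` is the rank of its first occurrence in sorted order, so
    tied values always share the lowest bin their rank block touches and
    bin sizes differ by at most one in the absence of ties.  A constant
    column lands in a single bin; heavily tied columns occupy fewer than
    ``bins`` bins.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if bins < 1:
        raise ValueError("bins must be >= 1")
    min_rank = np.searchsorted(np.sort(values), values, side="left")
    return (min_rank * bins // n).astype(np.int64)


def _entropy_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _gini(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - np.sum(p**2))


def _contingency(feature: np.ndarray, label: np.ndarray) -> np.ndarray:
    f_codes, _ = pd.factorize(feature, sort=True)
    l_codes, l_uniq = pd.factorize(label, sort=True)
    if len(l_uniq) < 2:
        raise UndefinedScoreError("label must contain both classes")
    table = np.zeros((f_codes.max() + 1, l_codes.max() + 1), dtype=np.int64)
    np.add.at(table, (f_codes, l_codes), 1)
    return table


def gain_ratio(feature: np.ndarray, label: np.ndarray) -> float:
    """Information gain ratio of a categorical feature vs a binary label."""
    table = _contingency(feature, label)
    n = table.sum()
    h_label = _entropy_bits(table.sum(axis=0))
    h_feature = _entropy_bits(table.sum(axis=1))
    if h_feature == 0:
        return 0.0
    h_cond = sum((row.sum() / n) * _entropy_bits(row) for row in table)
    return (h_label - h_cond) / h_feature


def gini_gain(feature: np.ndarray, label: np.ndarray) -> float:
    """Gini impurity reduction of the label after conditioning on the feature."""
    table = _contingency(feature, label)
    n = table.sum()
    g_label = _gini(table.sum(axis=0))
    g_cond = sum((row.sum() / n) * _gini(row) for row in table)
    return g_label - g_cond


def rank_and_select(table: pd.DataFrame, k: int = 5, bins: int = 4,
                    combine: str = "mean",
                    feature_columns: list[str] | None = None
                    ) -> RankedFeatures:
    """Score every feature column by both methods and select the top k.

    ``combine`` is one of ``mean`` (mean of the two per-method rank
    positions), ``gain_ratio_only`` or ``gini_only``.
    """
    if feature_columns is None:
        feature_columns = [c for c in table.columns
                           if c not in ("lesion_id", "label", "sequence")]
    label = table["label"].to_numpy()
    classes, counts = np.unique(label, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise UndefinedScoreError("need at least 2 lesions per class")

    gr = np.empty(len(feature_columns))
    gg = np.empty(len(feature_columns))
    for i, col in enumerate(feature_columns):
        binned = discretize_equal_frequency(table[col].to_numpy(), bins=bins)
        gr[i] = gain_ratio(binned, label)
        gg[i] = gini_gain(binned, label)

    rank_gr = rankdata(-gr, method="average")
    rank_gg = rankdata(-gg, method="average")
    if combine == "mean":
        combined = (rank_gr + rank_gg) / 2.0
    elif combine == "gain_ratio_only":
        combined = rank_gr
    elif combine == "gini_only":
        combined = rank_gg
    else:
        raise ValueError(f"unknown combine mode: {combine!r}")

    scores = pd.DataFrame({"gain_ratio": gr, "gini": gg,
                           "combined_rank": combined},
                          index=pd.Index(feature_columns, name="feature"))
    order = sorted(range(len(feature_columns)),
                   key=lambda i: (combined[i], -gr[i], feature_columns[i]))
    k = min(k, len(feature_columns))
    selected = [feature_columns[i] for i in order[:k]]
    return RankedFeatures(scores=scores, selected=selected)
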