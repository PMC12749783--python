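"""Fairness auditing of malignancy-score distributions across skin-tone classes.

A melanoma classifier assigns each benign lesion a malignancy risk score in
[0, 100]%. If the classifier treated all skin tones exchangeably, the score
distribution would not depend on the lesion's skin-tone class. The audit
quantifies departures with the two-sample Kolmogorov-Smirnov statistic
D = sup_t |F_i(t) - F_j(t)| between every pair of classes, and summarizes
how D grows with the ordinal distance Δ = |i - j| between classes: a scale
whose classes capture genuinely different score behavior shows D rising
with Δ. Per-class mean percentile ranks (midrank ties) summarize location
shifts on a common 0-100 scale. D is invariant under strictly monotone
transforms, so the log transform used for plotting never changes it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "FairnessReport",
    "log_scores",
    "ks_two_sample",
    "ks_p_value",
    "percentile_ranks",
    "ks_matrix",
    "ks_by_class_distance",
    "fairness_report",
    "SCORE_FLOOR",
]

#: Scores are floored here (percent scale) before taking logs, so a 0 maps
#: to ln(1e-4) rather than -inf.
SCORE_FLOOR = 1e-4


@dataclass
class FairnessReport:
    """Audit summary for one labeling scale."""

    scale: str
    class_labels: list[int]
    class_sizes: dict[int, int]
    mean_percentile_rank: dict[int, float]
    ks: np.ndarray  # symmetric, zero diagonal, NaN for empty classes
    ks_by_delta: dict[int, float]
    n_scores: int

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "class_labels": self.class_labels,
            "class_sizes": {int(k): v for k, v in self.class_sizes.items()},
            "mean_percentile_rank": {int(k): v for k, v in self.mean_percentile_rank.items()},
            "ks_matrix": [[None if np.isnan(v) else v for v in row] for row in self.ks],
            "ks_by_delta": {int(k): v for k, v in self.ks_by_delta.items()},
            "n_scores": self.n_scores,
        }


def log_scores(scores, floor: float = SCORE_FLOOR) -> np.ndarray:
    """Natural log of max(score, floor); strictly order-preserving above the floor."""
    s = np.asarray(scores, dtype=float)
    if (s < 0).any():
        raise ValueError("scores must be nonnegative")
    return np.log(np.maximum(s, floor))


def ks_two_sample(x, y) -> float:
    """Two-sample KS statistic: the supremum gap between the two ECDFs."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def ks_p_value(d: float, n1: int, n2: int) -> float:
    """Asymptotic two-sample KS p-value (Kolmogorov limiting distribution)."""
    en = np.sqrt(n1 * n2 / (n1 + n2))
    return float(_stats.kstwobign.sf(en * d))


def percentile_ranks(scores, classes) -> pd.Series:
    """Per-class mean percentile rank of scores in the pooled sample.

    Each score's percentile is 100 · (midrank - 0.5) / n, so a sample with
    no class structure averages near 50.
    """
    s = np.asarray(scores, dtype=float)
    c = np.asarray(classes)
    if s.size != c.size or s.size == 0:
        raise ValueError("scores and classes must be equal-length and non-empty")
    pct = 100.0 * (_stats.rankdata(s, method="average") - 0.5) / s.size
    return pd.Series(pct).groupby(pd.Series(c)).mean()


def ks_matrix(scores, classes, class_labels=None) -> tuple[list[int], np.ndarray]:
    """Pairwise KS matrix across classes (NaN rows/cols for empty classes)."""
    s = np.asarray(scores, dtype=float)
    c = np.asarray(classes, dtype=int)
    labels = sorted(set(c)) if class_labels is None else list(class_labels)
    k = len(labels)
    mat = np.full((k, k), np.nan)
    samples = {lab: s[c == lab] for lab in labels}
    for i, li in enumerate(labels):
        if samples[li].size == 0:
            continue
        mat[i, i] = 0.0
        for j in range(i + 1, k):
            lj = labels[j]
            if samples[lj].size == 0:
                continue
            d = ks_two_sample(samples[li], samples[lj])
            mat[i, j] = mat[j, i] = d
    return labels, mat


def ks_by_class_distance(scores, classes, class_labels=None) -> dict[int, float]:
    """Mean pairwise KS statistic at each ordinal class distance Δ >= 1.

    Pairs involving an empty class are omitted; a Δ with no surviving pair
    is absent from the result.
    """
    labels, mat = ks_matrix(scores, classes, class_labels)
    out: dict[int, list[float]] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if np.isnan(mat[i, j]):
                continue
            delta = abs(labels[j] - labels[i])
            out.setdefault(delta, []).append(mat[i, j])
    return {d: float(np.mean(v)) for d, v in sorted(out.items())}


def fairness_report(scores, classes, scale: str, class_labels=None) -> FairnessReport:
    """Full audit for one scale: sizes, mean percentile ranks, KS matrix, KS-by-Δ."""
    s = np.asarray(scores, dtype=float)
    c = np.asarray(classes, dtype=int)
    labels, mat = ks_matrix(s, c, class_labels)
    ranks = percentile_ranks(s, c)
    return FairnessReport(
        scale=scale,
        class_labels=[int(v) for v in labels],
        class_sizes={int(lab): int((c == lab).sum()) for lab in labels},
        mean_percentile_rank={int(k): float(v) for k, v in ranks.items()},
        ks=mat,
        ks_by_delta=ks_by_class_distance(s, c, labels),
        n_scores=int(s.size),
    )
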