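"""Aggregation of crowdsourced FST reads into per-image majority labels.

Annotators label dermoscopy images with Fitzpatrick Skin Type (I..VI,
coded 1..6). Quality control is sequential: each user carries a *trailing
average accuracy* over their recent gold-scored reads, and a read counts as
"qualified" only while its user ranks within the top 80th percentile of
current user accuracies. Per image, the majority label is the label chosen
by at least 70% of at least 3 qualified reads; with more than 12 qualified
reads a plurality suffices (ties unresolved).

The expected crowd-log schema (one row per read):
``user_id, image_id, order, label, is_gold, gold_label`` where ``order`` is
the user's read sequence index and gold rows carry the in-person reference
label used for scoring.
"""
from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import KappaResult, linear_weighted_kappa

__all__ = [
    "MajorityLabel",
    "trailing_accuracy",
    "qualify_reads",
    "majority_label",
    "majority_labels",
    "crowd_vs_reference",
    "DEFAULT_WINDOW",
]

#: Number of most recent gold-scored reads in the trailing-accuracy window.
DEFAULT_WINDOW = 50

_READ_COLUMNS = ["user_id", "image_id", "order", "label", "is_gold", "gold_label"]


@dataclass(frozen=True)
class MajorityLabel:
    """Aggregated label for one image; ``label is None`` means unresolved."""

    image_id: str
    label: int | None
    n_reads: int
    support: float


def trailing_accuracy(correct, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Running mean correctness over the last ``window`` scored reads.

    Position i holds the mean of the most recent ``window`` entries up to
    and including i (all entries while fewer than ``window`` have accrued).
    """
    c = np.asarray(correct, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("need a non-empty 1-D correctness sequence")
    if window < 1:
        raise ValueError("window must be >= 1")
    csum = np.concatenate([[0.0], np.cumsum(c)])
    idx = np.arange(1, c.size + 1)
    lo = np.maximum(idx - window, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


def qualify_reads(
    reads: pd.DataFrame, percentile: float = 80.0, window: int = DEFAULT_WINDOW
) -> pd.Series:
    """Flag each read as qualified under the sequential top-percentile rule.

    Reads are replayed in global chronological order (``order``, ties broken
    by ``user_id``). Gold reads first update their user's trailing accuracy;
    the read then qualifies iff the user's current accuracy sits at or above
    the (100 - percentile)-th percentile of all users' current accuracies.
    Users with no scored read yet cannot be ranked and their reads are
    unqualified.

    Returns a boolean Series aligned to ``reads.index``.
    """
    missing = [c for c in _READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"crowd log missing columns: {missing}")
    if reads["user_id"].nunique() < 2:
        raise ValueError("need reads from at least 2 users to rank accuracies")
    cut = 100.0 - percentile

    order = reads.sort_values(["order", "user_id"], kind="mergesort").index
    history: dict = {}
    current: dict = {}
    qualified = pd.Series(False, index=reads.index)
    for idx in order:
        row = reads.loc[idx]
        user = row["user_id"]
        if bool(row["is_gold"]):
            dq = history.setdefault(user, deque(maxlen=window))
            dq.append(1.0 if row["label"] == row["gold_label"] else 0.0)
            current[user] = sum(dq) / len(dq)
        if user not in current:
            continue
        threshold = float(np.percentile(list(current.values()), cut))
        qualified.loc[idx] = current[user] >= threshold - 1e-12
    return qualified


def majority_label(
    image_id: str, labels, threshold: float = 0.70, plurality_above: int = 12
) -> MajorityLabel:
    """Apply the majority rule to one image's qualified read labels.

    With ``n <= plurality_above`` reads: a label is assigned iff there are at
    least 3 reads and the top label's share is at least ``threshold`` (70%,
    boundary inclusive). With more reads, the plurality label wins; a tied
    plurality is unresolved.
    """
    labels = list(labels)
    n = len(labels)
    if n == 0:
        return MajorityLabel(image_id, None, 0, 0.0)
    counts = Counter(labels)
    (top, top_n), *rest = counts.most_common()
    tied = bool(rest) and rest[0][1] == top_n
    support = top_n / n
    if n > plurality_above:
        return MajorityLabel(image_id, None if tied else int(top), n, support)
    if n >= 3 and not tied and top_n >= threshold * n - 1e-9:
        return MajorityLabel(image_id, int(top), n, support)
    return MajorityLabel(image_id, None, n, support)


def majority_labels(
    reads: pd.DataFrame,
    qualified: pd.Series | None = None,
    percentile: float = 80.0,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Qualify reads (unless flags are supplied) and aggregate every image.

    Returns one row per image: image_id, label (NA when unresolved),
    n_reads, support.
    """
    if qualified is None:
        qualified = qualify_reads(reads, percentile=percentile, window=window)
    q = reads[qualified]
    rows = []
    for image_id, grp in q.groupby("image_id"):
        ml = majority_label(str(image_id), grp["label"].tolist())
        rows.append(
            {
                "image_id": image_id,
                "label": ml.label if ml.label is not None else pd.NA,
                "n_reads": ml.n_reads,
                "support": ml.support,
            }
        )
    # Images whose every read was unqualified still appear, unresolved.
    seen = {r["image_id"] for r in rows}
    for image_id in reads["image_id"].unique():
        if image_id not in seen:
            rows.append({"image_id": image_id, "label": pd.NA, "n_reads": 0, "support": 0.0})
    return pd.DataFrame(rows).sort_values("image_id").reset_index(drop=True)


def crowd_vs_reference(
    majority: pd.DataFrame, reference: pd.Series, k: int = 6
) -> tuple[np.ndarray, KappaResult]:
    """Confusion table and weighted kappa of majority labels vs in-person FST.

    ``reference`` maps image_id -> in-person class (1..k). Unresolved images
    and images without a reference are excluded from both outputs. The table
    is (reference class × crowd class).
    """
    merged = majority.dropna(subset=["label"]).copy()
    merged["reference"] = merged["image_id"].map(reference)
    merged = merged.dropna(subset=["reference"])
    table = np.zeros((k, k))
    ref = merged["reference"].astype(int).to_numpy()
    crowd = merged["label"].astype(int).to_numpy()
    np.add.at(table, (ref - 1, crowd - 1), 1.0)
    kappa = linear_weighted_kappa(ref, crowd, k)
    return table, kappa
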