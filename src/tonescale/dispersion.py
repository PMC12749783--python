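"""Cluster dispersion of subjective skin-tone classes in colorimeter space.

Each skin site contributes one point in the 2-D CIE (L*, b*) plane — the
triplicate-averaged colorimeter measurement, treated as ground truth — and
carries a class label under each subjective scale (FST, MST, Pantone). The
labels *define* the clusters; nothing is fitted. Two validity indices
quantify how coherently a scale's categories occupy color space:

* Davies-Bouldin index (DBI, Euclidean; lower = tighter/better separated),
* mean silhouette width (RSI), with the convention that a point in a
  singleton class contributes a silhouette of exactly 1.

A per-class "radius" — the population SD of member distances to the class
centroid — is reported separately for plotting circle geometry; it is *not*
the DBI scatter term (which is the mean distance, per the canonical
definition).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CoincidentCentroids

__all__ = [
    "ClassSummary",
    "DispersionReport",
    "select_single_rating",
    "class_centroids",
    "davies_bouldin",
    "silhouette_mean",
    "dispersion_compare",
]


@dataclass(frozen=True)
class ClassSummary:
    label: str
    centroid: tuple[float, float]
    radius: float  # population SD of member->centroid distances
    size: int


@dataclass
class DispersionReport:
    """Per-class geometry plus the two global validity indices for one scale."""

    scale: str
    classes: list[ClassSummary]
    dbi: float
    rsi: float
    n_points: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "dbi": self.dbi,
            "rsi": self.rsi,
            "n_points": self.n_points,
            "seed": self.seed,
            "classes": [
                {
                    "label": c.label,
                    "centroid": list(c.centroid),
                    "radius": c.radius,
                    "size": c.size,
                }
                for c in self.classes
            ],
        }


def select_single_rating(
    df: pd.DataFrame, col_a: str, col_b: str, rng: np.random.Generator
) -> pd.Series:
    """One rating per site: the available one, or a fair coin between the two.

    Sites where both raters rated get a uniform random pick (reproducible
    given the generator's seed); sites with a single rating keep it. Sites
    with neither rating yield NA and should be filtered beforehand.
    """
    a = df[col_a]
    b = df[col_b]
    pick_b = pd.Series(rng.random(len(df)) < 0.5, index=df.index)
    out = a.where(~(a.notna() & b.notna() & pick_b), b)
    out = out.where(a.notna(), b)
    return out


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    return pts


def class_centroids(points, labels) -> dict:
    """Arithmetic-mean centroid and SD-radius for every represented class."""
    pts = _as_points(points)
    labels = np.asarray(labels)
    out: dict = {}
    for lab in pd.unique(labels):
        members = pts[labels == lab]
        centroid = members.mean(axis=0)
        dists = np.linalg.norm(members - centroid, axis=1)
        out[lab] = ClassSummary(
            label=str(lab),
            centroid=tuple(float(v) for v in centroid),
            radius=float(dists.std()),  # population SD; 0 for singletons
            size=int(members.shape[0]),
        )
    return out


def davies_bouldin(points, labels) -> float:
    """Davies-Bouldin index with Euclidean distances and mean-distance scatter.

    DBI = mean over classes i of max_{j != i} (S_i + S_j) / M_ij, where S is
    the mean member-to-centroid distance and M the centroid separation.
    Raises :class:`CoincidentCentroids` when two class centroids coincide.
    """
    pts = _as_points(points)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 distinct classes")
    centroids = np.array([pts[labels == c].mean(axis=0) for c in classes])
    scatter = np.array(
        [
            np.linalg.norm(pts[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(classes)
        ]
    )
    ratios = np.zeros(len(classes))
    for i in range(len(classes)):
        best = -np.inf
        for j in range(len(classes)):
            if j == i:
                continue
            sep = float(np.linalg.norm(centroids[i] - centroids[j]))
            if sep == 0.0:
                raise CoincidentCentroids(
                    f"classes {classes[i]!r} and {classes[j]!r} share a centroid"
                )
            best = max(best, (scatter[i] + scatter[j]) / sep)
        ratios[i] = best
    return float(ratios.mean())


def silhouette_mean(points, labels) -> float:
    """Mean silhouette width over points; singleton classes contribute +1.

    s = (b - a) / max(a, b), with a the mean distance to own-class
    co-members and b the smallest mean distance to another class. A point
    that is the sole member of its class has no within-class distance; its
    silhouette is set to 1 by convention.
    """
    pts = _as_points(points)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 distinct classes")
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    masks = {c: labels == c for c in classes}
    svals = np.empty(pts.shape[0])
    for i in range(pts.shape[0]):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            svals[i] = 1.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, masks[c]].mean() for c in classes if c != labels[i])
        m = max(a, b)
        svals[i] = 0.0 if m == 0.0 else (b - a) / m
    return float(svals.mean())


def dispersion_compare(
    points,
    labels_by_scale: Mapping[str, np.ndarray],
    site_labels=None,
    seed: int | None = None,
) -> dict:
    """One :class:`DispersionReport` per scale on the *same* point set.

    ``labels_by_scale`` maps scale name -> per-point class labels. When
    ``site_labels`` is given, a per-anatomic-site breakdown is attached under
    the key ``"by_site"`` (sites where a scale has a single class are
    reported as None).
    """
    pts = _as_points(points)
    reports: dict = {}
    for scale, labels in labels_by_scale.items():
        labels = np.asarray(labels)
        if len(labels) != pts.shape[0]:
            raise ValueError(f"label length mismatch for scale {scale!r}")
        summaries = class_centroids(pts, labels)
        reports[scale] = DispersionReport(
            scale=scale,
            classes=sorted(summaries.values(), key=lambda c: c.label),
            dbi=davies_bouldin(pts, labels),
            rsi=silhouette_mean(pts, labels),
            n_points=pts.shape[0],
            seed=seed,
        )
    if site_labels is not None:
        site_labels = np.asarray(site_labels)
        by_site: dict = {}
        for site in pd.unique(site_labels):
            sel = site_labels == site
            site_out = {}
            for scale, labels in labels_by_scale.items():
                sub_labels = np.asarray(labels)[sel]
                if len(pd.unique(sub_labels)) < 2:
                    site_out[scale] = None
                    continue
                try:
                    site_out[scale] = {
                        "dbi": davies_bouldin(pts[sel], sub_labels),
                        "rsi": silhouette_mean(pts[sel], sub_labels),
                        "n": int(sel.sum()),
                    }
                except CoincidentCentroids:
                    site_out[scale] = None
            by_site[str(site)] = site_out
        reports["by_site"] = by_site
    return reports
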