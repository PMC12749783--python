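"""Diagnostic figures: dispersion scatter and fairness ECDF / KS-by-distance."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dispersion import DispersionReport
from .fairness import FairnessReport, log_scores


def dispersion_scatter(
    points: np.ndarray, labels: np.ndarray, report: DispersionReport, out_path: str | Path
) -> None:
    """Sites in the (L*, b*) plane colored by class, with SD-radius centroid circles."""
    fig, ax = plt.subplots(figsize=(6, 5))
    classes = sorted(set(str(l) for l in labels))
    cmap = plt.get_cmap("viridis", max(len(classes), 2))
    color_of = {c: cmap(i) for i, c in enumerate(classes)}
    for c in classes:
        sel = np.asarray([str(l) == c for l in labels])
        ax.scatter(points[sel, 0], points[sel, 1], s=12, color=color_of[c], label=c, alpha=0.6)
    for summary in report.classes:
        circ = plt.Circle(
            summary.centroid, max(summary.radius, 0.2),
            fill=False, color=color_of.get(summary.label, "k"), lw=1.5,
        )
        ax.add_patch(circ)
    ax.set_xlabel("L* (colorimeter mean)")
    ax.set_ylabel("b* (colorimeter mean)")
    ax.set_title(f"{report.scale}: DBI={report.dbi:.2f}, RSI={report.rsi:.2f}")
    if len(classes) <= 12:
        ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def fairness_figures(scores, classes, report: FairnessReport, out_dir: str | Path) -> None:
    """ECDFs of log scores per class and the mean-KS-by-distance curve."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logs = log_scores(np.asarray(scores, float))
    classes = np.asarray(classes, int)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for lab in report.class_labels:
        vals = np.sort(logs[classes == lab])
        if vals.size == 0:
            continue
        ax.step(vals, np.arange(1, vals.size + 1) / vals.size, where="post", label=str(lab))
    ax.set_xlabel("log score")
    ax.set_ylabel("ECDF")
    ax.set_title(f"{report.scale}: score distributions by class")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(out_dir / f"ecdf_{report.scale}.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    deltas = sorted(report.ks_by_delta)
    ax.plot(deltas, [report.ks_by_delta[d] for d in deltas], "o-")
    ax.set_xlabel("class distance Δ")
    ax.set_ylabel("mean KS statistic")
    ax.set_title(f"{report.scale}: KS by class distance")
    fig.tight_layout()
    fig.savefig(out_dir / f"ks_by_delta_{report.scale}.png", dpi=150)
    plt.close(fig)
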