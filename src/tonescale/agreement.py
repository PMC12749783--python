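"""Reliability and comparison statistics, implemented from first principles.

Covers the agreement measures used to compare skin-tone raters and devices:

* linear-weighted Cohen's kappa for ordered categorical scales,
* ICC(2,1) — two-way random effects, absolute agreement, single measurement —
  for repeated continuous measurements (colorimeter triplicates, image ITA),
* the paired t-test for systematic rating shifts,
* Pearson's chi-squared test of independence,
* per-class and overall percent concordance of a confusion table.

Only distribution functions (t, chi-squared) come from scipy; the statistics
themselves are computed here so every convention (fixed category range for
kappa weights, degenerate-input flags) is explicit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import (
    DegenerateMarginals,
    ZeroExpected,
    ZeroVariance,
    ZeroVarianceDifferences,
)

__all__ = [
    "KappaResult",
    "IccResult",
    "PairedTestResult",
    "ChiSquaredResult",
    "ConcordanceResult",
    "linear_weighted_kappa",
    "icc_agreement",
    "paired_mean_difference",
    "chi_squared_independence",
    "concordance_by_class",
    "agreement_heatmap",
]


@dataclass(frozen=True)
class KappaResult:
    """Linear-weighted kappa with its sample size; NaN + flag when degenerate."""

    kappa: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class IccResult:
    """ICC(2,1) together with the ANOVA mean squares it derives from."""

    icc: float
    n_subjects: int
    n_repeats: int
    ms_rows: float
    ms_cols: float
    ms_error: float


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p_value: float
    n: int


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class ConcordanceResult:
    """Percent agreement per reference class (NaN for empty rows) and overall."""

    per_class: np.ndarray
    overall: float
    n: int


def _rating_arrays(a, b, k: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 rating pairs")
    if k < 2:
        raise ValueError("scale must have k >= 2 levels")
    for arr, name in ((a, "rating_a"), (b, "rating_b")):
        if arr.min() < 1 or arr.max() > k:
            raise ValueError(f"{name} outside [1, {k}]")
    return a, b


def linear_weighted_kappa(rating_a, rating_b, k: int) -> KappaResult:
    """Cohen's kappa with linear disagreement weights on a k-level scale.

    kappa = 1 - sum(w * O) / sum(w * E), with w[i, j] = |i - j| / (k - 1),
    O the observed joint proportions and E the chance proportions from the
    two raters' marginals. Weights span the *full* scale range 1..k even when
    some levels are unobserved, so values are comparable across strata.

    When both raters used one identical category throughout, chance
    agreement is total and kappa undefined; a flagged NaN result is returned
    (never a silent 0).
    """
    a, b = _rating_arrays(rating_a, rating_b, k)
    n = a.size
    observed = np.zeros((k, k))
    np.add.at(observed, (a - 1, b - 1), 1.0)
    observed /= n
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    idx = np.arange(k)
    weights = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    denom = float((weights * expected).sum())
    if denom == 0.0:
        return KappaResult(kappa=float("nan"), n=n, degenerate=True)
    return KappaResult(kappa=1.0 - float((weights * observed).sum()) / denom, n=n)


def icc_agreement(measurements) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``measurements`` is an (n subjects × m repeats) matrix with no missing
    cells. From the two-way ANOVA mean squares (rows = subjects, columns =
    repeats):

        ICC = (MSR - MSE) / (MSR + (m-1)·MSE + m·(MSC - MSE)/n)

    Raises :class:`ZeroVariance` when the between-subject mean square is 0.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D matrix")
    n, m = x.shape
    if n < 2 or m < 2:
        raise ValueError("need >= 2 subjects and >= 2 repeats")
    if np.isnan(x).any():
        raise ValueError("missing cells not allowed; drop incomplete subjects first")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = m * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (m - 1)
    mse = max(ss_err / ((n - 1) * (m - 1)), 0.0)
    if msr == 0.0:
        raise ZeroVariance("between-subject mean square is zero; ICC undefined")
    icc = (msr - mse) / (msr + (m - 1) * mse + m * (msc - mse) / n)
    return IccResult(
        icc=float(icc), n_subjects=n, n_repeats=m,
        ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
    )


def paired_mean_difference(x, y, confidence: float = 0.95) -> PairedTestResult:
    """Classical paired t-test on the differences y - x with a t-based CI.

    ``y == x`` exactly returns a zero difference with p = 1 by convention;
    a *constant nonzero* difference has an undefined t statistic and raises
    :class:`ZeroVarianceDifferences`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 2")
    d = y - x
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, 0.0, 0.0, n - 1, 1.0, n)
        raise ZeroVarianceDifferences("constant nonzero paired differences")
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * _stats.t.sf(abs(t), df)
    tcrit = _stats.t.ppf(0.5 + confidence / 2.0, df)
    return PairedTestResult(mean, mean - tcrit * se, mean + tcrit * se, t, df, float(p), n)


def chi_squared_independence(table) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on an r × c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("table must be a nonnegative 2-D count matrix")
    total = obs.sum()
    if total <= 0:
        raise ValueError("table total must be positive")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        raise ZeroExpected("a cell has zero expected count; collapse empty rows/columns")
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_stats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return ChiSquaredResult(stat, dof, p)


def concordance_by_class(table) -> ConcordanceResult:
    """Percent agreement of a k × k (reference × assigned) confusion table.

    Per-class = 100 · diagonal / row total (NaN for an empty reference row);
    overall = 100 · trace / grand total.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != obs.shape[1]:
        raise ValueError("confusion table must be square")
    if obs.min() < 0 or obs.sum() <= 0:
        raise ValueError("counts must be nonnegative with positive total")
    row_totals = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_totals > 0, 100.0 * np.diag(obs) / row_totals, np.nan)
    overall = 100.0 * float(np.trace(obs)) / float(obs.sum())
    return ConcordanceResult(per_class, overall, int(obs.sum()))


def agreement_heatmap(
    pairs: pd.DataFrame,
    rating_a: str,
    rating_b: str,
    k: int,
    site_col: str = "anatomic_site",
    kind_col: str = "site_kind",
) -> pd.DataFrame:
    """Per-anatomic-site weighted-kappa table plus lesional-only and all-site rows.

    ``pairs`` holds one row per rated site with both raters' values present.
    Groups with fewer than 2 pairs (or degenerate marginals) report NaN. The
    all-site row is the kappa of the *pooled* pairs, not a mean of per-site
    values.
    """
    rows: list[dict] = []

    def _kappa(df: pd.DataFrame) -> tuple[float, int]:
        if len(df) < 2:
            return float("nan"), len(df)
        res = linear_weighted_kappa(df[rating_a].to_numpy(), df[rating_b].to_numpy(), k)
        return (float("nan") if res.degenerate else res.kappa), res.n

    nonlesional = pairs[pairs[kind_col] == "nonlesional"] if kind_col in pairs else pairs
    for site, grp in sorted(nonlesional.groupby(site_col), key=lambda t: str(t[0])):
        kap, n = _kappa(grp)
        rows.append({"group": site, "kappa": kap, "n": n})
    if kind_col in pairs:
        lesional = pairs[pairs[kind_col] == "lesional"]
        if len(lesional):
            kap, n = _kappa(lesional)
            rows.append({"group": "lesional", "kappa": kap, "n": n})
    kap, n = _kappa(pairs)
    rows.append({"group": "all", "kappa": kap, "n": n})
    return pd.DataFrame(rows)
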