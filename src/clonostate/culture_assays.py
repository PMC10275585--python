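"""Bulk-culture and plate-assay statistics.

Fold expansion of timewise culture counts, percent specific cytotoxicity of
a release assay, paired t-tests on before/after marker intensities,
Spearman rank correlation (exact permutation p at small n), and the
median-collapse + row-scaling + double dendrogram preprocessing behind the
cytokine heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "CultureSeries",
    "CytotoxicityWell",
    "fold_expansion",
    "cohort_fold_expansion",
    "fold_expansion_from_raw",
    "specific_cytotoxicity",
    "paired_ttest",
    "spearman",
    "cytokine_heatmap_prep",
]


@dataclass
class CultureSeries:
    """Timewise calculated absolute γδ T-cell counts for one culture.

    Counts are split-adjusted ("calculated absolute" numbers assuming every
    cell had been kept in culture), so fold expansion is a plain ratio of
    final to initial count.
    """

    sample_id: str
    days: list[float]
    counts: list[float]
    reseed_fractions: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.counts):
            raise ValueError("days and counts must align")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class CytotoxicityWell:
    """Release-assay counts: sample, spontaneous (negative) and maximal
    (positive) release."""

    sample: float
    negative: float
    positive: float

    def __post_init__(self) -> None:
        if self.positive == self.negative:
            raise ValueError("positive and negative controls must differ")


def fold_expansion(series: CultureSeries) -> float:
    """Final / initial calculated count."""
    if len(series.counts) < 2:
        raise ValueError("need at least two timepoints")
    return series.counts[-1] / series.counts[0]


def fold_expansion_from_raw(series: CultureSeries) -> float:
    """Cumulative fold from raw (post-split) counts and reseed fractions:
    Π Nₜ₊₁ / (fₜ · Nₜ), where fₜ is the fraction reseeded after timepoint t."""
    if series.reseed_fractions is None:
        return fold_expansion(series)
    f = series.reseed_fractions
    if len(f) != len(series.counts) - 1:
        raise ValueError("need one reseed fraction per interval")
    fold = 1.0
    for i in range(len(series.counts) - 1):
        fold *= series.counts[i + 1] / (f[i] * series.counts[i])
    return fold


def cohort_fold_expansion(series_list: Sequence[CultureSeries]) -> dict:
    """Per-sample folds with cohort mean ± SEM (sample sd, n−1)."""
    folds = np.array([fold_expansion(s) for s in series_list])
    n = len(folds)
    sem = folds.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return {
        "folds": {s.sample_id: f for s, f in zip(series_list, folds)},
        "mean": float(folds.mean()),
        "sem": float(sem),
        "n": n,
    }


def specific_cytotoxicity(well: CytotoxicityWell) -> dict:
    """[(sample − negative) / (positive − negative)] × 100%.

    The raw percentage may fall outside [0, 100]; a clamped convenience
    value is reported alongside.
    """
    pct = (well.sample - well.negative) / (well.positive - well.negative) * 100.0
    return {"percent": float(pct), "percent_clamped": float(np.clip(pct, 0.0, 100.0))}


def paired_ttest(before: Sequence[float], after: Sequence[float]) -> dict:
    """Classical two-sided paired t-test on the differences.

    Degenerate cases: all-zero differences give t = 0, p = 1; zero-variance
    differences with nonzero mean give p = 0 with ``degenerate=True``.
    """
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired vectors of equal length n >= 2")
    d = b - a
    n = d.size
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "degenerate": False}
        return {"t": np.inf if d.mean() > 0 else -np.inf, "df": n - 1, "p": 0.0, "degenerate": True}
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "df": n - 1, "p": float(p), "degenerate": False}


#: exact permutation p for spearman at or below this n
_SPEARMAN_EXACT_N = 9


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    The p-value is a two-sided exact permutation p (all n! orderings of y)
    for n ≤ 9, and the t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need paired vectors of length n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _SPEARMAN_EXACT_N:
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc**2).sum())
        obs = abs(rho)
        count = total = 0
        for perm in permutations(ry):
            pr = np.asarray(perm)
            prc = pr - pr.mean()
            r = float(rxc @ prc / (denom * np.sqrt((prc**2).sum())))
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def cytokine_heatmap_prep(
    matrix: pd.DataFrame,
    subtype_map: Optional[dict[str, str]] = None,
) -> dict:
    """Preprocess a cytokines x samples panel for heatmap display.

    Steps: collapse samples to the per-subtype median (when ``subtype_map``
    maps sample columns to subtypes), center and unit-variance scale each
    cytokine row (sample sd), drop constant rows with a warning, and
    cluster both rows and columns with Euclidean distance and average
    linkage. Returns the scaled matrix and both leaf orders.
    """
    M = matrix.copy()
    if subtype_map is not None:
        M = M.T.groupby(pd.Series(subtype_map)).median().T
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns after collapse")
    sd = M.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        import warnings

        warnings.warn(f"dropping {int(constant.sum())} constant row(s) after collapse")
        M = M.loc[~constant]
        sd = sd.loc[~constant]
    scaled = M.sub(M.mean(axis=1), axis=0).div(sd, axis=0)

    def _cluster(A: np.ndarray, names) -> tuple[Optional[np.ndarray], list]:
        # a single surviving row/column has nothing to cluster
        if A.shape[0] < 2:
            return None, list(names)
        link = sch.linkage(pdist(A, metric="euclidean"), method="average")
        return link, [names[i] for i in sch.leaves_list(link)]

    row_link, row_order = _cluster(scaled.to_numpy(), scaled.index)
    col_link, col_order = _cluster(scaled.to_numpy().T, scaled.columns)
    return {
        "scaled": scaled,
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_link,
        "col_linkage": col_link,
    }
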