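"""Marker-gene detection and coexpression gene modules.

Marker genes are found by a Wilcoxon rank-sum test per gene (cluster versus
the rest, or pairwise between two named clusters), with exact enumeration
of the null on tiny groups, a midrank normal approximation with continuity
correction otherwise, and Benjamini-Hochberg correction within each
cluster. Marker genes are then grouped into coexpression modules by
hierarchical clustering of their per-cluster aggregated expression
(correlation distance, average linkage).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "benjamini_hochberg",
    "marker_genes",
    "aggregate_cluster_expression",
    "GeneModuleDetector",
    "detect_modules",
    "GeneModule",
]

#: exact enumeration when both group sizes are at or below this
EXACT_MAX_N = 10


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Returns (rank-sum statistic W of x, two-sided p). For group sizes both
    ≤ 10 the p-value is exact: every C(n, n_x) assignment of the pooled
    midranks is enumerated and p is the fraction of assignments at least as
    extreme (|W − E[W]|) as observed, which handles ties correctly. Larger
    groups use the normal approximation with tie-corrected variance and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    if max(n1, n2) <= EXACT_MAX_N:
        obs = abs(w - mu)
        count = 0
        total = comb(n, n1)
        for idx in combinations(range(n), n1):
            if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-12:
                count += 1
        return w, count / total
    # tie-corrected variance: Var(W) = n1 n2 / (n (n-1)) * (Σ r² − n(n+1)²/4)
    var = n1 * n2 / (n * (n - 1)) * (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    return w, float(2.0 * stats.norm.sf(max(z, 0.0)))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _group_stats(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    Xin, Xout = X[mask], X[~mask]
    return Xin.mean(axis=0), Xout.mean(axis=0), (Xin > 0).mean(axis=0), (Xout > 0).mean(axis=0)


def _vectorized_ranksum(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal-approximation rank-sum p per gene (columns of X)."""
    n1 = int(mask.sum())
    n2 = X.shape[0] - n1
    n = n1 + n2
    ranks = stats.rankdata(X, axis=0)
    w = ranks[mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / (n * (n - 1)) * ((ranks**2).sum(axis=0) - n * (n + 1) ** 2 / 4.0)
    z = np.zeros_like(w)
    ok = var > 0
    z[ok] = (np.abs(w[ok] - mu) - 0.5) / np.sqrt(var[ok])
    p = np.ones_like(w)
    p[ok] = 2.0 * stats.norm.sf(np.maximum(z[ok], 0.0))
    return w, np.minimum(p, 1.0)


def marker_genes(
    log_norm_expr,
    labels,
    min_fc: float = 0.25,
    alpha: float = 0.05,
    min_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-cluster marker genes by Wilcoxon rank-sum (cluster vs rest, or
    the single pairwise contrast when exactly two labels are given).

    Returns one row per (cluster, gene) passing the filters, with columns
    ``log2_fc`` (difference of mean log-normalized expression on the log2
    scale), ``statistic``, ``pval``, ``padj`` (BH within cluster),
    ``frac_in``, ``frac_out``. Rows need ``padj ≤ alpha``,
    ``log2_fc ≥ min_fc`` and ``frac_in ≥ min_frac``. Singleton clusters are
    skipped with a warning. Exact p-values are used when both group sizes
    are ≤ 10.
    """
    X = log_norm_expr if isinstance(log_norm_expr, pd.DataFrame) else pd.DataFrame(np.asarray(log_norm_expr))
    labels = pd.Series(np.asarray(labels), index=X.index)
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("need at least two cluster labels")
    Xv = X.to_numpy(dtype=float)
    genes = X.columns
    rows = []
    targets = [uniq[0]] if len(uniq) == 2 else list(uniq)
    for cluster in targets:
        mask = (labels == cluster).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            import warnings

            warnings.warn(f"cluster {cluster!r} skipped: fewer than 2 cells per side")
            continue
        mean_in, mean_out, frac_in, frac_out = _group_stats(Xv, mask)
        lfc = (mean_in - mean_out) / np.log(2.0)
        if max(int(mask.sum()), int((~mask).sum())) <= EXACT_MAX_N:
            stat = np.empty(len(genes))
            pval = np.empty(len(genes))
            for j in range(len(genes)):
                stat[j], pval[j] = rank_sum_test(Xv[mask, j], Xv[~mask, j])
        else:
            stat, pval = _vectorized_ranksum(Xv, mask)
        padj = benjamini_hochberg(pval)
        keep = (padj <= alpha) & (lfc >= min_fc) & (frac_in >= min_frac)
        for j in np.flatnonzero(keep):
            rows.append(
                (cluster, genes[j], lfc[j], stat[j], pval[j], padj[j], frac_in[j], frac_out[j])
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "gene", "log2_fc", "statistic", "pval", "padj", "frac_in", "frac_out"],
    )


def aggregate_cluster_expression(log_norm_expr, labels) -> pd.DataFrame:
    """Cluster x gene matrix of per-cluster mean z-scored expression.

    Genes are z-scored across cells before averaging within clusters; with a
    single cluster the raw per-gene means are returned instead.
    """
    X = log_norm_expr if isinstance(log_norm_expr, pd.DataFrame) else pd.DataFrame(np.asarray(log_norm_expr))
    labels = pd.Series(np.asarray(labels), index=X.index)
    if labels.nunique() == 1:
        return X.groupby(labels, observed=True).mean()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = (X - mu) / sd
    return Z.groupby(labels, observed=True).mean()


@dataclass
class GeneModule:
    """A coexpression module: member genes and per-cluster mean activity."""

    module_id: int
    genes: list[str]
    activity: pd.Series


class GeneModuleDetector(BaseEstimator, ClusterMixin):
    """Group genes into k coexpression modules (sklearn-style clusterer).

    ``fit`` takes a cluster x gene activity matrix, computes the
    correlation distance (1 − Pearson across clusters) between genes, runs
    average-linkage hierarchical clustering and cuts the tree into
    ``n_modules``. Genes are processed in sorted-name order, making the
    result invariant to the input column order; constant genes get maximal
    distance (their correlation is undefined).
    """

    def __init__(self, n_modules: int = 12):
        self.n_modules = n_modules

    def fit(self, X: pd.DataFrame, y=None) -> "GeneModuleDetector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.n_modules > X.shape[1]:
            raise ValueError("n_modules exceeds the number of genes")
        order = sorted(X.columns)
        M = X[order].to_numpy(dtype=float).T  # genes x clusters
        sd = M.std(axis=1)
        centered = M - M.mean(axis=1, keepdims=True)
        denom = np.outer(sd, sd) * M.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = centered @ centered.T / denom
        corr[~np.isfinite(corr)] = 0.0  # constant genes: correlation undefined
        np.fill_diagonal(corr, 1.0)
        dist = 1.0 - corr
        condensed = dist[np.triu_indices_from(dist, k=1)]
        condensed = np.maximum(condensed, 0.0)
        if self.n_modules == len(order):
            labels = np.arange(1, len(order) + 1)
        else:
            Z = sch.linkage(condensed, method="average")
            labels = sch.fcluster(Z, t=self.n_modules, criterion="maxclust")
            self.linkage_ = Z
        self.gene_order_ = order
        self.labels_ = pd.Series(labels, index=order, name="module")
        self.modules_ = [
            GeneModule(
                module_id=int(m),
                genes=[g for g in order if self.labels_[g] == m],
                activity=X[[g for g in order if self.labels_[g] == m]].mean(axis=1),
            )
            for m in sorted(set(labels))
        ]
        return self

    def activity_matrix(self) -> pd.DataFrame:
        """Clusters x modules matrix of mean member-gene activity."""
        return pd.DataFrame({f"GM{m.module_id}": m.activity for m in self.modules_})


def detect_modules(activity: pd.DataFrame, k: int = 12) -> list[GeneModule]:
    """Functional wrapper over :class:`GeneModuleDetector`."""
    return GeneModuleDetector(n_modules=k).fit(activity).modules_
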