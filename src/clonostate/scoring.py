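"""Per-cell and per-cluster scoring of gene signatures and phenotypes.

Implements the scoring toolbox used to characterize expansion-culture cell
states:

* control-matched signature ("module") scores — mean expression over the
  signature genes minus the mean over random control genes drawn from the
  same average-expression bin;
* an innateness score — mean z-scored expression over innateness-associated
  genes minus the mean over adaptiveness-associated genes;
* the GZMA/GZMB log-ratio with lo/mo/hi categories;
* cell-cycle phase calls from S and G2-M signature scores;
* CD45RA/CD27 memory-phenotype gating with Gaussian-mixture thresholds;
* a decision-list annotator mapping cluster score profiles to named cell
  states (early differentiating, TRM precursor-like, APC-like, TRM
  precursor CTL, early exhaustive CTL).

The transform-shaped pieces are exposed as sklearn-style estimators
(:class:`SignatureScorer`, :class:`MemoryGate`,
:class:`ClusterStateAnnotator`) with thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

__all__ = [
    "GeneSignature",
    "ModuleScoreParams",
    "InnatenessReference",
    "SignatureScorer",
    "module_score",
    "innateness_score",
    "gzm_ratio",
    "group_gzm_ratio",
    "gzm_categories",
    "cell_cycle_phase",
    "memory_gate",
    "MemoryGate",
    "StateRules",
    "cluster_profiles",
    "assign_state",
    "ClusterStateAnnotator",
    "map_clusters_to_signatures",
    "read_signatures",
    "write_signatures",
]

D14_STATES = [
    "EarlyDifferentiating",
    "TRMPrecursorLike",
    "APCLike",
    "TRMPrecursorCTL",
    "EarlyExhaustiveCTL",
]
D0_STATES = ["AdaptiveLike", "InnateLike", "ActivationPrimedInnate"]


@dataclass
class GeneSignature:
    """A named gene set; optionally paired with a down-regulated set."""

    name: str
    genes: list[str]
    down_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes and not self.down_genes:
            raise ValueError(f"signature {self.name!r} is empty")
        self.genes = list(dict.fromkeys(self.genes))
        self.down_genes = list(dict.fromkeys(self.down_genes))


@dataclass
class ModuleScoreParams:
    """Control-gene sampling parameters for signature scoring."""

    n_bins: int = 25
    n_ctrl: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValueError("n_bins and n_ctrl must be >= 1")


@dataclass
class InnatenessReference:
    """Innateness/adaptiveness gene sets plus reference-population quartiles
    (CD4, CD8, iNKT, MAIT, NK) carried along for display."""

    up_set: list[str]
    down_set: list[str]
    reference_scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if set(self.up_set) & set(self.down_set):
            raise ValueError("up_set and down_set must be disjoint")


def _as_frame(expr) -> pd.DataFrame:
    if isinstance(expr, pd.DataFrame):
        return expr
    return pd.DataFrame(np.asarray(expr))


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Control-matched signature scoring (sklearn transformer).

    ``fit`` bins genes by average expression across cells and draws, per
    signature gene, ``n_ctrl`` control genes from the gene's bin (signature
    genes excluded; a gene whose bin holds no other candidates acts as its
    own control, so a signature covering every gene scores exactly 0).
    ``transform`` returns one score column per signature: per cell, the mean
    expression over signature genes minus the mean of the per-gene control
    averages. Deterministic under ``seed``.
    """

    def __init__(
        self,
        signatures: Sequence[GeneSignature] = (),
        n_bins: int = 25,
        n_ctrl: int = 50,
        seed: int = 0,
        gene_bins: Optional[Mapping[str, int]] = None,
    ):
        self.signatures = signatures
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.seed = seed
        self.gene_bins = gene_bins

    def fit(self, X, y=None) -> "SignatureScorer":
        X = _as_frame(X)
        genes = X.columns
        if self.gene_bins is not None:
            bins = pd.Series({g: self.gene_bins[g] for g in genes})
        else:
            mean_expr = X.mean(axis=0)
            rank = mean_expr.rank(method="min")
            bins = pd.cut(rank, bins=min(self.n_bins, len(genes)), labels=False)
        self.bins_ = pd.Series(np.asarray(bins), index=genes)
        rng = np.random.default_rng(self.seed)
        self.controls_: dict[str, dict[str, list[str]]] = {}
        self.used_genes_: dict[str, list[str]] = {}
        for sig in self.signatures:
            present = [g for g in sig.genes if g in genes]
            missing = set(sig.genes) - set(present)
            if missing:
                warnings.warn(
                    f"signature {sig.name!r}: {len(missing)} gene(s) absent, dropped"
                )
            if not present:
                raise ValueError(f"all genes of signature {sig.name!r} absent from matrix")
            sig_set = set(present)
            per_gene: dict[str, list[str]] = {}
            for g in present:
                candidates = [
                    c for c in genes[self.bins_.values == self.bins_[g]] if c not in sig_set
                ]
                if not candidates:
                    per_gene[g] = [g]  # own control: contribution cancels
                    continue
                k = min(self.n_ctrl, len(candidates))
                per_gene[g] = list(rng.choice(candidates, size=k, replace=False))
            self.controls_[sig.name] = per_gene
            self.used_genes_[sig.name] = present
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        out = {}
        for sig in self.signatures:
            present = self.used_genes_[sig.name]
            sig_mean = X[present].mean(axis=1)
            ctrl = np.zeros(len(X))
            for g in present:
                ctrl += X[self.controls_[sig.name][g]].mean(axis=1).to_numpy()
            ctrl /= len(present)
            out[sig.name] = sig_mean.to_numpy() - ctrl
        return pd.DataFrame(out, index=X.index)


def module_score(
    log_norm_expr,
    sig: GeneSignature,
    params: ModuleScoreParams | None = None,
    gene_bins: Optional[Mapping[str, int]] = None,
) -> pd.Series:
    """Per-cell control-matched score of one signature (see
    :class:`SignatureScorer`)."""
    params = params or ModuleScoreParams()
    scorer = SignatureScorer(
        signatures=[sig],
        n_bins=params.n_bins,
        n_ctrl=params.n_ctrl,
        seed=params.seed,
        gene_bins=gene_bins,
    ).fit(log_norm_expr)
    return scorer.transform(log_norm_expr)[sig.name]


def _zscore(X: pd.DataFrame) -> pd.DataFrame:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (X - mu) / sd


def innateness_score(log_norm_expr, ref: InnatenessReference) -> pd.Series:
    """Innateness score: mean per-gene z-scored expression over the
    innateness-associated set minus the mean over the adaptiveness set."""
    X = _as_frame(log_norm_expr)
    up = [g for g in ref.up_set if g in X.columns]
    down = [g for g in ref.down_set if g in X.columns]
    if not up or not down:
        raise ValueError("innateness reference sets not represented in the matrix")
    Z = _zscore(X[up + down])
    return Z[up].mean(axis=1) - Z[down].mean(axis=1)


def gzm_ratio(
    norm_expr,
    pseudocount: float = 1.0,
    gene_a: str = "GZMA",
    gene_b: str = "GZMB",
) -> pd.Series:
    """Per-cell log2((GZMA + pc) / (GZMB + pc)) on normalized counts."""
    X = _as_frame(norm_expr)
    for g in (gene_a, gene_b):
        if g not in X.columns:
            raise ValueError(f"{g} absent from the gene universe")
    return pd.Series(
        np.log2((X[gene_a] + pseudocount) / (X[gene_b] + pseudocount)),
        index=X.index,
        name="gzm_log2_ratio",
    )


def group_gzm_ratio(
    norm_expr,
    labels,
    pseudocount: float = 1.0,
    gene_a: str = "GZMA",
    gene_b: str = "GZMB",
) -> pd.Series:
    """Per-group log2 ratio of group-mean GZMA to group-mean GZMB."""
    X = _as_frame(norm_expr)
    for g in (gene_a, gene_b):
        if g not in X.columns:
            raise ValueError(f"{g} absent from the gene universe")
    labels = pd.Series(np.asarray(labels), index=X.index)
    means = X[[gene_a, gene_b]].groupby(labels, observed=True).mean()
    return np.log2((means[gene_a] + pseudocount) / (means[gene_b] + pseudocount))


def gzm_categories(group_ratios: pd.Series, cutoffs: Optional[tuple[float, float]] = None) -> pd.Series:
    """lo/mo/hi categories of per-group log ratios; tertiles by default,
    numeric cutoffs overridable."""
    if cutoffs is None:
        lo, hi = np.quantile(group_ratios, [1 / 3, 2 / 3])
    else:
        lo, hi = cutoffs
    def cat(v: float) -> str:
        if v <= lo:
            return "lo"
        if v <= hi:
            return "mo"
        return "hi"
    return group_ratios.map(cat)


def cell_cycle_phase(s_score, g2m_score) -> np.ndarray:
    """Phase call from S and G2-M signature scores: G1 when both are ≤ 0,
    else the phase of the larger score; ties resolve to G2M."""
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    phase = np.where((s <= 0) & (g <= 0), "G1", np.where(s > g, "S", "G2M"))
    return phase


def memory_gate(cd45ra, cd27) -> np.ndarray:
    """CD45RA/CD27 quadrant gate: CD27− → T_E regardless of CD45RA;
    CD27+ splits into T_N (CD45RA+) and T_CM (CD45RA−)."""
    ra = np.asarray(cd45ra, dtype=bool)
    c27 = np.asarray(cd27, dtype=bool)
    return np.where(~c27, "T_E", np.where(ra, "T_N", "T_CM"))


class MemoryGate(BaseEstimator):
    """Memory-phenotype gate with per-marker thresholds.

    ``fit`` learns one threshold per marker by a 2-component 1-D Gaussian
    mixture on log intensities (the posterior crossover between the two
    component means); manual thresholds override. ``predict`` applies the
    CD45RA/CD27 quadrant gate.
    """

    def __init__(self, thresholds: Optional[Mapping[str, float]] = None, seed: int = 0):
        self.thresholds = thresholds
        self.seed = seed

    def fit(self, protein: pd.DataFrame, y=None) -> "MemoryGate":
        self.thresholds_ = dict(self.thresholds or {})
        for marker in protein.columns:
            if marker in self.thresholds_:
                continue
            logx = np.log(protein[marker].to_numpy() + 1e-6).reshape(-1, 1)
            gm = GaussianMixture(n_components=2, random_state=self.seed).fit(logx)
            means = np.sort(gm.means_.ravel())
            grid = np.linspace(means[0], means[1], 512).reshape(-1, 1)
            post = gm.predict_proba(grid)
            hi_comp = int(np.argmax(gm.means_.ravel()))
            cross = int(np.argmax(post[:, hi_comp] >= 0.5))
            self.thresholds_[marker] = float(np.exp(grid[cross, 0]))
        return self

    def predict(self, protein: pd.DataFrame) -> np.ndarray:
        ra = protein["CD45RA"].to_numpy() > self.thresholds_["CD45RA"]
        c27 = protein["CD27"].to_numpy() > self.thresholds_["CD27"]
        return memory_gate(ra, c27)

    def fractions(self, protein: pd.DataFrame) -> pd.Series:
        calls = pd.Series(self.predict(protein))
        return calls.value_counts(normalize=True).reindex(["T_N", "T_CM", "T_E"], fill_value=0.0)


@dataclass
class StateRules:
    """Thresholds of the cluster-state decision list. Values are on the
    z-score / module-score scale; 0 means "above the cross-cluster average"."""

    marker_high: float = 0.0
    marker_low: float = 0.0
    score_high: float = 0.0
    gzm_low: float = 0.0
    required = (
        "ccr7_z",
        "znf683_z",
        "klrg1_z",
        "antigen_presentation",
        "exhaustion",
        "tilneo",
        "gzm_log_ratio",
    )


def cluster_profiles(
    log_norm_expr,
    labels,
    signatures: Mapping[str, GeneSignature],
    params: ModuleScoreParams | None = None,
) -> pd.DataFrame:
    """Per-cluster score/marker profile table feeding :func:`assign_state`.

    ``signatures`` must provide ``antigen_presentation``, ``exhaustion`` and
    ``tilneo`` gene sets. Columns: mean module score per signature, mean
    z-scored expression of CCR7/ZNF683/KLRG1, and the per-cluster
    GZMA/GZMB log-ratio.
    """
    X = _as_frame(log_norm_expr)
    labels = pd.Series(np.asarray(labels), index=X.index, name="cluster")
    params = params or ModuleScoreParams()
    needed = ["antigen_presentation", "exhaustion", "tilneo"]
    missing = [s for s in needed if s not in signatures]
    if missing:
        raise ValueError(f"missing rule signatures: {missing}")
    scorer = SignatureScorer(
        signatures=[signatures[s] for s in needed],
        n_bins=params.n_bins,
        n_ctrl=params.n_ctrl,
        seed=params.seed,
    ).fit(X)
    scores = scorer.transform(X)
    prof = scores.groupby(labels, observed=True).mean()
    for marker, col in (("CCR7", "ccr7_z"), ("ZNF683", "znf683_z"), ("KLRG1", "klrg1_z")):
        if marker not in X.columns:
            raise ValueError(f"rule marker {marker!r} absent from the matrix")
        z = _zscore(X[[marker]])[marker]
        prof[col] = z.groupby(labels, observed=True).mean()
    prof["gzm_log_ratio"] = group_gzm_ratio(np.expm1(X), labels)
    return prof


def assign_state(profiles: pd.DataFrame, rules: StateRules | None = None) -> pd.Series:
    """Map per-cluster profiles to cell-state labels by a fixed decision
    list: APC-like, then early exhaustive CTL, then TRM precursor CTL, then
    TRM precursor-like, with early differentiating as the fallthrough."""
    rules = rules or StateRules()
    missing = [c for c in rules.required if c not in profiles.columns]
    if missing:
        raise ValueError(f"profile table missing rule columns: {missing}")
    out = {}
    for cluster, row in profiles.iterrows():
        if row["ccr7_z"] > rules.marker_high and row["antigen_presentation"] > rules.score_high:
            out[cluster] = "APCLike"
        elif row["exhaustion"] > rules.score_high and row["gzm_log_ratio"] < rules.gzm_low:
            out[cluster] = "EarlyExhaustiveCTL"
        elif (
            row["znf683_z"] > rules.marker_high
            and row["klrg1_z"] < rules.marker_low
            and row["tilneo"] > rules.score_high
        ):
            out[cluster] = "TRMPrecursorCTL"
        elif row["znf683_z"] > rules.marker_high and row["klrg1_z"] < rules.marker_low:
            out[cluster] = "TRMPrecursorLike"
        else:
            out[cluster] = "EarlyDifferentiating"
    return pd.Series(out, name="state")


class ClusterStateAnnotator(BaseEstimator):
    """Annotate clusters with cell states (sklearn-style).

    ``fit(X, labels)`` computes cluster profiles and applies the decision
    list; ``predict(labels)`` maps cluster labels to the fitted states.
    """

    def __init__(
        self,
        signatures: Optional[Mapping[str, GeneSignature]] = None,
        rules: Optional[StateRules] = None,
        n_bins: int = 25,
        n_ctrl: int = 50,
        seed: int = 0,
    ):
        self.signatures = signatures
        self.rules = rules
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.seed = seed

    def fit(self, X, labels) -> "ClusterStateAnnotator":
        params = ModuleScoreParams(n_bins=self.n_bins, n_ctrl=self.n_ctrl, seed=self.seed)
        self.profiles_ = cluster_profiles(X, labels, self.signatures, params)
        self.cluster_states_ = assign_state(self.profiles_, self.rules)
        return self

    def predict(self, labels) -> np.ndarray:
        return pd.Series(np.asarray(labels)).map(self.cluster_states_).to_numpy()


def map_clusters_to_signatures(
    log_norm_expr,
    labels,
    state_signatures: Mapping[str, GeneSignature],
    params: ModuleScoreParams | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Score query clusters against state signatures and assign each cluster
    the best-matching state (argmax of the mean module score); the full
    cluster x signature similarity matrix is returned alongside."""
    if not state_signatures:
        raise ValueError("need at least one state signature")
    X = _as_frame(log_norm_expr)
    labels = pd.Series(np.asarray(labels), index=X.index)
    params = params or ModuleScoreParams()
    scorer = SignatureScorer(
        signatures=list(state_signatures.values()),
        n_bins=params.n_bins,
        n_ctrl=params.n_ctrl,
        seed=params.seed,
    ).fit(X)
    scores = scorer.transform(X)
    matrix = scores.groupby(labels, observed=True).mean()
    assignment = matrix.idxmax(axis=1)
    assignment.name = "best_state"
    return assignment, matrix


def read_signatures(path) -> dict[str, list[str]]:
    """Read a two-column (set_name, gene) TSV into named gene lists."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["set_name", "gene"])
    return {name: grp["gene"].tolist() for name, grp in df.groupby("set_name", sort=False)}


def write_signatures(sets: Mapping[str, Sequence[str]], path) -> None:
    rows = [(name, g) for name, genes in sets.items() for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
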