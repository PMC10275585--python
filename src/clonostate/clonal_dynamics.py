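"""Per-clone differentiation bias: joining clones with cell-state labels.

Quantifies, for every clone, its composition over grouped cell states
(TRM precursor-like, APC-like, CTL = TRM precursor CTL + early exhaustive
CTL, other), the pseudocounted APC:CTL ratio, and a three-way bias call;
summarises bias per clonotype class and size class; and tabulates
clonotype-class enrichment per cell cluster under both normalizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .repertoire import CloneRecord, partition_by_size

__all__ = [
    "CloneBiasRecord",
    "DEFAULT_STATE_GROUPS",
    "clone_state_composition",
    "apc_ctl_ratio",
    "classify_bias",
    "clone_bias_table",
    "subtype_bias_summary",
    "cluster_clonotype_enrichment",
    "ctl_bias_proportion_test",
]

#: mapping from annotated cell states to the three-way composition groups
DEFAULT_STATE_GROUPS: dict[str, str] = {
    "TRMPrecursorLike": "TRM",
    "APCLike": "APC",
    "TRMPrecursorCTL": "CTL",
    "EarlyExhaustiveCTL": "CTL",
}

GROUP_ORDER = ["TRM", "APC", "CTL", "other"]


@dataclass
class CloneBiasRecord:
    """Per-clone state composition, APC:CTL ratio and bias call."""

    clonotype_key: str
    class_name: str
    size: int
    fractions: dict[str, float]
    counts: dict[str, int]
    apc_ctl_ratio: float
    bias: str


def _state_counts(
    clone: CloneRecord,
    cell_states: pd.Series,
    state_groups: Mapping[str, str],
) -> dict[str, int]:
    counts = dict.fromkeys(GROUP_ORDER, 0)
    for cid in clone.cell_ids:
        if cid not in cell_states.index or pd.isna(cell_states[cid]):
            raise ValueError(f"cell {cid!r} of clone {clone.clonotype_key!r} has no state label")
        group = state_groups.get(str(cell_states[cid]), "other")
        counts[group] += 1
    return counts


def clone_state_composition(
    clones: Sequence[CloneRecord],
    cell_states: pd.Series,
    state_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-clone fraction vectors over the grouped states (rows sum to 1)."""
    state_groups = state_groups or DEFAULT_STATE_GROUPS
    rows = {}
    for clone in clones:
        counts = _state_counts(clone, cell_states, state_groups)
        total = sum(counts.values())
        rows[clone.clonotype_key] = {g: counts[g] / total for g in GROUP_ORDER}
    return pd.DataFrame.from_dict(rows, orient="index")[GROUP_ORDER]


def apc_ctl_ratio(n_apc: int, n_ctl: int, pseudocount: float = 0.5) -> float:
    """(n_APC + pc) / (n_CTL + pc) — Haldane-Anscombe pseudocount keeps the
    ratio finite and positive when either count is zero."""
    return (n_apc + pseudocount) / (n_ctl + pseudocount)


def classify_bias(ratio: float) -> str:
    """CTL_bias below 1, APC_bias above 1, balanced at exactly 1."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio < 1:
        return "CTL_bias"
    if ratio > 1:
        return "APC_bias"
    return "balanced"


def clone_bias_table(
    clones: Sequence[CloneRecord],
    cell_states: pd.Series,
    state_groups: Mapping[str, str] | None = None,
    pseudocount: float = 0.5,
    min_size: int = 3,
) -> list[CloneBiasRecord]:
    """Build per-clone bias records for clones of at least ``min_size`` cells
    (the per-clone ratio is noisy below a few cells; the floor is
    configurable)."""
    state_groups = state_groups or DEFAULT_STATE_GROUPS
    records = []
    for clone in clones:
        if clone.size < min_size:
            continue
        counts = _state_counts(clone, cell_states, state_groups)
        total = sum(counts.values())
        ratio = apc_ctl_ratio(counts["APC"], counts["CTL"], pseudocount)
        records.append(
            CloneBiasRecord(
                clonotype_key=clone.clonotype_key,
                class_name=clone.class_name,
                size=clone.size,
                fractions={g: counts[g] / total for g in GROUP_ORDER},
                counts=counts,
                apc_ctl_ratio=ratio,
                bias=classify_bias(ratio),
            )
        )
    return records


def subtype_bias_summary(
    records: Sequence[CloneBiasRecord],
    size_threshold: int = 10,
) -> pd.DataFrame:
    """Per clonotype class x size class (large / small / all): number of
    clones, % CTL-bias, % APC-bias, and the geometric mean APC:CTL ratio
    (over pseudocounted ratios). Empty cells are omitted."""
    rows = []
    classes = sorted({r.class_name for r in records})
    for cls in classes:
        cls_records = [r for r in records if r.class_name == cls]
        groups = {
            "all": cls_records,
            "large": [r for r in cls_records if r.size > size_threshold],
            "small": [r for r in cls_records if r.size <= size_threshold],
        }
        for size_class, grp in groups.items():
            if not grp:
                continue
            ratios = np.array([r.apc_ctl_ratio for r in grp])
            rows.append(
                {
                    "class": cls,
                    "size_class": size_class,
                    "n_clones": len(grp),
                    "pct_ctl_bias": 100.0 * np.mean([r.bias == "CTL_bias" for r in grp]),
                    "pct_apc_bias": 100.0 * np.mean([r.bias == "APC_bias" for r in grp]),
                    "geom_mean_ratio": float(np.exp(np.mean(np.log(ratios)))),
                }
            )
    return pd.DataFrame(rows)


def cluster_clonotype_enrichment(
    cell_classes: pd.Series,
    cell_clusters: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class x cluster percentage matrices under both normalizations.

    Returns ``(within_class, within_cluster)``: the first normalizes each
    clonotype class across clusters (rows sum to 100), the second each
    cluster across classes (columns sum to 100).
    """
    counts = pd.crosstab(cell_classes, cell_clusters)
    within_class = counts.div(counts.sum(axis=1), axis=0) * 100.0
    within_cluster = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return within_class, within_cluster


def ctl_bias_proportion_test(
    records_a: Sequence[CloneBiasRecord],
    records_b: Sequence[CloneBiasRecord],
) -> tuple[float, float]:
    """Two-sided two-proportion z-test comparing the fraction of CTL-bias
    clones between two groups of clones. Returns (z, p)."""
    from statsmodels.stats.proportion import proportions_ztest

    counts = np.array(
        [sum(r.bias == "CTL_bias" for r in records_a), sum(r.bias == "CTL_bias" for r in records_b)]
    )
    nobs = np.array([len(records_a), len(records_b)])
    if (nobs == 0).any():
        raise ValueError("both clone groups must be non-empty")
    z, p = proportions_ztest(counts, nobs, alternative="two-sided")
    return float(z), float(p)
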