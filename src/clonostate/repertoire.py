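"""Clonotype classification and clonal-expansion statistics for γδ TCRs.

Parses paired TRG/TRD chain calls from an AIRR rearrangement table, groups
cells into clones keyed on the amino-acid junctions of both chains, classes
each clonotype by its variable-segment usage (Vδ1 / Vδ2 / Vδ3 and Vγ9
status), and computes the descriptive statistics of clonal focusing: the
Gini coefficient of clone sizes, the cell fraction in the top-N clones, the
large/small clone-size partition, and the strong/weak classification of
single-clone expansion cultures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellClonotype",
    "CloneRecord",
    "strip_allele",
    "classify_clonotype",
    "classify_cells",
    "build_clones",
    "clone_table",
    "partition_by_size",
    "gini",
    "top_n_cell_fraction",
    "small_clone_cell_fraction",
    "classify_expansion",
    "expansion_summary",
]

_ALLELE_RE = re.compile(r"\*.*$")


def strip_allele(segment: str) -> str:
    """Drop the allele suffix of a gene-segment call (``TRGV9*01`` → ``TRGV9``)."""
    return _ALLELE_RE.sub("", segment.strip())


@dataclass
class CellClonotype:
    """Per-cell clonotype call derived from its productive chains."""

    cell_id: str
    delta_v: str  # Vd1 / Vd2 / Vd3 / other / missing
    gamma_v9: str  # pos / neg / missing
    gamma_j: Optional[str]
    clonotype_key: str
    class_name: str
    is_public_Vg9JgP_Vd2: bool
    partially_paired: bool
    ambiguous: bool


@dataclass
class CloneRecord:
    """A clone: the set of cells sharing one clonotype key."""

    clonotype_key: str
    cell_ids: set = field(default_factory=set)
    size: int = 0
    class_name: str = "other"
    is_public_Vg9JgP_Vd2: bool = False
    partially_paired: bool = False


def _delta_class(v_call: Optional[str]) -> str:
    if v_call is None:
        return "missing"
    v = strip_allele(v_call)
    if v == "TRDV1":
        return "Vd1"
    if v == "TRDV2":
        return "Vd2"
    if v == "TRDV3":
        return "Vd3"
    return "other"


def _pick_chain(rows: pd.DataFrame) -> tuple[pd.Series, bool]:
    """Pick one chain per locus: highest read support when a
    ``duplicate_count`` column is present, else lexicographically smallest
    v_call. Returns (row, had_conflict)."""
    if len(rows) == 1:
        return rows.iloc[0], False
    if "duplicate_count" in rows.columns and rows["duplicate_count"].notna().all():
        order = rows.sort_values(["duplicate_count", "v_call"], ascending=[False, True])
    else:
        order = rows.sort_values("v_call")
    return order.iloc[0], True


def classify_clonotype(chains: pd.DataFrame) -> CellClonotype:
    """Classify one cell's productive chains into a clonotype call.

    ``chains``: AIRR rows of a single cell. Unproductive rows are ignored;
    at least one productive chain is required. The clonotype key combines
    the (v_call, j_call, junction_aa) of each available locus; cells missing
    a locus are keyed on the available one and flagged ``partially_paired``.
    Unknown segments map to class ``other``, never an exception.
    """
    productive = chains[_productive_mask(chains)]
    if productive.empty:
        raise ValueError("cell has no productive chain")
    cell_id = str(productive["cell_id"].iloc[0])

    trd = productive[productive["locus"] == "TRD"]
    trg = productive[productive["locus"] == "TRG"]
    ambiguous = False
    d_row = g_row = None
    if len(trd):
        d_row, conflict = _pick_chain(trd)
        ambiguous |= conflict
    if len(trg):
        g_row, conflict = _pick_chain(trg)
        ambiguous |= conflict

    delta_v = _delta_class(d_row["v_call"] if d_row is not None else None)
    if g_row is None:
        gamma_v9, gamma_j = "missing", None
    else:
        gamma_v9 = "pos" if strip_allele(str(g_row["v_call"])) == "TRGV9" else "neg"
        gamma_j = strip_allele(str(g_row["j_call"]))

    parts = []
    for locus, row in (("TRD", d_row), ("TRG", g_row)):
        if row is not None:
            parts.append(
                f"{locus}:{strip_allele(str(row['v_call']))}|{strip_allele(str(row['j_call']))}|{row['junction_aa']}"
            )
    key = ";".join(parts)

    if delta_v == "Vd2":
        class_name = "Vg9posVd2" if gamma_v9 == "pos" else "Vg9negVd2"
    elif delta_v in ("Vd1", "Vd3"):
        class_name = delta_v
    else:
        class_name = "other"
    is_public = delta_v == "Vd2" and gamma_v9 == "pos" and gamma_j == "TRGJP"

    return CellClonotype(
        cell_id=cell_id,
        delta_v=delta_v,
        gamma_v9=gamma_v9,
        gamma_j=gamma_j,
        clonotype_key=key,
        class_name=class_name,
        is_public_Vg9JgP_Vd2=is_public,
        partially_paired=(d_row is None or g_row is None),
        ambiguous=ambiguous,
    )


def _productive_mask(chains: pd.DataFrame) -> pd.Series:
    prod = chains["productive"]
    if prod.dtype == bool:
        return prod
    return prod.astype(str).str.upper().isin(["T", "TRUE", "1"])


def classify_cells(airr: pd.DataFrame) -> list[CellClonotype]:
    """Classify every cell in an AIRR table that has ≥1 productive chain."""
    productive = airr[_productive_mask(airr)]
    return [classify_clonotype(rows) for _, rows in productive.groupby("cell_id", sort=True)]


def build_clones(cells: Iterable[CellClonotype]) -> list[CloneRecord]:
    """Group classified cells by clonotype key into clones.

    The sum of clone sizes equals the number of keyed cells.
    """
    clones: dict[str, CloneRecord] = {}
    for cell in cells:
        rec = clones.get(cell.clonotype_key)
        if rec is None:
            rec = CloneRecord(
                clonotype_key=cell.clonotype_key,
                class_name=cell.class_name,
                is_public_Vg9JgP_Vd2=cell.is_public_Vg9JgP_Vd2,
                partially_paired=cell.partially_paired,
            )
            clones[cell.clonotype_key] = rec
        rec.cell_ids.add(cell.cell_id)
        rec.size = len(rec.cell_ids)
    return [clones[k] for k in sorted(clones)]


def clone_table(clones: Sequence[CloneRecord]) -> pd.DataFrame:
    """Clone table as a DataFrame (one row per clone)."""
    return pd.DataFrame(
        {
            "clonotype_key": [c.clonotype_key for c in clones],
            "class": [c.class_name for c in clones],
            "size": [c.size for c in clones],
            "is_public": [c.is_public_Vg9JgP_Vd2 for c in clones],
            "cell_ids": [",".join(sorted(c.cell_ids)) for c in clones],
        }
    )


def partition_by_size(
    clones: Sequence[CloneRecord], threshold: int = 10
) -> tuple[list[CloneRecord], list[CloneRecord]]:
    """Split clones into large (> threshold cells) and small (≤ threshold)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    large = [c for c in clones if c.size > threshold]
    small = [c for c in clones if c.size <= threshold]
    return large, small


def gini(sizes: Sequence[float]) -> float:
    """Gini coefficient of clone sizes: Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄), in [0, 1).

    0 for perfectly even sizes; computed by the O(n log n) sorted identity,
    equivalent to the brute-force double loop.
    """
    x = np.asarray(sizes, dtype=float)
    if x.size == 0:
        raise ValueError("gini of empty size vector is undefined")
    if np.any(x <= 0):
        raise ValueError("clone sizes must be positive")
    n = x.size
    xs = np.sort(x)
    # Σᵢⱼ|xᵢ−xⱼ| = 2 Σᵢ (2i − n + 1) x_(i)   (0-based sorted index)
    total_abs_diff = 2.0 * np.sum((2.0 * np.arange(n) - n + 1.0) * xs)
    return float(total_abs_diff / (2.0 * n * n * x.mean()))


def top_n_cell_fraction(clones: Sequence[CloneRecord], n: int) -> float:
    """Fraction of all cells contained in the n largest clones.

    Ties at the size cut are broken by the stable order of clonotype_key.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 0.0
    ordered = sorted(clones, key=lambda c: (-c.size, c.clonotype_key))
    total = sum(c.size for c in clones)
    if total == 0:
        raise ValueError("no cells in clone list")
    return sum(c.size for c in ordered[:n]) / total


def small_clone_cell_fraction(clones: Sequence[CloneRecord], threshold: int = 10) -> float:
    """Fraction of all cells that sit in clones of ≤ threshold cells."""
    if not clones:
        raise ValueError("empty clone list")
    total = sum(c.size for c in clones)
    small = sum(c.size for c in clones if c.size <= threshold)
    return small / total


def classify_expansion(final_count: int, threshold: int = 500) -> str:
    """Strong expansion iff the single-clone culture yields > threshold cells."""
    if final_count < 0:
        raise ValueError("final_count must be >= 0")
    return "strong" if final_count > threshold else "weak"


def expansion_summary(final_counts: Sequence[int], threshold: int = 500) -> dict:
    """Batch summary of single-clone cultures: n strong / n total and the
    percentage of strongly expanding clones, rounded to one decimal.
    """
    calls = [classify_expansion(c, threshold) for c in final_counts]
    n_strong = sum(c == "strong" for c in calls)
    n_total = len(calls)
    if n_total == 0:
        raise ValueError("no cultures")
    return {
        "n_strong": n_strong,
        "n_total": n_total,
        "percent_strong": round(100.0 * n_strong / n_total, 1),
    }
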