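"""Synthetic paired repertoire + expression + protein data with ground truth.

The generator emulates the statistical structure of an in vitro expansion
culture of cord-blood γδ T cells profiled by paired scRNA-seq/scTCR-seq:

* clonotype classes (Vδ1, Vδ3, Vγ9−Vδ2+, Vγ9+Vδ2+) with class-dependent
  clone-size spectra (zero-truncated negative binomial);
* clone-level differentiation bias: each clone draws one state-probability
  vector from its class's Dirichlet prior, then assigns member cells
  multinomially across cell states;
* state-specific expression programs layered on a negative-binomial count
  model with per-cell lognormal library-size variation;
* per-state lognormal surface-protein intensities (CD45RA / CD27).

Cluster labels default to the true state labels (cell clustering itself is
treated as an upstream input), with an optional label-noise rate.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .datasets import AIRR_COLUMNS, CellDataset

__all__ = [
    "ClonotypeClassConfig",
    "SimConfig",
    "SimClone",
    "GroundTruth",
    "default_config",
    "simulate_repertoire",
    "simulate_cells",
    "simulate_dataset",
    "write_dataset",
]

# Default cell-state names for a day-14 expansion culture.
DEFAULT_STATES = [
    "EarlyDifferentiating",
    "TRMPrecursorLike",
    "APCLike",
    "TRMPrecursorCTL",
    "EarlyExhaustiveCTL",
]

# State-specific expression programs: gene -> log2 elevation over baseline.
DEFAULT_PROGRAMS = {
    "EarlyDifferentiating": {
        "SOX4": 3.0, "LEF1": 3.0, "TCF7": 2.5, "SELL": 2.0,
        "IL7R": 2.0, "IKZF2": 2.0, "MYB": 2.0, "BACH2": 2.0,
    },
    "TRMPrecursorLike": {
        "ZNF683": 3.0, "ITGAE": 2.5, "CXCR6": 2.0, "GZMA": 2.0,
        "ID3": 2.0, "RGS1": 2.0,
    },
    "APCLike": {
        "CCR7": 3.0, "CD74": 3.0, "HLA-DRA": 3.0, "HLA-DRB1": 2.5,
        "HLA-DPA1": 2.5, "LAMP3": 2.0, "HSPA8": 2.0, "HSPB1": 2.0,
    },
    "TRMPrecursorCTL": {
        "ZNF683": 2.5, "GZMA": 3.0, "NKG7": 2.5, "CST7": 2.5,
        "CCL5": 2.5, "IL32": 2.0, "CTSW": 2.0, "ENTPD1": 2.0,
        "CXCL13": 2.0, "ITGAE": 2.0,
    },
    "EarlyExhaustiveCTL": {
        "GZMB": 3.0, "LAG3": 2.5, "HAVCR2": 2.5, "PDCD1": 2.5,
        "TOX": 2.0, "TIGIT": 2.0, "CTLA4": 2.0, "KLRG1": 2.0,
        "MKI67": 2.0,
    },
}

# Per-state lognormal (location, scale) of surface markers, natural-log scale.
DEFAULT_PROTEIN_MODEL = {
    "EarlyDifferentiating": {"CD45RA": (5.0, 0.4), "CD27": (5.0, 0.4)},
    "TRMPrecursorLike": {"CD45RA": (2.0, 0.4), "CD27": (5.0, 0.4)},
    "APCLike": {"CD45RA": (2.0, 0.4), "CD27": (5.0, 0.4)},
    "TRMPrecursorCTL": {"CD45RA": (5.0, 0.4), "CD27": (2.0, 0.4)},
    "EarlyExhaustiveCTL": {"CD45RA": (2.0, 0.4), "CD27": (2.0, 0.4)},
}

# Clone-level Dirichlet concentrations over DEFAULT_STATES per clonotype
# class. Vδ1/Vδ3 clones are CTL-biased; Vδ2+ (especially Vγ9+) clones carry a
# larger APC-like component, mirroring the differentiation bias the analysis
# is designed to detect.
DEFAULT_CLASS_BIAS = {
    "Vd1": [7.5, 10.0, 2.5, 22.5, 7.5],
    "Vd3": [7.5, 10.0, 2.5, 22.5, 7.5],
    "Vg9negVd2": [10.0, 10.0, 7.5, 15.0, 7.5],
    "Vg9posVd2": [10.0, 10.0, 15.0, 10.0, 5.0],
}

_GAMMA_V_NON9 = ["TRGV2", "TRGV3", "TRGV4", "TRGV5", "TRGV8"]
_GAMMA_J = ["TRGJ1", "TRGJ2"]
_DELTA_J = ["TRDJ1", "TRDJ3"]


class ClonotypeClassConfig(BaseModel):
    """One clonotype class with its zero-truncated NB clone-size law."""

    name: str
    n_clones: int = Field(gt=0)
    size_mean: float = Field(ge=1.0, description="NB mean μ before truncation")
    size_dispersion: float = Field(gt=0.0, description="NB size parameter θ")


class SimConfig(BaseModel):
    """Full configuration of the synthetic dataset generator."""

    seed: int = 0
    clonotype_classes: list[ClonotypeClassConfig]
    state_names: list[str] = Field(default_factory=lambda: list(DEFAULT_STATES))
    class_bias: dict[str, list[float]] = Field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLASS_BIAS.items()})
    programs: dict[str, dict[str, float]] = Field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROGRAMS.items()})
    n_genes: int = Field(default=1000, gt=0)
    baseline_mean: float = Field(default=0.2, gt=0.0)
    nb_dispersion: float = Field(default=2.0, gt=0.0)
    library_size_sigma: float = Field(default=0.2, ge=0.0)
    protein_model: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_PROTEIN_MODEL.items()}
    )
    label_noise: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("state_names")
    @classmethod
    def _states_nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("state_names must be non-empty")
        return v

    @model_validator(mode="after")
    def _check_consistency(self) -> "SimConfig":
        for cls_cfg in self.clonotype_classes:
            conc = self.class_bias.get(cls_cfg.name)
            if conc is None:
                raise ValueError(f"no class_bias entry for class {cls_cfg.name!r}")
            if len(conc) != len(self.state_names):
                raise ValueError(
                    f"class_bias[{cls_cfg.name!r}] has {len(conc)} entries for "
                    f"{len(self.state_names)} states"
                )
            if any(a <= 0 for a in conc):
                raise ValueError(f"class_bias[{cls_cfg.name!r}] concentrations must be > 0")
        for state in self.programs:
            if state not in self.state_names:
                raise ValueError(f"program for unknown state {state!r}")
        program_genes = {g for prog in self.programs.values() for g in prog}
        if len(program_genes) > self.n_genes:
            raise ValueError("n_genes smaller than the number of program genes")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def gene_universe(self) -> list[str]:
        """Named program genes first, padded with filler genes to n_genes."""
        named = sorted({g for prog in self.programs.values() for g in prog})
        n_filler = self.n_genes - len(named)
        filler = [f"FILLER{i:05d}" for i in range(n_filler)]
        return named + filler


def default_config(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """Study-condition default: four clonotype classes whose clone-size
    spectra mimic an expansion culture — many small Vγ9+Vδ2+ clones, fewer
    but larger Vδ1/Vδ3 clones (sizes spanning 1 to ~100 cells).

    ``scale`` multiplies the clone counts to grow/shrink the dataset while
    keeping the per-clone laws fixed.
    """
    def n(x: int) -> int:
        return max(1, int(round(x * scale)))

    return SimConfig(
        seed=seed,
        clonotype_classes=[
            ClonotypeClassConfig(name="Vd1", n_clones=n(150), size_mean=9.0, size_dispersion=2.0),
            ClonotypeClassConfig(name="Vd3", n_clones=n(120), size_mean=7.0, size_dispersion=2.0),
            ClonotypeClassConfig(name="Vg9negVd2", n_clones=n(120), size_mean=6.0, size_dispersion=2.5),
            ClonotypeClassConfig(name="Vg9posVd2", n_clones=n(220), size_mean=4.0, size_dispersion=3.0),
        ],
    )


@dataclass
class SimClone:
    """A simulated clone: identity, clonotype class and drawn size."""

    clone_id: str
    class_name: str
    size: int
    delta_v: str
    delta_j: str
    delta_junction: str
    gamma_v: Optional[str]
    gamma_j: Optional[str]
    gamma_junction: Optional[str]


@dataclass
class GroundTruth:
    """Per-clone and per-cell truths recorded by the generator."""

    clone_class: dict[str, str]
    clone_state_probs: dict[str, np.ndarray]  # the Dirichlet draw
    clone_state_fractions: dict[str, np.ndarray]  # empirical fractions of drawn labels
    cell_state: pd.Series  # indexed by cell barcode
    cell_clone: pd.Series  # indexed by cell barcode
    state_names: list[str] = field(default_factory=list)


def _zero_truncated_nb(rng: np.random.Generator, mu: float, theta: float, size: int) -> np.ndarray:
    """Zero-truncated NB(μ, θ) by rejection-resampling zeros."""
    p = theta / (theta + mu)
    draws = rng.negative_binomial(theta, p, size=size)
    zero = draws == 0
    while zero.any():
        draws[zero] = rng.negative_binomial(theta, p, size=int(zero.sum()))
        zero = draws == 0
    return draws


def _random_junction(rng: np.random.Generator, length: int = 10) -> str:
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    middle = "".join(rng.choice(aa, size=length))
    return "C" + middle + "F"


def simulate_repertoire(config: SimConfig) -> list[SimClone]:
    """Draw the clone table: one record per configured clone, sizes i.i.d.
    from the class's zero-truncated NB. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    clones: list[SimClone] = []
    junctions_seen: set[tuple] = set()
    idx = 0
    for cls_cfg in config.clonotype_classes:
        sizes = _zero_truncated_nb(rng, cls_cfg.size_mean, cls_cfg.size_dispersion, cls_cfg.n_clones)
        for size in sizes:
            if cls_cfg.name == "Vg9posVd2":
                gv, gj, dv = "TRGV9", "TRGJP", "TRDV2"
            elif cls_cfg.name == "Vg9negVd2":
                gv = str(rng.choice(_GAMMA_V_NON9))
                gj = str(rng.choice(_GAMMA_J))
                dv = "TRDV2"
            elif cls_cfg.name == "Vd1":
                gv = str(rng.choice(_GAMMA_V_NON9))
                gj = str(rng.choice(_GAMMA_J))
                dv = "TRDV1"
            elif cls_cfg.name == "Vd3":
                gv = str(rng.choice(_GAMMA_V_NON9))
                gj = str(rng.choice(_GAMMA_J))
                dv = "TRDV3"
            else:
                gv = str(rng.choice(_GAMMA_V_NON9))
                gj = str(rng.choice(_GAMMA_J))
                dv = "TRDV1"
            dj = str(rng.choice(_DELTA_J))
            # junctions unique per clone so clonotype keys never collide
            while True:
                dj_aa = _random_junction(rng, 12)
                gj_aa = _random_junction(rng, 8)
                key = (dv, dj, dj_aa, gv, gj, gj_aa)
                if key not in junctions_seen:
                    junctions_seen.add(key)
                    break
            clones.append(
                SimClone(
                    clone_id=f"clone{idx:05d}",
                    class_name=cls_cfg.name,
                    size=int(size),
                    delta_v=dv,
                    delta_j=dj,
                    delta_junction=dj_aa,
                    gamma_v=gv,
                    gamma_j=gj,
                    gamma_junction=gj_aa,
                )
            )
            idx += 1
    return clones


def simulate_cells(clones: list[SimClone], config: SimConfig) -> tuple[CellDataset, GroundTruth]:
    """Simulate per-cell states, counts, chain calls and protein for the
    given clone table. Total cells equals the sum of clone sizes.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = config.gene_universe()
    gene_index = {g: i for i, g in enumerate(genes)}
    states = config.state_names
    n_states = len(states)

    # per-state mean vectors: baseline shifted by the program's log2 elevation
    state_means = np.full((n_states, len(genes)), config.baseline_mean, dtype=float)
    for state, prog in config.programs.items():
        si = states.index(state)
        for gene, lfc in prog.items():
            if gene not in gene_index:
                raise ValueError(f"program gene {gene!r} absent from gene universe")
            state_means[si, gene_index[gene]] *= 2.0 ** lfc

    total_cells = int(sum(c.size for c in clones))
    cell_ids, cell_clone, cell_state_idx = [], [], np.empty(total_cells, dtype=int)
    clone_class, clone_probs, clone_fracs = {}, {}, {}
    pos = 0
    for clone in clones:
        conc = np.asarray(config.class_bias[clone.class_name], dtype=float)
        probs = rng.dirichlet(conc)
        labels = rng.choice(n_states, size=clone.size, p=probs)
        counts = np.bincount(labels, minlength=n_states)
        clone_class[clone.clone_id] = clone.class_name
        clone_probs[clone.clone_id] = probs
        clone_fracs[clone.clone_id] = counts / clone.size
        for k in labels:
            cell_ids.append(f"CELL{pos:06d}-1")
            cell_clone.append(clone.clone_id)
            cell_state_idx[pos] = k
            pos += 1

    # counts: NB with per-cell lognormal library-size factor
    factors = np.exp(rng.normal(0.0, config.library_size_sigma, size=total_cells))
    mu = state_means[cell_state_idx] * factors[:, None]
    theta = config.nb_dispersion
    p = theta / (theta + mu)
    X = rng.negative_binomial(theta, p).astype(np.int32)

    state_labels = pd.Categorical.from_codes(cell_state_idx, categories=states)
    cluster = np.asarray(state_labels.astype(str))
    if config.label_noise > 0:
        flip = rng.random(total_cells) < config.label_noise
        cluster[flip] = rng.choice(states, size=int(flip.sum()))

    obs = pd.DataFrame(
        {
            "cluster": cluster,
            "sample": "SIM",
            "timepoint": "D14",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))

    # AIRR chain rows: one TRD and (unless missing) one TRG row per cell
    clone_by_id = {c.clone_id: c for c in clones}
    rows = []
    for cid, clid in zip(cell_ids, cell_clone):
        c = clone_by_id[clid]
        rows.append((cid, "TRD", c.delta_v, c.delta_j, c.delta_junction, "T"))
        if c.gamma_v is not None:
            rows.append((cid, "TRG", c.gamma_v, c.gamma_j, c.gamma_junction, "T"))
    airr = pd.DataFrame(rows, columns=AIRR_COLUMNS)

    # protein intensities per state
    markers = sorted({m for model in config.protein_model.values() for m in model})
    protein = np.empty((total_cells, len(markers)))
    for si, state in enumerate(states):
        mask = cell_state_idx == si
        model = config.protein_model.get(state, {})
        for mi, marker in enumerate(markers):
            loc, scale = model.get(marker, (0.0, 1.0))
            protein[mask, mi] = rng.lognormal(loc, scale, size=int(mask.sum()))
    protein_df = pd.DataFrame(protein, index=obs.index, columns=markers)

    truth = GroundTruth(
        clone_class=clone_class,
        clone_state_probs=clone_probs,
        clone_state_fractions=clone_fracs,
        cell_state=pd.Series(np.asarray(state_labels.astype(str)), index=obs.index, name="state"),
        cell_clone=pd.Series(cell_clone, index=obs.index, name="clone_id"),
        state_names=list(states),
    )
    return CellDataset(adata=adata, airr=airr, protein=protein_df), truth


def simulate_dataset(config: SimConfig) -> tuple[CellDataset, GroundTruth, list[SimClone]]:
    """Convenience wrapper: repertoire draw followed by cell simulation."""
    clones = simulate_repertoire(config)
    dataset, truth = simulate_cells(clones, config)
    return dataset, truth, clones


def write_dataset(dataset: CellDataset, directory, truth: GroundTruth | None = None) -> None:
    """Write the dataset as MTX triplet (genes x cells) + TSV/CSV side files.

    Layout: ``matrix.mtx`` (rows = genes, columns = cells, the common 10x
    triplet orientation), ``features.tsv``, ``barcodes.tsv``,
    ``airr_rearrangements.tsv``, ``protein.csv``, ``metadata.csv`` and,
    when ground truth is given, ``ground_truth_cells.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = dataset.counts().T.tocoo()  # genes x cells
    scipy.io.mmwrite(str(directory / "matrix.mtx"), X, field="integer")
    pd.DataFrame({"gene_id": dataset.gene_names, "gene_name": dataset.gene_names}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(dataset.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    dataset.airr.to_csv(directory / "airr_rearrangements.tsv", sep="\t", index=False)
    dataset.protein.to_csv(directory / "protein.csv", index_label="cell_id")
    dataset.adata.obs.to_csv(directory / "metadata.csv", index_label="cell_id")
    if truth is not None:
        pd.DataFrame({"state": truth.cell_state, "clone_id": truth.cell_clone}).to_csv(
            directory / "ground_truth_cells.csv", index_label="cell_id"
        )
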