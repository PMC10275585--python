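"""End-to-end orchestration: simulate/read → clonotype → score → modules →
bias → assay statistics, with a manifest recording the config hash and seed.

Every tabular output starts with a ``# config_hash=...`` comment line; rerun
with an identical config is bit-identical (no timestamps are written).
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonal_dynamics, culture_assays, gene_modules, repertoire, resources, scoring
from .config import PipelineConfig
from .datasets import CellDataset, normalize_log1p
from .io import read_dataset
from .simulate import default_config, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and input provenance."""

    def __init__(self, stage: str, provenance: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {provenance}: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str, provenance: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(name, provenance, exc) from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str, sep: str = "\t", index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep=sep, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    config hash, seed and produced files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    provenance = config.input_dir or "simulation"
    outputs: dict[str, str] = {}
    summary: dict[str, float] = {}

    with _stage("input", provenance):
        if config.input_dir is not None:
            dataset = read_dataset(config.input_dir)
        else:
            sim = config.sim or default_config(seed=config.seed)
            dataset, truth, _ = simulate_dataset(sim)
            sim_dir = out / "simulated_input"
            write_dataset(dataset, sim_dir, truth)
            outputs["simulated_input"] = str(sim_dir)

    with _stage("clonotype", provenance):
        cells = repertoire.classify_cells(dataset.airr)
        clones = repertoire.build_clones(cells)
        ctable = repertoire.clone_table(clones)
        _write_table(ctable, out / "clone_table.tsv", chash)
        outputs["clone_table"] = str(out / "clone_table.tsv")
        sizes = [c.size for c in clones]
        summary["n_clones"] = len(clones)
        summary["gini"] = repertoire.gini(sizes) if sizes else float("nan")
        summary["top_n_cell_fraction"] = (
            repertoire.top_n_cell_fraction(clones, config.top_n) if clones else float("nan")
        )
        vg9 = [c for c in clones if c.class_name == "Vg9posVd2"]
        if vg9:
            summary["vg9pos_vd2_small_clone_fraction"] = repertoire.small_clone_cell_fraction(
                vg9, config.size_threshold
            )

    with _stage("score", provenance):
        log_expr = pd.DataFrame(
            normalize_log1p(dataset, config.target_sum),
            index=dataset.cell_ids,
            columns=dataset.gene_names,
        )
        if config.signature_file is not None:
            sets = scoring.read_signatures(config.signature_file)
            signatures = {n: scoring.GeneSignature(name=n, genes=g) for n, g in sets.items()}
        else:
            signatures = resources.load_default_signatures()
        params = scoring.ModuleScoreParams(n_bins=config.n_bins, n_ctrl=config.n_ctrl, seed=config.seed)
        scorable = {
            n: s for n, s in signatures.items() if any(g in log_expr.columns for g in s.genes)
        }
        scorer = scoring.SignatureScorer(
            signatures=list(scorable.values()),
            n_bins=params.n_bins,
            n_ctrl=params.n_ctrl,
            seed=params.seed,
        ).fit(log_expr)
        scores = scorer.transform(log_expr)
        scores["gzm_log2_ratio"] = scoring.gzm_ratio(
            np.expm1(log_expr), pseudocount=config.gzm_pseudocount
        )
        if {"innateness_up", "innateness_down"} <= set(signatures):
            ref = scoring.InnatenessReference(
                up_set=signatures["innateness_up"].genes,
                down_set=signatures["innateness_down"].genes,
            )
            scores["innateness"] = scoring.innateness_score(log_expr, ref)
        if {"s_phase", "g2m"} <= set(scores.columns):
            scores["phase"] = scoring.cell_cycle_phase(scores["s_phase"], scores["g2m"])
        _write_table(scores, out / "cell_scores.csv", chash, sep=",", index=True)
        outputs["cell_scores"] = str(out / "cell_scores.csv")

        labels = dataset.adata.obs[config.label_column]
        annotator = scoring.ClusterStateAnnotator(
            signatures=signatures, n_bins=config.n_bins, n_ctrl=config.n_ctrl, seed=config.seed
        ).fit(log_expr, labels)
        cluster_states = annotator.cluster_states_.rename_axis("cluster").reset_index()
        _write_table(cluster_states, out / "cluster_states.tsv", chash)
        outputs["cluster_states"] = str(out / "cluster_states.tsv")

        if not dataset.protein.empty and {"CD45RA", "CD27"} <= set(dataset.protein.columns):
            gate = scoring.MemoryGate(seed=config.seed).fit(dataset.protein)
            fractions = gate.fractions(dataset.protein)
            _write_table(
                fractions.rename("fraction").rename_axis("phenotype").reset_index(),
                out / "memory_fractions.tsv",
                chash,
            )
            outputs["memory_fractions"] = str(out / "memory_fractions.tsv")

    with _stage("modules", provenance):
        markers = gene_modules.marker_genes(
            log_expr,
            labels,
            min_fc=config.marker_min_fc,
            alpha=config.marker_alpha,
            min_frac=config.marker_min_frac,
        )
        _write_table(markers, out / "marker_genes.tsv", chash)
        outputs["marker_genes"] = str(out / "marker_genes.tsv")
        marker_set = sorted(markers["gene"].unique())
        if len(marker_set) >= 2:
            activity = gene_modules.aggregate_cluster_expression(log_expr[marker_set], labels)
            k = min(config.n_modules, len(marker_set))
            detector = gene_modules.GeneModuleDetector(n_modules=k).fit(activity)
            module_rows = pd.DataFrame(
                [(f"GM{m.module_id}", g) for m in detector.modules_ for g in m.genes],
                columns=["module_id", "gene"],
            )
            _write_table(module_rows, out / "gene_modules.tsv", chash)
            _write_table(
                detector.activity_matrix().rename_axis("cluster").reset_index(),
                out / "module_activity.csv",
                chash,
                sep=",",
            )
            outputs["gene_modules"] = str(out / "gene_modules.tsv")
            outputs["module_activity"] = str(out / "module_activity.csv")

    with _stage("bias", provenance):
        cell_states = pd.Series(annotator.predict(labels), index=dataset.cell_ids)
        bias_records = clonal_dynamics.clone_bias_table(
            clones,
            cell_states,
            pseudocount=config.bias_pseudocount,
            min_size=config.min_clone_size,
        )
        bias_df = pd.DataFrame(
            {
                "clonotype_key": [r.clonotype_key for r in bias_records],
                "class": [r.class_name for r in bias_records],
                "size": [r.size for r in bias_records],
                **{
                    f"frac_{g}": [r.fractions[g] for r in bias_records]
                    for g in clonal_dynamics.GROUP_ORDER
                },
                "apc_ctl_ratio": [r.apc_ctl_ratio for r in bias_records],
                "bias": [r.bias for r in bias_records],
            }
        )
        _write_table(bias_df, out / "clone_bias.tsv", chash)
        outputs["clone_bias"] = str(out / "clone_bias.tsv")
        if bias_records:
            bias_summary = clonal_dynamics.subtype_bias_summary(bias_records, config.size_threshold)
            _write_table(bias_summary, out / "bias_summary.tsv", chash)
            outputs["bias_summary"] = str(out / "bias_summary.tsv")
        cell_classes = pd.Series(
            {c.cell_id: c.class_name for c in cells}, name="class"
        ).reindex(dataset.cell_ids)
        keep = cell_classes.notna()
        within_class, within_cluster = clonal_dynamics.cluster_clonotype_enrichment(
            cell_classes[keep], labels[keep]
        )
        _write_table(within_class.rename_axis("class").reset_index(), out / "enrichment_within_class.csv", chash, sep=",")
        _write_table(within_cluster.rename_axis("class").reset_index(), out / "enrichment_within_cluster.csv", chash, sep=",")
        outputs["enrichment_within_class"] = str(out / "enrichment_within_class.csv")
        outputs["enrichment_within_cluster"] = str(out / "enrichment_within_cluster.csv")

    with _stage("assays", provenance):
        counts = resources.load_culture_counts()
        series = [
            culture_assays.CultureSeries(
                sample_id=sid, days=grp["day"].tolist(), counts=grp["gd_count_millions"].tolist()
            )
            for sid, grp in counts.sort_values(["sample_id", "day"]).groupby("sample_id")
        ]
        cohort = culture_assays.cohort_fold_expansion(series)
        mfi = resources.load_chemokine_mfi()
        ttests = {}
        for marker, grp in mfi.groupby("marker"):
            wide = grp.pivot(index="sample_id", columns="day", values="mfi")
            res = culture_assays.paired_ttest(wide[0], wide[21])
            ttests[marker] = res["p"]
        assay_stats = {
            "fold_expansion_mean": cohort["mean"],
            "fold_expansion_sem": cohort["sem"],
            "fold_expansion_n": cohort["n"],
            "paired_ttest_p": ttests,
        }
        summary.update(
            fold_expansion_mean=cohort["mean"],
            fold_expansion_sem=cohort["sem"],
        )
        with open(out / "assay_stats.json", "w") as fh:
            json.dump({"config_hash": chash, **assay_stats}, fh, indent=2, sort_keys=True)
        outputs["assay_stats"] = str(out / "assay_stats.json")

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "outputs": outputs,
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
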