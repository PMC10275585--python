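"""Signature scores, phenotype gates and the cluster-state decision list."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from clonostate import resources
from clonostate.datasets import normalize_log1p
from clonostate.scoring import (
    ClusterStateAnnotator,
    GeneSignature,
    InnatenessReference,
    MemoryGate,
    ModuleScoreParams,
    SignatureScorer,
    assign_state,
    cell_cycle_phase,
    cluster_profiles,
    gzm_categories,
    gzm_ratio,
    group_gzm_ratio,
    innateness_score,
    map_clusters_to_signatures,
    memory_gate,
    module_score,
    read_signatures,
    write_signatures,
)


def expr_frame(rng, n_cells=200, n_genes=40, prefix="G"):
    X = rng.gamma(2.0, 1.0, size=(n_cells, n_genes))
    return pd.DataFrame(X, columns=[f"{prefix}{i:03d}" for i in range(n_genes)])


# --- module score -------------------------------------------------------------


def test_all_genes_signature_scores_exactly_zero(rng):
    X = expr_frame(rng)
    sig = GeneSignature(name="all", genes=list(X.columns))
    scores = module_score(X, sig)
    np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)


def test_module_score_detects_enriched_signature(rng):
    X = expr_frame(rng)
    enriched = list(X.columns[:5])
    half = X.index[: len(X) // 2]
    X.loc[half, enriched] += 3.0
    # wide bins keep non-signature control candidates in the enriched genes' bin
    scores = module_score(X, GeneSignature(name="up", genes=enriched), ModuleScoreParams(n_bins=4))
    assert scores[half].mean() > scores.drop(half).mean() + 1.0


def test_module_score_deterministic_under_seed(rng):
    X = expr_frame(rng)
    sig = GeneSignature(name="s", genes=list(X.columns[:4]))
    a = module_score(X, sig, ModuleScoreParams(seed=5))
    b = module_score(X, sig, ModuleScoreParams(seed=5))
    pd.testing.assert_series_equal(a, b)


def test_missing_signature_genes_warn_and_drop(rng):
    X = expr_frame(rng)
    sig = GeneSignature(name="s", genes=[X.columns[0], "ABSENT"])
    with pytest.warns(UserWarning, match="absent"):
        module_score(X, sig)
    with pytest.raises(ValueError):
        module_score(X, GeneSignature(name="gone", genes=["NOPE"]))


def test_gene_bins_override_controls_binning(rng):
    """Forcing every gene into one bin makes the controls a random draw from
    all non-signature genes, regardless of expression level."""
    X = expr_frame(rng, n_genes=10)
    sig = GeneSignature(name="s", genes=list(X.columns[:2]))
    bins = {g: 0 for g in X.columns}
    scorer = SignatureScorer(signatures=[sig], gene_bins=bins, n_ctrl=50).fit(X)
    for g in scorer.used_genes_["s"]:
        assert set(scorer.controls_["s"][g]) == set(X.columns[2:])


def test_module_score_tracks_scanpy_reference(medium_log_expr):
    """Cross-check against scanpy's score_genes on a simulated matrix: the
    two control-matched scores should be strongly correlated."""
    sc = pytest.importorskip("scanpy")
    import anndata as ad

    X = medium_log_expr.iloc[:800]
    genes = ["GZMB", "LAG3", "KLRG1", "MKI67"]
    ours = module_score(X, GeneSignature(name="exh", genes=genes))
    adata = ad.AnnData(X=X.to_numpy(), var=pd.DataFrame(index=X.columns))
    sc.tl.score_genes(adata, gene_list=genes, ctrl_size=50, n_bins=25, score_name="ref")
    r = np.corrcoef(ours.to_numpy(), adata.obs["ref"].to_numpy())[0, 1]
    assert r > 0.95


# --- innateness ---------------------------------------------------------------


def test_innateness_score_orders_known_populations(rng):
    X = expr_frame(rng, n_genes=20)
    up, down = list(X.columns[:5]), list(X.columns[5:10])
    innate_cells = X.index[:50]
    X.loc[innate_cells, up] += 2.0
    X.loc[innate_cells, down] -= 1.0
    ref = InnatenessReference(up_set=up, down_set=down)
    score = innateness_score(X, ref)
    assert score[innate_cells].mean() > score.drop(innate_cells).mean() + 0.5
    # z-scores are centered per gene, so the score has mean zero over cells
    assert score.mean() == pytest.approx(0.0, abs=1e-10)


def test_innateness_reference_rejects_overlap():
    with pytest.raises(ValueError):
        InnatenessReference(up_set=["A", "B"], down_set=["B"])


def test_innateness_requires_represented_sets(rng):
    X = expr_frame(rng, n_genes=4)
    ref = InnatenessReference(up_set=["NOPE1"], down_set=["NOPE2"])
    with pytest.raises(ValueError):
        innateness_score(X, ref)


# --- GZMA/GZMB ratio ----------------------------------------------------------


def test_gzm_ratio_arithmetic():
    X = pd.DataFrame({"GZMA": [3.0, 0.0], "GZMB": [1.0, 0.0]})
    r = gzm_ratio(X, pseudocount=1.0)
    assert r.iloc[0] == pytest.approx(1.0)  # log2(4/2)
    assert r.iloc[1] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        gzm_ratio(X[["GZMA"]])


def test_group_gzm_ratio_and_categories():
    X = pd.DataFrame({"GZMA": [7.0, 7.0, 0.0, 0.0, 1.0, 1.0], "GZMB": [0.0, 0.0, 7.0, 7.0, 1.0, 1.0]})
    labels = ["hiA", "hiA", "hiB", "hiB", "even", "even"]
    r = group_gzm_ratio(X, labels, pseudocount=1.0)
    assert r["hiA"] == pytest.approx(3.0)
    assert r["hiB"] == pytest.approx(-3.0)
    assert r["even"] == pytest.approx(0.0)
    cats = gzm_categories(r, cutoffs=(-1.0, 1.0))
    assert cats.to_dict() == {"hiA": "hi", "hiB": "lo", "even": "mo"}


def test_gzm_categories_default_tertiles():
    r = pd.Series({"a": -2.0, "b": 0.0, "c": 2.0})
    cats = gzm_categories(r)
    assert cats.to_dict() == {"a": "lo", "b": "mo", "c": "hi"}


# --- cell cycle and memory gates ---------------------------------------------


def test_cell_cycle_phase_decision_table():
    s = [-1.0, 0.5, 0.1, 0.3, 0.0]
    g = [-0.5, 0.1, 0.4, 0.3, 0.0]
    assert list(cell_cycle_phase(s, g)) == ["G1", "S", "G2M", "G2M", "G1"]


def test_memory_gate_quadrants():
    ra = [True, False, True, False]
    c27 = [True, True, False, False]
    assert list(memory_gate(ra, c27)) == ["T_N", "T_CM", "T_E", "T_E"]


def test_memory_gate_estimator_separates_bimodal_markers(rng):
    lo = rng.lognormal(2.0, 0.3, size=300)
    hi = rng.lognormal(5.0, 0.3, size=300)
    protein = pd.DataFrame(
        {
            "CD45RA": np.concatenate([hi, lo]),
            "CD27": np.concatenate([hi[:300], lo[:300]]),
        }
    )
    gate = MemoryGate(seed=0).fit(protein)
    thr_ra = gate.thresholds_["CD45RA"]
    assert np.exp(2.0 + 3 * 0.3) < thr_ra < np.exp(5.0 - 3 * 0.3)
    fracs = gate.fractions(protein)
    assert fracs.sum() == pytest.approx(1.0, abs=1e-12)
    assert fracs["T_N"] == pytest.approx(0.5, abs=0.05)


def test_memory_gate_manual_thresholds_override():
    protein = pd.DataFrame({"CD45RA": [10.0, 0.1], "CD27": [10.0, 10.0]})
    gate = MemoryGate(thresholds={"CD45RA": 1.0, "CD27": 1.0}).fit(protein)
    assert list(gate.predict(protein)) == ["T_N", "T_CM"]


@given(
    arrays(np.float64, shape=(20, 2), elements=st.floats(0.01, 1e4)),
)
def test_memory_gate_fractions_sum_to_one_property(values):
    protein = pd.DataFrame(values, columns=["CD45RA", "CD27"])
    gate = MemoryGate(thresholds={"CD45RA": 10.0, "CD27": 10.0}).fit(protein)
    assert gate.fractions(protein).sum() == pytest.approx(1.0, abs=1e-12)


# --- cluster-state annotation -------------------------------------------------


def test_assign_state_decision_list_on_synthetic_profiles():
    profiles = pd.DataFrame(
        {
            "ccr7_z": [1.0, -0.5, -0.5, -0.5, -0.5],
            "znf683_z": [0.0, -0.5, 1.0, 1.0, -0.2],
            "klrg1_z": [0.0, 1.0, -1.0, -1.0, 0.1],
            "antigen_presentation": [0.8, -0.1, -0.1, -0.1, -0.1],
            "exhaustion": [-0.1, 0.9, -0.1, -0.1, -0.2],
            "tilneo": [0.0, 0.0, 0.7, -0.3, 0.0],
            "gzm_log_ratio": [0.5, -1.5, 1.0, 1.0, 0.0],
        },
        index=["c0", "c1", "c2", "c3", "c4"],
    )
    states = assign_state(profiles)
    assert states.to_dict() == {
        "c0": "APCLike",
        "c1": "EarlyExhaustiveCTL",
        "c2": "TRMPrecursorCTL",
        "c3": "TRMPrecursorLike",
        "c4": "EarlyDifferentiating",
    }


def test_assign_state_requires_rule_columns():
    with pytest.raises(ValueError, match="missing rule columns"):
        assign_state(pd.DataFrame({"ccr7_z": [0.0]}))


def test_annotator_recovers_simulated_states(medium_sim, medium_log_expr):
    """On a full simulation with true cluster labels, the decision list
    recovers every simulated state."""
    _, dataset, truth, _ = medium_sim
    signatures = resources.load_default_signatures()
    annot = ClusterStateAnnotator(signatures=signatures, seed=0).fit(
        medium_log_expr, truth.cell_state
    )
    mapping = annot.cluster_states_
    assert all(mapping[state] == state for state in mapping.index)
    preds = annot.predict(truth.cell_state)
    assert (preds == truth.cell_state.to_numpy()).all()


def test_map_clusters_to_signatures_recovers_states(medium_sim, medium_log_expr):
    _, dataset, truth, _ = medium_sim
    state_sigs = resources.default_state_signatures()
    assignment, matrix = map_clusters_to_signatures(
        medium_log_expr, truth.cell_state, state_sigs
    )
    assert set(matrix.columns) == set(state_sigs)
    assert all(assignment[state] == state for state in assignment.index)


def test_cluster_profiles_requires_markers(rng):
    X = expr_frame(rng, n_genes=6)
    sigs = {
        n: GeneSignature(name=n, genes=[X.columns[0]])
        for n in ("antigen_presentation", "exhaustion", "tilneo")
    }
    with pytest.raises(ValueError, match="CCR7"):
        cluster_profiles(X, ["a"] * 100 + ["b"] * 100, sigs)


# --- signature file round trip ------------------------------------------------


def test_signature_file_round_trip(tmp_path):
    sets = {"alpha": ["G1", "G2"], "beta": ["G3"]}
    path = tmp_path / "sigs.tsv"
    write_signatures(sets, path)
    assert read_signatures(path) == sets


def test_packaged_signatures_load():
    sigs = resources.load_default_signatures()
    assert {"innateness_up", "innateness_down", "tilneo", "exhaustion"} <= set(sigs)
    ref = resources.default_innateness_reference()
    assert not set(ref.up_set) & set(ref.down_set)
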