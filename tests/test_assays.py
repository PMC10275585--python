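"""Bulk-culture statistics: fold expansion, cytotoxicity, paired t,
Spearman and cytokine-heatmap preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

from clonostate.culture_assays import (
    CultureSeries,
    CytotoxicityWell,
    cohort_fold_expansion,
    cytokine_heatmap_prep,
    fold_expansion,
    fold_expansion_from_raw,
    paired_ttest,
    spearman,
    specific_cytotoxicity,
)

# --- fold expansion --------------------------------------------------------------


def test_fold_expansion_plain_ratio():
    s = CultureSeries(sample_id="s", days=[0, 7, 21], counts=[0.05, 10.0, 49500.0])
    assert fold_expansion(s) == pytest.approx(990_000.0)


def test_culture_series_validation():
    with pytest.raises(ValueError):
        CultureSeries(sample_id="s", days=[0, 7], counts=[1.0])
    with pytest.raises(ValueError):
        CultureSeries(sample_id="s", days=[0, 7], counts=[1.0, -2.0])
    with pytest.raises(ValueError):
        CultureSeries(sample_id="s", days=[7, 0], counts=[1.0, 2.0])
    with pytest.raises(ValueError):
        fold_expansion(CultureSeries(sample_id="s", days=[0], counts=[1.0]))


@given(
    st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=3, max_size=8),
)
def test_fold_of_concatenation_is_product_of_segment_folds(counts):
    days = list(range(len(counts)))
    whole = CultureSeries(sample_id="w", days=days, counts=counts)
    cut = len(counts) // 2
    first = CultureSeries(sample_id="a", days=days[: cut + 1], counts=counts[: cut + 1])
    second = CultureSeries(sample_id="b", days=days[cut:], counts=counts[cut:])
    assert fold_expansion(whole) == pytest.approx(
        fold_expansion(first) * fold_expansion(second), rel=1e-12
    )


def test_fold_expansion_from_raw_reseed_fractions():
    # raw counts after splitting: keep half each passage
    s = CultureSeries(
        sample_id="s",
        days=[0, 1, 2],
        counts=[100.0, 400.0, 400.0],
        reseed_fractions=[0.5, 0.5],
    )
    # 400/(0.5*100) * 400/(0.5*400) = 8 * 2 = 16
    assert fold_expansion_from_raw(s) == pytest.approx(16.0)
    s.reseed_fractions = [0.5]
    with pytest.raises(ValueError):
        fold_expansion_from_raw(s)


def test_cohort_fold_expansion_mean_sem():
    series = [
        CultureSeries(sample_id=f"s{i}", days=[0, 21], counts=[1.0, f])
        for i, f in enumerate([10.0, 20.0, 30.0])
    ]
    cohort = cohort_fold_expansion(series)
    assert cohort["mean"] == pytest.approx(20.0)
    assert cohort["sem"] == pytest.approx(10.0 / np.sqrt(3))
    assert cohort["n"] == 3
    assert cohort["folds"]["s1"] == pytest.approx(20.0)


# --- cytotoxicity -----------------------------------------------------------------


def test_specific_cytotoxicity_cases():
    assert specific_cytotoxicity(CytotoxicityWell(100, 100, 1000))["percent"] == 0.0
    assert specific_cytotoxicity(CytotoxicityWell(1000, 100, 1000))["percent"] == 100.0
    assert specific_cytotoxicity(CytotoxicityWell(550, 100, 1000))["percent"] == pytest.approx(50.0)
    res = specific_cytotoxicity(CytotoxicityWell(50, 100, 1000))
    assert res["percent"] < 0
    assert res["percent_clamped"] == 0.0
    with pytest.raises(ValueError):
        CytotoxicityWell(50, 100, 100)


# --- paired t ---------------------------------------------------------------------


def test_paired_ttest_identical_vectors():
    res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res["t"] == 0.0 and res["p"] == 1.0 and not res["degenerate"]


def test_paired_ttest_constant_nonzero_shift_degenerate():
    res = paired_ttest([1.0, 2.0], [2.0, 3.0])
    assert res["p"] == 0.0 and res["degenerate"]


def test_paired_ttest_matches_scipy():
    before = [58.2, 44.0, 50.2]
    after = [436.3, 578.2, 431.0]
    res = paired_ttest(before, after)
    ref = stats.ttest_rel(after, before)
    assert res["t"] == pytest.approx(ref.statistic, abs=1e-12)
    assert res["p"] == pytest.approx(ref.pvalue, abs=1e-12)
    assert res["df"] == 2


@given(
    st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=3),
    st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=3),
)
def test_paired_ttest_df2_closed_form(before, after):
    """For n = 3 (df = 2) the two-sided p equals 1 − |t|/√(2 + t²)."""
    d = np.asarray(after) - np.asarray(before)
    assume(d.std(ddof=1) > 1e-6)
    res = paired_ttest(before, after)
    t = res["t"]
    assert res["p"] == pytest.approx(1.0 - abs(t) / np.sqrt(2.0 + t * t), abs=1e-9)


def test_paired_ttest_validates_shapes():
    with pytest.raises(ValueError):
        paired_ttest([1.0], [2.0])
    with pytest.raises(ValueError):
        paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])


# --- spearman ---------------------------------------------------------------------


def test_spearman_monotone_extremes():
    rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / 24)  # two of 24 permutations reach |rho| = 1
    rho, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
    assert rho == pytest.approx(-1.0)


def test_spearman_known_toy():
    rho, p = spearman([1, 2, 3, 4], [1, 3, 2, 4])
    assert rho == pytest.approx(0.8, abs=1e-12)
    # exact permutation count over 4! orderings
    assert 0 < p < 1


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError):
        spearman([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman([1, 2], [1, 2])


@given(
    st.lists(st.integers(min_value=0, max_value=20), min_size=4, max_size=12),
)
def test_spearman_equals_pearson_on_midranks(values):
    y = list(reversed(sorted(values)))
    x = list(range(len(values)))
    assume(len(set(y)) > 1)
    rho, _ = spearman(x, y)
    ref = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
    assert rho == pytest.approx(ref, abs=1e-12)


def test_spearman_large_n_uses_t_approximation(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(scale=0.5, size=30)
    rho, p = spearman(x, y)
    ref_rho, ref_p = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref_rho, abs=1e-12)
    assert p == pytest.approx(ref_p, rel=1e-6)


# --- cytokine heatmap prep --------------------------------------------------------


def test_heatmap_rows_centered_and_scaled(rng):
    M = pd.DataFrame(rng.normal(size=(6, 5)), index=[f"cyt{i}" for i in range(6)])
    prep = cytokine_heatmap_prep(M)
    scaled = prep["scaled"]
    np.testing.assert_allclose(scaled.mean(axis=1).to_numpy(), 0.0, atol=1e-12)
    np.testing.assert_allclose(scaled.std(axis=1, ddof=1).to_numpy(), 1.0, atol=1e-12)
    assert sorted(prep["row_order"]) == sorted(scaled.index)
    assert sorted(prep["col_order"]) == sorted(scaled.columns)


def test_heatmap_constant_row_dropped_with_warning():
    M = pd.DataFrame([[1.0, 3.0], [2.0, 2.0]], index=["r1", "r2"], columns=["a", "b"])
    with pytest.warns(UserWarning, match="constant"):
        prep = cytokine_heatmap_prep(M)
    assert list(prep["scaled"].index) == ["r1"]
    np.testing.assert_allclose(
        prep["scaled"].loc["r1"].to_numpy(), [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
    )


def test_heatmap_identical_columns_merge_first(rng):
    M = pd.DataFrame(rng.normal(size=(5, 3)), columns=["s1", "s2", "s3"])
    M["s2"] = M["s1"]
    prep = cytokine_heatmap_prep(M)
    first_merge = prep["col_linkage"][0]
    assert first_merge[2] == pytest.approx(0.0, abs=1e-12)
    merged = {prep["scaled"].columns[int(first_merge[0])], prep["scaled"].columns[int(first_merge[1])]}
    assert merged == {"s1", "s2"}
    # identical columns end up adjacent in the leaf order
    order = prep["col_order"]
    assert abs(order.index("s1") - order.index("s2")) == 1


def test_heatmap_median_collapse(rng):
    M = pd.DataFrame(
        rng.normal(size=(4, 6)),
        index=[f"cyt{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    subtype_map = {f"s{i}": ("Vd1" if i < 3 else "Vd2") for i in range(6)}
    prep = cytokine_heatmap_prep(M, subtype_map)
    assert set(prep["scaled"].columns) == {"Vd1", "Vd2"}
    # verify the collapse itself on the unscaled medians
    collapsed = M[["s0", "s1", "s2"]].median(axis=1)
    merged = M.T.groupby(pd.Series(subtype_map)).median().T
    np.testing.assert_allclose(merged["Vd1"].to_numpy(), collapsed.to_numpy())
    with pytest.raises(ValueError):
        cytokine_heatmap_prep(M, {c: "one" for c in M.columns})


# --- packaged reference tables -----------------------------------------------------


def test_packaged_culture_counts_fold_statistics():
    from clonostate import resources

    counts = resources.load_culture_counts()
    series = [
        CultureSeries(sample_id=sid, days=grp["day"].tolist(), counts=grp["gd_count_millions"].tolist())
        for sid, grp in counts.sort_values(["sample_id", "day"]).groupby("sample_id")
    ]
    cohort = cohort_fold_expansion(series)
    assert cohort["n"] == 6
    assert cohort["mean"] > 1e5  # million-fold scale expansion
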