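"""Size factors, neighborhood normalization, FRep aggregation, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frepscreen import (
    absolute_size_factors,
    barcode_log_ratio,
    combine_replicates,
    compare_screens,
    gene_frep_score,
    neighborhood_normalize,
    score_screen,
    size_factors,
)
from frepscreen.scoring import MAD_TO_SD, depth_gauge


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def test_pure_depth_shift_gives_sqrt2_factors(rng):
    base = pd.Series(rng.integers(10, 1000, 200))
    counts = pd.DataFrame({"s1": base, "s2": 2 * base})
    factors = size_factors(counts)
    assert factors["s1"] == pytest.approx(1 / np.sqrt(2))
    assert factors["s2"] == pytest.approx(np.sqrt(2))


def test_single_sample_factor_is_one(rng):
    counts = pd.DataFrame({"only": rng.integers(1, 100, 100)})
    assert size_factors(counts)["only"] == pytest.approx(1.0)


def test_all_zero_sample_rejected_by_name(rng):
    counts = pd.DataFrame({"good": rng.integers(1, 50, 60), "dead": 0})
    with pytest.raises(ValueError, match="dead"):
        size_factors(counts)


def test_fallback_to_total_count_scaling_below_min_common(rng):
    base = rng.integers(1, 50, 20)
    counts = pd.DataFrame({"s1": base, "s2": 3 * base})
    factors = size_factors(counts, min_common=50)
    assert factors["s2"] / factors["s1"] == pytest.approx(3.0)


def test_median_of_ratios_robust_to_de_subset(rng):
    """With 10% shifted barcodes the median beats total-count scaling."""
    n = 1000
    mu = rng.lognormal(3, 1, n)
    shifted = np.ones(n)
    shifted[:100] = 4.0  # DE subset inflates sample 2 only
    true_ratio = 2.0
    errors_mor, errors_total = [], []
    for _ in range(10):
        c1 = rng.poisson(mu)
        c2 = rng.poisson(true_ratio * mu * shifted)
        counts = pd.DataFrame({"a": c1, "b": c2})
        f = size_factors(counts)
        est_mor = f["b"] / f["a"]
        est_total = c2.sum() / c1.sum()
        errors_mor.append(abs(np.log(est_mor / true_ratio)))
        errors_total.append(abs(np.log(est_total / true_ratio)))
    assert np.mean(errors_mor) < np.mean(errors_total)


def test_absolute_factors_absorb_single_sample_scaling(rng):
    base = rng.integers(5, 500, 300)
    counts = pd.DataFrame(
        {"a": rng.poisson(base), "b": rng.poisson(base), "c": rng.poisson(base)}
    )
    factors = absolute_size_factors(counts, reference_depth=1e4)
    scaled = counts.copy()
    scaled["b"] = scaled["b"] * 7
    factors7 = absolute_size_factors(scaled, reference_depth=1e4)
    assert factors7["b"] / factors["b"] == pytest.approx(7.0, rel=1e-12)
    assert factors7["a"] == pytest.approx(factors["a"], rel=1e-12)
    assert factors7["c"] == pytest.approx(factors["c"], rel=1e-12)


# ---------------------------------------------------------------------------
# log ratios
# ---------------------------------------------------------------------------


def test_equal_counts_zero_ratio():
    pellet = pd.Series([100], index=["b1"])
    total = pd.Series([100], index=["b1"])
    out = barcode_log_ratio(pellet, total, 1.0, 1.0)
    assert out.loc["b1", "log_ratio"] == 0.0


def test_zero_pellet_with_pseudocount():
    pellet = pd.Series([0], index=["b1"])
    total = pd.Series([100], index=["b1"])
    out = barcode_log_ratio(pellet, total, 1.0, 1.0, pseudocount=0.5)
    assert out.loc["b1", "log_ratio"] == pytest.approx(np.log2(0.5 / 100.5))
    assert out.loc["b1", "log_ratio"] == pytest.approx(-7.6510517, abs=1e-6)


def test_joint_scaling_with_recomputed_factors_leaves_ratio_unchanged(rng):
    base = rng.integers(1, 400, 250)
    counts = pd.DataFrame({"pellet": rng.poisson(base), "total": rng.poisson(base)})
    factors = absolute_size_factors(counts, reference_depth=5e4)
    out = barcode_log_ratio(
        counts["pellet"], counts["total"], factors["pellet"], factors["total"]
    )
    scaled = counts * 3
    factors3 = absolute_size_factors(scaled, reference_depth=5e4)
    out3 = barcode_log_ratio(
        scaled["pellet"], scaled["total"], factors3["pellet"], factors3["total"]
    )
    np.testing.assert_allclose(out3["log_ratio"], out["log_ratio"], atol=1e-12)


def test_depth_gauge_is_geometric_mean():
    counts = pd.DataFrame({"a": [10, 10], "b": [40, 40]})
    assert depth_gauge(counts) == pytest.approx(np.sqrt(20 * 80))


# ---------------------------------------------------------------------------
# neighborhood normalization
# ---------------------------------------------------------------------------


def _rows(log_ratio, abundance):
    return pd.DataFrame(
        {"log_ratio": log_ratio, "reference_abundance": abundance},
        index=[f"b{i}" for i in range(len(log_ratio))],
    )


def test_identical_log_ratios_give_zero_nns():
    rows = _rows(np.full(50, 1.3), 100 + np.arange(50))
    out = neighborhood_normalize(rows, window=11, min_count=20)
    assert (out["nns"] == 0).all()


def test_probe_two_robust_sds_above_center_scores_two():
    # window of 201: 100 ratios at -1, 100 at +1, probe at median + 2 * 1.4826 * MAD
    lr = np.concatenate([np.full(100, -1.0), [0.0], np.full(100, 1.0)])
    abundance = 1000.0 + np.arange(201)
    probe = 1.0 + 2.0 * MAD_TO_SD * 2.0  # median 1, MAD 2 with the probe included
    lr[100] = probe
    rows = _rows(lr, abundance)
    out = neighborhood_normalize(rows, window=201, min_count=20)
    assert out.loc["b100", "nns"] == pytest.approx(2.0)
    # brute-force the probe's full window
    med = np.median(lr)
    mad = np.median(np.abs(lr - med))
    assert out.loc["b100", "nns"] == pytest.approx(
        (probe - med) / (MAD_TO_SD * mad)
    )


def test_windows_match_brute_force_recomputation(rng):
    n, window = 300, 31
    rows = _rows(rng.normal(size=n), 50 + rng.random(n) * 1000)
    out = neighborhood_normalize(rows, window=window, min_count=20)
    lr = out["log_ratio"].to_numpy()
    half = window // 2
    for i in range(len(out)):
        lo, hi = max(0, i - half), min(len(out), i + half + 1)
        med = np.median(lr[lo:hi])
        mad = np.median(np.abs(lr[lo:hi] - med))
        assert out["nbhd_location"].iloc[i] == pytest.approx(med)
        assert out["nns"].iloc[i] == pytest.approx(
            (lr[i] - med) / max(MAD_TO_SD * mad, 1e-8)
        )


def test_null_calibration_of_nns(rng):
    n = 10_000
    rows = _rows(rng.normal(size=n), 20 + rng.random(n) * 5000)
    out = neighborhood_normalize(rows, window=201, min_count=20)
    assert abs(out["nns"].mean()) < 0.05
    assert 0.9 < out["nns"].std() < 1.1


@pytest.mark.parametrize(
    "kwargs,match",
    [
        ({"window": 10}, "odd"),
        ({"window": 1}, "odd|>= 3"),
        ({"window": 501}, "exceeds"),
    ],
)
def test_neighborhood_window_validation(rng, kwargs, match):
    rows = _rows(rng.normal(size=100), 100 + np.arange(100))
    with pytest.raises(ValueError, match=match):
        neighborhood_normalize(rows, min_count=20, **kwargs)


def test_neighborhood_needs_three_surviving_barcodes():
    rows = _rows(np.ones(5), [1, 2, 3, 50, 60])
    with pytest.raises(ValueError, match="at least 3"):
        neighborhood_normalize(rows, window=3, min_count=20)


# ---------------------------------------------------------------------------
# gene aggregation and replicate combination
# ---------------------------------------------------------------------------


def _library_from(frame_rows):
    from frepscreen import GuideLibrary

    return GuideLibrary(
        pd.DataFrame(
            frame_rows, columns=["barcode", "guide_id", "gene", "is_control"]
        )
    )


def test_single_guide_single_barcode_score_passes_through():
    lib = _library_from([("AAAAAA", "g1", "Y1", False)])
    scores = pd.DataFrame({"nns": [1.7]}, index=pd.Index(["AAAAAA"], name="barcode"))
    out = gene_frep_score(scores, lib)
    assert out["Y1"] == pytest.approx(1.7)


def test_gene_score_is_mean_over_guides():
    lib = _library_from(
        [
            ("AAAAAA", "g1", "Y1", False),
            ("CCCCCC", "g2", "Y1", False),
            ("GGGGGG", "g3", "Y1", False),
            ("TTTTTT", "g4", "Y2", False),
        ]
    )
    scores = pd.DataFrame(
        {"nns": [2.0, 0.0, 1.0]},
        index=pd.Index(["AAAAAA", "CCCCCC", "GGGGGG"], name="barcode"),
    )
    out = gene_frep_score(scores, lib)
    assert out["Y1"] == pytest.approx(1.0)
    assert np.isnan(out["Y2"])  # no surviving barcode


def test_combine_replicates_symmetric_scores():
    table = pd.DataFrame({"r1": [1.0], "r2": [-1.0], "r3": [1.0], "r4": [-1.0]},
                         index=["Y1"])
    out = combine_replicates(table)
    assert out.loc["Y1", "frep_score"] == 0.0
    assert out.loc["Y1", "t_stat"] == 0.0
    assert out.loc["Y1", "p_value"] == pytest.approx(1.0)


def test_combine_replicates_closed_form_t():
    table = pd.DataFrame(
        {"r1": [1.8], "r2": [2.2], "r3": [2.0], "r4": [2.0]}, index=["Y1"]
    )
    out = combine_replicates(table)
    sd = np.sqrt((0.2**2 + 0.2**2) / 3)  # 0.163299
    t_expected = 2.0 / (sd / 2.0)  # 24.4949
    assert out.loc["Y1", "frep_score"] == pytest.approx(2.0)
    assert out.loc["Y1", "t_stat"] == pytest.approx(t_expected, rel=1e-6)
    assert out.loc["Y1", "p_value"] == pytest.approx(
        2 * stats.t.sf(t_expected, df=3), rel=1e-9
    )
    # cross-check against scipy's own one-sample t-test
    ref = stats.ttest_1samp([1.8, 2.2, 2.0, 2.0], 0.0)
    assert out.loc["Y1", "t_stat"] == pytest.approx(ref.statistic)
    assert out.loc["Y1", "p_value"] == pytest.approx(ref.pvalue)


def test_combine_replicates_zero_variance_flagged_and_floored():
    table = pd.DataFrame({f"r{i}": [2.0] for i in range(1, 5)}, index=["Y1"])
    out = combine_replicates(table)
    assert out.loc["Y1", "frep_score"] == 2.0
    assert out.loc["Y1", "p_value"] == pytest.approx(1e-12)
    assert out.loc["Y1", "flag"] == "zero_variance"


def test_combine_replicates_insufficient_replicates_flagged():
    table = pd.DataFrame({"r1": [1.5], "r2": [np.nan]}, index=["Y1"])
    out = combine_replicates(table)
    assert out.loc["Y1", "frep_score"] == 1.5
    assert np.isnan(out.loc["Y1", "p_value"])
    assert out.loc["Y1", "flag"] == "insufficient_replicates"


# ---------------------------------------------------------------------------
# screen pipeline and comparisons
# ---------------------------------------------------------------------------


def test_score_screen_missing_pellet_names_pattern(small_library, small_screen):
    counts, _ = small_screen
    dropped = counts.drop(columns=[c for c in counts.columns if "pellet" in c])
    with pytest.raises(ValueError, match="pellet_rep"):
        score_screen(dropped, small_library)


def test_identical_screens_correlate_perfectly(rng):
    scores = pd.Series(rng.normal(size=100), index=[f"Y{i}" for i in range(100)])
    comparison = compare_screens(scores, scores.copy())
    assert comparison.pearson_r == pytest.approx(1.0)
    non_hits = comparison.table[comparison.table["score_a"] < 2.0]
    assert (non_hits["label"] == "neither").all()


def test_independent_null_screens_nearly_uncorrelated(rng):
    genes = [f"Y{i}" for i in range(1000)]
    a = pd.Series(rng.normal(size=1000), index=genes)
    b = pd.Series(rng.normal(size=1000), index=genes)
    assert abs(compare_screens(a, b).pearson_r) < 0.1


def test_interaction_labels():
    a = pd.Series({"alle": 3.5, "aggr": 0.5, "both": 2.5, "none": 0.1})
    b = pd.Series({"alle": 0.5, "aggr": 3.5, "both": 2.5, "none": 0.2})
    table = compare_screens(a, b).table
    assert table.loc["alle", "label"] == "alleviating"
    assert table.loc["aggr", "label"] == "aggravating"
    assert table.loc["both", "label"] == "shared"
    assert table.loc["none", "label"] == "neither"


def test_compare_requires_three_shared_genes():
    a = pd.Series({"Y1": 1.0, "Y2": 2.0})
    b = pd.Series({"Y1": 1.0, "Y2": 2.0})
    with pytest.raises(ValueError, match="3 shared"):
        compare_screens(a, b)
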