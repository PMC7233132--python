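"""Pearson cell-cell correlation, significance, and pseudo-space ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from tissuemap import (
    build_features,
    correlate,
    correlation_pvalue,
    pseudo_space,
    raster_scan_neighborhoods,
)
from tissuemap.neighborhoods import NeighborhoodSet
from tissuemap.regions import FeatureMatrix, RegionAssignment

from conftest import random_cell_table


def _nbhd_from_counts(counts: pd.DataFrame, samples=None) -> NeighborhoodSet:
    n = len(counts)
    return NeighborhoodSet(
        centers=pd.DataFrame(
            {
                "sample_id": samples if samples is not None else "s1",
                "x_um": np.arange(n, dtype=float) * 15.0,
                "y_um": 0.0,
                "z_um": 0.0,
            }
        ),
        radius=30.0,
        geometry={"s1": "cylinder2D"},
        counts=counts.reset_index(drop=True),
        mfi_sums=pd.DataFrame(index=range(n)),
    )


def _closed_form_r(x, y):
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


def test_identical_counts_correlate_perfectly(rng):
    a = rng.integers(0, 20, size=30).astype(float)
    counts = pd.DataFrame({"A": a, "B": a})
    result = correlate(_nbhd_from_counts(counts))
    assert result.r_per_sample["s1"].loc["A", "B"] == pytest.approx(1.0)


def test_perfect_anticorrelation():
    counts = pd.DataFrame({"A": [0, 1, 2, 3], "B": [3, 2, 1, 0]}, dtype=float)
    result = correlate(_nbhd_from_counts(counts))
    assert result.r_per_sample["s1"].loc["A", "B"] == pytest.approx(-1.0)


def test_matrix_matches_closed_form(rng):
    counts = pd.DataFrame(
        rng.integers(0, 15, size=(200, 6)).astype(float),
        columns=list("ABCDEF"),
    )
    r = correlate(_nbhd_from_counts(counts)).r_per_sample["s1"]
    for a in counts.columns:
        for b in counts.columns:
            expected = _closed_form_r(counts[a].to_numpy(), counts[b].to_numpy())
            assert r.loc[a, b] == pytest.approx(expected, abs=1e-12)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    counts=arrays(
        np.float64,
        shape=st.tuples(st.integers(5, 40), st.just(3)),
        elements=st.integers(0, 30).map(float),
    )
)
def test_correlation_closed_form_property(counts):
    df = pd.DataFrame(counts, columns=list("ABC"))
    r = correlate(_nbhd_from_counts(df)).r_per_sample["s1"]
    for a in df.columns:
        for b in df.columns:
            x, y = df[a].to_numpy(), df[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                assert np.isnan(r.loc[a, b])
            else:
                expected = _closed_form_r(x, y)
                assert r.loc[a, b] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_phenotype_reported_missing(rng):
    counts = pd.DataFrame(
        {"A": rng.integers(0, 9, size=20).astype(float), "B": 4.0}
    )
    r = correlate(_nbhd_from_counts(counts)).r_per_sample["s1"]
    assert np.isnan(r.loc["A", "B"]) and np.isnan(r.loc["B", "B"])
    assert r.loc["A", "A"] == pytest.approx(1.0)


def test_region_scope_matches_standalone_recomputation(rng):
    counts = pd.DataFrame(
        rng.integers(0, 12, size=(60, 3)).astype(float), columns=list("ABC")
    )
    nbhd = _nbhd_from_counts(counts)
    region = np.tile([1, 2], 30)
    assignment = RegionAssignment(region=region)
    for label in (1, 2):
        scoped = correlate(nbhd, scope=str(label), assignment=assignment)
        standalone = correlate(_nbhd_from_counts(counts.loc[region == label]))
        pd.testing.assert_frame_equal(
            scoped.r_per_sample["s1"], standalone.r_per_sample["s1"]
        )


def test_cohort_mean_is_unweighted_across_samples(rng):
    counts = pd.DataFrame(
        rng.integers(0, 12, size=(80, 3)).astype(float), columns=list("ABC")
    )
    samples = np.repeat(["s1", "s2"], 40)
    nbhd = _nbhd_from_counts(counts, samples=samples)
    nbhd.geometry["s2"] = "cylinder2D"
    result = correlate(nbhd)
    manual = (
        result.r_per_sample["s1"].to_numpy() + result.r_per_sample["s2"].to_numpy()
    ) / 2
    np.testing.assert_allclose(result.r_mean.to_numpy(), manual, atol=1e-12)


def test_pooled_mode_concatenates(rng):
    counts = pd.DataFrame(
        rng.integers(0, 12, size=(80, 2)).astype(float), columns=list("AB")
    )
    samples = np.repeat(["s1", "s2"], 40)
    nbhd = _nbhd_from_counts(counts, samples=samples)
    nbhd.geometry["s2"] = "cylinder2D"
    pooled = correlate(nbhd, pooled=True)
    expected = _closed_form_r(counts["A"].to_numpy(), counts["B"].to_numpy())
    assert pooled.r_mean.loc["A", "B"] == pytest.approx(expected, abs=1e-12)


def test_too_few_neighborhoods_rejected():
    counts = pd.DataFrame({"A": [1.0, 2.0], "B": [2.0, 1.0]})
    with pytest.raises(ValueError):
        correlate(_nbhd_from_counts(counts))


# -- p-values --------------------------------------------------------------


def test_pvalue_zero_correlation_is_one():
    assert correlation_pvalue(0.0, n=10) == pytest.approx(1.0)


def test_pvalue_matches_t_cdf_oracle():
    # r = 1/sqrt(2), n = 6 -> t = 2.0 exactly, df = 4
    r = 1.0 / np.sqrt(2.0)
    expected = 2.0 * stats.t.sf(2.0, df=4)
    assert correlation_pvalue(r, n=6) == pytest.approx(expected, abs=1e-9)


def test_pvalue_monotone_in_abs_r():
    rs = np.linspace(0.0, 0.99, 50)
    ps = np.array([correlation_pvalue(r, n=20) for r in rs])
    assert (np.diff(ps) < 0).all()
    np.testing.assert_allclose(
        [correlation_pvalue(-r, n=20) for r in rs], ps, atol=1e-12
    )


def test_pvalue_conventions_and_errors():
    assert correlation_pvalue(1.0, n=5) == 0.0
    assert correlation_pvalue(-1.0, n=5) == 0.0
    assert np.isnan(correlation_pvalue(np.nan, n=5))
    with pytest.raises(ValueError):
        correlation_pvalue(0.5, n=2)


# -- pseudo-space ----------------------------------------------------------


def _features(values, names):
    return FeatureMatrix(np.asarray(values, dtype=float), "composition", tuple(names))


def test_ordering_descends_in_negative_weighted_feature(rng):
    b = np.linspace(1.0, 0.0, 40)
    feats = _features(np.column_stack([b, 1 - b]), ("B", "T"))
    result = pseudo_space(feats, {"B": -1.0, "T": 1.0}, window=1)
    np.testing.assert_array_equal(result.order, np.arange(40))  # already sorted
    shuffled = rng.permutation(40)
    feats2 = _features(np.column_stack([b[shuffled], 1 - b[shuffled]]), ("B", "T"))
    result2 = pseudo_space(feats2, {"B": -1.0, "T": 1.0}, window=1)
    np.testing.assert_allclose(b[shuffled][result2.order], np.sort(b)[::-1])


def test_window_one_is_identity_smoothing(rng):
    values = rng.random((30, 2))
    feats = _features(values, ("A", "B"))
    result = pseudo_space(feats, {"A": 1.0}, window=1)
    sorted_values = values[result.order]
    expected = sorted_values / sorted_values.max(axis=0)
    np.testing.assert_allclose(result.curves.to_numpy(), expected, atol=1e-12)


def test_curve_maxima_are_one(rng):
    values = rng.random((100, 3))
    values[:, 2] = 0.0  # all-zero feature stays zero
    feats = _features(values, ("A", "B", "C"))
    result = pseudo_space(feats, {"A": 1.0}, window=7)
    maxima = result.curves.max(axis=0)
    assert maxima["A"] == pytest.approx(1.0)
    assert maxima["B"] == pytest.approx(1.0)
    assert maxima["C"] == 0.0


def test_ordering_invariant_to_positive_weight_rescaling(rng):
    values = rng.random((50, 2))
    feats = _features(values, ("A", "B"))
    r1 = pseudo_space(feats, {"A": -1.0, "B": 2.0}, window=5)
    r2 = pseudo_space(feats, {"A": -10.0, "B": 20.0}, window=5)
    np.testing.assert_array_equal(r1.order, r2.order)


def test_pseudo_space_errors(rng):
    feats = _features(rng.random((10, 2)), ("A", "B"))
    with pytest.raises(ValueError):
        pseudo_space(feats, {"A": 1.0}, window=0)
    with pytest.raises(ValueError):
        pseudo_space(feats, {"A": 0.0, "B": 0.0}, window=3)
    with pytest.raises(ValueError):
        pseudo_space(feats, {"Z": 1.0}, window=3)


def test_pseudo_space_on_tissue_curves_cross(rng):
    # two-compartment strip: B-rich left half, T-rich right half
    cells = random_cell_table(
        rng, 800, phenotypes=("B", "T"), box=((0, 0, 0), (400, 100, 0))
    )
    left = cells.data["x_um"] < 200
    cells.data.loc[left, "phenotype"] = rng.choice(["B", "T"], p=[0.9, 0.1], size=left.sum())
    cells.data.loc[~left, "phenotype"] = rng.choice(
        ["B", "T"], p=[0.1, 0.9], size=(~left).sum()
    )
    nbhd = raster_scan_neighborhoods(cells, 30.0).nonempty()
    feats = build_features(nbhd, "composition")
    result = pseudo_space(feats, {"B": -1.0, "T": 1.0}, window=25)
    b_curve = result.curves["B"].to_numpy()
    t_curve = result.curves["T"].to_numpy()
    # B dominates the left end, T the right end, with a single crossover
    assert b_curve[0] > t_curve[0]
    assert t_curve[-1] > b_curve[-1]
    sign_changes = np.sum(np.diff(np.sign(b_curve - t_curve)) != 0)
    assert sign_changes == 1
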