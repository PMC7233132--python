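"""Feature normalization, Davies-Bouldin, SOM clustering, model selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, davies_bouldin_score

from tissuemap import (
    annotate_regions,
    assign_regions,
    build_features,
    davies_bouldin,
    raster_scan_neighborhoods,
    select_region_count,
    train_som,
)
from tissuemap.regions import FeatureMatrix, RegionAssignment

from conftest import random_cell_table


def _feature_matrix(values, mode="raw"):
    values = np.asarray(values, dtype=float)
    names = tuple(f"f{i}" for i in range(values.shape[1]))
    return FeatureMatrix(values, mode, names)


# -- build_features --------------------------------------------------------


def test_composition_row_normalization(rng):
    cells = random_cell_table(rng, 200)
    nbhd = raster_scan_neighborhoods(cells, 25.0)
    feats = build_features(nbhd, "composition")
    sums = feats.values.sum(axis=1)
    nonzero = nbhd.counts.sum(axis=1).to_numpy() > 0
    np.testing.assert_allclose(sums[nonzero], 1.0, atol=1e-12)
    assert (sums[~nonzero] == 0).all()


def test_composition_of_equal_counts_row(rng):
    cells = random_cell_table(rng, 2, phenotypes=("A", "B"), box=((0, 0, 0), (1, 1, 0)))
    cells.data["phenotype"] = ["A", "B"]
    cells.data[["x_um", "y_um"]] = 0.0
    nbhd = raster_scan_neighborhoods(cells, 10.0)
    feats = build_features(nbhd, "composition")
    np.testing.assert_allclose(feats.values, [[0.5, 0.5]])


def test_standardized_moments(rng):
    cells = random_cell_table(rng, 400)
    nbhd = raster_scan_neighborhoods(cells, 25.0)
    feats = build_features(nbhd, "standardized")
    np.testing.assert_allclose(feats.values.mean(axis=0), 0.0, atol=1e-9)
    sds = feats.values.std(axis=0, ddof=1)
    degenerate = feats.column_sds == 0
    np.testing.assert_allclose(sds[~degenerate], 1.0, atol=1e-9)


def test_standardized_arithmetic_sequence(rng):
    # counts column (1, 2, 3) standardizes to (-1, 0, 1): sample-SD z-score
    from tissuemap.neighborhoods import NeighborhoodSet

    nbhd = NeighborhoodSet(
        centers=pd.DataFrame(
            {"sample_id": "s1", "x_um": [0.0, 10.0, 20.0], "y_um": 0.0, "z_um": 0.0}
        ),
        radius=10.0,
        geometry={"s1": "cylinder2D"},
        counts=pd.DataFrame({"A": [1, 2, 3]}),
        mfi_sums=pd.DataFrame(index=range(3)),
    )
    feats = build_features(nbhd, "standardized")
    np.testing.assert_allclose(feats.values[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_zero_variance_column_warns_and_zeroes(rng, caplog):
    cells = random_cell_table(rng, 50, phenotypes=("A", "B"))
    nbhd = raster_scan_neighborhoods(cells, 25.0)
    nbhd.counts["B"] = 3  # constant column
    with caplog.at_level("WARNING", logger="tissuemap.regions"):
        feats = build_features(nbhd, "standardized")
    assert "zero-variance" in caplog.text
    assert (feats.values[:, list(feats.feature_names).index("B")] == 0).all()


def test_include_mfi_appends_channels(rng):
    cells = random_cell_table(rng, 100)
    nbhd = raster_scan_neighborhoods(cells, 25.0)
    feats = build_features(nbhd, "raw", include_mfi=True)
    assert feats.feature_names == tuple(nbhd.counts.columns) + tuple(nbhd.mfi_sums.columns)


# -- Davies-Bouldin --------------------------------------------------------


def test_db_point_mass_clusters_zero():
    X = np.array([[0.0, 0.0]] * 5 + [[10.0, 0.0]] * 5)
    labels = np.array([0] * 5 + [1] * 5)
    assert davies_bouldin(X, labels) == 0.0


def test_db_hand_computed_example():
    # clusters {0,1} and {10,11} in 1D: s_i = 0.5, d = 10, DB = 0.1
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([0, 0, 1, 1])
    assert davies_bouldin(X, labels) == pytest.approx(0.1, abs=1e-12)


def test_db_matches_sklearn_on_random_labelings(rng):
    X = rng.normal(size=(120, 4))
    for _ in range(50):
        k = int(rng.integers(2, 6))
        labels = rng.integers(0, k, size=len(X))
        if len(np.unique(labels)) < 2:
            continue
        ours = davies_bouldin(X, labels)
        theirs = davies_bouldin_score(X, labels)
        assert ours == pytest.approx(theirs, abs=1e-9)


def test_db_random_worse_than_kmeans(rng):
    centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
    X = np.vstack([rng.normal(c, 0.3, size=(40, 2)) for c in centers])
    km = KMeans(n_clusters=4, n_init=5, random_state=0).fit_predict(X)
    rand = rng.integers(0, 4, size=len(X))
    assert davies_bouldin(X, km) < davies_bouldin(X, rand)


def test_db_rejects_fewer_than_two_clusters():
    with pytest.raises(ValueError):
        davies_bouldin(np.zeros((4, 2)), np.zeros(4, dtype=int))


# -- SOM -------------------------------------------------------------------


def test_som_fixed_points_recover_partition(rng):
    distinct = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
    X = np.repeat(distinct, 20, axis=0)
    prototypes, labels = train_som(_feature_matrix(X), nr=3, seed=1)
    # each prototype sits exactly on one of the points
    d = np.linalg.norm(prototypes[:, None, :] - distinct[None, :, :], axis=2)
    assert sorted(d.argmin(axis=1)) == [0, 1, 2]
    assert np.allclose(d.min(axis=1), 0.0)
    truth = np.repeat(np.arange(3), 20)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_som_two_blobs_matches_kmeans(rng):
    X = np.vstack(
        [rng.normal([0, 0], 0.2, size=(60, 2)), rng.normal([6, 6], 0.2, size=(60, 2))]
    )
    _, labels = train_som(_feature_matrix(X), nr=2, seed=3)
    km = KMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(X)
    assert adjusted_rand_score(km, labels) == 1.0


def test_som_deterministic_across_runs(rng):
    X = rng.normal(size=(150, 4))
    results = [train_som(_feature_matrix(X), nr=4, seed=11) for _ in range(5)]
    for prototypes, labels in results[1:]:
        np.testing.assert_array_equal(labels, results[0][1])
        np.testing.assert_array_equal(prototypes, results[0][0])


def test_som_parameter_errors(rng):
    X = _feature_matrix(rng.normal(size=(5, 2)))
    with pytest.raises(ValueError):
        train_som(X, nr=6, seed=0)
    with pytest.raises(ValueError):
        train_som(X, nr=1, seed=0)


# -- model selection -------------------------------------------------------


def _four_blobs(rng, n_per=50, sd=0.1):
    centers = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    return np.vstack([rng.normal(c, sd, size=(n_per, 2)) for c in centers])


def test_sweep_selects_four_blobs(rng):
    hits = 0
    for seed in range(20):
        X = _four_blobs(np.random.default_rng(seed))
        model = select_region_count(_feature_matrix(X), (2, 8), seed=seed)
        hits += model.nr == 4
    assert hits >= 18  # >= 90% of 20 seeds


def test_db_curve_shape_single_blob(rng):
    X = rng.normal(size=(80, 3))
    model = select_region_count(_feature_matrix(X), (2, 5), seed=0)
    assert sorted(model.db_curve) == [2, 3, 4, 5]
    assert model.nr == min(model.db_curve, key=model.db_curve.get)


def test_duplicated_dataset_same_nr(rng):
    X = _four_blobs(rng)
    m1 = select_region_count(_feature_matrix(X), (2, 8), seed=5)
    m2 = select_region_count(_feature_matrix(np.vstack([X, X])), (2, 8), seed=5)
    assert m1.nr == m2.nr


def test_insufficient_data_error():
    with pytest.raises(ValueError):
        select_region_count(_feature_matrix(np.zeros((3, 2))), (2, 3), seed=0)


def test_feature_column_permutation_leaves_labels(rng):
    X = _four_blobs(rng)
    X = np.column_stack([X, rng.normal(size=len(X))])
    fm = FeatureMatrix(X, "raw", ("a", "b", "c"))
    perm = [2, 0, 1]
    fm_perm = FeatureMatrix(X[:, perm], "raw", ("c", "a", "b"))
    _, labels = train_som(fm, nr=4, seed=2)
    _, labels_perm = train_som(fm_perm, nr=4, seed=2)
    assert adjusted_rand_score(labels, labels_perm) == 1.0


# -- annotation ------------------------------------------------------------


def test_annotation_merges_labels():
    assignment = RegionAssignment(region=np.array([1, 2, 3, 4, 3]))
    annotated = annotate_regions(assignment, {3: "TZ", 4: "TZ"})
    labels = annotated.labels()
    assert (labels[np.isin(annotated.region, [3, 4])] == "TZ").all()
    np.testing.assert_array_equal(annotated.region, assignment.region)


def test_empty_annotation_map_is_identity():
    assignment = RegionAssignment(region=np.array([1, 2]))
    annotated = annotate_regions(assignment, {})
    assert annotated.annotations == {}


def test_unknown_region_key_rejected():
    assignment = RegionAssignment(region=np.array([1, 2]))
    with pytest.raises(ValueError, match="unknown region"):
        annotate_regions(assignment, {9: "TZ"})


def test_merge_pigeonhole(rng):
    region = rng.integers(1, 7, size=100)
    assignment = RegionAssignment(region=region)
    mapping = {int(r): f"group{int(r) % 2}" for r in np.unique(region)}
    annotated = annotate_regions(assignment, mapping)
    assert len(np.unique(annotated.labels())) <= len(np.unique(region))


def test_assign_regions_is_one_based(rng):
    X = _four_blobs(rng)
    fm = _feature_matrix(X)
    model = select_region_count(fm, (2, 6), seed=0)
    assignment = assign_regions(model, fm)
    assert assignment.region.min() >= 1
    assert assignment.region.max() <= model.nr
    assert len(assignment.region) == len(X)
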