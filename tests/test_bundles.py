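"""Feature standardization and SOM bundle-clustering tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from esdrought import (
    build_feature_matrix,
    generate_cluster_features,
    som_cluster,
    summarize_bundles,
)
from esdrought.bundles import FeatureMatrix, SelfOrganizingMap, standardize
from esdrought.drought import summarize_drought
from esdrought.exceptions import ConfigurationError, InsufficientDataError


def _matrix(data, names=None):
    data = np.asarray(data, dtype=float)
    names = names or [f"f{i}" for i in range(data.shape[1])]
    z, means, sds = standardize(data, names)
    return FeatureMatrix(z, names, means, sds,
                         cell_index=np.arange(len(data)),
                         grid_shape=(len(data), 1))


def test_two_point_zscore_closed_form():
    z, _, _ = standardize(np.array([[0.0], [1.0]]), ["a"])
    assert z[:, 0] == pytest.approx([-np.sqrt(2) / 2, np.sqrt(2) / 2])


def test_standardization_idempotent_and_errors():
    rng = np.random.default_rng(1)
    data = rng.normal(size=(200, 3))
    z1, _, _ = standardize(data, list("abc"))
    z2, _, _ = standardize(z1, list("abc"))
    assert np.allclose(z1, z2, atol=1e-12)
    with pytest.raises(ConfigurationError, match="b"):
        standardize(np.column_stack([data[:, 0], np.full(200, 7.0)]), ["a", "b"])


def test_build_feature_matrix_from_landscape(small_landscape, small_es):
    summary = summarize_drought(
        small_landscape.variables["SPEI"].astype(float), small_landscape.mask
    )
    fm = build_feature_matrix(small_es, summary.spei_f)
    assert fm.names == ["WR", "SC", "CS", "FS", "SPEI_F"]
    assert fm.values.shape[0] == int(small_landscape.mask.sum())
    assert np.allclose(fm.values.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(fm.values.std(axis=0, ddof=1), 1.0, atol=1e-9)
    per_year = build_feature_matrix(small_es, summary.spei_f, period_stat="per-year")
    assert per_year.values.shape[0] == fm.values.shape[0] * small_landscape.n_years


def test_som_recovers_separated_clusters():
    centroids = np.zeros((4, 5))
    for i in range(1, 4):
        centroids[i, i - 1] = 8.0  # pairwise separation >= 8 SD
    data, truth = generate_cluster_features(centroids, n=3000, sd=1.0, seed=4)
    fm = _matrix(data)
    assignment = som_cluster(fm, k=4, epochs=50, seed=11)
    assert assignment.realized_k == 4
    assert adjusted_rand_score(truth, assignment.labels) >= 0.9


def test_som_determinism_and_duplicate_consistency():
    data, _ = generate_cluster_features(np.diag([6.0, 6.0, 6.0]), n=600, seed=2)
    fm = _matrix(data)
    a = som_cluster(fm, k=3, grid_shape=(1, 3), epochs=30, seed=5)
    b = som_cluster(fm, k=3, grid_shape=(1, 3), epochs=30, seed=5)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.codebook, b.codebook)
    # duplicated rows always land in the same unit
    dup = _matrix(np.vstack([data, data]))
    d = som_cluster(dup, k=3, grid_shape=(1, 3), epochs=30, seed=5)
    assert np.array_equal(d.labels[: len(data)], d.labels[len(data):])


def test_som_k1_and_quantization_error_bound():
    rng = np.random.default_rng(8)
    data = rng.normal(size=(300, 4))
    fm = _matrix(data)
    one = som_cluster(fm, k=1, grid_shape=(1, 1), epochs=20, seed=0)
    assert set(one.labels) == {1}
    trained = som_cluster(fm, k=4, epochs=50, seed=0)
    grand = np.linalg.norm(fm.values - fm.values.mean(axis=0), axis=1).mean()
    assert trained.quantization_error <= grand + 1e-12
    with pytest.raises(InsufficientDataError):
        som_cluster(_matrix(rng.normal(size=(20, 2))), k=4)


def test_summaries_recover_centroids_and_degenerate_bundle():
    centroids = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    data, truth = generate_cluster_features(centroids, n=1500, sd=0.5, seed=3)
    fm = _matrix(data)
    assignment = som_cluster(fm, k=3, grid_shape=(1, 3), epochs=50, seed=1)
    table = summarize_bundles(assignment, fm)
    # map each bundle to its nearest true centroid and check the means
    for b in range(1, 4):
        sub = table[table.bundle == b].sort_values("feature")
        means = sub["mean"].to_numpy()
        dists = np.linalg.norm(centroids - means, axis=1)
        assert dists.min() <= 0.1  # within 0.1 of a planted centroid (SD units ~ 0.5)
    # single-row bundle statistics
    single = FeatureMatrix(np.array([[1.0], [2.0], [50.0]]), ["a"],
                           np.zeros(1), np.ones(1), np.arange(3), (3, 1))
    from esdrought.bundles import BundleAssignment

    asg = BundleAssignment(np.array([1, 1, 2]), np.zeros((2, 1)), 0.0, (3, 1),
                           np.arange(3), 2)
    t = summarize_bundles(asg, single)
    row = t[(t.bundle == 2) & (t.feature == "a")].iloc[0]
    assert row["median"] == row["mean"] == 50.0
    assert row.iqr_high - row.iqr_low == 0.0


def test_relabeling_permutes_summary_only():
    data, _ = generate_cluster_features(np.diag([7.0, 7.0]), n=400, seed=6)
    fm = _matrix(data)
    asg = som_cluster(fm, k=2, grid_shape=(1, 2), epochs=30, seed=2)
    t1 = summarize_bundles(asg, fm)
    swapped = asg
    swapped.labels = 3 - asg.labels  # swap bundle ids 1 <-> 2
    t2 = summarize_bundles(swapped, fm)
    a = t1.sort_values(["bundle", "feature"]).reset_index(drop=True)
    b = t2.replace({"bundle": {1: 2, 2: 1}}).sort_values(["bundle", "feature"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)
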