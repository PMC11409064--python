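import numpy as np
import pandas as pd
import pytest

from conftest import metric_frame
from phagecomp.composition import METRIC_NAMES
from phagecomp.pca import (
    GENERATED_FAMILY,
    family_centroids,
    fit_pca,
    nearest_family_of_outliers,
    nn_clustering,
    weighted_distance,
)


@pytest.fixture()
def space():
    return fit_pca(metric_frame(60, 20, seed=11, shift={"gc": -0.1}))


def test_fit_pca_basic_invariants(space):
    assert space.variance_share.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(space.variance_share) <= 1e-12).all()  # nonincreasing
    np.testing.assert_allclose(space.coordinates.mean(axis=0), 0.0, atol=1e-9)
    # loadings orthonormal
    p = space.loadings.shape[0]
    np.testing.assert_allclose(space.loadings.T @ space.loadings, np.eye(p), atol=1e-9)
    # transform of the training matrix reproduces coordinates
    frame = metric_frame(60, 20, seed=11, shift={"gc": -0.1})
    np.testing.assert_allclose(space.transform(frame), space.coordinates.to_numpy(), atol=1e-9)


def test_fit_pca_dominant_direction():
    rng = np.random.default_rng(0)
    t = rng.normal(size=100)
    frame = metric_frame(100, 0, seed=2)
    # one strong shared direction across all metrics
    for m in METRIC_NAMES:
        frame[m] = frame[m].std() * 0.05 * rng.normal(size=100) + t
    share = fit_pca(frame).variance_share
    assert share[0] > 0.9


def test_fit_pca_rejects_constant_column_and_tiny_n():
    frame = metric_frame(30, 0, seed=1)
    frame["CpG"] = 1.0
    with pytest.raises(ValueError, match="CpG"):
        fit_pca(frame)
    with pytest.raises(ValueError):
        fit_pca(metric_frame(10, 5, seed=1))


def test_weighted_distance_oracle_and_metric_properties(space):
    rng = np.random.default_rng(5)
    w = space.variance_share
    for _ in range(50):
        a, b, c = rng.normal(size=(3, len(w)))
        d_ab = weighted_distance(space, a, b)
        brute = np.sqrt(np.sum((w * a - w * b) ** 2))
        assert d_ab == pytest.approx(brute, rel=1e-12)
        assert weighted_distance(space, a, a) == 0.0
        assert d_ab == pytest.approx(weighted_distance(space, b, a), rel=1e-12)
        assert d_ab <= weighted_distance(space, a, c) + weighted_distance(space, c, b) + 1e-12


def _blob_frame(centers: dict[str, np.ndarray], n_each: int, seed: int, spread=0.05,
                n_generated: int = 0, generated_center: np.ndarray | None = None) -> pd.DataFrame:
    """Families as tight Gaussian blobs in metric space."""
    rng = np.random.default_rng(seed)
    rows, fams, prov = [], [], []
    for fam, center in centers.items():
        rows.append(center + rng.normal(scale=spread, size=(n_each, 19)))
        fams += [fam] * n_each
        prov += ["natural"] * n_each
    if n_generated:
        rows.append(generated_center + rng.normal(scale=spread, size=(n_generated, 19)))
        fams += [None] * n_generated
        prov += ["generated"] * n_generated
    X = np.vstack(rows)
    frame = pd.DataFrame(X, columns=list(METRIC_NAMES),
                         index=[f"s{i}" for i in range(len(X))])
    frame["provenance"] = prov
    frame["family"] = fams
    return frame


def test_nn_clustering_separated_blobs():
    rng = np.random.default_rng(0)
    centers = {"FamA": rng.normal(size=19), "FamB": rng.normal(size=19) + 8.0}
    space = fit_pca(_blob_frame(centers, 15, seed=3))
    rates = nn_clustering(space, min_members=10)
    assert (rates["cluster_rate"] == 1.0).all()
    assert (rates["expected_rate"] == 0.5).all()
    assert (rates["p_binomial"] < 0.01).all()


def test_nn_clustering_random_labels_near_null():
    rng = np.random.default_rng(1)
    frame = _blob_frame({"FamA": np.zeros(19)}, 200, seed=4, spread=1.0)
    labels = np.array(["FamA"] * 100 + ["FamB"] * 100)
    rng.shuffle(labels)
    frame["family"] = labels
    space = fit_pca(frame)
    rates = nn_clustering(space, min_members=10)
    for _, row in rates.iterrows():
        sd = np.sqrt(row["expected_rate"] * (1 - row["expected_rate"]) / row["n_members"])
        assert abs(row["cluster_rate"] - row["expected_rate"]) < 3 * sd


def test_nn_clustering_invariant_to_row_order():
    rng = np.random.default_rng(2)
    centers = {"FamA": np.zeros(19), "FamB": np.full(19, 3.0), "FamC": np.full(19, -3.0)}
    frame = _blob_frame(centers, 12, seed=5)
    space1 = fit_pca(frame)
    perm = rng.permutation(len(frame))
    space2 = fit_pca(frame.iloc[perm])
    r1 = nn_clustering(space1, min_members=10)["cluster_rate"]
    r2 = nn_clustering(space2, min_members=10)["cluster_rate"]
    pd.testing.assert_series_equal(r1, r2)


def test_family_centroids_brute_force_oracle():
    rng = np.random.default_rng(6)
    centers = {"FamA": rng.normal(size=19), "FamB": rng.normal(size=19),
               "FamC": rng.normal(size=19)}
    frame = _blob_frame(centers, 30, seed=7, spread=0.3,
                        n_generated=30, generated_center=rng.normal(size=19))
    space = fit_pca(frame)
    table = family_centroids(space, min_members=25)
    labels = space.group_labels()
    W = space.weighted_coordinates
    for fam, row in table.iterrows():
        members = W[labels == fam].to_numpy()
        own = members.mean(axis=0)
        dists = np.linalg.norm(members - own, axis=1)
        assert row["within_10th"] == pytest.approx(np.percentile(dists, 10))
        assert row["within_median"] == pytest.approx(np.percentile(dists, 50))
        assert row["within_90th"] == pytest.approx(np.percentile(dists, 90))
        assert row["within_10th"] <= row["within_median"] <= row["within_90th"]
        others = [g for g in table.index if g != fam]
        cumulative = sum(
            np.linalg.norm(own - W[labels == g].to_numpy().mean(axis=0)) for g in others
        )
        assert row["cumulative_distance"] == pytest.approx(cumulative)
        if fam != GENERATED_FAMILY:
            gen = W[labels == GENERATED_FAMILY].to_numpy().mean(axis=0)
            assert row["dist_to_generated_centroid"] == pytest.approx(np.linalg.norm(own - gen))


def test_family_centroids_identical_members_zero_percentiles():
    frame = _blob_frame({"FamA": np.full(19, 2.0), "FamB": np.zeros(19)}, 30, seed=8, spread=0.2)
    frame.loc[frame["family"] == "FamA", list(METRIC_NAMES)] = 2.0
    # keep metrics non-constant overall via FamB noise
    space = fit_pca(frame)
    row = family_centroids(space, min_members=25).loc["FamA"]
    assert row["within_10th"] == pytest.approx(0.0, abs=1e-9)
    assert row["within_90th"] == pytest.approx(0.0, abs=1e-9)


def test_nearest_family_of_outliers_planted():
    rng = np.random.default_rng(9)
    centers = {"FamA": np.zeros(19), "FamB": np.full(19, 6.0)}
    frame = _blob_frame(centers, 25, seed=10, spread=0.05,
                        n_generated=30, generated_center=np.full(19, -6.0))
    # plant 10 generated points essentially on top of distinct FamB members
    gen_ids = frame.index[frame["provenance"] == "generated"][:10]
    famb_anchor = frame.loc[frame["family"] == "FamB", list(METRIC_NAMES)].iloc[:10].to_numpy()
    frame.loc[gen_ids, list(METRIC_NAMES)] = famb_anchor + rng.normal(scale=1e-4, size=(10, 19))
    space = fit_pca(frame)
    tally = nearest_family_of_outliers(space)
    assert tally.loc["FamB", "count"] == 10
    # conservation: tally total equals the number of non-clustering focal members
    labels = space.group_labels()
    rates = nn_clustering(space, min_members=10)
    non_clustering = rates.loc[GENERATED_FAMILY, "n_members"] - rates.loc[GENERATED_FAMILY, "n_clustered"]
    assert tally["count"].sum() == non_clustering


def test_nearest_family_of_outliers_empty_when_all_cluster():
    centers = {"FamA": np.zeros(19), "FamB": np.full(19, 8.0)}
    frame = _blob_frame(centers, 20, seed=11, spread=0.05,
                        n_generated=20, generated_center=np.full(19, -8.0))
    tally = nearest_family_of_outliers(fit_pca(frame))
    assert len(tally) == 0
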