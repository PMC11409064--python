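"""Weighted-PCA compositional space and family clustering statistics.

PCA is fitted on the scaled (unit-variance) 19-metric matrix of ALL
genomes. Distances in the 19-dimensional PC space are Euclidean after each
component is multiplied by its variance share (the proportion of total
variance that component explains), so components explaining more variance
dominate the geometry without any arbitrary component truncation.

Family clustering is quantified by the rate at which a genome's single
nearest neighbour (in the weighted space) belongs to its own family,
compared against the random-association null N_f / N by a one-sided
binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .composition import METRIC_NAMES
from .sequence_io import GENERATED

logger = logging.getLogger(__name__)

#: pseudo-family label under which generated sequences enter the family analyses
GENERATED_FAMILY = "transformer-generated"


@dataclass
class PcaSpace:
    """A fitted compositional PC space and the coordinates of its genomes."""

    loadings: np.ndarray          # p x p, columns = components
    variance_share: np.ndarray    # length p, nonincreasing, sums to 1
    center: np.ndarray
    scale: np.ndarray
    coordinates: pd.DataFrame     # n x p raw PC scores, indexed by genome id
    meta: pd.DataFrame            # provenance / family / quality_bin per genome
    metric_names: tuple[str, ...] = METRIC_NAMES

    @property
    def weighted_coordinates(self) -> pd.DataFrame:
        return self.coordinates * self.variance_share

    def transform(self, metrics: pd.DataFrame) -> np.ndarray:
        z = (metrics[list(self.metric_names)].to_numpy() - self.center) / self.scale
        return z @ self.loadings

    def group_labels(self) -> pd.Series:
        """Family label per genome; generated sequences form one pseudo-family.

        Natural genomes without a family annotation get NA and are excluded
        from family-restricted analyses.
        """
        fam = self.meta["family"].copy()
        fam[self.meta["provenance"] == GENERATED] = GENERATED_FAMILY
        return fam


def fit_pca(frame: pd.DataFrame, metric_names: tuple[str, ...] = METRIC_NAMES) -> PcaSpace:
    """Center + unit-variance scale, then full eigendecomposition via SVD."""
    if len(frame) < 20:
        raise ValueError("need at least 20 profiles to fit the PC space")
    X = frame[list(metric_names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite metrics")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    constant = np.asarray(metric_names)[scale == 0]
    if constant.size:
        raise ValueError(f"constant metric column(s): {', '.join(constant)}")
    Z = (X - center) / scale
    # full SVD: columns of V are the component loadings
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (len(frame) - 1)
    share = var / var.sum()
    coords = Z @ vt.T
    meta_cols = [c for c in ("provenance", "family", "quality_bin") if c in frame.columns]
    return PcaSpace(
        loadings=vt.T,
        variance_share=share,
        center=center,
        scale=scale,
        coordinates=pd.DataFrame(coords, index=frame.index, columns=[f"PC{i+1}" for i in range(len(s))]),
        meta=frame[meta_cols].copy(),
        metric_names=tuple(metric_names),
    )


def weighted_distance(space: PcaSpace, a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance after per-component variance-share weighting."""
    w = space.variance_share
    d = w * (np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return float(np.sqrt(np.sum(d * d)))


def _weighted_matrix(space: PcaSpace, restrict: pd.Index | None = None) -> pd.DataFrame:
    W = space.weighted_coordinates
    return W.loc[restrict] if restrict is not None else W


def family_centroids(space: PcaSpace, min_members: int = 25) -> pd.DataFrame:
    """Per-family centroid geometry: distance to the generated pseudo-family
    centroid, within-family member-to-centroid distance percentiles, and the
    cumulative distance to all other qualifying centroids.

    Centroids are per-component means of the raw PC scores; all distances are
    taken in the weighted space. Families below ``min_members`` are excluded.
    """
    labels = space.group_labels()
    W = space.weighted_coordinates
    counts = labels.value_counts()
    qualifying = sorted(counts[counts >= min_members].index)
    if not qualifying:
        raise ValueError(f"no family with >= {min_members} members")
    centroids = {f: W[labels == f].mean(axis=0).to_numpy() for f in qualifying}
    gen_centroid = centroids.get(GENERATED_FAMILY)

    rows = []
    for f in qualifying:
        members = W[labels == f].to_numpy()
        own = centroids[f]
        dists = np.sqrt(((members - own) ** 2).sum(axis=1))
        cumulative = sum(
            float(np.sqrt(((own - centroids[g]) ** 2).sum())) for g in qualifying if g != f
        )
        rows.append(
            {
                "family": f,
                "n_members": int(counts[f]),
                "dist_to_generated_centroid": (
                    float(np.sqrt(((own - gen_centroid) ** 2).sum()))
                    if gen_centroid is not None and f != GENERATED_FAMILY
                    else np.nan
                ),
                "within_10th": float(np.percentile(dists, 10)),
                "within_median": float(np.percentile(dists, 50)),
                "within_90th": float(np.percentile(dists, 90)),
                "cumulative_distance": cumulative,
            }
        )
    return pd.DataFrame(rows).set_index("family")


def _nearest_neighbor_labels(W: np.ndarray) -> np.ndarray:
    """Index of each point's single nearest neighbour, excluding itself.

    sklearn returns neighbours sorted by distance with ties in index order,
    so exact ties resolve to the lowest row index deterministically.
    """
    nn = NearestNeighbors(n_neighbors=2, algorithm="auto").fit(W)
    _, idx = nn.kneighbors(W)
    out = np.empty(len(W), dtype=int)
    for i in range(len(W)):
        out[i] = idx[i, 1] if idx[i, 0] == i else idx[i, 0]
    return out


def nn_clustering(space: PcaSpace, min_members: int = 10) -> pd.DataFrame:
    """Per-family nearest-neighbour cluster rate against the N_f/N null.

    Families below ``min_members`` are excluded from reporting but their
    members remain in the space as potential neighbours.
    """
    labels = space.group_labels().dropna()
    if labels.nunique() < 2:
        raise ValueError("need >= 2 families")
    W = _weighted_matrix(space, labels.index).to_numpy()
    lab = labels.to_numpy()
    nn_idx = _nearest_neighbor_labels(W)
    nn_lab = lab[nn_idx]
    N = len(lab)
    counts = labels.value_counts()
    rows = []
    for f in sorted(counts[counts >= min_members].index):
        mask = lab == f
        n_f = int(mask.sum())
        successes = int((nn_lab[mask] == f).sum())
        expected = counts[f] / N
        p = stats.binomtest(successes, n_f, p=expected, alternative="greater").pvalue
        rows.append(
            {
                "family": f,
                "n_members": n_f,
                "n_clustered": successes,
                "cluster_rate": successes / n_f,
                "expected_rate": float(expected),
                "p_binomial": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("family")


def nearest_family_of_outliers(space: PcaSpace, focal_family: str = GENERATED_FAMILY) -> pd.DataFrame:
    """For focal-family members whose nearest neighbour is NOT focal, tally
    the neighbour's family and test each for enrichment against N_f/N."""
    labels = space.group_labels().dropna()
    if focal_family not in labels.values:
        raise ValueError(f"focal family {focal_family!r} absent")
    W = _weighted_matrix(space, labels.index).to_numpy()
    lab = labels.to_numpy()
    nn_lab = lab[_nearest_neighbor_labels(W)]
    focal = lab == focal_family
    outsiders = nn_lab[focal & (nn_lab != focal_family)]
    n_out = len(outsiders)
    N = len(lab)
    counts = labels.value_counts()
    rows = []
    for f, c in zip(*np.unique(outsiders, return_counts=True)):
        expected = counts[f] / N
        p = stats.binomtest(int(c), n_out, p=expected, alternative="greater").pvalue
        rows.append({"family": f, "count": int(c), "expected_rate": float(expected), "p_binomial": float(p)})
    return pd.DataFrame(rows, columns=["family", "count", "expected_rate", "p_binomial"]).set_index("family")


def plot_projection(space: PcaSpace, path, min_members: int = 25) -> None:
    """Unweighted PC1-vs-PC2 scatter of families with >= min_members."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = space.group_labels().dropna()
    counts = labels.value_counts()
    keep = counts[counts >= min_members].index
    fig, ax = plt.subplots(figsize=(7, 6))
    for f in sorted(keep):
        sub = space.coordinates.loc[labels[labels == f].index]
        ax.scatter(sub["PC1"], sub["PC2"], s=8, alpha=0.6, label=f)
    vs = space.variance_share
    ax.set_xlabel(f"PC1 ({vs[0]*100:.1f}% of variance)")
    ax.set_ylabel(f"PC2 ({vs[1]*100:.1f}% of variance)")
    ax.legend(fontsize=7, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
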