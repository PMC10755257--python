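"""Statistical analysis of heme structure collections.

Four tools mirror the analysis workflow of the distortion database:

* per-mode amplitude histograms grouped by axial ligand, protein function
  or fold, with a structure-resolution filter;
* PCA on fitted Cartesian coordinates (iterative least-squares fit of all
  structures to their mean, then covariance eigendecomposition), with
  eigenvectors exportable as 25-atom displacements and compared against
  the saddling/ruffling/doming modes by inner product;
* LDA on the 12 NSD amplitudes for two groups, returning the discriminant
  expressed as a linear combination of the mode vectors;
* cluster analysis (CAN) with K-means, spectral, agglomerative and
  Gaussian-mixture clustering, always with k = number of target groups.

Clustering hyperparameters beyond k are pinned library defaults with a
fixed seed (0) for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .exceptions import DimensionError
from .mode_basis import MODE_NAMES, ModeBasis
from .nsd_engine import kabsch_fit
from .reference_geometry import LABEL_INDEX, SKELETON_LABELS

RESOLUTION_RANGE = (1.4, 8.2)  # selectable resolution filter bounds, Angstrom

CLUSTER_METHODS = ("K-means", "Spectral", "Agglomerative", "Gaussian mixture")


# --------------------------------------------------------------------------
# Histograms
# --------------------------------------------------------------------------


@dataclass
class HistogramResult:
    status: str                            # "ok" | "empty"
    distributions: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict
    )  # mode -> group -> (counts, bin_edges)
    n_used: int = 0


def nsd_histograms(
    features: pd.DataFrame,
    groups: pd.Series | list,
    resolution: pd.Series | list | None = None,
    resolution_max: float = RESOLUTION_RANGE[1],
    bins: int | np.ndarray = 20,
) -> HistogramResult:
    """Binned per-mode amplitude distributions, one per group.

    ``features`` must hold the 12 mode columns.  Rows with resolution above
    ``resolution_max`` are dropped (missing resolutions are kept).  Counts
    are conserved: for each mode the histogram counts over all groups sum
    to the number of rows that pass the filter.
    """
    lo, hi = RESOLUTION_RANGE
    if not (lo <= resolution_max <= hi):
        raise ValueError(f"resolution_max must lie in [{lo}, {hi}]")
    groups = pd.Series(list(groups), index=features.index)
    mask = pd.Series(True, index=features.index)
    if resolution is not None:
        res = pd.Series(list(resolution), index=features.index, dtype=float)
        mask = res.isna() | (res <= resolution_max)
    sub = features.loc[mask]
    if sub.empty:
        return HistogramResult(status="empty")
    sub_groups = groups.loc[mask]
    # common bin edges per mode so group histograms are comparable
    result: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for mode in MODE_NAMES:
        col = sub[mode].to_numpy(dtype=float)
        edges = np.histogram_bin_edges(col, bins=bins)
        per_group = {}
        for g in sorted(sub_groups.unique()):
            counts, _ = np.histogram(col[(sub_groups == g).to_numpy()],
                                     bins=edges)
            per_group[g] = (counts, edges)
        result[mode] = per_group
    return HistogramResult(status="ok", distributions=result, n_used=len(sub))


# --------------------------------------------------------------------------
# PCA on fitted coordinates
# --------------------------------------------------------------------------


@dataclass
class PCAResult:
    mean_coords: np.ndarray                # (25, 3)
    eigenvectors: np.ndarray               # (n_components, 75), zero-padded
    contribution_ratios: np.ndarray
    projections: np.ndarray                # (n, n_components)
    mode_inner_products: pd.DataFrame      # component x {saddling,ruffling,doming}
    fit_iterations: int = 0


def _fit_subset(coords: np.ndarray, target: np.ndarray,
                idx: np.ndarray) -> np.ndarray:
    """Rigid-fit ``coords`` to ``target`` using only atoms ``idx``."""
    rot, trans, _ = kabsch_fit(coords[idx], target[idx])
    return coords @ rot.T + trans


def pca_coordinates(
    structures: list[np.ndarray],
    basis: ModeBasis,
    fit_atoms: list[str] | None = None,
    pca_atoms: list[str] | None = None,
    n_components: int = 10,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> PCAResult:
    """PCA of heme coordinates after iterative least-squares fit to the mean.

    The mean is initialized with the first structure; all structures are
    rigidly fitted to it over ``fit_atoms`` and the mean recomputed, until
    the mean moves by less than ``tol`` A RMSD.  The covariance of the
    ``pca_atoms`` coordinates is then eigendecomposed; each eigenvector is
    reported as a 25-atom displacement (zero outside ``pca_atoms``) along
    with its inner products with the saddling, ruffling and doming modes.
    """
    coords = [np.asarray(s, dtype=float) for s in structures]
    if any(c.shape != (25, 3) for c in coords):
        raise DimensionError("every structure must be a (25, 3) skeleton")
    if len(coords) < 2:
        raise DimensionError("PCA needs at least 2 structures")
    fit_atoms = list(fit_atoms or SKELETON_LABELS)
    pca_atoms = list(pca_atoms or SKELETON_LABELS)
    if not fit_atoms or not pca_atoms:
        raise DimensionError("atom selections must be non-empty")
    n_components = min(n_components, len(coords) - 1,
                       3 * len(pca_atoms))
    fit_idx = np.array([LABEL_INDEX[lab] for lab in fit_atoms])
    pca_idx = np.array([LABEL_INDEX[lab] for lab in pca_atoms])

    mean = coords[0].copy()
    aligned = coords
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = [_fit_subset(c, mean, fit_idx) for c in coords]
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum() / 25.0))
        mean = new_mean
        if shift < tol:
            break

    x = np.array([c[pca_idx].reshape(-1) for c in aligned])
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(x)

    evecs_full = np.zeros((n_components, 75))
    for k in range(n_components):
        ev = pca.components_[k].reshape(len(pca_idx), 3)
        for j, atom in enumerate(pca_idx):
            evecs_full[k, 3 * atom : 3 * atom + 3] = ev[j]

    inner = {
        name: evecs_full @ basis[name].vector
        for name in ("saddling", "ruffling", "doming")
    }
    table = pd.DataFrame(inner, index=[f"PC{k+1}" for k in range(n_components)])
    return PCAResult(
        mean_coords=mean,
        eigenvectors=evecs_full,
        contribution_ratios=pca.explained_variance_ratio_,
        projections=proj,
        mode_inner_products=table,
        fit_iterations=iterations,
    )


# --------------------------------------------------------------------------
# LDA on NSD amplitudes
# --------------------------------------------------------------------------


@dataclass
class LDAResult:
    direction: np.ndarray           # (12,), unit norm, in mode space
    feature_vector: np.ndarray      # (75,) displacement, unit norm
    projections: np.ndarray
    group_labels: tuple
    group_means: np.ndarray         # projected means, (2,)
    separation: float               # resubstitution accuracy, percent
    ridge_applied: bool = False


def lda_nsd(
    features: pd.DataFrame | np.ndarray,
    groups: pd.Series | list,
    basis: ModeBasis,
    ridge_factor: float = 1e-6,
) -> LDAResult:
    """Two-group linear discriminant on the 12 NSD amplitudes.

    Fits class-conditional Gaussians with a shared (pooled) covariance; the
    discriminant direction is S_pooled^-1 (mu_2 - mu_1), normalized.  A
    ridge of ``ridge_factor * trace(S)/12`` is added when the pooled
    covariance is rank-deficient.  The direction is also returned as a
    75-component displacement: the same linear combination of the 12 mode
    vectors.
    """
    x = (features[list(MODE_NAMES)].to_numpy(dtype=float)
         if isinstance(features, pd.DataFrame) else np.asarray(features, float))
    if x.shape[1] != 12:
        raise DimensionError("LDA expects the 12 NSD amplitude columns")
    g = np.asarray(list(groups))
    labels = tuple(pd.unique(g))
    if len(labels) != 2:
        raise DimensionError(f"LDA needs exactly two groups, got {len(labels)}")
    x1, x2 = x[g == labels[0]], x[g == labels[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise DimensionError("each group needs at least 2 rows")
    mu1, mu2 = x1.mean(0), x2.mean(0)
    s = ((x1 - mu1).T @ (x1 - mu1) + (x2 - mu2).T @ (x2 - mu2)) / (
        len(x) - 2
    )
    ridge_applied = False
    if np.linalg.matrix_rank(s, tol=1e-10 * max(np.trace(s), 1e-300)) < 12:
        s = s + (ridge_factor * np.trace(s) / 12.0) * np.eye(12)
        ridge_applied = True
    w = scipy.linalg.solve(s, mu2 - mu1, assume_a="pos")
    w = w / np.linalg.norm(w)

    proj = x @ w
    m1, m2 = proj[g == labels[0]].mean(), proj[g == labels[1]].mean()
    threshold = 0.5 * (m1 + m2)
    predicted = np.where((proj > threshold) == (m2 > m1), labels[1], labels[0])
    separation = 100.0 * float(np.mean(predicted == g))

    feature_vector = basis.matrix.T @ w
    feature_vector = feature_vector / np.linalg.norm(feature_vector)
    return LDAResult(
        direction=w, feature_vector=feature_vector, projections=proj,
        group_labels=labels, group_means=np.array([m1, m2]),
        separation=separation, ridge_applied=ridge_applied,
    )


# --------------------------------------------------------------------------
# Cluster analysis (CAN)
# --------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    method: str
    labels: np.ndarray
    n_clusters: int
    contingency: pd.DataFrame       # cluster x group counts (heat-map table)


def cluster_nsd(
    features: pd.DataFrame | np.ndarray,
    groups: pd.Series | list,
    method: str,
    seed: int = 0,
) -> ClusteringResult:
    """Cluster hemes by NSD amplitudes; k = number of target groups."""
    x = (features[list(MODE_NAMES)].to_numpy(dtype=float)
         if isinstance(features, pd.DataFrame) else np.asarray(features, float))
    g = np.asarray(list(groups))
    k = len(pd.unique(g))
    if k < 2:
        raise DimensionError("need at least two target groups")
    if k > len(x):
        raise DimensionError("more clusters requested than data rows")
    if method == "K-means":
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(x)
    elif method == "Spectral":
        labels = SpectralClustering(
            n_clusters=k, random_state=seed, assign_labels="kmeans",
        ).fit_predict(x)
    elif method == "Agglomerative":
        labels = AgglomerativeClustering(n_clusters=k).fit_predict(x)
    elif method == "Gaussian mixture":
        labels = GaussianMixture(
            n_components=k, random_state=seed
        ).fit_predict(x)
    else:
        raise ValueError(
            f"unknown clustering method {method!r}; choose from {CLUSTER_METHODS}"
        )
    contingency = pd.crosstab(
        pd.Series(labels, name="cluster"), pd.Series(g, name="group")
    )
    return ClusteringResult(
        method=method, labels=np.asarray(labels),
        n_clusters=len(np.unique(labels)), contingency=contingency,
    )
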