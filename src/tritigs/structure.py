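"""Population structure: PCA, Ward clustering, k-means with BIC, and DAPC.

PCA is run on the column-centered (optionally standardized) dosage matrix.
k-means model selection follows the find.clusters convention:
BIC(k) = n·ln(WSS_k/n) + k·ln(n), minimized over candidate k.  DAPC is a
linear discriminant analysis on the retained principal components; marker
loadings per discriminant axis are recovered by composing the PCA
eigenvectors with the discriminant coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import GenotypeMatrix

__all__ = [
    "PCAResult",
    "ClusterModel",
    "DAPCResult",
    "run_pca",
    "hierarchical_clusters",
    "kmeans_bic",
    "run_dapc",
    "composition_table",
]


@dataclass
class PCAResult:
    """Principal components of the dosage matrix."""

    scores: np.ndarray  # accessions x components
    eigenvalues: np.ndarray  # full covariance spectrum (variance units)
    proportion: np.ndarray  # eigenvalue / total variance, sums to 1
    components: np.ndarray  # markers x components (eigenvectors)
    center: np.ndarray
    scale: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def n_for_variance(self, target: float) -> int:
        """Smallest number of leading components capturing ``target`` variance."""
        cum = np.cumsum(self.proportion)
        return int(np.searchsorted(cum, target - 1e-12) + 1)


@dataclass
class ClusterModel:
    """A clustering of the panel (hierarchical or k-means)."""

    method: str  # "hierarchical" | "kmeans"
    k: int
    labels: np.ndarray  # 1..k per accession
    wss: dict | None = None  # k -> within-cluster sum of squares (kmeans)
    bic: dict | None = None  # k -> BIC (kmeans)
    linkage_matrix: np.ndarray | None = None  # hierarchical


@dataclass
class DAPCResult:
    """Discriminant analysis of principal components."""

    n_pca: int
    n_da: int
    coordinates: np.ndarray  # accessions x n_da
    posteriors: np.ndarray  # accessions x k, rows sum to 1
    assignments: np.ndarray  # 1..k
    loadings: np.ndarray  # markers x n_da
    variance_retained: float  # proportion of variance in the n_pca PCs
    groups: np.ndarray  # class labels in posterior column order


def run_pca(g: GenotypeMatrix, n_components: int | None = None, scale: bool = False) -> PCAResult:
    """PCA of the dosage matrix (centered; unscaled by default).

    Requires a complete matrix — impute first.  Eigenvalues are the
    covariance spectrum; proportions are relative to the total column
    variance, so they sum to 1 over all components.
    """
    if g.has_missing():
        raise ValueError("matrix has missing values; run impute_mean first")
    X = g.dosages.astype(float)
    n, m = X.shape
    max_comp = min(n - 1, m)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    center = X.mean(axis=0)
    Xc = X - center
    scale_vec = None
    if scale:
        scale_vec = Xc.std(axis=0, ddof=1)
        scale_vec[scale_vec == 0] = 1.0
        Xc = Xc / scale_vec
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    proportion = eig / total_var
    scores = U[:, :n_components] * s[:n_components]
    return PCAResult(scores, eig, proportion, Vt[:n_components].T, center, scale_vec)


def hierarchical_clusters(g: GenotypeMatrix, k: int) -> ClusterModel:
    """Ward-D2 agglomeration on Euclidean distances, tree cut at k groups."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > g.n_accessions:
        raise ValueError("k cannot exceed the number of accessions")
    if g.has_missing():
        raise ValueError("matrix has missing values; run impute_mean first")
    Z = linkage(g.dosages, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterModel("hierarchical", k, labels.astype(int), linkage_matrix=Z)


def kmeans_bic(
    pca: PCAResult,
    k_range=range(1, 11),
    n_starts: int = 20,
    seed: int = 0,
    n_pca: int | None = None,
    variance_target: float = 0.95,
    max_iter: int = 300,
) -> ClusterModel:
    """Best-of-``n_starts`` k-means on retained PC scores, BIC-selected k.

    BIC(k) = n·ln(WSS_k/n) + k·ln(n); the k with the smallest BIC wins.
    ``n_pca`` defaults to the number of components capturing
    ``variance_target`` of the variance (same retention rule as DAPC).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    if n_pca is None:
        n_pca = min(pca.n_for_variance(variance_target), pca.n_components)
    X = pca.scores[:, :n_pca]
    n = X.shape[0]
    if any(k < 1 or k > n for k in k_range):
        raise ValueError("k_range must lie within [1, n_accessions]")
    wss, bic, fits = {}, {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed, max_iter=max_iter)
        km.fit(X)
        wss[k] = float(km.inertia_)
        bic[k] = n * np.log(wss[k] / n) + k * np.log(n)
        fits[k] = km
    best = min(bic, key=lambda k: (bic[k], k))
    labels = fits[best].labels_.astype(int) + 1
    return ClusterModel("kmeans", best, labels, wss=wss, bic=bic)


def run_dapc(
    pca: PCAResult,
    labels,
    n_pca: int | None = None,
    n_da: int | None = None,
    variance_target: float = 0.95,
) -> DAPCResult:
    """Linear discriminant analysis on the first ``n_pca`` PC scores.

    Group posteriors are Gaussian with a shared within-group covariance.
    Marker loadings per DA axis compose the PCA eigenvectors with the
    discriminant coefficients, so high-loading markers are those driving
    between-group separation on the original dosage scale.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = groups[counts < 2]
        raise ValueError(f"groups with fewer than 2 members: {small.tolist()}")
    k = len(groups)
    if n_pca is None:
        n_pca = min(pca.n_for_variance(variance_target), pca.n_components)
    if n_pca > pca.n_components:
        raise ValueError("n_pca exceeds available components")
    if n_da is None:
        n_da = k - 1
    if n_da > k - 1:
        raise ValueError("n_da cannot exceed k - 1")
    X = pca.scores[:, :n_pca]
    lda = LinearDiscriminantAnalysis(solver="eigen")
    lda.fit(X, labels)
    coords = lda.transform(X)[:, :n_da]
    post = lda.predict_proba(X)
    assign = lda.predict(X)
    scalings = lda.scalings_[:, :n_da]
    loadings = pca.components[:, :n_pca] @ scalings
    var_ret = float(pca.proportion[:n_pca].sum())
    return DAPCResult(n_pca, n_da, coords, post, assign, loadings, var_ret, groups)


def composition_table(labels, type_labels, type_names=("spring", "winter")) -> pd.DataFrame:
    """Cluster-by-type composition (counts and within-cluster percentages).

    ``type_labels`` is a boolean/0-1 array (1 = second entry of
    ``type_names``); types are descriptive metadata and play no role in
    the clustering itself.
    """
    labels = np.asarray(labels)
    t = np.asarray(type_labels).astype(int)
    rows = []
    for c in np.unique(labels):
        mask = labels == c
        n = int(mask.sum())
        n1 = int(t[mask].sum())
        rows.append(
            {
                "cluster": int(c),
                "n": n,
                type_names[0]: n - n1,
                type_names[1]: n1,
                f"pct_{type_names[1]}": 100.0 * n1 / n,
            }
        )
    return pd.DataFrame(rows)
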