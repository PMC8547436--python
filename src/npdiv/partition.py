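"""Chemistry-based grouping of isolates.

Bray-Curtis dissimilarities on TIC-normalized abundance profiles,
classical principal-coordinate analysis (metric MDS via Gower
double-centering), average-linkage hierarchical clustering with the
number of clusters selected by mean silhouette width, and PERMANOVA for
testing group separation on the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .containers import FeatureTable
from .errors import DegenerateDataError, UndefinedDistanceError

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "ClusterAssignment",
    "PermanovaResult",
    "bray_curtis",
    "distance_matrix",
    "pcoa",
    "cluster_isolates",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over isolates."""

    data: np.ndarray
    ids: list
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n) or len(self.ids) != n:
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise UndefinedDistanceError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(table: FeatureTable, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise distances between samples (columns) of an abundance table."""
    profiles = table.abundances.T.to_numpy()
    if metric == "braycurtis" and (profiles.sum(axis=1) == 0).any():
        raise UndefinedDistanceError("sample with all-zero profile")
    condensed = pdist(profiles, metric=metric)
    return DistanceMatrix(squareform(condensed), list(table.samples), metric)


@dataclass
class PCoAResult:
    """Principal coordinates of a distance matrix.

    Axes are ordered by descending eigenvalue; ``proportion_explained``
    is computed over the positive eigenvalues. Negative eigenvalues
    (non-Euclidean distances) are dropped, not corrected, and flagged.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues_dropped: bool


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-9) -> PCoAResult:
    """Classical (metric) multidimensional scaling.

    Gower-center ``-0.5 * D**2``, eigendecompose, and scale each
    retained eigenvector by the square root of its eigenvalue. Axes with
    eigenvalues at or below ``eig_tol`` (relative to the largest) are
    dropped.
    """
    n = dm.n
    if n < 2:
        raise DegenerateDataError("PCoA needs at least two samples")
    d2 = dm.data**2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(eigvals.max(), 1.0)
    keep = eigvals > eig_tol * scale
    negative = bool((eigvals < -eig_tol * scale).any())
    kept_vals = eigvals[keep]
    vecs = eigvecs[:, keep]
    # deterministic sign: largest-magnitude loading positive per axis
    for j in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, j]))
        if vecs[pivot, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(kept_vals)
    positive_sum = eigvals[eigvals > 0].sum()
    proportion = kept_vals / positive_sum if positive_sum > 0 else kept_vals * 0.0
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords,
            index=dm.ids,
            columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
        ),
        eigenvalues=kept_vals,
        proportion_explained=proportion,
        negative_eigenvalues_dropped=negative,
    )


@dataclass
class ClusterAssignment:
    """Hierarchical-clustering labels with silhouette-selected k."""

    labels: pd.Series  # isolate -> 1..k
    k: int
    silhouette_by_k: dict = field(default_factory=dict)

    @property
    def mean_silhouette(self) -> float:
        return self.silhouette_by_k[self.k]


def cluster_isolates(
    dm: DistanceMatrix,
    k_range=range(2, 11),
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Average-linkage (UPGMA) clustering with silhouette model selection.

    The tree is cut at every k in ``k_range`` (restricted to
    ``[2, n - 1]``); the labeling maximizing the mean silhouette width
    ``s(i) = (b_i - a_i) / max(a_i, b_i)`` computed from the distance
    matrix is returned, with ties broken toward smaller k (parsimony).
    """
    n = dm.n
    if n < 3:
        raise DegenerateDataError("clustering needs at least three samples")
    if np.allclose(dm.data, 0):
        raise DegenerateDataError("all points identical; silhouette undefined")
    ks = sorted(k for k in k_range if 2 <= k <= n - 1)
    if not ks:
        raise ValueError("k_range must intersect [2, n - 1]")
    tree = linkage(squareform(dm.data, checks=False), method=linkage_method)
    silhouettes: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in ks:
        raw = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(raw)) < 2:
            continue
        labelings[k] = raw
        silhouettes[k] = float(silhouette_score(dm.data, raw, metric="precomputed"))
    if not silhouettes:
        raise DegenerateDataError("no cut produced at least two clusters")
    best_k = select_k(silhouettes)
    raw = labelings[best_k]
    # relabel 1..k in order of first appearance for determinism
    remap = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([remap[lab] for lab in raw], index=dm.ids, name="cluster")
    return ClusterAssignment(labels=labels, k=len(remap), silhouette_by_k=silhouettes)


def select_k(silhouettes: dict) -> int:
    """Argmax of mean silhouette over candidate k; ties go to smaller k."""
    return min(silhouettes, key=lambda k: (-silhouettes[k], k))


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_perm: int


def _ss_terms(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Within-group sum of squares from squared distances."""
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        if idx.size > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss_within


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance.

    The pseudo-F statistic is
    ``(SS_between / (k - 1)) / (SS_within / (N - k))`` with sums of
    squares computed from squared distances; the p-value counts
    label permutations whose statistic reaches the observed one, with
    the observed configuration included (+1 convention), so p is never
    zero.
    """
    labels = pd.Series(labels)
    if len(labels) != dm.n:
        raise ValueError("labels must match the distance matrix")
    codes, uniques = pd.factorize(labels.to_numpy())
    k = len(uniques)
    if k < 2:
        raise DegenerateDataError("PERMANOVA needs at least two groups")
    counts = np.bincount(codes)
    if (counts == len(labels)).any():
        raise DegenerateDataError("a group equals the whole sample")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = dm.n
    d2 = dm.data**2
    ss_total = d2.sum() / (2 * n)
    df_between, df_within = k - 1, n - k

    def pseudo_f(codes_: np.ndarray) -> float:
        ss_within = _ss_terms(d2, codes_, k)
        ss_between = ss_total - ss_within
        return (ss_between / df_between) / (ss_within / df_within)

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), p_value=float(p), n_perm=n_perm)
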