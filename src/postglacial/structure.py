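"""Exploratory population structure: distances, UPGMA, PCoA, K-means.

Distances are either individual-level Euclidean distances on one-hot site
indicators or population-level Edwards angular (chord) distances on
haplotype frequencies.  Hierarchical clustering compares several
agglomeration rules by cophenetic correlation; ordination is classical
metric MDS (PCoA, cmdscale); K selection uses both the elbow on
within-group variance and the average silhouette width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .seqdata import Alignment, HaplotypeTable, T


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    level: str  # "individual" | "population"
    method: str  # "euclidean-indicator" | "edwards-angular"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class Ordination:
    coordinates: np.ndarray  # items x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_explained: np.ndarray  # % per retained axis, over positive eigenvalues
    negative_eigenvalues: np.ndarray
    labels: list[str]
    flags: dict = field(default_factory=dict)


@dataclass
class ClusteringResult:
    K: int | None = None
    assignments: np.ndarray | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    within_var_by_k: dict[int, float] = field(default_factory=dict)
    elbow_k: int | None = None
    linkage: np.ndarray | None = None
    method: str | None = None
    cophenetic_by_method: dict[str, float] = field(default_factory=dict)
    newick: str | None = None
    seed: int | None = None
    flags: dict = field(default_factory=dict)


def edwards_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Edwards angular (chord) distance sqrt(1 - sum_i sqrt(p1_i p2_i))."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    s = float(np.sum(np.sqrt(p1 * p2)))
    return float(np.sqrt(max(0.0, 1.0 - s)))


def pairwise_distances(
    data: Alignment | HaplotypeTable, level: str = "individual", method: str | None = None
) -> DistanceMatrix:
    """Distance matrix at individual or population level.

    individual: Euclidean distance between per-site one-hot indicator
    vectors of each sequence (so d^2 = 2 x number of differing sites).
    population: Edwards angular distance on haplotype frequencies.
    """
    if level == "individual":
        if not isinstance(data, Alignment):
            raise TypeError("individual-level distances need an Alignment")
        if not data.is_clean:
            raise ValueError("alignment must be trimmed first")
        n, L = data.seqs.shape
        onehot = np.zeros((n, L, 4))
        for state in range(4):
            onehot[:, :, state] = data.seqs == state
        flat = onehot.reshape(n, L * 4)
        mat = squareform(pdist(flat, metric="euclidean"))
        return DistanceMatrix(list(data.sample_ids), mat, "individual", "euclidean-indicator")
    if level == "population":
        if not isinstance(data, HaplotypeTable):
            raise TypeError("population-level distances need a HaplotypeTable")
        sizes = data.sample_sizes()
        empty = [p for p in data.populations if sizes[p] == 0]
        if empty:
            raise ValueError(f"empty populations: {empty}")
        freqs = data.frequencies()
        pops = data.populations
        m = len(pops)
        mat = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                d = edwards_distance(freqs[pops[i]].to_numpy(), freqs[pops[j]].to_numpy())
                mat[i, j] = mat[j, i] = d
        return DistanceMatrix(pops, mat, "population", "edwards-angular")
    raise ValueError(f"unknown level {level!r}")


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick string with branch lengths from an ultrametric linkage."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


DEFAULT_AGGLOMERATION = ("average", "single", "complete", "weighted")


def upgma_with_method_selection(
    dm: DistanceMatrix, candidate_methods: tuple[str, ...] = DEFAULT_AGGLOMERATION
) -> ClusteringResult:
    """Hierarchical clustering with the agglomeration rule chosen by
    cophenetic correlation against the original distances.

    Ties are broken toward "average" (UPGMA) when it is among the
    candidates, otherwise toward the earlier-listed method.
    """
    if dm.n < 3:
        raise ValueError("need n >= 3 for hierarchical clustering")
    cond = dm.condensed()
    result = ClusteringResult()
    constant = np.allclose(cond, cond[0])
    best = None
    for m in candidate_methods:
        Z = hierarchy.linkage(cond, method=m)
        if constant:
            corr = np.nan
        else:
            coph = hierarchy.cophenet(Z)
            if np.allclose(coph, coph[0]):
                corr = np.nan
            else:
                corr = float(pearsonr(cond, coph)[0])
        result.cophenetic_by_method[m] = corr
        key = (-1.0 if np.isnan(corr) else corr, 1.0 if m == "average" else 0.0)
        if best is None or key > best[0]:
            best = (key, m, Z)
    _, method, Z = best
    result.method = method
    result.linkage = Z
    result.newick = _linkage_to_newick(Z, dm.labels)
    if constant or all(np.isnan(v) for v in result.cophenetic_by_method.values()):
        result.flags["cophenetic_undefined"] = True
    return result


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical metric MDS (principal coordinates analysis).

    Double-centers -D^2/2 and eigendecomposes.  Variance explained is
    reported over positive eigenvalues only; negative eigenvalues (from
    non-Euclidean distances) are returned separately, never folded into the
    denominator.
    """
    if dm.n < 3:
        raise ValueError("need n >= 3 for ordination")
    D = dm.matrix
    n = dm.n
    B = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ B @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(evals).max()))
    pos = evals > tol
    neg = evals < -tol
    flags = {}
    if not pos.any():
        flags["degenerate"] = True
        coords = np.zeros((n, 1))
        return Ordination(coords, evals, np.array([]), evals[neg], list(dm.labels), flags)
    k = int(pos.sum()) if n_axes is None else min(n_axes, int(pos.sum()))
    lam = evals[:k]
    coords = evecs[:, :k] * np.sqrt(lam)
    var_exp = 100.0 * lam / evals[pos].sum()
    return Ordination(coords, evals, var_exp, evals[neg], list(dm.labels), flags)


def select_k(
    data: np.ndarray | DistanceMatrix,
    k_range: range | list[int] = range(2, 7),
    n_restarts: int = 25,
    seed: int = 0,
) -> ClusteringResult:
    """K-means over a range of K with silhouette and elbow selection.

    Accepts either a coordinate matrix (items x dims) or a DistanceMatrix,
    which is first embedded by PCoA.  Reports the silhouette-optimal K,
    the elbow K (largest second difference of within-group variance), and
    assignments at the silhouette-optimal K.  k-means++ with ``n_restarts``
    random initialisations; reproducible under ``seed``.
    """
    if isinstance(data, DistanceMatrix):
        points = pcoa(data).coordinates
    else:
        points = np.asarray(data, dtype=float)
    n = points.shape[0]
    n_distinct = np.unique(points, axis=0).shape[0]
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if n_distinct < max(ks):
        raise ValueError(
            f"only {n_distinct} distinct points; cannot form {max(ks)} clusters"
        )
    result = ClusteringResult(seed=seed)
    labels_by_k = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed)
        lab = km.fit_predict(points)
        labels_by_k[k] = lab
        result.within_var_by_k[k] = float(km.inertia_)
        result.silhouette_by_k[k] = float(silhouette_score(points, lab))
    # diagnostic curves are kept on the result for plotting/inspection
    sil_k = max(result.silhouette_by_k, key=result.silhouette_by_k.get)
    result.K = sil_k
    result.assignments = labels_by_k[sil_k]
    # anchor the elbow curve at K=1 (total within-group variance) so the
    # smallest candidate K can itself be the elbow
    if len(ks) >= 2:
        ext_ks = [min(ks) - 1] + ks if min(ks) >= 2 else ks
        w = []
        for k in ext_ks:
            if k in result.within_var_by_k:
                w.append(result.within_var_by_k[k])
            elif k == 1:
                w.append(float(((points - points.mean(axis=0)) ** 2).sum()))
            else:
                km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++",
                            random_state=seed)
                km.fit(points)
                w.append(float(km.inertia_))
        w = np.array(w)
        if len(w) >= 3:
            second_diff = w[:-2] - 2 * w[1:-1] + w[2:]
            result.elbow_k = ext_ks[1:-1][int(np.argmax(second_diff))]
    return result


def plot_k_selection(result: ClusteringResult, axes=None):
    """Elbow (within-group variance) and average-silhouette curves."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    ks = sorted(result.within_var_by_k)
    axes[0].plot(ks, [result.within_var_by_k[k] for k in ks], "o-")
    if result.elbow_k is not None:
        axes[0].axvline(result.elbow_k, ls="--", c="k", lw=0.8)
    axes[0].set_xlabel("K")
    axes[0].set_ylabel("within-group variance")
    axes[1].plot(ks, [result.silhouette_by_k[k] for k in ks], "o-")
    axes[1].axvline(result.K, ls="--", c="k", lw=0.8)
    axes[1].set_xlabel("K")
    axes[1].set_ylabel("average silhouette width")
    return axes
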