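"""Hierarchical clustering and PCA of the sample x score matrix.

Samples are compared by Pearson correlation distance d = 1 - r between
their score (or variable) vectors and clustered agglomeratively with
average linkage (UPGMA): the distance between two clusters is the
unweighted mean of all cross-pair distances.  PCA is computed by SVD of
the column-centered matrix; missing entries, if any, are filled first
by iterative low-rank SVD reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "PCAResult",
    "pearson_distance",
    "upgma_cluster",
    "cut_clusters",
    "pca_svd",
    "rand_index",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage convention.

    ``merges`` row i is (id_a, id_b, height, size): original leaves are
    ids 0..n-1, the cluster formed at row i gets id n+i.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 4)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def linkage_matrix(self) -> np.ndarray:
        return np.asarray(self.merges, dtype=float)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: _quote_newick(self.labels[i]) for i in range(n)}
        for i, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            # ultrametric branch lengths: each child sits at half its merge height
            la = (h - height[a]) / 2.0
            lb = (h - height[b]) / 2.0
            node[n + i] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + i] = h
        return node[n + len(self.merges) - 1] + ";"


def _quote_newick(label: str) -> str:
    if any(c in label for c in " ():,;"):
        return "'" + label.replace("'", "''") + "'"
    return label


def pearson_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise 1 - Pearson correlation between sample rows."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 variables per sample")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(matrix.index[sd == 0])
        raise ValueError(f"constant row(s) have undefined correlation: {bad}")
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(labels=list(matrix.index), d=d)


def upgma_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the closest pair of clusters is merged; the distance
    from the new cluster to any other is the size-weighted average of
    the members' distances, i.e. the unweighted mean over all cross
    pairs of the original matrix.  Ties are broken by the smallest
    (id_a, id_b) pair for determinism.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    # active cluster id -> (row in work matrix)
    d = dist.d.copy()
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    pos = {cid: i for i, cid in enumerate(active)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                key = (d[pos[a], pos[b]], min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_h, _a, _b), a, b = best
        h = d[pos[a], pos[b]]
        na, nb = sizes[a], sizes[b]
        ia, ib = pos[a], pos[b]
        # new cluster distances: size-weighted average (UPGMA)
        new_row = (na * d[ia, :] + nb * d[ib, :]) / (na + nb)
        d[ia, :] = new_row
        d[:, ia] = new_row
        d[ia, ia] = 0.0
        merges[step] = (min(a, b), max(a, b), h, na + nb)
        # cluster `a`'s slot now represents the merged cluster
        sizes[next_id] = na + nb
        pos[next_id] = ia
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1
    return Dendrogram(labels=list(dist.labels), merges=merges)


def cut_clusters(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition into k clusters by undoing the last k-1 merges.

    Returns sample label -> cluster id (0-based, ordered by first
    appearance in the label list).
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = {}
    for i, (a, b, _h, _s) in enumerate(dend.merges[: n - k]):
        parent[int(a)] = n + i
        parent[int(b)] = n + i

    def find(x: int) -> int:
        while x in parent:
            x = parent[x]
        return x

    roots: dict[int, int] = {}
    out = {}
    for i, label in enumerate(dend.labels):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out[label] = roots[r]
    return out


def rand_index(labels_a: list, labels_b: list) -> float:
    """Rand index between two partitions given as per-sample labels."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("partitions must label the same samples")
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same_a[iu] == same_b[iu]).sum()
    return float(agree) / len(iu[0])


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # variable x component
    explained_variance_ratio: np.ndarray
    completed: pd.DataFrame  # matrix after imputation (original scale)
    n_imputation_iterations: int


def pca_svd(
    matrix: pd.DataFrame,
    center: bool = True,
    unit_variance: bool = False,
    rank: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PCAResult:
    """PCA by SVD with iterative low-rank imputation of missing entries.

    Missing entries are initialized at the column mean; the matrix is
    then repeatedly reconstructed from its rank-``rank`` truncated SVD
    (after centering/scaling) and the missing cells replaced by the
    reconstruction, until the filled values change by less than ``tol``
    (RMS) or ``max_iter`` is reached.  On a complete matrix the loop is
    a no-op and the result is the direct SVD of the (centered) data.
    """
    n, p = matrix.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    X = matrix.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if miss.all(axis=1).any() or miss.all(axis=0).any():
        raise ValueError("a row or column is entirely missing")
    if (miss.mean(axis=1) >= 0.5).any() or (miss.mean(axis=0) >= 0.5).any():
        raise ValueError("more than 50% missing in a row or column")
    rank = min(rank, n - 1, p)

    n_iter = 0
    if miss.any():
        col_mean = np.nanmean(X, axis=0)
        X[miss] = np.take(col_mean, np.nonzero(miss)[1])
        for n_iter in range(1, max_iter + 1):
            mu = X.mean(axis=0) if center else np.zeros(p)
            sd = X.std(axis=0, ddof=1) if unit_variance else np.ones(p)
            sd[sd == 0] = 1.0
            Z = (X - mu) / sd
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            recon = (U[:, :rank] * s[:rank]) @ Vt[:rank] * sd + mu
            delta = np.sqrt(np.mean((X[miss] - recon[miss]) ** 2))
            X[miss] = recon[miss]
            if delta < tol:
                break
        else:
            warnings.warn("SVD imputation did not converge; using last iterate")

    mu = X.mean(axis=0) if center else np.zeros(p)
    sd = X.std(axis=0, ddof=1) if unit_variance else np.ones(p)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=ratio,
        completed=pd.DataFrame(X, index=matrix.index, columns=matrix.columns),
        n_imputation_iterations=n_iter,
    )
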