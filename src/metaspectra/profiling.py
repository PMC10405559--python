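"""Unsupervised comparison of sample profiles.

Missing (zero) entries are imputed by adding the smallest positive value of
the matrix as a global pseudo-count, the matrix is log2 transformed, and the
samples are compared by average-linkage (UPGMA) hierarchical clustering on
Euclidean distances and by PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Dendrogram:
    """Result of UPGMA agglomeration.

    ``merges`` lists (node_a, node_b, height) triples; leaves are labelled by
    sample_id, internal nodes by consecutive integers starting at n_leaves
    (a leaf's node id is its index in ``leaves``).  Heights are cophenetic
    (average pairwise) distances and are non-decreasing along the merges.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a dendrogram over n leaves has n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k flat clusters; returns sample_id -> cluster label."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        parent = list(range(n + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for step, (a, b, _) in enumerate(self.merges[: n - k]):
            node = n + step
            parent[find(a)] = node
            parent[find(b)] = node
        roots: dict[int, int] = {}
        out = {}
        for i, leaf in enumerate(self.leaves):
            r = find(i)
            out[leaf] = roots.setdefault(r, len(roots))
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences parent - child."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node_str = {i: label for i, label in enumerate(self.leaves)}
        for step, (a, b, h) in enumerate(self.merges):
            node = n + step
            left = f"{node_str[a]}:{h - height[a]:.6g}"
            right = f"{node_str[b]}:{h - height[b]:.6g}"
            node_str[node] = f"({left},{right})"
            height[node] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node_str[root] + ";"


@dataclass
class PcaResult:
    scores: pd.DataFrame          # observations x components
    loadings: pd.DataFrame        # features x components
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if (np.diff(ve) > 1e-9).any():
            raise ValueError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must sum to <= 1")


# ---------------------------------------------------------------------------
# Imputation + transform
# ---------------------------------------------------------------------------

def impute_log2(matrix: pd.DataFrame, shift_all: bool = True) -> pd.DataFrame:
    """Pseudo-count imputation followed by log2.

    The smallest strictly positive entry m is added to every cell (default)
    or, with ``shift_all=False``, substituted only into the zero cells; the
    result is log2 transformed.  The default keeps the transform strictly
    monotone while filling zeros.  All-zero input is an error.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("profile matrix must be non-negative")
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("cannot impute an all-zero matrix")
    m = positive.min()
    out = vals + m if shift_all else np.where(vals == 0, m, vals)
    return pd.DataFrame(np.log2(out), index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def _euclidean_condensed(obs: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(obs, metric="euclidean")


def upgma_from_distance(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage agglomeration of a square distance matrix.

    At each step the pair of active clusters at minimum average pairwise
    distance is merged; ties broken by the smaller (node_a, node_b) pair with
    node_a < node_b.  O(n^3), which is ample for sample-level dendrograms.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    d = np.asarray(dist, dtype=float)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape must match labels")
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> cluster size
    dd: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(dd.items(), key=lambda kv: (kv[1], kv[0]))
        size_a, size_b = active.pop(a), active.pop(b)
        new_dd = {}
        for (i, j), v in dd.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dd[(i, j)] = v
        for c in active:
            da = dd[(min(a, c), max(a, c))]
            db = dd[(min(b, c), max(b, c))]
            new_dd[(min(c, next_id), max(c, next_id))] = (
                size_a * da + size_b * db
            ) / (size_a + size_b)
        dd = new_dd
        merges.append((a, b, h))
        active[next_id] = size_a + size_b
        next_id += 1
    return Dendrogram(leaves=list(labels), merges=merges)


def hierarchical_cluster(
    matrix: pd.DataFrame, metric: str = "euclidean", linkage: str = "average"
) -> Dendrogram:
    """UPGMA dendrogram over the matrix's columns (samples).

    Only Euclidean/average is implemented; the arguments exist to make the
    method choice explicit at call sites.
    """
    if metric != "euclidean" or linkage != "average":
        raise NotImplementedError("only euclidean distance with average linkage")
    labels = [str(c) for c in matrix.columns]
    if len(labels) < 2:
        raise ValueError("need at least 2 samples to cluster")
    obs = matrix.to_numpy(dtype=float).T
    from scipy.spatial.distance import squareform

    d = squareform(_euclidean_condensed(obs))
    return upgma_from_distance(d, labels)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of samples: the profile's columns become observations.

    Features (clusters) are mean-centered, not scaled.  Axis signs are fixed
    by making the largest-magnitude loading of each component positive.
    """
    obs = matrix.to_numpy(dtype=float).T  # samples x features
    n_obs, n_feat = obs.shape
    max_rank = min(n_obs - 1, n_feat) if n_obs > 1 else 1
    if n_components is None:
        n_components = max_rank
    if n_components > min(n_obs, n_feat):
        raise ValueError("n_components exceeds matrix rank bound")
    centered = obs - obs.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    total_var = float((s**2).sum())
    ve = (s**2 / total_var) if total_var > 0 else np.zeros_like(s)
    comp = [f"PC{i+1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (u[:, :n_components] * s[:n_components]), index=matrix.columns, columns=comp
    )
    loadings = pd.DataFrame(vt[:n_components].T, index=matrix.index, columns=comp)
    return PcaResult(scores, loadings, ve[:n_components])
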