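"""Shared-neighbor similarity between conditions and its clustering.

The similarity between two conditions is the average fraction of a cell's
k nearest neighbors (pooled graph over all cells) that carry the other
condition's label, symmetrized by averaging the two directions. A Jaccard
variant (overlap of neighbor sets) is available as an alternative metric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors


def knn_neighbors(embedding: np.ndarray, k: int) -> list[np.ndarray]:
    """k nearest neighbors per cell by Euclidean distance, self excluded.

    Ties are broken by cell index (lower index wins), which also makes
    duplicate points well-defined.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError(f"k must be in [1, n_cells-1], got k={k}, n={n}")
    nn = NearestNeighbors(n_neighbors=min(n, k + 2)).fit(X)
    dist, idx = nn.kneighbors(X)
    out = []
    for i in range(n):
        order = sorted(
            (float(dist[i, j]), int(idx[i, j]))
            for j in range(idx.shape[1])
            if idx[i, j] != i
        )
        out.append(np.array([j for _, j in order[:k]], dtype=int))
    return out


def condition_similarity(
    neighbors: list[np.ndarray],
    condition_labels: pd.Series | np.ndarray,
    metric: str = "composition",
) -> pd.DataFrame:
    """Condition x condition shared-neighbor similarity matrix.

    metric="composition" (default): S(A, B) is the mean over cells of A of
    the fraction of their neighbors labeled B, averaged with the reverse
    direction. metric="jaccard": mean Jaccard overlap between the neighbor
    sets of cell pairs drawn from the two conditions.
    """
    labels = pd.Series(condition_labels).reset_index(drop=True)
    if labels.isna().any():
        raise ValueError("every cell must carry a condition label")
    if len(labels) != len(neighbors):
        raise ValueError("labels and neighbor lists differ in length")
    if metric not in ("composition", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    conditions = [c for c in pd.unique(labels)]
    counts = labels.value_counts()
    conditions = [c for c in conditions if counts[c] > 0]
    label_arr = labels.to_numpy()

    if metric == "jaccard":
        n = len(neighbors)
        M = np.zeros((n, n), dtype=bool)
        for i, nbrs in enumerate(neighbors):
            M[i, nbrs] = True
        inter = (M.astype(np.int32) @ M.astype(np.int32).T).astype(float)
        sizes = M.sum(axis=1).astype(float)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            J = np.where(union > 0, inter / union, 0.0)
        out = pd.DataFrame(0.0, index=conditions, columns=conditions)
        for a in conditions:
            ia = np.flatnonzero(label_arr == a)
            for b in conditions:
                ib = np.flatnonzero(label_arr == b)
                block = J[np.ix_(ia, ib)]
                if a == b and len(ia) > 1:
                    total = block.sum() - np.trace(block)
                    out.loc[a, b] = total / (len(ia) * (len(ia) - 1))
                else:
                    out.loc[a, b] = float(block.mean())
        return out

    frac = pd.DataFrame(0.0, index=conditions, columns=conditions)
    for cond in conditions:
        cells = np.flatnonzero(label_arr == cond)
        if len(cells) == 0:
            warnings.warn(f"condition {cond!r} has no cells; dropped")
            continue
        acc = {c: 0.0 for c in conditions}
        for c in cells:
            nbr_labels = label_arr[neighbors[c]]
            k = len(nbr_labels)
            for other in conditions:
                acc[other] += float(np.mean(nbr_labels == other)) if k else 0.0
        for other in conditions:
            frac.loc[cond, other] = acc[other] / len(cells)

    sym = (frac + frac.T) / 2.0
    return sym


def cluster_conditions(similarity: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomeration on distance 1 - S; returns the linkage."""
    S = similarity.to_numpy(dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("similarity matrix must be square and symmetric")
    if S.shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")
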