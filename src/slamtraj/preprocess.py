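"""Cell filtering, normalization, HVG selection, gene-set scoring,
cell-cycle regression, and per-condition KNN moments."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import LayeredCountMatrix


@dataclass
class CellFilterConfig:
    """Closed-interval gates on detected genes and mitochondrial fraction."""

    min_genes: int = 2000
    max_genes: int = 5000
    min_mito_frac: float = 0.075
    max_mito_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if self.min_mito_frac >= self.max_mito_frac:
            raise ValueError("min_mito_frac must be < max_mito_frac")


def filter_cells(
    matrix: LayeredCountMatrix,
    mito_gene_set: set[str],
    cfg: CellFilterConfig | None = None,
) -> LayeredCountMatrix:
    """Keep cells passing both range tests on the total layer.

    Detected genes are total-layer entries > 0; the mitochondrial fraction
    is the share of total counts on ``mito_gene_set`` genes. Both ranges are
    closed intervals. Idempotent by construction.
    """
    cfg = cfg or CellFilterConfig()
    unknown = mito_gene_set - set(matrix.genes)
    if unknown:
        raise ValueError(f"mito genes not in matrix: {sorted(unknown)[:5]}")
    total = matrix.layer("total")
    n_detected = (total > 0).sum(axis=0)
    col_sums = total.sum(axis=0)
    mito_idx = [i for i, g in enumerate(matrix.genes) if g in mito_gene_set]
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            col_sums > 0, total[mito_idx, :].sum(axis=0) / col_sums, 0.0
        )
    keep = (
        (n_detected >= cfg.min_genes)
        & (n_detected <= cfg.max_genes)
        & (mito_frac >= cfg.min_mito_frac)
        & (mito_frac <= cfg.max_mito_frac)
    )
    if not keep.any():
        warnings.warn("filter_cells removed every cell", stacklevel=2)
    return matrix.subset_cells(keep)


def normalize_log(
    matrix, target_sum: float | None = None, cells: list[str] | None = None
) -> np.ndarray:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    ``matrix`` may be a LayeredCountMatrix (its total layer is used) or a
    gene x cell array. The default target is the median of column sums.
    """
    if isinstance(matrix, LayeredCountMatrix):
        cells = matrix.cells
        data = matrix.layer("total")
    else:
        data = np.asarray(matrix, dtype=float)
    col_sums = data.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = int(np.flatnonzero(col_sums <= 0)[0])
        name = cells[bad] if cells is not None else f"column {bad}"
        raise ValueError(f"cell {name} has zero total counts")
    if target_sum is None:
        target_sum = float(np.median(col_sums))
    return np.log1p(data * (target_sum / col_sums))


def select_hvg(
    norm_matrix: np.ndarray, genes: list[str], n: int = 2000, n_bins: int = 20
) -> list[str]:
    """Top-n genes by normalized dispersion (variance/mean, z-scored in bins).

    Genes are placed into ``n_bins`` equal-count bins of mean expression;
    dispersion is z-scored within each bin; ties break by gene identifier.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(genes):
        raise ValueError(f"n={n} exceeds gene count {len(genes)}")
    X = np.asarray(norm_matrix, dtype=float)
    mean = X.mean(axis=1)
    var = X.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    ranks = pd.Series(mean).rank(method="first").to_numpy()
    bins = np.ceil(ranks / (len(genes) / n_bins)).astype(int)
    z = np.zeros(len(genes))
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = dispersion[sel].mean(), dispersion[sel].std()
        z[sel] = (dispersion[sel] - mu) / sd if sd > 0 else 0.0
    order = sorted(range(len(genes)), key=lambda i: (-z[i], genes[i]))
    return [genes[i] for i in order[:n]]


def score_gene_set(
    norm_matrix: np.ndarray,
    genes: list[str],
    gene_set: set[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell module score: mean(set genes) - mean(expression-matched controls).

    For every set gene, ``n_ctrl`` control genes are drawn (seeded, with
    replacement) from the same mean-expression bin out of ``n_bins``
    equal-count bins.
    """
    X = np.asarray(norm_matrix, dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}
    set_idx = sorted(gene_index[g] for g in gene_set if g in gene_index)
    if not set_idx:
        raise ValueError("no gene of the set is present in the matrix")
    mean = X.mean(axis=1)
    ranks = pd.Series(mean).rank(method="first").to_numpy()
    bins = np.ceil(ranks / (len(genes) / n_bins)).astype(int)
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    for gi in set_idx:
        pool = bin_members[bins[gi]]
        ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=True))
    set_mean = X[set_idx, :].mean(axis=0)
    ctrl_mean = X[np.asarray(ctrl_idx), :].mean(axis=0)
    return set_mean - ctrl_mean


def regress_out_cell_cycle(
    norm_matrix: np.ndarray,
    genes: list[str],
    s_genes: set[str],
    g2m_genes: set[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Regress the S-minus-G2M score difference out of every gene.

    The covariate is x_c = score_S(c) - score_G2M(c); each gene's expression
    is replaced by the least-squares residual plus the gene's mean, so
    per-gene means are preserved exactly.
    """
    X = np.asarray(norm_matrix, dtype=float)
    s_score = score_gene_set(X, genes, s_genes, n_bins, n_ctrl, seed)
    g2m_score = score_gene_set(X, genes, g2m_genes, n_bins, n_ctrl, seed + 1)
    x = s_score - g2m_score
    xc = x - x.mean()
    var_x = float(xc @ xc)
    if var_x <= 1e-12 * len(x):
        warnings.warn("cell-cycle covariate has zero variance; matrix unchanged")
        return X.copy()
    slope = (X @ xc) / var_x  # per gene
    return X - np.outer(slope, xc)


@dataclass
class MomentsMatrix:
    """KNN-smoothed first-order layer values for one condition."""

    genes: list[str]
    cells: list[str]
    layers: dict[str, np.ndarray]
    n_pcs: int
    k: int
    neighbor_lists: list[np.ndarray] = field(default_factory=list)


def _knn_smooth(values: np.ndarray, neighbor_lists: list[np.ndarray]) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for c, nbrs in enumerate(neighbor_lists):
        idx = np.concatenate(([c], nbrs)).astype(int)
        out[:, c] = values[:, idx].mean(axis=1)
    return out


def compute_moments(
    matrix: LayeredCountMatrix,
    condition_labels: pd.Series | None = None,
    n_pcs: int = 30,
    k: int = 30,
    layers: tuple[str, ...] = ("nascent", "old"),
) -> dict[str, MomentsMatrix]:
    """Smooth layers over a per-condition KNN graph in PCA space.

    PCA (centered, unscaled) is computed on the log-normalized total layer
    within each condition separately; the KNN graph (k Euclidean neighbors,
    symmetrized by union) never crosses conditions, so no smoothing leaks
    between conditions. Smoothed values are means over {cell} + neighbors.
    """
    if condition_labels is None:
        condition_labels = pd.Series("all", index=matrix.cells)
    condition_labels = condition_labels.reindex(matrix.cells)
    if condition_labels.isna().any():
        raise ValueError("every cell needs a condition label")
    out: dict[str, MomentsMatrix] = {}
    for cond in pd.unique(condition_labels):
        cell_idx = np.flatnonzero((condition_labels == cond).to_numpy())
        if len(cell_idx) <= k:
            raise ValueError(
                f"condition {cond!r} has {len(cell_idx)} cells, need > k={k}"
            )
        sub = matrix.subset_cells(cell_idx)
        if k == 0:
            neighbor_lists = [np.empty(0, dtype=int) for _ in range(sub.n_cells)]
        else:
            norm = normalize_log(sub)
            n_comp = min(n_pcs, sub.n_cells - 1, sub.n_genes)
            pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(norm.T)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
            _, idx = nn.kneighbors(pcs)
            directed = [set(row[1:]) for row in idx]  # drop self
            sym = [set(s) for s in directed]
            for i, nbrs in enumerate(directed):
                for j in nbrs:
                    sym[j].add(i)
            neighbor_lists = [np.array(sorted(s), dtype=int) for s in sym]
        smoothed = {
            name: _knn_smooth(sub.layer(name), neighbor_lists) for name in layers
        }
        out[str(cond)] = MomentsMatrix(
            genes=list(sub.genes),
            cells=list(sub.cells),
            layers=smoothed,
            n_pcs=n_pcs,
            k=k,
            neighbor_lists=neighbor_lists,
        )
    return out
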