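"""Clone-wise somatic copy-number scoring from transcriptomes.

A deliberately simplified genomic-smoothing substrate (reference centering
plus a moving average along the genome, no HMM/denoising) feeds the
clone-level statistic: the average per-cell standard deviation across
genomic positions, divided by the same average over all pooled
normal-sample cells. Clones scoring strictly above the highest normal
score are called aberrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom


@dataclass
class SmoothedProfileMatrix:
    """Reference-centered, genomically smoothed expression (gene x cell)."""

    values: pd.DataFrame  # index: gene_id in genomic order
    window: int
    reference_cells: list[str]
    chromosomes: pd.Series  # per ordered gene
    n_dropped_genes: int = 0


def _genomic_order(coords: pd.DataFrame, natural_sort: bool = False) -> pd.DataFrame:
    chroms = list(dict.fromkeys(coords["chrom"]))
    if natural_sort:
        def keyfun(c):
            digits = "".join(ch for ch in c if ch.isdigit())
            return (int(digits) if digits else 1_000_000, c)
        chroms = sorted(chroms, key=keyfun)
    rank = {c: i for i, c in enumerate(chroms)}
    return coords.sort_values(
        by=["chrom", "start"], key=lambda col: col.map(rank) if col.name == "chrom" else col
    )


def smooth_genomic_expression(
    expr: pd.DataFrame,
    coords: pd.DataFrame,
    reference_cells: list[str],
    window: int = 101,
    clip: float = 3.0,
    natural_sort: bool = False,
) -> SmoothedProfileMatrix:
    """Center expression on the reference-cell mean and smooth along the genome.

    ``expr`` is gene x cell; ``coords`` needs columns gene_id, chrom, start.
    Genes are ordered by (chromosome first-appearance order, start); the
    centered values are clipped to +-clip and averaged over a centered
    window of ``window`` genes, truncated at chromosome ends. Smoothing
    never crosses a chromosome boundary. Genes without coordinates are
    dropped (counted).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if not reference_cells:
        raise ValueError("need at least one reference cell")
    missing_ref = [c for c in reference_cells if c not in expr.columns]
    if missing_ref:
        raise ValueError(f"reference cells missing from matrix: {missing_ref[:5]}")
    coords = _genomic_order(coords, natural_sort=natural_sort)
    known = coords["gene_id"].isin(expr.index)
    n_dropped = int((~expr.index.isin(coords["gene_id"])).sum())
    ordered_genes = coords.loc[known, "gene_id"].tolist()
    chroms = coords.loc[known, "chrom"].reset_index(drop=True)

    X = expr.loc[ordered_genes].to_numpy(dtype=float)
    centered = X - X[:, [expr.columns.get_loc(c) for c in reference_cells]].mean(
        axis=1, keepdims=True
    )
    centered = np.clip(centered, -clip, clip)

    smoothed = np.empty_like(centered)
    half = window // 2
    for chrom in chroms.unique():
        idx = np.flatnonzero((chroms == chrom).to_numpy())
        block = centered[idx]
        csum = np.cumsum(np.vstack([np.zeros((1, block.shape[1])), block]), axis=0)
        for j, _ in enumerate(idx):
            lo = max(0, j - half)
            hi = min(len(idx), j + half + 1)
            smoothed[idx[j]] = (csum[hi] - csum[lo]) / (hi - lo)

    values = pd.DataFrame(smoothed, index=ordered_genes, columns=expr.columns)
    return SmoothedProfileMatrix(
        values=values,
        window=window,
        reference_cells=list(reference_cells),
        chromosomes=chroms,
        n_dropped_genes=n_dropped,
    )


def cluster_clones(
    profiles: SmoothedProfileMatrix, k: int = 2
) -> tuple[pd.Series, np.ndarray, bool]:
    """Ward-linkage hierarchical clustering of cell profiles, cut into k groups.

    Returns (clone assignment per cell, linkage matrix, degenerate flag).
    The cut is degenerate when all cells are identical.
    """
    X = profiles.values.to_numpy(dtype=float).T  # cells x genes
    n_cells = X.shape[0]
    if n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    if k > n_cells:
        raise ValueError(f"k={k} exceeds number of cells {n_cells}")
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    degenerate = bool(np.allclose(X, X[0]))
    if degenerate:
        warnings.warn("all cell profiles identical; clone cut is arbitrary")
    assignment = pd.Series(labels, index=profiles.values.columns, name="clone")
    return assignment, Z, degenerate


@dataclass
class CloneScore:
    clone: str | int
    n_cells: int
    score: float
    aberrant: bool | None = None


def scna_score(
    profiles: SmoothedProfileMatrix,
    clone_assignment: pd.Series,
    normal_profiles: pd.DataFrame,
) -> list[CloneScore]:
    """Average per-cell genomic SD per clone over the pooled-normal average.

    The per-cell statistic is the standard deviation across genomic
    positions of that cell's smoothed profile; the denominator pools all
    normal-sample cells.
    """
    if normal_profiles.shape[1] == 0:
        raise ValueError("normal profile set is empty")
    normal_sd = normal_profiles.to_numpy(dtype=float).std(axis=0, ddof=0)
    denom = float(normal_sd.mean())
    if denom <= 0:
        raise ValueError("normal profiles have zero genomic variance")
    scores = []
    for clone in pd.unique(clone_assignment):
        cells = clone_assignment.index[clone_assignment == clone]
        if len(cells) == 0:
            warnings.warn(f"clone {clone!r} has no cells; skipped")
            continue
        cell_sd = profiles.values[cells].to_numpy(dtype=float).std(axis=0, ddof=0)
        scores.append(
            CloneScore(clone=clone, n_cells=len(cells), score=float(cell_sd.mean()) / denom)
        )
    return scores


def call_aberrant(
    scores: list[CloneScore], normal_scores: list[float]
) -> list[CloneScore]:
    """Aberrant iff score strictly exceeds the highest normal score."""
    if not normal_scores:
        raise ValueError("need at least one normal score")
    cutoff = max(normal_scores)
    return [
        CloneScore(s.clone, s.n_cells, s.score, aberrant=bool(s.score > cutoff))
        for s in scores
    ]


def cna_region_enrichment(
    deregulated_genes: set[str],
    region_genes: set[str],
    universe: set[str],
    n_tests: int = 1,
) -> tuple[float, float]:
    """Bonferroni-corrected upper-tail hypergeometric overlap test.

    Returns (raw p, corrected p capped at 1) for the overlap between the
    deregulated set and the region's genes within the universe.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not deregulated_genes <= universe or not region_genes <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    M = len(universe)
    K = len(region_genes)
    n = len(deregulated_genes)
    x = len(deregulated_genes & region_genes)
    p_raw = float(hypergeom.sf(x - 1, M, K, n))
    return p_raw, min(1.0, p_raw * n_tests)
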