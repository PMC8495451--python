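"""Signature-gradient binning and the associated statistics.

Cells are ordered by decreasing signature score and assigned to bins
(near-equal-count by default); per-bin cell-state fractions feed a Pearson
correlation against bin index (t-based significance), a head-vs-rest
chi-squared enrichment per state (BH adjusted), and per-cluster
Kruskal-Wallis plus post hoc one-vs-rest rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class BinTable:
    """Bin assignments plus per-bin per-state counts and fractions."""

    assignments: pd.Series  # per barcode: bin index (0 = start of gradient)
    n_bins: int
    scheme: str
    counts: pd.DataFrame | None = None  # bins x states
    fractions: pd.DataFrame | None = None
    constant_scores: bool = False


@dataclass
class StatResult:
    name: str
    estimate: float
    p: float
    p_adj: float | None = None
    method: str | None = None
    flags: tuple[str, ...] = ()


def assign_bins(
    scores: pd.Series, n_bins: int = 40, scheme: str = "quantile"
) -> BinTable:
    """Order cells by decreasing score and partition them into bins.

    scheme="quantile" yields near-equal-count bins (sizes differ by at most
    one); scheme="width" yields equal score-width bins. Bin 0 is the start
    of the gradient (highest scores). Ties break by barcode.
    """
    scores = pd.Series(scores)
    if n_bins > len(scores):
        raise ValueError(f"n_bins={n_bins} exceeds cell count {len(scores)}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if scheme not in ("quantile", "width"):
        raise ValueError(f"unknown scheme {scheme!r}")
    constant = bool(np.ptp(scores.to_numpy(dtype=float)) == 0)
    if constant:
        warnings.warn("constant scores: all cells fall into one effective bin")
    order = sorted(scores.index, key=lambda bc: (-scores[bc], bc))
    n = len(order)
    if scheme == "quantile":
        # first (n % n_bins) bins take the extra cell
        base, extra = divmod(n, n_bins)
        sizes = [base + (1 if b < extra else 0) for b in range(n_bins)]
        bins = np.repeat(np.arange(n_bins), sizes)
    else:
        smax, smin = scores[order[0]], scores[order[-1]]
        span = smax - smin
        if span == 0:
            bins = np.zeros(n, dtype=int)
        else:
            # descending score -> ascending bin index
            vals = scores.loc[order].to_numpy(dtype=float)
            bins = np.minimum(((smax - vals) / span * n_bins).astype(int), n_bins - 1)
    assignments = pd.Series(bins, index=pd.Index(order, name="barcode"), name="bin")
    return BinTable(
        assignments=assignments, n_bins=n_bins, scheme=scheme, constant_scores=constant
    )


def state_distribution(bin_table: BinTable, state_labels: pd.Series) -> BinTable:
    """Fill per-bin per-state counts and row-normalized fractions."""
    states = pd.Series(state_labels).reindex(bin_table.assignments.index)
    if states.isna().any():
        missing = states.index[states.isna()][:5].tolist()
        raise ValueError(f"cells without a state label: {missing}")
    df = pd.DataFrame({"bin": bin_table.assignments, "state": states})
    counts = (
        df.groupby(["bin", "state"], observed=False).size().unstack(fill_value=0)
    )
    counts = counts.reindex(range(bin_table.n_bins), fill_value=0)
    row_sums = counts.sum(axis=1)
    fractions = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return BinTable(
        assignments=bin_table.assignments,
        n_bins=bin_table.n_bins,
        scheme=bin_table.scheme,
        counts=counts,
        fractions=fractions,
        constant_scores=bin_table.constant_scores,
    )


def gradient_correlation(bin_table: BinTable, state: str) -> StatResult:
    """Pearson r between bin index and state fraction, t-based p-value."""
    if bin_table.fractions is None:
        raise ValueError("call state_distribution first")
    if state not in bin_table.fractions.columns:
        raise KeyError(f"state {state!r} not present")
    y = bin_table.fractions[state].to_numpy(dtype=float)
    x = np.arange(1, bin_table.n_bins + 1, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 bins")
    if np.ptp(y) == 0:
        return StatResult(
            name=f"pearson:{state}", estimate=np.nan, p=np.nan,
            method="pearson-t", flags=("zero_variance",),
        )
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return StatResult(name=f"pearson:{state}", estimate=r, p=p, method="pearson-t")


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    n = table.sum()
    a, b, c, d = table.ravel()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("table has a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def state_enrichment_test(
    bin_table: BinTable,
    state_labels: pd.Series,
    head_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-state head-vs-rest 2x2 chi-squared, BH-adjusted across states.

    The "start of the gradient" is the first ``head_fraction`` of bins.
    Rows: state, chi2, p, p_adj, odds direction, skipped flag.
    """
    if not 0 < head_fraction < 1:
        raise ValueError("head_fraction must be in (0, 1)")
    states = pd.Series(state_labels).reindex(bin_table.assignments.index)
    if states.isna().any():
        raise ValueError("every cell needs a state label")
    head_bins = max(1, int(round(head_fraction * bin_table.n_bins)))
    in_head = bin_table.assignments < head_bins
    rows = []
    for state in sorted(states.unique()):
        is_state = states == state
        table = np.array(
            [
                [int((is_state & in_head).sum()), int((is_state & ~in_head).sum())],
                [int((~is_state & in_head).sum()), int((~is_state & ~in_head).sum())],
            ]
        )
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected == 0).any():
            rows.append((state, np.nan, np.nan, True, 0.0))
            continue
        chi2, p = chi2_2x2(table)
        head_rate = table[0, 0] / table[0, :].sum()
        rest_rate = table[1, 0] / table[1, :].sum()
        rows.append((state, chi2, p, False, np.sign(head_rate - rest_rate)))
    out = pd.DataFrame(rows, columns=["state", "chi2", "p", "skipped", "direction"])
    ok = ~out["skipped"]
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def cluster_signature_tests(
    signature_scores: pd.DataFrame,
    cluster_labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis per signature plus post hoc one-vs-rest rank-sum tests.

    Signatures whose FDR-adjusted Kruskal-Wallis p is < ``alpha`` get a post
    hoc Wilcoxon rank-sum test of each cluster against all others,
    BH-adjusted within the signature. Star coding: * < 0.05, ** < 0.01,
    *** < 0.001 on adjusted p. Singleton clusters are excluded.
    """
    labels = pd.Series(cluster_labels).reindex(signature_scores.index)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    sizes = labels.value_counts()
    small = sizes.index[sizes < 2].tolist()
    if small:
        warnings.warn(f"excluding singleton clusters: {small}")
        keep = ~labels.isin(small)
        signature_scores = signature_scores.loc[keep]
        labels = labels.loc[keep]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters with >= 2 cells")

    kw_rows = []
    for sig in signature_scores.columns:
        groups = [signature_scores.loc[labels == cl, sig].to_numpy() for cl in clusters]
        H, p = stats.kruskal(*groups)
        kw_rows.append((sig, float(H), float(p)))
    kw = pd.DataFrame(kw_rows, columns=["signature", "H", "p"])
    kw["p_adj"] = multipletests(kw["p"], method="fdr_bh")[1]

    post_rows = []
    for sig, p_adj in zip(kw["signature"], kw["p_adj"]):
        if p_adj >= alpha:
            continue
        raw = []
        for cl in clusters:
            in_cl = (labels == cl).to_numpy()
            a = signature_scores.loc[in_cl, sig].to_numpy()
            b = signature_scores.loc[~in_cl, sig].to_numpy()
            w, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            raw.append((cl, float(w), float(p)))
        adj = multipletests([p for _, _, p in raw], method="fdr_bh")[1]
        for (cl, w, p), pa in zip(raw, adj):
            stars = "***" if pa < 0.001 else "**" if pa < 0.01 else "*" if pa < 0.05 else ""
            post_rows.append((sig, cl, w, p, float(pa), stars))
    post = pd.DataFrame(
        post_rows, columns=["signature", "cluster", "W", "p", "p_adj", "stars"]
    )
    return kw.merge(post, on="signature", how="left", suffixes=("_kw", "_posthoc"))
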