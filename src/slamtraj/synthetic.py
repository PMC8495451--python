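"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline is tested against fixtures produced
here: barcoded/UMI'd read observations carrying T->C conversions, cell
populations evolving under two-layer kinetic ODEs, genomically ordered
expression with clonal gain/loss segments, and multi-condition embeddings
with controllable overlap.

All generators are deterministic for a fixed config (identical seed =>
bit-identical output). The kinetic simulator evaluates the ODE solution
through its own closed form, independent of the fitting code in
:mod:`slamtraj.kinetics`, so recovery tests are not circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import LayeredCountMatrix

_BASES = np.array(list("ACGT"))


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _umi_string(code: int, length: int = 8) -> str:
    chars = []
    for _ in range(length):
        chars.append("ACGT"[code & 3])
        code >>= 2
    return "".join(chars)


@dataclass
class ReadSimConfig:
    """Parameters of the read-level conversion simulator.

    ``labeled_fraction`` is the probability that a molecule was transcribed
    during the labeling window; ``conversion_rate`` is the per-T probability
    of a T->C conversion on a labeled molecule; ``error_rate`` is the
    per-base sequencing error probability applied independently per read.
    """

    n_genes: int = 10
    n_cells: int = 20
    mean_molecules_per_cell: float = 50.0
    mean_reads_per_molecule: float = 1.5
    labeled_fraction: float = 0.3
    conversion_rate: float = 0.05
    error_rate: float = 0.0
    mean_T_per_read: float = 20.0
    snp_density: float = 0.0
    seed: int = 0
    gene_length: int = 400
    read_length: int = 80
    n_chromosomes: int = 2

    def __post_init__(self) -> None:
        _check_prob("labeled_fraction", self.labeled_fraction)
        _check_prob("conversion_rate", self.conversion_rate)
        _check_prob("error_rate", self.error_rate)
        _check_prob("snp_density", self.snp_density)
        for name in ("n_genes", "n_cells", "gene_length", "read_length", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.read_length > self.gene_length:
            raise ValueError("read_length must not exceed gene_length")
        for name in ("mean_molecules_per_cell", "mean_reads_per_molecule", "mean_T_per_read"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReadSimResult:
    """Reads plus companion truth and annotation tables.

    ``reads`` columns: barcode, umi, gene_id, covered_T, converted,
    other_mismatch (position lists comma-joined, gene-local 0-based on the
    transcribed strand). ``truth`` has one row per (barcode, umi, gene_id)
    molecule. ``snps`` lists simulated SNP positions (gene-local).
    ``gene_table`` holds coordinates/strand; ``gene_t_positions`` the
    reference T offsets per gene.
    """

    reads: pd.DataFrame
    truth: pd.DataFrame
    snps: pd.DataFrame
    gene_table: pd.DataFrame
    gene_t_positions: dict[str, np.ndarray]


def _join(positions: Sequence[int]) -> str:
    return ",".join(str(int(p)) for p in sorted(positions))


def simulate_reads(cfg: ReadSimConfig) -> ReadSimResult:
    """Simulate barcoded/UMI'd read observations with T->C conversions.

    Labeled molecules acquire conversions per T position with probability
    ``conversion_rate``; all reads additionally acquire errors per base with
    probability ``error_rate`` (uniform substitution, so an error at a T
    yields C with probability 1/3). Reads of one molecule share the
    molecule's conversion events but each covers a random subinterval.
    Heterozygous SNPs at density ``snp_density`` put the alternative allele
    on half the molecules, producing consistent false conversions (T->C
    SNPs) or other mismatches removable only via the SNP mask.
    """
    rng = np.random.default_rng(cfg.seed)
    t_density = min(1.0, cfg.mean_T_per_read / cfg.read_length)

    genes = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    cells = [f"cell{c:04d}" for c in range(cfg.n_cells)]

    # reference layout per gene: T positions, the rest A; strand alternates
    gene_t_positions: dict[str, np.ndarray] = {}
    gene_rows = []
    snp_rows = []
    snp_is_t: dict[str, dict[int, bool]] = {}
    per_chrom_offset: dict[str, int] = {}
    for gi, gene in enumerate(genes):
        is_t = rng.random(cfg.gene_length) < t_density
        gene_t_positions[gene] = np.flatnonzero(is_t)
        chrom = f"chr{(gi % cfg.n_chromosomes) + 1}"
        offset = per_chrom_offset.get(chrom, 0)
        start = offset
        end = start + cfg.gene_length
        per_chrom_offset[chrom] = end + 100
        strand = "+" if gi % 2 == 0 else "-"
        gene_rows.append((gene, chrom, start, end, strand))
        snp_mask = rng.random(cfg.gene_length) < cfg.snp_density
        snp_pos = np.flatnonzero(snp_mask)
        snp_is_t[gene] = {}
        for p in snp_pos:
            snp_rows.append((gene, int(p), bool(is_t[p])))
            snp_is_t[gene][int(p)] = bool(is_t[p])
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    snps = pd.DataFrame(snp_rows, columns=["gene_id", "pos", "ref_is_T"])

    read_rows = []
    truth_rows = []
    max_start = cfg.gene_length - cfg.read_length
    for cell in cells:
        n_mol = int(rng.poisson(cfg.mean_molecules_per_cell))
        if n_mol == 0:
            continue
        gene_idx = rng.integers(0, cfg.n_genes, size=n_mol)
        labeled = rng.random(n_mol) < cfg.labeled_fraction
        umi_codes: set[int] = set()
        for m in range(n_mol):
            code = int(rng.integers(0, 4**8))
            while code in umi_codes:
                code = int(rng.integers(0, 4**8))
            umi_codes.add(code)
            umi = _umi_string(code)
            gene = genes[gene_idx[m]]
            t_pos = gene_t_positions[gene]

            # molecule-level state: which T positions carry a conversion
            converted_mask = np.zeros(len(t_pos), dtype=bool)
            if labeled[m] and cfg.conversion_rate > 0:
                converted_mask = rng.random(len(t_pos)) < cfg.conversion_rate
            # heterozygous SNP alleles, consistent across reads of a molecule
            snp_alt: dict[int, bool] = {}
            for p, ref_t in snp_is_t[gene].items():
                snp_alt[p] = bool(rng.random() < 0.5)
            converted_pos = set(int(p) for p in t_pos[converted_mask])
            for p, ref_t in snp_is_t[gene].items():
                if snp_alt[p] and ref_t:
                    converted_pos.add(p)  # alt allele C at a reference T

            n_reads = 1 + int(rng.poisson(max(cfg.mean_reads_per_molecule - 1.0, 0.0)))
            n_true_conv = len(converted_pos)
            truth_rows.append((cell, umi, gene, bool(labeled[m]), n_true_conv))

            for _ in range(n_reads):
                start = int(rng.integers(0, max_start + 1))
                stop = start + cfg.read_length
                cov_t = t_pos[(t_pos >= start) & (t_pos < stop)]
                conv = [int(p) for p in cov_t if int(p) in converted_pos]
                other = []
                # non-T SNPs with alt allele show as consistent mismatches
                for p, ref_t in snp_is_t[gene].items():
                    if start <= p < stop and snp_alt[p] and not ref_t:
                        other.append(p)
                if cfg.error_rate > 0:
                    conv_set = set(conv)
                    other_set = set(other)
                    err = rng.random(cfg.read_length) < cfg.error_rate
                    cov_t_set = set(int(p) for p in cov_t)
                    for off in np.flatnonzero(err):
                        p = start + int(off)
                        sub = int(rng.integers(0, 3))  # index among 3 non-ref bases
                        if p in cov_t_set:
                            if p in conv_set:
                                # observed base was C; error -> A/G/T
                                conv_set.discard(p)
                                if sub != 2:  # A or G: mismatch; T: looks unconverted
                                    other_set.add(p)
                            else:
                                # observed base was T; error -> A/C/G
                                if sub == 1:
                                    conv_set.add(p)  # false conversion
                                else:
                                    other_set.add(p)
                        else:
                            other_set.add(p)  # non-T base; any substitution mismatches
                    conv = sorted(conv_set)
                    other = sorted(other_set)
                read_rows.append(
                    (cell, umi, gene, _join(cov_t), _join(conv), _join(other))
                )

    reads = pd.DataFrame(
        read_rows,
        columns=["barcode", "umi", "gene_id", "covered_T", "converted", "other_mismatch"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["barcode", "umi", "gene_id", "labeled", "n_true_conversions"]
    )
    return ReadSimResult(reads, truth, snps, gene_table, gene_t_positions)


# ---------------------------------------------------------------------------
# kinetic population simulator
# ---------------------------------------------------------------------------


@dataclass
class KineticSimConfig:
    """Ranges for per-gene kinetic parameters and the count noise model."""

    n_genes: int = 100
    n_cells: int = 300
    alpha_range: tuple[float, float] = (5.0, 20.0)
    beta_range: tuple[float, float] = (0.8, 1.25)
    gamma_range: tuple[float, float] = (0.25, 0.6)
    t_switch_range: tuple[float, float] = (6.0, 12.0)
    t_max: float = 16.0
    noise: str = "poisson"  # "poisson" | "nb" | "none"
    nb_dispersion: float = 10.0
    one_sided_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_range", "beta_range", "gamma_range", "t_switch_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive with lo <= hi")
        if not 0 < self.t_switch_range[1] <= self.t_max:
            raise ValueError("t_switch range must lie in (0, t_max]")
        if self.noise not in ("poisson", "nb", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        _check_prob("one_sided_fraction", self.one_sided_fraction)


def _closed_form_uv(alpha, beta, gamma, t_switch, t):
    """Independent closed-form evaluation of the two-layer ODE.

    Induction from (0, 0) up to ``t_switch``, then repression with alpha=0.
    Written without reference to the fitting module on purpose.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    u_inf = alpha / beta
    s_inf = alpha / gamma
    near_degenerate = abs(gamma - beta) < 1e-9 * max(gamma, beta)

    def s_ind(tt):
        if near_degenerate:
            return s_inf * (1 - np.exp(-gamma * tt)) - alpha * tt * np.exp(-gamma * tt)
        return s_inf * (1 - np.exp(-gamma * tt)) + alpha * (
            np.exp(-gamma * tt) - np.exp(-beta * tt)
        ) / (gamma - beta)

    u = np.empty_like(t)
    s = np.empty_like(t)
    ind = t <= t_switch
    u[ind] = u_inf * (1 - np.exp(-beta * t[ind]))
    s[ind] = s_ind(t[ind])
    rep = ~ind
    if np.any(rep):
        u0 = u_inf * (1 - np.exp(-beta * t_switch))
        s0 = s_ind(t_switch)
        dt = t[rep] - t_switch
        u[rep] = u0 * np.exp(-beta * dt)
        if near_degenerate:
            s[rep] = s0 * np.exp(-gamma * dt) + beta * u0 * dt * np.exp(-gamma * dt)
        else:
            s[rep] = s0 * np.exp(-gamma * dt) + beta * u0 * (
                np.exp(-beta * dt) - np.exp(-gamma * dt)
            ) / (gamma - beta)
    return u, s


def kinetic_expectations(alpha, beta, gamma, t_switch, t, mode="two_sided"):
    """Noise-free (u, s) expectations for one gene at times ``t``.

    ``mode`` selects the observed dynamic range: two-sided genes follow
    induction then repression around ``t_switch``; induction-only genes never
    switch; repression-only genes start at the induction steady state and
    decay from t=0.
    """
    t = np.asarray(t, dtype=float)
    if mode == "induction":
        return _closed_form_uv(alpha, beta, gamma, np.inf, t)
    if mode == "repression":
        u0 = alpha / beta
        s0 = alpha / gamma
        u = u0 * np.exp(-beta * t)
        if abs(gamma - beta) < 1e-9 * max(gamma, beta):
            s = s0 * np.exp(-gamma * t) + beta * u0 * t * np.exp(-gamma * t)
        else:
            s = s0 * np.exp(-gamma * t) + beta * u0 * (
                np.exp(-beta * t) - np.exp(-gamma * t)
            ) / (gamma - beta)
        return u, s
    if mode == "two_sided":
        return _closed_form_uv(alpha, beta, gamma, t_switch, t)
    raise ValueError(f"unknown mode {mode!r}")


def simulate_kinetic_population(
    cfg: KineticSimConfig,
) -> tuple[LayeredCountMatrix, dict]:
    """Simulate a cell population under per-gene two-layer kinetics.

    Returns the layered count matrix (layers "nascent" = u, "old" = s,
    "total") and a truth dict with per-cell true times and the per-gene
    parameter table.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    cells = [f"cell{c:04d}" for c in range(cfg.n_cells)]

    t_true = np.sort(rng.uniform(0.0, cfg.t_max, size=cfg.n_cells))
    alpha = np.exp(rng.uniform(*np.log(cfg.alpha_range), size=cfg.n_genes))
    beta = np.exp(rng.uniform(*np.log(cfg.beta_range), size=cfg.n_genes))
    gamma = np.exp(rng.uniform(*np.log(cfg.gamma_range), size=cfg.n_genes))
    t_switch = rng.uniform(*cfg.t_switch_range, size=cfg.n_genes)

    modes = np.array(["two_sided"] * cfg.n_genes, dtype=object)
    n_one = int(round(cfg.one_sided_fraction * cfg.n_genes))
    if n_one:
        one_idx = rng.choice(cfg.n_genes, size=n_one, replace=False)
        half = n_one // 2
        modes[one_idx[:half]] = "induction"
        modes[one_idx[half:]] = "repression"

    u_mean = np.zeros((cfg.n_genes, cfg.n_cells))
    s_mean = np.zeros((cfg.n_genes, cfg.n_cells))
    for g in range(cfg.n_genes):
        u_mean[g], s_mean[g] = kinetic_expectations(
            alpha[g], beta[g], gamma[g], t_switch[g], t_true, mode=modes[g]
        )

    if cfg.noise == "none":
        nascent = u_mean.copy()
        old = s_mean.copy()
    elif cfg.noise == "poisson":
        nascent = rng.poisson(u_mean).astype(float)
        old = rng.poisson(s_mean).astype(float)
    else:  # negative binomial, variance mu + mu^2/theta
        theta = cfg.nb_dispersion
        nascent = np.where(
            u_mean > 0, rng.negative_binomial(theta, theta / (theta + u_mean)), 0
        ).astype(float)
        old = np.where(
            s_mean > 0, rng.negative_binomial(theta, theta / (theta + s_mean)), 0
        ).astype(float)

    matrix = LayeredCountMatrix(
        genes=genes,
        cells=cells,
        layers={"nascent": nascent, "old": old, "total": nascent + old},
    )
    params = pd.DataFrame(
        {
            "gene_id": genes,
            "alpha": alpha,
            "beta": beta,
            "gamma": gamma,
            "t_switch": t_switch,
            "mode": modes,
        }
    )
    truth = {
        "t": pd.Series(t_true, index=cells, name="t_true"),
        "params": params,
        "u_mean": u_mean,
        "s_mean": s_mean,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# clonal copy-number expression simulator
# ---------------------------------------------------------------------------


@dataclass
class CloneSimConfig:
    """Genomically ordered expression with clonal gain/loss segments.

    ``segments[k]`` lists (chrom_index, start_gene, end_gene, shift) tuples
    for clone ``k`` (end exclusive, indices within the chromosome's gene
    range). Normal cells carry no shift.
    """

    n_genes: int = 400
    n_chromosomes: int = 2
    n_normal_cells: int = 100
    n_clone_cells: tuple[int, ...] = (100,)
    segments: tuple[tuple[tuple[int, int, int, float], ...], ...] = (((0, 20, 60, 1.0),),)
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes")
        if len(self.segments) != len(self.n_clone_cells):
            raise ValueError("segments and n_clone_cells must have one entry per clone")
        per_chrom = self.n_genes // self.n_chromosomes
        for clone_segments in self.segments:
            by_chrom: dict[int, list[tuple[int, int]]] = {}
            for chrom, start, end, _shift in clone_segments:
                if not (0 <= chrom < self.n_chromosomes):
                    raise ValueError(f"chromosome index {chrom} out of range")
                if not (0 <= start < end <= per_chrom):
                    raise ValueError(f"segment ({start}, {end}) outside gene range")
                for s0, e0 in by_chrom.get(chrom, []):
                    if start < e0 and s0 < end:
                        raise ValueError("overlapping segments within one clone")
                by_chrom.setdefault(chrom, []).append((start, end))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_clone_expression(
    cfg: CloneSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Simulate genomically ordered expression for normal cells plus clones.

    Returns (expression gene x cell DataFrame, gene coordinate BED-like
    table, clone labels per cell, is_normal flags per cell).
    """
    rng = np.random.default_rng(cfg.seed)
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    n_genes = per_chrom * cfg.n_chromosomes
    genes, bed_rows = [], []
    for c in range(cfg.n_chromosomes):
        for i in range(per_chrom):
            gene = f"gene{c * per_chrom + i:04d}"
            genes.append(gene)
            bed_rows.append((f"chr{c + 1}", i * 1000, i * 1000 + 500, gene, 0, "+"))
    coords = pd.DataFrame(
        bed_rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"]
    )

    cells, labels = [], []
    shifts_by_cell = []
    zero_shift = np.zeros(n_genes)
    for i in range(cfg.n_normal_cells):
        cells.append(f"normal{i:04d}")
        labels.append("normal")
        shifts_by_cell.append(zero_shift)
    for k, n_cells in enumerate(cfg.n_clone_cells):
        shift = np.zeros(n_genes)
        for chrom, start, end, value in cfg.segments[k]:
            shift[chrom * per_chrom + start : chrom * per_chrom + end] += value
        for i in range(n_cells):
            cells.append(f"clone{k}_{i:04d}")
            labels.append(f"clone{k}")
            shifts_by_cell.append(shift)

    base = np.stack(shifts_by_cell, axis=1)  # genes x cells
    expr = base + rng.normal(0.0, cfg.noise_sd, size=base.shape)
    expression = pd.DataFrame(expr, index=genes, columns=cells)
    clone_labels = pd.Series(labels, index=cells, name="clone")
    is_normal = pd.Series([lab == "normal" for lab in labels], index=cells, name="is_normal")
    return expression, coords, clone_labels, is_normal


# ---------------------------------------------------------------------------
# multi-condition embedding simulator
# ---------------------------------------------------------------------------


def simulate_condition_dataset(
    n_conditions: int,
    n_cells_per_condition: int,
    separation: float,
    dim: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, pd.Series]:
    """Gaussian blobs: condition c is centered at separation * e_c.

    Unit isotropic noise; with separation 0 all conditions are exchangeable.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if n_conditions < 1 or n_cells_per_condition < 1:
        raise ValueError("need at least one condition and one cell")
    rng = np.random.default_rng(seed)
    n = n_conditions * n_cells_per_condition
    points = rng.normal(size=(n, dim))
    labels = []
    for c in range(n_conditions):
        sl = slice(c * n_cells_per_condition, (c + 1) * n_cells_per_condition)
        points[sl, c % dim] += separation
        labels.extend([f"cond{c}"] * n_cells_per_condition)
    index = pd.Index([f"cell{i:05d}" for i in range(n)], name="barcode")
    return points, pd.Series(labels, index=index, name="condition")
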