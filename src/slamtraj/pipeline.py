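"""End-to-end pipeline: simulate -> quantify -> preprocess -> kinetics ->
scna -> similarity -> gradient, with a structured run log."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import gradient as gradient_mod
from . import io as io_mod
from . import kinetics as kin
from . import preprocess as pp
from . import scna as scna_mod
from . import similarity as sim_mod
from . import slam, synthetic
from .config import write_resolved_config


class RunLog:
    """Timestamped structured events, one line per discard/flag/stage."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, stage: str, event: str, **fields) -> None:
        self.events.append(
            {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage,
             "event": event, **fields}
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev, sort_keys=True, default=str) + "\n")


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute every stage on synthetic data as configured.

    All randomness derives from config["seed"]; rerunning with the same
    config yields byte-identical text outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    seed = int(config["seed"])
    write_resolved_config(config, out)

    # --- simulate ---------------------------------------------------------
    sim_cfg = config["simulate"]
    read_cfg = synthetic.ReadSimConfig(seed=seed, **sim_cfg["reads"])
    read_sim = synthetic.simulate_reads(read_cfg)
    io_mod.write_tsv(read_sim.reads, out / "reads.tsv")
    io_mod.write_tsv(read_sim.truth, out / "read_truth.tsv")
    io_mod.write_bed(read_sim.gene_table, out / "genes.bed")
    io_mod.write_minimal_vcf(io_mod.snp_records_from_sim(read_sim), out / "snps.vcf")
    log.add("simulate", "reads", n_reads=len(read_sim.reads),
            n_molecules=len(read_sim.truth))

    kin_cfg = synthetic.KineticSimConfig(seed=seed + 1, **sim_cfg["kinetics"])
    kin_matrix, kin_truth = synthetic.simulate_kinetic_population(kin_cfg)
    io_mod.write_layered_matrix(kin_matrix, out / "kinetic_counts")
    io_mod.write_tsv(kin_truth["params"], out / "kinetic_truth_params.tsv")
    log.add("simulate", "kinetic_population", n_genes=kin_matrix.n_genes,
            n_cells=kin_matrix.n_cells)

    clone_cfg_raw = dict(sim_cfg["clones"])
    shift = clone_cfg_raw.pop("shift")
    n_genes = clone_cfg_raw["n_genes"]
    per_chrom = n_genes // 2
    clone_cfg = synthetic.CloneSimConfig(
        seed=seed + 2,
        segments=tuple(
            ((0, 0, per_chrom // 2, shift),) for _ in clone_cfg_raw["n_clone_cells"]
        ),
        n_clone_cells=tuple(clone_cfg_raw.pop("n_clone_cells")),
        **clone_cfg_raw,
    )
    expr, clone_coords, clone_labels, is_normal = synthetic.simulate_clone_expression(
        clone_cfg
    )
    expr.rename_axis("gene_id").reset_index().to_csv(
        out / "clone_expression.tsv", sep="\t", index=False, float_format="%.6g",
        lineterminator="\n",
    )
    io_mod.write_bed(clone_coords, out / "clone_genes.bed")
    io_mod.write_tsv(
        pd.DataFrame({"barcode": clone_labels.index, "clone": clone_labels.values,
                      "is_normal": is_normal.values}),
        out / "clone_truth.tsv",
    )
    log.add("simulate", "clone_expression", n_cells=expr.shape[1])

    cond_cfg = sim_cfg["conditions"]
    embedding, cond_labels = synthetic.simulate_condition_dataset(
        cond_cfg["n_conditions"], cond_cfg["n_cells_per_condition"],
        cond_cfg["separation"], cond_cfg["dim"], seed=seed + 3,
    )
    emb_df = pd.DataFrame(
        embedding, index=cond_labels.index,
        columns=[f"dim{i}" for i in range(embedding.shape[1])],
    )
    io_mod.write_tsv(emb_df.reset_index(), out / "embedding.tsv")
    io_mod.write_tsv(cond_labels.reset_index(), out / "condition_labels.tsv")
    log.add("simulate", "conditions", n_cells=len(cond_labels))

    # --- quantify ---------------------------------------------------------
    mask = slam.parse_snp_mask(out / "snps.vcf").to_gene_frame(read_sim.gene_table)
    matrix, collapse = slam.quantify_reads(read_sim.reads, mask)
    io_mod.write_layered_matrix(matrix, out / "slam_counts")
    io_mod.write_tsv(collapse.audit, out / "molecule_audit.tsv")
    io_mod.write_tsv(collapse.discard, out / "molecule_discard.tsv")
    log.add("quantify", "molecules", n_calls=len(collapse.calls),
            n_discarded=int(collapse.discard["count"].sum()))

    # --- preprocess + kinetics (on the kinetic simulation) ----------------
    matrix_k = kin_matrix
    if config["filter"]["enabled"]:
        fcfg = pp.CellFilterConfig(
            min_genes=config["filter"]["min_genes"],
            max_genes=config["filter"]["max_genes"],
            min_mito_frac=config["filter"]["mito_range"][0],
            max_mito_frac=config["filter"]["mito_range"][1],
        )
        matrix_k = pp.filter_cells(matrix_k, set(), fcfg)
        log.add("preprocess", "filter_cells", n_cells=matrix_k.n_cells)
    nonzero = matrix_k.layer("total").sum(axis=0) > 0
    if not nonzero.all():
        matrix_k = matrix_k.subset_cells(nonzero)
        log.add("preprocess", "drop_zero_count_cells",
                n_dropped=int((~nonzero).sum()))
    k = min(config["moments"]["k"], matrix_k.n_cells - 1)
    moments = pp.compute_moments(
        matrix_k, n_pcs=config["moments"]["n_pcs"], k=k
    )["all"]
    log.add("preprocess", "moments", k=k, n_pcs=config["moments"]["n_pcs"])

    root = kin.RootPrior(
        root_cells=frozenset(moments.cells[: max(1, len(moments.cells) // 10)]),
        penalty=float(config["kinetics"]["lambda"]),
        theta=float(config["kinetics"]["theta"]),
    )
    fits = kin.fit_all_genes(
        moments,
        root=root if root.penalty > 0 else None,
        min_shared=config["kinetics"]["min_shared"],
        max_iter=config["kinetics"]["max_iter"],
        tol=config["kinetics"]["tol"],
    )
    fit_rows = [
        (g, f.params.alpha, f.params.beta, f.params.gamma, f.params.t_switch,
         f.loss, f.one_sided, f.mode, f.converged, f.degenerate)
        for g, f in sorted(fits.items())
    ]
    io_mod.write_tsv(
        pd.DataFrame(fit_rows, columns=["gene", "alpha", "beta", "gamma", "t_switch",
                                        "loss", "one_sided", "orientation",
                                        "converged", "degenerate"]),
        out / "kinetic_fits.tsv",
    )
    tau, n_inf = kin.compute_latent_time(fits, moments.cells)
    io_mod.write_tsv(
        pd.DataFrame({"barcode": moments.cells, "latent_time": tau,
                      "n_informative_genes": n_inf}),
        out / "latent_time.tsv",
    )
    velocities = kin.velocity_matrix(fits, moments)
    edges = kin.velocity_graph(
        velocities, moments.layers["old"], moments.neighbor_lists
    )
    io_mod.write_tsv(
        pd.DataFrame(edges, columns=["cell", "neighbor", "score"]),
        out / "velocity_graph.tsv",
    )
    log.add("kinetics", "fits", n_genes=len(fits))

    # --- scna -------------------------------------------------------------
    normal_cells = is_normal.index[is_normal].tolist()
    profiles = scna_mod.smooth_genomic_expression(
        expr, clone_coords, normal_cells,
        window=config["scna"]["window"], clip=config["scna"]["clip"],
    )
    tumor_cells = is_normal.index[~is_normal].tolist()
    tumor_profiles = scna_mod.SmoothedProfileMatrix(
        values=profiles.values[tumor_cells], window=profiles.window,
        reference_cells=profiles.reference_cells, chromosomes=profiles.chromosomes,
    )
    assignment, _, _ = scna_mod.cluster_clones(tumor_profiles, k=config["scna"]["k"])
    normal_profile_vals = profiles.values[normal_cells]
    scores = scna_mod.scna_score(tumor_profiles, assignment, normal_profile_vals)
    # normal "samples" for the cutoff: split normals in half as pseudo-samples
    half = len(normal_cells) // 2
    normal_scores = [
        s.score
        for s in scna_mod.scna_score(
            scna_mod.SmoothedProfileMatrix(
                values=profiles.values[normal_cells], window=profiles.window,
                reference_cells=profiles.reference_cells,
                chromosomes=profiles.chromosomes,
            ),
            pd.Series(
                ["normalA"] * half + ["normalB"] * (len(normal_cells) - half),
                index=normal_cells,
            ),
            normal_profile_vals,
        )
    ]
    called = scna_mod.call_aberrant(scores, normal_scores)
    io_mod.write_tsv(
        pd.DataFrame(
            [(c.clone, c.n_cells, c.score, c.aberrant) for c in called],
            columns=["clone", "n_cells", "score", "aberrant"],
        ),
        out / "scna_scores.tsv",
    )
    io_mod.write_tsv(
        pd.DataFrame({"barcode": assignment.index, "clone": assignment.values}),
        out / "scna_clones.tsv",
    )
    log.add("scna", "scores", n_clones=len(called))

    # --- similarity -------------------------------------------------------
    k_sim = min(config["similarity"]["k"], len(cond_labels) - 1)
    nbrs = sim_mod.knn_neighbors(embedding, k=k_sim)
    S = sim_mod.condition_similarity(
        nbrs, cond_labels, metric=config["similarity"]["metric"]
    )
    S.rename_axis("condition").reset_index().to_csv(
        out / "condition_similarity.tsv", sep="\t", index=False,
        float_format="%.6g", lineterminator="\n",
    )
    Z = sim_mod.cluster_conditions(S)
    io_mod.write_tsv(
        pd.DataFrame(Z, columns=["left", "right", "height", "size"]),
        out / "condition_linkage.tsv",
    )
    log.add("similarity", "matrix", k=k_sim)

    # --- gradient ---------------------------------------------------------
    # demo gradient: order tumor cells by their first principal genomic
    # profile component and test clone enrichment along it
    from sklearn.decomposition import PCA

    pc1 = PCA(n_components=1, svd_solver="full").fit_transform(
        profiles.values[tumor_cells].to_numpy(dtype=float).T
    )[:, 0]
    scores_series = pd.Series(pc1, index=tumor_cells)
    n_bins = min(config["gradient"]["n_bins"], len(tumor_cells))
    bins = gradient_mod.assign_bins(
        scores_series, n_bins=n_bins, scheme=config["gradient"]["scheme"]
    )
    table = gradient_mod.state_distribution(bins, clone_labels.loc[tumor_cells])
    io_mod.write_tsv(
        table.fractions.rename_axis("bin").reset_index(), out / "gradient_bins.tsv"
    )
    stats_rows = []
    enrich = gradient_mod.state_enrichment_test(
        table, clone_labels.loc[tumor_cells],
        head_fraction=config["gradient"]["head_fraction"],
    )
    for state in table.fractions.columns:
        res = gradient_mod.gradient_correlation(table, state)
        row = enrich.loc[enrich["state"] == state].iloc[0]
        stats_rows.append((state, res.estimate, res.p, row["chi2"], row["p_adj"]))
    io_mod.write_tsv(
        pd.DataFrame(stats_rows, columns=["state", "r", "p", "chi2", "chi2_p_adj"]),
        out / "gradient_stats.tsv",
    )
    log.add("gradient", "stats", n_bins=n_bins)

    log.write(out / "runlog.jsonl")
    return out
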