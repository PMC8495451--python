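import numpy as np
import pandas as pd
import pytest

from slamtraj import synthetic as syn


@pytest.fixture(scope="session")
def small_read_sim():
    cfg = syn.ReadSimConfig(
        n_genes=8,
        n_cells=15,
        mean_molecules_per_cell=40.0,
        mean_reads_per_molecule=1.8,
        labeled_fraction=0.4,
        conversion_rate=0.1,
        error_rate=0.002,
        mean_T_per_read=15.0,
        snp_density=0.005,
        seed=11,
    )
    return syn.simulate_reads(cfg)


@pytest.fixture(scope="session")
def kinetic_population():
    cfg = syn.KineticSimConfig(n_genes=30, n_cells=250, noise="poisson", seed=5)
    return syn.simulate_kinetic_population(cfg)


def brute_force_classify(reads_df: pd.DataFrame, mask_pairs: set) -> dict:
    """Independent per-position set-algebra reimplementation of the
    molecule classifier, used as the oracle in equivalence tests.

    Returns {(barcode, umi, gene): "nascent" | "old"} for gene-unambiguous
    (barcode, umi) keys.
    """

    def parse(x):
        if isinstance(x, float) or x == "" or x is None:
            return set()
        return set(int(p) for p in str(x).split(","))

    groups: dict = {}
    for _, row in reads_df.iterrows():
        groups.setdefault((row.barcode, row.umi), []).append(row)
    labels = {}
    for (bc, umi), rows in groups.items():
        genes = {r.gene_id for r in rows}
        if len(genes) != 1:
            continue  # gene-ambiguous: discarded
        gene = rows[0].gene_id
        # dedupe identical records
        seen = set()
        uniq = []
        for r in rows:
            sig = (r.covered_T, r.converted, r.other_mismatch)
            if sig not in seen:
                seen.add(sig)
                uniq.append(r)
        obs: dict = {}
        for r in uniq:
            cov = parse(r.covered_T)
            conv = parse(r.converted)
            other = parse(r.other_mismatch)
            for p in cov:
                if (gene, p) in mask_pairs:
                    continue
                if p in conv:
                    cat = "C"
                elif p in other:
                    cat = "M"
                else:
                    cat = "T"
                obs.setdefault(p, set()).add(cat)
        converted = {p for p, cats in obs.items() if cats == {"C"}}
        labels[(bc, umi, gene)] = "nascent" if converted else "old"
    return labels
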