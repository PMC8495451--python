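import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from slamtraj import synthetic as syn
from slamtraj.scna import (
    CloneScore,
    SmoothedProfileMatrix,
    call_aberrant,
    cluster_clones,
    cna_region_enrichment,
    scna_score,
    smooth_genomic_expression,
)


def make_coords(n_genes, n_chrom=2):
    per = n_genes // n_chrom
    rows = []
    for c in range(n_chrom):
        for i in range(per):
            rows.append((f"chr{c + 1}", i * 1000, i * 1000 + 500,
                         f"g{c * per + i:04d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def make_expr(n_genes=100, n_cells=10, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    cells = [f"c{i:03d}" for i in range(n_cells)]
    return pd.DataFrame(rng.normal(0, sd, (n_genes, n_cells)),
                        index=genes, columns=cells)


class TestSmoothing:
    def test_reference_identical_gives_zero(self):
        expr = make_expr(100, 6, sd=0.0)  # all zeros
        coords = make_coords(100)
        out = smooth_genomic_expression(expr, coords, ["c000", "c001"], window=5)
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_window_one_is_identity_on_centered(self):
        expr = make_expr(60, 5, seed=1)
        coords = make_coords(60)
        ref = ["c000", "c001"]
        out = smooth_genomic_expression(expr, coords, ref, window=1)
        centered = expr.loc[out.values.index] - expr[ref].mean(axis=1).loc[
            out.values.index].to_numpy()[:, None]
        np.testing.assert_allclose(out.values.to_numpy(),
                                   np.clip(centered.to_numpy(), -3, 3))

    def test_step_segment_matches_brute_force_moving_average(self):
        n = 400
        expr = make_expr(n, 4, sd=0.0)
        expr.iloc[50:250, 3] = 1.0  # 200-gene step in one cell, chr1
        coords = make_coords(n)
        out = smooth_genomic_expression(expr, coords, ["c000", "c001"], window=101)
        got = out.values["c003"].to_numpy()
        # brute-force truncated moving average per chromosome
        centered = np.zeros(n)
        centered[50:200] = 1.0   # chr1 part of the segment
        brute = np.zeros(n)
        for chrom_block in (slice(0, 200), slice(200, 400)):
            vals = centered[chrom_block]
            for j in range(len(vals)):
                lo, hi = max(0, j - 50), min(len(vals), j + 51)
                brute[chrom_block.start + j] = vals[lo:hi].mean()
        # segment extends into chr2 genes 200..250
        centered2 = np.zeros(200)
        centered2[:50] = 1.0
        for j in range(200):
            lo, hi = max(0, j - 50), min(200, j + 51)
            brute[200 + j] = centered2[lo:hi].mean()
        np.testing.assert_allclose(got, brute, atol=1e-12)
        assert got[125] == pytest.approx(1.0)  # plateau at segment center

    def test_smoothing_does_not_cross_chromosomes(self):
        n = 100
        expr = make_expr(n, 3, sd=0.0)
        expr.iloc[49, 2] = 10.0  # last gene of chr1 (per_chrom = 50)
        coords = make_coords(n)
        out = smooth_genomic_expression(expr, coords, ["c000"], window=11)
        vals = out.values["c002"].to_numpy()
        assert vals[49] > 0
        assert np.all(vals[50:] == 0.0)

    def test_locality(self):
        n = 200
        expr = make_expr(n, 3, seed=2, sd=0.5)  # stay inside the +-3 clip
        coords = make_coords(n)
        ref = ["c000"]
        base = smooth_genomic_expression(expr, coords, ref, window=11)
        bumped = expr.copy()
        bumped.iloc[25, 2] += 1.0
        out = smooth_genomic_expression(bumped, coords, ref, window=11)
        diff = (out.values - base.values)["c002"].to_numpy()
        changed = np.flatnonzero(np.abs(diff) > 1e-12)
        assert changed.min() >= 20 and changed.max() <= 30

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_genomic_expression(make_expr(20, 2), make_coords(20), ["c000"],
                                      window=10)

    def test_missing_reference_cell_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            smooth_genomic_expression(make_expr(20, 2), make_coords(20), ["zz"])


def planted_cohort(shift=1.0, sd=0.1, seed=0, n_cells=100):
    cfg = syn.CloneSimConfig(
        n_genes=400, n_normal_cells=n_cells, n_clone_cells=(n_cells,),
        segments=(((0, 20, 60, shift),),), noise_sd=sd, seed=seed,
    )
    return syn.simulate_clone_expression(cfg)


class TestClusterClones:
    def test_two_planted_clones_recovered(self):
        expr, coords, labels, is_normal = planted_cohort(shift=1.0, sd=0.1)
        profiles = smooth_genomic_expression(
            expr, coords, is_normal.index[is_normal].tolist(), window=11
        )
        assignment, _, degenerate = cluster_clones(profiles, k=2)
        assert not degenerate
        agreement = max(
            (assignment[labels == "normal"] == 1).mean(),
            (assignment[labels == "normal"] == 2).mean(),
        )
        assert agreement >= 0.99

    def test_identical_cells_flagged_degenerate(self):
        expr = make_expr(40, 10, sd=0.0)
        profiles = smooth_genomic_expression(expr, make_coords(40), ["c000"],
                                             window=5)
        with pytest.warns(UserWarning):
            _, _, degenerate = cluster_clones(profiles, k=2)
        assert degenerate

    def test_k1_single_clone(self):
        expr = make_expr(40, 8, seed=3)
        profiles = smooth_genomic_expression(expr, make_coords(40), ["c000"],
                                             window=5)
        assignment, _, _ = cluster_clones(profiles, k=1)
        assert assignment.nunique() == 1

    def test_k_larger_than_cells_rejected(self):
        expr = make_expr(40, 4, seed=3)
        profiles = smooth_genomic_expression(expr, make_coords(40), ["c000"],
                                             window=5)
        with pytest.raises(ValueError):
            cluster_clones(profiles, k=5)


class TestScnaScore:
    def _profiles(self, expr, coords, normals):
        return smooth_genomic_expression(expr, coords, normals, window=11)

    def test_reference_clone_scores_one(self):
        expr, coords, labels, is_normal = planted_cohort(shift=0.0, sd=0.2,
                                                         n_cells=200)
        normals = is_normal.index[is_normal].tolist()
        profiles = self._profiles(expr, coords, normals)
        scores = scna_score(profiles, labels, profiles.values[normals])
        clone_score = [s for s in scores if s.clone == "clone0"][0]
        # null clone drawn from the reference distribution: S ~ 1 within 3 SE
        normal_sds = profiles.values[normals].std(axis=0, ddof=0)
        se = normal_sds.std() / np.sqrt(200) / normal_sds.mean()
        assert abs(clone_score.score - 1.0) <= 3 * se + 0.02

    def test_shifted_clone_scores_above_one(self):
        expr, coords, labels, is_normal = planted_cohort(shift=1.0, sd=0.2)
        normals = is_normal.index[is_normal].tolist()
        profiles = self._profiles(expr, coords, normals)
        scores = scna_score(profiles, labels, profiles.values[normals])
        by_clone = {s.clone: s.score for s in scores}
        assert by_clone["clone0"] > 1.0
        assert by_clone["clone0"] > by_clone["normal"]

    def test_zero_variance_guard(self):
        expr = make_expr(40, 6, sd=0.0)
        profiles = self._profiles(expr, make_coords(40), ["c000", "c001"])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=expr.columns)
        with pytest.raises(ValueError):
            scna_score(profiles, labels, profiles.values[["c000", "c001"]])

    def test_scale_invariance(self):
        expr, coords, labels, is_normal = planted_cohort(shift=1.0, sd=0.2)
        normals = is_normal.index[is_normal].tolist()
        p1 = self._profiles(expr, coords, normals)
        p2 = SmoothedProfileMatrix(
            values=p1.values * 5.0, window=p1.window,
            reference_cells=p1.reference_cells, chromosomes=p1.chromosomes,
        )
        s1 = {s.clone: s.score for s in scna_score(p1, labels, p1.values[normals])}
        s2 = {s.clone: s.score for s in scna_score(p2, labels, p2.values[normals])}
        for clone in s1:
            assert s1[clone] == pytest.approx(s2[clone], rel=1e-12)


class TestCallAberrant:
    def test_equality_is_not_aberrant(self):
        scores = [CloneScore("a", 10, 1.5)]
        called = call_aberrant(scores, [1.5, 1.2])
        assert called[0].aberrant is False

    def test_epsilon_above_is_aberrant(self):
        called = call_aberrant([CloneScore("a", 10, 1.5 + 1e-9)], [1.5])
        assert called[0].aberrant is True

    def test_empty_normals_rejected(self):
        with pytest.raises(ValueError):
            call_aberrant([CloneScore("a", 1, 1.0)], [])

    @pytest.mark.parametrize("seed", range(5))
    def test_simulated_cohort_sensitivity_specificity(self, seed):
        # 5 normal samples + 2 aberrant clones with strong shifts
        rng = np.random.default_rng(seed)
        cfg = syn.CloneSimConfig(
            n_genes=400, n_normal_cells=150, n_clone_cells=(60, 60),
            segments=(
                ((0, 0, 100, 1.0),),
                ((1, 50, 150, -1.0),),
            ),
            noise_sd=0.2, seed=seed,
        )
        expr, coords, labels, is_normal = syn.simulate_clone_expression(cfg)
        normals = is_normal.index[is_normal].tolist()
        profiles = smooth_genomic_expression(expr, coords, normals, window=51)
        # normal "samples": split the normal cells into 5 pseudo-samples
        sample_labels = pd.Series(
            [f"n{i % 5}" for i in range(len(normals))], index=normals
        )
        normal_scores = [
            s.score
            for s in scna_score(
                SmoothedProfileMatrix(profiles.values[normals], profiles.window,
                                      profiles.reference_cells,
                                      profiles.chromosomes),
                sample_labels, profiles.values[normals],
            )
        ]
        tumor = is_normal.index[~is_normal].tolist()
        clone_scores = scna_score(
            SmoothedProfileMatrix(profiles.values[tumor], profiles.window,
                                  profiles.reference_cells, profiles.chromosomes),
            labels[tumor], profiles.values[normals],
        )
        called = call_aberrant(clone_scores, normal_scores)
        assert all(c.aberrant for c in called)


class TestCnaRegionEnrichment:
    def test_independent_overlap_large_p(self):
        universe = {f"g{i}" for i in range(100)}
        region = {f"g{i}" for i in range(10)}
        dereg = {f"g{i}" for i in range(0, 100, 10)}  # overlap 1 = expectation
        p_raw, _ = cna_region_enrichment(dereg, region, universe)
        assert p_raw > 0.5

    def test_maximal_overlap_exact_tail(self):
        universe = {f"g{i}" for i in range(100)}
        region = {f"g{i}" for i in range(10)}
        dereg = set(region)
        p_raw, _ = cna_region_enrichment(dereg, region, universe)
        # exact tail: P(X >= 10) = 1 / C(100, 10)
        from math import comb
        assert p_raw == pytest.approx(1 / comb(100, 10), rel=1e-9)
        assert p_raw == pytest.approx(5.777e-14, rel=1e-3)

    def test_bonferroni_cap(self):
        universe = {f"g{i}" for i in range(100)}
        region = {f"g{i}" for i in range(50)}
        dereg = {f"g{i}" for i in range(40, 60)}
        p_raw, p_adj = cna_region_enrichment(dereg, region, universe, n_tests=39)
        assert p_adj == min(1.0, p_raw * 39)

    def test_matches_scipy_tail(self):
        universe = {f"g{i}" for i in range(80)}
        region = {f"g{i}" for i in range(15)}
        dereg = {f"g{i}" for i in range(5, 30)}
        x = len(dereg & region)
        p_raw, _ = cna_region_enrichment(dereg, region, universe)
        assert p_raw == pytest.approx(hypergeom.sf(x - 1, 80, 15, 25), rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cna_region_enrichment(set(), set(), set())
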