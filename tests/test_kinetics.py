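import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import spearmanr

from slamtraj import kinetics as kin
from slamtraj import preprocess as pp
from slamtraj import synthetic as syn
from slamtraj.kinetics import (
    GeneFit,
    KineticParams,
    RootPrior,
    compute_latent_time,
    compute_velocity,
    filter_velocity_genes,
    fit_gene_kinetics,
    fit_mirror_candidates,
    orient_one_sided,
    solve_kinetics,
    velocity_graph,
)


def integrate_reference(alpha, beta, gamma, t_switch, t):
    """Generic numerical ODE oracle for the two-layer model."""

    def rhs(tt, y):
        a = alpha if tt <= t_switch else 0.0
        return [a - beta * y[0], beta * y[0] - gamma * y[1]]

    sol = solve_ivp(rhs, (0.0, t), [0.0, 0.0], rtol=1e-10, atol=1e-12,
                    max_step=min(0.05, t_switch / 4 if t_switch else 0.05))
    return sol.y[0, -1], sol.y[1, -1]


class TestSolveKinetics:
    def test_induction_origin(self):
        p = KineticParams(1.0, 1.0, 1.0, 5.0)
        u, s = solve_kinetics(p, [0.0], "induction")
        assert u[0] == 0.0 and s[0] == 0.0

    def test_fixed_point(self):
        p = KineticParams(2.0, 1.0, 0.5, 1000.0)
        u, s = solve_kinetics(p, [500.0], "induction")
        assert u[0] == pytest.approx(2.0, abs=1e-9)
        assert s[0] == pytest.approx(4.0, abs=1e-9)

    def test_hand_example_against_ode(self):
        # alpha=1, beta=2, gamma=1, t=1 induction
        p = KineticParams(1.0, 2.0, 1.0, 10.0)
        u, s = solve_kinetics(p, [1.0], "induction")
        u_ref, s_ref = integrate_reference(1.0, 2.0, 1.0, 10.0, 1.0)
        assert u[0] == pytest.approx(0.5 * (1 - np.exp(-2.0)), rel=1e-9)
        assert u[0] == pytest.approx(u_ref, rel=1e-8)
        assert s[0] == pytest.approx(s_ref, rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_grid_against_numerical_integrator(self, seed):
        rng = np.random.default_rng(seed)
        alpha, beta, gamma = rng.uniform(0.3, 4.0, 3)
        if seed % 2:
            beta = gamma  # exercise the removable singularity
        ts = rng.uniform(1.0, 6.0)
        p = KineticParams(alpha, beta, gamma, ts)
        for t in rng.uniform(0.05, 2 * ts, 4):
            branch = "induction" if t <= ts else "repression"
            u, s = solve_kinetics(p, [t], branch)
            u_ref, s_ref = integrate_reference(alpha, beta, gamma, ts, float(t))
            assert u[0] == pytest.approx(u_ref, rel=1e-6, abs=1e-9)
            assert s[0] == pytest.approx(s_ref, rel=1e-6, abs=1e-9)

    def test_repression_requires_post_switch_time(self):
        p = KineticParams(1.0, 1.0, 0.5, 5.0)
        with pytest.raises(ValueError):
            solve_kinetics(p, [1.0], "repression")

    def test_unknown_branch(self):
        with pytest.raises(ValueError):
            solve_kinetics(KineticParams(1, 1, 2, 1), [0.5], "sideways")


class TestFilterVelocityGenes:
    def test_shared_threshold(self):
        nascent = np.zeros((2, 30))
        old = np.zeros((2, 30))
        nascent[0, :20] = 1
        old[0, :20] = 1
        nascent[1, :] = 1  # old stays zero -> no shared counts
        keep = filter_velocity_genes(nascent, old, min_shared=20)
        assert keep.tolist() == [True, False]

    def test_brute_force_recount(self):
        rng = np.random.default_rng(0)
        nascent = rng.poisson(0.5, (50, 100))
        old = rng.poisson(0.5, (50, 100))
        keep = filter_velocity_genes(nascent, old, min_shared=10)
        for g in range(50):
            expected = sum(
                1 for c in range(100) if nascent[g, c] > 0 and old[g, c] > 0
            ) >= 10
            assert keep[g] == expected


class TestFitGeneKinetics:
    def test_noise_free_recovery(self):
        # data exactly on the curve: loss tiny, gamma/beta within 1%
        rng = np.random.default_rng(1)
        alpha, beta, gamma, ts = 3.0, 1.0, 0.4, 7.0
        t = np.sort(rng.uniform(0, 14.0, 300))
        u, s = syn.kinetic_expectations(alpha, beta, gamma, ts, t)
        fit = fit_gene_kinetics(u, s, max_iter=12, tol=1e-8)
        assert fit.loss <= 1e-6
        assert fit.params.gamma / fit.params.beta == pytest.approx(
            gamma / beta, rel=0.01
        )

    def test_constant_input_degenerate(self):
        fit = fit_gene_kinetics(np.full(50, 2.0), np.full(50, 4.0))
        assert fit.degenerate
        assert fit.weight == 0.0

    def test_alpha_over_beta_recovered(self):
        rng = np.random.default_rng(2)
        alpha, beta, gamma, ts = 5.0, 1.0, 0.5, 8.0
        t = np.sort(rng.uniform(0, 14.0, 400))
        u, s = syn.kinetic_expectations(alpha, beta, gamma, ts, t)
        fit = fit_gene_kinetics(u, s, max_iter=12, tol=1e-8)
        assert fit.params.alpha / fit.params.beta == pytest.approx(
            alpha / beta, rel=0.05
        )


class TestOrientOneSided:
    def _mirror_fits(self, loss_a=1.0, loss_b=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 50
        t = np.sort(rng.uniform(0, 5, n))
        params = KineticParams(1.0, 1.0, 0.5, 6.0)
        fit_a = GeneFit(params=params, t=t, branch=np.zeros(n, int),
                        loss=loss_a, mode="induction")
        fit_b = GeneFit(params=params, t=t[::-1].copy(),
                        branch=np.ones(n, int), loss=loss_b, mode="repression")
        cells = [f"c{i}" for i in range(n)]
        return fit_a, fit_b, cells

    def test_lambda_zero_is_pure_loss(self):
        fit_a, fit_b, cells = self._mirror_fits(loss_a=2.0, loss_b=1.0)
        root = RootPrior(frozenset(cells[:5]), penalty=0.0)
        assert orient_one_sided((fit_a, fit_b), cells, root) is fit_b

    def test_equal_loss_tie_broken_by_root(self):
        fit_a, fit_b, cells = self._mirror_fits(1.0, 1.0)
        # fit_a puts the first cells early (ascending t); root = first 10%
        root = RootPrior(frozenset(cells[:5]), penalty=10.0)
        assert orient_one_sided((fit_a, fit_b), cells, root) is fit_a
        # root at the other end flips the choice
        root = RootPrior(frozenset(cells[-5:]), penalty=10.0)
        assert orient_one_sided((fit_a, fit_b), cells, root) is fit_b

    def test_large_lambda_dominates_loss(self):
        fit_a, fit_b, cells = self._mirror_fits(loss_a=1.5, loss_b=1.0)
        root = RootPrior(frozenset(cells[:5]), penalty=1e9)
        assert orient_one_sided((fit_a, fit_b), cells, root) is fit_a

    def test_empty_root_with_penalty_rejected(self):
        with pytest.raises(ValueError):
            RootPrior(frozenset(), penalty=1.0)

    def test_missing_root_cells_rejected(self):
        fit_a, fit_b, cells = self._mirror_fits()
        root = RootPrior(frozenset({"nope"}), penalty=1.0)
        with pytest.raises(ValueError):
            orient_one_sided((fit_a, fit_b), cells, root)

    def test_repression_only_gene_oriented_by_root(self):
        # a pure-decay gene fit both ways; root cells are the true earliest
        rng = np.random.default_rng(3)
        alpha, beta, gamma = 4.0, 1.0, 0.5
        t_true = np.sort(rng.uniform(0, 6.0, 200))
        u, s = syn.kinetic_expectations(alpha, beta, gamma, None, t_true,
                                        mode="repression")
        u += rng.normal(0, 0.02, u.shape)
        s = np.maximum(s + rng.normal(0, 0.02, s.shape), 0)
        u = np.maximum(u, 0)
        cells = [f"c{i}" for i in range(200)]
        candidates = fit_mirror_candidates(u, s)
        root = RootPrior(frozenset(cells[:20]), penalty=10.0 * candidates[0].loss)
        chosen = orient_one_sided(candidates, cells, root)
        rho = spearmanr(chosen.t, t_true).statistic
        assert rho > 0.9


class TestLatentTime:
    def test_single_gene_monotone(self):
        rng = np.random.default_rng(4)
        t_true = np.sort(rng.uniform(0, 10, 100))
        u, s = syn.kinetic_expectations(2.0, 1.0, 0.5, 6.0, t_true)
        fit = fit_gene_kinetics(u, s, max_iter=12, tol=1e-8)
        cells = [f"c{i}" for i in range(100)]
        tau, n_inf = compute_latent_time({"g": fit}, cells)
        assert spearmanr(tau, t_true).statistic == pytest.approx(1.0, abs=1e-9)
        assert tau.min() == 0.0 and tau.max() == 1.0

    def test_reversing_orientations_reverses_order(self):
        rng = np.random.default_rng(5)
        n = 80
        cells = [f"c{i}" for i in range(n)]
        fits, flipped = {}, {}
        for g in range(5):
            t = rng.uniform(0, 1, n)
            params = KineticParams(1.0, 1.0, 0.5, 6.0)
            fits[f"g{g}"] = GeneFit(params=params, t=t,
                                    branch=np.zeros(n, int), loss=0.1)
            flipped[f"g{g}"] = GeneFit(params=params, t=t.max() - t,
                                       branch=np.zeros(n, int), loss=0.1)
        tau, _ = compute_latent_time(fits, cells)
        tau_flipped, _ = compute_latent_time(flipped, cells)
        assert spearmanr(tau, tau_flipped).statistic == pytest.approx(-1.0, abs=1e-9)

    def test_population_recovery(self):
        cfg = syn.KineticSimConfig(n_genes=60, n_cells=300, noise="poisson", seed=6)
        mat, truth = syn.simulate_kinetic_population(cfg)
        moments = pp.compute_moments(mat, n_pcs=30, k=30)["all"]
        fits = kin.fit_all_genes(moments, min_shared=20)
        tau, _ = compute_latent_time(fits, moments.cells)
        assert spearmanr(tau, truth["t"].to_numpy()).statistic >= 0.8

    def test_no_informative_gene_raises(self):
        with pytest.raises(ValueError):
            compute_latent_time({}, ["c1"])


class TestVelocity:
    def test_zero_at_steady_state(self):
        p = KineticParams(2.0, 1.0, 0.5, 1000.0)
        v = compute_velocity(p, np.array([2.0]), np.array([4.0]))
        assert abs(v[0]) <= 1e-12

    def test_sign_above_steady_ratio(self):
        p = KineticParams(2.0, 1.0, 0.5, 1000.0)
        assert compute_velocity(p, np.array([3.0]), np.array([4.0]))[0] > 0
        assert compute_velocity(p, np.array([1.0]), np.array([4.0]))[0] < 0

    def test_induction_phase_velocities_nonnegative(self):
        t = np.linspace(0.0, 5.0, 50)
        u, s = syn.kinetic_expectations(2.0, 1.0, 0.5, 6.0, t)
        p = KineticParams(2.0, 1.0, 0.5, 6.0)
        v = compute_velocity(p, u, s)
        assert np.all(v >= -1e-10)

    def test_analytic_steady_state_zero_for_fitted_genes(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a, b, g = rng.uniform(0.5, 3.0, 3)
            p = KineticParams(a, b, g, 100.0)
            v = compute_velocity(p, np.array([a / b]), np.array([a / g]))
            assert abs(v[0]) <= 1e-8


class TestVelocityGraph:
    def test_aligned_and_antiparallel(self):
        # 2 genes, 3 cells; cell 0's velocity points exactly at cell 1
        x = np.array([[0.0, 1.0, -1.0], [0.0, 2.0, -2.0]])
        v = np.zeros((2, 3))
        v[:, 0] = [1.0, 2.0]
        edges = velocity_graph(v, x, [np.array([1, 2]), np.array([0]), np.array([0])])
        scores = {(c, n): s for c, n, s in edges}
        assert scores[(0, 1)] == pytest.approx(1.0)
        assert scores[(0, 2)] == pytest.approx(-1.0)

    def test_zero_norm_scores_zero(self):
        x = np.zeros((2, 2))
        v = np.zeros((2, 2))
        edges = velocity_graph(v, x, [np.array([1]), np.array([0])])
        assert all(s == 0.0 for _, _, s in edges)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        n_genes, n_cells = 6, 20
        x = rng.normal(0, 1, (n_genes, n_cells))
        v = rng.normal(0, 1, (n_genes, n_cells))
        nbrs = [np.array([j for j in range(n_cells) if j != i][:4])
                for i in range(n_cells)]
        edges = velocity_graph(v, x, nbrs)
        for c, n, s in edges:
            delta = x[:, n] - x[:, c]
            expected = float(v[:, c] @ delta
                             / (np.linalg.norm(v[:, c]) * np.linalg.norm(delta)))
            assert s == pytest.approx(expected, abs=1e-12)
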