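"""Two-layer kinetic model: per-gene fitting, latent time, velocities.

The model couples a nascent layer u and an old layer s:

    du/dt = alpha - beta * u
    ds/dt = beta * u - gamma * s

with transcription switched on (induction, from (0, 0)) until ``t_switch``
and off afterwards (repression). Genes observed on only one branch are
ambiguous up to time reversal; a root prior (a set of cells asserted to be
the developmental origin) breaks the tie by penalizing orientations that
place root cells late.

Identifiability: scaling (alpha, beta, gamma) by c and dividing times by c
leaves the curves unchanged, so the fitter pins beta = 1 and only the
ratios gamma/beta and alpha/beta (and relative times) are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize

from .preprocess import MomentsMatrix

_T_IND_MAX = 12.0  # induction horizon in 1/beta units (saturated to ~6e-6)
_GRID_POINTS = 512


@dataclass
class KineticParams:
    alpha: float
    beta: float
    gamma: float
    t_switch: float
    scaling: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise ValueError("alpha, beta, gamma must be positive")
        if self.t_switch <= 0:
            raise ValueError("t_switch must be positive")


@dataclass
class RootPrior:
    """Cells asserted to sit at the developmental origin."""

    root_cells: frozenset[str]
    penalty: float = 0.0  # lambda
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty weight must be >= 0")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if self.penalty > 0 and not self.root_cells:
            raise ValueError("non-zero penalty requires a non-empty root cell set")


def _ode_solution(alpha, beta, gamma, t, u0=0.0, s0=0.0):
    """General solution of the two-layer ODE from state (u0, s0) at t=0.

    u(t) = a/b + (u0 - a/b) e^{-bt}
    s(t) = a/g + (s0 - a/g) e^{-gt} + (b*u0 - a)(e^{-bt} - e^{-gt})/(g - b)
    with the removable g == b singularity replaced by its analytic limit.
    """
    t = np.asarray(t, dtype=float)
    expb = np.exp(-beta * t)
    expg = np.exp(-gamma * t)
    u = alpha / beta + (u0 - alpha / beta) * expb
    if abs(gamma - beta) < 1e-6 * max(gamma, beta):
        cross = (beta * u0 - alpha) * t * expg
    else:
        cross = (beta * u0 - alpha) * (expb - expg) / (gamma - beta)
    s = alpha / gamma + (s0 - alpha / gamma) * expg + cross
    return u, s


def solve_kinetics(params: KineticParams, t, branch: str):
    """Evaluate (u, s) on one branch at global times ``t``.

    Induction starts from (0, 0); repression starts from the induction state
    at ``t_switch`` with alpha = 0 and expects ``t >= t_switch``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a, b, g, ts = params.alpha, params.beta, params.gamma, params.t_switch
    if branch == "induction":
        return _ode_solution(a, b, g, t, 0.0, 0.0)
    if branch == "repression":
        if np.any(t < ts):
            raise ValueError("repression branch requires t >= t_switch")
        u0, s0 = _ode_solution(a, b, g, np.array([ts]), 0.0, 0.0)
        return _ode_solution(0.0, b, g, t - ts, float(u0[0]), float(s0[0]))
    raise ValueError(f"unknown branch {branch!r}")


def filter_velocity_genes(
    nascent: np.ndarray, old: np.ndarray, min_shared: int = 20
) -> np.ndarray:
    """Boolean gene mask: >= min_shared cells positive in BOTH layers."""
    shared = ((np.asarray(nascent) > 0) & (np.asarray(old) > 0)).sum(axis=1)
    keep = shared >= min_shared
    if not keep.any():
        warnings.warn("no gene passes the shared-count filter", stacklevel=2)
    return keep


# ---------------------------------------------------------------------------
# per-gene fit
# ---------------------------------------------------------------------------


@dataclass
class GeneFit:
    """Fitted parameters and per-cell assignments for one gene.

    ``t`` holds global gene-local times (repression cells at
    t_switch + time-since-switch); ``branch`` is 0 for induction, 1 for
    repression. ``mode`` records the dynamic range the fit used
    ("both", "induction", "repression").
    """

    params: KineticParams
    t: np.ndarray
    branch: np.ndarray
    loss: float
    mode: str = "both"
    converged: bool = True
    degenerate: bool = False
    one_sided: bool = False
    weight: float = 1.0


def _curves(alpha, gamma, t_switch, mode, n=_GRID_POINTS):
    """Phase-curve sample points (t, u, s, branch) for the E-step grid."""
    beta = 1.0
    t_rep_max = 10.0 / min(gamma, beta)
    if mode == "induction":
        t = np.linspace(0.0, t_switch, n)
        u, s = _ode_solution(alpha, beta, gamma, t)
        return t, u, s, np.zeros(n, dtype=int)
    if mode == "repression":
        # decay from the induction steady state; t_switch plays no role
        dt = np.linspace(0.0, t_rep_max, n)
        u, s = _ode_solution(0.0, beta, gamma, dt, alpha / beta, alpha / gamma)
        return dt, u, s, np.ones(n, dtype=int)
    t_ind = np.linspace(0.0, t_switch, n // 2)
    u_i, s_i = _ode_solution(alpha, beta, gamma, t_ind)
    u0, s0 = u_i[-1], s_i[-1]
    dt = np.linspace(0.0, t_rep_max, n - n // 2)
    u_r, s_r = _ode_solution(0.0, beta, gamma, dt, u0, s0)
    t = np.concatenate([t_ind, t_switch + dt])
    u = np.concatenate([u_i, u_r])
    s = np.concatenate([s_i, s_r])
    branch = np.concatenate([np.zeros(len(t_ind), dtype=int), np.ones(len(dt), dtype=int)])
    return t, u, s, branch


def _model_us(alpha, gamma, t_switch, t, branch, mode):
    """(u, s) at per-cell times for the current parameters."""
    beta = 1.0
    u = np.empty_like(t)
    s = np.empty_like(t)
    ind = branch == 0
    if mode == "repression":
        u[:], s[:] = _ode_solution(0.0, beta, gamma, t, alpha / beta, alpha / gamma)
        return u, s
    if ind.any():
        ti = np.minimum(t[ind], t_switch)
        u[ind], s[ind] = _ode_solution(alpha, beta, gamma, ti)
    rep = ~ind
    if rep.any():
        u0, s0 = _ode_solution(alpha, beta, gamma, np.array([t_switch]))
        dt = np.maximum(t[rep] - t_switch, 0.0)
        u[rep], s[rep] = _ode_solution(0.0, beta, gamma, dt, float(u0[0]), float(s0[0]))
    return u, s


def _golden_refine(u_obs, s_obs, alpha, gamma, t_switch, mode, t0, step,
                   branch, lo_clip, hi_clip, iters=24):
    """Vectorized golden-section refinement of per-cell times on one branch."""
    lo = np.clip(t0 - step, lo_clip, hi_clip)
    hi = np.clip(t0 + step, lo_clip, hi_clip)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0

    def d2_at(tt):
        u_m, s_m = _model_us(alpha, gamma, t_switch, tt, branch, mode)
        return (u_obs - u_m) ** 2 + (s_obs - s_m) ** 2

    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = d2_at(c), d2_at(d)
    for _ in range(iters):
        take_left = fc < fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = d2_at(c), d2_at(d)
    t_ref = (a + b) / 2.0
    return t_ref, d2_at(t_ref)


def _assign_times(u_obs, s_obs, alpha, gamma, t_switch, mode, refine=True):
    """E-step: nearest point on the phase curve per cell.

    The dense grid argmin is optionally refined by golden-section search.
    For two-sided fits both branches are refined independently and the
    better candidate wins per cell -- near the switch and near the origin
    the branches approach each other and the raw grid argmin can pick the
    wrong one.
    """
    t_grid, u_g, s_g, branch_g = _curves(alpha, gamma, t_switch, mode)
    d2 = (u_obs[:, None] - u_g[None, :]) ** 2 + (s_obs[:, None] - s_g[None, :]) ** 2
    best = np.argmin(d2, axis=1)
    t = t_grid[best]
    branch = branch_g[best]
    loss_grid = d2[np.arange(len(best)), best]
    if not refine:
        return t, branch, float(loss_grid.sum())

    if mode != "both":
        step = np.gradient(t_grid)[best]
        t_ref, loss_ref = _golden_refine(
            u_obs, s_obs, alpha, gamma, t_switch, mode, t, step, branch,
            0.0, float(t_grid[-1]),
        )
        use = loss_ref <= loss_grid
        return (
            np.where(use, t_ref, t),
            branch,
            float(np.where(use, loss_ref, loss_grid).sum()),
        )

    n_ind = _GRID_POINTS // 2
    t_rep_end = float(t_grid[-1])
    candidates = []
    for b, (sl, lo_clip, hi_clip) in (
        (0, (slice(0, n_ind), 0.0, t_switch)),
        (1, (slice(n_ind, None), t_switch, t_rep_end)),
    ):
        sub = d2[:, sl]
        best_b = np.argmin(sub, axis=1) + (0 if b == 0 else n_ind)
        t_b = t_grid[best_b]
        step_b = np.gradient(t_grid)[best_b]
        branch_b = np.full(len(t_b), b, dtype=int)
        t_ref, loss_ref = _golden_refine(
            u_obs, s_obs, alpha, gamma, t_switch, mode, t_b, step_b,
            branch_b, lo_clip, hi_clip,
        )
        grid_loss_b = sub[np.arange(len(best_b)), best_b - (0 if b == 0 else n_ind)]
        use = loss_ref <= grid_loss_b
        candidates.append(
            (np.where(use, t_ref, t_b),
             np.where(use, loss_ref, grid_loss_b))
        )
    (t0c, l0), (t1c, l1) = candidates
    pick1 = l1 < l0
    t = np.where(pick1, t1c, t0c)
    branch = pick1.astype(int)
    loss = np.where(pick1, l1, l0)
    return t, branch, float(loss.sum())


def _init_params(u_obs, s_obs):
    top = np.argsort(u_obs + s_obs)[-max(3, len(u_obs) // 10):]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s_obs[top] > 0, u_obs[top] / s_obs[top], 1.0)
    gamma0 = float(np.clip(np.median(ratio), 1e-2, 1e2))
    alpha0 = float(max(u_obs.max(), 1e-3))
    return alpha0, gamma0



def _aitken_alpha(u_obs, s_obs, a0, gamma, t_switch, mode):
    """Self-consistent transcription rate via Aitken-accelerated fixed point.

    Assignments depend on alpha and alpha's least-squares profile depends on
    the assignments; the plain fixed-point iteration contracts slowly
    (ratio ~0.75), so two Aitken extrapolation rounds are used.
    """
    a = a0
    f_u = f_s = None
    for _ in range(2):
        seq = [a]
        for _ in range(2):
            tt, bb, _ = _assign_times(u_obs, s_obs, seq[-1], gamma, t_switch, mode)
            f_u, f_s = _model_us(1.0, gamma, t_switch, tt, bb, mode)
            denom = float(f_u @ f_u + f_s @ f_s)
            seq.append(
                max(float(u_obs @ f_u + s_obs @ f_s) / denom, 1e-8)
                if denom > 0 else 1e-8
            )
        d1, d2 = seq[1] - seq[0], seq[2] - seq[1]
        if d1 != 0 and abs(d1 - d2) > 1e-15 and 0 < d2 / d1 < 0.99:
            a = max(seq[0] + d1 / (1 - d2 / d1), 1e-8)
        else:
            a = seq[2]
    tt, bb, _ = _assign_times(u_obs, s_obs, a, gamma, t_switch, mode)
    f_u, f_s = _model_us(1.0, gamma, t_switch, tt, bb, mode)
    return a, f_u, f_s


def fit_gene_kinetics(
    u_obs: np.ndarray,
    s_obs: np.ndarray,
    mode: str = "both",
    max_iter: int = 5,
    tol: float = 1e-3,
    polish: bool = True,
) -> GeneFit:
    """Alternating fit of one gene's kinetics on smoothed layer values.

    E-step: each cell is assigned the branch and time minimizing squared
    distance to the phase curve (dense 512-point grid, then golden-section
    refinement). M-step: (alpha, gamma, t_switch) by Nelder-Mead on the
    squared loss with beta pinned to 1. ``mode`` restricts the dynamic
    range for one-sided candidate fits.
    """
    u_obs = np.asarray(u_obs, dtype=float)
    s_obs = np.asarray(s_obs, dtype=float)
    if u_obs.shape != s_obs.shape or u_obs.ndim != 1:
        raise ValueError("u and s must be 1-D arrays of equal length")
    var = float(u_obs.var() + s_obs.var())
    if var < 1e-12:
        params = KineticParams(
            alpha=max(float(u_obs.mean()), 1e-6) or 1e-6,
            beta=1.0,
            gamma=1.0,
            t_switch=_T_IND_MAX,
        )
        return GeneFit(
            params=params,
            t=np.zeros_like(u_obs),
            branch=np.zeros(len(u_obs), dtype=int),
            loss=0.0,
            mode=mode,
            degenerate=True,
            weight=0.0,
        )

    alpha, gamma = _init_params(u_obs, s_obs)
    t_switch = _T_IND_MAX if mode != "both" else _T_IND_MAX / 2.0
    # coarse grid start to dodge local optima in the EM; the moment-ratio
    # init is biased for decaying genes, so gamma is scanned broadly
    best = (np.inf, gamma, t_switch)
    ts_grid = (2.0, 4.0, 6.0, 8.0, 10.0) if mode == "both" else (t_switch,)
    for g0 in gamma * np.array([0.25, 0.5, 1.0, 2.0, 4.0]):
        for ts0 in ts_grid:
            _, _, l0 = _assign_times(u_obs, s_obs, alpha, g0, ts0, mode,
                                     refine=False)
            if l0 < best[0]:
                best = (l0, float(g0), float(ts0))
    _, gamma, t_switch = best
    t, branch, loss = _assign_times(u_obs, s_obs, alpha, gamma, t_switch, mode,
                                    refine=False)
    converged = False

    def _profiled_alpha(g, ts):
        # the whole trajectory is linear in alpha, so alpha has a closed form
        f_u, f_s = _model_us(1.0, g, ts, t, branch, mode)
        denom = float(f_u @ f_u + f_s @ f_s)
        if denom <= 0:
            return 1e-8, f_u, f_s
        return max(float(u_obs @ f_u + s_obs @ f_s) / denom, 1e-8), f_u, f_s

    for _ in range(max_iter):
        x0 = [np.log(gamma)]
        if mode == "both":
            x0.append(np.log(t_switch))

        def objective(x):
            g = np.exp(np.clip(x[0], -6, 6))
            ts = np.exp(np.clip(x[1], -3, 4)) if mode == "both" else t_switch
            a, f_u, f_s = _profiled_alpha(g, ts)
            return float(((u_obs - a * f_u) ** 2 + (s_obs - a * f_s) ** 2).sum())

        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 50, "xatol": 1e-4, "fatol": 1e-8})
        gamma = float(np.exp(np.clip(res.x[0], -6, 6)))
        if mode == "both":
            t_switch = float(np.exp(np.clip(res.x[1], -3, 4)))
        alpha = _profiled_alpha(gamma, t_switch)[0]
        t, branch, new_loss = _assign_times(u_obs, s_obs, alpha, gamma, t_switch,
                                            mode, refine=False)
        if abs(loss - new_loss) <= tol * max(loss, 1e-12):
            loss = new_loss
            converged = True
            break
        loss = new_loss
    # final polish helpers -------------------------------------------------
    def _adopt(x, refine):
        nonlocal gamma, t_switch, alpha, t, branch
        gamma = float(np.exp(np.clip(x[0], -6, 6)))
        if mode == "both":
            t_switch = float(np.exp(np.clip(x[1], -3, 4)))
        # re-assign before profiling alpha so the profile uses fresh times
        t, branch, _ = _assign_times(u_obs, s_obs, alpha, gamma, t_switch, mode,
                                     refine=refine)
        alpha = _profiled_alpha(gamma, t_switch)[0]
        tt, bb, l = _assign_times(u_obs, s_obs, alpha, gamma, t_switch, mode,
                                  refine=refine)
        return tt, bb, l

    x0 = np.array([np.log(gamma)] + ([np.log(t_switch)] if mode == "both" else []))
    t, branch, loss = _adopt(x0, refine=True)
    # near-noise-free data sits below the grid-quantization floor; only then
    # is a joint search over sub-grid (golden-refined) assignments worthwhile
    if polish and loss < 0.05 * var * len(u_obs):
        a_start = max(alpha, 1e-8)

        def residuals(x):
            # deterministic in x: the alpha fixed point always starts from
            # the same seed value, else finite differences are inconsistent
            g = np.exp(np.clip(x[0], -6, 6))
            ts = np.exp(np.clip(x[1], -3, 4)) if mode == "both" else t_switch
            a, f_u, f_s = _aitken_alpha(u_obs, s_obs, a_start, g, ts, mode)
            return np.concatenate([u_obs - a * f_u, s_obs - a * f_s])

        # variable-projection least squares with decreasing finite-difference
        # steps: the reassignment inside the residual adds micro-noise that
        # a single small diff_step cannot average out
        for ds in (1e-3, 1e-4, 1e-5):
            res = least_squares(residuals, x0, method="lm", diff_step=ds,
                                xtol=1e-15, ftol=1e-15, max_nfev=50)
            if float(res.cost * 2) <= float((residuals(x0) ** 2).sum()):
                x0 = res.x
        g_new = float(np.exp(np.clip(x0[0], -6, 6)))
        ts_new = float(np.exp(np.clip(x0[1], -3, 4))) if mode == "both" else t_switch
        a_new, _, _ = _aitken_alpha(u_obs, s_obs, a_start, g_new, ts_new, mode)
        t_n, b_n, loss_n = _assign_times(u_obs, s_obs, a_new, g_new, ts_new, mode)
        if loss_n <= loss:  # keep the polish only when it actually helps
            gamma, t_switch, alpha = g_new, ts_new, a_new
            t, branch, loss = t_n, b_n, loss_n

    frac_ind = float((branch == 0).mean())
    one_sided = mode == "both" and (frac_ind > 0.9 or frac_ind < 0.1)
    weight = max(0.0, 1.0 - loss / (var * len(u_obs)))
    params = KineticParams(alpha=alpha, beta=1.0, gamma=gamma, t_switch=t_switch)
    return GeneFit(
        params=params,
        t=t,
        branch=branch,
        loss=loss,
        mode=mode,
        converged=converged,
        one_sided=one_sided,
        weight=weight,
    )


def fit_mirror_candidates(u_obs, s_obs, max_iter: int = 5, tol: float = 1e-3,
                          polish: bool = True):
    """The two one-sided readings of an ambiguous gene (induction vs repression)."""
    cand_ind = fit_gene_kinetics(u_obs, s_obs, mode="induction",
                                 max_iter=max_iter, tol=tol, polish=polish)
    cand_rep = fit_gene_kinetics(u_obs, s_obs, mode="repression",
                                 max_iter=max_iter, tol=tol, polish=polish)
    return cand_ind, cand_rep


def root_penalty(fit: GeneFit, cells: list[str], root: RootPrior) -> float:
    """Fraction of root cells assigned a later gene-local time than the
    theta-quantile of all cells' times."""
    root_idx = [i for i, c in enumerate(cells) if c in root.root_cells]
    if not root_idx:
        return 0.0
    threshold = np.quantile(fit.t, root.theta)
    return float(np.mean(fit.t[root_idx] > threshold))


def orient_one_sided(
    candidates: tuple[GeneFit, GeneFit], cells: list[str], root: RootPrior
) -> GeneFit:
    """Pick the mirror fit minimizing loss + lambda * root-late fraction.

    With penalty weight 0 this reduces exactly to the unregularized
    comparison (argmin loss; first candidate wins ties).
    """
    if root.penalty > 0 and not any(c in root.root_cells for c in cells):
        raise ValueError("root prior cells not found among fitted cells")
    scores = []
    for cand in candidates:
        score = cand.loss
        if root.penalty > 0:
            score = score + root.penalty * root_penalty(cand, cells, root)
        scores.append(score)
    return candidates[int(np.argmin(scores))]


def fit_all_genes(
    moments: MomentsMatrix,
    genes: list[str] | None = None,
    root: RootPrior | None = None,
    min_shared: int = 20,
    max_iter: int = 5,
    tol: float = 1e-3,
    polish: bool = False,
) -> dict[str, GeneFit]:
    """Fit every gene passing the shared-count filter; orient one-sided genes.

    A gene whose unregularized fit places >90% of cells on a single branch
    is re-fit as the two one-sided mirror candidates and oriented with the
    root prior (or by pure loss when no prior is given).
    """
    u = moments.layers["nascent"]
    s = moments.layers["old"]
    keep = filter_velocity_genes(u, s, min_shared=min_shared)
    names = moments.genes if genes is None else genes
    fits: dict[str, GeneFit] = {}
    for gi in np.flatnonzero(keep):
        fit = fit_gene_kinetics(u[gi], s[gi], max_iter=max_iter, tol=tol,
                                polish=polish)
        if fit.degenerate:
            fits[names[gi]] = fit
            continue
        if fit.one_sided:
            candidates = fit_mirror_candidates(u[gi], s[gi], max_iter=max_iter,
                                               tol=tol, polish=polish)
            prior = root if root is not None else RootPrior(frozenset(), 0.0)
            oriented = orient_one_sided(candidates, moments.cells, prior)
            oriented = replace(oriented, one_sided=True)
            fits[names[gi]] = oriented
        else:
            fits[names[gi]] = fit
    return fits


# ---------------------------------------------------------------------------
# latent time and velocity
# ---------------------------------------------------------------------------


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cutoff = 0.5 * w.sum()
    return float(v[np.searchsorted(cum, cutoff)])


def compute_latent_time(
    fits: dict[str, GeneFit], cells: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate gene-local times into a per-cell latent time in [0, 1].

    Each informative gene's times are min-max normalized; the per-cell
    latent time is the weight (goodness-of-fit) weighted median across
    genes, min-max rescaled to [0, 1]. Returns (tau, n_informative); cells
    without any informative gene get NaN.
    """
    informative = [f for f in fits.values() if f.weight > 0 and not f.degenerate]
    if not informative:
        raise ValueError("no informative gene fit available")
    n = len(cells)
    times = np.empty((len(informative), n))
    weights = np.empty(len(informative))
    for i, fit in enumerate(informative):
        t = fit.t
        span = t.max() - t.min()
        times[i] = (t - t.min()) / span if span > 0 else 0.0
        weights[i] = fit.weight
    tau = np.array([_weighted_median(times[:, c], weights) for c in range(n)])
    n_informative = np.full(n, len(informative))
    span = tau.max() - tau.min()
    if span > 0:
        tau = (tau - tau.min()) / span
    return tau, n_informative


def compute_velocity(params: KineticParams, u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """ds/dt = beta * u - gamma * s on smoothed per-cell values."""
    return params.beta * np.asarray(u, dtype=float) - params.gamma * np.asarray(
        s, dtype=float
    )


def velocity_matrix(fits: dict[str, GeneFit], moments: MomentsMatrix) -> np.ndarray:
    """Stack per-gene velocities into a gene x cell matrix (NaN = unfitted)."""
    out = np.full((len(moments.genes), len(moments.cells)), np.nan)
    index = {g: i for i, g in enumerate(moments.genes)}
    for gene, fit in fits.items():
        gi = index[gene]
        out[gi] = compute_velocity(
            fit.params, moments.layers["nascent"][gi], moments.layers["old"][gi]
        )
    return out


def velocity_graph(
    velocities: np.ndarray,
    expression: np.ndarray,
    neighbor_lists: list[np.ndarray],
) -> list[tuple[int, int, float]]:
    """Cosine similarity between each cell's velocity vector and the
    expression displacement toward each of its neighbors.

    ``velocities`` and ``expression`` are gene x cell over the fitted genes
    (rows with NaN are ignored). Returns (cell, neighbor, score) triples.
    """
    v = np.asarray(velocities, dtype=float)
    x = np.asarray(expression, dtype=float)
    valid = ~np.isnan(v).any(axis=1)
    v = v[valid]
    x = x[valid]
    edges = []
    for c, nbrs in enumerate(neighbor_lists):
        vc = v[:, c]
        nv = np.linalg.norm(vc)
        for nb in nbrs:
            delta = x[:, nb] - x[:, c]
            nd = np.linalg.norm(delta)
            if nv == 0 or nd == 0:
                score = 0.0
            else:
                score = float(vc @ delta / (nv * nd))
            edges.append((c, int(nb), score))
    return edges
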