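"""Reusable simulation studies exercising the full pipeline.

These are the package's own verification experiments: numerical-identity
checks (ridge equivalence, low-rank inversion, gradients, projections),
the exactness study comparing the relaxation-plus-rounding pipeline with
exhaustive enumeration on small instances, the proximity-hypothesis
simulations, the decoy ablation contrasting lambda > 0 with lambda = 0,
and the predictive-power comparison of true versus random TF sets. The
test suite and the acceptance script both run them.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import networkx as nx
import numpy as np

from grip.core import (RegulationProblem, SolverConfig, brute_force_oracle,
                       check_tightness, gradient_G, objective_G,
                       project_capped_simplex, randomized_rounding,
                       ridge_oracle, solve_relaxation)
from grip.evaluate import oos_mse
from grip.ppi import PPINetwork, dsd_matrix, distance_submatrix, proximity_test
from grip.synthetic import (SyntheticSpec, degree_preserving_randomization,
                            generate_instance, support_recovery_f1)


def _random_problem(rng: np.random.Generator, m: int, n: int,
                    rho: float | None = None, lam: float = 0.0,
                    k: int | None = None,
                    strong: bool = False) -> RegulationProblem:
    """A random dense instance with a metric-like random S.

    ``strong=True`` plants exactly k large coefficients with little noise,
    the regime where the Boolean relaxation is typically tight; the default
    regime draws a random number of modest coefficients under real noise.
    """
    X = rng.standard_normal((m, n))
    beta = np.zeros(n)
    if strong:
        nnz = int(k if k is not None else rng.integers(1, 4))
        beta[rng.choice(n, nnz, replace=False)] = (
            rng.choice([-1.0, 1.0], nnz) * rng.uniform(1.5, 2.5, nnz))
        noise = 0.05
    else:
        nnz = rng.integers(1, min(n, 4) + 1)
        beta[rng.choice(n, nnz, replace=False)] = rng.normal(0, 1, nnz)
        noise = 0.5
    y = X @ beta + rng.standard_normal(m) * noise
    # embed points in the plane so S is a genuine metric
    pts = rng.random((n, 2)) * 4
    S = np.abs(pts[:, None, :] - pts[None, :, :]).sum(axis=2)
    np.fill_diagonal(S, 0.0)
    return RegulationProblem(
        y=y, X=X, tf_ids=[f"TF{i}" for i in range(n)], S=S,
        rho=float(rho if rho is not None else rng.choice([0.5, 1.0, 2.0])),
        lam=float(lam),
        k=min(n, int(k if k is not None else rng.integers(1, 4))))


# --- identity checks -------------------------------------------------------

def ridge_equivalence_study(n_instances: int = 100, seed: int = 0) -> dict:
    """Max |G(u; lam=0) - ridge(support(u))| over random Boolean selectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(5, 51))
        n = int(rng.integers(2, 21))
        p = _random_problem(rng, m, n, lam=0.0)
        u = (rng.random(n) < 0.4).astype(float)
        val_g = objective_G(u, p)
        val_r = ridge_oracle(np.flatnonzero(u), p.X, p.y, p.rho)
        worst = max(worst, abs(val_g - val_r))
    return {"max_abs_err": worst, "n": n_instances}


def woodbury_study(n_trials: int = 50, seed: int = 0) -> dict:
    """Entrywise agreement of direct vs low-rank inversion paths."""
    from grip.core import compute_M
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        m = int(rng.integers(3, 51))
        n = int(rng.integers(2, 51))
        X = rng.standard_normal((m, n))
        u = rng.random(n)  # fractional
        if rng.random() < 0.3:
            u = np.round(u)
        rho = float(rng.choice([0.3, 1.0, 5.0]))
        Md = compute_M(u, X, rho, "direct")
        Mw = compute_M(u, X, rho, "woodbury")
        worst = max(worst, float(np.abs(Md - Mw).max()))
    return {"max_abs_err": worst, "n": n_trials}


def gradient_study(n_instances: int = 10, n_points: int = 20,
                   seed: int = 0, h: float = 1e-6) -> dict:
    """Max per-coordinate relative error vs central finite differences.

    The denominator is floored at 1: the central-difference oracle itself
    carries roundoff noise of order eps * |G| / h (about 1e-9 here), so a
    strict relative comparison on near-zero coordinates would measure the
    oracle's noise, not the gradient.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        p = _random_problem(rng, 8, 5, lam=float(rng.choice([0.0, 0.3])))
        for _ in range(n_points):
            u = rng.uniform(0.1, 0.9, p.n)
            g = gradient_G(u, p)
            for i in range(p.n):
                e = np.zeros(p.n)
                e[i] = h
                fd = (objective_G(u + e, p) - objective_G(u - e, p)) / (2 * h)
                rel = abs(g[i] - fd) / max(1.0, abs(fd))
                worst = max(worst, rel)
    return {"max_rel_err": worst, "n": n_instances * n_points}


def _projection_dual_oracle(v: np.ndarray, k: float) -> np.ndarray:
    """Independent projection via bisection on the budget dual variable."""
    w = np.clip(v, 0.0, 1.0)
    if w.sum() <= k:
        return w
    lo, hi = 0.0, float(v.max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.clip(v - mid, 0.0, 1.0).sum() > k:
            lo = mid
        else:
            hi = mid
    return np.clip(v - 0.5 * (lo + hi), 0.0, 1.0)


def projection_study(n_vectors: int = 200, max_n: int = 1000,
                     seed: int = 0, slsqp_max_n: int = 200) -> dict:
    """Projection vs a generic QP solver (small n) and a dual oracle.

    SLSQP handles sizes up to ``slsqp_max_n``; beyond that the bisection
    oracle on the dual variable provides the reference (SLSQP's dense
    iterations become the bottleneck, not the projection).
    """
    from scipy.optimize import LinearConstraint, minimize
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(np.exp(rng.uniform(np.log(2), np.log(max_n))))
        v = rng.standard_normal(n) * rng.choice([0.5, 2.0, 10.0])
        k = float(rng.uniform(0.5, max(1.0, 0.5 * n)))
        mine = project_capped_simplex(v, k)
        assert mine.min() >= 0 and mine.max() <= 1 + 1e-12
        assert mine.sum() <= k + 1e-8
        again = project_capped_simplex(mine, k)
        worst = max(worst, float(np.abs(mine - again).max()))  # idempotent
        if n <= slsqp_max_n:
            res = minimize(lambda u: 0.5 * np.sum((u - v) ** 2),
                           np.clip(v, 0, 1), jac=lambda u: u - v,
                           bounds=[(0.0, 1.0)] * n,
                           constraints=[LinearConstraint(np.ones((1, n)),
                                                         -np.inf, k)],
                           method="SLSQP",
                           options={"maxiter": 300, "ftol": 1e-14})
            ref = res.x
        else:
            ref = _projection_dual_oracle(v, k)
        worst = max(worst, float(np.abs(mine - ref).max()))
    return {"max_abs_err": worst, "n": n_vectors}


# --- exactness vs enumeration ---------------------------------------------

def exactness_study(n_instances: int = 100, seed: int = 0,
                    max_n: int = 12, max_k: int = 3) -> dict:
    """Relaxation + rounding vs exhaustive enumeration on small instances.

    Returns the fraction of certificate-flagged instances whose rounded
    objective matches enumeration exactly, the worst relative objective
    gap over all instances, and the solver convergence rate.
    """
    rng = np.random.default_rng(seed)
    n_flagged = 0
    n_flagged_exact = 0
    worst_gap = 0.0
    n_converged = 0
    for i in range(n_instances):
        m = int(rng.integers(6, 31))
        n = int(rng.integers(4, max_n + 1))
        k = int(rng.integers(1, max_k + 1))
        lam = float(rng.choice([0.0, 0.1, 0.5]))
        p = _random_problem(rng, m, n, lam=lam, k=k, strong=(i % 2 == 0))
        cfg = SolverConfig(seed=int(rng.integers(2 ** 31)))
        sol = solve_relaxation(p, cfg)
        n_converged += sol.converged
        tight = check_tightness(sol, p)
        rounded = randomized_rounding(sol.u_hat, p, cfg.n_rounding_samples,
                                      cfg.seed)
        best = brute_force_oracle(p)
        gap = (rounded.objective - best.objective) / max(1e-12,
                                                         abs(best.objective))
        worst_gap = max(worst_gap, gap)
        if tight.xi_exists:
            n_flagged += 1
            n_flagged_exact += math.isclose(rounded.objective,
                                            best.objective,
                                            rel_tol=1e-9, abs_tol=1e-9)
    return {"n": n_instances, "n_flagged": n_flagged,
            "flagged_exact_rate": (n_flagged_exact / n_flagged
                                   if n_flagged else 1.0),
            "worst_rel_gap": worst_gap,
            "convergence_rate": n_converged / n_instances}


# --- proximity hypothesis simulations --------------------------------------

def _planted_regulon_network(seed: int, n_nodes: int = 60,
                             n_regulons: int = 3, regulon_size: int = 4,
                             p_edge: float = 0.1):
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        g = nx.gnp_random_graph(n_nodes, p_edge,
                                seed=int(rng.integers(2 ** 31)))
        if not nx.is_connected(g):
            continue
        g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
        nodes = sorted(g.nodes)
        chosen = rng.choice(len(nodes), n_regulons * regulon_size,
                            replace=False)
        regulons = {}
        for r in range(n_regulons):
            members = [nodes[i] for i in
                       chosen[r * regulon_size:(r + 1) * regulon_size]]
            for a, b in itertools.combinations(members, 2):
                g.add_edge(a, b)
            regulons[f"TG{r}"] = set(members)
        nx.set_edge_attributes(g, "physical", "interaction_type")
        return PPINetwork(graph=g), regulons, nodes
    raise RuntimeError("no connected background graph after 50 draws")


def proximity_hypothesis_study(n_seeds: int = 20, n_null_seeds: int = 100,
                               n_background: int = 20, seed: int = 0) -> dict:
    """Mann–Whitney p-values for planted regulons and for null regulons.

    Planted: regulon members form cliques, so their DSD distances pool
    below the background distribution. Null: regulons are drawn uniformly
    from the background, so the p-value should be roughly uniform.
    """
    planted_ps = []
    for s in range(n_seeds):
        net, regulons, nodes = _planted_regulon_network(seed + s)
        dsd = dsd_matrix(net, n_steps=7)
        rng = np.random.default_rng(seed + s)
        background = [nodes[i] for i in
                      rng.choice(len(nodes), n_background, replace=False)]
        res = proximity_test(regulons, background, "dsd", dsd)
        planted_ps.append(res.p_value)

    null_ps = []
    net, _, nodes = _planted_regulon_network(seed, n_regulons=0)
    dsd = dsd_matrix(net, n_steps=7)
    for s in range(n_null_seeds):
        rng = np.random.default_rng(seed + 1000 + s)
        background = [nodes[i] for i in
                      rng.choice(len(nodes), n_background, replace=False)]
        regulons = {f"TG{r}": set(rng.choice(background, 3, replace=False))
                    for r in range(3)}
        res = proximity_test(regulons, background, "dsd", dsd)
        null_ps.append(res.p_value)
    return {"planted_median_p": float(np.median(planted_ps)),
            "null_median_p": float(np.median(null_ps)),
            "n": n_seeds, "n_null": n_null_seeds}


# --- decoy ablation --------------------------------------------------------

def decoy_ablation_study(n_seeds: int = 50, seed: int = 0,
                         lam_grid: tuple[float, ...] = (0.0, 0.5, 1.0),
                         cv_folds: int = 3,
                         with_randomized_network: bool = True) -> dict:
    """Support recovery with and without the proximity term.

    For each seeded decoy instance: fit with lam = 0; pick the best
    positive lam from ``lam_grid`` by cross-validated held-out MSE; fit
    with it; optionally repeat the positive-lam fit with a
    degree-preserving randomized network. Reports mean recovery F1 per arm
    and win/tie/loss counts of the positive-lam arm against lam = 0.
    """
    pos = [l for l in lam_grid if l > 0]
    f1_zero, f1_pos, f1_rand = [], [], []
    wins = ties = 0
    for s in range(n_seeds):
        inst = generate_instance(SyntheticSpec(seed=seed + s))
        p0 = inst.problem
        cfg = SolverConfig(seed=seed + s)
        truth = inst.true_support

        def fit(p):
            sol = solve_relaxation(p, cfg)
            return randomized_rounding(sol.u_hat, p,
                                       cfg.n_rounding_samples, cfg.seed)

        r0 = fit(dataclasses.replace(p0, lam=0.0))
        f1_zero.append(support_recovery_f1(r0.support, truth))

        # best positive lam by CV held-out MSE (the CV grid includes 0 by
        # contract; the ablation contrasts the best lam > 0 with lam = 0)
        lam_best = _best_positive_lam(p0, pos, cv_folds, seed + s, cfg)
        rp = fit(dataclasses.replace(p0, lam=lam_best))
        f1_pos.append(support_recovery_f1(rp.support, truth))
        wins += f1_pos[-1] > f1_zero[-1]
        ties += f1_pos[-1] == f1_zero[-1]

        if with_randomized_network:
            rnet = degree_preserving_randomization(inst.network, seed=seed + s)
            rdsd = dsd_matrix(rnet, n_steps=7, component="largest")
            S2, _, _ = distance_submatrix(rdsd, p0.tf_ids, "max_fill")
            np.fill_diagonal(S2, 0.0)
            rr = fit(dataclasses.replace(p0, S=S2, lam=lam_best))
            f1_rand.append(support_recovery_f1(rr.support, truth))

    out = {"n": n_seeds,
           "mean_f1_lam0": float(np.mean(f1_zero)),
           "mean_f1_lam_pos": float(np.mean(f1_pos)),
           "wins": wins, "ties": ties, "losses": n_seeds - wins - ties,
           "win_fraction": wins / n_seeds}
    if with_randomized_network:
        out["mean_f1_randomized_net"] = float(np.mean(f1_rand))
        out["randomized_not_better_fraction"] = float(
            np.mean([r <= p for r, p in zip(f1_rand, f1_pos)]))
    return out


def _best_positive_lam(p0: RegulationProblem, pos_lams, cv_folds: int,
                       seed: int, cfg: SolverConfig) -> float:
    from grip.core import cross_validate
    if len(pos_lams) == 1:
        return float(pos_lams[0])
    choice, scores = cross_validate(
        p0.X, p0.y, p0.S, rho_grid=(p0.rho,),
        lam_grid=tuple([0.0] + list(pos_lams)), k_grid=(p0.k,),
        n_folds=cv_folds, seed=seed, config=cfg)
    means = (scores[scores["lam"] > 0]
             .groupby("lam")["mse"].mean().sort_values(kind="stable"))
    return float(means.index[0])


# --- predictive power ------------------------------------------------------

def oos_comparison_study(n_seeds: int = 100, seed: int = 0,
                         noise_sd: float = 0.0) -> dict:
    """OOS MSE with the true TFs vs an equal-sized random TF set."""
    n_true_better = 0
    for s in range(n_seeds):
        inst = generate_instance(SyntheticSpec(
            seed=seed + s, noise_sd=noise_sd,
            decoy=dict(enabled=False)))
        rng = np.random.default_rng(seed + 7000 + s)
        others = [t for t in inst.problem.tf_ids if t not in inst.true_tfs]
        random_tfs = [others[i] for i in
                      rng.choice(len(others), len(inst.true_tfs),
                                 replace=False)]
        mse_true = oos_mse(inst.expression, "TG1", inst.true_tfs,
                           seed=seed + s)
        mse_rand = oos_mse(inst.expression, "TG1", random_tfs, seed=seed + s)
        n_true_better += mse_true < mse_rand
    return {"n": n_seeds, "true_better_fraction": n_true_better / n_seeds}
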