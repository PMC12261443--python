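"""Sparse TF selection as a Boolean program with a network-proximity penalty.

For one target gene with expression ``y`` (m cells) and candidate-TF
expression matrix ``X`` (m x n), the selection problem is the
L0-constrained ridge regression

    min_{||beta||_0 <= k}  ||y - X beta||^2 + rho ||beta||^2,

which is equivalent to minimizing ``y^T M(u) y`` over Boolean selector
vectors u with ``sum u_i <= k``, where

    M(u) = (1/rho * X D(u) X^T + I)^{-1},  D(u) = diag(u).

Proximity of the selected TFs in the PPI network is encouraged by adding
``lambda * u^T S u`` with S a pairwise TF distance matrix (diffusion state
distance). The Boolean constraint is relaxed to the capped simplex
``{u : sum u_i <= k, 0 <= u_i <= 1}``, the relaxation is solved with a
projected L-BFGS method, exactness of the relaxation is certified by a
score-separation condition, and fractional solutions are converted back to
Boolean supports by randomized rounding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

__all__ = [
    "RegulationProblem", "RelaxedSolution", "BooleanSolution",
    "TightnessReport", "SolverConfig", "InferenceResult",
    "compute_M", "objective_G", "ridge_oracle", "gradient_G",
    "project_capped_simplex", "solve_relaxation", "check_tightness",
    "randomized_rounding", "sample_boolean_selectors", "brute_force_oracle",
    "cross_validate", "infer_regulators",
]


@dataclass
class RegulationProblem:
    """One target gene's inference instance.

    Attributes
    ----------
    y : (m,) centered target-gene expression.
    X : (m, n) column-standardized candidate-TF expression.
    tf_ids : n candidate TF symbols aligned with the columns of X and S.
    S : (n, n) symmetric non-negative TF distance matrix, zero diagonal.
    rho : ridge weight (> 0).
    lam : proximity weight (>= 0); 0 disables the network term.
    k : sparsity budget, 1 <= k <= n.
    """

    y: np.ndarray
    X: np.ndarray
    tf_ids: list[str]
    S: np.ndarray
    rho: float
    lam: float
    k: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        m, n = self.X.shape
        if self.y.shape != (m,):
            raise ValueError(f"y has length {self.y.shape[0]}, X has {m} rows")
        if len(self.tf_ids) != n:
            raise ValueError("tf_ids length does not match X columns")
        if self.S.shape != (n, n):
            raise ValueError("S must be n x n aligned with X columns")
        for name, arr in (("y", self.y), ("X", self.X), ("S", self.S)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if not np.allclose(self.S, self.S.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        if np.any(np.abs(np.diag(self.S)) > 1e-10):
            raise ValueError("S must have zero diagonal")
        if np.any(self.S < -1e-12):
            raise ValueError("S must be non-negative")
        if not self.rho > 0:
            raise ValueError("rho must be > 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (1 <= self.k <= n):
            raise ValueError(f"k must satisfy 1 <= k <= n (got {self.k})")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def _gram(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Cached (X^T X, X^T y, y^T y); every G/gradient evaluation only
        needs these, so repeated solver calls cost O(n^3) not O(m n^2)."""
        cache = getattr(self, "_gram_cache", None)
        if cache is None:
            cache = (self.X.T @ self.X, self.X.T @ self.y,
                     float(self.y @ self.y))
            object.__setattr__(self, "_gram_cache", cache)
        return cache


@dataclass
class RelaxedSolution:
    """Fractional selector from the relaxed problem.

    ``objective_trace`` holds G at the initial point and after every
    accepted step (non-increasing by construction).
    """

    u_hat: np.ndarray
    objective: float
    n_iterations: int
    converged: bool
    projected_gradient_norm: float
    objective_trace: np.ndarray | None = None


@dataclass
class BooleanSolution:
    """Boolean selector with its support and objective value."""

    u_tilde: np.ndarray
    support: tuple[int, ...]
    objective: float


@dataclass
class TightnessReport:
    """Score-separation certificate for exactness of the relaxation.

    ``scores[i] = (x_i^T M y)^2 + 2 lam * (S u)_i`` evaluated at the
    relaxed optimum; the relaxation is certified exact when every in-support
    score strictly exceeds every out-of-support score, i.e. a separating
    threshold exists in ``(max_out, min_in]``.
    """

    scores: np.ndarray
    support: tuple[int, ...]
    min_in: float
    max_out: float
    xi_exists: bool


@dataclass
class SolverConfig:
    """Projected quasi-Newton settings; all randomness flows from ``seed``.

    ``grad_tol`` is relative: iteration stops when the projected-gradient
    norm falls below ``grad_tol * max(1, |G(u)|)``, so the stopping rule is
    invariant to the overall scale of the objective (which grows with the
    number of cells). ``ftol`` is the relative objective-decrease floor:
    three consecutive accepted steps improving G by less than
    ``ftol * max(1, |G|)`` also count as convergence (the iterate is
    objective-stationary to working precision).
    """

    init: str | np.ndarray = "uniform"
    max_iter: int = 500
    grad_tol: float = 1e-6
    ftol: float = 1e-10
    lbfgs_memory: int = 10
    n_rounding_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.grad_tol > 0:
            raise ValueError("grad_tol must be > 0")
        if self.n_rounding_samples < 1:
            raise ValueError("n_rounding_samples must be >= 1")


@dataclass
class InferenceResult:
    """Ranked regulator call for one target gene."""

    tf_ids: list[str]
    ranked_tfs: list[str]
    relaxed: RelaxedSolution
    boolean: BooleanSolution
    tightness: TightnessReport
    rho: float
    lam: float
    k: int

    def to_frame(self, tg: str = "") -> pd.DataFrame:
        u = self.relaxed.u_hat
        sel = self.boolean.u_tilde
        rank = np.full(len(self.tf_ids), 0, dtype=int)
        for r, tf in enumerate(self.ranked_tfs, start=1):
            rank[self.tf_ids.index(tf)] = r
        return pd.DataFrame({
            "tg": tg, "tf": self.tf_ids, "u_hat": u,
            "selected": sel.astype(int), "rank": rank,
        })


# --- core linear algebra ---------------------------------------------------

def _check_u(u: np.ndarray, n: int) -> np.ndarray:
    u = np.asarray(u, dtype=float).ravel()
    if u.shape != (n,):
        raise ValueError(f"u has length {u.shape[0]}, expected {n}")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite values in u")
    return u


def compute_M(u: np.ndarray, X: np.ndarray, rho: float,
              method: str = "direct") -> np.ndarray:
    """The m x m matrix ``M = (1/rho X D(u) X^T + I)^{-1}``.

    ``method="direct"`` inverts the m x m matrix; ``method="woodbury"``
    uses the low-rank identity

        M = I - (1/rho) X D^{1/2} (I + (1/rho) D^{1/2} X^T X D^{1/2})^{-1}
            D^{1/2} X^T

    (valid for any u >= 0, fractional included), which only inverts an
    n x n matrix and is the scalable path when cells outnumber TFs.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    u = _check_u(u, n)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    if method == "direct":
        A = X @ (u[:, None] * X.T) / rho + np.eye(m)
        return np.linalg.inv(A)
    if method == "woodbury":
        d = np.sqrt(np.clip(u, 0.0, None))
        B = X * d[None, :]
        K = np.eye(n) + (B.T @ B) / rho
        return np.eye(m) - (B @ np.linalg.solve(K, B.T)) / rho
    raise ValueError(f"unknown method {method!r}")


def _fit_terms(u: np.ndarray, problem: RegulationProblem
               ) -> tuple[float, np.ndarray]:
    """``(y^T M y, X^T M y)`` at u via the n x n Woodbury system."""
    XtX, Xty, yty = problem._gram()
    rho = problem.rho
    d = np.sqrt(np.clip(u, 0.0, None))
    K = np.eye(problem.n) + (d[:, None] * XtX * d[None, :]) / rho
    t = np.linalg.solve(K, d * Xty)
    yMy = yty - float((d * Xty) @ t) / rho
    XtMy = Xty - ((XtX * d[None, :]) @ t) / rho
    return yMy, XtMy


def objective_G(u: np.ndarray, problem: RegulationProblem) -> float:
    """The relaxed objective ``G(u) = y^T M(u) y + lam * u^T S u``."""
    u = _check_u(u, problem.n)
    yMy, _ = _fit_terms(u, problem)
    val = yMy
    if problem.lam:
        val += problem.lam * float(u @ (problem.S @ u))
    return val


def gradient_G(u: np.ndarray, problem: RegulationProblem) -> np.ndarray:
    """Exact gradient ``-(1/rho)(X^T M y) ** 2 + 2 lam S u``."""
    u = _check_u(u, problem.n)
    _, c = _fit_terms(u, problem)
    g = -(c * c) / problem.rho
    if problem.lam:
        g = g + 2.0 * problem.lam * (problem.S @ u)
    return g


def ridge_oracle(support: Sequence[int], X: np.ndarray, y: np.ndarray,
                 rho: float) -> float:
    """Closed-form ridge objective restricted to a TF support.

    Returns ``min_beta ||y - X_S beta||^2 + rho ||beta||^2``; by the matrix
    inversion identity this equals ``y^T M(u) y`` at the support indicator.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    support = sorted(set(int(i) for i in support))
    if any(i < 0 or i >= X.shape[1] for i in support):
        raise IndexError("support index out of range")
    if not support:
        return float(y @ y)
    Xs = X[:, support]
    K = Xs.T @ Xs + rho * np.eye(len(support))
    beta = np.linalg.solve(K, Xs.T @ y)
    r = y - Xs @ beta
    return float(r @ r + rho * beta @ beta)


# --- capped-simplex projection --------------------------------------------

def project_capped_simplex(v: np.ndarray, k: float) -> np.ndarray:
    """Euclidean projection onto ``{u : sum u_i <= k, 0 <= u_i <= 1}``.

    If clipping to the box already satisfies the budget the clip is the
    projection; otherwise the unique projection is ``clip(v - theta, 0, 1)``
    with the threshold ``theta > 0`` solving ``sum clip(v - theta, 0, 1) = k``,
    found exactly from the sorted breakpoints of that piecewise-linear sum.
    """
    if not k > 0:
        raise ValueError("budget k must be > 0")
    v = np.asarray(v, dtype=float).ravel()
    w = np.clip(v, 0.0, 1.0)
    s = w.sum()
    if s <= k:
        return w
    # breakpoints of f(theta) = sum clip(v - theta, 0, 1); f(0) = s > k
    bps = np.unique(np.concatenate([v, v - 1.0]))
    bps = np.concatenate([[0.0], bps[bps > 0]])
    f_at = np.clip(v[None, :] - bps[:, None], 0.0, 1.0).sum(axis=1)
    j = int(np.searchsorted(-f_at, -k, side="right")) - 1  # last f >= k
    theta_lo = bps[j]
    theta_hi = bps[j + 1] if j + 1 < len(bps) else theta_lo + 1.0
    mid = 0.5 * (theta_lo + theta_hi)
    ones = v - mid >= 1.0
    active = (v - mid > 0.0) & ~ones
    n_act = int(active.sum())
    if n_act == 0:
        theta = theta_lo  # f is flat and equal to k on this segment
    else:
        theta = (v[active].sum() + ones.sum() - k) / n_act
    return np.clip(v - theta, 0.0, 1.0)


# --- projected quasi-Newton solver ----------------------------------------

def _two_loop(g: np.ndarray, s_hist: list[np.ndarray],
              y_hist: list[np.ndarray]) -> np.ndarray:
    """Standard L-BFGS two-loop recursion for the search direction -H g."""
    q = g.copy()
    alphas = []
    rhos = [1.0 / (yk @ sk) for sk, yk in zip(s_hist, y_hist)]
    for sk, yk, rk in zip(reversed(s_hist), reversed(y_hist), reversed(rhos)):
        a = rk * (sk @ q)
        alphas.append(a)
        q -= a * yk
    if s_hist:
        sk, yk = s_hist[-1], y_hist[-1]
        gamma = (sk @ yk) / (yk @ yk)
        q *= gamma
    for (sk, yk, rk), a in zip(zip(s_hist, y_hist, rhos), reversed(alphas)):
        b = rk * (yk @ q)
        q += (a - b) * sk
    return -q


def solve_relaxation(problem: RegulationProblem,
                     config: SolverConfig | None = None) -> RelaxedSolution:
    """Minimize G over the capped simplex by projected L-BFGS.

    Each iterate takes a limited-memory quasi-Newton step, projects it onto
    the capped simplex, and backtracks along the projected arc until an
    Armijo decrease holds (falling back to the projected-gradient direction
    when the quasi-Newton direction fails). The objective sequence is
    non-increasing; convergence is declared when the projected-gradient
    norm ``||u - proj(u - g)||`` drops below ``grad_tol``.
    """
    config = config or SolverConfig()
    n, k = problem.n, problem.k
    if isinstance(config.init, str):
        if config.init == "uniform":
            u = np.full(n, min(k / n, 1.0))
        elif config.init == "zeros":
            u = np.zeros(n)
        else:
            raise ValueError(f"unknown init {config.init!r}")
    else:
        u = project_capped_simplex(np.asarray(config.init, dtype=float), k)

    f = objective_G(u, problem)
    if not math.isfinite(f):
        raise FloatingPointError("non-finite objective at the initial point")
    trace = [f]
    g = gradient_G(u, problem)
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    c1 = 1e-4

    def _tol(fval: float) -> float:
        return config.grad_tol * max(1.0, abs(fval))

    pg_norm = float(np.linalg.norm(u - project_capped_simplex(u - g, k)))
    n_iter = 0
    n_stag = 0
    converged = pg_norm <= _tol(f)

    while n_iter < config.max_iter and not converged:
        n_iter += 1
        directions = []
        if s_hist:
            d_qn = _two_loop(g, s_hist, y_hist)
            if float(d_qn @ g) < 0.0:  # only try genuine descent directions
                directions.append(d_qn)
        directions.append(-g)

        u_new = f_new = None
        for d in directions:
            alpha = 1.0
            for _ in range(30):
                cand = project_capped_simplex(u + alpha * d, k)
                step = cand - u
                slope = float(g @ step)
                if np.linalg.norm(step) == 0.0:
                    break
                f_cand = objective_G(cand, problem)
                if slope < 0.0 and f_cand <= f + c1 * slope:
                    u_new, f_new = cand, f_cand
                    break
                alpha *= 0.5
            if u_new is not None:
                break
        if u_new is None:
            # no feasible descent step exists at machine precision: the
            # iterate is stationary to working accuracy
            converged = True
            break

        if f_new > f + 1e-8 * max(1.0, abs(f)):
            raise RuntimeError("objective increased along accepted step; "
                               "gradient is inconsistent with the objective")
        if f - f_new <= config.ftol * max(1.0, abs(f)):
            n_stag += 1
        else:
            n_stag = 0
        g_new = gradient_G(u_new, problem)
        sk = u_new - u
        yk = g_new - g
        if float(sk @ yk) > 1e-10:
            s_hist.append(sk)
            y_hist.append(yk)
            if len(s_hist) > config.lbfgs_memory:
                s_hist.pop(0)
                y_hist.pop(0)
        u, f, g = u_new, min(f_new, f), g_new
        trace.append(f)
        if not math.isfinite(f):
            raise FloatingPointError("non-finite objective during iteration")
        pg_norm = float(np.linalg.norm(u - project_capped_simplex(u - g, k)))
        if pg_norm <= _tol(f) or n_stag >= 3:
            converged = True

    u = np.clip(u, 0.0, 1.0)
    return RelaxedSolution(u_hat=u, objective=float(f), n_iterations=n_iter,
                           converged=bool(converged),
                           projected_gradient_norm=pg_norm,
                           objective_trace=np.asarray(trace))


# --- exactness certificate -------------------------------------------------

def check_tightness(u_star: RelaxedSolution | np.ndarray,
                    problem: RegulationProblem,
                    support_tol: float = 1e-4) -> TightnessReport:
    """Evaluate the score-separation certificate at the relaxed optimum.

    The per-TF score is ``(x_i^T M y)^2 + 2 lam (S u)_i`` with M evaluated
    at the relaxed solution. The relaxation is certified exact when the
    smallest score inside the support ``{i : u_i > support_tol}`` strictly
    exceeds the largest score outside it (trivially true for an empty or
    full support). A support larger than the budget k cannot belong to any
    feasible Boolean vector — ties spread across the budget boundary force
    a fractional optimum — so separation is only certified when
    ``|support| <= k``.
    """
    u = u_star.u_hat if isinstance(u_star, RelaxedSolution) else np.asarray(u_star)
    u = _check_u(u, problem.n)
    _, c = _fit_terms(u, problem)
    scores = c * c + 2.0 * problem.lam * (problem.S @ u)
    inside = u > support_tol
    support = tuple(int(i) for i in np.flatnonzero(inside))
    if inside.all() or not inside.any():
        min_in = float(scores[inside].min()) if inside.any() else math.inf
        max_out = float(scores[~inside].max()) if (~inside).any() else -math.inf
        xi = len(support) <= problem.k
    else:
        min_in = float(scores[inside].min())
        max_out = float(scores[~inside].max())
        xi = (min_in > max_out) and len(support) <= problem.k
    return TightnessReport(scores=scores, support=support, min_in=min_in,
                           max_out=max_out, xi_exists=bool(xi))


# --- randomized rounding ---------------------------------------------------

def sample_boolean_selectors(u_hat: np.ndarray, n_samples: int,
                             seed: int) -> np.ndarray:
    """Raw Bernoulli draws ``P[u_i = 1] = u_hat_i`` (no budget repair)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    return (rng.random((n_samples, u_hat.size)) < u_hat[None, :])


def randomized_rounding(u_hat: np.ndarray, problem: RegulationProblem,
                        n_samples: int = 100, seed: int = 0,
                        local_search: bool = True) -> BooleanSolution:
    """Convert a fractional selector to the best sampled Boolean selector.

    Boolean vectors are drawn coordinate-wise from Bernoulli(u_hat), so the
    draws match the fractional solution in expectation and respect the
    budget in expectation. Draws exceeding the budget are repaired by
    keeping the k drawn coordinates with largest u_hat; the deterministic
    top-k thresholding candidate always joins the pool. The candidate with
    minimum objective G wins, and is then polished by a deterministic
    best-improvement local search over single-coordinate swaps, additions
    and removals — the fractional optimum can put zero mass on coordinates
    of the best Boolean support, which Bernoulli draws alone can never
    reach.
    """
    u_hat = _check_u(u_hat, problem.n)
    k = problem.k
    draws = sample_boolean_selectors(u_hat, n_samples, seed)
    order = np.argsort(-u_hat, kind="stable")

    candidates: dict[tuple[int, ...], np.ndarray] = {}

    def add(mask: np.ndarray) -> None:
        if mask.sum() > k:
            drawn = [i for i in order if mask[i]]
            keep = drawn[:k]
            mask = np.zeros_like(mask)
            mask[keep] = True
        supp = tuple(int(i) for i in np.flatnonzero(mask))
        candidates.setdefault(supp, mask)

    topk = np.zeros(problem.n, dtype=bool)
    topk[[i for i in order[:k] if u_hat[i] > 1e-12]] = True
    add(topk)
    for row in draws:
        add(row.copy())

    def value(supp: tuple[int, ...]) -> float:
        u = np.zeros(problem.n)
        u[list(supp)] = 1.0
        return objective_G(u, problem)

    best_supp, best_val = (), math.inf
    for supp in sorted(candidates):
        val = value(supp)
        if val < best_val - 1e-15:
            best_supp, best_val = supp, val

    if local_search:
        improved = True
        while improved:
            improved = False
            cur = set(best_supp)
            moves: list[tuple[int, ...]] = []
            outside = [j for j in range(problem.n) if j not in cur]
            if len(cur) < k:
                moves += [tuple(sorted(cur | {j})) for j in outside]
            moves += [tuple(sorted(cur - {i})) for i in cur]
            moves += [tuple(sorted((cur - {i}) | {j}))
                      for i in cur for j in outside]
            for supp in moves:
                val = value(supp)
                if val < best_val - 1e-10 * max(1.0, abs(best_val)):
                    best_supp, best_val = supp, val
                    improved = True

    mask = np.zeros(problem.n, dtype=bool)
    mask[list(best_supp)] = True
    return BooleanSolution(u_tilde=mask.astype(float), support=tuple(best_supp),
                           objective=float(best_val))


# --- enumeration oracle ----------------------------------------------------

def brute_force_oracle(problem: RegulationProblem,
                       max_supports: int = 300_000) -> BooleanSolution:
    """Exhaustively minimize G over all Boolean supports of size 0..k.

    Test oracle only; ties broken toward the lexicographically smallest
    support.
    """
    n, k = problem.n, problem.k
    if n > 20:
        raise ValueError("brute force restricted to n <= 20")
    total = sum(math.comb(n, j) for j in range(k + 1))
    if total > max_supports:
        raise ValueError(f"{total} supports exceed enumeration budget")
    best_supp: tuple[int, ...] = ()
    best_val = math.inf
    for size in range(k + 1):
        for supp in itertools.combinations(range(n), size):
            u = np.zeros(n)
            u[list(supp)] = 1.0
            val = objective_G(u, problem)
            if val < best_val - 1e-12:
                best_supp, best_val = supp, val
    u = np.zeros(n)
    u[list(best_supp)] = 1.0
    return BooleanSolution(u_tilde=u, support=best_supp, objective=float(best_val))


# --- cross-validation and orchestration ------------------------------------

def _ridge_fit_predict(X_tr, y_tr, X_te, support, rho):
    support = list(support)
    if not support:
        return np.zeros(X_te.shape[0])
    Xs = X_tr[:, support]
    beta = np.linalg.solve(Xs.T @ Xs + rho * np.eye(len(support)), Xs.T @ y_tr)
    return X_te[:, support] @ beta


def cross_validate(X: np.ndarray, y: np.ndarray, S: np.ndarray,
                   rho_grid: Sequence[float] = (0.1, 1.0, 10.0),
                   lam_grid: Sequence[float] = (0.0, 0.01, 0.1, 1.0),
                   k_grid: Sequence[int] = (3, 5, 10),
                   n_folds: int = 5, seed: int = 0,
                   config: SolverConfig | None = None,
                   ) -> tuple[dict, pd.DataFrame]:
    """Grid-search (rho, lam, k) by k-fold held-out MSE.

    For every grid point the selector is fit on the training folds
    (relaxation + rounding), a ridge model restricted to the selected
    support is refit on the same training folds, and its MSE on the
    held-out fold is recorded. The winner minimizes mean held-out MSE with
    deterministic tie-breaks: smaller k, then smaller lam, then smaller rho.
    The lam grid must contain 0 so the no-proximity ablation is always a
    candidate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not len(rho_grid) or not len(lam_grid) or not len(k_grid):
        raise ValueError("hyper-parameter grids must be non-empty")
    if 0.0 not in [float(l) for l in lam_grid]:
        raise ValueError("lam grid must include 0 (no-proximity ablation)")
    m, n = X.shape
    if m < 2 * n_folds:
        raise ValueError("a fold would have < 2 samples")
    base = config or SolverConfig()
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    records = []
    for rho in rho_grid:
        for lam in lam_grid:
            for k in k_grid:
                k_eff = min(int(k), n)
                fold_mses = []
                for fold, (tr, te) in enumerate(splits):
                    prob = RegulationProblem(
                        y=y[tr], X=X[tr], tf_ids=[str(i) for i in range(n)],
                        S=S, rho=float(rho), lam=float(lam), k=k_eff)
                    relaxed = solve_relaxation(prob, base)
                    boolean = randomized_rounding(
                        relaxed.u_hat, prob, base.n_rounding_samples,
                        seed=base.seed)
                    pred = _ridge_fit_predict(X[tr], y[tr], X[te],
                                              boolean.support, float(rho))
                    mse = float(np.mean((y[te] - pred) ** 2))
                    fold_mses.append(mse)
                    records.append({"rho": float(rho), "lam": float(lam),
                                    "k": k_eff, "fold": fold, "mse": mse})
    scores = pd.DataFrame.from_records(records)
    means = (scores.groupby(["rho", "lam", "k"], as_index=False)["mse"].mean()
             .sort_values(["mse", "k", "lam", "rho"],
                          kind="stable").reset_index(drop=True))
    best = means.iloc[0]
    choice = {"rho": float(best["rho"]), "lam": float(best["lam"]),
              "k": int(best["k"]), "cv_mse": float(best["mse"])}
    return choice, scores


def infer_regulators(X: np.ndarray, y: np.ndarray, tf_ids: Sequence[str],
                     S: np.ndarray, config: SolverConfig | None = None,
                     rho: float | None = None, lam: float | None = None,
                     k: int | None = None,
                     grids: dict | None = None,
                     n_folds: int = 5) -> InferenceResult:
    """Full single-TG pipeline: (optional CV) -> relax -> certify -> round.

    When any of (rho, lam, k) is None the missing values are chosen by
    cross-validation over ``grids`` (defaults as in :func:`cross_validate`).
    Rounding is skipped when the relaxed solution is already Boolean within
    1e-6. Selected TFs are ranked by their fractional selector value.
    """
    config = config or SolverConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    tf_ids = [str(t) for t in tf_ids]
    if rho is None or lam is None or k is None:
        grids = grids or {}
        choice, _ = cross_validate(
            X, y, S,
            rho_grid=grids.get("rho", (0.1, 1.0, 10.0)),
            lam_grid=grids.get("lam", (0.0, 0.01, 0.1, 1.0)),
            k_grid=grids.get("k", (3, 5, 10)),
            n_folds=n_folds, seed=config.seed, config=config)
        rho = choice["rho"] if rho is None else rho
        lam = choice["lam"] if lam is None else lam
        k = choice["k"] if k is None else k

    problem = RegulationProblem(y=y, X=X, tf_ids=tf_ids, S=S,
                                rho=float(rho), lam=float(lam), k=int(k))
    relaxed = solve_relaxation(problem, config)
    tight = check_tightness(relaxed, problem)
    u = relaxed.u_hat
    if np.all(np.minimum(np.abs(u), np.abs(1.0 - u)) < 1e-6):
        mask = u > 0.5
        boolean = BooleanSolution(
            u_tilde=mask.astype(float),
            support=tuple(int(i) for i in np.flatnonzero(mask)),
            objective=objective_G(mask.astype(float), problem))
    else:
        boolean = randomized_rounding(u, problem, config.n_rounding_samples,
                                      seed=config.seed)
    ranked = sorted(boolean.support, key=lambda i: (-u[i], i))
    return InferenceResult(
        tf_ids=tf_ids, ranked_tfs=[tf_ids[i] for i in ranked],
        relaxed=relaxed, boolean=boolean, tightness=tight,
        rho=float(rho), lam=float(lam), k=int(k))
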