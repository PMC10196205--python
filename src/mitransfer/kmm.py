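"""Kernel mean matching: importance weights for covariate shift.

Given source samples ``x^s_1..n`` and target samples ``x^t_1..p``, KMM finds
per-source weights ``beta`` minimizing the squared maximum mean discrepancy

    || (1/n) sum_i beta_i Phi(x^s_i) - (1/p) sum_j Phi(x^t_j) ||^2_H

in the RKHS of a Gaussian kernel ``k(x, y) = exp(-||x-y||^2 / (2 sigma^2))``.
Expanding the norm gives the quadratic program

    min_beta  (1/2) beta' K beta - kappa' beta
    s.t.      0 <= beta_i <= B,   |sum_i beta_i - n| <= n * eps,

with ``K = k(Xs, Xs)`` and ``kappa_i = (n/p) sum_j k(x^s_i, x^t_j)``.  At the
optimum ``beta_i`` approximates the density ratio p_target/p_source at
``x^s_i``.  The box bound ``B`` caps the influence of any single trial and
the slack ``eps`` keeps the weights a proper reweighting (mean ~ 1).

The QP is solved with a monotone FISTA (accelerated projected gradient);
projection onto the feasible set (a box intersected with a sum band) reduces
to a scalar bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.distance import cdist, pdist

MEDIAN_HEURISTIC = "median"


@dataclass
class KernelConfig:
    """Gaussian-kernel and feasible-set settings.

    ``sigma="median"`` resolves to the median pairwise distance of the pooled
    features at fit time.  ``upper_bound=1, sum_tolerance=None`` reproduces
    the bare ``beta in [0, 1]`` box (no sum constraint).
    """

    sigma: Union[float, str] = MEDIAN_HEURISTIC
    upper_bound: float = 10.0
    sum_tolerance: Union[float, None] = 0.01
    ridge: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.sigma, str):
            if self.sigma != MEDIAN_HEURISTIC:
                raise ValueError(f"unknown sigma sentinel {self.sigma!r}")
        elif self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.upper_bound < 1.0:
            raise ValueError("upper_bound must be >= 1")
        if self.sum_tolerance is not None and self.sum_tolerance < 0:
            raise ValueError("sum_tolerance must be >= 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass
class SourceWeightVector:
    """Per-source-trial importance weights and the achieved squared MMD."""

    weights: np.ndarray
    objective: float
    sigma: float
    config: KernelConfig = field(repr=False, default_factory=KernelConfig)


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """``exp(-||x - y||^2 / (2 sigma^2))`` for every row pair."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"dimension mismatch: {x.shape[1]} vs {y.shape[1]}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-cdist(x, y, "sqeuclidean") / (2.0 * sigma ** 2))


def median_heuristic_sigma(
    x: np.ndarray, max_points: int = 1000, seed: int = 0
) -> float:
    """Median pairwise Euclidean distance (zero self/duplicate pairs excluded).

    For more than ``max_points`` rows a seeded subsample is used.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        x = x[rng.choice(x.shape[0], size=max_points, replace=False)]
    d = pdist(x)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all rows identical: pairwise spread is degenerate")
    return float(np.median(d))


def mmd_squared(
    x_source: np.ndarray,
    x_target: np.ndarray,
    weights: np.ndarray,
    sigma: float,
) -> float:
    """Direct kernel-sum evaluation of the squared weighted MMD."""
    x_source = np.atleast_2d(np.asarray(x_source, dtype=float))
    x_target = np.atleast_2d(np.asarray(x_target, dtype=float))
    w = np.asarray(weights, dtype=float)
    n, p = x_source.shape[0], x_target.shape[0]
    if w.shape != (n,):
        raise ValueError("weights length must match source count")
    k_ss = gaussian_kernel(x_source, x_source, sigma)
    k_st = gaussian_kernel(x_source, x_target, sigma)
    k_tt = gaussian_kernel(x_target, x_target, sigma)
    return float(
        w @ k_ss @ w / n ** 2
        - 2.0 * (w @ k_st.sum(axis=1)) / (n * p)
        + k_tt.sum() / p ** 2
    )


def _project_box_sumband(
    v: np.ndarray, upper: float, lo: float, hi: float, iters: int = 60
) -> np.ndarray:
    """Euclidean projection onto ``{0 <= b <= upper, lo <= sum(b) <= hi}``.

    The KKT solution is ``clip(v + t, 0, upper)`` for a scalar shift ``t``
    (zero if the clipped point already satisfies the sum band); ``t`` is
    found by bisection on the monotone map ``t -> sum(clip(v + t, 0, upper))``.
    """
    b = np.clip(v, 0.0, upper)
    s = b.sum()
    if lo <= s <= hi:
        return b
    target = lo if s < lo else hi
    t_lo = -upper - float(v.max())
    t_hi = upper - float(v.min())
    for _ in range(iters):
        t_mid = 0.5 * (t_lo + t_hi)
        if np.clip(v + t_mid, 0.0, upper).sum() < target:
            t_lo = t_mid
        else:
            t_hi = t_mid
    return np.clip(v + 0.5 * (t_lo + t_hi), 0.0, upper)


def _solve_qp(
    k: np.ndarray,
    kappa: np.ndarray,
    upper: float,
    sum_lo: float,
    sum_hi: float,
    max_iter: int = 20000,
    rtol: float = 1e-13,
) -> np.ndarray:
    """Monotone FISTA for ``min 1/2 b'Kb - kappa'b`` over the feasible set.

    Starts from the feasible uniform vector and tracks the best iterate, so
    the returned objective never exceeds the uniform-weight objective.
    """
    n = k.shape[0]
    # Lipschitz constant of the gradient: lambda_max(K), by power iteration
    v = np.ones(n) / np.sqrt(n)
    for _ in range(100):
        v_new = k @ v
        norm = np.linalg.norm(v_new)
        if norm == 0:
            break
        v = v_new / norm
    lip = max(float(v @ k @ v), 1e-12)

    def objective(b: np.ndarray) -> float:
        return float(0.5 * b @ k @ b - kappa @ b)

    b = _project_box_sumband(np.ones(n), upper, sum_lo, sum_hi)
    y = b.copy()
    t_k = 1.0
    best, best_obj = b.copy(), objective(b)
    prev_check = best_obj
    for it in range(max_iter):
        b_new = _project_box_sumband(y - (k @ y - kappa) / lip, upper, sum_lo, sum_hi)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        y = b_new + ((t_k - 1.0) / t_new) * (b_new - b)
        b, t_k = b_new, t_new
        if it % 50 == 49:
            obj = objective(b)
            if obj < best_obj:
                best, best_obj = b.copy(), obj
            if abs(prev_check - obj) <= rtol * max(1.0, abs(obj)):
                break
            prev_check = obj
    obj = objective(b)
    if obj < best_obj:
        best = b
    return best


def solve_weights(
    x_source: np.ndarray,
    x_target: np.ndarray,
    cfg: KernelConfig | None = None,
    seed: int = 0,
    jitter: float = 1e-8,
) -> SourceWeightVector:
    """Fit KMM importance weights for the source sample.

    ``seed`` only affects the subsample used by the median heuristic when
    ``cfg.sigma == "median"``.  Returns the weights together with the achieved
    squared MMD (constant target-target term included).
    """
    cfg = cfg or KernelConfig()
    x_source = np.atleast_2d(np.asarray(x_source, dtype=float))
    x_target = np.atleast_2d(np.asarray(x_target, dtype=float))
    n, p = x_source.shape[0], x_target.shape[0]
    if n < 2 or p < 2:
        raise ValueError("need at least 2 source and 2 target samples")
    if not (np.isfinite(x_source).all() and np.isfinite(x_target).all()):
        raise ValueError("features must be finite")
    sigma = (
        median_heuristic_sigma(np.vstack([x_source, x_target]), seed=seed)
        if cfg.sigma == MEDIAN_HEURISTIC
        else float(cfg.sigma)
    )
    k = gaussian_kernel(x_source, x_source, sigma)
    # ridge selects the smooth minimum-norm solution among the (generally
    # non-unique) MMD minimizers — the one that tracks the density ratio;
    # jitter merely guarantees positive definiteness
    k[np.diag_indices_from(k)] += cfg.ridge + jitter
    kappa = (n / p) * gaussian_kernel(x_source, x_target, sigma).sum(axis=1)
    if cfg.sum_tolerance is None:
        sum_lo, sum_hi = 0.0, n * cfg.upper_bound  # box only
    else:
        sum_lo = n * (1.0 - cfg.sum_tolerance)
        sum_hi = n * (1.0 + cfg.sum_tolerance)
    weights = _solve_qp(k, kappa, cfg.upper_bound, sum_lo, sum_hi)
    # guard: if regularization traded away raw MMD vs the feasible uniform
    # start, keep the start (preserves the optimality contract exactly)
    uniform = _project_box_sumband(np.ones(n), cfg.upper_bound, sum_lo, sum_hi)
    if mmd_squared(x_source, x_target, weights, sigma) > mmd_squared(
        x_source, x_target, uniform, sigma
    ):
        weights = uniform
    return SourceWeightVector(
        weights=weights,
        objective=mmd_squared(x_source, x_target, weights, sigma),
        sigma=sigma,
        config=cfg,
    )
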