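"""Curvilinear-gradient least-squares optimisation.

Given a residual function r(p) (model minus data, m residuals over n
parameters), each iteration linearises r around the current point,

    r(dp) ~= r0 + J dp,
    Q(dp)  = r^T r = Q0 + dp^T G + (1/2) dp^T H dp,
    G = 2 J^T r0,   H = 2 J^T J,

and, instead of taking the full Newton step dp = -H^{-1} G (exact only
where the linearisation holds), searches the TRUE objective along the
steepest-descent curve of the quadratic form,

    L(a) = (exp(-H a) - I) H^{-1} G,   a in [0, inf),

which leaves the current point tangent to -G (steepest descent) and bends
into the Newton step as a -> inf.  The best point on the curve is
accepted, the quadratic model is rebuilt there, and the process repeats
until the objective stops decreasing.  The curve is evaluated through the
eigendecomposition of H, where the coefficient (exp(-lambda a) - 1)/lambda
has the finite limit -a as lambda -> 0, so a singular Hessian needs no
regularisation on the path itself.

Parameters are optimised on an internal per-parameter scale (default
max(|p0|, 1)) because conductances and slope factors can differ by five
orders of magnitude, and box bounds are enforced by projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ResidualFunction",
    "QuadraticModel",
    "FitResult",
    "jacobian",
    "quadratic_model",
    "newton_step",
    "curvilinear_trajectory",
    "line_search",
    "optimise",
    "objective_surface",
]

_EIG_FLOOR = 1e-10  # eigenvalue floor relative to lambda_max, Newton step only


@dataclass
class ResidualFunction:
    """Black-box residual contract: p (n,) -> weighted residuals (m,).

    ``lower``/``upper`` are box bounds (defaults unbounded) and ``scale``
    the per-parameter magnitudes used internally by the optimiser
    (defaults to max(|p0|, 1) at fit time).
    """

    fn: Callable[[np.ndarray], np.ndarray]
    names: Sequence[str] | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(np.asarray(p, dtype=float)), dtype=float)

    def bounds_for(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(n, -np.inf) if self.lower is None else np.asarray(self.lower, float)
        hi = np.full(n, np.inf) if self.upper is None else np.asarray(self.upper, float)
        if lo.size != n or hi.size != n:
            raise ValueError("bounds do not match the parameter count")
        return lo, hi


@dataclass(frozen=True)
class QuadraticModel:
    """Local quadratic model Q0 + dp^T G + (1/2) dp^T H dp of the objective."""

    Q0: float
    G: np.ndarray
    H: np.ndarray

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of the (symmetric PSD) Hessian, cached."""
        cache = getattr(self, "_eig", None)
        if cache is None:
            lam, V = np.linalg.eigh(self.H)
            lam = np.maximum(lam, 0.0)  # Gram matrix; clip FP noise
            cache = (lam, V)
            object.__setattr__(self, "_eig", cache)
        return cache

    def value(self, dp: np.ndarray) -> float:
        """Predicted objective at increment dp."""
        return float(self.Q0 + dp @ self.G + 0.5 * dp @ self.H @ dp)


@dataclass
class FitResult:
    """Outcome of an optimisation run."""

    p: np.ndarray
    objective: float
    history: list[float]
    n_iterations: int
    termination: str
    restart_index: int = 0
    restart_objectives: list[float] = field(default_factory=list)


def jacobian(
    rf,
    p: np.ndarray,
    *,
    r0: np.ndarray | None = None,
    rel_step: float = 1e-4,
    abs_step: float = 1e-8,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> np.ndarray:
    """Forward finite-difference Jacobian of the residual, column by column.

    The step for column j is ``max(rel_step * |p_j|, abs_step)``; when the
    forward probe leaves the bounds or returns non-finite residuals the
    column falls back to a backward step, then raises.
    """
    fn = rf if callable(rf) else rf.fn
    p = np.asarray(p, dtype=float)
    if r0 is None:
        r0 = np.asarray(fn(p), dtype=float)
    n = p.size
    J = np.empty((r0.size, n))
    for j in range(n):
        h = max(rel_step * abs(p[j]), abs_step)
        if upper is not None and p[j] + h > upper[j]:
            h = -h
        for attempt in range(2):
            probe = p.copy()
            probe[j] += h
            rj = np.asarray(fn(probe), dtype=float)
            if np.all(np.isfinite(rj)):
                J[:, j] = (rj - r0) / h
                break
            h = -h  # retry from the other side
        else:
            raise FloatingPointError(
                f"residual non-finite when probing parameter {j}"
            )
    return J


def quadratic_model(r0: np.ndarray, J: np.ndarray) -> QuadraticModel:
    """Build Q0 = r0^T r0, G = 2 J^T r0, H = 2 J^T J."""
    r0 = np.asarray(r0, dtype=float)
    J = np.asarray(J, dtype=float)
    if J.shape[0] != r0.size:
        raise ValueError("J rows must match residual length")
    return QuadraticModel(float(r0 @ r0), 2.0 * J.T @ r0, 2.0 * J.T @ J)


def newton_step(qm: QuadraticModel, *, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Minimiser -H^{-1} G of the quadratic model.

    Near-singular Hessians are handled by flooring eigenvalues at
    ``eig_floor * lambda_max``; a zero Hessian gives a zero step.
    """
    lam, V = qm.eig()
    lmax = lam.max() if lam.size else 0.0
    if lmax <= 0.0:
        return np.zeros_like(qm.G)
    lam_r = np.maximum(lam, eig_floor * lmax)
    return -V @ ((V.T @ qm.G) / lam_r)


def curvilinear_trajectory(qm: QuadraticModel, a: float) -> np.ndarray:
    """Point L(a) = (exp(-H a) - I) H^{-1} G on the descent curve.

    Evaluated through the eigendecomposition H = V diag(lam) V^T as
    V diag(phi(lam)) V^T G with phi(lam) = (exp(-lam a) - 1)/lam and the
    limits phi(0) = -a and phi(lam, a=inf) = -1/lam.  a = 0 is the current
    point; a -> inf is the full Newton step.
    """
    if a < 0:
        raise ValueError("trajectory parameter a must be >= 0")
    lam, V = qm.eig()
    g = V.T @ qm.G
    if np.isinf(a):
        lmax = lam.max() if lam.size else 0.0
        lam_r = np.maximum(lam, _EIG_FLOOR * lmax) if lmax > 0 else np.ones_like(lam)
        phi = -1.0 / lam_r
    else:
        x = lam * a
        small = x < 1e-12
        with np.errstate(over="ignore"):
            phi = np.where(small, -a, np.expm1(-x) / np.where(small, 1.0, lam))
    return V @ (phi * g)


def _objective(fn, p) -> float:
    r = np.asarray(fn(p), dtype=float)
    if not np.all(np.isfinite(r)):
        return np.inf
    return float(r @ r)


def line_search(
    rf,
    p: np.ndarray,
    qm: QuadraticModel,
    *,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    n_grid: int = 20,
) -> tuple[np.ndarray, float]:
    """Minimise the true objective along the curvilinear path from p.

    The path parameter is sampled on a log grid spanning steepest-descent
    (a ~ 1/lambda_max) through Newton (a ~ 1/lambda_min) scales, plus the
    exact Newton endpoint; the best grid point is then refined by bracketed
    scalar minimisation in log(a).  Steps are projected onto the box
    bounds before evaluation.  Returns ``(dp, Q)`` and never a point worse
    than p itself.
    """
    fn = rf if callable(rf) else rf.fn
    p = np.asarray(p, dtype=float)
    lam, _ = qm.eig()
    lmax = lam.max() if lam.size else 0.0
    if lmax <= 0.0 or not np.any(qm.G):
        return np.zeros_like(p), qm.Q0

    def clipped(dp):
        pt = p + dp
        if lower is not None:
            pt = np.maximum(pt, lower)
        if upper is not None:
            pt = np.minimum(pt, upper)
        return pt - p

    def eval_at(a: float) -> tuple[np.ndarray, float]:
        dp = clipped(curvilinear_trajectory(qm, a))
        return dp, _objective(fn, p + dp)

    lmin_pos = lam[lam > _EIG_FLOOR * lmax].min() if np.any(lam > _EIG_FLOOR * lmax) else lmax
    a_lo, a_hi = 1e-3 / lmax, 1e3 / lmin_pos
    grid = np.geomspace(a_lo, a_hi, n_grid)

    best_a, best_dp, best_q = 0.0, np.zeros_like(p), qm.Q0
    evals = []
    for a in grid:
        dp, q = eval_at(a)
        evals.append(q)
        if q < best_q:
            best_a, best_dp, best_q = a, dp, q
    dp_newton = clipped(newton_step(qm))
    q_newton = _objective(fn, p + dp_newton)
    if q_newton < best_q:
        best_dp, best_q = dp_newton, q_newton
        best_a = np.inf

    if 0.0 < best_a < np.inf:
        i = int(np.argmin(evals))
        la, lb = np.log(grid[max(i - 1, 0)]), np.log(grid[min(i + 1, n_grid - 1)])
        if lb > la:
            res = minimize_scalar(
                lambda u: eval_at(float(np.exp(u)))[1],
                bounds=(la, lb),
                method="bounded",
                options={"maxiter": 12, "xatol": 1e-3},
            )
            dp, q = eval_at(float(np.exp(res.x)))
            if q < best_q:
                best_dp, best_q = dp, q
    if not np.isfinite(best_q):
        return np.zeros_like(p), qm.Q0
    return best_dp, best_q


@dataclass
class FitOptions:
    """Optimiser controls.

    ``tol`` is the relative objective decrease below which a run stops;
    ``restarts`` adds seeded random starts drawn uniformly within the
    bounds.  Iterative reweighting (weights ~ 1/(|r| + eps), refreshed
    every ``reweight_every`` accepted iterations) is available but off by
    default: it changes the objective being minimised.
    """

    tol: float = 1e-8
    max_iterations: int = 100
    restarts: int = 0
    seed: int | None = None
    jac_rel_step: float = 1e-4
    jac_abs_step: float = 1e-8
    n_grid: int = 20
    reweight_every: int | None = None
    reweight_eps: float = 1e-3
    verbose: bool = False
    callback: Callable[[int, np.ndarray, float], None] | None = None


def _run_single(fn, p0, lo, hi, opts: FitOptions) -> FitResult:
    p = np.clip(np.asarray(p0, dtype=float), lo, hi)
    w_irls = None
    def residual(x):
        r = np.asarray(fn(x), dtype=float)
        return r if w_irls is None else r * w_irls
    r0 = residual(p)
    Q = float(r0 @ r0)
    history = [Q]
    termination = "max_iterations"
    it = 0
    for it in range(1, opts.max_iterations + 1):
        J = jacobian(
            residual, p, r0=r0,
            rel_step=opts.jac_rel_step, abs_step=opts.jac_abs_step,
            lower=lo, upper=hi,
        )
        qm = quadratic_model(r0, J)
        dp, Qnew = line_search(residual, p, qm, lower=lo, upper=hi, n_grid=opts.n_grid)
        if Qnew >= Q:
            termination = "no_decrease"
            break
        rel = (Q - Qnew) / max(Q, np.finfo(float).tiny)
        if rel < opts.tol:
            termination = "tol"
            break
        p = p + dp
        Q = Qnew
        history.append(Q)
        if opts.callback is not None:
            opts.callback(it, p, Q)
        if opts.verbose:
            print(f"  iter {it:3d}  Q = {Q:.6g}")
        if opts.reweight_every and it % opts.reweight_every == 0:
            r_plain = np.asarray(fn(p), dtype=float)
            w = 1.0 / (np.abs(r_plain) + opts.reweight_eps)
            w_irls = w / w.mean()
        r0 = residual(p)
        Q = float(r0 @ r0)
    # final objective without IRLS weights, so runs are comparable
    Q_final = _objective(fn, p)
    return FitResult(p, Q_final, history, len(history) - 1, termination)


def optimise(
    rf: ResidualFunction,
    p0: np.ndarray,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit by repeated quadratic modelling and curvilinear line searches.

    Runs from ``p0`` and, if requested, from ``options.restarts`` extra
    seeded starts drawn uniformly within the box bounds; the best run
    wins.  The objective history within each run is non-increasing.
    """
    opts = options or FitOptions()
    p0 = np.asarray(p0, dtype=float)
    n = p0.size
    lo, hi = rf.bounds_for(n) if isinstance(rf, ResidualFunction) else (
        np.full(n, -np.inf), np.full(n, np.inf))
    scale = None
    if isinstance(rf, ResidualFunction) and rf.scale is not None:
        scale = np.asarray(rf.scale, dtype=float)
    if scale is None:
        scale = np.maximum(np.abs(p0), 1.0)
    fn_raw = rf.fn if isinstance(rf, ResidualFunction) else rf

    def fn_scaled(q):
        return fn_raw(q * scale)

    starts = [p0 / scale]
    if opts.restarts:
        rng = np.random.default_rng(opts.seed)
        flo = np.where(np.isfinite(lo), lo, -1e3)
        fhi = np.where(np.isfinite(hi), hi, 1e3)
        for _ in range(opts.restarts):
            starts.append(rng.uniform(flo, fhi) / scale)

    best: FitResult | None = None
    restart_objs: list[float] = []
    for k, q0 in enumerate(starts):
        res = _run_single(fn_scaled, q0, lo / scale, hi / scale, opts)
        restart_objs.append(res.objective)
        if best is None or res.objective < best.objective:
            res.restart_index = k
            best = res
    assert best is not None
    best.p = best.p * scale
    best.restart_objectives = restart_objs
    return best


def objective_surface(
    rf,
    p: np.ndarray,
    i: int,
    j: int,
    grid_i: np.ndarray,
    grid_j: np.ndarray,
) -> np.ndarray:
    """RMS objective over a 2-D parameter grid, all other parameters fixed.

    Entry [a, b] is sqrt(mean r^2) at p with p[i] = grid_i[a] and
    p[j] = grid_j[b].  Used to visualise the fitting landscape around an
    optimum.
    """
    fn = rf if callable(rf) else rf.fn
    p = np.asarray(p, dtype=float)
    n = p.size
    if not (0 <= i < n and 0 <= j < n) or i == j:
        raise ValueError("need two distinct valid parameter indices")
    out = np.empty((len(grid_i), len(grid_j)))
    for a, vi in enumerate(grid_i):
        for b, vj in enumerate(grid_j):
            pt = p.copy()
            pt[i] = vi
            pt[j] = vj
            r = np.asarray(fn(pt), dtype=float)
            out[a, b] = np.sqrt(np.mean(r**2)) if np.all(np.isfinite(r)) else np.inf
    return out
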