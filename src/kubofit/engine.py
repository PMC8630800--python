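"""Gauss-Newton least-squares engine.

Minimizes the weighted cost C(p) = r^T W r, r = D - M(p), by iterating
p <- p + dp with the Gauss-Newton step (2 J^T W J) dp = -grad(C)^T, a
backtracking Armijo line search, and box-bound projection.  Convergence
and stalling are judged by the scale invariant gradient norm (SIGN),

    SIGN_i = || grad(C)_i (.) sigma_p,i || / C_{i-1},

the norm of the elementwise product of the cost gradient with the
per-parameter standard errors, normalized by the previous iteration's
cost.  SIGN is invariant to rescaling the data and model by a common
factor, to rescaling the weights, and to the number of data points,
which makes a single stopping threshold (default 1e-9) portable across
problems.  Stalls -- step collapse with a clearly nonzero gradient, from
boundaries or from a nearly singular Gauss-Newton Hessian -- are
resolved by restarting from a random point inside the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import diagnostics

__all__ = [
    "StallSignal", "FitOptions", "FitState", "FitResult",
    "cost", "jacobian", "gradient", "gn_hessian", "solve_step",
    "armijo_backtrack", "apply_bounds", "sign_metric",
    "check_stop", "check_stall", "random_restart", "fit",
]


class StallSignal(Exception):
    """Raised when an iteration cannot make progress (nearly singular
    Gauss-Newton Hessian, failed line search, ...)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class FitOptions:
    """Engine configuration.

    ``bounds`` is an (N_p, 2) array of [lo, hi] per parameter; every
    parameter must be bounded for random restarts to be defined.
    ``ratio_floors`` lists (i, j, factor) triples enforcing
    p[i] > factor * p[j] (used for the physical bound
    T_hom^-1 > T_LT^-1 / 2).
    """

    bounds: np.ndarray = None
    fd_rel_step: float = 1e-4
    sign_stop: float = 1e-9
    stop_window: int = 3
    cost_slack: float = 0.10
    stall_window: int = 3
    stall_rel_dev: float = 0.01
    max_iters: int = 300
    max_restarts: int = 20
    rng_seed: int = 0
    armijo_c1: float = 1e-4
    armijo_shrink: float = 0.5
    armijo_max_backtracks: int = 25
    rcond_min: float = 1e-12
    sign_mode: str = "elementwise"
    ratio_floors: tuple = ()

    def validate(self, n_params: int) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (n_params, 2):
            raise ValueError(f"bounds must be ({n_params}, 2)")
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("each bound must satisfy lo < hi")
        for thr in (self.fd_rel_step, self.sign_stop, self.cost_slack,
                    self.stall_rel_dev):
            if not thr > 0:
                raise ValueError("all thresholds must be > 0")
        if self.stop_window < 1 or self.stall_window < 1:
            raise ValueError("windows must be >= 1")


@dataclass
class FitState:
    """Per-iteration history of a fit."""

    p: np.ndarray = None
    cost_trace: list = field(default_factory=list)
    sign_trace: list = field(default_factory=list)
    restart_log: list = field(default_factory=list)  # (iteration, reason)
    boundary_active: np.ndarray = None
    status: str = "running"
    n_model_evals: int = 0
    iters_since_restart: int = 0
    cost_floor: float = 0.0


@dataclass
class FitResult:
    """Converged (or best-effort) fit with uncertainty diagnostics."""

    p_hat: np.ndarray
    cost: float
    vcov: np.ndarray
    sigma: np.ndarray
    ci95: np.ndarray
    vif: np.ndarray
    state: FitState

    @property
    def status(self) -> str:
        return self.state.status


# ---------------------------------------------------------------------------
# elementary operations


def cost(residual: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Weighted sum of squares C = sum_i w_i r_i^2 (chi^2)."""
    r = np.asarray(residual, dtype=float).ravel()
    if weights is None:
        return float(r @ r)
    w = np.asarray(weights, dtype=float).ravel()
    if w.shape != r.shape:
        raise ValueError("residual and weights must have the same length")
    return float(r @ (w * r))


def jacobian(model: Callable[[np.ndarray], np.ndarray], p: np.ndarray,
             bounds: Optional[np.ndarray] = None, rel_step: float = 1e-4,
             counter: Optional[list] = None,
             ratio_floors: Sequence = ()) -> np.ndarray:
    """Central-difference Jacobian, column k = dM/dp_k.

    Uses exactly 2 * N_p model evaluations.  Steps are
    rel_step * max(|p_k|, scale_k) with scale_k the bounds width, and
    evaluation points are clipped inside the bounds and any ratio-floor
    constraints (the divided difference uses the actual point
    separation).
    """
    p = np.asarray(p, dtype=float)
    n_p = p.size
    cols = []
    for k in range(n_p):
        scale = 1.0
        lo, hi = -np.inf, np.inf
        if bounds is not None:
            lo, hi = bounds[k]
            if np.isfinite(lo) and np.isfinite(hi):
                scale = hi - lo
        # keep evaluation points feasible for p[i] > factor * p[j]
        for (i, j, factor) in ratio_floors:
            if k == i:
                lo = max(lo, factor * p[j] * (1.0 + 1e-9))
            elif k == j and factor > 0:
                hi = min(hi, p[i] / factor * (1.0 - 1e-9))
        h = rel_step * max(abs(p[k]), scale)
        hi_pt = min(p[k] + h, hi)
        lo_pt = max(p[k] - h, lo)
        if hi_pt == lo_pt:
            raise ValueError(f"degenerate finite-difference step for "
                             f"parameter {k}")
        p_hi = p.copy(); p_hi[k] = hi_pt
        p_lo = p.copy(); p_lo[k] = lo_pt
        m_hi = np.asarray(model(p_hi), dtype=float).ravel()
        m_lo = np.asarray(model(p_lo), dtype=float).ravel()
        if counter is not None:
            counter.append(2)
        col = (m_hi - m_lo) / (hi_pt - lo_pt)
        if not np.all(np.isfinite(col)):
            raise FloatingPointError(
                f"non-finite model output while differentiating parameter {k}")
        cols.append(col)
    return np.column_stack(cols)


def gradient(residual: np.ndarray, weights: Optional[np.ndarray],
             J: np.ndarray) -> np.ndarray:
    """Cost gradient (row vector): grad C = -2 r^T W J for r = D - M."""
    r = np.asarray(residual, dtype=float).ravel()
    if J.shape[0] != r.size:
        raise ValueError("residual/Jacobian shape mismatch")
    wr = r if weights is None else np.asarray(weights).ravel() * r
    return -2.0 * (wr @ J)


def gn_hessian(J: np.ndarray, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Gauss-Newton Hessian approximation 2 J^T W J (symmetric PSD; the
    residual-weighted model Hessian is dropped)."""
    if weights is None:
        H = J.T @ J
    else:
        H = J.T @ (np.asarray(weights).ravel()[:, None] * J)
    return 2.0 * H


def solve_step(hessian: np.ndarray, grad: np.ndarray,
               rcond_min: float = 1e-12) -> np.ndarray:
    """Solve (grad grad C) dp = -grad C^T.  A reciprocal condition
    estimate below ``rcond_min`` raises :class:`StallSignal` instead of
    returning an unreliable step."""
    H = np.asarray(hessian, dtype=float)
    g = np.asarray(grad, dtype=float).ravel()
    try:
        eig = np.linalg.eigvalsh(H)
    except np.linalg.LinAlgError:
        raise StallSignal("singular_hessian")
    emax = float(eig[-1])
    if emax <= 0 or not np.isfinite(emax):
        raise StallSignal("singular_hessian")
    if eig[0] <= 0 or eig[0] / emax < rcond_min:
        raise StallSignal("singular_hessian")
    return np.linalg.solve(H, -g)


def armijo_backtrack(p: np.ndarray, dp: np.ndarray,
                     cost_fn: Callable[[np.ndarray], float],
                     grad: np.ndarray, options: FitOptions,
                     cost_p: Optional[float] = None):
    """Backtracking line search subject to the Armijo condition
    C(p + s dp) <= C(p) + c1 s grad.dp.  Returns (s, p_new, cost_new).
    Raises :class:`StallSignal` on an ascent direction or when no
    acceptable step fraction is found."""
    dp = np.asarray(dp, dtype=float)
    if not np.all(np.isfinite(dp)):
        raise StallSignal("line_search")
    slope = float(np.asarray(grad).ravel() @ dp)
    if slope >= 0:
        raise StallSignal("line_search")
    c0 = cost_fn(p) if cost_p is None else cost_p
    s = 1.0
    for _ in range(options.armijo_max_backtracks + 1):
        cand = p + s * dp
        c_new = cost_fn(cand)
        if c_new <= c0 + options.armijo_c1 * s * slope:
            return s, cand, c_new
        s *= options.armijo_shrink
    raise StallSignal("line_search")


def apply_bounds(p: np.ndarray, dp: np.ndarray, bounds: np.ndarray,
                 ratio_floors: Sequence = ()):
    """Project p + dp onto the box [lo, hi] (clamping, not reflection)
    and onto any ratio-floor constraints p[i] > factor * p[j].  Returns
    (corrected dp, boundary_active mask)."""
    p = np.asarray(p, dtype=float)
    target = p + np.asarray(dp, dtype=float)
    b = np.asarray(bounds, dtype=float)
    clipped = np.clip(target, b[:, 0], b[:, 1])
    for (i, j, factor) in ratio_floors:
        floor = factor * clipped[j]
        if clipped[i] <= floor:
            clipped[i] = min(floor * (1.0 + 1e-9) + 1e-300, b[i, 1])
    active = clipped != target
    return clipped - p, active


def sign_metric(grad: np.ndarray, sigma_p: np.ndarray, cost_prev: float,
                mode: str = "elementwise") -> float:
    """Scale invariant gradient norm.

    ``elementwise`` (default): || grad (.) sigma_p ||_2 / C_prev.
    ``dot``: | grad . sigma_p | / C_prev (the scalar-product reading,
    exposed for comparison; it can cancel between parameters).
    """
    if cost_prev == 0.0:
        return 0.0
    if cost_prev < 0:
        raise ValueError("cost_prev must be >= 0")
    g = np.asarray(grad, dtype=float).ravel()
    s = np.asarray(sigma_p, dtype=float).ravel()
    if mode == "elementwise":
        return float(np.linalg.norm(g * s) / cost_prev)
    if mode == "dot":
        return float(abs(g @ s) / cost_prev)
    raise ValueError(f"unknown SIGN mode {mode!r}")


def check_stop(state: FitState, options: FitOptions) -> bool:
    """True iff the last ``stop_window`` iterations since the last
    restart all have SIGN < sign_stop and cost within ``cost_slack`` of
    the best cost ever encountered."""
    w = options.stop_window
    if state.iters_since_restart < w:
        return False
    signs = state.sign_trace[-w:]
    costs = state.cost_trace[-w:]
    best = min(state.cost_trace)
    # costs at the floating-point floor count as equal to the best
    ceiling = max((1.0 + options.cost_slack) * best, state.cost_floor)
    return (all(s < options.sign_stop for s in signs)
            and all(c <= ceiling for c in costs))


def check_stall(state: FitState, options: FitOptions) -> bool:
    """True iff SIGN and cost are both flat (relative spread below
    ``stall_rel_dev``) over the stall window while the stop test fails."""
    w = options.stall_window
    if state.iters_since_restart < w:
        return False
    if check_stop(state, options):
        return False

    def flat(trace):
        seg = np.asarray(trace[-w:], dtype=float)
        mid = np.mean(np.abs(seg))
        if mid == 0:
            return True
        return (seg.max() - seg.min()) / mid < options.stall_rel_dev

    return flat(state.sign_trace) and flat(state.cost_trace)


def random_restart(bounds: np.ndarray, rng: np.random.Generator,
                   ratio_floors: Sequence = ()) -> np.ndarray:
    """Uniform random point within the (finite) bounds."""
    b = np.asarray(bounds, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("random restarts require finite bounds on every "
                         "parameter")
    p = rng.uniform(b[:, 0], b[:, 1])
    dp, _ = apply_bounds(p, np.zeros_like(p), b, ratio_floors)
    return p + dp


# ---------------------------------------------------------------------------
# the full loop


def fit(model: Callable[[np.ndarray], np.ndarray], data: np.ndarray,
        weights: Optional[np.ndarray], p0: np.ndarray,
        options: FitOptions) -> FitResult:
    """Run the full Gauss-Newton/SIGN loop until convergence or budget
    exhaustion.  Returns the best-ever parameters with covariance, 95%
    confidence half-widths and VIFs evaluated there.  Budget exhaustion
    is reported through ``result.status`` (never an exception)."""
    data = np.asarray(data, dtype=float).ravel()
    p = np.asarray(p0, dtype=float).copy()
    n_p = p.size
    options.validate(n_p)
    bounds = np.asarray(options.bounds, dtype=float)
    rng = np.random.default_rng(options.rng_seed)

    state = FitState(boundary_active=np.zeros(n_p, dtype=bool))
    evals = []

    def eval_model(q):
        state.n_model_evals += 1
        return np.asarray(model(q), dtype=float).ravel()

    def cost_at(q):
        return cost(data - eval_model(q), weights)

    # a cost at the roundoff floor of the data norm is a zero residual in
    # floating point: SIGN short-circuits to 0 (converged) there
    c_floor = (4.0 * np.finfo(float).eps) ** 2 * cost(data, weights)
    state.cost_floor = c_floor

    # start inside the box
    dp0, _ = apply_bounds(p, np.zeros(n_p), bounds, options.ratio_floors)
    p = p + dp0
    c = cost_at(p)
    prev_cost = c
    best_cost, best_p = c, p.copy()
    n_d = data.size
    n_restarts = 0

    def do_restart(iteration, reason):
        nonlocal p, c, prev_cost, n_restarts
        p = random_restart(bounds, rng, options.ratio_floors)
        c = cost_at(p)
        prev_cost = c
        state.restart_log.append((iteration, reason))
        state.iters_since_restart = 0
        n_restarts += 1

    for it in range(options.max_iters):
        r = data - eval_model(p)
        c = cost(r, weights)
        stall_reason = None
        try:
            J = jacobian(model, p, bounds, options.fd_rel_step,
                         counter=evals, ratio_floors=options.ratio_floors)
            state.n_model_evals += 2 * n_p
            grad = gradient(r, weights, J)
            H = gn_hessian(J, weights)
            try:
                rep = diagnostics.covariance(J, weights, c, n_d, n_p)
                sigma_p = rep.sigma
            except diagnostics.SingularCovarianceError:
                raise StallSignal("singular_hessian")
            sg = (0.0 if prev_cost <= c_floor
                  else sign_metric(grad, sigma_p, prev_cost,
                                   options.sign_mode))
        except (StallSignal, FloatingPointError) as err:
            reason = err.reason if isinstance(err, StallSignal) else "nonfinite"
            state.cost_trace.append(c)
            state.sign_trace.append(np.inf)
            if c < best_cost:
                best_cost, best_p = c, p.copy()
            if n_restarts >= options.max_restarts:
                state.status = "budget_exhausted"
                break
            do_restart(it, reason)
            continue

        state.cost_trace.append(c)
        state.sign_trace.append(sg)
        state.iters_since_restart += 1
        if c < best_cost:
            best_cost, best_p = c, p.copy()

        if check_stop(state, options):
            state.status = "converged"
            break

        if check_stall(state, options):
            if n_restarts >= options.max_restarts:
                state.status = "budget_exhausted"
                break
            do_restart(it, "stall")
            continue

        if sg < options.sign_stop:
            # below the stopping threshold the step is numerically
            # meaningless (zero gradient at roundoff); hold position and
            # let the stop/stall windows resolve
            prev_cost = c
            continue

        prev_cost = c
        try:
            dp = solve_step(H, grad, options.rcond_min)
            # project the target onto the feasible region first; the box
            # and the ratio-floor half-spaces are convex, so every
            # backtracked fraction of the corrected step stays feasible
            dp_corr, active = apply_bounds(p, dp, bounds,
                                           options.ratio_floors)
            state.boundary_active |= active
            s, cand, c_new = armijo_backtrack(
                p, dp_corr, cost_at, grad, options, cost_p=c)
            p = cand
        except StallSignal as err:
            if n_restarts >= options.max_restarts:
                state.status = "budget_exhausted"
                break
            do_restart(it, err.reason)
            continue
    else:
        state.status = "budget_exhausted"

    state.p = best_p
    # final diagnostics at the returned optimum
    J = jacobian(model, best_p, bounds, options.fd_rel_step,
                 ratio_floors=options.ratio_floors)
    state.n_model_evals += 2 * n_p
    r = data - eval_model(best_p)
    c_hat = cost(r, weights)
    try:
        rep = diagnostics.covariance(J, weights, c_hat, n_d, n_p)
        vcov, sigma = rep.vcov, rep.sigma
    except diagnostics.SingularCovarianceError:
        vcov = np.full((n_p, n_p), np.nan)
        sigma = np.full(n_p, np.nan)
    ci95 = diagnostics.confidence_intervals_from_sigma(sigma, 0.95)
    try:
        vif = diagnostics.vif(J, weights).vif
    except Exception:
        vif = np.full(n_p, np.nan)
    return FitResult(p_hat=best_p, cost=c_hat, vcov=vcov, sigma=sigma,
                     ci95=ci95, vif=vif, state=state)
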