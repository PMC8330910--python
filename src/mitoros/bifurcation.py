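"""Steady-state relaxation, parameter sweeps and hysteresis detection.

The continuation strategy is relaxation-based, mirroring how the two
branches of the respiratory chain are traced in practice: for each value
of the swept parameter an initial-value problem is integrated to a
steady state, and the result seeds the next grid point.  A discontinuous
jump of an observable (by default the ubiquinol fraction of the quinone
pool) between adjacent grid points marks the bifurcation; sweeping back
over the same grid without a reverse jump demonstrates hysteresis.
Unstable steady states are not located.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SteadyResult",
    "BranchPoint",
    "Branch",
    "FunctionModel",
    "relax_to_steady",
    "sweep_parameter",
    "accumulate_ros",
    "protocol_sequence",
]


class FunctionModel:
    """Adapter turning ``f(x, p)`` into the model protocol used here.

    Useful for toy systems (``dx/dt = x - x**3 + p`` and friends) in
    tests and examples.
    """

    def __init__(self, f: Callable, n: int = 1, p: float = 0.0,
                 observe: Callable | None = None):
        self.f = f
        self.n = n
        self.p = p
        self._observe = observe

    def rhs(self, t, x):
        return np.atleast_1d(self.f(x, self.p))

    def residual_scale(self, x):
        return np.maximum(np.abs(x), 1.0)

    def steady_mask(self):
        return np.ones(self.n, dtype=bool)

    def observables(self, x):
        if self._observe is None:
            return {f"x{i}": float(v) for i, v in enumerate(np.atleast_1d(x))}
        return self._observe(x)


@dataclass
class SteadyResult:
    x: np.ndarray
    converged: bool
    residual: float
    t_used: float


def _residual(model, x: np.ndarray) -> float:
    dx = np.abs(model.rhs(0.0, x))
    scale = model.residual_scale(x) if hasattr(model, "residual_scale") \
        else np.maximum(np.abs(x), 1.0)
    mask = model.steady_mask() if hasattr(model, "steady_mask") \
        else np.ones_like(dx, dtype=bool)
    return float(np.max(dx[mask] / scale[mask])) if mask.any() else 0.0


def relax_to_steady(model, x0: np.ndarray, *, tol: float = 1e-6,
                    t_cap: float = 1e4, first_chunk: float = 10.0,
                    rtol: float = 1e-8, atol: float = 1e-10) -> SteadyResult:
    """Integrate until the scaled residual ||dx/dt||_inf drops below tol.

    The system is integrated in growing time chunks with a stiff (BDF)
    solver; integration stops as soon as the per-variable scaled residual
    is below ``tol`` (so a state that is already steady is returned after
    a single check).  If the simulated-time cap is reached without
    convergence the result is flagged, never silently accepted.
    """
    x = np.asarray(x0, dtype=float).copy()
    res = _residual(model, x)
    if res < tol:
        return SteadyResult(x, True, res, 0.0)
    jac = model.jacobian if hasattr(model, "jacobian") else None
    sparsity = (model.jac_sparsity()
                if jac is None and hasattr(model, "jac_sparsity") else None)

    if hasattr(model, "steady_function"):
        return _relax_newton(model, x, tol, t_cap, first_chunk, rtol, atol, jac)

    def steady_event(t, y):
        return _residual(model, y) - tol

    steady_event.terminal = True
    sol = solve_ivp(model.rhs, (0.0, t_cap), x, method="BDF",
                    rtol=rtol, atol=atol, jac=jac, jac_sparsity=sparsity,
                    events=steady_event, first_step=min(first_chunk, t_cap) / 10)
    x = sol.y[:, -1]
    res = _residual(model, x)
    if not sol.success:
        return SteadyResult(x, False, res, float(sol.t[-1]))
    converged = res < tol or sol.status == 1  # 1: steady event fired
    return SteadyResult(x, converged, res, float(sol.t[-1]))


def _newton_polish(model, func, jac, x0, tol, maxit: int = 40):
    """Damped Newton descent on the scaled steady residual.

    Returns the best iterate reached (which may not meet ``tol``); the
    caller decides whether to accept it outright or to keep integrating
    from it.  Returns None if no progress at all could be made.
    """
    x = x0.copy()
    best = None
    for _ in range(maxit):
        f = func(x)
        J = jac(x)
        r = np.abs(J).max(axis=1)
        r[r == 0.0] = 1.0
        try:
            dx = np.linalg.solve(J / r[:, None], f / r)
        except np.linalg.LinAlgError:
            break
        res0 = _residual(model, x)
        lam = 1.0
        while lam > 1e-8:
            xn = x - lam * dx
            if _residual(model, xn) < res0 * (1.0 - 0.1 * lam) + 1e-16:
                break
            lam *= 0.5
        else:
            break  # no descent: fall through to the LM finisher
        x = xn
        best = x
        if _residual(model, x) < tol:
            return x
    # damped Newton stalled above tolerance: finish with a
    # Levenberg-Marquardt solve (robust to the near-singular directions
    # created by very slow modes)
    from scipy.optimize import root

    start = best if best is not None else x0
    if _residual(model, start) > 1e-4:
        return best  # too far out for the LM finisher to be worthwhile
    sol = root(func, start, jac=jac, method="lm",
               options={"xtol": 1e-14, "ftol": 1e-14, "maxiter": 300})
    if sol.success and _residual(model, sol.x) < _residual(model, start):
        return sol.x
    return best


def _relax_newton(model, x, tol, t_cap, first_chunk, rtol, atol, jac,
                  accept_dist: float = 0.2):
    """Pseudo-transient continuation: short stiff integrations damp the
    fast modes, then a damped-Newton solve of the conservation-constrained
    algebraic system lands exactly on the steady state.  A Newton result
    is only accepted if it is physical (non-negative amounts) and close
    to the current trajectory point, so the polish cannot hop to the
    other branch of a bistable system."""
    def same_branch(xa, xb) -> bool:
        # branch identity in the respiratory-chain models is carried by
        # the ubiquinol fraction; fall back to a scaled state distance
        if hasattr(model, "observables"):
            obs_a, obs_b = model.observables(xa), model.observables(xb)
            if "qh2_fraction" in obs_a:
                return abs(obs_a["qh2_fraction"]
                           - obs_b["qh2_fraction"]) < accept_dist
        scale = np.maximum(np.abs(xa), 0.1)
        return float(np.max(np.abs(xb - xa) / scale)) < accept_dist

    res = _residual(model, x)
    t_used, chunk = 0.0, first_chunk
    while True:
        if res < 1e-2:  # polish only once the fast modes have decayed
            xs = _newton_polish(model, model.steady_function(x),
                                model.steady_jacobian(x), x, tol)
            if xs is not None:
                body = xs[: len(xs) - (1 if model.psi_dynamic else 0)]
                res_s = _residual(model, xs)
                if body.min() > -1e-9 and same_branch(x, xs) and res_s < res:
                    # accept Newton progress; fully converged or a better
                    # starting point for the next integration stretch
                    x = np.where(np.abs(xs) < 1e-15, 0.0, xs)
                    res = _residual(model, x)
            if res < tol:
                return SteadyResult(x, True, res, t_used)
        if t_used >= t_cap:
            return SteadyResult(x, res < tol, res, t_used)
        chunk = min(chunk, t_cap - t_used)
        ivp = solve_ivp(model.rhs, (0.0, chunk), x, method="BDF",
                        rtol=rtol, atol=atol, jac=jac)
        if not ivp.success:
            return SteadyResult(x, False, res, t_used)
        x = ivp.y[:, -1]
        t_used += chunk
        res = _residual(model, x)
        chunk *= 30.0


@dataclass
class BranchPoint:
    """One steady state along a swept parameter."""

    parameter: float
    x: np.ndarray
    observables: dict[str, float]
    branch_label: str = "active"


@dataclass
class Branch:
    """Ordered steady states plus the detected jump location, if any."""

    points: list[BranchPoint] = field(default_factory=list)
    direction: str = "up"
    jump_parameter: float | None = None
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"parameter": p.parameter, "branch_label": p.branch_label}
            row.update(p.observables)
            rows.append(row)
        return pd.DataFrame(rows)

    def observable(self, key: str) -> np.ndarray:
        return np.array([p.observables[key] for p in self.points])

    @property
    def parameters(self) -> np.ndarray:
        return np.array([p.parameter for p in self.points])


def sweep_parameter(model, grid: Sequence[float], x_init: np.ndarray,
                    set_param: Callable, *, jump_key: str = "qh2_fraction",
                    jump_threshold: float = 0.25, start_label: str = "active",
                    tol: float = 1e-6, t_cap: float = 1e4) -> Branch:
    """Chain steady states over a monotone parameter grid.

    ``set_param(model, x, p)`` installs parameter value ``p`` (a clamped
    pool level, a rate constant, ...) before each relaxation; each
    converged state seeds the next grid point.  A change of the
    ``jump_key`` observable exceeding ``jump_threshold`` between adjacent
    points is recorded as a branch jump at the midpoint parameter.
    Non-convergence aborts the sweep, returning the partial branch with
    ``converged=False``.
    """
    grid = np.asarray(list(grid), dtype=float)
    d = np.diff(grid)
    if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("parameter grid must be strictly monotone")
    direction = "down" if (grid.size > 1 and d[0] < 0) else "up"
    branch = Branch(direction=direction)
    x = np.asarray(x_init, dtype=float).copy()
    for p in grid:
        set_param(model, x, float(p))
        res = relax_to_steady(model, x, tol=tol, t_cap=t_cap)
        if not res.converged:
            branch.converged = False
            return branch
        x = res.x
        branch.points.append(
            BranchPoint(float(p), x.copy(), model.observables(x), start_label))
    obs = branch.observable(jump_key)
    jumps = np.nonzero(np.abs(np.diff(obs)) > jump_threshold)[0]
    if jumps.size:
        j = int(jumps[0])
        branch.jump_parameter = 0.5 * (grid[j] + grid[j + 1])
        flip = {"active": "inactive", "inactive": "active"}[start_label]
        for point in branch.points[j + 1:]:
            point.branch_label = flip
    return branch


def accumulate_ros(trajectory: pd.DataFrame, window_s: float = 60.0,
                   complex_amounts: Mapping[str, float] | None = None,
                   rate_columns: Mapping[str, str] | None = None
                   ) -> dict[str, float]:
    """Time-integral of ROS rates over a window, per complex amount.

    ``trajectory`` must contain a ``time`` column and per-site rate
    columns (default ``ros_rate_cii``/``ros_rate_ciii``); integration is
    trapezoidal from the first time point over ``window_s`` seconds, and
    each integral is divided by the corresponding complex amount.
    """
    cols = dict(rate_columns
                or {"cii": "ros_rate_cii", "ciii": "ros_rate_ciii"})
    amounts = dict(complex_amounts or {k: 1.0 for k in cols})
    t = np.asarray(trajectory["time"], dtype=float)
    t_end = t[0] + window_s
    if t_end > t[-1] + 1e-12:
        raise ValueError("window extends beyond the trajectory")
    out = {}
    for key, col in cols.items():
        y = np.asarray(trajectory[col], dtype=float)
        inside = t <= t_end
        tt, yy = t[inside], y[inside]
        if tt[-1] < t_end:  # interpolate the window endpoint
            y_end = np.interp(t_end, t, y)
            tt = np.append(tt, t_end)
            yy = np.append(yy, y_end)
        out[key] = float(np.trapezoid(yy, tt)) / amounts[key]
    return out


def protocol_sequence(model, x0: np.ndarray,
                      events: Sequence[tuple[float, str, float]],
                      t_end: float, *, dt_report: float = 1.0,
                      rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """Timed additions of glutamate / antimycin / myxothiazol.

    ``events`` are ``(time, agent, value)`` tuples; for ``"glutamate"``
    the value is the buffered external concentration installed at that
    time, for inhibitors it is the remaining-activity fraction (0 =
    complete block).  Integration proceeds piecewise between events; the
    returned frame carries the model observables (ROS rates of both
    complexes among them) on a uniform reporting grid.
    """
    from .rates import apply_inhibitor

    events = sorted(events, key=lambda e: e[0])
    seen: dict[tuple[float, str], float] = {}
    for t, agent, value in events:
        if agent not in ("glutamate", "antimycin", "myxothiazol"):
            raise ValueError(f"unknown protocol agent {agent!r}")
        key = (t, agent)
        if key in seen and seen[key] != value:
            raise ValueError(f"contradictory events for {agent!r} at t={t}")
        seen[key] = value

    work = model.copy()
    x = np.asarray(x0, dtype=float).copy()
    times = [t for t, _, _ in events] + [t_end]
    frames = []
    t_prev = 0.0
    idx = 0
    jac = work.jacobian if hasattr(work, "jacobian") else None
    for t_next in times:
        if t_next > t_prev:
            t_eval = np.arange(t_prev, t_next + dt_report / 2, dt_report)
            sol = solve_ivp(work.rhs, (t_prev, t_next), x, method="BDF",
                            t_eval=t_eval, rtol=rtol, atol=atol, jac=jac)
            if not sol.success:  # pragma: no cover
                raise RuntimeError(f"integration failed: {sol.message}")
            obs = [work.observables(sol.y[:, j]) for j in range(sol.y.shape[1])]
            frame = pd.DataFrame(obs)
            frame.insert(0, "time", sol.t)
            frames.append(frame)
            x = sol.y[:, -1].copy()
            t_prev = t_next
        if idx < len(events) and events[idx][0] <= t_next:
            while idx < len(events) and events[idx][0] <= t_next:
                _, agent, value = events[idx]
                if agent == "glutamate":
                    work.clamped["glu_ext"] = value
                    work.set_pool(x, "glu_ext", value)
                else:
                    work.rates = apply_inhibitor(work.rates, agent, value)
                idx += 1
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(subset="time", keep="last").reset_index(drop=True)
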