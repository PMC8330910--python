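"""Relaxation continuation on toy systems with analytic answers."""

import numpy as np
import pandas as pd
import pytest

from mitoros.bifurcation import (
    FunctionModel,
    accumulate_ros,
    relax_to_steady,
    sweep_parameter,
)


def test_linear_toy_relaxes_to_fixed_point():
    m = FunctionModel(lambda x, p: -x + 1.0)
    res = relax_to_steady(m, np.array([0.0]))
    assert res.converged
    assert res.x[0] == pytest.approx(1.0, abs=2e-6)


def test_relax_is_idempotent_from_a_steady_state():
    m = FunctionModel(lambda x, p: -x + 1.0)
    res = relax_to_steady(m, np.array([1.0]))
    assert res.converged and res.t_used == 0.0
    assert res.x[0] == 1.0


def test_bistable_toy_converges_to_basin_root():
    """dx/dt = x - x^3 + p from the positive basin lands on the positive
    root of the cubic, cross-checked with a polynomial root oracle."""
    p = 0.2
    m = FunctionModel(lambda x, pp: x - x ** 3 + pp, p=p)
    res = relax_to_steady(m, np.array([0.8]))
    roots = np.roots([-1.0, 0.0, 1.0, p])
    pos = max(r.real for r in roots if abs(r.imag) < 1e-12)
    assert res.x[0] == pytest.approx(pos, abs=1e-6)


def test_cubic_fold_detected_within_one_grid_step():
    """Up-sweep of dx/dt = x - x^3 + p jumps at the fold p = 2/(3*sqrt(3))."""
    m = FunctionModel(lambda x, p: x - x ** 3 + p,
                      observe=lambda x: {"qh2_fraction": float(x[0])})
    grid = np.linspace(-0.6, 0.6, 61)
    branch = sweep_parameter(m, grid, np.array([-1.0]),
                             lambda mm, x, p: setattr(mm, "p", p),
                             jump_threshold=0.5)
    fold = 2.0 / (3.0 * np.sqrt(3.0))
    step = grid[1] - grid[0]
    assert branch.jump_parameter is not None
    assert abs(branch.jump_parameter - fold) <= step
    labels = [pt.branch_label for pt in branch.points]
    assert "active" in labels and "inactive" in labels


def test_sweep_requires_monotone_grid():
    m = FunctionModel(lambda x, p: -x)
    with pytest.raises(ValueError, match="monotone"):
        sweep_parameter(m, [0.0, 1.0, 0.5], np.array([0.0]),
                        lambda mm, x, p: None)


# --------------------------------------------------------------------------
# accumulated ROS
# --------------------------------------------------------------------------

def _traj(t, cii, ciii):
    return pd.DataFrame({"time": t, "ros_rate_cii": cii,
                         "ros_rate_ciii": ciii})


def test_accumulate_ros_zero_and_rectangle():
    t = np.linspace(0.0, 100.0, 101)
    zero = accumulate_ros(_traj(t, 0.0 * t, 0.0 * t), 60.0)
    assert zero == {"cii": 0.0, "ciii": 0.0}
    const = accumulate_ros(_traj(t, np.full_like(t, 2e-6),
                                 np.full_like(t, 1e-6)),
                           60.0, {"cii": 0.25, "ciii": 0.5})
    assert const["cii"] == pytest.approx(60.0 * 2e-6 / 0.25, rel=1e-12)
    assert const["ciii"] == pytest.approx(60.0 * 1e-6 / 0.5, rel=1e-12)


def test_accumulate_ros_piecewise_linear_matches_quadrature_oracle():
    from scipy.integrate import quad

    knots_t = np.array([0.0, 13.0, 27.0, 45.0, 80.0])
    knots_v = np.array([0.0, 3e-6, 1e-6, 5e-6, 2e-6])
    rate = lambda tt: np.interp(tt, knots_t, knots_v)
    t = np.unique(np.concatenate([np.linspace(0, 80, 161), knots_t]))
    acc = accumulate_ros(_traj(t, rate(t), rate(t)), 60.0,
                         {"cii": 1.0, "ciii": 1.0})
    oracle, _ = quad(rate, 0.0, 60.0, points=list(knots_t), limit=200)
    assert acc["cii"] == pytest.approx(oracle, rel=1e-6)


def test_accumulate_ros_window_beyond_trajectory_errors():
    t = np.linspace(0.0, 30.0, 31)
    with pytest.raises(ValueError, match="window"):
        accumulate_ros(_traj(t, t, t), 60.0)


# --------------------------------------------------------------------------
# protocol validation
# --------------------------------------------------------------------------

def test_protocol_rejects_unknown_agents_and_contradictions():
    from mitoros.bifurcation import protocol_sequence
    from mitoros.mito import build_isolated_mito_model, default_mito_initial

    m = build_isolated_mito_model()
    x0 = default_mito_initial(m)
    with pytest.raises(ValueError, match="unknown protocol agent"):
        protocol_sequence(m, x0, [(1.0, "rotenone", 0.0)], 2.0)
    with pytest.raises(ValueError, match="contradictory"):
        protocol_sequence(m, x0, [(1.0, "glutamate", 0.05),
                                  (1.0, "glutamate", 0.1)], 2.0)
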