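"""Finite-volume transport operator: exactness, conservation, convergence."""

import numpy as np
import pytest

from conftest import make_empty_phantom
from mitoros.h2o2 import (
    FieldState,
    PdeParams,
    assemble_operator,
    axis_profile,
    solve_transient,
    steady_state,
)

TINY_J = 1e-300  # effectively zero production (params require positive)


def test_constant_field_is_exact_steady_solution():
    """With no production and every boundary at c0, the uniform field has
    exactly zero residual (discrete conservation of the full operator)."""
    ph = make_empty_phantom((4.0, 4.0, 4.0), 0.5)
    op = assemble_operator(ph, PdeParams(j_normal_um_min=TINY_J,
                                         j_high_um_min=TINY_J))
    c = np.full(ph.shape, 5.0)
    assert np.abs(op.rhs(c)).max() < 1e-12


def test_interior_diffusion_rows_sum_to_zero():
    ph = make_empty_phantom((4.0, 4.0, 4.0), 0.5)
    op = assemble_operator(ph, PdeParams(u_isf_m_s=1e-300,
                                         j_normal_um_min=TINY_J,
                                         j_high_um_min=TINY_J))
    row_sums = np.asarray(op.A.sum(axis=1)).ravel().reshape(ph.shape)
    interior = row_sums[1:-1, 1:-1, 1:-1]
    assert np.abs(interior).max() < 1e-9


def test_1d_slab_steady_matches_analytic_line():
    """Dirichlet 5 and 10 nM across y, no flow, no production: the steady
    profile is linear to solver precision."""
    ph = make_empty_phantom((1.0, 10.0, 1.0), 0.25)
    op = assemble_operator(
        ph, PdeParams(u_isf_m_s=1e-300, j_normal_um_min=TINY_J,
                      j_high_um_min=TINY_J),
        lateral_bcs={"y0": 5.0, "y1": 10.0, "z0": None, "z1": None})
    c = op.steady(rtol=1e-14)
    ys = ph.voxel_centers()[1]
    L = 10.0
    analytic = 5.0 + (10.0 - 5.0) * (ys - ys[0] + 0.125) / L
    profile = c[c.shape[0] // 2, :, c.shape[2] // 2]
    err = np.abs(profile - analytic) / 10.0
    assert err.max() < 1e-10


def test_slab_with_source_converges_on_refinement():
    """Uniform production between two Dirichlet walls: the steady solution
    approaches the analytic parabola at first order or better in h."""
    errs = []
    for h in (0.5, 0.25):
        ph = make_empty_phantom((1.0, 10.0, 1.0), h)
        ph.labels[:] = 1  # uniform production everywhere
        params = PdeParams(u_isf_m_s=1e-300, j_normal_um_min=6.0,
                           j_high_um_min=6.0)
        op = assemble_operator(ph, params,
                               lateral_bcs={"y0": 5.0, "y1": 5.0,
                                            "z0": None, "z1": None})
        c = op.steady(rtol=1e-14)
        ys = ph.voxel_centers()[1]
        J, D, L = params.j_normal_nM_s, params.d_um2_s, 10.0
        y = ys - ys[0] + h / 2.0
        analytic = 5.0 + J / (2.0 * D) * y * (L - y)
        errs.append(np.abs(c[0, :, 0] - analytic).max())
    assert errs[1] < errs[0] / 1.9


def test_mass_balance_closes_each_step(coarse_phantom):
    op = assemble_operator(coarse_phantom)
    c = coarse_phantom.initial_concentration()
    for dt in (1e-3, 5e-3):
        c1 = op.step(c, dt)
        assert op.mass_balance_residual(c, c1, dt) < 1e-8
        c = c1


def test_positivity_preserved(coarse_phantom):
    op = assemble_operator(coarse_phantom)
    c = coarse_phantom.initial_concentration()
    for _ in range(10):
        c = op.step(c, 5e-3)
        assert c.min() > -1e-9


def test_steady_equals_long_time_transient(coarse_phantom):
    op = assemble_operator(coarse_phantom)
    ss = steady_state(op)
    init = FieldState(coarse_phantom.initial_concentration(), 0.0)
    fields, _ = solve_transient(op, init, [2.0], dt_max=2e-2)
    diff = np.abs(fields[-1].concentration - ss.concentration)
    assert diff.max() < 1e-3


def test_axis_profile_exact_on_constant_and_linear_fields(phantom0):
    const = FieldState(np.full(phantom0.shape, 7.5), 0.0)
    xs, prof = axis_profile(const, phantom0)
    np.testing.assert_allclose(prof, 7.5, rtol=1e-12)
    xv = phantom0.voxel_centers()[0]
    linear = FieldState(np.broadcast_to(
        2.0 + 0.3 * xv[:, None, None],
        phantom0.shape).copy(), 0.0)
    xs, prof = axis_profile(linear, phantom0)
    np.testing.assert_allclose(prof, 2.0 + 0.3 * xs, rtol=1e-12)


def test_field_state_rejects_non_finite_values():
    with pytest.raises(ValueError):
        FieldState(np.array([[[np.nan]]]), 0.0)


def test_params_validated_and_units_converted():
    p = PdeParams()
    assert p.d_um2_s == pytest.approx(1830.0)
    assert p.u_um_s == pytest.approx(0.5)
    assert p.j_normal_nM_s == pytest.approx(5.05 * 1000.0 / 60.0)
    with pytest.raises(ValueError):
        PdeParams(d_m2_s=0.0)
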