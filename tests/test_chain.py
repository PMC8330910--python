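"""Respiratory-chain core: inhibitors, ROS rates, conservation laws."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mitoros.chain import (
    bound_quinone,
    build_cii_topology,
    build_ciii_topology,
    default_chain_rates,
    ros_rate,
)
from mitoros.microstates import enumerate_states
from mitoros.mito import build_isolated_cii_model, default_mito_initial
from mitoros.rates import RateSet, apply_inhibitor


# --------------------------------------------------------------------------
# inhibitors
# --------------------------------------------------------------------------

def test_myxothiazol_complete_block_zeroes_qo_binding():
    r = apply_inhibitor(default_chain_rates(), "myxothiazol", 0.0)
    assert r["k_qo_on"] == 0.0


def test_myxothiazol_partial_block_scales_printed_constant():
    base = default_chain_rates()
    assert base["k_qo_on"] == 700.0
    r = apply_inhibitor(base, "myxothiazol", 4e-8)
    assert r["k_qo_on"] == pytest.approx(2.8e-5, rel=1e-12)


def test_antimycin_blocks_qi_binding_and_dissociation_only():
    base = default_chain_rates()
    r = apply_inhibitor(base, "antimycin", 0.0)
    for key in ("k_qi_on", "k_qi_off", "k_qi_qh2_on", "k_qi_qh2_off"):
        assert r[key] == 0.0
    for key in base:
        if key not in ("k_qi_on", "k_qi_off", "k_qi_qh2_on", "k_qi_qh2_off"):
            assert r[key] == base[key]


def test_rotenone_disables_complex_i_input():
    r = apply_inhibitor(default_chain_rates(), "rotenone", 0.0)
    assert r["k_ci"] == 0.0


def test_unknown_inhibitor_and_bad_fraction_rejected():
    with pytest.raises(ValueError, match="unknown inhibitor"):
        apply_inhibitor(default_chain_rates(), "cyanide", 0.0)
    with pytest.raises(ValueError):
        apply_inhibitor(default_chain_rates(), "antimycin", 1.5)


def test_rateset_rejects_negative_constants():
    with pytest.raises(ValueError):
        RateSet(k_x=-1.0)


# --------------------------------------------------------------------------
# ROS rates
# --------------------------------------------------------------------------

def test_ros_rate_zero_without_semiquinone():
    space = enumerate_states(build_ciii_topology())
    occ = np.zeros(space.n_states)
    occ[0] = 0.25  # all complex in the fully oxidised, empty-site state
    assert ros_rate(space, occ, "ciii_qo", 2e-5) == 0.0


def test_ros_rate_direct_substitution_and_linearity():
    space = enumerate_states(build_cii_topology())
    fadh = space.level_indicator("flavin", "FADH")
    occ = np.zeros(space.n_states)
    idx = np.nonzero(fadh)[0][0]
    occ[idx] = 1.0
    assert ros_rate(space, occ, "cii_flavin", 2e-5) == pytest.approx(2e-5)
    occ[idx] = 3.0
    assert ros_rate(space, occ, "cii_flavin", 2e-5) == pytest.approx(6e-5)


def test_ros_rate_unknown_site_and_wrong_complex():
    space = enumerate_states(build_cii_topology())
    occ = np.zeros(space.n_states)
    with pytest.raises(ValueError, match="unknown ROS site"):
        ros_rate(space, occ, "complex_iv", 1.0)
    with pytest.raises(ValueError, match="belongs to complex"):
        ros_rate(space, occ, "ciii_qo", 1.0)


# --------------------------------------------------------------------------
# conservation along trajectories
# --------------------------------------------------------------------------

def _closed_model():
    """Isolated complex II model with all buffers released (closed system)."""
    m = build_isolated_cii_model(4e-8)
    m.clamped = {}
    x = default_mito_initial(m, psi0=50.0)
    m.set_pool(x, "succ", 0.5)
    m.set_pool(x, "fum", 0.05)
    return m, x


def test_complex_totals_and_quinone_conserved_along_trajectory():
    m, x = _closed_model()
    cii = enumerate_states(build_cii_topology())
    ciii = enumerate_states(build_ciii_topology())
    bq2, bq3 = bound_quinone(cii), bound_quinone(ciii)

    def totals(y):
        o2, o3 = m.occupancy(y, "cii"), m.occupancy(y, "ciii")
        quin = (m.pool_value(y, "q") + m.pool_value(y, "qh2")
                + bq2 @ o2 + bq3 @ o3)
        return np.array([o2.sum(), o3.sum(), quin])

    sol = solve_ivp(m.rhs, (0.0, 200.0), x, method="BDF", rtol=1e-8,
                    atol=1e-10, jac=m.jacobian,
                    t_eval=np.linspace(0, 200, 9))
    ref = totals(sol.y[:, 0])
    for j in range(sol.y.shape[1]):
        drift = np.abs(totals(sol.y[:, j]) - ref) / ref
        assert drift.max() < 1e-8


def test_electron_balance_closes_along_trajectory():
    """Electrons in from succinate = stored + terminal + superoxide."""
    m, x = _closed_model()
    cii = enumerate_states(build_cii_topology())
    ciii = enumerate_states(build_ciii_topology())
    e2, e3 = cii.electron_content(), ciii.electron_content()

    def inventory(y):
        stored = e2 @ m.occupancy(y, "cii") + e3 @ m.occupancy(y, "ciii")
        pools = 2.0 * (m.pool_value(y, "qh2") + m.pool_value(y, "succ")
                       + m.pool_value(y, "nadh"))
        sinks = m.pool_value(y, "e_term") + m.pool_value(y, "e_ros")
        return stored + pools + sinks

    sol = solve_ivp(m.rhs, (0.0, 500.0), x, method="BDF", rtol=1e-9,
                    atol=1e-11, jac=m.jacobian,
                    t_eval=np.linspace(0, 500, 6))
    ref = inventory(sol.y[:, 0])
    for j in range(sol.y.shape[1]):
        assert abs(inventory(sol.y[:, j]) - ref) / ref < 1e-6


def test_detailed_balance_toy_relaxes_to_boltzmann_ratios():
    """With charge couplings off, a closed reversible pair of centres
    relaxes to the equilibrium implied by its rate-constant ratios."""
    from mitoros.microstates import (ComplexTopology, RedoxCenter,
                                     TransitionRule, build_rhs)

    R = TransitionRule.make
    topo = ComplexTopology(
        "pair",
        (RedoxCenter("a", ("ox", "red")), RedoxCenter("b", ("ox", "red"))),
        (R("ab", {"a": "red", "b": "ox"}, {"a": "ox", "b": "red"}, "kf"),
         R("ba", {"a": "ox", "b": "red"}, {"a": "red", "b": "ox"}, "kr")))
    space = enumerate_states(topo)
    rhs = build_rhs(space, topo.rules, {"kf": 5.0, "kr": 2.0})
    f = lambda t, y: rhs(y, {}, 0.0)[0]
    y0 = np.array([0.0, 0.0, 1.0, 0.0])  # all in |a=red, b=ox>
    sol = solve_ivp(f, (0, 100), y0, rtol=1e-11, atol=1e-13)
    # states |red,ox> and |ox,red> exchange with Keq = kf/kr
    ratio = sol.y[1, -1] / sol.y[2, -1]
    assert ratio == pytest.approx(5.0 / 2.0, rel=1e-6)
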