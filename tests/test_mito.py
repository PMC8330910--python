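"""Matrix reactions, membrane potential and the Ca2+ uniporter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoros.constants import RT_F, rt_over_f
from mitoros.mito import (
    MembraneParams,
    MitoState,
    aat_rate,
    ca_uniporter_flux,
    delta_psi_rhs,
    oxidation_chain_rates,
)


def test_thermal_voltage_matches_printed_value():
    assert rt_over_f() == pytest.approx(25.693, abs=5e-4)


# --------------------------------------------------------------------------
# aminotransferase
# --------------------------------------------------------------------------

def test_aat_rate_zero_and_equilibrium_and_arithmetic():
    assert aat_rate(0.0, 5.0, 0.0, 3.0, 1.0, 1.0) == 0.0
    # k_f*oaa*glu == k_r*asp*akg -> net zero
    assert aat_rate(2.0, 3.0, 6.0, 1.0, 1.0, 1.0) == pytest.approx(0.0)
    assert aat_rate(2.0, 3.0, 1.0, 1.0, 1.0, 0.5) == pytest.approx(5.5)


def test_aat_rate_rejects_negative_amounts():
    with pytest.raises(ValueError):
        aat_rate(-1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


# --------------------------------------------------------------------------
# oxidation chain
# --------------------------------------------------------------------------

def test_oxidation_chain_zero_and_poised():
    zero = oxidation_chain_rates(MitoState())
    assert zero["fumarase"] == 0.0 and zero["mdh"] == 0.0
    from mitoros.mito import default_matrix_rates
    r = default_matrix_rates()
    # poise each reaction at its equilibrium ratio
    fum, mal = 1.0, r["k_fum_f"] / r["k_fum_r"]
    nadh, nad = 0.5, 1.5
    oaa = r["k_mdh_f"] * mal * nad / (r["k_mdh_r"] * nadh)
    s = MitoState(fum=fum, mal=mal, oaa=oaa, nadh=nadh, nad=nad)
    rates = oxidation_chain_rates(s, r)
    assert rates["fumarase"] == pytest.approx(0.0, abs=1e-12)
    assert rates["mdh"] == pytest.approx(0.0, abs=1e-12)


def test_glutamate_lowers_steady_oxaloacetate():
    """Succinate oxidation with AAT off accumulates oxaloacetate; with
    glutamate present the AAT drain holds it strictly lower."""
    from mitoros.bifurcation import relax_to_steady
    from mitoros.mito import build_isolated_mito_model, default_mito_initial

    oaa = {}
    for glu in (0.0, 0.05):
        m = build_isolated_mito_model(glu_ext=glu)
        res = relax_to_steady(m, default_mito_initial(m), t_cap=1e6)
        assert res.converged
        oaa[glu] = m.pool_value(res.x, "oaa")
    assert oaa[0.05] < oaa[0.0]


def test_mitostate_rejects_negative_amounts():
    with pytest.raises(ValueError):
        MitoState(succ=-0.1)


# --------------------------------------------------------------------------
# Ca2+ uniporter
# --------------------------------------------------------------------------

def test_uniporter_zero_gradient_gives_zero_flux():
    for psi in (-120.0, 0.0, 80.0, 200.0):
        assert ca_uniporter_flux(psi, 3.0, 3.0) == pytest.approx(0.0, abs=1e-15)


def test_uniporter_small_psi_limit_matches_series():
    """The psi -> 0 limit equals the analytic series limit of the printed
    expression, checked against direct evaluation at psi = +-1e-6 mV."""
    p = MembraneParams()
    ca_o, ca_i = 10.0, 0.1
    limit = p.p_ca * (p.rt_over_f / p.z_ca) * (ca_o - ca_i)
    assert ca_uniporter_flux(0.0, ca_o, ca_i, p) == pytest.approx(limit,
                                                                  rel=1e-9)
    for psi in (1e-6, -1e-6):
        assert ca_uniporter_flux(psi, ca_o, ca_i, p) == pytest.approx(
            limit, rel=1e-6)


def test_uniporter_energised_orientation_gives_influx():
    assert ca_uniporter_flux(150.0, 20.0, 1e-4) > 0.0


@settings(deadline=None, max_examples=60, derandomize=True)
@given(psi=st.floats(-400.0, 400.0), ca_o=st.floats(0.0, 50.0),
       ca_i=st.floats(0.0, 5.0))
def test_uniporter_never_nan_and_continuous(psi, ca_o, ca_i):
    for form in ("verbatim", "ghk"):
        j = ca_uniporter_flux(psi, ca_o, ca_i, form=form)
        assert np.isfinite(j)
        j2 = ca_uniporter_flux(psi + 1e-7, ca_o, ca_i, form=form)
        assert abs(j2 - j) < 1e-3 * max(abs(j), 1.0)


def test_uniporter_ghk_form_shares_zero_psi_limit():
    p = MembraneParams()
    a = ca_uniporter_flux(0.0, 7.0, 0.5, p, form="verbatim")
    b = ca_uniporter_flux(0.0, 7.0, 0.5, p, form="ghk")
    assert a == pytest.approx(b, rel=1e-9)
    with pytest.raises(ValueError, match="unknown uniporter form"):
        ca_uniporter_flux(0.0, 1.0, 1.0, form="nernst")


# --------------------------------------------------------------------------
# membrane potential balance
# --------------------------------------------------------------------------

def test_delta_psi_rhs_direct_substitution():
    # 0.1 nmol/mg/s of Ca2+ uptake carries 2 charges: |dpsi/dt| = 100 mV/s
    assert abs(delta_psi_rhs([-2.0 * 0.1], 500.0)) == pytest.approx(100.0)
    assert delta_psi_rhs([], 500.0) == 0.0
    assert delta_psi_rhs([0.3, -0.3]) == pytest.approx(0.0)


def test_leak_balances_pumping_at_steady_state():
    """With pumping flux J and leak k*psi, the steady potential is
    psi* = f_over_c * J / k_leak."""
    k_leak, f_over_c, pump = 2.0, 500.0, 0.6
    psi_star = f_over_c * pump / k_leak
    dpsi = delta_psi_rhs([pump], f_over_c) - k_leak * psi_star
    assert dpsi == pytest.approx(0.0, abs=1e-12)


def test_membrane_params_validation():
    assert MembraneParams().rt_over_f == pytest.approx(RT_F)
    with pytest.raises(ValueError):
        MembraneParams(k_leak=-1.0)
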