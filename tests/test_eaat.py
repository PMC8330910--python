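"""EAAT transport cycle: ordered binding, stoichiometry, thermodynamics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mitoros.constants import RT_F
from mitoros.eaat import (
    BindingConstants,
    EaatPool,
    EaatRates,
    IonEnvironment,
    eaat_cycle_flux,
    outer_binding_fraction,
)


def test_no_glutamate_binding_without_sodium():
    env = IonEnvironment(na_o=0.0, glu_o=100.0)
    assert outer_binding_fraction(env) == 0.0


def test_saturation_of_every_step_drives_fraction_to_one():
    env = IonEnvironment(na_o=1e7, h_o=1e3, glu_o=1e7, k_o=0.0)
    assert outer_binding_fraction(env) == pytest.approx(1.0, abs=1e-4)


def test_fractions_match_explicit_partition_sum():
    """Oracle: the sequential binding polynomial written out term by term."""
    kd = BindingConstants()
    env = IonEnvironment(na_o=50.0, h_o=3e-5, glu_o=0.05, k_o=4.0)
    x1 = env.na_o / kd.k_na1
    x2 = env.na_o / kd.k_na2
    xh = env.h_o / kd.k_h
    xg = env.glu_o / kd.k_glu
    x3 = env.na_o / kd.k_na3
    xk = env.k_o / kd.k_k
    terms = [1.0, x1, x1 * x2 * xh, x1 * x2 * xh * xg,
             x1 * x2 * xh * xg * x3, xk]
    expected = terms[4] / sum(terms)
    assert outer_binding_fraction(env, kd) == pytest.approx(expected,
                                                            rel=1e-12)


def test_half_maximal_uptake_near_20_uM_glutamate():
    f = lambda g: outer_binding_fraction(IonEnvironment(glu_o=g))
    half = brentq(lambda g: f(g) - f(1e9) / 2.0, 1e-6, 10.0)
    assert half == pytest.approx(0.020, rel=0.15)


def test_state_fractions_conserve_transporter():
    pool = EaatPool(0.3, 0.7)
    fr = pool.state_fractions(IonEnvironment(glu_o=0.02))
    assert sum(fr.values()) == pytest.approx(pool.total, rel=1e-12)
    assert all(v >= 0.0 for v in fr.values())


def test_zero_glutamate_both_sides_gives_zero_glutamate_flux():
    env = IonEnvironment(glu_o=0.0, glu_i=0.0)
    glu_flux, charge, *_ = eaat_cycle_flux(env, EaatPool(0.5, 0.5))
    assert glu_flux == 0.0 and charge == 0.0


def test_charge_flux_is_twice_glutamate_flux_exactly():
    env = IonEnvironment(glu_o=0.05, vm=-70.0)
    for pool in (EaatPool(0.9, 0.1), EaatPool(0.2, 0.8)):
        glu_flux, charge, *_ = eaat_cycle_flux(env, pool)
        assert charge == 2.0 * glu_flux


def _cycle_steady_flux(env: IonEnvironment) -> float:
    """Net flux with the transporter distribution at cycle steady state."""
    rates = EaatRates()

    def imbalance(t_out):
        p = EaatPool(t_out, 1.0 - t_out)
        _, _, j_load, j_ret = eaat_cycle_flux(env, p, rates)
        return j_load - j_ret

    t = brentq(imbalance, 1e-12, 1.0 - 1e-12)
    return eaat_cycle_flux(env, EaatPool(t, 1.0 - t), rates)[0]


def test_no_internal_potassium_stalls_the_cycle():
    """Without internal K+ the carrier cannot return; at cycle steady
    state the flux collapses to (near) zero."""
    active = _cycle_steady_flux(IonEnvironment(glu_o=0.05))
    stalled = _cycle_steady_flux(IonEnvironment(glu_o=0.05, k_i=0.0))
    assert active > 0.0
    assert abs(stalled) < 0.02 * active


def test_reversal_potential_equals_nernst_prediction():
    """Thermodynamic consistency: with detailed-balance rate constants,
    zero net flux occurs exactly at the combined electrochemical
    equilibrium (3 Na+ + H+ + Glu- in, K+ out, +2 charges)."""
    env0 = IonEnvironment(glu_o=0.005, glu_i=2.0)

    def flux_at(vm):
        e = IonEnvironment(glu_o=env0.glu_o, glu_i=env0.glu_i, vm=vm)
        return _cycle_steady_flux(e)

    vm_rev = brentq(flux_at, -200.0, 200.0)
    nernst = RT_F / 2.0 * np.log(
        (env0.na_o / env0.na_i) ** 3 * (env0.h_o / env0.h_i)
        * (env0.glu_o / env0.glu_i) * (env0.k_i / env0.k_o))
    assert vm_rev == pytest.approx(nernst, abs=1e-6)


def test_hyperpolarisation_increases_forward_flux():
    fluxes = [_cycle_steady_flux(IonEnvironment(glu_o=0.05, vm=vm))
              for vm in np.linspace(-90.0, 0.0, 7)]
    assert all(a > b > 0 for a, b in zip(fluxes, fluxes[1:]))


def test_negative_concentration_rejected():
    with pytest.raises(ValueError):
        IonEnvironment(na_o=-1.0)
    with pytest.raises(ValueError):
        BindingConstants(k_glu=0.0)
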