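"""State-enumeration engine: counts, ordering, and oracle equivalence.

The derivative evaluator built from pattern rules is checked against a
deliberately naive oracle that loops over every microstate and applies
each rule by dictionary matching -- fully independent of the compiled
index arithmetic it verifies.
"""

import itertools

import numpy as np
import pytest

from mitoros.microstates import (
    ComplexTopology,
    RedoxCenter,
    TransitionRule,
    build_rhs,
    enumerate_states,
)
from mitoros.chain import build_cii_topology, build_ciii_topology

R = TransitionRule.make


# --------------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------------

def brute_force_rhs(topology, rules, rates, occupancy, env, psi=0.0,
                    rt_f=25.693):
    """Naive per-state rule application: the reference for build_rhs."""
    centers = topology.centers
    level_sets = [c.levels for c in centers]
    states = list(itertools.product(*level_sets))
    index = {s: i for i, s in enumerate(states)}
    docc = np.zeros(len(states))
    pool = {}
    charge = 0.0
    for rule in rules:
        src_pat, tgt_pat = dict(rule.source), dict(rule.target)
        for s in states:
            named = {c.name: lv for c, lv in zip(centers, s)}
            if any(named[k] != v for k, v in src_pat.items()):
                continue
            named.update(tgt_pat)
            target = tuple(named[c.name] for c in centers)
            r = rates[rule.rate_key]
            for e in rule.env:
                r *= env[e]
            if rule.charge:
                r *= np.exp(-rule.charge * rule.alpha * psi / rt_f)
            r *= occupancy[index[s]]
            docc[index[s]] -= r
            docc[index[target]] += r
            for name, sto in rule.stoich:
                pool[name] = pool.get(name, 0.0) + sto * r
            charge += rule.charge * r
    return docc, pool, charge


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------

def test_single_two_level_center_gives_two_states():
    topo = ComplexTopology("toy", (RedoxCenter("a", ("ox", "red")),))
    assert enumerate_states(topo).n_states == 2


@pytest.mark.parametrize(
    "builder, expected",
    [(build_ciii_topology, 4 * 2 * 2 * 4 * 2), (build_cii_topology, 3 * 3 * 4)],
)
def test_chain_state_counts_match_explicit_product(builder, expected):
    topo = builder()
    space = enumerate_states(topo)
    assert space.n_states == expected
    # explicit enumeration: every level combination appears exactly once
    combos = set(map(tuple, space.states))
    full = set(itertools.product(*[range(c.n_levels) for c in topo.centers]))
    assert combos == full


def test_enumeration_is_lexicographic_and_invertible():
    space = enumerate_states(build_cii_topology())
    for i in range(space.n_states):
        assert space.state_index(space.states[i]) == i
    # lexicographic: first center is the slowest index
    assert list(space.states[0]) == [0, 0, 0]
    assert list(space.states[1]) == [0, 0, 1]


def test_empty_topology_rejected():
    with pytest.raises(ValueError):
        ComplexTopology("bad", ())


def test_center_needs_two_levels():
    with pytest.raises(ValueError):
        RedoxCenter("x", ("only",))


def test_rule_referencing_unknown_center_rejected():
    bad = R("r", {"nope": "ox"}, {"nope": "red"}, "k")
    with pytest.raises(ValueError):
        ComplexTopology("bad", (RedoxCenter("a", ("ox", "red")),), (bad,))


# --------------------------------------------------------------------------
# derivative evaluator
# --------------------------------------------------------------------------

def _toy3():
    """Three-center toy with five rules, incl. env factors and side effects."""
    centers = (
        RedoxCenter("a", ("ox", "red")),
        RedoxCenter("b", ("ox", "red")),
        RedoxCenter("site", ("empty", "Q", "QH2")),
    )
    rules = (
        R("bind", {"site": "empty"}, {"site": "Q"}, "k_on", env=("q",),
          stoich={"q": -1}),
        R("release", {"site": "Q"}, {"site": "empty"}, "k_off",
          stoich={"q": +1}),
        R("et", {"a": "red", "b": "ox"}, {"a": "ox", "b": "red"}, "k_et",
          charge=1.0),
        R("et_rev", {"a": "ox", "b": "red"}, {"a": "red", "b": "ox"}, "k_etr",
          charge=-1.0),
        R("reduce_site", {"b": "red", "site": "Q"}, {"b": "ox", "site": "QH2"},
          "k_q"),
    )
    topo = ComplexTopology("toy3", centers, rules)
    rates = {"k_on": 2.0, "k_off": 0.7, "k_et": 1.3, "k_etr": 0.4, "k_q": 5.0}
    return topo, rules, rates


def test_rhs_matches_brute_force_oracle_on_toys():
    rng = np.random.default_rng(42)
    topo, rules, rates = _toy3()
    space = enumerate_states(topo)
    rhs = build_rhs(space, rules, rates, rt_f=25.693)
    for psi in (0.0, 90.0, -40.0):
        occ = rng.uniform(0.0, 1.0, space.n_states)
        env = {"q": 1.7}
        docc, pools, charge = rhs(occ, env, psi)
        docc_o, pools_o, charge_o = brute_force_rhs(
            topo, rules, rates, occ, env, psi)
        np.testing.assert_allclose(docc, docc_o, rtol=1e-13, atol=1e-15)
        assert set(pools) == set(pools_o)
        for k in pools:
            assert pools[k] == pytest.approx(pools_o[k], rel=1e-13)
        assert charge == pytest.approx(charge_o, rel=1e-13)


@pytest.mark.parametrize("builder", [build_cii_topology, build_ciii_topology])
def test_rhs_matches_oracle_on_full_chain_complexes(builder):
    from mitoros.chain import default_chain_rates

    topo = builder()
    space = enumerate_states(topo)
    rates = default_chain_rates()
    rng = np.random.default_rng(7)
    occ = rng.uniform(0, 0.1, space.n_states)
    env = {"q": 1.2, "qh2": 2.8, "succ": 5.0, "fum": 0.3, "oaa": 0.01}
    rhs = build_rhs(space, topo.rules, rates, rt_f=25.693)
    docc, pools, charge = rhs(occ, env, 150.0)
    docc_o, pools_o, charge_o = brute_force_rhs(
        topo, topo.rules, rates, occ, env, 150.0)
    np.testing.assert_allclose(docc, docc_o, rtol=1e-12, atol=1e-16)
    for k in pools_o:
        assert pools[k] == pytest.approx(pools_o[k], rel=1e-12)
    assert charge == pytest.approx(charge_o, rel=1e-12)


def test_occupancy_derivative_sums_to_zero():
    topo, rules, rates = _toy3()
    space = enumerate_states(topo)
    rhs = build_rhs(space, rules, rates)
    occ = np.linspace(0.1, 1.0, space.n_states)
    docc, _, _ = rhs(occ, {"q": 3.0}, 120.0)
    assert abs(docc.sum()) < 1e-14


def test_symmetric_two_state_equilibrium():
    """Forward = backward rate 1/s: steady occupancy (0.5, 0.5)."""
    from scipy.integrate import solve_ivp

    topo = ComplexTopology(
        "flip", (RedoxCenter("a", ("ox", "red")),),
        (R("f", {"a": "ox"}, {"a": "red"}, "k"),
         R("b", {"a": "red"}, {"a": "ox"}, "k")))
    space = enumerate_states(topo)
    rhs = build_rhs(space, topo.rules, {"k": 1.0})
    f = lambda t, y: rhs(y, {}, 0.0)[0]
    sol = solve_ivp(f, (0, 50), [1.0, 0.0], rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(sol.y[:, -1], [0.5, 0.5], atol=1e-8)


def test_missing_rate_key_named_in_error():
    topo, rules, rates = _toy3()
    space = enumerate_states(topo)
    bad = dict(rates)
    del bad["k_et"]
    with pytest.raises(KeyError, match="k_et"):
        build_rhs(space, rules, bad)


def test_detailed_balance_equilibrium():
    """Closed reversible toy relaxes to the Boltzmann ratio k_f/k_r."""
    from scipy.integrate import solve_ivp

    kf, kr = 3.0, 1.0
    topo = ComplexTopology(
        "db", (RedoxCenter("a", ("ox", "red")),),
        (R("f", {"a": "ox"}, {"a": "red"}, "kf"),
         R("b", {"a": "red"}, {"a": "ox"}, "kr")))
    space = enumerate_states(topo)
    rhs = build_rhs(space, topo.rules, {"kf": kf, "kr": kr})
    f = lambda t, y: rhs(y, {}, 0.0)[0]
    sol = solve_ivp(f, (0, 100), [1.0, 0.0], rtol=1e-12, atol=1e-14)
    ratio = sol.y[1, -1] / sol.y[0, -1]
    assert ratio == pytest.approx(kf / kr, rel=1e-6)


def test_topology_json_round_trip():
    import json

    from mitoros.chain import build_ciii_topology
    from mitoros.microstates import topology_from_dict, topology_to_dict

    topo = build_ciii_topology()
    doc = json.loads(json.dumps(topology_to_dict(topo)))
    back = topology_from_dict(doc)
    assert back.complex_id == topo.complex_id
    assert back.centers == topo.centers
    assert back.rules == topo.rules
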