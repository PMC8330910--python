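"""Respiratory-chain core: complexes II and III and the ubiquinone pool.

Complex III is resolved as Qo x bL x bH x Qi x (FeS-c1 lumped) = 4*2*2*4*2
= 128 joint redox states implementing the Mitchell Q-cycle: ubiquinol
bound at the Qo site gives its first electron to the FeS/c1 relay
(releasing two protons to the positive side) leaving a semiquinone (SQ);
the SQ gives the second electron either to heme bL -- whose transfer to
bH carries one charge across the membrane -- or to molecular oxygen,
producing superoxide.  bH reduces quinone at the Qi site in two
one-electron steps.  The FeS/c1 relay is reoxidised by a lumped,
irreversible cytochrome-c/complex-IV step translocating two further
charges per electron.

Complex II is flavin x dicarboxylate site x quinone site = 3*3*4 = 36
states: succinate bound at the dicarboxylate site reduces FAD to FADH2
(releasing fumarate); the flavin is reoxidised in two one-electron steps
through the site quinone, passing through the ROS-producing flavin
semiquinone FADH*.  Oxaloacetate competes for the dicarboxylate site with
slow dissociation (tight-binding inhibition).

Superoxide production is pseudo-first-order in site semiquinone
(k_ros = 2e-5 s^-1 by default; oxygen absorbed into the constant), and
the producing transition reoxidises the semiquinone so electron count is
conserved.
"""

from __future__ import annotations

import numpy as np

from .microstates import (
    ComplexTopology,
    RedoxCenter,
    StateSpace,
    TransitionRule,
    enumerate_states,
)
from .rates import RateSet

__all__ = [
    "QUINONE_LEVELS",
    "build_cii_topology",
    "build_ciii_topology",
    "default_chain_rates",
    "ros_rate",
    "bound_quinone",
    "reduced_quinone_bound",
]

R = TransitionRule.make

#: quinone-site levels and their electron content (SQ = 1, QH2 = 2)
QUINONE_LEVELS = ("empty", "Q", "SQ", "QH2")
_Q_E = (0.0, 0.0, 1.0, 2.0)


def build_ciii_topology() -> ComplexTopology:
    """Q-cycle topology of complex III (128 microstates)."""
    centers = (
        RedoxCenter("Qo", QUINONE_LEVELS, _Q_E),
        RedoxCenter("bL", ("ox", "red"), (0.0, 1.0)),
        RedoxCenter("bH", ("ox", "red"), (0.0, 1.0)),
        RedoxCenter("Qi", QUINONE_LEVELS, _Q_E),
        RedoxCenter("c1", ("ox", "red"), (0.0, 1.0)),
    )
    rules = (
        # --- Qo site: ubiquinol binding / quinone release ---
        R("qo_qh2_bind", {"Qo": "empty"}, {"Qo": "QH2"}, "k_qo_on",
          env=("qh2",), stoich={"qh2": -1}),
        R("qo_qh2_release", {"Qo": "QH2"}, {"Qo": "empty"}, "k_qo_off",
          stoich={"qh2": +1}),
        R("qo_q_release", {"Qo": "Q"}, {"Qo": "empty"}, "k_qoq_off",
          stoich={"q": +1}),
        R("qo_q_bind", {"Qo": "empty"}, {"Qo": "Q"}, "k_qoq_on",
          env=("q",), stoich={"q": -1}),
        # --- Qo chemistry: bifurcated oxidation of QH2 ---
        R("qo_e1", {"Qo": "QH2", "c1": "ox"}, {"Qo": "SQ", "c1": "red"},
          "k_qo_e1", protons_out=2.0),
        R("qo_e1_rev", {"Qo": "SQ", "c1": "red"}, {"Qo": "QH2", "c1": "ox"},
          "k_qo_e1r", protons_out=-2.0),
        R("qo_e2", {"Qo": "SQ", "bL": "ox"}, {"Qo": "Q", "bL": "red"},
          "k_qo_e2"),
        R("qo_e2_rev", {"Qo": "Q", "bL": "red"}, {"Qo": "SQ", "bL": "ox"},
          "k_qo_e2r"),
        R("qo_ros", {"Qo": "SQ"}, {"Qo": "Q"}, "k_ros_qo",
          stoich={"ros_ciii": +1, "e_ros": +1}, ros_site="ciii_qo"),
        # --- trans-membrane electron transfer (one charge) ---
        R("bl_bh", {"bL": "red", "bH": "ox"}, {"bL": "ox", "bH": "red"},
          "k_bl_bh", charge=+1.0),
        R("bl_bh_rev", {"bL": "ox", "bH": "red"}, {"bL": "red", "bH": "ox"},
          "k_bl_bh_r", charge=-1.0),
        # --- Qi site: two-step quinone reduction ---
        R("qi_e1", {"bH": "red", "Qi": "Q"}, {"bH": "ox", "Qi": "SQ"},
          "k_qi_e1"),
        R("qi_e1_rev", {"bH": "ox", "Qi": "SQ"}, {"bH": "red", "Qi": "Q"},
          "k_qi_e1r"),
        R("qi_e2", {"bH": "red", "Qi": "SQ"}, {"bH": "ox", "Qi": "QH2"},
          "k_qi_e2", protons_out=-2.0),  # 2 H+ taken from the matrix
        R("qi_e2_rev", {"bH": "ox", "Qi": "QH2"}, {"bH": "red", "Qi": "SQ"},
          "k_qi_e2r", protons_out=2.0),
        # --- Qi site: quinone binding / ubiquinol release (antimycin site) ---
        R("qi_q_bind", {"Qi": "empty"}, {"Qi": "Q"}, "k_qi_on",
          env=("q",), stoich={"q": -1}),
        R("qi_q_release", {"Qi": "Q"}, {"Qi": "empty"}, "k_qi_off",
          stoich={"q": +1}),
        R("qi_qh2_release", {"Qi": "QH2"}, {"Qi": "empty"}, "k_qi_qh2_off",
          stoich={"qh2": +1}),
        R("qi_qh2_bind", {"Qi": "empty"}, {"Qi": "QH2"}, "k_qi_qh2_on",
          env=("qh2",), stoich={"qh2": -1}),
        # --- lumped c1 -> c -> complex IV -> O2 (two charges per electron) ---
        R("terminal", {"c1": "red"}, {"c1": "ox"}, "k_term",
          charge=+2.0, stoich={"e_term": +1}),
    )
    return ComplexTopology("ciii", centers, rules)


def build_cii_topology() -> ComplexTopology:
    """Succinate-dehydrogenase topology of complex II (36 microstates)."""
    centers = (
        RedoxCenter("flavin", ("FAD", "FADH", "FADH2"), (0.0, 1.0, 2.0)),
        # bound succinate carries the 2 electrons it will donate
        RedoxCenter("dic", ("empty", "succ", "oaa"), (0.0, 2.0, 0.0)),
        RedoxCenter("q", QUINONE_LEVELS, _Q_E),
    )
    rules = (
        # --- dicarboxylate site ---
        R("succ_bind", {"dic": "empty"}, {"dic": "succ"}, "k_succ_on",
          env=("succ",), stoich={"succ": -1}),
        R("succ_release", {"dic": "succ"}, {"dic": "empty"}, "k_succ_off",
          stoich={"succ": +1}),
        R("oaa_bind", {"dic": "empty"}, {"dic": "oaa"}, "k_oaa_on",
          env=("oaa",), stoich={"oaa": -1}),
        R("oaa_release", {"dic": "oaa"}, {"dic": "empty"}, "k_oaa_off",
          stoich={"oaa": +1}),
        # --- FAD reduction by bound succinate (fumarate released) ---
        R("fad_red", {"flavin": "FAD", "dic": "succ"},
          {"flavin": "FADH2", "dic": "empty"}, "k_red", stoich={"fum": +1}),
        R("fad_red_rev", {"flavin": "FADH2", "dic": "empty"},
          {"flavin": "FAD", "dic": "succ"}, "k_red_r", env=("fum",),
          stoich={"fum": -1}),
        # --- quinone site of complex II ---
        R("cii_q_bind", {"q": "empty"}, {"q": "Q"}, "k_cq_on",
          env=("q",), stoich={"q": -1}),
        R("cii_q_release", {"q": "Q"}, {"q": "empty"}, "k_cq_off",
          stoich={"q": +1}),
        R("cii_qh2_release", {"q": "QH2"}, {"q": "empty"}, "k_cqh2_off",
          stoich={"qh2": +1}),
        R("cii_qh2_bind", {"q": "empty"}, {"q": "QH2"}, "k_cqh2_on",
          env=("qh2",), stoich={"qh2": -1}),
        # --- flavin -> site quinone, two one-electron steps ---
        R("f_e1", {"flavin": "FADH2", "q": "Q"}, {"flavin": "FADH", "q": "SQ"},
          "k_f_e1"),
        R("f_e1_rev", {"flavin": "FADH", "q": "SQ"},
          {"flavin": "FADH2", "q": "Q"}, "k_f_e1r"),
        R("f_e2", {"flavin": "FADH", "q": "SQ"}, {"flavin": "FAD", "q": "QH2"},
          "k_f_e2"),
        R("f_e2_rev", {"flavin": "FAD", "q": "QH2"},
          {"flavin": "FADH", "q": "SQ"}, "k_f_e2r"),
        # the remaining one-electron combinations (same constants reused);
        # without them |FAD,SQ> would be a kinetic trap
        R("f_e3", {"flavin": "FADH2", "q": "SQ"},
          {"flavin": "FADH", "q": "QH2"}, "k_f_e1"),
        R("f_e3_rev", {"flavin": "FADH", "q": "QH2"},
          {"flavin": "FADH2", "q": "SQ"}, "k_f_e1r"),
        R("f_e4", {"flavin": "FADH", "q": "Q"}, {"flavin": "FAD", "q": "SQ"},
          "k_f_e2"),
        R("f_e4_rev", {"flavin": "FAD", "q": "SQ"},
          {"flavin": "FADH", "q": "Q"}, "k_f_e2r"),
        # --- Messner-Imlay flavin-semiquinone superoxide ---
        R("flavin_ros", {"flavin": "FADH"}, {"flavin": "FAD"}, "k_ros_flavin",
          stoich={"ros_cii": +1, "e_ros": +1}, ros_site="cii_flavin"),
    )
    return ComplexTopology("cii", centers, rules)


def default_chain_rates() -> RateSet:
    """Default rate constants of the respiratory-chain core.

    Printed constants (700 (nmol/mg)^-1 s^-1 ubiquinol binding at Qo,
    175 (nmol/mg)^-1 s^-1 succinate binding to complex II, 2e-5 s^-1 ROS
    formation) are fixed; the remaining constants are free parameters
    calibrated once by ``scripts/calibrate.py`` so that the isolated
    complex II ROS peak falls near 50 uM succinate and the glutamate
    sweep bifurcates below 100 uM (see docs/methods.md).
    """
    return RateSet(
        # complex III
        k_qo_on=700.0, k_qo_off=300.0,
        k_qoq_on=50.0, k_qoq_off=800.0,
        k_qo_e1=300.0, k_qo_e1r=3000.0,
        k_qo_e2=2.0e4, k_qo_e2r=200.0,
        k_ros_qo=2.0e-5,
        k_bl_bh=1.0e3, k_bl_bh_r=100.0,
        k_qi_e1=500.0, k_qi_e1r=50.0,
        k_qi_e2=500.0, k_qi_e2r=50.0,
        k_qi_on=30.0, k_qi_off=100.0,
        k_qi_qh2_on=10.0, k_qi_qh2_off=500.0,
        k_term=1.5e3,
        # complex II; the flavin <-> quinone-pool link is thermoneutral and
        # FAD reduction by succinate has Keq ~ 1, so the flavin redox poise
        # titrates with the succinate/fumarate couple (semiquinone maximal
        # at half-reduction, near succinate ~ fumarate)
        k_succ_on=175.0, k_succ_off=50.0,
        k_oaa_on=100.0, k_oaa_off=0.01,
        k_red=1.3, k_red_r=4.55,
        k_cq_on=200.0, k_cq_off=5.0,
        k_cqh2_on=2.0, k_cqh2_off=20.0,
        k_f_e1=300.0, k_f_e1r=300.0,
        k_f_e2=300.0, k_f_e2r=300.0,
        k_ros_flavin=2.0e-5,
        # lumped complex I (NADH + Q -> NAD + QH2), removed by rotenone
        k_ci=20.0,
    )


_ROS_SITES = {
    "cii_flavin": ("cii", "flavin", "FADH"),
    "ciii_qo": ("ciii", "Qo", "SQ"),
}


def ros_rate(space: StateSpace, occupancy: np.ndarray, site: str,
             k_ros: float) -> float:
    """Superoxide production rate (nmol mg^-1 s^-1) at a semiquinone site.

    The rate is ``k_ros`` times the total occupancy of microstates holding
    a semiquinone at the site; the producing transition reoxidises the
    semiquinone (flavin FADH* -> FAD; Qo SQ -> Q) so electrons balance.
    """
    if site not in _ROS_SITES:
        raise ValueError(f"unknown ROS site {site!r}; known: {sorted(_ROS_SITES)}")
    complex_id, center, level = _ROS_SITES[site]
    if space.complex_id != complex_id:
        raise ValueError(
            f"site {site!r} belongs to complex {complex_id!r}, "
            f"got state space for {space.complex_id!r}"
        )
    return k_ros * space.level_occupancy(occupancy, center, level)


def bound_quinone(space: StateSpace) -> np.ndarray:
    """Quinone molecules bound per microstate (for pool conservation)."""
    out = np.zeros(space.n_states)
    for c in space.centers:
        if c.levels == QUINONE_LEVELS:
            ax = space.center_axis(c.name)
            occupied = np.array([0.0, 1.0, 1.0, 1.0])
            out += occupied[space.states[:, ax]]
    return out


def reduced_quinone_bound(space: StateSpace) -> np.ndarray:
    """Reduction equivalents of bound quinone (SQ counts 1/2, QH2 counts 1)."""
    out = np.zeros(space.n_states)
    for c in space.centers:
        if c.levels == QUINONE_LEVELS:
            ax = space.center_axis(c.name)
            red = np.array([0.0, 0.0, 0.5, 1.0])
            out += red[space.states[:, ax]]
    return out
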