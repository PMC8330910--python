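"""Mitochondrial matrix compartment and isolated-mitochondria scenarios.

Couples the respiratory-chain core (:mod:`mitoros.chain`) to matrix
metabolite dynamics: the succinate -> fumarate -> malate -> oxaloacetate
oxidation chain, the aspartate aminotransferase (AAT) that drains
oxaloacetate when glutamate is present, the electrogenic
aspartate/glutamate carrier, membrane-potential balance with proton
leak, and the Ca2+ uniporter.

Oxaloacetate is a tight, slowly dissociating inhibitor of the complex II
dicarboxylate site; AAT (oaa + glu -> asp + akg) lowers free
oxaloacetate, relieving the inhibition -- the glutamate "activation" of
complex II at the heart of the model.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import CustomFlux, Model, PoolReaction
from .bifurcation import relax_to_steady
from .chain import (
    bound_quinone,
    build_cii_topology,
    build_ciii_topology,
    default_chain_rates,
    reduced_quinone_bound,
    ros_rate,
)
from .constants import RT_F, um_to_amount
from .microstates import enumerate_states
from .rates import RateSet, apply_inhibitor

__all__ = [
    "MitoState",
    "MembraneParams",
    "aat_rate",
    "oxidation_chain_rates",
    "ca_uniporter_flux",
    "delta_psi_rhs",
    "default_matrix_rates",
    "build_isolated_cii_model",
    "build_isolated_mito_model",
    "simulate_isolated_cii",
    "simulate_ca_pulses",
    "CII_TOTAL",
    "CIII_TOTAL",
    "Q_TOTAL",
    "NAD_TOTAL",
]

# complex amounts and conserved pool totals (nmol per mg protein)
CII_TOTAL = 0.25
CIII_TOTAL = 0.25
Q_TOTAL = 4.0
NAD_TOTAL = 2.0

MITO_POOLS = (
    "q", "qh2",
    "succ", "fum", "mal", "oaa", "asp", "glu_m", "akg",
    "nadh", "nad",
    "ca_out", "glu_ext",
    "ros_cii", "ros_ciii", "e_term", "e_ros",
)

ACCUMULATORS = ("ros_cii", "ros_ciii", "e_term", "e_ros")


@dataclass
class MitoState:
    """Matrix metabolite amounts (nmol/mg), external Ca2+ and potential."""

    succ: float = 0.0
    fum: float = 0.0
    mal: float = 0.0
    oaa: float = 0.0
    asp: float = 0.0
    glu_m: float = 0.0
    akg: float = 0.0
    nadh: float = 0.2
    nad: float = 1.8
    atp: float = 0.0
    adp: float = 0.0
    pi: float = 0.0
    ca_out: float = 0.0
    delta_psi: float = 0.0

    def __post_init__(self) -> None:
        for f in ("succ", "fum", "mal", "oaa", "asp", "glu_m", "akg",
                  "nadh", "nad", "atp", "adp", "pi"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class MembraneParams:
    """Inner-membrane electrical parameters (printed defaults)."""

    k_leak: float = 2.0       # s^-1 mV^-1 proton-leak conductance
    f_over_c: float = 500.0   # mV per nmol of translocated charge per mg
    p_ca: float = 0.005       # s^-1 mV^-1 uniporter permeability
    z_ca: float = 2.0
    rt_over_f: float = RT_F   # ~25.693 mV at 298 K

    def __post_init__(self) -> None:
        for f in ("k_leak", "f_over_c", "p_ca", "z_ca", "rt_over_f"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def aat_rate(oaa: float, glu_m: float, asp: float, akg: float,
             k_f: float, k_r: float) -> float:
    """Net aspartate-aminotransferase rate, k_f*oaa*glu - k_r*asp*akg."""
    if min(oaa, glu_m, asp, akg) < 0:
        raise ValueError("metabolite amounts must be >= 0")
    return k_f * oaa * glu_m - k_r * asp * akg


def oxidation_chain_rates(state: MitoState, rates: RateSet | None = None
                          ) -> dict[str, float]:
    """Net fumarase and malate-dehydrogenase rates for a matrix state.

    Both reactions are reversible mass action; MDH consumes NAD+ and its
    equilibrium lies strongly toward malate, so oxaloacetate stays low
    unless drained (by AAT or by Krebs-cycle condensation).
    """
    r = rates or default_matrix_rates()
    fumarase = r["k_fum_f"] * state.fum - r["k_fum_r"] * state.mal
    mdh = r["k_mdh_f"] * state.mal * state.nad - r["k_mdh_r"] * state.oaa * state.nadh
    return {"fumarase": fumarase, "mdh": mdh}


def _flux_factor(psi: float, z: float, rt_f: float) -> float:
    """g(psi) = psi * exp(u) / (1 - exp(u)), u = z*psi/rt_f, NaN-free.

    Continuous through psi = 0 where the analytic limit is -rt_f/z.
    """
    u = z * psi / rt_f
    if abs(u) < 1e-6:
        # series of psi/(exp(-u)-1): -rt_f/z - psi/2 - z*psi^2/(12*rt_f)
        return -rt_f / z - psi / 2.0 - z * psi * psi / (12.0 * rt_f)
    if u > 0:
        # exp(u)/(1-exp(u)) = -1/(1-exp(-u)), overflow-safe
        return -psi / (1.0 - math.exp(-u))
    return psi * math.exp(u) / (1.0 - math.exp(u))


def ca_uniporter_flux(delta_psi: float, ca_o: float, ca_i: float,
                      params: MembraneParams | None = None,
                      form: str = "verbatim") -> float:
    """Ca2+ uniporter flux (nmol mg^-1 s^-1), positive = uptake.

    ``form="verbatim"`` evaluates the printed constant-field expression
    P * psi * (ca_o - ca_i) * exp(u)/(1 - exp(u)) with a global
    orientation sign of -1 so that an energised membrane (psi > 0,
    matrix-negative) with ca_o > ca_i imports Ca2+.  ``form="ghk"``
    uses the standard Goldman flux in which only the internal
    concentration is weighted by the exponential.  Both forms share the
    analytic psi -> 0 limit P*(rt_f/z)*(ca_o - ca_i).
    """
    p = params or MembraneParams()
    z, rt_f = p.z_ca, p.rt_over_f
    if form == "verbatim":
        return -p.p_ca * (ca_o - ca_i) * _flux_factor(delta_psi, z, rt_f)
    if form == "ghk":
        u = z * delta_psi / rt_f
        if abs(u) < 1e-6:
            grad = ca_o - ca_i + (ca_o + ca_i) * u / 2.0
            return p.p_ca * (rt_f / z) * grad / (1.0 + u / 2.0)
        if u > 0:
            # psi*(ca_o*exp(u) - ca_i)/(exp(u) - 1), overflow-safe
            eu = math.exp(-u)
            return p.p_ca * delta_psi * (ca_o - ca_i * eu) / (1.0 - eu)
        eu = math.exp(u)
        return p.p_ca * delta_psi * (ca_o * eu - ca_i) / (eu - 1.0)
    raise ValueError(f"unknown uniporter form {form!r}")


def delta_psi_rhs(charge_fluxes: Sequence[float],
                  f_over_c: float = 500.0) -> float:
    """d(psi)/dt in mV/s from signed charge fluxes (nmol mg^-1 s^-1)."""
    return f_over_c * float(np.sum(charge_fluxes))


def default_matrix_rates() -> RateSet:
    """Matrix-reaction rate constants (free parameters, calibrated once)."""
    return RateSet(
        k_fum_f=50.0, k_fum_r=12.0,       # fumarate <-> malate, Keq ~ 4.2
        k_mdh_f=2.0, k_mdh_r=2000.0,      # MDH equilibrium far toward malate
        k_aat_f=50.0, k_aat_r=50.0,
        k_agc=100.0,                      # aspartate/glutamate carrier
        k_dic=0.05,                       # dicarboxylate carrier (malate efflux)
        k_ogc=0.5,                       # oxoglutarate carrier (akg efflux)
        k_nsh_f=0.05, k_nsh_r=0.005,        # residual NAD(H) turnover (poise leak)
        k_glu_x=0.01,                     # matrix glutamate consumption/efflux
        k_asp_x=5.0,                      # aspartate efflux not coupled to AGC
        k_gc=1.0,                         # glutamate/H+ symport (glutamate carrier)
        k_leak=2.0,                       # proton leak, s^-1 mV^-1
    )


def _matrix_reactions() -> list[PoolReaction]:
    P = PoolReaction.make
    return [
        P("fumarase_f", "k_fum_f", {"fum": 1}, {"mal": 1}),
        P("fumarase_r", "k_fum_r", {"mal": 1}, {"fum": 1}),
        P("mdh_f", "k_mdh_f", {"mal": 1, "nad": 1}, {"oaa": 1, "nadh": 1}),
        P("mdh_r", "k_mdh_r", {"oaa": 1, "nadh": 1}, {"mal": 1, "nad": 1}),
        P("aat_f", "k_aat_f", {"oaa": 1, "glu_m": 1}, {"asp": 1, "akg": 1}),
        P("aat_r", "k_aat_r", {"asp": 1, "akg": 1}, {"oaa": 1, "glu_m": 1}),
        # aspartate out / external glutamate in, electrogenic (+1 into matrix)
        P("agc", "k_agc", {"asp": 1, "glu_ext": 1}, {"glu_m": 1}, charge=-1.0),
        # dicarboxylate carrier: malate leaves the matrix
        P("dic_export", "k_dic", {"mal": 1}, {}),
        # oxoglutarate carrier: alpha-ketoglutarate leaves the matrix
        P("akg_export", "k_ogc", {"akg": 1}, {}),
        # residual matrix NAD(H) turnover restoring a resting redox poise
        P("nadh_turnover_f", "k_nsh_f", {"nadh": 1}, {"nad": 1}),
        P("nadh_turnover_r", "k_nsh_r", {"nad": 1}, {"nadh": 1}),
        # lumped matrix glutamate consumption (GDH) / efflux
        P("glu_m_use", "k_glu_x", {"glu_m": 1}, {}),
        # aspartate efflux not coupled to glutamate entry
        P("asp_efflux", "k_asp_x", {"asp": 1}, {}),
        # glutamate/H+ symport: electroneutral glutamate entry
        P("glu_symport", "k_gc", {"glu_ext": 1}, {"glu_m": 1}),
    ]


class UniporterFlux(CustomFlux):
    """Ca2+ uniporter as a model flux: d(ca_out)/dt = -J, 2 charges in."""

    def __init__(self, form: str = "verbatim"):
        super().__init__("ca_uniporter", stoich={"ca_out": -1.0}, charge=-2.0)
        self.form = form

    def rate(self, pools, psi, rates, params):
        mp = MembraneParams(
            k_leak=rates.get("k_leak", 2.0),
            f_over_c=params.get("f_over_c", 500.0),
            p_ca=params.get("p_ca", 0.005),
        )
        return ca_uniporter_flux(psi, pools["ca_out"], params.get("ca_in", 1e-4),
                                 mp, form=self.form)


def _register_chain_observers(model: Model) -> None:
    cii = enumerate_states(build_cii_topology())
    ciii = enumerate_states(build_ciii_topology())
    bq_cii, bq_ciii = bound_quinone(cii), bound_quinone(ciii)
    rq_cii, rq_ciii = reduced_quinone_bound(cii), reduced_quinone_bound(ciii)
    sq_qo = ciii.level_indicator("Qo", "SQ")
    fadh = cii.level_indicator("flavin", "FADH")
    oaa_bound = cii.level_indicator("dic", "oaa")

    def qh2_fraction(m: Model, x):
        """Ubiquinol fraction of the free pool (the quantity the sweep
        and jump detection monitor)."""
        q, qh2 = m.pool_value(x, "q"), m.pool_value(x, "qh2")
        return qh2 / (q + qh2) if (q + qh2) > 0 else 0.0

    def qh2_fraction_total(m: Model, x):
        """Reduction level of all ubiquinone incl. site-bound (SQ = 1/2)."""
        occ2, occ3 = m.occupancy(x, "cii"), m.occupancy(x, "ciii")
        reduced = m.pool_value(x, "qh2") + rq_cii @ occ2 + rq_ciii @ occ3
        total = (m.pool_value(x, "q") + m.pool_value(x, "qh2")
                 + bq_cii @ occ2 + bq_ciii @ occ3)
        return reduced / total if total > 0 else 0.0

    model.add_observer("qh2_fraction", qh2_fraction)
    model.add_observer("qh2_fraction_total", qh2_fraction_total)
    model.add_observer(
        "ros_rate_cii",
        lambda m, x: m.rates["k_ros_flavin"] * (fadh @ m.occupancy(x, "cii")))
    model.add_observer(
        "ros_rate_ciii",
        lambda m, x: m.rates["k_ros_qo"] * (sq_qo @ m.occupancy(x, "ciii")))
    model.add_observer(
        "sq_qo_fraction",
        lambda m, x: (sq_qo @ m.occupancy(x, "ciii")) / CIII_TOTAL)
    model.add_observer(
        "cii_oaa_fraction",
        lambda m, x: (oaa_bound @ m.occupancy(x, "cii")) / CII_TOTAL)
    model.add_observer("oaa", lambda m, x: m.pool_value(x, "oaa"))
    model.add_observer("psi", lambda m, x: m.psi(x))


def _base_model(rates: RateSet, clamped: dict, params: dict) -> Model:
    model = Model(MITO_POOLS, rates, clamped=clamped,
                  accumulators=ACCUMULATORS, params=params)
    cii_topo, ciii_topo = build_cii_topology(), build_ciii_topology()
    cii, ciii = enumerate_states(cii_topo), enumerate_states(ciii_topo)
    model.add_space(cii, cii_topo.rules, CII_TOTAL)
    model.add_space(ciii, ciii_topo.rules, CIII_TOTAL)
    # total ubiquinone: free Q + free QH2 + site-bound quinone is conserved
    poff = model.pool_slice.start
    idx = np.concatenate([
        np.arange(model.space_slice("cii").start, model.space_slice("cii").stop),
        np.arange(model.space_slice("ciii").start, model.space_slice("ciii").stop),
        [poff + model.pool_index["q"], poff + model.pool_index["qh2"]],
    ])
    w = np.concatenate([bound_quinone(cii), bound_quinone(ciii), [1.0, 1.0]])
    model.add_conservation(idx, w, poff + model.pool_index["q"])
    _register_chain_observers(model)
    return model


def build_isolated_cii_model(myxothiazol_fraction: float = 0.0,
                             fum_clamp: float = 0.10,
                             rates: RateSet | None = None) -> Model:
    """Functionally isolated complex II (rotenone + myxothiazol).

    Succinate and fumarate are buffered (clamped); the dicarboxylate site
    sees no oxaloacetate.  Complex III remains present with its ubiquinol
    binding scaled by the myxothiazol remaining fraction, providing the
    residual electron drain of partial inhibition.
    """
    r = RateSet(rates or default_chain_rates())
    r.setdefault("k_leak", 2.0)
    r = apply_inhibitor(r, "rotenone", 0.0)
    r = apply_inhibitor(r, "myxothiazol", myxothiazol_fraction)
    clamped = {"succ": 0.05, "fum": fum_clamp, "oaa": 0.0, "glu_ext": 0.0,
               "ca_out": 1e-4}
    model = _base_model(r, clamped, {"f_over_c": 500.0})
    return model


def build_isolated_mito_model(rates: RateSet | None = None,
                              matrix_rates: RateSet | None = None,
                              *,
                              succinate: float = 5.0,
                              glu_ext: float = 0.0,
                              uniporter: bool = True,
                              uniporter_form: str = "verbatim") -> Model:
    """Isolated mitochondria on succinate + rotenone (glutamate-sweep setup).

    Succinate and external glutamate are buffered; fumarate, malate,
    oxaloacetate, aspartate, alpha-ketoglutarate, matrix glutamate and the
    NAD pool are dynamic.  Rotenone removes the complex-I input, so MDH
    equilibrium (with NADH accumulating) governs oxaloacetate levels.
    """
    r = RateSet(rates or default_chain_rates())
    r.update(matrix_rates or default_matrix_rates())
    r = apply_inhibitor(r, "rotenone", 0.0)
    clamped = {"succ": succinate, "glu_ext": glu_ext}
    if not uniporter:
        clamped["ca_out"] = 1e-4
    params = {"f_over_c": 500.0, "p_ca": 0.005, "ca_in": 1e-4}
    model = _base_model(r, clamped, params)
    for rxn in _matrix_reactions():
        model.add_reaction(rxn)
    poff = model.pool_slice.start
    nadh_i, nad_i = (poff + model.pool_index["nadh"], poff + model.pool_index["nad"])
    model.add_conservation([nadh_i, nad_i], [1.0, 1.0], nad_i)
    if uniporter:
        model.add_custom(UniporterFlux(form=uniporter_form))
    return model


def default_mito_initial(model: Model, psi0: float = 120.0) -> np.ndarray:
    pools = {"q": 3.0, "qh2": 0.5, "fum": 1e-3, "mal": 1e-3, "asp": 1.0,
             "nadh": 0.2, "nad": NAD_TOTAL - 0.2, "ca_out": 1e-4}
    return model.initial_state(pools, psi0=psi0)


# --------------------------------------------------------------------------
# scenario: ROS of functionally isolated complex II vs succinate (Fig-2 type)
# --------------------------------------------------------------------------

def simulate_isolated_cii(succinate_grid_um: Sequence[float],
                          myxothiazol_fraction: float,
                          *,
                          rates: RateSet | None = None,
                          fum_clamp: float = 0.10,
                          normalize: bool = True,
                          reference_fraction: float = 4e-8,
                          tol: float = 1e-8,
                          t_cap: float = 3e7) -> pd.DataFrame:
    """Steady flavin-site ROS rate vs succinate for isolated complex II.

    Each grid point is relaxed from the same fully oxidised initial state
    (the system latches near complete pool reduction on this timescale,
    so seeding one point from another would mix branch identities), then
    Newton-polished to the exact steady state.  Returns a DataFrame with
    columns ``succinate_um``, ``ros_rate`` (raw, nmol mg^-1 s^-1) and,
    if ``normalize``, ``ros_norm`` -- the curve normalised to the grid
    maximum of the reference (``myxothiazol_fraction = 4e-8``) curve.
    """
    grid = np.asarray(list(succinate_grid_um), dtype=float)
    if np.any(grid <= 0):
        raise ValueError("succinate concentrations must be positive")

    def raw_curve(fraction: float) -> np.ndarray:
        model = build_isolated_cii_model(fraction, fum_clamp=fum_clamp,
                                         rates=rates)
        out = np.empty(grid.size)
        for i, c_um in enumerate(grid):
            x = default_mito_initial(model, psi0=0.0)
            model.clamped["succ"] = um_to_amount(c_um)
            model.set_pool(x, "succ", model.clamped["succ"])
            res = relax_to_steady(model, x, tol=tol, t_cap=t_cap)
            if not res.converged:  # pragma: no cover
                raise RuntimeError(
                    f"no steady state at succinate {c_um} uM "
                    f"(residual {res.residual:.2e})")
            out[i] = model.observables(res.x)["ros_rate_cii"]
        return out

    ros = raw_curve(myxothiazol_fraction)
    df = pd.DataFrame({"succinate_um": grid, "ros_rate": ros})
    if normalize:
        if myxothiazol_fraction == reference_fraction:
            ref_max = ros.max()
        else:
            ref_max = raw_curve(reference_fraction).max()
        df["ros_norm"] = ros / ref_max
    return df


# --------------------------------------------------------------------------
# scenario: Ca2+ pulse trains (Fig-6 type)
# --------------------------------------------------------------------------

def simulate_ca_pulses(n_pulses: int,
                       pulse_amount: float = 20.0,
                       with_glutamate: bool = False,
                       *,
                       glu_ext: float = 0.004,
                       pulse_interval: float = 300.0,
                       pre_time: float = 600.0,
                       dt_report: float = 0.5,
                       rates: RateSet | None = None,
                       matrix_rates: RateSet | None = None) -> pd.DataFrame:
    """Membrane potential and external Ca2+ under repeated 20-nmol pulses.

    The model is first relaxed to its pre-pulse steady state (rotenone +
    succinate, with or without buffered external glutamate); each pulse
    then instantaneously raises external Ca2+ by ``pulse_amount`` (nmol
    per chamber, == nmol/mg at 1 mg protein).  Matrix Ca2+ is held
    constant; uptake discharges psi, which recovers by electron-transport
    pumping.  Returns a time series of psi, external Ca2+ and ROS rates.
    """
    from scipy.integrate import solve_ivp

    model = build_isolated_mito_model(
        rates=rates, matrix_rates=matrix_rates,
        glu_ext=glu_ext if with_glutamate else 0.0)
    x = default_mito_initial(model)
    res = relax_to_steady(model, x, t_cap=max(pre_time, 1e6))
    x = res.x

    frames = []
    t0 = 0.0
    for pulse in range(max(n_pulses, 0) + 1):
        if pulse > 0:
            model.set_pool(x, "ca_out", model.pool_value(x, "ca_out")
                           + pulse_amount)
        t_end = t0 + (pulse_interval if n_pulses else pulse_interval)
        t_eval = np.arange(t0, t_end + dt_report / 2, dt_report)
        sol = solve_ivp(model.rhs, (t0, t_end), x, method="BDF",
                        t_eval=t_eval, rtol=1e-8, atol=1e-10,
                        jac=model.jacobian)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integration failed: {sol.message}")
        obs = [model.observables(sol.y[:, j]) for j in range(sol.y.shape[1])]
        frame = pd.DataFrame(obs)
        frame.insert(0, "time", sol.t)
        frame["ca_out"] = [model.pool_value(sol.y[:, j], "ca_out")
                           for j in range(sol.y.shape[1])]
        frame["pulse"] = pulse
        frames.append(frame)
        x = sol.y[:, -1].copy()
        t0 = t_end
        if n_pulses == 0:
            break
    return pd.concat(frames, ignore_index=True)
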