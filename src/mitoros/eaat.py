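"""Plasma-membrane glutamate transport (EAAT cycle).

One catalytic cycle moves 1 glutamate + 3 Na+ + 1 H+ into the cell and
1 K+ out, translocating a net +2 charge inward, so uptake is favoured by
a negative membrane potential.  Outer (and inner) ion binding is ordered
-- sodium first, then proton and glutamate, then the remaining sodium --
and treated as a fast equilibrium; the two conformational translocation
steps (fully-loaded carrier inward; potassium-bound carrier outward) are
the slow transitions, each with a symmetric voltage split of the charge
it moves.  The cycle is reversible: with unfavourable gradients the
transporter runs backwards (glutamate release).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import RT_F

__all__ = [
    "IonEnvironment",
    "BindingConstants",
    "EaatRates",
    "EaatPool",
    "outer_binding_fraction",
    "inner_binding_fraction",
    "eaat_cycle_flux",
    "CHARGE_PER_CYCLE",
]

#: net charge moved into the cell per completed forward cycle
CHARGE_PER_CYCLE = 2.0
#: voltage-coupled charge assigned to the loaded translocation step; the
#: K+ return is treated as electroneutral, so the whole net +2 moves with
#: the loaded carrier (this keeps uptake monotonically enhanced by
#: hyperpolarisation, as observed, while the cycle's reversal potential
#: depends only on the sum of the two charges)
Q_LOADED = 2.0
Q_RETURN = 0.0


@dataclass
class IonEnvironment:
    """Ion and substrate concentrations (mM) and membrane potential (mV).

    ``vm`` is the plasma-membrane potential, negative inside at rest.
    """

    na_o: float = 140.0
    na_i: float = 10.0
    k_o: float = 5.0
    k_i: float = 140.0
    h_o: float = 4.0e-5   # pH 7.4
    h_i: float = 4.0e-5
    glu_o: float = 1e-6
    glu_i: float = 1e-3
    vm: float = -70.0

    def __post_init__(self) -> None:
        for f in ("na_o", "na_i", "k_o", "k_i", "h_o", "h_i",
                  "glu_o", "glu_i"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class BindingConstants:
    """Dissociation constants (mM) of the fast-equilibrium binding steps.

    Defaults put half-maximal uptake near 20 uM external glutamate with
    physiological sodium.
    """

    k_na1: float = 25.0
    k_na2: float = 25.0
    k_na3: float = 40.0
    k_h: float = 2.0e-5
    k_glu: float = 0.08
    k_k: float = 20.0

    def __post_init__(self) -> None:
        for f in ("k_na1", "k_na2", "k_na3", "k_h", "k_glu", "k_k"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class EaatRates:
    """Rate constants (s^-1) of the two slow conformational steps.

    Equal forward/backward products keep the cycle thermodynamically
    consistent: zero net flux coincides with zero combined
    electrochemical driving force.
    """

    k_load_f: float = 50.0   # loaded outward -> inward
    k_load_r: float = 50.0
    k_ret_f: float = 500.0   # K+-bound inward -> outward (rate-limiting)
    k_ret_r: float = 500.0


@dataclass
class EaatPool:
    """Slow-state occupancies; fast binding states are fractions of them."""

    t_out: float = 0.5
    t_in: float = 0.5

    @property
    def total(self) -> float:
        return self.t_out + self.t_in

    def state_fractions(self, env: IonEnvironment,
                        kd: BindingConstants | None = None) -> dict[str, float]:
        """Occupancy of the named cycle states (sums to ``total``)."""
        kd = kd or BindingConstants()
        po = _site_fractions(env.na_o, env.h_o, env.glu_o, env.k_o, kd)
        pi = _site_fractions(env.na_i, env.h_i, env.glu_i, env.k_i, kd)
        return {
            "T": self.t_out * po["free"],
            "T.Na": self.t_out * po["na"],
            "T(H).Na2": self.t_out * po["na2h"],
            "T(H).Na2.Glu": self.t_out * po["na_h_glu"],
            "T(H).Na3.Glu": self.t_out * po["loaded"],
            "T.K": self.t_out * po["k"],
            "T'": self.t_in * (pi["free"] + pi["na"] + pi["na2h"]
                               + pi["na_h_glu"]),
            "T'(H).Na3.Glu": self.t_in * pi["loaded"],
            "T'.K": self.t_in * pi["k"],
        }


def _site_fractions(na: float, h: float, glu: float, k: float,
                    kd: BindingConstants) -> dict[str, float]:
    """Fast-equilibrium distribution over binding states on one side.

    Ordered sequential loading with a true binding polynomial:
    T -> T.Na -> T(H).Na2 -> T(H).Na2.Glu -> T(H).Na3.Glu, with K+
    binding to the free carrier as the exclusive alternative.  Using the
    partition function (rather than a product of independent saturation
    factors) keeps every state ratio exactly mass-action, which is what
    makes the full cycle thermodynamically consistent.  The loaded
    fraction still vanishes without sodium however much glutamate is
    present.
    """
    x1 = na / kd.k_na1
    x2 = na / kd.k_na2
    xh = h / kd.k_h
    xg = glu / kd.k_glu
    x3 = na / kd.k_na3
    xk = k / kd.k_k
    t_na = x1
    t_na2h = x1 * x2 * xh
    t_glu = t_na2h * xg
    t_loaded = t_glu * x3
    z = 1.0 + t_na + t_na2h + t_glu + t_loaded + xk
    return {"free": 1.0 / z, "na": t_na / z, "na2h": t_na2h / z,
            "na_h_glu": t_glu / z, "loaded": t_loaded / z, "k": xk / z}


def outer_binding_fraction(env: IonEnvironment,
                           kd: BindingConstants | None = None) -> float:
    """Fraction of outward-facing transporter that is fully loaded.

    Sequential-equilibrium binding polynomial over the ordered steps
    (Na+, then H+/Na+, glutamate, Na+): zero whenever external sodium is
    zero, approaching one when every ligand saturates its step.
    """
    kd = kd or BindingConstants()
    return _site_fractions(env.na_o, env.h_o, env.glu_o, env.k_o, kd)["loaded"]


def inner_binding_fraction(env: IonEnvironment,
                           kd: BindingConstants | None = None) -> float:
    """Fully loaded fraction of the inward-facing transporter."""
    kd = kd or BindingConstants()
    return _site_fractions(env.na_i, env.h_i, env.glu_i, env.k_i, kd)["loaded"]


def _vm_factor(charge: float, vm: float, rt_f: float) -> float:
    """Symmetric voltage split: exp(-charge*vm/(2*RT/F)), capped."""
    arg = -charge * vm / (2.0 * rt_f)
    return math.exp(max(min(arg, 60.0), -60.0))


def eaat_cycle_flux(env: IonEnvironment, pool: EaatPool,
                    rates: EaatRates | None = None,
                    kd: BindingConstants | None = None,
                    rt_f: float = RT_F) -> tuple[float, float, float, float]:
    """Instantaneous EAAT fluxes.

    Returns ``(glu_influx, charge_influx, j_load, j_return)`` where
    ``glu_influx`` is the net rate of the loaded translocation step
    (glutamate delivered to the cytosol per time, negative when the
    transporter runs in reverse), ``charge_influx`` is the
    stoichiometrically coupled net charge entry ``2 * glu_influx``, and
    the last two are the individual slow-step net rates (they agree at
    cycle steady state).
    """
    rates = rates or EaatRates()
    kd = kd or BindingConstants()
    po = _site_fractions(env.na_o, env.h_o, env.glu_o, env.k_o, kd)
    pi = _site_fractions(env.na_i, env.h_i, env.glu_i, env.k_i, kd)
    j_load = (rates.k_load_f * pool.t_out * po["loaded"]
              * _vm_factor(Q_LOADED, env.vm, rt_f)
              - rates.k_load_r * pool.t_in * pi["loaded"]
              * _vm_factor(-Q_LOADED, env.vm, rt_f))
    j_ret = (rates.k_ret_f * pool.t_in * pi["k"]
             * _vm_factor(Q_RETURN, env.vm, rt_f)
             - rates.k_ret_r * pool.t_out * po["k"]
             * _vm_factor(-Q_RETURN, env.vm, rt_f))
    return j_load, CHARGE_PER_CYCLE * j_load, j_load, j_ret
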