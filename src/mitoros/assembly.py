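"""Coupled ODE assembly: respiratory complexes + metabolite pools + membrane.

A :class:`Model` packs one state vector out of

* the microstate occupancies of each respiratory complex,
* a list of pool species (free ubiquinone/ubiquinol, matrix metabolites,
  external Ca2+, cumulative ROS/electron counters, ...),
* the inner-membrane potential ``psi`` (mV, positive = energised).

Each time derivative is the sum of the reaction rates in which the
variable participates: microstate transition rules (see
:mod:`mitoros.microstates`), mass-action pool reactions, and custom
fluxes with bespoke rate laws (Ca2+ uniporter, ATP synthase, ...).
Charge-translocating events feed ``d(psi)/dt = f_over_c * sum(charges)``
minus the proton-leak conductance term ``k_leak * psi`` (leak expressed
directly in mV/s per mV, matching its printed s^-1 mV^-1 units).

Pool species may be *clamped* (buffered at a fixed value: derivative
forced to zero) or marked as *accumulators* (cumulative counters excluded
from steady-state residuals).
"""

from __future__ import annotations

import copy as _copy
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .constants import RT_F
from .microstates import CompiledRule, StateSpace, TransitionRule, compile_rules
from .rates import RateSet

__all__ = ["PoolReaction", "CustomFlux", "Model"]

_EXP_CAP = 60.0


def _psi_factor(charge: float, alpha: float, psi: float, rt_f: float) -> float:
    """exp(-charge*alpha*psi/rt_f), with the exponent capped for robustness
    against wild states probed by numerical Jacobians."""
    arg = -charge * alpha * psi / rt_f
    if arg > _EXP_CAP:
        arg = _EXP_CAP
    elif arg < -_EXP_CAP:
        arg = -_EXP_CAP
    return float(np.exp(arg))


@dataclass(frozen=True)
class PoolReaction:
    """Mass-action reaction between pool species.

    rate = k[rate_key] * prod(pool[r]**n for r, n in reactants)
           * exp(-charge * alpha * psi / RT_F)

    ``charge`` is the signed charge translocated per event (positive =
    potential-building); it both biases the rate and contributes to
    ``d(psi)/dt``.  Reversible reactions are written as two entries.
    """

    name: str
    rate_key: str
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    charge: float = 0.0
    alpha: float = 0.5

    @classmethod
    def make(cls, name, rate_key, reactants, products, charge=0.0, alpha=0.5):
        return cls(name, rate_key, tuple(dict(reactants).items()),
                   tuple(dict(products).items()), charge, alpha)


class CustomFlux:
    """A flux with an arbitrary rate law.

    Subclasses (or instances constructed with ``law``) implement
    ``rate(pools, psi, rates, params) -> float``; the flux then applies
    ``stoich`` increments to pools and ``charge`` per event to the
    membrane charge balance.
    """

    def __init__(self, name: str, stoich: Mapping[str, float],
                 charge: float = 0.0, law=None):
        self.name = name
        self.stoich = dict(stoich)
        self.charge = charge
        self._law = law

    def rate(self, pools: Mapping[str, float], psi: float,
             rates: Mapping[str, float], params: Mapping[str, float]) -> float:
        if self._law is None:
            raise NotImplementedError
        return self._law(pools, psi, rates, params)


@dataclass
class _Space:
    space: StateSpace
    rules: tuple[TransitionRule, ...]
    total: float
    compiled: list[CompiledRule] = field(default_factory=list)


class Model:
    """A complete ODE model over complexes, pools and membrane potential."""

    def __init__(
        self,
        pool_names: Sequence[str],
        rates: RateSet,
        *,
        clamped: Mapping[str, float] | None = None,
        accumulators: Sequence[str] = (),
        params: Mapping[str, float] | None = None,
        psi_dynamic: bool = True,
        rt_f: float = RT_F,
    ):
        self.pool_names = list(pool_names)
        self.pool_index = {n: i for i, n in enumerate(self.pool_names)}
        self.rates = RateSet(rates)
        self.clamped = dict(clamped or {})
        self.accumulators = set(accumulators)
        self.params = dict(params or {})
        self.psi_dynamic = psi_dynamic
        self.rt_f = rt_f
        self.spaces: list[_Space] = []
        self.reactions: list[PoolReaction] = []
        self.customs: list[CustomFlux] = []
        self.observers: dict[str, object] = {}
        self.conservations: list[tuple[np.ndarray, np.ndarray, float, int]] = []

    # --- construction -----------------------------------------------------

    def add_space(self, space: StateSpace, rules: Sequence[TransitionRule],
                  total: float) -> None:
        for rule in rules:
            if rule.rate_key not in self.rates:
                raise KeyError(
                    f"rule {rule.name!r}: missing rate constant {rule.rate_key!r}")
            for name, _ in rule.stoich:
                if name not in self.pool_index:
                    raise KeyError(
                        f"rule {rule.name!r}: unknown pool species {name!r}")
            for name in rule.env:
                if name not in self.pool_index:
                    raise KeyError(
                        f"rule {rule.name!r}: unknown env species {name!r}")
        self.spaces.append(
            _Space(space, tuple(rules), total, compile_rules(space, rules)))

    def add_reaction(self, reaction: PoolReaction) -> None:
        if reaction.rate_key not in self.rates:
            raise KeyError(f"reaction {reaction.name!r}: missing rate "
                           f"constant {reaction.rate_key!r}")
        for name, _ in reaction.reactants + reaction.products:
            if name not in self.pool_index:
                raise KeyError(
                    f"reaction {reaction.name!r}: unknown species {name!r}")
        self.reactions.append(reaction)

    def add_custom(self, flux: CustomFlux) -> None:
        for name in flux.stoich:
            if name not in self.pool_index:
                raise KeyError(f"flux {flux.name!r}: unknown species {name!r}")
        self.customs.append(flux)

    def add_observer(self, name: str, func) -> None:
        """Register ``func(model, x) -> float`` as a named observable."""
        self.observers[name] = func

    def add_conservation(self, indices, weights,
                         replace_index: int) -> None:
        """Declare a conserved linear combination ``w . x = const``.

        At steady-state solves the (singular) ODE row ``replace_index``
        is substituted by this constraint (with the constant read off the
        reference state), removing the null direction the conservation
        law creates.  Complex-occupancy totals are added automatically;
        pool-level invariants (total ubiquinone, NAD(H), adenine) are
        declared by the model builders.
        """
        self.conservations.append((
            np.asarray(indices, dtype=int),
            np.asarray(weights, dtype=float),
            int(replace_index)))

    def copy(self) -> "Model":
        """Shallow-structural copy safe for independent rate/clamp edits."""
        out = _copy.copy(self)
        out.rates = RateSet(self.rates)
        out.clamped = dict(self.clamped)
        out.params = dict(self.params)
        out.accumulators = set(self.accumulators)
        return out

    # --- state vector layout ----------------------------------------------

    @property
    def n_pools(self) -> int:
        return len(self.pool_names)

    @property
    def n_states(self) -> int:
        n = sum(s.space.n_states for s in self.spaces) + self.n_pools
        return n + (1 if self.psi_dynamic else 0)

    def space_slice(self, complex_id: str) -> slice:
        off = 0
        for s in self.spaces:
            if s.space.complex_id == complex_id:
                return slice(off, off + s.space.n_states)
            off += s.space.n_states
        raise KeyError(complex_id)

    @property
    def pool_slice(self) -> slice:
        off = sum(s.space.n_states for s in self.spaces)
        return slice(off, off + self.n_pools)

    @property
    def psi_index(self) -> int:
        if not self.psi_dynamic:
            raise ValueError("psi is not dynamic in this model")
        return self.n_states - 1

    def pool_value(self, x: np.ndarray, name: str) -> float:
        return float(x[self.pool_slice.start + self.pool_index[name]])

    def set_pool(self, x: np.ndarray, name: str, value: float) -> None:
        x[self.pool_slice.start + self.pool_index[name]] = value

    def occupancy(self, x: np.ndarray, complex_id: str) -> np.ndarray:
        return x[self.space_slice(complex_id)]

    def psi(self, x: np.ndarray) -> float:
        if self.psi_dynamic:
            return float(x[self.psi_index])
        return float(self.params.get("psi_fixed", 0.0))

    def initial_state(self, pool_values: Mapping[str, float] | None = None,
                      psi0: float = 0.0) -> np.ndarray:
        """All complex amount in the first (fully oxidised/empty) microstate."""
        x = np.zeros(self.n_states)
        off = 0
        for s in self.spaces:
            x[off] = s.total
            off += s.space.n_states
        vals = dict(pool_values or {})
        vals.update(self.clamped)
        for name, v in vals.items():
            self.set_pool(x, name, v)
        if self.psi_dynamic:
            x[self.psi_index] = psi0
        return x

    # --- right-hand side --------------------------------------------------

    def pools_dict(self, x: np.ndarray) -> dict[str, float]:
        vals = x[self.pool_slice]
        return dict(zip(self.pool_names, vals.tolist()))

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(x)
        pools = self.pools_dict(x)
        # clamped species are buffered: rate laws see the clamp value
        for name, v in self.clamped.items():
            pools[name] = v
        psi = self.psi(x)
        rt_f = self.rt_f
        rates = self.rates
        poff = self.pool_slice.start
        pidx = self.pool_index
        charge_flux = 0.0

        off = 0
        for s in self.spaces:
            n = s.space.n_states
            occ = x[off:off + n]
            docc = dx[off:off + n]
            for comp in s.compiled:
                rule = comp.rule
                k = rates[rule.rate_key]
                if k == 0.0:
                    continue
                r = k
                for name in rule.env:
                    r *= pools[name]
                if rule.charge != 0.0:
                    r *= _psi_factor(rule.charge, rule.alpha, psi, rt_f)
                rv = r * occ[comp.src]
                np.subtract.at(docc, comp.src, rv)
                np.add.at(docc, comp.dst, rv)
                total = float(rv.sum())
                for name, sto in comp.stoich_items:
                    dx[poff + pidx[name]] += sto * total
                if rule.charge != 0.0:
                    charge_flux += rule.charge * total
            off += n

        for rxn in self.reactions:
            k = rates[rxn.rate_key]
            if k == 0.0:
                continue
            r = k
            for name, n in rxn.reactants:
                c = pools[name]
                r *= c if n == 1.0 else c ** n
            if rxn.charge != 0.0:
                r *= _psi_factor(rxn.charge, rxn.alpha, psi, rt_f)
            for name, n in rxn.reactants:
                dx[poff + pidx[name]] -= n * r
            for name, n in rxn.products:
                dx[poff + pidx[name]] += n * r
            if rxn.charge != 0.0:
                charge_flux += rxn.charge * r

        for flux in self.customs:
            r = flux.rate(pools, psi, rates, self.params)
            for name, sto in flux.stoich.items():
                dx[poff + pidx[name]] += sto * r
            if flux.charge != 0.0:
                charge_flux += flux.charge * r

        for name in self.clamped:
            dx[poff + pidx[name]] = 0.0

        if self.psi_dynamic:
            f_over_c = self.params.get("f_over_c", 0.0)
            k_leak = self.rates.get("k_leak", 0.0)
            dx[self.psi_index] = f_over_c * charge_flux - k_leak * psi
        return dx

    # --- steady-state residual & sparsity ----------------------------------

    def residual_scale(self, x: np.ndarray) -> np.ndarray:
        """Per-variable scale for steady-state residuals."""
        scale = np.maximum(np.abs(x), 1e-2)
        if self.psi_dynamic:
            scale[self.psi_index] = max(abs(x[self.psi_index]), 10.0)
        return scale

    def steady_mask(self) -> np.ndarray:
        """Variables that must be stationary at a steady state."""
        mask = np.ones(self.n_states, dtype=bool)
        poff = self.pool_slice.start
        for name in self.accumulators:
            mask[poff + self.pool_index[name]] = False
        return mask

    def jac_sparsity(self):
        """Conservative Jacobian sparsity pattern (pools/psi rows dense)."""
        from scipy.sparse import lil_matrix

        n = self.n_states
        sp = lil_matrix((n, n), dtype=np.int8)
        poff = self.pool_slice.start
        off = 0
        for s in self.spaces:
            for comp in s.compiled:
                rule = comp.rule
                cols = (off + comp.src).tolist()
                rows = cols + (off + comp.dst).tolist()
                for rr in rows:
                    for cc in cols:
                        sp[rr, cc] = 1
                    for name in rule.env:
                        sp[rr, poff + self.pool_index[name]] = 1
                    if rule.charge != 0.0 and self.psi_dynamic:
                        sp[rr, self.psi_index] = 1
            off += s.space.n_states
        sp[poff:poff + self.n_pools, :] = 1
        if self.psi_dynamic:
            sp[self.psi_index, :] = 1
        return sp.tocsr()

    # --- analytic Jacobian --------------------------------------------------

    def jacobian(self, t: float, x: np.ndarray) -> np.ndarray:
        """Exact dense Jacobian of :meth:`rhs` (custom fluxes by FD)."""
        n = self.n_states
        J = np.zeros((n, n))
        pools = self.pools_dict(x)
        for name, v in self.clamped.items():
            pools[name] = v
        psi = self.psi(x)
        rt_f = self.rt_f
        rates = self.rates
        poff = self.pool_slice.start
        pidx = self.pool_index
        psi_i = self.psi_index if self.psi_dynamic else -1
        f_over_c = self.params.get("f_over_c", 0.0)
        charge_row = np.zeros(n)  # d(charge_flux)/dx

        def env_product(names, skip=None):
            p = 1.0
            for nm in names:
                if nm != skip:
                    p *= pools[nm]
            return p

        off = 0
        for s in self.spaces:
            ns = s.space.n_states
            occ = x[off:off + ns]
            for comp in s.compiled:
                rule = comp.rule
                k = rates[rule.rate_key]
                if k == 0.0:
                    continue
                pf = (_psi_factor(rule.charge, rule.alpha, psi, rt_f)
                      if rule.charge != 0.0 else 1.0)
                a = k * env_product(rule.env) * pf
                src_g = off + comp.src
                dst_g = off + comp.dst
                # d/d occupancy
                np.add.at(J, (src_g, src_g), -a)
                np.add.at(J, (dst_g, src_g), +a)
                rate_vec = a * occ[comp.src]
                total = float(rate_vec.sum())
                cols_extra: list[tuple[int, np.ndarray]] = []
                for nm in rule.env:
                    da = k * env_product(rule.env, skip=nm) * pf
                    cols_extra.append((poff + pidx[nm], da * occ[comp.src]))
                if rule.charge != 0.0 and self.psi_dynamic:
                    dpsi = -rule.charge * rule.alpha / rt_f
                    cols_extra.append((psi_i, rate_vec * dpsi))
                for col, dvec in cols_extra:
                    np.add.at(J[:, col], src_g, -dvec)
                    np.add.at(J[:, col], dst_g, +dvec)
                # pool side effects and charge flux derivatives
                for name, sto in comp.stoich_items:
                    row = poff + pidx[name]
                    J[row, src_g] += sto * a
                    for col, dvec in cols_extra:
                        J[row, col] += sto * float(dvec.sum())
                if rule.charge != 0.0:
                    charge_row[src_g] += rule.charge * a
                    for col, dvec in cols_extra:
                        charge_row[col] += rule.charge * float(dvec.sum())
            off += ns

        for rxn in self.reactions:
            k = rates[rxn.rate_key]
            if k == 0.0:
                continue
            pf = (_psi_factor(rxn.charge, rxn.alpha, psi, rt_f)
                  if rxn.charge != 0.0 else 1.0)
            conc = {nm: pools[nm] for nm, _ in rxn.reactants}
            r = k * pf
            for nm, nn in rxn.reactants:
                r *= conc[nm] if nn == 1.0 else conc[nm] ** nn
            cols: list[tuple[int, float]] = []
            for nm, nn in rxn.reactants:
                rest = k * pf
                for nm2, n2 in rxn.reactants:
                    if nm2 == nm:
                        if n2 != 1.0:
                            rest *= n2 * conc[nm2] ** (n2 - 1.0)
                    else:
                        rest *= conc[nm2] if n2 == 1.0 else conc[nm2] ** n2
                cols.append((poff + pidx[nm], rest))
            if rxn.charge != 0.0 and self.psi_dynamic:
                cols.append((psi_i, r * (-rxn.charge * rxn.alpha / rt_f)))
            for col, dr in cols:
                for nm, nn in rxn.reactants:
                    J[poff + pidx[nm], col] -= nn * dr
                for nm, nn in rxn.products:
                    J[poff + pidx[nm], col] += nn * dr
                if rxn.charge != 0.0:
                    charge_row[col] += rxn.charge * dr

        for flux in self.customs:
            deps = list(getattr(flux, "depends", flux.stoich.keys()))
            r0 = flux.rate(pools, psi, rates, self.params)
            cols = []
            for nm in deps:
                h = 1e-7 * max(abs(pools[nm]), 1e-8)
                p2 = dict(pools)
                p2[nm] = pools[nm] + h
                cols.append((poff + pidx[nm],
                             (flux.rate(p2, psi, rates, self.params) - r0) / h))
            if self.psi_dynamic:
                h = 1e-7 * max(abs(psi), 1e-3)
                cols.append((psi_i,
                             (flux.rate(pools, psi + h, rates, self.params)
                              - r0) / h))
            for col, dr in cols:
                for nm, sto in flux.stoich.items():
                    J[poff + pidx[nm], col] += sto * dr
                if flux.charge != 0.0:
                    charge_row[col] += flux.charge * dr

        if self.psi_dynamic:
            J[psi_i, :] = f_over_c * charge_row
            J[psi_i, psi_i] -= self.rates.get("k_leak", 0.0)
        for name in self.clamped:
            i = poff + pidx[name]
            J[i, :] = 0.0
            J[:, i] = 0.0  # rhs reads the buffered value, not the state entry
        return J

    # --- steady-state algebraic system --------------------------------------

    def _touched_pools(self) -> set[str]:
        """Pools whose derivative row is structurally nonzero."""
        touched: set[str] = set()
        for s in self.spaces:
            for rule in s.rules:
                touched.update(name for name, _ in rule.stoich)
        for rxn in self.reactions:
            touched.update(name for name, _ in rxn.reactants)
            touched.update(name for name, _ in rxn.products)
        for flux in self.customs:
            touched.update(flux.stoich)
        return touched

    def _steady_structure(self, x_ref: np.ndarray):
        poff = self.pool_slice.start
        pins: list[tuple[int, float]] = []
        for name, v in self.clamped.items():
            pins.append((poff + self.pool_index[name], v))
        touched = self._touched_pools()
        for name in self.pool_names:
            i = poff + self.pool_index[name]
            if name in self.accumulators:
                pins.append((i, float(x_ref[i])))
            elif name not in self.clamped and name not in touched:
                pins.append((i, float(x_ref[i])))
        space_rows = []
        off = 0
        for s in self.spaces:
            space_rows.append((off, s.space.n_states,
                               float(x_ref[off:off + s.space.n_states].sum())))
            off += s.space.n_states
        cons = [(idx, w, float(w @ x_ref[idx]), ri)
                for idx, w, ri in self.conservations]
        pin_idx = np.array([i for i, _ in pins], dtype=int)
        pin_val = np.array([v for _, v in pins])
        return pin_idx, pin_val, space_rows, cons

    def steady_function(self, x_ref: np.ndarray):
        """Algebraic system F(x) = 0 whose roots are steady states.

        ODE rows made singular by conservation laws, clamps, accumulators
        or structurally inert pools are replaced by the corresponding
        pinning/conservation equations, yielding a square nonsingular
        system suitable for Newton polishing of a relaxed trajectory.
        """
        pin_idx, pin_val, space_rows, cons = self._steady_structure(x_ref)

        def func(x):
            f = self.rhs(0.0, x)
            f[pin_idx] = x[pin_idx] - pin_val
            for start, n, total in space_rows:
                f[start] = x[start:start + n].sum() - total
            for idx, w, total, ri in cons:
                f[ri] = float(w @ x[idx]) - total
            return f

        return func

    def steady_jacobian(self, x_ref: np.ndarray):
        """Analytic Jacobian of :meth:`steady_function`."""
        pin_idx, pin_val, space_rows, cons = self._steady_structure(x_ref)

        def jac(x):
            J = self.jacobian(0.0, x)
            J[pin_idx, :] = 0.0
            J[pin_idx, pin_idx] = 1.0
            for start, n, _ in space_rows:
                J[start, :] = 0.0
                J[start, start:start + n] = 1.0
            for idx, w, _, ri in cons:
                J[ri, :] = 0.0
                J[ri, idx] = w
            return J

        return jac

    # --- observables --------------------------------------------------------

    def observables(self, x: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, func in self.observers.items():
            out[name] = float(func(self, x))
        return out
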