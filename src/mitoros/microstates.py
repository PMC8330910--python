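"""Combinatorial redox-state bookkeeping for respiratory complexes.

A respiratory complex is modelled as a set of fixed electron carriers and
ligand-binding sites (:class:`RedoxCenter`), each with a small number of
occupancy/redox levels.  The joint state of a complex is one level per
center (:class:`MicroState`), and the full enumeration of joint states
(:class:`StateSpace`) supplies the ODE variables of the respiratory-chain
core: the model tracks the amount of complex residing in each microstate.

Chemistry is expressed as :class:`TransitionRule` objects: a partial
assignment of center levels (the source pattern) maps to another partial
assignment (the target pattern) at a mass-action rate.  The same rule is
applied uniformly to every microstate matching its source pattern, so the
number of rate constants stays far below the number of states.  Rules may
consume or produce pool species (ubiquinone, succinate, ...), translocate
charge across the membrane (making the rate depend on the membrane
potential), and divert electrons to superoxide.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .constants import RT_F

__all__ = [
    "RedoxCenter",
    "TransitionRule",
    "ComplexTopology",
    "StateSpace",
    "CompiledRule",
    "enumerate_states",
    "compile_rules",
    "build_rhs",
    "topology_to_dict",
    "topology_from_dict",
]


@dataclass(frozen=True)
class RedoxCenter:
    """One carrier or site inside a complex.

    Parameters
    ----------
    name:
        Label used by transition rules (e.g. ``"Qo"``, ``"bL"``, ``"flavin"``).
    levels:
        Ordered level labels, e.g. ``("empty", "Q", "SQ", "QH2")`` for a
        quinone-binding site or ``("ox", "red")`` for a one-electron heme.
    electrons:
        Electron content of each level, used for electron-balance audits.
        Defaults to zero for every level.
    """

    name: str
    levels: tuple[str, ...]
    electrons: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"center {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"center {self.name!r} has duplicate level labels")
        if self.electrons is not None and len(self.electrons) != len(self.levels):
            raise ValueError(f"center {self.name!r}: electrons/levels length mismatch")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise KeyError(f"center {self.name!r} has no level {label!r}") from None


def _freeze(mapping: Mapping[str, object] | None) -> tuple[tuple[str, object], ...]:
    if not mapping:
        return ()
    return tuple(sorted(mapping.items()))


@dataclass(frozen=True)
class TransitionRule:
    """A mass-action transition applied uniformly over matching microstates.

    ``source`` and ``target`` are partial assignments ``{center: level}``;
    every microstate agreeing with ``source`` transitions to the microstate
    obtained by substituting ``target`` (centers absent from both patterns
    keep their level).  The instantaneous rate for one matching state is::

        k[rate_key] * occupancy(state) * prod(pool[e] for e in env) * psi_factor

    where ``psi_factor = exp(-charge * alpha * psi / RT_F)`` accounts for
    charge moved across the membrane (``charge > 0`` builds the potential,
    and a positive potential opposes the step).

    ``stoich`` lists signed increments of pool species per event (e.g.
    ``{"qh2": -1}`` for ubiquinol binding).  ``protons_out`` counts protons
    released to the positive side per event (bookkeeping only; the energetic
    coupling is carried by ``charge``).  ``ros_site`` tags superoxide-producing
    transitions with the site label.
    """

    name: str
    source: tuple[tuple[str, str], ...]
    target: tuple[tuple[str, str], ...]
    rate_key: str
    env: tuple[str, ...] = ()
    stoich: tuple[tuple[str, float], ...] = ()
    charge: float = 0.0
    alpha: float = 0.5
    protons_out: float = 0.0
    ros_site: str | None = None

    @classmethod
    def make(
        cls,
        name: str,
        source: Mapping[str, str],
        target: Mapping[str, str],
        rate_key: str,
        *,
        env: Sequence[str] = (),
        stoich: Mapping[str, float] | None = None,
        charge: float = 0.0,
        alpha: float = 0.5,
        protons_out: float = 0.0,
        ros_site: str | None = None,
    ) -> "TransitionRule":
        return cls(
            name=name,
            source=_freeze(source),
            target=_freeze(target),
            rate_key=rate_key,
            env=tuple(env),
            stoich=_freeze(stoich),
            charge=charge,
            alpha=alpha,
            protons_out=protons_out,
            ros_site=ros_site,
        )

    @property
    def source_dict(self) -> dict[str, str]:
        return dict(self.source)

    @property
    def target_dict(self) -> dict[str, str]:
        return dict(self.target)

    @property
    def stoich_dict(self) -> dict[str, float]:
        return dict(self.stoich)


@dataclass(frozen=True)
class ComplexTopology:
    """Centers plus the transition rules acting on them."""

    complex_id: str
    centers: tuple[RedoxCenter, ...]
    rules: tuple[TransitionRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.centers:
            raise ValueError("topology needs at least one center")
        names = [c.name for c in self.centers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate center names")
        by_name = {c.name: c for c in self.centers}
        for rule in self.rules:
            for cname, level in rule.source + rule.target:
                if cname not in by_name:
                    raise ValueError(
                        f"rule {rule.name!r} references unknown center {cname!r}"
                    )
                by_name[cname].level_index(level)  # raises on bad level

    def center(self, name: str) -> RedoxCenter:
        for c in self.centers:
            if c.name == name:
                return c
        raise KeyError(name)


class StateSpace:
    """Full enumeration of the microstates of one complex.

    States are ordered lexicographically over center levels (the first
    center is the slowest index), so state ``i`` decodes uniquely into one
    level per center and vice versa.
    """

    def __init__(self, topology: ComplexTopology):
        self.topology = topology
        self.complex_id = topology.complex_id
        self.centers = topology.centers
        shape = tuple(c.n_levels for c in self.centers)
        self.shape = shape
        self.n_states = int(np.prod(shape))
        grids = [range(n) for n in shape]
        self.states = np.array(list(itertools.product(*grids)), dtype=np.int64)
        # strides for lexicographic ravel: index = sum(level * stride)
        strides = np.ones(len(shape), dtype=np.int64)
        for i in range(len(shape) - 2, -1, -1):
            strides[i] = strides[i + 1] * shape[i + 1]
        self.strides = strides
        self._center_index = {c.name: i for i, c in enumerate(self.centers)}

    def center_axis(self, name: str) -> int:
        return self._center_index[name]

    def state_index(self, levels: Sequence[int]) -> int:
        return int(np.dot(np.asarray(levels, dtype=np.int64), self.strides))

    def state_label(self, index: int) -> str:
        levels = self.states[index]
        return "|".join(
            f"{c.name}={c.levels[l]}" for c, l in zip(self.centers, levels)
        )

    def labels(self) -> list[str]:
        return [self.state_label(i) for i in range(self.n_states)]

    def level_occupancy(self, occupancy: np.ndarray, center: str, level: str) -> float:
        """Total occupancy of all microstates with ``center`` at ``level``."""
        ax = self.center_axis(center)
        lv = self.topology.center(center).level_index(level)
        mask = self.states[:, ax] == lv
        return float(np.dot(mask, occupancy))

    def electron_content(self) -> np.ndarray:
        """Electrons stored in each microstate (per unit occupancy)."""
        out = np.zeros(self.n_states)
        for ax, c in enumerate(self.centers):
            e = np.zeros(c.n_levels) if c.electrons is None else np.asarray(c.electrons)
            out += e[self.states[:, ax]]
        return out

    def level_indicator(self, center: str, level: str) -> np.ndarray:
        ax = self.center_axis(center)
        lv = self.topology.center(center).level_index(level)
        return (self.states[:, ax] == lv).astype(float)


def enumerate_states(topology: ComplexTopology) -> StateSpace:
    """Enumerate the Cartesian product of center levels, lexicographically."""
    return StateSpace(topology)


@dataclass
class CompiledRule:
    """A rule resolved to explicit (source state, target state) index pairs."""

    rule: TransitionRule
    src: np.ndarray  # indices of matching source states
    dst: np.ndarray  # corresponding target state indices
    stoich_items: tuple[tuple[str, float], ...] = field(init=False)

    def __post_init__(self) -> None:
        self.stoich_items = self.rule.stoich


def compile_rules(
    space: StateSpace, rules: Sequence[TransitionRule]
) -> list[CompiledRule]:
    """Resolve pattern rules into explicit state-index transition lists."""
    compiled = []
    for rule in rules:
        mask = np.ones(space.n_states, dtype=bool)
        for cname, level in rule.source:
            ax = space.center_axis(cname)
            lv = space.topology.center(cname).level_index(level)
            mask &= space.states[:, ax] == lv
        src = np.nonzero(mask)[0]
        levels = space.states[src].copy()
        for cname, level in rule.target:
            ax = space.center_axis(cname)
            lv = space.topology.center(cname).level_index(level)
            levels[:, ax] = lv
        dst = levels @ space.strides
        compiled.append(CompiledRule(rule=rule, src=src, dst=dst))
    return compiled


def rule_rate(
    compiled: CompiledRule,
    k: float,
    occupancy: np.ndarray,
    env: Mapping[str, float],
    psi: float,
    rt_f: float = RT_F,
) -> np.ndarray:
    """Per-source-state transition rates for one compiled rule."""
    rule = compiled.rule
    rate = k
    for name in rule.env:
        rate *= env[name]
    if rule.charge != 0.0:
        rate *= np.exp(-rule.charge * rule.alpha * psi / rt_f)
    return rate * occupancy[compiled.src]


def build_rhs(
    space: StateSpace,
    rules: Sequence[TransitionRule],
    rates: Mapping[str, float],
    rt_f: float = RT_F,
):
    """Compile ``rules`` into a derivative evaluator for one complex.

    Returns ``f(occupancy, env, psi) -> (d_occupancy, pool_fluxes, charge_flux)``
    where ``pool_fluxes`` maps pool species to net production rates and
    ``charge_flux`` is the net charge translocated per time (positive =
    potential-building).  The occupancy derivative sums to zero exactly:
    every event moves occupancy from one microstate to another.
    """
    for rule in rules:
        if rule.rate_key not in rates:
            raise KeyError(
                f"rule {rule.name!r}: missing rate constant {rule.rate_key!r}"
            )
    compiled = compile_rules(space, rules)

    def rhs(occupancy, env, psi=0.0):
        docc = np.zeros(space.n_states)
        pool_fluxes: dict[str, float] = {}
        charge_flux = 0.0
        for comp in compiled:
            r = rule_rate(comp, rates[comp.rule.rate_key], occupancy, env, psi, rt_f)
            np.subtract.at(docc, comp.src, r)
            np.add.at(docc, comp.dst, r)
            total = float(r.sum())
            for name, s in comp.stoich_items:
                pool_fluxes[name] = pool_fluxes.get(name, 0.0) + s * total
            if comp.rule.charge != 0.0:
                charge_flux += comp.rule.charge * total
        return docc, pool_fluxes, charge_flux

    return rhs


# --------------------------------------------------------------------------
# JSON serialisation
# --------------------------------------------------------------------------

def topology_to_dict(topology: ComplexTopology) -> dict:
    """JSON-ready document describing a topology and its rules."""
    return {
        "complex_id": topology.complex_id,
        "centers": [
            {"name": c.name, "levels": list(c.levels),
             "electrons": None if c.electrons is None else list(c.electrons)}
            for c in topology.centers
        ],
        "rules": [
            {"name": r.name, "source": dict(r.source), "target": dict(r.target),
             "rate_key": r.rate_key, "env": list(r.env),
             "stoich": dict(r.stoich), "charge": r.charge, "alpha": r.alpha,
             "protons_out": r.protons_out, "ros_site": r.ros_site}
            for r in topology.rules
        ],
    }


def topology_from_dict(document: dict) -> ComplexTopology:
    """Inverse of :func:`topology_to_dict` (validates on construction)."""
    centers = tuple(
        RedoxCenter(c["name"], tuple(c["levels"]),
                    None if c.get("electrons") is None
                    else tuple(c["electrons"]))
        for c in document["centers"])
    rules = tuple(
        TransitionRule.make(
            r["name"], r["source"], r["target"], r["rate_key"],
            env=r.get("env", ()), stoich=r.get("stoich"),
            charge=r.get("charge", 0.0), alpha=r.get("alpha", 0.5),
            protons_out=r.get("protons_out", 0.0),
            ros_site=r.get("ros_site"))
        for r in document["rules"])
    return ComplexTopology(document["complex_id"], centers, rules)
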