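"""Rate-constant sets and respiratory-chain inhibitors.

Bimolecular constants are in (nmol/mg)^-1 s^-1, unimolecular in s^-1.
Classical inhibitors act by scaling specific constants: rotenone removes
the complex-I electron input (quinone binding to complex I set to zero),
myxothiazol scales ubiquinol binding at the Qo site of complex III, and
antimycin blocks both ubiquinone binding and dissociation at the Qi
("N") site.  Partial inhibition is a remaining-activity fraction applied
to the targeted constants.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

__all__ = ["RateSet", "apply_inhibitor", "INHIBITOR_TARGETS"]


class RateSet(dict):
    """Mapping rate_constant_key -> value; all values must be >= 0."""

    def __init__(self, values: Mapping[str, float] | None = None, **kw: float):
        super().__init__()
        merged = dict(values or {})
        merged.update(kw)
        for k, v in merged.items():
            self[k] = v

    def __setitem__(self, key: str, value: float) -> None:
        value = float(value)
        if value < 0:
            raise ValueError(f"rate constant {key!r} must be >= 0, got {value}")
        super().__setitem__(key, value)

    def copy(self) -> "RateSet":
        return RateSet(self)

    def scaled(self, keys: Iterable[str], factor: float) -> "RateSet":
        out = self.copy()
        for k in keys:
            out[k] = self[k] * factor
        return out


#: rate keys targeted by each inhibitor
INHIBITOR_TARGETS: dict[str, tuple[str, ...]] = {
    "rotenone": ("k_ci",),
    "myxothiazol": ("k_qo_on",),
    "antimycin": ("k_qi_on", "k_qi_off", "k_qi_qh2_on", "k_qi_qh2_off"),
}


def apply_inhibitor(
    rates: RateSet, inhibitor: str, remaining_fraction: float = 0.0
) -> RateSet:
    """Return a copy of ``rates`` with the inhibitor's targets scaled.

    ``remaining_fraction`` is the residual activity in [0, 1]; 0 is a
    complete block.
    """
    if inhibitor not in INHIBITOR_TARGETS:
        raise ValueError(
            f"unknown inhibitor {inhibitor!r}; known: {sorted(INHIBITOR_TARGETS)}"
        )
    if not 0.0 <= remaining_fraction <= 1.0:
        raise ValueError("remaining_fraction must be within [0, 1]")
    return rates.scaled(INHIBITOR_TARGETS[inhibitor], remaining_fraction)
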