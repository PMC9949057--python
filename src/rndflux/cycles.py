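"""Thermodynamic-cycle algebra for free-energy legs.

A :class:`FreeEnergyLeg` is a directed ΔG with an uncertainty and endpoint
labels (e.g. ``SSD -> membrane``).  Legs obtained from *independent*
calculations compose by signed summation with root-sum-square (quadrature)
error propagation:

    ΔG = Σ_i s_i ΔG_i,      σ = sqrt(Σ_i σ_i²),  s_i ∈ {+1, −1}.

An indirect route (e.g. binding-site → membrane → solvent → second site)
assembled this way can be compared against an independent direct estimate of
the same transition with :func:`closure_check`, which reports the
discrepancy as a z-score against the combined uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "FreeEnergyLeg",
    "ThermodynamicCycle",
    "ClosureReport",
    "compose",
    "ddg",
    "closure_check",
]

#: Estimation methods a leg may carry.
LEG_METHODS = ("wham", "mbar", "bar", "ti", "exp", "composed", "literature")


@dataclass(frozen=True)
class FreeEnergyLeg:
    """A directed free-energy difference ``from_state -> to_state``.

    value and error are in kJ/mol; ``error`` is a one-sigma uncertainty and
    must be non-negative.
    """

    value: float
    error: float
    from_state: str
    to_state: str
    method: str = "literature"
    label: str = ""

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError(f"leg error must be >= 0, got {self.error}")
        if self.method not in LEG_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {LEG_METHODS}"
            )

    def reversed(self) -> "FreeEnergyLeg":
        """The same leg traversed backwards: value negated, endpoints swapped."""
        return replace(
            self, value=-self.value, from_state=self.to_state, to_state=self.from_state
        )

    def rounded(self) -> str:
        """Paper-style summary ``+23 ± 4`` (nearest integer kJ/mol)."""
        v = round(self.value)
        e = round(self.error)
        return f"{v:+d} ± {e:d} kJ/mol"


@dataclass
class ThermodynamicCycle:
    """An ordered set of signed legs forming one route between two states.

    ``signs`` holds +1 (traverse forward) or −1 (traverse backward) per leg.
    ``independent`` declares that the legs come from statistically
    independent calculations, which is what makes quadrature error
    composition valid.
    """

    legs: list[FreeEnergyLeg]
    signs: list[int] = field(default_factory=list)
    label: str = ""
    independent: bool = True

    def __post_init__(self) -> None:
        if not self.signs:
            self.signs = [1] * len(self.legs)
        if len(self.signs) != len(self.legs):
            raise ValueError("signs and legs must have equal length")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")

    def compose(self, allow_correlated: bool = False) -> FreeEnergyLeg:
        return compose(
            self.legs,
            signs=self.signs,
            independent=self.independent,
            allow_correlated=allow_correlated,
            label=self.label,
        )


def _oriented(leg: FreeEnergyLeg, sign: int) -> FreeEnergyLeg:
    return leg if sign == 1 else leg.reversed()


def compose(
    legs: Sequence[FreeEnergyLeg],
    signs: Sequence[int] | None = None,
    independent: bool = True,
    allow_correlated: bool = False,
    label: str = "",
) -> FreeEnergyLeg:
    """Signed sum of legs with quadrature errors.

    The oriented legs must chain head-to-tail: the ``to_state`` of each leg
    equals the ``from_state`` of the next.  Raises ValueError naming the gap
    otherwise, and refuses correlated legs unless ``allow_correlated``.
    """
    legs = list(legs)
    if not legs:
        raise ValueError("cannot compose an empty set of legs")
    if signs is None:
        signs = [1] * len(legs)
    if len(signs) != len(legs):
        raise ValueError("signs and legs must have equal length")
    if not independent and not allow_correlated:
        raise ValueError(
            "legs are declared correlated; quadrature error composition is "
            "invalid (pass allow_correlated=True to override)"
        )
    oriented = [_oriented(leg, s) for leg, s in zip(legs, signs)]
    for a, b in zip(oriented, oriented[1:]):
        if a.to_state != b.from_state:
            raise ValueError(
                f"endpoint chain broken: leg ending at {a.to_state!r} followed "
                f"by leg starting at {b.from_state!r}"
            )
    value = sum(leg.value for leg in oriented)
    error = math.sqrt(sum(leg.error**2 for leg in oriented))
    return FreeEnergyLeg(
        value=value,
        error=error,
        from_state=oriented[0].from_state,
        to_state=oriented[-1].to_state,
        method="composed",
        label=label,
    )


def ddg(leg_a: FreeEnergyLeg, leg_b: FreeEnergyLeg, label: str = "") -> FreeEnergyLeg:
    """Difference of two legs of the same transformation, ΔΔG = a − b.

    Used for relative estimates built from two decoupling/perturbation legs
    (e.g. a species removed from a binding site versus from solution):
    the endpoint difference labels name the environments compared.
    """
    value = leg_a.value - leg_b.value
    error = math.hypot(leg_a.error, leg_b.error)
    return FreeEnergyLeg(
        value=value,
        error=error,
        from_state=leg_b.from_state if leg_b.from_state else leg_a.from_state,
        to_state=leg_a.from_state,
        method="composed",
        label=label or f"ddG({leg_a.label or 'a'} - {leg_b.label or 'b'})",
    )


@dataclass(frozen=True)
class ClosureReport:
    """Comparison of two independent routes between the same endpoints."""

    discrepancy: float
    combined_error: float
    z: float
    passed: bool
    threshold: float


def closure_check(
    route_a: FreeEnergyLeg,
    route_b: FreeEnergyLeg,
    z_threshold: float = 2.0,
) -> ClosureReport:
    """Check two routes agree within their combined uncertainty.

    discrepancy = a − b; z = |discrepancy| / sqrt(σ_a² + σ_b²).  A |z| at or
    below ``z_threshold`` counts as consistent.
    """
    if (route_a.from_state, route_a.to_state) != (route_b.from_state, route_b.to_state):
        raise ValueError(
            "routes must share endpoints: "
            f"{route_a.from_state!r}->{route_a.to_state!r} vs "
            f"{route_b.from_state!r}->{route_b.to_state!r}"
        )
    disc = route_a.value - route_b.value
    comb = math.hypot(route_a.error, route_b.error)
    z = abs(disc) / comb if comb > 0 else (0.0 if disc == 0 else math.inf)
    return ClosureReport(
        discrepancy=disc,
        combined_error=comb,
        z=z,
        passed=z <= z_threshold,
        threshold=z_threshold,
    )


def read_ledger(path) -> list[FreeEnergyLeg]:
    """Read legs from a tab-separated ledger (label, from, to, value, error, method)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "from", "to", "value", "error", "method"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ledger missing columns: {sorted(missing)}")
    return [
        FreeEnergyLeg(
            value=float(r["value"]),
            error=float(r["error"]),
            from_state=str(r["from"]),
            to_state=str(r["to"]),
            method=str(r["method"]),
            label=str(r["label"]),
        )
        for _, r in df.iterrows()
    ]


def write_ledger(path, legs: Iterable[FreeEnergyLeg]) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "label": leg.label,
                "from": leg.from_state,
                "to": leg.to_state,
                "value": leg.value,
                "error": leg.error,
                "method": leg.method,
            }
            for leg in legs
        ]
    )
    with open(path, "w") as fh:
        fh.write("# free-energy leg ledger; value/error in kJ/mol\n")
        df.to_csv(fh, sep="\t", index=False)
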