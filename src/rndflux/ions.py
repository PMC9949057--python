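"""Electrochemical-gradient coupling and transport stoichiometry.

The free energy of moving one mole of an ion of valence ``z`` from the
extracellular to the intracellular side of a membrane held at potential
ΔV (inside minus outside, volts) is

    ΔG_influx = R·T·ln([X]_in / [X]_out) + z·F·ΔV      (kJ/mol)

with ΔG_efflux = −ΔG_influx.  The potential at which ΔG vanishes is the
Nernst (reversal) potential.  If substrate export costs ``export_dG`` > 0,
the number of coupled ions required is export_dG / |ΔG_ion| for an ion
moving down its gradient; the ceiling of that ratio is the minimal integer
stoichiometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from rndflux.constants import FARADAY, R_GAS

__all__ = [
    "IonGradient",
    "delta_g_influx",
    "delta_g",
    "reversal_potential",
    "ions_per_substrate",
    "stoichiometry_curve",
    "NOT_DRIVABLE",
]

#: Distinguished marker used in stoichiometry tables for grid points where
#: the gradient opposes (cannot drive) export.  Deliberately not NaN so it
#: survives round-trips through text tables unambiguously.
NOT_DRIVABLE = "not_drivable"

Direction = Literal["influx", "efflux"]


@dataclass(frozen=True)
class IonGradient:
    """A transmembrane concentration gradient of one ionic species.

    Concentrations in mM (only their ratio matters), temperature in K.
    Defaults are standard cellular values; T defaults to 310 K.
    """

    ion: str
    z: int
    conc_in: float
    conc_out: float
    T: float = 310.0

    def __post_init__(self) -> None:
        if self.conc_in <= 0 or self.conc_out <= 0:
            raise ValueError("concentrations must be positive")
        if self.z == 0:
            raise ValueError("valence z must be non-zero")
        if self.T <= 0:
            raise ValueError("temperature must be positive")


#: Standard cellular gradients quoted for Na+ and K+.
SODIUM = IonGradient(ion="Na+", z=+1, conc_in=12.0, conc_out=145.0)
POTASSIUM = IonGradient(ion="K+", z=+1, conc_in=150.0, conc_out=4.0)


def delta_g_influx(gradient: IonGradient, dV: float) -> float:
    """ΔG (kJ/mol) of moving one mole of ion from outside to inside at ΔV (V)."""
    chemical = R_GAS * gradient.T * math.log(gradient.conc_in / gradient.conc_out)
    electrical = gradient.z * FARADAY * dV / 1000.0  # C/mol * V = J/mol -> kJ/mol
    return chemical + electrical


def delta_g(gradient: IonGradient, dV: float, direction: Direction) -> float:
    """ΔG of one mole of ion moving in the given direction at ΔV (V)."""
    g = delta_g_influx(gradient, dV)
    if direction == "influx":
        return g
    if direction == "efflux":
        return -g
    raise ValueError(f"direction must be 'influx' or 'efflux', got {direction!r}")


def reversal_potential(gradient: IonGradient) -> float:
    """Nernst potential (volts): the ΔV at which the influx ΔG is zero."""
    return (
        -(R_GAS * 1000.0 * gradient.T / (gradient.z * FARADAY))
        * math.log(gradient.conc_in / gradient.conc_out)
    )


def ions_per_substrate(
    export_dG: float,
    gradient: IonGradient,
    dV: float,
    direction: Direction,
    mode: Literal["continuous", "ceiling"] = "ceiling",
) -> float | int:
    """Number of ions whose down-gradient movement pays for one export event.

    ``export_dG`` (kJ/mol, > 0) is the free-energy cost of exporting one
    substrate.  The chosen ion movement direction must be spontaneous
    (ΔG_ion < 0) at this potential, else a ValueError is raised.
    """
    if export_dG <= 0:
        raise ValueError(f"export_dG must be positive, got {export_dG}")
    g_ion = delta_g(gradient, dV, direction)
    if g_ion >= 0:
        raise ValueError(
            f"gradient cannot drive export at this potential: {gradient.ion} "
            f"{direction} ΔG = {g_ion:+.3f} kJ/mol at ΔV = {dV * 1000:.0f} mV"
        )
    n = export_dG / abs(g_ion)
    if mode == "continuous":
        return n
    if mode == "ceiling":
        return math.ceil(n)
    raise ValueError(f"mode must be 'continuous' or 'ceiling', got {mode!r}")


def stoichiometry_curve(
    export_dG: float | Sequence[float],
    gradient: IonGradient,
    dV_grid: Iterable[float],
    direction: Direction,
) -> pd.DataFrame:
    """Stoichiometry versus membrane potential.

    One row per (ΔV, export ΔG) pair with the per-ion ΔG in the chosen
    direction, the continuous ion number and its ceiling.  Grid points where
    the gradient cannot drive export carry the :data:`NOT_DRIVABLE` marker.
    """
    dV_grid = list(dV_grid)
    if not dV_grid:
        raise ValueError("dV_grid must contain at least one potential")
    export_values = (
        [float(export_dG)] if isinstance(export_dG, (int, float)) else list(export_dG)
    )
    rows = []
    for dv in dV_grid:
        g_ion = delta_g(gradient, dv, direction)
        for ex in export_values:
            if g_ion >= 0:
                rows.append(
                    {
                        "dV_V": dv,
                        "ion_dG_kJ_mol": g_ion,
                        "export_dG_kJ_mol": ex,
                        "n_continuous": NOT_DRIVABLE,
                        "n_ceiling": NOT_DRIVABLE,
                    }
                )
            else:
                n = ex / abs(g_ion)
                rows.append(
                    {
                        "dV_V": dv,
                        "ion_dG_kJ_mol": g_ion,
                        "export_dG_kJ_mol": ex,
                        "n_continuous": n,
                        "n_ceiling": math.ceil(n),
                    }
                )
    return pd.DataFrame(rows)
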