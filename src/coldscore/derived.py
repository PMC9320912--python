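"""Derived physiological traits.

Four of the panel's traits are not read off an instrument but computed from
paired raw measurements:

* root-shoot ratio            RSR = RFW / SFW
* membrane stability index    MSI = (1 - C1/C2) x 100, from electrolyte
  leakage conductivities after 40 degC incubation (C1) and boiling (C2)
* water use efficiency        WUE = Pn / Tr
* Rubisco carboxylation proxy Pn / Ci

All four are scalar formulas with strict domain checks; they accept floats
or numpy arrays (broadcasting applies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class ConductivityPair:
    """Electrolyte-leakage conductivities: c1 after 40 degC, c2 after boiling."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c2 <= 0:
            raise DomainError(f"boiled conductivity c2 must be > 0, got {self.c2}")
        if not 0 <= self.c1 <= self.c2:
            raise DomainError(
                f"need 0 <= c1 <= c2, got c1={self.c1}, c2={self.c2}"
            )


@dataclass(frozen=True)
class GasExchangeRecord:
    """One gas-exchange reading: Pn, Tr, Ci, Gs in instrument units."""

    pn: float
    tr: float
    ci: float
    gs: float


def root_shoot_ratio(rfw, sfw):
    """RSR = root fresh weight / seedling fresh weight."""
    if np.any(np.asarray(sfw) <= 0):
        raise DomainError(f"seedling fresh weight must be > 0, got {sfw}")
    return rfw / np.asarray(sfw) if isinstance(rfw, np.ndarray) else rfw / sfw


def membrane_stability_index(pair: ConductivityPair) -> float:
    """MSI in percent: 100 x (1 - c1/c2); 100 = fully intact membranes."""
    return (1.0 - pair.c1 / pair.c2) * 100.0


def water_use_efficiency(g: GasExchangeRecord) -> float:
    """WUE = Pn / Tr (carbon fixed per unit water transpired)."""
    if g.tr <= 0:
        raise DomainError(f"transpiration rate must be > 0, got {g.tr}")
    return g.pn / g.tr


def rubisco_proxy(g: GasExchangeRecord) -> float:
    """Carboxylation-efficiency surrogate Pn / Ci."""
    if g.ci <= 0:
        raise DomainError(f"intercellular CO2 must be > 0, got {g.ci}")
    return g.pn / g.ci
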