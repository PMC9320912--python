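"""Trait definitions and the trait registry.

A :class:`TraitDefinition` declares what a measured trait is and, crucially,
its direction of association with cold resistance: ``direction=+1`` means a
larger value indicates a more resistant genotype (membership is the plain
min-max normalisation of the cold-resistance coefficient), ``direction=-1``
means the trait rises with injury (membership is inverted, 1 minus that
quantity).

The default registry ships the 29-trait maize seedling panel with directions
-1 for malondialdehyde, superoxide production, hydrogen peroxide and
intercellular CO2 (all of which increase with cold damage) and +1 for every
other trait.  The assignment is a documented assumption and can be
overridden by loading a registry CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from . import reference
from .errors import FormatError, RegistryError

VALID_CATEGORIES = frozenset(
    {"growth", "photosynthetic", "membrane", "ROS", "antioxidant", "osmotic", "polyamine"}
)

REGISTRY_COLUMNS = ("name", "long_name", "category", "units", "direction", "strictly_positive")


@dataclass(frozen=True)
class TraitDefinition:
    """One measured trait and how it relates to cold resistance."""

    name: str
    long_name: str
    category: str
    units: str
    direction: int
    strictly_positive: bool = True

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise RegistryError(
                f"trait {self.name!r}: direction must be +1 or -1, got {self.direction!r}"
            )
        if self.category not in VALID_CATEGORIES:
            raise RegistryError(
                f"trait {self.name!r}: unknown category {self.category!r}; "
                f"expected one of {sorted(VALID_CATEGORIES)}"
            )
        if not self.name:
            raise RegistryError("trait name must be non-empty")


class TraitRegistry:
    """An ordered, name-unique collection of trait definitions."""

    def __init__(self, traits: Iterable[TraitDefinition]):
        self._traits: dict[str, TraitDefinition] = {}
        for t in traits:
            if t.name in self._traits:
                raise RegistryError(f"duplicate trait name {t.name!r} in registry")
            self._traits[t.name] = t

    def __iter__(self) -> Iterator[TraitDefinition]:
        return iter(self._traits.values())

    def __len__(self) -> int:
        return len(self._traits)

    def __contains__(self, name: object) -> bool:
        return name in self._traits

    def __getitem__(self, name: str) -> TraitDefinition:
        try:
            return self._traits[name]
        except KeyError:
            raise RegistryError(f"trait {name!r} not in registry") from None

    @property
    def names(self) -> list[str]:
        return list(self._traits)

    def direction(self, name: str) -> int:
        return self[name].direction

    def subset(self, names: Iterable[str]) -> "TraitRegistry":
        """Registry restricted to ``names``, preserving the given order."""
        return TraitRegistry(self[n] for n in names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.name, t.long_name, t.category, t.units, t.direction, t.strictly_positive)
                for t in self
            ],
            columns=list(REGISTRY_COLUMNS),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_registry(path: str | Path) -> TraitRegistry:
    """Read a trait registry from CSV.

    The file must carry the header
    ``name,long_name,category,units,direction,strictly_positive``.
    """
    df = pd.read_csv(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"registry file {path} missing column(s): {', '.join(missing)}")
    traits = []
    for _, row in df.iterrows():
        traits.append(
            TraitDefinition(
                name=str(row["name"]),
                long_name=str(row["long_name"]),
                category=str(row["category"]),
                units=str(row["units"]),
                direction=int(row["direction"]),
                strictly_positive=bool(row["strictly_positive"]),
            )
        )
    return TraitRegistry(traits)


def default_registry() -> TraitRegistry:
    """The 29-trait maize seedling panel with default direction assignments."""
    return TraitRegistry(
        TraitDefinition(
            name=name,
            long_name=long_name,
            category=category,
            units=units,
            direction=direction,
            strictly_positive=True,
        )
        for name, long_name, category, units, direction, *_ in reference.TRAIT_TABLE
    )
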