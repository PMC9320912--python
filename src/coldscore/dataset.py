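"""Replicate-level phenotype data and per-cell trait means.

The on-disk interchange format is a tidy CSV with the exact header
``genotype,treatment,replicate,trait,value`` — one row per single
measurement.  :func:`load_phenotypes` validates the table against a trait
registry and a declared control/stress treatment pair and returns a
:class:`PhenotypeDataset`; :func:`replicate_means` collapses replicates to
the per-(genotype, treatment, trait) means that every downstream statistic
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, RegistryError, ValidationError
from .registry import TraitRegistry

PHENOTYPE_COLUMNS = ("genotype", "treatment", "replicate", "trait", "value")


def _ordered_unique(values: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class PhenotypeDataset:
    """Validated replicate-level measurements for a two-treatment cohort.

    ``data`` holds one row per measurement with columns
    ``genotype, treatment, replicate, trait, value``.  ``control`` and
    ``stress`` name the two treatment levels (defaults CK = normal
    temperature, LT = cold treatment).
    """

    data: pd.DataFrame
    registry: TraitRegistry
    control: str = "CK"
    stress: str = "LT"
    genotypes: list[str] = field(init=False)
    traits: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self._validate()
        self.genotypes = _ordered_unique(self.data["genotype"])
        self.traits = [n for n in self.registry.names if n in set(self.data["trait"])]

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing column(s): {', '.join(missing)}")
        if self.control == self.stress:
            raise ValidationError("control and stress treatment labels must differ")

        declared = {self.control, self.stress}
        bad = sorted(set(df["treatment"].astype(str)) - declared)
        if bad:
            raise ValidationError(
                f"unknown treatment label(s) {bad}; declared levels are "
                f"control={self.control!r}, stress={self.stress!r}"
            )

        unknown = sorted(set(df["trait"].astype(str)) - set(self.registry.names))
        if unknown:
            raise RegistryError(f"trait(s) not in registry: {', '.join(unknown)}")

        values = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
        nonfinite = ~np.isfinite(values)
        if nonfinite.any():
            row = int(np.flatnonzero(nonfinite)[0])
            raise ParseError(
                f"non-numeric or non-finite value {df['value'].iloc[row]!r} "
                f"in data row {row}"
            )
        self.data = df.assign(value=values)

        strict = {t.name for t in self.registry if t.strictly_positive}
        mask = self.data["trait"].isin(strict) & (self.data["value"] <= 0)
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            rec = self.data.iloc[row]
            raise ValidationError(
                f"trait {rec['trait']!r} is ratio-scale (strictly positive) but "
                f"genotype {rec['genotype']!r} {rec['treatment']} replicate "
                f"{rec['replicate']} has value {rec['value']}"
            )

    def require_complete(self, drop_incomplete: bool = False) -> "PhenotypeDataset":
        """Check every genotype has every trait in both treatments.

        With ``drop_incomplete=True`` genotypes with missing cells are
        removed listwise instead of raising (the comprehensive score averages
        over a fixed trait set, so partial genotypes cannot be scored).
        """
        counts = self.data.groupby(["genotype", "treatment", "trait"]).size()
        expected = 2 * len(self.traits)
        per_geno = counts.groupby("genotype").size()
        incomplete = [g for g in self.genotypes if per_geno.get(g, 0) < expected]
        if not incomplete:
            return self
        if drop_incomplete:
            kept = self.data[~self.data["genotype"].isin(incomplete)]
            if kept.empty:
                raise ValidationError("all genotypes dropped as incomplete")
            return PhenotypeDataset(kept, self.registry, self.control, self.stress)
        raise ValidationError(
            f"incomplete cells for genotype(s) {incomplete}; every genotype needs "
            "every trait under both treatments (pass drop_incomplete=True to drop)"
        )

    # -- accessors ----------------------------------------------------------
    def replicate_counts(self) -> pd.Series:
        """Number of replicates per (genotype, treatment, trait) cell."""
        return self.data.groupby(["genotype", "treatment", "trait"]).size()

    def trait_values(self, trait: str) -> pd.DataFrame:
        if trait not in self.traits:
            raise RegistryError(f"trait {trait!r} not present in dataset")
        return self.data[self.data["trait"] == trait]

    def to_csv(self, path: str | Path) -> None:
        self.data.loc[:, list(PHENOTYPE_COLUMNS)].to_csv(path, index=False)


@dataclass
class TraitMeansTable:
    """Mean value per (genotype, treatment, trait), replicates averaged."""

    frame: pd.DataFrame  # columns: genotype, treatment, trait, value
    genotypes: list[str]
    traits: list[str]
    control: str
    stress: str

    def wide(self, treatment: str) -> pd.DataFrame:
        """Genotype x trait matrix of means under one treatment."""
        sub = self.frame[self.frame["treatment"] == treatment]
        wide = sub.pivot(index="genotype", columns="trait", values="value")
        return wide.reindex(index=self.genotypes, columns=self.traits)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_phenotypes(
    path: str | Path,
    registry: TraitRegistry,
    control: str = "CK",
    stress: str = "LT",
    drop_incomplete: bool = False,
) -> PhenotypeDataset:
    """Read and validate a tidy phenotype CSV.

    Raises :class:`FormatError` for a bad header, :class:`RegistryError` for
    traits absent from ``registry``, :class:`ParseError` (with the row
    number) for non-numeric values and :class:`ValidationError` for unknown
    treatment labels or non-positive ratio-scale values.
    """
    try:
        df = pd.read_csv(path, dtype={"genotype": str, "treatment": str, "trait": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"phenotype file {path} is empty") from exc
    ds = PhenotypeDataset(df, registry, control=control, stress=stress)
    return ds.require_complete(drop_incomplete=drop_incomplete)


def write_phenotypes(ds: PhenotypeDataset, path: str | Path) -> None:
    ds.to_csv(path)


def replicate_means(ds: PhenotypeDataset) -> TraitMeansTable:
    """Arithmetic mean over replicates for every (genotype, treatment, trait)."""
    means = (
        ds.data.groupby(["genotype", "treatment", "trait"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    return TraitMeansTable(
        frame=means,
        genotypes=ds.genotypes,
        traits=ds.traits,
        control=ds.control,
        stress=ds.stress,
    )
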