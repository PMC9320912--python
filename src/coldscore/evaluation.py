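"""Fuzzy-membership comprehensive evaluation of cold resistance.

This is the pipeline's core computation.  Given per-genotype trait means
under a control (CK) and a cold (LT) treatment:

rate change (RC, %)
    RC_ij = (T_LTij - T_CKij) / T_CKij x 100 — the percent response of
    trait i in genotype j to cold.

cold-resistance coefficient (CRC)
    CRC_ij = T_LTij / T_CKij, the stress/control ratio.  Note the identity
    CRC = 1 + RC/100.  CRC is scale-free: changing a trait's measurement
    units leaves it untouched.

membership value (U_ij)
    Within each trait, CRC values are min-max normalised across genotypes
    to [0, 1].  For a trait positively associated with resistance,

        U_ij = (CRC_ij - CRC_i_min) / (CRC_i_max - CRC_i_min);

    for a damage-indicating trait the value is inverted, U_ij = 1 - (that
    quantity).  A trait whose CRC range is degenerate (all genotypes equal)
    is uninformative and assigned U = 0.5 everywhere, with a warning.

comprehensive score (U_j)
    The unweighted mean of U_ij over all traits: each genotype's overall
    cold-resistance standing in [0, 1].

genetic coefficient of variation (CV_g, %)
    Per trait and treatment, the SD of genotype means over their mean,
    x100.  The sample (n-1) SD is used by default since the genotypes are a
    sample of germplasm; ``ddof=0`` switches to the population convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import PhenotypeDataset, TraitMeansTable, replicate_means
from .errors import DomainError, RegistryError
from .registry import TraitRegistry


def rate_change(mean_lt, mean_ck):
    """Percent rate change (T_LT - T_CK) / T_CK x 100; requires T_CK > 0."""
    ck = np.asarray(mean_ck, dtype=float)
    if np.any(ck <= 0):
        raise DomainError(f"control mean must be > 0, got {mean_ck}")
    result = (np.asarray(mean_lt, dtype=float) - ck) / ck * 100.0
    return float(result) if result.ndim == 0 else result


@dataclass
class CRCMatrix:
    """Cold-resistance coefficients, genotypes x traits, with row extrema."""

    values: pd.DataFrame          # index: genotype, columns: trait
    trait_min: pd.Series          # per trait, min over genotypes
    trait_max: pd.Series

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MembershipMatrix:
    """Membership values U_ij and comprehensive scores U_j."""

    values: pd.DataFrame          # index: genotype, columns: trait, in [0, 1]
    scores: pd.Series             # U_j per genotype
    degenerate_traits: list[str]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


def cold_resistance_coefficients(means: TraitMeansTable) -> CRCMatrix:
    """CRC_ij = T_LTij / T_CKij from a trait-means table."""
    ck = means.wide(means.control)
    lt = means.wide(means.stress)
    bad = (ck <= 0) | ck.isna()
    if bad.any().any():
        stacked = bad.stack()
        genotype, trait = stacked[stacked].index[0]
        raise DomainError(
            f"control mean must be > 0 to form a stress/control ratio; "
            f"genotype {genotype!r}, trait {trait!r} has {ck.loc[genotype, trait]!r}"
        )
    crc = lt / ck
    return CRCMatrix(values=crc, trait_min=crc.min(axis=0), trait_max=crc.max(axis=0))


def membership_values(crc: CRCMatrix, registry: TraitRegistry) -> MembershipMatrix:
    """Direction-aware min-max membership U_ij and the per-genotype mean U_j."""
    missing = [t for t in crc.traits if t not in registry]
    if missing:
        raise RegistryError(f"trait(s) missing from registry: {', '.join(missing)}")

    span = crc.trait_max - crc.trait_min
    degenerate = [t for t in crc.traits if span[t] == 0]
    if degenerate:
        warnings.warn(
            f"trait(s) {degenerate} have identical CRC for all genotypes; "
            "membership set to 0.5 (uninformative)",
            stacklevel=2,
        )

    u = (crc.values - crc.trait_min) / span.replace(0, np.nan)
    for t in crc.traits:
        if registry.direction(t) == -1:
            u[t] = 1.0 - u[t]
    u[degenerate] = 0.5
    scores = u.mean(axis=1)
    return MembershipMatrix(values=u, scores=scores, degenerate_traits=degenerate)


def genetic_cv(values: Sequence[float] | np.ndarray, ddof: int = 1) -> float:
    """CV_g in percent: SD over mean x 100 of per-genotype values of one trait.

    Requires at least two genotypes and a non-zero mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError(f"need >= 2 genotypes for a coefficient of variation, got {x.size}")
    mean = x.mean()
    if mean == 0:
        raise DomainError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=ddof) / mean * 100.0)


@dataclass
class CohortEvaluation:
    """All products of the comprehensive evaluation for one cohort."""

    crc: CRCMatrix
    membership: MembershipMatrix
    rc_summary: pd.DataFrame      # per trait: mean/min/max of per-genotype RC, RC of grand means
    cvg: pd.DataFrame             # per trait: CV_g under control and stress
    score_cv: float               # CV (%) of the U_j scores across genotypes

    @property
    def scores(self) -> pd.Series:
        return self.membership.scores


def evaluate_cohort(
    ds: PhenotypeDataset,
    registry: TraitRegistry | None = None,
    traits: Iterable[str] | None = None,
    cv_ddof: int = 1,
) -> CohortEvaluation:
    """Run the full evaluation: means -> RC -> CRC -> U_ij -> U_j -> CV_g.

    ``traits`` optionally restricts the comprehensive score to a subset of
    the registry (the default uses every measured trait).
    """
    registry = registry if registry is not None else ds.registry
    means = replicate_means(ds)
    if traits is not None:
        keep = list(traits)
        unknown = [t for t in keep if t not in means.traits]
        if unknown:
            raise RegistryError(f"trait subset not in dataset: {', '.join(unknown)}")
        means.traits = keep
        means.frame = means.frame[means.frame["trait"].isin(keep)]

    crc = cold_resistance_coefficients(means)
    membership = membership_values(crc, registry)

    rc = (crc.values - 1.0) * 100.0  # identity CRC = 1 + RC/100
    ck = means.wide(means.control)
    lt = means.wide(means.stress)
    grand_rc = (lt.mean(axis=0) - ck.mean(axis=0)) / ck.mean(axis=0) * 100.0
    rc_summary = pd.DataFrame(
        {
            "mean_rc": rc.mean(axis=0),
            "min_rc": rc.min(axis=0),
            "max_rc": rc.max(axis=0),
            "rc_of_grand_means": grand_rc,
        }
    ).rename_axis("trait")

    cvg = pd.DataFrame(
        {
            means.control: [genetic_cv(ck[t], ddof=cv_ddof) for t in means.traits],
            means.stress: [genetic_cv(lt[t], ddof=cv_ddof) for t in means.traits],
        },
        index=pd.Index(means.traits, name="trait"),
    )

    score_cv = genetic_cv(membership.scores.to_numpy(), ddof=cv_ddof)
    return CohortEvaluation(
        crc=crc,
        membership=membership,
        rc_summary=rc_summary,
        cvg=cvg,
        score_cv=score_cv,
    )
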