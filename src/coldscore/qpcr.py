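"""Relative gene expression from qPCR cycle thresholds (2^-ddCt).

For a target gene and an internal reference gene measured in a stressed and
a control condition, the fold change is

    ddCt = (Ct_target - Ct_ref)_stress - (Ct_target - Ct_ref)_control
    fold = 2 ** (-ddCt)

Replicate Ct values are averaged per condition *before* the subtraction
(the standard Livak reading); per-replicate fold changes are additionally
available for dispersion estimates.  No amplification-efficiency correction
is applied.

Input CSV layout: ``gene,genotype,treatment,replicate,ct`` with the
reference gene present for every (genotype, treatment) condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError

CT_COLUMNS = ("gene", "genotype", "treatment", "replicate", "ct")


@dataclass(frozen=True)
class CtRecord:
    """Replicate Ct values for one gene in one (genotype, treatment) condition."""

    gene: str
    condition: str
    ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct) == 0:
            raise DomainError(f"empty Ct set for {self.gene} / {self.condition}")
        if not np.all(np.isfinite(self.ct)):
            raise DomainError(f"non-finite Ct for {self.gene} / {self.condition}")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct))


def relative_expression(
    target_stress: CtRecord,
    ref_stress: CtRecord,
    target_control: CtRecord,
    ref_control: CtRecord,
) -> float:
    """Fold change 2^-ddCt of the target gene, stress vs control.

    The control condition used as its own calibrator gives exactly 1.
    """
    d_stress = target_stress.mean_ct - ref_stress.mean_ct
    d_control = target_control.mean_ct - ref_control.mean_ct
    return float(2.0 ** -(d_stress - d_control))


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV and check its layout."""
    df = pd.read_csv(path, dtype={"gene": str, "genotype": str, "treatment": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Ct table missing column(s): {', '.join(missing)}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any():
        row = int(ct.isna().idxmax())
        raise FormatError(f"non-numeric Ct value in data row {row}")
    return df.assign(ct=ct.astype(float))


def fold_change_table(
    ct: pd.DataFrame,
    reference_gene: str,
    control: str = "CK",
    stress: str = "LT",
) -> pd.DataFrame:
    """2^-ddCt per (gene, genotype), stress relative to control.

    Returns columns ``gene, genotype, fold_change, fold_sd`` where
    ``fold_sd`` is the standard deviation of per-replicate fold changes
    (each replicate's Ct paired with the condition-mean reference Ct) —
    the usual error-bar convention.
    """
    genes = [g for g in ct["gene"].unique() if g != reference_gene]
    rows = []
    for genotype, sub in ct.groupby("genotype", sort=False):
        ref = sub[sub["gene"] == reference_gene]
        for treatment in (control, stress):
            if ref[ref["treatment"] == treatment].empty:
                raise ValidationError(
                    f"reference gene {reference_gene!r} missing for genotype "
                    f"{genotype!r} under {treatment!r}"
                )
        ref_mean = {t: ref[ref["treatment"] == t]["ct"].mean() for t in (control, stress)}
        for gene in genes:
            tgt = sub[sub["gene"] == gene]
            if tgt.empty:
                continue
            recs = {}
            for treatment in (control, stress):
                vals = tgt[tgt["treatment"] == treatment]["ct"].to_numpy()
                if vals.size == 0:
                    raise ValidationError(
                        f"gene {gene!r} missing for genotype {genotype!r} "
                        f"under {treatment!r}"
                    )
                recs[treatment] = vals
            d_control = recs[control].mean() - ref_mean[control]
            ddct = (recs[stress] - ref_mean[stress]) - d_control
            per_rep = 2.0 ** -ddct
            rows.append(
                {
                    "gene": gene,
                    "genotype": genotype,
                    "fold_change": float(2.0 ** -(recs[stress].mean() - ref_mean[stress] - d_control)),
                    "fold_sd": float(np.std(per_rep, ddof=1)) if per_rep.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "genotype", "fold_change", "fold_sd"])
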