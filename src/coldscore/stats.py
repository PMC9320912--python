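"""Factorial ANOVA, Pearson correlation structure and PCA for the cohort.

* :func:`factorial_anova` — fixed-effects two-way ANOVA (genotype G,
  temperature T, their interaction) per trait on the balanced replicate-
  level design, with the closed-form sums-of-squares decomposition.
* :func:`correlation_matrix` — Pearson r across genotype means per trait
  pair within one treatment, two-sided p via the exact t transform,
  significance counts at 0.05 and 0.01 (uncorrected, matching how such
  screens are conventionally reported).
* :func:`pca` — PCA on standardized variables (i.e. the eigendecomposition
  of the trait correlation matrix), retaining components with eigenvalue
  strictly greater than 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import PhenotypeDataset, TraitMeansTable
from .errors import DomainError, ValidationError

PCA_SCOPES = ("pooled", "control", "stress", "crc")


@dataclass
class AnovaResult:
    """Two-way factorial ANOVA table for one trait.

    ``table`` rows are G, T, G:T and Residual with columns
    ``df, ss, ms, F, p``.  On a degenerate input (zero residual variance)
    F and p are NaN, flagged by ``degenerate``.
    """

    trait: str
    table: pd.DataFrame
    ss_total: float
    degenerate: bool = False

    def __getitem__(self, factor: str) -> pd.Series:
        return self.table.loc[factor]


def _cell_layout(ds: PhenotypeDataset, trait: str) -> np.ndarray:
    """Values as an (n_genotypes, 2, n_reps) array; errors if unbalanced."""
    sub = ds.trait_values(trait)
    counts = sub.groupby(["genotype", "treatment"]).size()
    n_rep = int(counts.iloc[0])
    if counts.nunique() != 1 or len(counts) != 2 * len(ds.genotypes):
        raise ValidationError(
            f"trait {trait!r}: unbalanced design (unequal replicate counts); "
            "the closed-form factorial decomposition requires equal replicates "
            "per (genotype, treatment) cell"
        )
    if n_rep < 2:
        raise DomainError(
            f"trait {trait!r}: need >= 2 replicates per cell for a residual "
            f"degree of freedom, got {n_rep}"
        )
    ordered = sub.sort_values("replicate", kind="stable")
    arr = np.empty((len(ds.genotypes), 2, n_rep))
    g_index = {g: k for k, g in enumerate(ds.genotypes)}
    t_index = {ds.control: 0, ds.stress: 1}
    for (genotype, treatment), grp in ordered.groupby(["genotype", "treatment"]):
        arr[g_index[genotype], t_index[treatment], :] = grp["value"].to_numpy()
    return arr


def anova_from_array(y: np.ndarray, trait: str = "") -> AnovaResult:
    """Closed-form balanced two-way ANOVA on an (a, b, r) array."""
    a, b, r = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    cell = y.mean(axis=2)
    g_mean = y.mean(axis=(1, 2))
    t_mean = y.mean(axis=(0, 2))
    ss_g = float(b * r * ((g_mean - grand) ** 2).sum())
    ss_t = float(a * r * ((t_mean - grand) ** 2).sum())
    ss_cells = float(r * ((cell - grand) ** 2).sum())
    ss_gt = ss_cells - ss_g - ss_t
    ss_res = ss_total - ss_cells
    df = {"G": a - 1, "T": b - 1, "G:T": (a - 1) * (b - 1), "Residual": a * b * (r - 1)}
    ss = {"G": ss_g, "T": ss_t, "G:T": max(ss_gt, 0.0), "Residual": max(ss_res, 0.0)}
    ms = {k: ss[k] / df[k] for k in df}
    degenerate = ms["Residual"] <= 0
    rows = []
    for factor in ("G", "T", "G:T"):
        if degenerate:
            f_stat, p = np.nan, np.nan
        else:
            f_stat = ms[factor] / ms["Residual"]
            p = float(sps.f.sf(f_stat, df[factor], df["Residual"]))
        rows.append((factor, df[factor], ss[factor], ms[factor], f_stat, p))
    rows.append(("Residual", df["Residual"], ss["Residual"], ms["Residual"], np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["factor", "df", "ss", "ms", "F", "p"]
    ).set_index("factor")
    return AnovaResult(trait=trait, table=table, ss_total=ss_total, degenerate=degenerate)


def factorial_anova(ds: PhenotypeDataset, trait: str) -> AnovaResult:
    """Fixed-effects G x T ANOVA with interaction for one trait."""
    return anova_from_array(_cell_layout(ds, trait), trait=trait)


@dataclass
class CorrelationResult:
    """Pearson correlation structure of trait means within one treatment."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_genotypes: int
    n_significant_05: int  # unique trait pairs with p < 0.05
    n_significant_01: int


def correlation_matrix(means: TraitMeansTable, treatment: str) -> CorrelationResult:
    """Pearson r and two-sided p across genotypes for every trait pair."""
    wide = means.wide(treatment)
    n = len(wide)
    if n < 3:
        raise DomainError(f"need >= 3 genotypes for correlation tests, got {n}")

    constant = [t for t in wide.columns if np.ptp(wide[t].to_numpy()) == 0]
    if constant:
        warnings.warn(
            f"trait(s) {constant} are constant under {treatment}; "
            "their correlations are undefined and reported as missing",
            stacklevel=2,
        )

    r = wide.corr(method="pearson")  # NaN for constant columns
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = rv * np.sqrt(n - 2) / np.sqrt(1.0 - rv**2)
        pv = 2.0 * sps.t.sf(np.abs(t_stat), df=n - 2)
    pv[np.abs(rv) >= 1.0] = 0.0
    pv[np.isnan(rv)] = np.nan
    np.fill_diagonal(pv, 0.0)
    p = pd.DataFrame(pv, index=r.index, columns=r.columns)

    iu = np.triu_indices(len(r), k=1)
    upper = pv[iu]
    finite = upper[np.isfinite(upper)]
    return CorrelationResult(
        r=pd.DataFrame(rv, index=r.index, columns=r.columns),
        p=p,
        n_genotypes=n,
        n_significant_05=int((finite < 0.05).sum()),
        n_significant_01=int((finite < 0.01).sum()),
    )


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the trait panel."""

    eigenvalues: np.ndarray          # descending
    percent_variance: np.ndarray     # sums to 100
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame           # trait x component, orthonormal columns
    n_retained: int                  # eigenvalue > 1 (strict)
    scope: str


def pca(means: TraitMeansTable, scope: str = "pooled") -> PCAResult:
    """PCA on standardized trait values.

    ``scope`` selects the observation rows: ``pooled`` (default) stacks
    genotype x treatment means (one row per genotype per treatment),
    ``control``/``stress`` use one treatment's genotype means, and ``crc``
    uses the stress/control ratio matrix.
    """
    if scope not in PCA_SCOPES:
        raise DomainError(f"scope must be one of {PCA_SCOPES}, got {scope!r}")
    if scope == "pooled":
        x = pd.concat([means.wide(means.control), means.wide(means.stress)], axis=0)
    elif scope == "control":
        x = means.wide(means.control)
    elif scope == "stress":
        x = means.wide(means.stress)
    else:
        x = means.wide(means.stress) / means.wide(means.control)

    if x.shape[1] < 2:
        raise DomainError("PCA needs at least 2 traits")
    if x.shape[0] < 2:
        raise DomainError("PCA needs at least 2 observation rows")
    constant = [t for t in x.columns if np.ptp(x[t].to_numpy()) == 0]
    if constant:
        raise DomainError(
            f"trait(s) {constant} are constant; standardization is undefined"
        )

    corr = np.corrcoef(x.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] = -eigvec[:, k]

    percent = eigval / eigval.sum() * 100.0
    loadings = pd.DataFrame(
        eigvec,
        index=pd.Index(x.columns, name="trait"),
        columns=[f"PC{k + 1}" for k in range(len(eigval))],
    )
    return PCAResult(
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=loadings,
        n_retained=int((eigval > 1.0).sum()),
        scope=scope,
    )
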