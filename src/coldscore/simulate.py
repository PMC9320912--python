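"""Synthetic two-temperature phenotype cohorts and qPCR Ct tables.

The generator emulates the study design the pipeline expects: a panel of
genotypes (default 39) measured for the 29-trait registry under a 22 degC
control and a 10 degC cold treatment, three replicates each.  The model is
multiplicative log-normal — every trait is positive and ratio-scaled, and
the downstream analysis works on stress/control ratios, which log-normal
structure keeps well behaved:

    value(g, t, r, i) = baseline_i x G(g, i) x [m_i x I(g, i)]^(t = LT) x eps

* ``baseline_i``: control-condition cohort mean of trait i (calibrated
  defaults, see :mod:`coldscore.reference`).
* ``G(g, i)``: mean-one log-normal genotype effect at the trait's
  between-genotype CV (defaults: the published control-treatment CV_g).
* ``m_i``: the cold-effect multiplier 1 + RC_i/100 (defaults: the published
  cohort-mean rate changes, e.g. 0.514 for seedling length, 3.219 for
  malondialdehyde, 4.118 for proline).
* ``I(g, i)``: genotype-specific cold response.  A single latent resistance
  score z_g per genotype is mapped to multipliers exp(d_i * gamma * z_g)
  (d_i the trait's direction of association, gamma ``resistance_effect``)
  plus mean-zero log-normal interaction noise.  The realized multipliers
  are renormalised to arithmetic mean 1 across the cohort per trait — the
  usual factorial identifiability constraint — so the cohort-mean rate
  change stays on the configured m_i.  Resistant genotypes (high z) keep
  resistance-supporting traits closer to their control values and
  accumulate less damage, which makes the comprehensive score a meaningful
  recovery target.
* ``eps``: mean-one log-normal replicate residual (default CV 3%, a free
  choice: the source study does not report within-genotype variance).

All draws come from one ``numpy.random.default_rng(seed)`` stream in a fixed
documented order (latent scores, genotype effects, interaction noise,
residuals), so a seed pins the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .dataset import PhenotypeDataset
from .errors import ConfigError, DomainError
from .registry import TraitRegistry, default_registry


def _lognormal_sigma(cv: float) -> float:
    """Log-scale SD of a log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults reproduce the published study conditions: 39 genotypes, 3
    replicates, the 29-trait registry with published cold-effect multipliers
    and control-treatment genotype CVs.
    """

    n_genotypes: int = 39
    n_replicates: int = 3
    seed: int = 0
    traits: Sequence[str] | None = None          # default: all 29
    baselines: Mapping[str, float] | None = None  # control-condition means
    multipliers: Mapping[str, float] | None = None  # m_i = 1 + RC_i/100
    genotype_cv: Mapping[str, float] | float | None = None  # per-trait or scalar
    interaction_cv: float = 0.05
    residual_cv: float = 0.03
    resistance_effect: float = 0.15  # gamma: log-scale spread of the latent gradient
    control: str = "CK"
    stress: str = "LT"

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigError(f"need >= 2 genotypes, got {self.n_genotypes}")
        if self.n_replicates < 1:
            raise ConfigError(f"need >= 1 replicate, got {self.n_replicates}")
        for name, value in (
            ("interaction_cv", self.interaction_cv),
            ("residual_cv", self.residual_cv),
            ("resistance_effect", self.resistance_effect),
        ):
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")

    # -- resolved per-trait vectors -----------------------------------------
    def trait_names(self) -> list[str]:
        return list(self.traits) if self.traits is not None else list(reference.TRAIT_NAMES)

    def _resolve(self, override, column: int, default_scale) -> np.ndarray:
        """Per-trait vector: user override where given, scaled default otherwise."""
        names = self.trait_names()
        defaults = {row[0]: row[column] for row in reference.TRAIT_TABLE}
        out = []
        for n in names:
            if isinstance(override, (int, float)):
                out.append(float(override))
            elif override is not None and n in override:
                out.append(float(override[n]))
            elif n in defaults:
                out.append(default_scale(float(defaults[n])))
            else:
                raise ConfigError(f"no default for unknown trait {n!r}; supply a value")
        return np.asarray(out)

    def baseline_vector(self) -> np.ndarray:
        b = self._resolve(self.baselines, column=8, default_scale=lambda x: x)
        if np.any(b <= 0):
            raise ConfigError("baselines must be > 0")
        return b

    def multiplier_vector(self) -> np.ndarray:
        # table stores RC percent; convert defaults to m = 1 + RC/100
        m = self._resolve(self.multipliers, column=5, default_scale=lambda x: 1.0 + x / 100.0)
        if np.any(m <= 0):
            raise ConfigError("cold-effect multipliers must be > 0")
        return m

    def genotype_cv_vector(self) -> np.ndarray:
        # table stores CV_g percent; convert defaults to a fraction
        cv = self._resolve(self.genotype_cv, column=6, default_scale=lambda x: x / 100.0)
        if np.any(cv < 0):
            raise ConfigError("genotype CVs must be >= 0")
        return cv


@dataclass
class SyntheticTruth:
    """Realized latent structure of a generated cohort, for recovery tests."""

    latent_resistance: pd.Series      # z_g per genotype
    genotype_effects: pd.DataFrame    # G(g, i)
    interaction_effects: pd.DataFrame  # I(g, i) applied under stress
    multipliers: pd.Series            # configured m_i per trait
    config: GeneratorConfig = field(repr=False)


def generate_phenotypes(
    cfg: GeneratorConfig,
    registry: TraitRegistry | None = None,
) -> tuple[PhenotypeDataset, SyntheticTruth]:
    """Draw one cohort; identical config + seed gives identical output."""
    registry = registry if registry is not None else default_registry()
    traits = cfg.trait_names()
    for t in traits:
        if t not in registry:
            raise ConfigError(f"trait {t!r} not in registry")

    n_g, n_r, n_t = cfg.n_genotypes, cfg.n_replicates, len(traits)
    baseline = cfg.baseline_vector()
    m = cfg.multiplier_vector()
    cv_g = cfg.genotype_cv_vector()
    directions = np.array([registry.direction(t) for t in traits], dtype=float)

    rng = np.random.default_rng(cfg.seed)
    # Draw order is part of the contract: z, G, interaction noise, residuals.
    z = rng.standard_normal(n_g)

    sigma_g = np.array([_lognormal_sigma(c) for c in cv_g])
    g_eff = np.exp(rng.standard_normal((n_g, n_t)) * sigma_g - 0.5 * sigma_g**2)

    sigma_i = _lognormal_sigma(cfg.interaction_cv)
    gamma = cfg.resistance_effect
    log_i = (
        np.outer(z, directions) * gamma
        + rng.standard_normal((n_g, n_t)) * sigma_i
    )
    i_eff = np.exp(log_i)
    i_eff /= i_eff.mean(axis=0)  # identifiability: mean interaction = 1 per trait

    sigma_e = _lognormal_sigma(cfg.residual_cv)
    eps = np.exp(
        rng.standard_normal((n_g, 2, n_r, n_t)) * sigma_e - 0.5 * sigma_e**2
    )

    # values[g, t, r, i]; treatment axis 0 = control, 1 = stress
    stress_factor = m * i_eff  # (n_g, n_t)
    values = baseline * g_eff[:, None, None, :] * eps
    values[:, 1, :, :] *= stress_factor[:, None, :]

    genotypes = [f"G{k + 1:03d}" for k in range(n_g)]
    index = pd.MultiIndex.from_product(
        [genotypes, [cfg.control, cfg.stress], range(1, n_r + 1), traits],
        names=["genotype", "treatment", "replicate", "trait"],
    )
    data = pd.DataFrame({"value": values.reshape(-1)}, index=index).reset_index()

    ds = PhenotypeDataset(
        data, registry.subset(traits), control=cfg.control, stress=cfg.stress
    )
    truth = SyntheticTruth(
        latent_resistance=pd.Series(z, index=genotypes, name="latent_resistance"),
        genotype_effects=pd.DataFrame(g_eff, index=genotypes, columns=traits),
        interaction_effects=pd.DataFrame(i_eff, index=genotypes, columns=traits),
        multipliers=pd.Series(m, index=traits, name="multiplier"),
        config=cfg,
    )
    return ds, truth


def generate_qpcr(
    fold_changes: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    reference_gene: str = "REF",
    reference_ct: float = 20.0,
    target_ct_control: float = 26.0,
    control: str = "CK",
    stress: str = "LT",
) -> pd.DataFrame:
    """Synthetic Ct table realizing configured fold changes.

    ``fold_changes`` maps gene -> genotype -> true stress/control fold
    change.  The reference gene's Ct is constant in expectation across
    conditions; the target gene's stress Ct is shifted by -log2(fold).
    Gaussian noise of SD ``ct_noise_sd`` is added per replicate well.
    """
    if n_replicates < 1:
        raise ConfigError(f"need >= 1 replicate, got {n_replicates}")
    if ct_noise_sd < 0:
        raise ConfigError(f"ct_noise_sd must be >= 0, got {ct_noise_sd}")
    for gene, per_geno in fold_changes.items():
        for genotype, fold in per_geno.items():
            if fold <= 0:
                raise DomainError(
                    f"fold change must be > 0, got {fold} for {gene}/{genotype}"
                )

    rng = np.random.default_rng(seed)
    genotypes: list[str] = sorted({g for per in fold_changes.values() for g in per})
    rows = []
    for genotype in genotypes:
        for treatment in (control, stress):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (reference_gene, genotype, treatment, rep,
                     reference_ct + rng.normal(0.0, ct_noise_sd))
                )
        for gene, per_geno in fold_changes.items():
            if genotype not in per_geno:
                continue
            shift = float(np.log2(per_geno[genotype]))
            for treatment in (control, stress):
                base = target_ct_control - (shift if treatment == stress else 0.0)
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        (gene, genotype, treatment, rep,
                         base + rng.normal(0.0, ct_noise_sd))
                    )
    return pd.DataFrame(rows, columns=["gene", "genotype", "treatment", "replicate", "ct"])
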