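"""End-to-end run: phenotypes CSV in, CSV tables plus report.json out.

:func:`run_pipeline` composes the whole analysis in order — load/validate,
replicate means, comprehensive membership evaluation, per-trait factorial
ANOVA, correlation structure under both treatments, PCA, hierarchical
classification and (optionally) qPCR fold changes — and writes every table
to the output directory along with a single ``report.json`` that mirrors
the result objects.  The report is deterministic: given identical inputs
and options, reruns are byte-identical (every written file is also recorded
with a sha256 checksum).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_genotypes
from .dataset import load_phenotypes, replicate_means
from .errors import ColdscoreError, ConfigError
from .evaluation import evaluate_cohort
from .qpcr import fold_change_table, load_ct_table
from .registry import default_registry, load_registry
from .stats import correlation_matrix, factorial_anova, pca

log = logging.getLogger("coldscore")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, in one committable object."""

    phenotypes: str | Path
    out_dir: str | Path
    registry: str | Path | None = None      # None -> default 29-trait panel
    qpcr: str | Path | None = None
    reference_gene: str | None = None
    control: str = "CK"
    stress: str = "LT"
    trait_subset: Sequence[str] | None = None
    cv_ddof: int = 1
    pca_scope: str = "pooled"
    k: int = 4
    linkage: str = "ward"
    metric: str = "euclidean"
    drop_incomplete: bool = False
    run_anova: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "phenotypes" not in raw or "out_dir" not in raw:
            raise ConfigError("config must set 'phenotypes' and 'out_dir'")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("phenotypes", "registry", "qpcr"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if self.qpcr is not None and not self.reference_gene:
            raise ConfigError("qpcr input requires reference_gene")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round(obj: Any, nd: int = 6) -> Any:
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return None if not np.isfinite(obj) else round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write outputs; returns the report dict."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, index=index, float_format="%.10g")
        written[name] = path

    registry = load_registry(cfg.registry) if cfg.registry else default_registry()
    ds = load_phenotypes(
        cfg.phenotypes, registry, control=cfg.control, stress=cfg.stress,
        drop_incomplete=cfg.drop_incomplete,
    )
    log.info("loaded %d genotypes x %d traits x 2 treatments",
             len(ds.genotypes), len(ds.traits))

    means = replicate_means(ds)
    evaluation = evaluate_cohort(
        ds, traits=cfg.trait_subset, cv_ddof=cfg.cv_ddof
    )
    emit("crc.csv", evaluation.crc.values)
    emit("membership.csv", evaluation.membership.values)
    scores = evaluation.scores.rename("u_score").rename_axis("genotype")
    emit("scores.csv", scores.to_frame())
    emit("rc_summary.csv", evaluation.rc_summary)
    emit("cvg.csv", evaluation.cvg)

    anova_rows = []
    if cfg.run_anova:
        for trait in ds.traits:
            res = factorial_anova(ds, trait)
            for factor in ("G", "T", "G:T", "Residual"):
                row = res.table.loc[factor]
                anova_rows.append(
                    (trait, factor, int(row["df"]), row["ss"], row["ms"],
                     row["F"], row["p"])
                )
        anova_df = pd.DataFrame(
            anova_rows, columns=["trait", "factor", "df", "ss", "ms", "F", "p"]
        )
        emit("anova.csv", anova_df, index=False)

    corr = {t: correlation_matrix(means, label)
            for t, label in (("control", cfg.control), ("stress", cfg.stress))}
    emit("corr_r_control.csv", corr["control"].r)
    emit("corr_p_control.csv", corr["control"].p)
    emit("corr_r_stress.csv", corr["stress"].r)
    emit("corr_p_stress.csv", corr["stress"].p)

    pca_res = pca(means, scope=cfg.pca_scope)
    eigen_df = pd.DataFrame(
        {
            "eigenvalue": pca_res.eigenvalues,
            "percent_variance": pca_res.percent_variance,
            "cumulative_percent": pca_res.cumulative_percent,
        },
        index=pd.Index([f"PC{k+1}" for k in range(len(pca_res.eigenvalues))],
                       name="component"),
    )
    emit("pca_eigen.csv", eigen_df)
    emit("pca_loadings.csv", pca_res.loadings)

    classification = classify_genotypes(
        evaluation.membership, k=cfg.k, method=cfg.linkage, metric=cfg.metric
    )
    emit("types.csv", classification.assignments, index=False)
    linkage_df = pd.DataFrame(
        classification.linkage, columns=["left", "right", "height", "n_members"]
    )
    emit("linkage.csv", linkage_df, index=False)
    (out / "dendrogram.nwk").write_text(classification.to_newick() + "\n")
    written["dendrogram.nwk"] = out / "dendrogram.nwk"

    qpcr_summary = None
    if cfg.qpcr is not None:
        ct = load_ct_table(cfg.qpcr)
        folds = fold_change_table(
            ct, reference_gene=cfg.reference_gene,
            control=cfg.control, stress=cfg.stress,
        )
        emit("qpcr_fold.csv", folds, index=False)
        qpcr_summary = [
            {"gene": r.gene, "genotype": r.genotype,
             "fold_change": r.fold_change, "fold_sd": r.fold_sd}
            for r in folds.itertuples()
        ]

    ranking = scores.sort_values(ascending=False)
    report = {
        "coldscore_version": __version__,
        "config": {
            "control": cfg.control, "stress": cfg.stress,
            "cv_ddof": cfg.cv_ddof, "pca_scope": cfg.pca_scope,
            "k": cfg.k, "linkage": cfg.linkage, "metric": cfg.metric,
        },
        "cohort": {
            "n_genotypes": len(ds.genotypes),
            "n_traits": len(ds.traits),
            "n_replicates": int(ds.replicate_counts().iloc[0]),
        },
        "rc_summary": {
            t: {"mean_rc": evaluation.rc_summary.loc[t, "mean_rc"],
                "rc_of_grand_means": evaluation.rc_summary.loc[t, "rc_of_grand_means"]}
            for t in evaluation.rc_summary.index
        },
        "cvg": {
            t: {cfg.control: evaluation.cvg.loc[t, cfg.control],
                cfg.stress: evaluation.cvg.loc[t, cfg.stress]}
            for t in evaluation.cvg.index
        },
        "anova": {
            trait: {
                factor: {"F": res_F, "p": res_p}
                for (t2, factor, _df, _ss, _ms, res_F, res_p) in anova_rows
                if t2 == trait and factor != "Residual"
            }
            for trait in ds.traits
        } if cfg.run_anova else None,
        "correlations": {
            label: {
                "n_significant_05": corr[label].n_significant_05,
                "n_significant_01": corr[label].n_significant_01,
            }
            for label in ("control", "stress")
        } | {
            "pooled_n_significant_05":
                corr["control"].n_significant_05 + corr["stress"].n_significant_05,
            "pooled_n_significant_01":
                corr["control"].n_significant_01 + corr["stress"].n_significant_01,
        },
        "pca": {
            "scope": pca_res.scope,
            "n_retained": pca_res.n_retained,
            "eigenvalues": list(pca_res.eigenvalues[: max(pca_res.n_retained, 5)]),
            "percent_variance": list(pca_res.percent_variance[: max(pca_res.n_retained, 5)]),
            "cumulative_retained_percent":
                float(pca_res.cumulative_percent[pca_res.n_retained - 1])
                if pca_res.n_retained else 0.0,
        },
        "scores": {
            "min": float(scores.min()), "max": float(scores.max()),
            "cv_percent": evaluation.score_cv,
            "ranking": [{"genotype": g, "u_score": float(v)}
                        for g, v in ranking.items()],
        },
        "types": {
            "per_genotype": {r.genotype: r.type
                             for r in classification.assignments.itertuples()},
            "summary": [
                {"type": r.type, "n": int(r.n), "mean_u": r.mean_u,
                 "min_u": r.min_u, "max_u": r.max_u}
                for r in classification.summary.itertuples()
            ],
        },
        "qpcr": qpcr_summary,
    }
    report["files"] = {name: _sha256(path) for name, path in sorted(written.items())}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(_round(report), indent=2, sort_keys=True) + "\n")
    log.info("wrote %d files to %s", len(written) + 1, out)
    return report


def run_from_yaml(path: str | Path) -> dict:
    try:
        return run_pipeline(RunConfig.from_yaml(path))
    except ColdscoreError:
        raise
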