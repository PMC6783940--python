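"""End-to-end orchestration: simulate/ingest -> express -> score -> model -> cluster/PCA.

Every stage writes its artifact as TSV (plus a JSON provenance sidecar)
so any stage can be re-run from the previous stage's files; the whole
run is deterministic given (config, inputs, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import FactorialDesign, code_levels, table1_design
from .multivariate import cut_clusters, pca_svd, pearson_distance, upgma_cluster
from .qpcr import CtTable, relative_expression
from .rsm import anova, fit_quadratic
from .scoring import PanelConfig, ScoreWeights, score_pipeline
from .simulate import (
    CALIBRATOR_SAMPLE,
    generate_ct_table,
    wnt_dominant_preset,
)

logger = logging.getLogger("stemfactor")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs"]

EXIT_VALIDATION = 2
EXIT_NUMERICAL = 3


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    out_dir: Path
    seed: int = 0
    scenario: str = "wnt_dominant"     # or "file" with ct_path set
    ct_path: Path | None = None
    noise_sd: float = 0.25
    effect_scale: float = 1.0
    pcr_replicates: int = 3
    reference_gene: str = "GAPDH"
    calibrator_sample: str = CALIBRATOR_SAMPLE
    include_controls_in_normalization: bool = True
    include_controls_in_fit: bool = False
    coding_scheme: str = "nominal"
    n_clusters: int = 2
    panels_path: Path | None = None
    weights_path: Path | None = None

    def content_hash(self) -> str:
        # hash the analysis-relevant settings; the output location is not
        # part of the scientific configuration
        payload = {k: str(v) for k, v in vars(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    models: dict[str, dict]
    cluster_assignments: dict[str, int]
    pca_explained: list[float]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "models": self.models,
                "cluster_assignments": self.cluster_assignments,
                "pca_explained_variance_ratio": self.pca_explained,
            },
            indent=2,
            sort_keys=True,
        )


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "sample") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def _sidecar(path: Path, config: PipelineConfig, stage: str, n_in: int, n_out: int) -> None:
    meta = {
        "stage": stage,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "records_in": n_in,
        "records_out": n_out,
        "version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def validate_inputs(
    ct: CtTable, design: FactorialDesign, panels: PanelConfig
) -> list[str]:
    """Cross-check Ct data, design and panel configuration; returns findings."""
    findings: list[str] = []
    obs_labels = set(design.observations()["observation"])
    control_labels = {ct.calibrator_sample, "E8", "E6"}
    for sample in ct.samples:
        if sample not in obs_labels and sample not in control_labels:
            findings.append(f"sample {sample!r} in Ct table absent from design")
    genes = {g.upper() for g in ct.target_genes}
    from .scoring import _canonical

    measured = {_canonical(g) for g in genes}
    for panel, panel_genes in panels.panels.items():
        for gene in panel_genes:
            if _canonical(gene) not in measured:
                findings.append(f"panel {panel!r} gene {gene!r} missing from Ct data")
    return findings


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages, writing artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = (
        PanelConfig.from_yaml(config.panels_path) if config.panels_path else PanelConfig.default()
    )
    weights = (
        ScoreWeights.from_yaml(config.weights_path)
        if config.weights_path
        else ScoreWeights.default()
    )

    # -- stage 1: design ---------------------------------------------------
    design = table1_design()
    obs = design.observations()
    X = code_levels(design, scheme=config.coding_scheme)
    conc = obs.rename(columns={n: f"{n}_conc" for n in design.factor_names})
    runs = conc.merge(X.reset_index(), on="observation")
    _write_tsv(runs.set_index("observation"), out / "runs.tsv", index_label="observation")
    _sidecar(out / "runs.tsv", config, "design", 0, len(runs))
    logger.info("design: %d runs, %d observations", design.n_runs, len(obs))

    # -- stage 2: Ct data --------------------------------------------------
    if config.scenario == "file":
        if config.ct_path is None:
            raise ValueError("scenario 'file' requires ct_path")
        ct = CtTable.from_csv(
            config.ct_path, config.reference_gene, config.calibrator_sample
        )
    else:
        scenario = wnt_dominant_preset(
            effect_scale=config.effect_scale,
            noise_sd=config.noise_sd,
            seed=config.seed,
            pcr_replicates=config.pcr_replicates,
        )
        ct = generate_ct_table(scenario)
    ct.to_csv(out / "ct.csv")
    _sidecar(out / "ct.csv", config, "ct", 0, len(ct.records))
    findings = validate_inputs(ct, design, panels)
    if findings:
        raise ValueError("input validation failed: " + "; ".join(findings))
    logger.info("ct: %d records, %d samples", len(ct.records), len(ct.samples))

    # -- stage 3: relative expression -------------------------------------
    expr = relative_expression(ct)
    _write_tsv(expr, out / "expression.tsv")
    _sidecar(out / "expression.tsv", config, "express", len(ct.records), expr.size)

    # -- stage 4: normalize / panels / scores ------------------------------
    factorial_labels = list(obs["observation"])
    cohort = expr if config.include_controls_in_normalization else expr.loc[factorial_labels]
    norm, panel_vals, scores = score_pipeline(cohort, panels, weights)
    _write_tsv(norm, out / "normalized.tsv")
    _write_tsv(panel_vals, out / "panels.tsv")
    _write_tsv(scores, out / "scores.tsv")
    _sidecar(out / "scores.tsv", config, "score", expr.size, scores.size)
    logger.info("scores: %d samples x %d scores", *scores.shape)

    # -- stage 5: quadratic models per score -------------------------------
    fit_scores = scores.loc[factorial_labels] if config.include_controls_in_fit is False else scores
    models = {}
    for name in fit_scores.columns:
        fit = fit_quadratic(X, fit_scores[name], response=name)
        table = anova(fit)
        mdir = out / f"model_{name.lower()}"
        mdir.mkdir(exist_ok=True)
        coef = pd.DataFrame({"estimate": fit.coefficients})
        coef = coef.join(table[["ss", "F", "p", "significant"]], how="left")
        _write_tsv(coef, mdir / "coefficients.tsv", index_label="term")
        (mdir / "summary.json").write_text(
            json.dumps(
                {
                    "r2": fit.r2,
                    "r2_adj": fit.r2_adj,
                    "df_total": fit.df_total,
                    "df_model": fit.df_model,
                    "df_residual": fit.df_residual,
                },
                indent=2,
                sort_keys=True,
            )
        )
        models[name] = {
            "r2": fit.r2,
            "r2_adj": fit.r2_adj,
            "df_residual": fit.df_residual,
            "coefficients": fit.coefficients.to_dict(),
            "significant_terms": list(table.index[table["significant"]]),
        }
        logger.info("model %s: r2=%.3f r2_adj=%.3f", name, fit.r2, fit.r2_adj)

    # -- stage 6: clustering + PCA ------------------------------------------
    cluster_input = scores.loc[factorial_labels]
    dist = pearson_distance(cluster_input)
    dend = upgma_cluster(dist)
    assignments = cut_clusters(dend, config.n_clusters)
    (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
    pd.Series(assignments, name="cluster").to_csv(
        out / "clusters.tsv", sep="\t", index_label="sample"
    )
    pca = pca_svd(cluster_input)
    _write_tsv(pca.scores, out / "pca_scores.tsv")
    _write_tsv(pca.loadings, out / "pca_loadings.tsv", index_label="variable")
    pd.DataFrame(
        {"explained_variance_ratio": pca.explained_variance_ratio},
        index=pca.scores.columns,
    ).to_csv(out / "pca_explained.tsv", sep="\t", index_label="component")
    logger.info(
        "cluster: k=%d; PCA PC1 %.1f%%",
        config.n_clusters,
        100 * pca.explained_variance_ratio[0],
    )

    report = RunReport(
        config_hash=config.content_hash(),
        seed=config.seed,
        models=models,
        cluster_assignments=assignments,
        pca_explained=[float(x) for x in pca.explained_variance_ratio],
    )
    (out / "report.json").write_text(report.to_json())
    return report
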