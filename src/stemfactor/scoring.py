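"""Marker-panel aggregation and weighted lineage scores.

Relative expression is first min-max normalized per gene across the
analyzed samples, so every gene lies on [0, 1] with its lowest sample
at 0 and highest at 1.  Genes are then averaged within lineage marker
panels (pluripotency, ectoderm, mesendoderm, mesoderm, endoderm), and
each lineage score is a fixed zero-sum weighted combination of the five
panel values.  The score weights reward the panel(s) of the lineage in
question and penalize competing fates; because each weight row sums to
zero, a sample expressing all panels equally scores zero everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PanelConfig",
    "ScoreWeights",
    "minmax_normalize",
    "compute_panels",
    "compute_scores",
    "score_pipeline",
    "DegenerateGeneError",
    "PanelConfigError",
]

# Synonymous gene symbols collapsed before panel lookup (upper-cased).
GENE_ALIASES = {
    "BRACHYURY": "T",
    "TBXT": "T",
    "NGFR": "P75",
    "POU5F1": "OCT4",
}


class PanelConfigError(ValueError):
    """Raised when panels/weights do not match the data or each other."""


class DegenerateGeneError(ValueError):
    """Raised when a gene is constant across samples (min == max)."""


def _canonical(gene: str) -> str:
    g = gene.upper()
    return GENE_ALIASES.get(g, g)


def _load_packaged(name: str) -> dict:
    text = resources.files("stemfactor.data").joinpath(name).read_text()
    return yaml.safe_load(text)


@dataclass
class PanelConfig:
    """Mapping of panel name -> ordered marker gene symbols."""

    panels: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.panels.items():
            if not genes:
                raise PanelConfigError(f"panel {name!r} is empty")

    @classmethod
    def default(cls) -> "PanelConfig":
        return cls(_load_packaged("panels.yaml")["panels"])

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh)["panels"])

    @property
    def panel_names(self) -> list[str]:
        return list(self.panels)

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.panels.values() for g in genes]


@dataclass
class ScoreWeights:
    """Score name x panel name weight matrix."""

    matrix: pd.DataFrame

    @classmethod
    def default(cls) -> "ScoreWeights":
        raw = _load_packaged("weights.yaml")["weights"]
        return cls(pd.DataFrame(raw).T)

    @classmethod
    def from_yaml(cls, path) -> "ScoreWeights":
        with open(path) as fh:
            raw = yaml.safe_load(fh)["weights"]
        return cls(pd.DataFrame(raw).T)

    @property
    def score_names(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def panel_names(self) -> list[str]:
        return list(self.matrix.columns)


def minmax_normalize(
    expr: pd.DataFrame, on_degenerate: str = "error"
) -> pd.DataFrame:
    """Per-gene min-max normalization to [0, 1] across samples.

    Parameters
    ----------
    expr : DataFrame, samples x genes
    on_degenerate : {"error", "zero"}
        What to do with a gene constant across samples: raise (default)
        or map it to all-zero with a warning.
    """
    if len(expr) < 2:
        raise ValueError("normalization needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    lo = expr.min(axis=0)
    hi = expr.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        genes = list(expr.columns[degenerate])
        if on_degenerate == "zero":
            warnings.warn(f"gene(s) constant across samples mapped to 0: {genes}")
            span = span.mask(degenerate, 1.0)
        else:
            raise DegenerateGeneError(
                f"gene(s) constant across samples (min == max): {genes}"
            )
    return (expr - lo) / span


def compute_panels(norm: pd.DataFrame, config: PanelConfig | None = None) -> pd.DataFrame:
    """Average normalized marker genes into sample x panel values.

    Gene symbols are matched case-insensitively and through the alias
    map (T = Brachyury = TBXT, P75 = NGFR).
    """
    config = config or PanelConfig.default()
    by_canonical = {_canonical(g): g for g in norm.columns}
    panels = {}
    for panel, genes in config.panels.items():
        cols = []
        for gene in genes:
            key = _canonical(gene)
            if key not in by_canonical:
                raise PanelConfigError(
                    f"panel {panel!r} gene {gene!r} missing from expression data"
                )
            cols.append(by_canonical[key])
        panels[panel] = norm[cols].mean(axis=1)
    return pd.DataFrame(panels)


def compute_scores(panels: pd.DataFrame, weights: ScoreWeights | None = None) -> pd.DataFrame:
    """Weighted lineage scores; columns ordered as the weight rows.

    score(sample, k) = sum_p weight(k, p) * panel(sample, p).
    """
    weights = weights or ScoreWeights.default()
    if set(weights.panel_names) != set(panels.columns):
        raise PanelConfigError(
            f"panel names {sorted(panels.columns)} do not match weight columns "
            f"{sorted(weights.panel_names)}"
        )
    aligned = panels[weights.panel_names]
    scores = aligned @ weights.matrix.T
    scores.attrs["lineage_assignment"] = scores.idxmax(axis=1).to_dict()
    return scores


def score_pipeline(
    expr: pd.DataFrame,
    config: PanelConfig | None = None,
    weights: ScoreWeights | None = None,
    on_degenerate: str = "error",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Normalize -> panels -> scores; returns (normalized, panels, scores)."""
    norm = minmax_normalize(expr, on_degenerate=on_degenerate)
    panels = compute_panels(norm, config)
    scores = compute_scores(panels, weights)
    return norm, panels, scores
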