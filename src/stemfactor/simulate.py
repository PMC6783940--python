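"""Synthetic factorial qPCR data from ground-truth response surfaces.

Each marker gene's true log2 relative expression (relative to the
calibrator condition) follows a full quadratic surface in the coded
factor levels.  Cycle-threshold values are generated by inverting the
comparative-Ct readout: a gene with log2 relative expression L amplifies
L cycles earlier, so target Ct = baseline - L plus Gaussian noise on the
Ct scale (the natural error scale of qPCR), and the reference gene is a
stable endogenous control.  Running the expression pipeline on noiseless
synthetic data therefore returns 2^L exactly, which makes every
downstream stage testable against known ground truth.

The ``wnt_dominant_preset`` encodes a scenario in which Wnt activation
(CHIR) dominates lineage commitment: mesendoderm markers rise steeply
with CHIR, pluripotency and ectoderm markers fall, mesoderm markers
peak at the intermediate CHIR level, and FGF x CHIR synergies carry the
signs seen in the reference screen (negative on pluripotency, positive
on ectoderm/mesoderm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FactorialDesign, code_levels, quadratic_terms, table1_design
from .qpcr import CtTable

__all__ = [
    "GeneSurface",
    "SyntheticScenario",
    "generate_ct_table",
    "wnt_dominant_preset",
    "REFERENCE_GENE",
    "CALIBRATOR_SAMPLE",
]

REFERENCE_GENE = "GAPDH"
CALIBRATOR_SAMPLE = "mTeSR1"

MARKER_GENES = [
    "OCT4", "NANOG",          # pluripotency
    "FGF5", "PAX6", "P75",    # ectoderm
    "MIXL1", "T",             # mesendoderm
    "NKX2.5", "MESP1",        # mesoderm
    "SOX17", "PDX1",          # endoderm
]


@dataclass(frozen=True)
class GeneSurface:
    """Ground-truth quadratic surface for one gene's log2 expression.

    ``coefficients`` maps model-term name (intercept, linear, squared,
    interaction) to its value on the coded scale, acting on log2
    relative expression.  ``baseline_ct`` is the Ct the gene would show
    at log2 relative expression 0.
    """

    gene: str
    coefficients: dict[str, float]
    baseline_ct: float = 25.0

    def __post_init__(self) -> None:
        if not (10.0 < self.baseline_ct < 35.0):
            raise ValueError(f"{self.gene}: baseline Ct {self.baseline_ct} outside (10, 35)")
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError(f"{self.gene}: non-finite coefficient")

    def log2_expression(self, coded_row: pd.Series) -> float:
        """Evaluate the surface at one coded design row."""
        return float(
            sum(beta * coded_row.get(term, 0.0) for term, beta in self.coefficients.items())
        )


@dataclass
class SyntheticScenario:
    """A complete recipe for one synthetic factorial qPCR dataset."""

    design: FactorialDesign
    surfaces: list[GeneSurface]
    noise_sd: float = 0.25          # Gaussian Ct noise SD, cycles
    pcr_replicates: int = 3         # technical replicates per (sample, gene)
    seed: int = 0
    reference_offset: float = 18.0  # reference-gene Ct
    # control condition label -> gene -> true log2 relative expression
    controls: dict[str, dict[str, float]] = field(default_factory=dict)
    coding_scheme: str = "nominal"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pcr_replicates < 1:
            raise ValueError("pcr_replicates must be >= 1")
        if CALIBRATOR_SAMPLE not in self.controls:
            raise ValueError(f"scenario must include the calibrator control {CALIBRATOR_SAMPLE!r}")

    @property
    def genes(self) -> list[str]:
        return [s.gene for s in self.surfaces]

    def true_log2_expression(self) -> pd.DataFrame:
        """Noise-free log2 relative expression, observation x gene.

        Factorial observations are evaluated on their surfaces; control
        conditions use their override values.
        """
        X = code_levels(self.design, scheme=self.coding_scheme)
        rows = {}
        for obs in X.index:
            rows[obs] = {s.gene: s.log2_expression(X.loc[obs]) for s in self.surfaces}
        for label, overrides in self.controls.items():
            rows[label] = {g: float(overrides.get(g, 0.0)) for g in self.genes}
        return pd.DataFrame(rows).T[self.genes]


def generate_ct_table(scenario: SyntheticScenario) -> CtTable:
    """Draw a seeded synthetic Ct table for the scenario.

    Draw order is fixed for reproducibility: observations in design
    order then controls in declaration order; within each observation,
    the reference gene first then marker genes in surface order; within
    each gene, technical replicates in index order.  In-memory Ct values
    are exact; CSV output writes them with 4 decimals.
    """
    rng = np.random.default_rng(scenario.seed)
    truth = scenario.true_log2_expression()
    baseline = {s.gene: s.baseline_ct for s in scenario.surfaces}
    records = []
    for obs in truth.index:
        for rep in range(1, scenario.pcr_replicates + 1):
            eps = rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0
            records.append(
                {
                    "sample": obs,
                    "gene": REFERENCE_GENE,
                    "replicate": rep,
                    "ct": scenario.reference_offset + eps,
                }
            )
        for gene in truth.columns:
            L = truth.loc[obs, gene]
            for rep in range(1, scenario.pcr_replicates + 1):
                eps = rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0
                records.append(
                    {
                        "sample": obs,
                        "gene": gene,
                        "replicate": rep,
                        "ct": baseline[gene] - L + eps,
                    }
                )
    return CtTable(
        records=pd.DataFrame(records),
        reference_gene=REFERENCE_GENE,
        calibrator_sample=CALIBRATOR_SAMPLE,
    )


def _scaled(coeffs: dict[str, float], scale: float) -> dict[str, float]:
    """Scale every non-intercept coefficient by the effect scale."""
    return {
        term: (beta if term == "intercept" else beta * scale)
        for term, beta in coeffs.items()
    }


def wnt_dominant_preset(
    effect_scale: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    pcr_replicates: int = 3,
) -> SyntheticScenario:
    """Scenario with dominant CHIR (Wnt) control of lineage commitment.

    Coded levels run -1 (no addition), -1/3 (one-third input), +1 (full
    input).  Dominant CHIR main effects use |beta| of 2-4 log2 units,
    synergies 0.5-1.  Mesoderm markers carry a concave CHIR response
    with vertex at the coded -1/3 level (maximal commitment at the
    intermediate dose); mesendoderm markers increase monotonically in
    CHIR.  ``effect_scale`` multiplies every non-intercept coefficient,
    so 0 yields a null dataset with no factor structure.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    s = effect_scale
    # Terms act on the coded scale: FGF2 = X1, TGFb = X2, CHIR = X3,
    # no addition = -1, one-third input = -1/3, full input = +1.
    pluri = {
        "intercept": -1.0,
        "FGF2": 0.5,
        "CHIR": -3.5,
        "CHIR^2": -0.5,
        "FGF2:CHIR": -0.75,
    }
    ecto = {
        "intercept": 0.0,
        "FGF2": -0.7,
        "TGFb^2": -0.6,
        "CHIR": -3.5,
        "CHIR^2": -0.5,
        "FGF2:CHIR": 0.7,
    }
    # monotone in CHIR on [-1, 1]: derivative 2 - 2*X3 >= 0
    mesend = {"intercept": 2.0, "CHIR": 2.0, "CHIR^2": -1.0}
    # concave in CHIR with vertex -(b3 + b13*X1)/(2*b33) inside
    # (-2/3, +1/3) for every FGF2 stratum, so the interior dose wins
    meso = {"intercept": 1.5, "CHIR": -2.27, "CHIR^2": -3.4, "FGF2:CHIR": 0.6}
    endo = {"intercept": 1.5, "FGF2": 0.6, "CHIR": 2.5, "CHIR^2": 0.8}
    by_gene = {
        "OCT4": pluri, "NANOG": pluri,
        "FGF5": ecto, "PAX6": ecto, "P75": ecto,
        "MIXL1": mesend, "T": mesend,
        "NKX2.5": meso, "MESP1": meso,
        "SOX17": endo, "PDX1": endo,
    }
    surfaces = [
        GeneSurface(gene=g, coefficients=_scaled(c, s), baseline_ct=24.0 + 0.5 * i)
        for i, (g, c) in enumerate(by_gene.items())
    ]
    # controls: calibrator is 0 by definition; E8 keeps cells pluripotent
    controls = {
        CALIBRATOR_SAMPLE: {g: 0.0 for g in by_gene},
        "E8": {
            g: (0.3 if c is pluri else -1.0) for g, c in by_gene.items()
        },
    }
    return SyntheticScenario(
        design=table1_design(e6_replicates=3),
        surfaces=surfaces,
        noise_sd=noise_sd,
        pcr_replicates=pcr_replicates,
        seed=seed,
        controls=controls,
    )


def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    """Serialize a scenario (surfaces, noise model, controls, seed) to YAML."""
    import yaml

    payload = {
        "noise_sd": scenario.noise_sd,
        "pcr_replicates": scenario.pcr_replicates,
        "seed": scenario.seed,
        "reference_offset": scenario.reference_offset,
        "coding_scheme": scenario.coding_scheme,
        "surfaces": [
            {
                "gene": s.gene,
                "baseline_ct": s.baseline_ct,
                "coefficients": dict(s.coefficients),
            }
            for s in scenario.surfaces
        ],
        "controls": scenario.controls,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def scenario_from_yaml(path) -> SyntheticScenario:
    """Load a scenario YAML; the design is always the 27-condition screen."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    surfaces = [
        GeneSurface(
            gene=s["gene"],
            coefficients={k: float(v) for k, v in s["coefficients"].items()},
            baseline_ct=float(s.get("baseline_ct", 25.0)),
        )
        for s in payload["surfaces"]
    ]
    return SyntheticScenario(
        design=table1_design(e6_replicates=3),
        surfaces=surfaces,
        noise_sd=float(payload.get("noise_sd", 0.25)),
        pcr_replicates=int(payload.get("pcr_replicates", 3)),
        seed=int(payload.get("seed", 0)),
        reference_offset=float(payload.get("reference_offset", 18.0)),
        controls={
            str(k): {str(g): float(v) for g, v in d.items()}
            for k, d in payload.get("controls", {}).items()
        },
        coding_scheme=str(payload.get("coding_scheme", "nominal")),
    )
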