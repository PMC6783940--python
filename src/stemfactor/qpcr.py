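"""Relative qPCR quantification by the comparative-Ct (2^-ΔΔCt) method.

Within each sample a target gene's mean Ct is normalized to an
endogenous reference gene (ΔCt); each sample's ΔCt is then normalized
to a designated calibrator sample (ΔΔCt), and relative expression is
2^-ΔΔCt.  The calibrator therefore maps to exactly 1 for every gene.
Technical PCR replicates are averaged on the Ct scale before ΔCt is
formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CtTable", "relative_expression", "CtDataError"]


class CtDataError(ValueError):
    """Raised for malformed or incomplete Ct data."""


@dataclass
class CtTable:
    """Long-format cycle-threshold measurements.

    ``records`` columns: ``sample``, ``gene``, ``replicate`` (technical
    PCR replicate index), ``ct`` (cycles).  ``reference_gene`` is the
    endogenous control (e.g. GAPDH); ``calibrator_sample`` the condition
    all expression is expressed relative to (e.g. mTeSR1).
    """

    records: pd.DataFrame
    reference_gene: str
    calibrator_sample: str
    drop_undetermined: bool = False

    REQUIRED_COLUMNS = ("sample", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise CtDataError(f"Ct table missing columns: {missing}")
        rec = self.records.copy()
        rec["ct"] = pd.to_numeric(rec["ct"], errors="coerce")
        bad = ~np.isfinite(rec["ct"]) | (rec["ct"] <= 0)
        if bad.any():
            if self.drop_undetermined:
                n = int(bad.sum())
                warnings.warn(f"dropping {n} undetermined/invalid Ct record(s)")
                rec = rec[~bad]
            else:
                first = rec[bad].iloc[0]
                raise CtDataError(
                    "non-finite or non-positive Ct value for sample "
                    f"{first['sample']!r}, gene {first['gene']!r}"
                )
        self.records = rec.reset_index(drop=True)
        self._validate_coverage()

    def _validate_coverage(self) -> None:
        rec = self.records
        genes = set(rec["gene"])
        if self.reference_gene not in genes:
            raise CtDataError(f"reference gene {self.reference_gene!r} absent from data")
        samples_with_ref = set(rec.loc[rec["gene"] == self.reference_gene, "sample"])
        for sample in rec["sample"].unique():
            if sample not in samples_with_ref:
                raise CtDataError(
                    f"sample {sample!r} has no reference-gene ({self.reference_gene!r}) measurement"
                )
        cal = rec[rec["sample"] == self.calibrator_sample]
        if cal.empty:
            raise CtDataError(f"calibrator sample {self.calibrator_sample!r} absent from data")
        cal_genes = set(cal["gene"])
        for gene in genes:
            if gene not in cal_genes:
                raise CtDataError(
                    f"calibrator sample {self.calibrator_sample!r} lacks gene {gene!r}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.records["sample"].unique())

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.records["gene"].unique() if g != self.reference_gene]

    @classmethod
    def from_csv(
        cls, path, reference_gene: str, calibrator_sample: str, **kwargs
    ) -> "CtTable":
        return cls(pd.read_csv(path), reference_gene, calibrator_sample, **kwargs)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.4f")


def relative_expression(ct: CtTable) -> pd.DataFrame:
    """Compute the sample x gene relative-expression matrix (2^-ΔΔCt).

    Returns a DataFrame of strictly positive relative quantities whose
    row for the calibrator sample equals 1 for every gene.  Method and
    calibrator provenance is recorded in ``DataFrame.attrs``.
    """
    mean_ct = (
        ct.records.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack("gene")
    )
    ref = mean_ct[ct.reference_gene]
    targets = [g for g in mean_ct.columns if g != ct.reference_gene]
    missing = mean_ct[targets].isna()
    if missing.to_numpy().any():
        gene = missing.any(axis=0).idxmax() if missing.any().any() else None
        gene = [g for g in targets if missing[g].any()][0]
        sample = missing.index[missing[gene]][0]
        raise CtDataError(f"sample {sample!r} lacks a Ct measurement for gene {gene!r}")
    delta_ct = mean_ct[targets].sub(ref, axis=0)
    ddct = delta_ct - delta_ct.loc[ct.calibrator_sample]
    expr = np.power(2.0, -ddct)
    expr.attrs["method"] = "2^-ddCt"
    expr.attrs["reference_gene"] = ct.reference_gene
    expr.attrs["calibrator_sample"] = ct.calibrator_sample
    return expr
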