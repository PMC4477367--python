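"""Survival cohort container and plain-text I/O.

A cohort couples a gene x patient expression matrix with right-censored
overall-survival records and the clinical covariates used by the
multivariate Cox models (age, FIGO stage, tumour grade, residual tumour
size class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = ["os_months", "event", "age", "stage", "grade", "residual"]


@dataclass
class SurvivalCohort:
    """Expression matrix plus aligned clinical records for one split.

    Parameters
    ----------
    expression
        Genes as rows, patients as columns; continuous values on a
        median-centred scale.  Replicate gene rows must already be
        combined (averaged) so the index is unique.
    clinical
        Indexed by patient id; columns ``os_months`` (positive float),
        ``event`` (1 = death observed, 0 = censored), ``age`` (years),
        ``stage`` (``III``/``IV``), ``grade`` (``G3``/``G4``) and
        ``residual`` (``0-10mm``/``>10mm``).
    split_label
        Cohort role, e.g. ``training``, ``test`` or ``external``.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    split_label: str = "training"

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError(
                "duplicate gene rows; combine replicates by averaging first"
            )
        if self.clinical.index.has_duplicates:
            raise ValueError("duplicate patient ids in clinical table")
        missing = [c for c in ("os_months", "event") if c not in self.clinical]
        if missing:
            raise ValueError(f"clinical table lacks columns: {missing}")
        patients = list(self.expression.columns)
        if set(patients) != set(self.clinical.index):
            raise ValueError(
                "patient ids differ between expression and clinical records"
            )
        # align clinical rows to expression column order
        self.clinical = self.clinical.loc[patients]
        if (self.clinical["os_months"] <= 0).any():
            raise ValueError("os_months must be positive")
        if not self.clinical["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def patients(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def os_months(self) -> pd.Series:
        return self.clinical["os_months"]

    @property
    def event(self) -> pd.Series:
        return self.clinical["event"]

    def n_patients(self) -> int:
        return self.expression.shape[1]

    def write(self, outdir: str | Path) -> None:
        """Write ``expression_<split>.tsv`` and ``clinical_<split>.tsv``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        expr = self.expression.copy()
        expr.index.name = "gene"
        expr.to_csv(outdir / f"expression_{self.split_label}.tsv", sep="\t")
        clin = self.clinical.copy()
        clin.index.name = "patient_id"
        clin.to_csv(outdir / f"clinical_{self.split_label}.tsv", sep="\t")


def read_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    split_label: str = "training",
) -> SurvivalCohort:
    """Load a cohort from the expression/clinical TSV pair.

    Replicate gene rows (duplicate index entries) are combined by
    averaging their expression values.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        expr = expr.groupby(level=0).mean()
    clin = pd.read_csv(clinical_path, sep="\t", index_col=0)
    clin.index = clin.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return SurvivalCohort(expression=expr, clinical=clin, split_label=split_label)


def median_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """Centre each patient column at its median."""
    return expression.sub(expression.median(axis=0), axis=1)
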