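"""Core data containers: expression matrices, clinical tables, cohorts.

All tabular data is held in pandas objects; the thin dataclass wrappers add
the invariants the analysis relies on (scale bookkeeping for expression,
required outcome columns for clinical data, sample alignment for cohorts)
and TSV round-tripping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import GeneSignature, default_signature

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "CtTable",
    "CohortDataset",
    "SurvivalOutcome",
    "CLINICAL_COVARIATES",
    "OUTCOME_COLUMNS",
]

#: The six clinicopathological covariates used in the survival models.
#: ``figo_stage`` is coded ordinally (II=0, III=1, IV=2) and
#: ``residual_disease`` ordinally (none=0, <=1cm=1, >1cm=2) so that the
#: clinical block stays at six variables.
CLINICAL_COVARIATES: tuple[str, ...] = (
    "age",
    "histology_serous",
    "figo_stage",
    "grade_high",
    "peritoneal",
    "residual_disease",
)

OUTCOME_COLUMNS: tuple[str, ...] = (
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "response",
)


@dataclass
class ExpressionMatrix:
    """Samples x genes relative-expression matrix.

    ``scale`` records whether ``values`` holds linear relative expression
    (strictly positive) or its log2.  Missing entries (NaN) are allowed
    before imputation.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.scale == "linear":
            bad = (self.values <= 0).any().any()
            if bad:
                raise ValueError("linear-scale expression must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "log2") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        df.index.name = None
        return cls(values=df, scale=scale)


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold values (samples x genes, Ct units).

    Housekeeping genes appear as regular columns; ``calibrator_id`` names
    the reference sample all expression values are expressed relative to.
    """

    ct: pd.DataFrame
    hkg_genes: tuple[str, ...]
    calibrator_id: str

    def __post_init__(self) -> None:
        missing_hkg = [g for g in self.hkg_genes if g not in self.ct.columns]
        if missing_hkg:
            raise ValueError(f"housekeeping genes absent from Ct table: {missing_hkg}")
        if self.calibrator_id not in self.ct.index:
            raise ValueError(f"calibrator sample {self.calibrator_id!r} absent from Ct table")
        vals = self.ct.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("Ct values must be finite where present")

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.columns if g not in self.hkg_genes]

    def to_tsv(self, path: str | Path) -> None:
        self.ct.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")

    @classmethod
    def from_tsv(
        cls, path: str | Path, hkg_genes: tuple[str, ...], calibrator_id: str
    ) -> "CtTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        return cls(ct=df, hkg_genes=tuple(hkg_genes), calibrator_id=calibrator_id)


@dataclass
class ClinicalTable:
    """Per-sample outcomes and clinicopathological covariates.

    Required columns: survival endpoints (``os_months``/``os_event``,
    ``pfs_months``/``pfs_event``), the binary first-line treatment
    ``response`` (1 = responder) and the six covariates in
    :data:`CLINICAL_COVARIATES`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [
            c for c in OUTCOME_COLUMNS + CLINICAL_COVARIATES if c not in self.table.columns
        ]
        if missing:
            raise ValueError(f"clinical table misses required columns: {missing}")
        for ep in ("os", "pfs"):
            t = self.table[f"{ep}_months"].to_numpy(dtype=float)
            e = self.table[f"{ep}_event"].dropna().to_numpy(dtype=float)
            if (t[~np.isnan(t)] <= 0).any():
                raise ValueError(f"{ep} times must be > 0")
            if not np.isin(e, [0.0, 1.0]).all():
                raise ValueError(f"{ep} event flags must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def outcome(self, endpoint: str) -> "SurvivalOutcome":
        endpoint = endpoint.upper()
        if endpoint not in ("OS", "PFS"):
            raise ValueError("endpoint must be 'OS' or 'PFS'")
        key = endpoint.lower()
        return SurvivalOutcome(
            time=self.table[f"{key}_months"].to_numpy(dtype=float),
            event=self.table[f"{key}_event"].to_numpy(dtype=int),
            endpoint=endpoint,
        )

    def covariates(self) -> pd.DataFrame:
        return self.table.loc[:, list(CLINICAL_COVARIATES)].astype(float)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        df.index.name = None
        return cls(table=df)


@dataclass
class SurvivalOutcome:
    """Right-censored survival outcome (times in months, event in {0,1})."""

    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if (self.time <= 0).any():
            raise ValueError("survival times must be > 0")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event flags must be 0/1")

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class CohortDataset:
    """Aligned expression + clinical data for one patient cohort.

    ``true_subtype`` is only populated for synthetic cohorts, where the
    generating immune-low/mixed/high labels are known.
    """

    expression: ExpressionMatrix
    clinical: ClinicalTable
    signature: GeneSignature = field(default_factory=default_signature)
    true_subtype: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise ValueError(
                "expression and clinical tables must share identical, "
                "identically ordered sample identifiers"
            )
        if self.true_subtype is not None and list(self.true_subtype.index) != self.expression.sample_ids:
            raise ValueError("true_subtype index must match the cohort samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def write(self, outdir: str | Path, config_json: dict | None = None) -> None:
        """Write the cohort as two TSV files plus an optional JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(outdir / "expression.tsv")
        self.clinical.to_tsv(outdir / "clinical.tsv")
        if self.true_subtype is not None:
            self.true_subtype.rename("true_subtype").to_csv(
                outdir / "true_subtype.tsv", sep="\t", index_label="sample_id"
            )
        if config_json is not None:
            (outdir / "config.json").write_text(json.dumps(config_json, indent=2))

    @classmethod
    def read(cls, indir: str | Path, scale: str = "log2") -> "CohortDataset":
        indir = Path(indir)
        expr = ExpressionMatrix.from_tsv(indir / "expression.tsv", scale=scale)
        clin = ClinicalTable.from_tsv(indir / "clinical.tsv")
        subtype_path = indir / "true_subtype.tsv"
        subtype = None
        if subtype_path.exists():
            subtype = pd.read_csv(subtype_path, sep="\t", index_col=0)["true_subtype"]
        return cls(expression=expr, clinical=clin, true_subtype=subtype)
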