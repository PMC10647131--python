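"""Data containers shared across the pipeline.

An :class:`ExpressionCohort` is a genes × samples matrix of continuous,
log-scale expression values with a per-sample dataset-of-origin label, the
in-memory form of the tab-separated expression files the pipeline reads.
A :class:`PhenotypeTable` carries the per-sample clinical annotation:
treatment-response class (pCR or RD), covariates used for stratified
splitting, and optional relapse-free-survival fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONSE_RD = "RD"
RESPONSE_PCR = "pCR"

#: phenotype column names the pipeline recognises
RESPONSE_COL = "response"
DATASET_COL = "dataset_of_origin"
TIME_COL = "time"
EVENT_COL = "event"


class CohortError(ValueError):
    """Raised when a cohort or phenotype table violates its contract."""


@dataclass
class ExpressionCohort:
    """Genes × samples expression matrix with dataset-of-origin labels.

    Parameters
    ----------
    expr
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Values are continuous and finite (NaN is tolerated only
        to mark an unmeasured gene in a sample; prediction handles it).
    dataset_of_origin
        Series mapping each sample id to the label of the dataset it came
        from. Defaults to a single dataset labelled ``"dataset0"``.
    """

    expr: pd.DataFrame
    dataset_of_origin: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dataset_of_origin is None:
            self.dataset_of_origin = pd.Series(
                "dataset0", index=self.expr.columns, name=DATASET_COL
            )
        self.dataset_of_origin = self.dataset_of_origin.reindex(self.expr.columns)
        self.validate()

    def validate(self) -> None:
        if self.expr.index.has_duplicates:
            dupes = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate gene ids: {dupes[:5]}")
        if self.expr.columns.has_duplicates:
            dupes = self.expr.columns[self.expr.columns.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample ids: {dupes[:5]}")
        if self.dataset_of_origin.isna().any():
            missing = self.dataset_of_origin.index[self.dataset_of_origin.isna()]
            raise CohortError(f"samples without dataset label: {list(missing[:5])}")
        vals = self.expr.to_numpy()
        if np.isinf(vals).any():
            raise CohortError("expression matrix contains infinite values")

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionCohort":
        return ExpressionCohort(
            self.expr.loc[:, list(sample_ids)],
            self.dataset_of_origin.loc[list(sample_ids)],
        )

    def to_tsv(self, path) -> None:
        """Write as TSV: first column gene id, remaining columns samples."""
        out = self.expr.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, dataset_of_origin=None) -> "ExpressionCohort":
        expr = pd.read_csv(path, sep="\t", index_col=0)
        expr.index = expr.index.astype(str)
        if dataset_of_origin is not None and not isinstance(
            dataset_of_origin, pd.Series
        ):
            dataset_of_origin = pd.Series(dataset_of_origin, index=expr.columns)
        return cls(expr, dataset_of_origin)


@dataclass
class PhenotypeTable:
    """Per-sample clinical annotation indexed by sample id.

    Recognised columns: ``response`` ({pCR, RD}), ``age`` (years),
    ``grade`` / ``t_stage`` / ``n_stage`` (categorical, with an explicit
    ``"Unknown"`` level), ``dataset_of_origin``, and optional survival
    fields ``time`` (months, > 0) and ``event`` (0/1) plus any Cox
    covariates (surgery type, menopausal status, radiotherapy).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.table.index.has_duplicates:
            raise CohortError("duplicate sample ids in phenotype table")
        if RESPONSE_COL in self.table.columns:
            resp = self.table[RESPONSE_COL].dropna()
            bad = set(resp.unique()) - {RESPONSE_RD, RESPONSE_PCR}
            if bad:
                raise CohortError(f"invalid response labels: {sorted(bad)}")
        if TIME_COL in self.table.columns:
            t = self.table[TIME_COL].dropna()
            if (t <= 0).any():
                raise CohortError("survival times must be > 0")
        if EVENT_COL in self.table.columns:
            ev = self.table[EVENT_COL].dropna()
            if not set(np.unique(ev)).issubset({0, 1}):
                raise CohortError("event indicator must be 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def response(self) -> pd.Series:
        if RESPONSE_COL not in self.table.columns:
            raise CohortError("phenotype table has no response column")
        return self.table[RESPONSE_COL]

    def matches(self, cohort: ExpressionCohort) -> bool:
        return set(self.table.index) >= set(cohort.samples)

    def subset(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.table.loc[list(sample_ids)])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, index_col=0))


def response_indicator(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Encode response labels as 1 for RD (positive class) and 0 for pCR."""
    arr = np.asarray(labels)
    bad = set(arr.tolist()) - {RESPONSE_RD, RESPONSE_PCR}
    if bad:
        raise CohortError(f"invalid response labels: {sorted(bad)}")
    return (arr == RESPONSE_RD).astype(np.int8)
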