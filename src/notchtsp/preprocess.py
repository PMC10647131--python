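"""Per-dataset normalisation, cohort merging and balanced stratified splitting.

The pipeline order is fixed: Z-score each dataset separately first, then
merge on common genes. Z-scoring after merging would let the dataset with
more samples dominate each gene's centring, so the two orders are not
interchangeable.

The train/test partition is a randomized balance search: candidate splits
are drawn stratified on the cross of response class × dataset of origin
(keeping class proportions within ±1 sample per stratum), and the candidate
minimizing the worst covariate imbalance is kept. Continuous covariates are
compared by standardized mean difference, categorical ones by total
variation distance over levels, with missing values treated as an explicit
"Unknown" level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    DATASET_COL,
    RESPONSE_COL,
    CohortError,
    ExpressionCohort,
    PhenotypeTable,
)

UNKNOWN = "Unknown"


def zscore_by_dataset(cohort: ExpressionCohort) -> ExpressionCohort:
    """Standardize each gene to mean 0, unit sd within each dataset group.

    Uses the sample standard deviation (n−1 denominator). Zero-variance
    rows map to all zeros rather than NaN so that degenerate genes stay
    usable downstream. Each dataset group needs at least two samples.
    """
    values = cohort.expr.to_numpy(dtype=float, copy=True)
    origin = cohort.dataset_of_origin.to_numpy()
    for ds in pd.unique(origin):
        cols = np.flatnonzero(origin == ds)
        if cols.size < 2:
            raise CohortError(
                f"dataset group {ds!r} has {cols.size} sample(s); "
                "need >= 2 to Z-score"
            )
        block = values[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        centered = block - mean
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centered / sd, 0.0)
        values[:, cols] = z
    expr = pd.DataFrame(values, index=cohort.expr.index, columns=cohort.expr.columns)
    return ExpressionCohort(expr, cohort.dataset_of_origin.copy())


def merge_on_common_genes(cohorts: Sequence[ExpressionCohort]) -> ExpressionCohort:
    """Concatenate cohorts column-wise over the intersection of their genes.

    Gene order follows the first cohort; dataset-of-origin labels are kept
    per sample. Duplicate sample ids across cohorts are an error.
    """
    if not cohorts:
        raise CohortError("no cohorts to merge")
    common = list(cohorts[0].expr.index)
    for c in cohorts[1:]:
        present = set(c.expr.index)
        common = [g for g in common if g in present]
    if not common:
        raise CohortError("cohorts share no genes")
    all_samples = [s for c in cohorts for s in c.samples]
    if len(set(all_samples)) != len(all_samples):
        dupes = pd.Index(all_samples)
        dupes = dupes[dupes.duplicated()].unique().tolist()
        raise CohortError(f"duplicate sample ids across cohorts: {dupes[:5]}")
    expr = pd.concat([c.expr.loc[common] for c in cohorts], axis=1)
    origin = pd.concat([c.dataset_of_origin for c in cohorts])
    return ExpressionCohort(expr, origin)


@dataclass(frozen=True)
class SplitResult:
    """A train/test partition with its covariate-balance diagnostic."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    balance: float  # max |standardized difference| over requested covariates
    balance_by_covariate: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, "train") for s in self.train_ids] + [
            (s, "test") for s in self.test_ids
        ]
        return pd.DataFrame(rows, columns=["sample_id", "partition"])


def _covariate_arrays(table: pd.DataFrame, covariates: Iterable[str]):
    """Pre-encode covariates for fast repeated balance scoring."""
    encoded = []
    for cov in covariates:
        if cov not in table.columns:
            raise CohortError(f"covariate {cov!r} not in phenotype table")
        col = table[cov]
        if col.isna().all():
            raise CohortError(f"covariate {cov!r} has only missing values")
        if pd.api.types.is_numeric_dtype(col) and col.nunique(dropna=True) > 2:
            encoded.append((cov, "numeric", col.to_numpy(dtype=float)))
        else:
            filled = col.astype(object).where(col.notna(), UNKNOWN).astype(str)
            codes, _ = pd.factorize(filled)
            encoded.append((cov, "categorical", codes))
    return encoded


def _balance_score(encoded, train_mask: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    test_mask = ~train_mask
    for cov, kind, arr in encoded:
        if kind == "numeric":
            finite = np.isfinite(arr)
            a = arr[train_mask & finite]
            b = arr[test_mask & finite]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
            out[cov] = 0.0 if pooled == 0 else abs(a.mean() - b.mean()) / pooled
        else:
            k = arr.max() + 1
            pa = np.bincount(arr[train_mask], minlength=k) / train_mask.sum()
            pb = np.bincount(arr[test_mask], minlength=k) / test_mask.sum()
            out[cov] = 0.5 * np.abs(pa - pb).sum()  # total variation distance
    return out


def _stratum_targets(sizes: np.ndarray, train_fraction: float) -> np.ndarray:
    """Per-stratum train counts: floors plus largest-remainder top-up so the
    overall train size is exactly round(fraction × n)."""
    n = int(sizes.sum())
    total = int(round(train_fraction * n))
    raw = train_fraction * sizes
    base = np.floor(raw).astype(int)
    remainder = raw - base
    extra = total - base.sum()
    order = np.argsort(-remainder, kind="stable")
    targets = base.copy()
    for idx in order[:extra]:
        targets[idx] += 1
    return targets


def stratified_split(
    pheno: PhenotypeTable,
    train_fraction: float = 0.7,
    covariates: Sequence[str] = (),
    seed: int = 0,
    n_candidates: int = 1000,
) -> SplitResult:
    """Draw a covariate-balanced train/test partition.

    ``n_candidates`` stratified random splits are generated from the seed
    and the one minimizing the maximum absolute standardized difference
    across ``covariates`` is returned. The partition is disjoint and
    exhaustive, with |train| = round(train_fraction × n), and reproducible
    for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise CohortError("train_fraction must be in (0, 1)")
    table = pheno.table
    n = len(table)
    strata_cols = [c for c in (RESPONSE_COL, DATASET_COL) if c in table.columns]
    if strata_cols:
        key = table[strata_cols].astype(str).agg("|".join, axis=1)
        strata_codes, _ = pd.factorize(key)
    else:
        strata_codes = np.zeros(n, dtype=int)
    n_strata = strata_codes.max() + 1
    sizes = np.bincount(strata_codes, minlength=n_strata)
    targets = _stratum_targets(sizes, train_fraction)
    members = [np.flatnonzero(strata_codes == g) for g in range(n_strata)]

    encoded = _covariate_arrays(table, covariates)
    rng = np.random.default_rng(seed)
    best_mask = None
    best_scores: dict[str, float] = {}
    best = np.inf
    for _ in range(max(1, n_candidates)):
        mask = np.zeros(n, dtype=bool)
        for g in range(n_strata):
            picked = rng.permutation(members[g])[: targets[g]]
            mask[picked] = True
        scores = _balance_score(encoded, mask) if encoded else {}
        worst = max(scores.values()) if scores else 0.0
        if worst < best:
            best, best_mask, best_scores = worst, mask, scores
            if not encoded:
                break
    assert best_mask is not None
    ids = np.asarray(table.index)
    return SplitResult(
        train_ids=tuple(ids[best_mask]),
        test_ids=tuple(ids[~best_mask]),
        balance=0.0 if not best_scores else float(best),
        balance_by_covariate={k: float(v) for k, v in best_scores.items()},
    )
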