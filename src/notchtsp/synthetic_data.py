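"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a merged multi-dataset expression cohort:

* planted rank-switching pairs — for each planted pair a latent ordering
  indicator is drawn per sample (Bernoulli with a class-specific switch
  probability, default 0.9 in RD and 0.1 in pCR) and the two expression
  values are realized as (z + δ, z − δ) around a shared latent level z,
  with the sign of δ set by the indicator; this keeps marginal
  distributions realistic while controlling the within-sample order
  exactly;
* null genes — independent standard normals;
* dataset structure — samples are assigned to datasets in blocks and each
  gene gets a per-dataset location/scale jitter, so per-dataset Z-scoring
  has real work to do;
* class imbalance and clinical covariates — RD:pCR defaults to 2:1 and
  age/grade/T-stage/N-stage are drawn to match a typical cohort table
  (covariates are independent of class by default, for balance testing);
* signature-linked survival — exponential event times whose hazard scales
  with the RD vote count, with uniform censoring calibrated to a target
  censoring fraction.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import (
    DATASET_COL,
    EVENT_COL,
    RESPONSE_COL,
    RESPONSE_PCR,
    RESPONSE_RD,
    TIME_COL,
    CohortError,
    ExpressionCohort,
    PhenotypeTable,
)
from .mechanism import PairConstraintSet

_GRADE_FREQS = {"Grade1": 0.01, "Grade2": 0.15, "Grade3": 0.69, "Unknown": 0.15}
_T_FREQS = {"T1": 0.04, "T2": 0.45, "T3": 0.26, "T4": 0.19, "Unknown": 0.06}
_N_FREQS = {"N0": 0.23, "N1": 0.39, "N2": 0.15, "N3": 0.09, "Unknown": 0.14}


@dataclass
class SimConfig:
    """Conditions of the simulated study.

    Defaults mirror the cohort structure the pipeline targets: ~300
    samples with a 2:1 RD:pCR imbalance pooled from 3 datasets, 5 planted
    switching pairs with switch probabilities 0.9 (RD) / 0.1 (pCR), and a
    background of null genes.
    """

    n_samples: int = 300
    rd_fraction: float = 2 / 3
    n_planted_pairs: int = 5
    p_switch_rd: float = 0.9
    p_switch_pcr: float = 0.1
    n_null_genes: int = 90
    n_datasets: int = 3
    gene_budget: int | None = None  # cap on total genes, None = no cap
    # expression realization: the order gap δ is uniform on delta_range,
    # bounded away from 0 so per-dataset centring cannot flip orderings
    delta_range: tuple[float, float] = (0.3, 1.2)
    dataset_shift_sd: float = 0.25
    dataset_scale_range: tuple[float, float] = (0.8, 1.25)
    # covariates
    age_mean: float = 50.0
    age_sd: float = 11.0
    grade_freqs: dict[str, float] = field(default_factory=lambda: dict(_GRADE_FREQS))
    t_stage_freqs: dict[str, float] = field(default_factory=lambda: dict(_T_FREQS))
    n_stage_freqs: dict[str, float] = field(default_factory=lambda: dict(_N_FREQS))
    # survival
    baseline_hazard: float = 0.02  # events per month at zero votes
    log_hr_per_vote: float = math.log(2.5) / 4
    censoring_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_switch_rd, self.p_switch_pcr):
            if not 0 <= p <= 1:
                raise CohortError("switch probabilities must be in [0, 1]")
        if not 0 < self.rd_fraction < 1:
            raise CohortError("rd_fraction must be in (0, 1)")
        if min(self.n_samples, self.n_planted_pairs, self.n_null_genes) < 0:
            raise CohortError("counts must be non-negative")
        n_genes = 2 * self.n_planted_pairs + self.n_null_genes
        if self.gene_budget is not None and n_genes > self.gene_budget:
            raise CohortError(
                f"{n_genes} genes requested but gene_budget={self.gene_budget}"
            )


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[ExpressionCohort, PhenotypeTable, dict]:
    """Draw one cohort; returns (expression, phenotype, truth record).

    The truth record lists the planted pair identities, the configured
    switch probabilities, the null gene names, and the per-sample true
    vote counts (sum of latent ordering indicators), which downstream
    survival simulation uses.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    n_rd = int(round(cfg.rd_fraction * n))
    labels = np.array([RESPONSE_RD] * n_rd + [RESPONSE_PCR] * (n - n_rd))
    rng.shuffle(labels)
    is_rd = labels == RESPONSE_RD

    # dataset blocks of near-equal size
    bounds = np.linspace(0, n, cfg.n_datasets + 1).round().astype(int)
    origin = np.empty(n, dtype=object)
    for d in range(cfg.n_datasets):
        origin[bounds[d] : bounds[d + 1]] = f"dataset{d}"

    up_genes = [f"UP{i:02d}" for i in range(cfg.n_planted_pairs)]
    dn_genes = [f"DN{i:02d}" for i in range(cfg.n_planted_pairs)]
    null_genes = [f"NULL{i:03d}" for i in range(cfg.n_null_genes)]
    genes = [g for pair in zip(up_genes, dn_genes) for g in pair] + null_genes

    values = np.empty((len(genes), n))
    p_vec = np.where(is_rd, cfg.p_switch_rd, cfg.p_switch_pcr)
    true_votes = np.zeros(n, dtype=int)
    d_lo, d_hi = cfg.delta_range
    for j in range(cfg.n_planted_pairs):
        indicator = rng.random(n) < p_vec
        true_votes += indicator
        z = rng.normal(0.0, 1.0, size=n)
        delta = rng.uniform(d_lo, d_hi, size=n)
        sign = np.where(indicator, 1.0, -1.0)
        values[2 * j] = z + sign * delta  # up gene
        values[2 * j + 1] = z - sign * delta  # down gene
    values[2 * cfg.n_planted_pairs :] = rng.normal(
        0.0, 1.0, size=(cfg.n_null_genes, n)
    )

    # per-dataset location/scale jitter, drawn per gene; the two members of
    # a planted pair share their draw so the jitter cannot flip the planted
    # within-sample ordering
    lo, hi = cfg.dataset_scale_range
    for d in range(cfg.n_datasets):
        cols = slice(bounds[d], bounds[d + 1])
        shift = rng.normal(0.0, cfg.dataset_shift_sd, size=(len(genes), 1))
        scale = rng.uniform(lo, hi, size=(len(genes), 1))
        for j in range(cfg.n_planted_pairs):
            shift[2 * j + 1, 0] = shift[2 * j, 0]
            scale[2 * j + 1, 0] = scale[2 * j, 0]
        values[:, cols] = shift + scale * values[:, cols]

    expr = pd.DataFrame(values, index=genes, columns=samples)
    origin_s = pd.Series(origin, index=samples, name=DATASET_COL)
    cohort = ExpressionCohort(expr, origin_s)

    def _draw_cat(freqs: dict[str, float]) -> np.ndarray:
        levels = list(freqs)
        probs = np.array(list(freqs.values()), dtype=float)
        return rng.choice(levels, size=n, p=probs / probs.sum())

    pheno = pd.DataFrame(
        {
            RESPONSE_COL: labels,
            "age": rng.normal(cfg.age_mean, cfg.age_sd, size=n).round(1),
            "grade": _draw_cat(cfg.grade_freqs),
            "t_stage": _draw_cat(cfg.t_stage_freqs),
            "n_stage": _draw_cat(cfg.n_stage_freqs),
            DATASET_COL: origin,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    truth = {
        "planted_pairs": list(zip(up_genes, dn_genes)),
        "null_genes": null_genes,
        "p_switch_rd": cfg.p_switch_rd,
        "p_switch_pcr": cfg.p_switch_pcr,
        "true_votes": pd.Series(true_votes, index=samples, name="true_votes"),
        "seed": cfg.seed,
    }
    return cohort, PhenotypeTable(pheno), truth


def _censoring_horizon(hazards: np.ndarray, target: float) -> float:
    """Solve for the uniform-censoring upper bound giving the target
    expected censoring fraction."""

    def frac_censored(c: float) -> float:
        lc = hazards * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-9, 1e-9
    while frac_censored(hi) > target:
        hi *= 10
        if hi > 1e12:
            return hi
    return brentq(lambda c: frac_censored(c) - target, lo, hi, xtol=1e-10)


def simulate_survival(
    votes, cfg: SimConfig, seed: int | None = None, censoring_time: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard h0·exp(logHR_per_vote × votes).

    Censoring times are uniform on [0, c], with c solved numerically so
    the expected censoring fraction matches ``cfg.censoring_fraction``
    (or taken from ``censoring_time`` when given). Returns (observed
    time, event indicator); time is in months.
    """
    v = np.asarray(votes, dtype=float)
    if cfg.baseline_hazard <= 0:
        raise CohortError("baseline hazard must be positive")
    ss = np.random.SeedSequence(
        (cfg.seed & 0x7FFFFFFF, 9001) if seed is None else (seed & 0x7FFFFFFF, 9001)
    )
    rng = np.random.default_rng(ss)
    hazards = cfg.baseline_hazard * np.exp(cfg.log_hr_per_vote * v)
    event_times = rng.exponential(1.0 / hazards)
    c = (
        censoring_time
        if censoring_time is not None
        else _censoring_horizon(hazards, cfg.censoring_fraction)
    )
    censor_times = rng.uniform(0.0, max(c, 1e-12), size=v.size)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    observed = np.maximum(observed, 1e-9)  # times must stay positive
    return observed, event


def fixture_mechanism(
    truth: dict, extra_null_pairs: int = 0, seed: int | None = None
) -> PairConstraintSet:
    """Mechanism containing the planted pairs plus null-gene decoy pairs.

    Decoys pair genes from one half of the null pool against the other
    (so no gene appears on both sides), sampled without replacement and
    shuffled together with the planted pairs, deterministically from the
    seed (default: the truth record's seed).
    """
    planted = [tuple(p) for p in truth["planted_pairs"]]
    nulls = list(truth["null_genes"])
    half = len(nulls) // 2
    null_up, null_dn = nulls[:half], nulls[half:]
    max_pairs = len(null_up) * len(null_dn)
    if extra_null_pairs > max_pairs:
        raise CohortError(
            f"{extra_null_pairs} null pairs requested but only {max_pairs} "
            f"are possible from {len(nulls)} null genes"
        )
    rng = np.random.default_rng(truth["seed"] if seed is None else seed)
    chosen = rng.choice(max_pairs, size=extra_null_pairs, replace=False)
    decoys = [
        (null_up[i // len(null_dn)], null_dn[i % len(null_dn)]) for i in sorted(chosen)
    ]
    pairs = planted + decoys
    order = rng.permutation(len(pairs))
    return PairConstraintSet([pairs[i] for i in order])
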