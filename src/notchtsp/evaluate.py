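"""Classification performance: confusion metrics, ROC/PRC, DeLong tests,
and a logistic-regression harness for comparing gene signatures.

The positive class is RD (residual disease) throughout; a classifier's
score is its RD-vote fraction or RD probability. AUC is the tie-corrected
Mann–Whitney probability P(score_RD > score_pCR) + ½·P(equal). DeLong's
method estimates the variance of that statistic from its structural
components, giving a normal test of AUC against 0.5 (one classifier) or of
the difference between two correlated AUCs measured on the same samples.

The precision–recall area uses step-wise summation (Σ precision·Δrecall,
as in average precision), not trapezoids, which avoids the optimistic bias
of linear interpolation in PR space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .cohort import ExpressionCohort, response_indicator


class EvalError(ValueError):
    """Raised on invalid evaluation input."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion table; positive class is RD."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvalError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, predicted, truth) -> "ConfusionCounts":
        yhat = response_indicator(predicted)
        y = response_indicator(truth)
        return cls(
            tp=int(((yhat == 1) & (y == 1)).sum()),
            fp=int(((yhat == 1) & (y == 0)).sum()),
            tn=int(((yhat == 0) & (y == 0)).sum()),
            fn=int(((yhat == 0) & (y == 1)).sum()),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, balanced accuracy and MCC from counts.

    A metric whose denominator is empty (no positives for sensitivity, no
    negatives for specificity) is reported as NaN; MCC is defined as 0
    when any marginal is zero.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = tp / (tp + fn) if tp + fn > 0 else math.nan
    spec = tn / (tn + fp) if tn + fp > 0 else math.nan
    bal = (
        (sens + spec) / 2
        if not (math.isnan(sens) or math.isnan(spec))
        else math.nan
    )
    marginals = [tp + fn, tn + fp, tp + fp, tn + fn]
    if 0 in marginals:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(marginals))
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": bal,
        "mcc": mcc,
    }


def _scores_and_classes(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = response_indicator(labels)
    if s.shape != y.shape:
        raise EvalError("scores and labels must align")
    if y.sum() == 0 or y.sum() == y.size:
        raise EvalError("both classes must be present")
    return s, y


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Tie-corrected AUC plus the ROC curve at every distinct threshold."""
    s, y = _scores_and_classes(scores, labels)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return auc, curve


def pr_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Step-wise precision–recall area (average precision) plus the curve.

    The no-skill baseline equals the positive prevalence.
    """
    s = np.asarray(scores, dtype=float)
    y = response_indicator(labels)
    if y.sum() == 0:
        raise EvalError("at least one positive (RD) sample required")
    ap = float(average_precision_score(y, s))
    precision, recall, thr = precision_recall_curve(y, s)
    curve = pd.DataFrame(
        {
            "threshold": np.append(thr, np.nan),
            "recall": recall,
            "precision": precision,
        }
    )
    return ap, curve


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components: V10 per positive, V01 per negative."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


@dataclass(frozen=True)
class DeLongResult:
    """AUC (or AUC difference) with its DeLong variance-based test."""

    auc: float
    se: float
    z: float
    p: float  # one-sided upper tail
    ci_low: float
    ci_high: float
    degenerate: bool = False


def delong_vs_half(scores, labels) -> DeLongResult:
    """Test AUC > 0.5 by DeLong's variance of the Mann–Whitney statistic.

    Returns the one-sided upper-tail p and a 95% Wald CI truncated to
    [0, 1]. Score vectors with zero component variance (e.g. constant
    scores) are flagged degenerate and reported with p = 1.
    """
    s, y = _scores_and_classes(scores, labels)
    m, n = int(y.sum()), int((y == 0).sum())
    if m < 2 or n < 2:
        raise EvalError("need >= 2 samples in each class for DeLong variance")
    v10, v01 = _delong_components(s, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        return DeLongResult(auc, 0.0, 0.0, 1.0, auc, auc, degenerate=True)
    se = math.sqrt(var)
    z = (auc - 0.5) / se
    return DeLongResult(
        auc=auc,
        se=se,
        z=z,
        p=float(norm.sf(z)),
        ci_low=max(0.0, auc - 1.96 * se),
        ci_high=min(1.0, auc + 1.96 * se),
        degenerate=False,
    )


def delong_paired(scores_a, scores_b, labels) -> DeLongResult:
    """One-sided DeLong test that AUC_a > AUC_b on the same samples.

    The ``auc`` field of the result holds the AUC difference (a − b).
    Identical score vectors give difference 0 and p = 1, flagged
    degenerate.
    """
    sa, y = _scores_and_classes(scores_a, labels)
    sb = np.asarray(scores_b, dtype=float)
    if sb.shape != sa.shape:
        raise EvalError("paired score vectors must have equal length")
    m, n = int(y.sum()), int((y == 0).sum())
    v10a, v01a = _delong_components(sa, y)
    v10b, v01b = _delong_components(sb, y)
    diff = float(v10a.mean() - v10b.mean())
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = d10.var(ddof=1) / m + d01.var(ddof=1) / n
    if var <= 0:
        p = 1.0 if diff <= 0 else 0.0
        return DeLongResult(diff, 0.0, 0.0, p, diff, diff, degenerate=True)
    se = math.sqrt(var)
    z = diff / se
    return DeLongResult(
        auc=diff,
        se=se,
        z=z,
        p=float(norm.sf(z)),
        ci_low=diff - 1.96 * se,
        ci_high=diff + 1.96 * se,
        degenerate=False,
    )


@dataclass
class EvalReport:
    """Full classification report for one score/label vector pair."""

    auc_roc: float
    auc_ci_low: float
    auc_ci_high: float
    auc_p_vs_chance: float
    au_prc: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcc: float
    n: int
    n_rd: int
    n_pcr: int

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def evaluate_predictions(predictions: pd.DataFrame, truth) -> EvalReport:
    """Score a prediction table (columns ``score`` and ``label``) against
    true response labels."""
    truth = (
        truth.loc[predictions.index] if isinstance(truth, pd.Series) else truth
    )
    y = response_indicator(truth)
    dl = delong_vs_half(predictions["score"].to_numpy(), truth)
    ap, _ = pr_auc(predictions["score"].to_numpy(), truth)
    cm = confusion_metrics(ConfusionCounts.from_labels(predictions["label"], truth))
    return EvalReport(
        auc_roc=dl.auc,
        auc_ci_low=dl.ci_low,
        auc_ci_high=dl.ci_high,
        auc_p_vs_chance=dl.p,
        au_prc=ap,
        n=int(y.size),
        n_rd=int(y.sum()),
        n_pcr=int((y == 0).sum()),
        **cm,
    )


@dataclass
class HarnessResult:
    """Per-signature test AUCs with paired DeLong comparison to a reference."""

    table: pd.DataFrame  # signature, n_genes_used, auc, delong_p_vs_reference
    scores: dict[str, np.ndarray]
    skipped: list[str]


def logistic_signature_harness(
    train_cohort: ExpressionCohort,
    train_labels,
    test_cohort: ExpressionCohort,
    test_labels,
    gene_lists: dict[str, list[str]],
    reference: str | np.ndarray,
    ridge_c: float = 1.0,
) -> HarnessResult:
    """Re-train each gene list as a ridge logistic model and compare AUCs.

    For every named gene list the measured genes (present in both cohorts)
    feed an L2-penalized logistic regression fit on the training samples;
    its RD probabilities on the test samples give the test AUC and a
    paired one-sided DeLong test against the reference. The reference is
    either the name of one of the lists or an externally supplied test
    score vector (e.g. the fixed voting signature's scores). Lists with no
    measured genes are skipped with a warning.
    """
    y_train = response_indicator(train_labels)
    measured = set(train_cohort.expr.index) & set(test_cohort.expr.index)
    scores: dict[str, np.ndarray] = {}
    used: dict[str, int] = {}
    skipped: list[str] = []
    for name, genes in gene_lists.items():
        genes_used = [g for g in dict.fromkeys(genes) if g in measured]
        if not genes_used:
            skipped.append(name)
            warnings.warn(f"signature {name!r}: no genes measured; skipped")
            continue
        Xtr = train_cohort.expr.loc[genes_used].to_numpy(dtype=float).T
        Xte = test_cohort.expr.loc[genes_used].to_numpy(dtype=float).T
        model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=2000)
        model.fit(Xtr, y_train)
        scores[name] = model.predict_proba(Xte)[:, 1]
        used[name] = len(genes_used)

    if isinstance(reference, str):
        if reference not in scores:
            raise EvalError(f"reference signature {reference!r} was not fitted")
        ref_scores = scores[reference]
    else:
        ref_scores = np.asarray(reference, dtype=float)

    rows = []
    for name, s in scores.items():
        auc, _ = roc_auc(s, test_labels)
        dl = delong_paired(ref_scores, s, test_labels)
        rows.append((name, used[name], auc, dl.p))
    table = pd.DataFrame(
        rows, columns=["signature", "n_genes_used", "auc", "delong_p_vs_reference"]
    )
    return HarnessResult(table=table, scores=scores, skipped=skipped)
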