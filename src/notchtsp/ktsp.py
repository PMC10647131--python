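"""Rank-based top-scoring-pairs scoring, search and voting prediction.

A gene pair (u, d) is informative when the within-sample ordering of u and d
switches between classes. Its switch score is

    delta = P(expr_u > expr_d | RD) − P(expr_u > expr_d | pCR),

with strict inequality (equal values contribute nothing to either
proportion), so delta ∈ [−1, 1] and is exactly antisymmetric under swapping
the two genes. Candidate pairs come only from a biological mechanism (see
:mod:`notchtsp.mechanism`); pairs outside it are never scored.

Prediction is by voting: a pair votes for RD when its up-gene is strictly
above its down-gene in that sample, and a sample is called RD when the vote
count reaches the signature's threshold (scaled proportionally when some
signature genes are unmeasured). Because votes depend only on within-sample
orderings, predictions are invariant to any strictly increasing transform
applied to a sample's values.

The module ships the published fixed signature of five pairs with a
two-vote threshold (:func:`notch_5tsp`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import RESPONSE_PCR, RESPONSE_RD, ExpressionCohort, response_indicator
from .mechanism import MechanismError, PairConstraintSet


class KTSPError(ValueError):
    """Raised on invalid scoring or prediction input."""


@dataclass(frozen=True)
class ScoredPair:
    """A gene pair with its switch score and secondary rank statistic."""

    gene_up: str
    gene_down: str
    delta: float = math.nan
    tiebreak: float = math.nan

    def swapped(self) -> "ScoredPair":
        return replace(
            self,
            gene_up=self.gene_down,
            gene_down=self.gene_up,
            delta=-self.delta,
            tiebreak=-self.tiebreak,
        )


@dataclass
class TSPSignature:
    """An ordered list of voting pairs plus the RD vote threshold."""

    pairs: list[ScoredPair]
    vote_threshold: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.vote_threshold <= len(self.pairs):
            raise KTSPError(
                f"vote_threshold {self.vote_threshold} outside 1..{len(self.pairs)}"
            )
        for p in self.pairs:
            if p.gene_up == p.gene_down:
                raise KTSPError(f"pair with identical genes: {p.gene_up!r}")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out: dict[str, None] = {}
        for p in self.pairs:
            out.setdefault(p.gene_up)
            out.setdefault(p.gene_down)
        return list(out)

    def to_tsv(self, path) -> None:
        """Write pairs as TSV with a comment header carrying k and threshold."""
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\tvote_threshold={self.vote_threshold}\n")
            fh.write("gene_up\tgene_down\tdelta\ttiebreak\n")
            for p in self.pairs:
                fh.write(f"{p.gene_up}\t{p.gene_down}\t{p.delta}\t{p.tiebreak}\n")

    @classmethod
    def from_tsv(cls, path) -> "TSPSignature":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#"):
                raise KTSPError("signature file must start with a '# k=...' header")
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").split("\t")
            )
            df = pd.read_csv(fh, sep="\t", dtype={"gene_up": str, "gene_down": str})
        pairs = [
            ScoredPair(r.gene_up, r.gene_down, float(r.delta), float(r.tiebreak))
            for r in df.itertuples()
        ]
        sig = cls(pairs, vote_threshold=int(meta["vote_threshold"]))
        if sig.k != int(meta["k"]):
            raise KTSPError("signature header k does not match number of pairs")
        return sig


#: The published fixed 5-pair signature (k = 5, two votes call RD).
_NOTCH_5TSP_PAIRS = (
    ("GARS", "PDCD10"),
    ("CCND1", "FNDC3A"),
    ("CMA1", "PTHLH"),
    ("F2R", "KLF4"),
    ("PCDH7", "TOX"),
)


def notch_5tsp() -> TSPSignature:
    """The fixed Notch 5-TSPs signature: five pairs, two-vote RD threshold.

    Each pair votes RD when its first gene is expressed above its second
    within a sample; switch scores are not part of the published constant
    and are left NaN.
    """
    return TSPSignature(
        [ScoredPair(u, d) for u, d in _NOTCH_5TSP_PAIRS], vote_threshold=2
    )


def tsp_score(
    expr_up: np.ndarray,
    expr_down: np.ndarray,
    labels,
    gene_up: str = "gene_up",
    gene_down: str = "gene_down",
) -> ScoredPair:
    """Score one pair: class difference in P(up > down) plus a tiebreak.

    ``labels`` holds RD/pCR per sample. The tiebreak is the difference of
    class-mean (up − down) values; when the inputs are within-sample ranks
    (as :func:`constrained_search` supplies) this is the classic k-TSP
    secondary rank statistic. delta itself only depends on orderings, so it
    is identical whether raw values or within-sample ranks are passed.
    """
    up = np.asarray(expr_up, dtype=float)
    down = np.asarray(expr_down, dtype=float)
    if up.shape != down.shape or up.ndim != 1:
        raise KTSPError("expression vectors must be 1-D and equal length")
    y = response_indicator(labels)
    if y.shape != up.shape:
        raise KTSPError("labels must align with expression vectors")
    n_rd = int(y.sum())
    n_pcr = int(y.size - n_rd)
    if n_rd == 0 or n_pcr == 0:
        raise KTSPError("both classes must be present to score a pair")
    greater = up > down
    diff = up - down
    rd_hits = int(greater[y == 1].sum())
    pcr_hits = int(greater[y == 0].sum())
    # single-fraction form keeps delta exactly antisymmetric under gene swap
    delta = (rd_hits * n_pcr - pcr_hits * n_rd) / (n_rd * n_pcr)
    tiebreak = diff[y == 1].mean() - diff[y == 0].mean()
    return ScoredPair(gene_up, gene_down, float(delta), float(tiebreak))


def constrained_search(
    cohort: ExpressionCohort,
    labels,
    mech: PairConstraintSet,
    min_delta: float = 0.0,
) -> list[ScoredPair]:
    """Score every mechanism pair and keep those with delta > min_delta.

    The result is sorted by delta descending, then tiebreak descending,
    then mechanism pair order. Tiebreaks are computed on within-sample
    ranks of the full cohort matrix, so they are comparable across pairs.
    Pairs outside the mechanism are never scored.
    """
    if len(mech) == 0:
        raise MechanismError("mechanism is empty")
    missing = [g for g in mech.genes if g not in cohort.expr.index]
    if missing:
        raise KTSPError(
            f"mechanism genes not measured (restrict first): {missing[:5]}"
        )
    y = response_indicator(
        labels.loc[cohort.samples] if isinstance(labels, pd.Series) else labels
    )
    if y.size != cohort.n_samples:
        raise KTSPError("labels must align with cohort samples")
    if y.sum() == 0 or y.sum() == y.size:
        raise KTSPError("both classes must be present")

    values = cohort.expr.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(cohort.expr.index)}
    up_idx = np.fromiter((gene_index[u] for u, _ in mech.pairs), dtype=int)
    dn_idx = np.fromiter((gene_index[d] for _, d in mech.pairs), dtype=int)

    greater = values[up_idx] > values[dn_idx]  # pairs × samples
    rd, pcr = y == 1, y == 0
    n_rd, n_pcr = int(rd.sum()), int(pcr.sum())
    delta = (
        greater[:, rd].sum(axis=1) * n_pcr - greater[:, pcr].sum(axis=1) * n_rd
    ) / (n_rd * n_pcr)

    ranks = rankdata(values, axis=0)  # within-sample ranks, ties averaged
    rank_diff = ranks[up_idx] - ranks[dn_idx]
    tiebreak = rank_diff[:, rd].mean(axis=1) - rank_diff[:, pcr].mean(axis=1)

    keep = np.flatnonzero(delta > min_delta)
    order = keep[np.lexsort((keep, -tiebreak[keep], -delta[keep]))]
    return [
        ScoredPair(
            mech.pairs[i][0], mech.pairs[i][1], float(delta[i]), float(tiebreak[i])
        )
        for i in order
    ]


def predict(cohort: ExpressionCohort, sig: TSPSignature) -> pd.DataFrame:
    """Vote each signature pair per sample and call RD above the threshold.

    A pair votes RD in a sample when its up-gene value is strictly greater
    than its down-gene value; ties and unmeasured pairs contribute no vote,
    and unmeasured pairs reduce that sample's ``k_available``. The RD call
    uses a proportionally scaled threshold, ceil(t × k_available / k), so a
    cohort missing one signature gene (k_available = 4) still predicts.

    Returns a DataFrame indexed by sample id with columns ``votes``,
    ``k_available``, ``score`` (votes / k_available) and ``label``.
    """
    n = cohort.n_samples
    votes = np.zeros(n, dtype=int)
    k_avail = np.zeros(n, dtype=int)
    for p in sig.pairs:
        if p.gene_up not in cohort.expr.index or p.gene_down not in cohort.expr.index:
            continue
        up = cohort.expr.loc[p.gene_up].to_numpy(dtype=float)
        down = cohort.expr.loc[p.gene_down].to_numpy(dtype=float)
        measurable = np.isfinite(up) & np.isfinite(down)
        k_avail += measurable
        votes += measurable & (up > down)
    if (k_avail == 0).any():
        bad = [s for s, k in zip(cohort.samples, k_avail) if k == 0]
        raise KTSPError(f"no measurable signature pair in sample(s): {bad[:5]}")
    eff_threshold = np.ceil(sig.vote_threshold * k_avail / sig.k).astype(int)
    labels = np.where(votes >= eff_threshold, RESPONSE_RD, RESPONSE_PCR)
    return pd.DataFrame(
        {
            "votes": votes,
            "k_available": k_avail,
            "score": votes / k_avail,
            "label": labels,
        },
        index=pd.Index(cohort.samples, name="sample_id"),
    )
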