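"""Bootstrap feature selection with a regularized random forest (RRF).

Candidate gene pairs are turned into binary order-indicator features
(1 when the pair's up-gene is strictly above its down-gene in a sample).
An RRF is an ordinary random forest whose split criterion penalizes
features not yet used anywhere in the forest: a feature outside the
forest-global selected set only wins a node if its Gini gain times the
regularization coefficient still beats every already-selected feature's
raw gain. This drives the forest toward a compact feature set.

Class imbalance is handled by multiplicative prior weights on the samples
(default 1.0 for pCR, 0.6 for RD, up-weighting the minority class) which
enter both the weighted Gini impurity and the node class totals.

Selection stability is measured by refitting the RRF on B bootstrap
resamples of the training data (stratified by class, size n, with
replacement) and counting, for each pair, the resamples in which it was
used in at least one split. The top-k most frequently selected pairs form
the final voting signature.

The tree-growing kernel is JIT-compiled with numba: the bootstrap × forest
workload (B × n_trees trees) is the hot loop of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .cohort import ExpressionCohort, response_indicator
from .ktsp import KTSPError, ScoredPair, TSPSignature


@dataclass
class RRFConfig:
    """Tuning knobs of the regularized random forest.

    coef_reg
        Gain multiplier applied to features outside the selected set,
        in (0, 1]; 1 disables regularization.
    feature_fraction
        Fraction of features drawn as split candidates at each node
        (mtry-style), in (0, 1].
    class_weights
        Multiplicative sample weights per response class.
    n_trees, max_depth
        Forest size and depth cap (``None`` = unlimited).
    min_node
        Minimum samples a node needs to be split further.
    """

    coef_reg: float = 0.5
    feature_fraction: float = 0.1
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"pCR": 1.0, "RD": 0.6}
    )
    n_trees: int = 100
    max_depth: int | None = None
    min_node: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coef_reg <= 1:
            raise KTSPError("coef_reg must be in (0, 1]")
        if not 0 < self.feature_fraction <= 1:
            raise KTSPError("feature_fraction must be in (0, 1]")
        if any(w <= 0 for w in self.class_weights.values()):
            raise KTSPError("class weights must be positive")


@dataclass
class RRFFit:
    """Result of one RRF fit: the selected set and per-feature importance."""

    selected: np.ndarray  # boolean mask over features
    importance: np.ndarray  # cumulative weighted impurity decrease

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def pair_indicators(
    cohort: ExpressionCohort, pairs: Sequence[tuple[str, str] | ScoredPair]
) -> np.ndarray:
    """Binary order-indicator matrix (samples × pairs).

    Entry (s, j) is 1 iff pair j's up-gene is strictly above its down-gene
    in sample s; ties give 0. All pair genes must be measured.
    """
    names = [
        (p.gene_up, p.gene_down) if isinstance(p, ScoredPair) else tuple(p)
        for p in pairs
    ]
    missing = sorted(
        {g for pr in names for g in pr if g not in cohort.expr.index}
    )
    if missing:
        raise KTSPError(f"pair genes not measured: {missing[:5]}")
    values = cohort.expr.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(cohort.expr.index)}
    up_idx = np.array([gene_index[u] for u, _ in names], dtype=int)
    dn_idx = np.array([gene_index[d] for _, d in names], dtype=int)
    sub = values[np.concatenate([up_idx, dn_idx])]
    if not np.isfinite(sub).all():
        raise KTSPError("pair genes contain non-finite values")
    return (values[up_idx] > values[dn_idx]).T.astype(np.uint8)


def regularized_gain(raw_gain: float, feature_in_set: bool, coef_reg: float) -> float:
    """Penalized split gain: unchanged inside the selected set, scaled by
    ``coef_reg`` outside it."""
    if raw_gain < 0:
        raise KTSPError("raw_gain must be non-negative")
    return raw_gain if feature_in_set else coef_reg * raw_gain


@njit(cache=False)
def _grow_forest(X, y, w, coef_reg, k_cand, n_trees, max_depth, min_node, seed):
    """Grow a regularized weighted-Gini forest over binary features.

    Trees differ only through the random candidate-feature draw at each
    node; the selected set and importances are forest-global and persist
    across trees. Impurity is weighted Gini scaled by node weight, so a
    split's raw gain is the weighted impurity decrease. Returns
    (selected uint8[p], importance float64[p]).
    """
    n, p = X.shape
    np.random.seed(seed)
    selected = np.zeros(p, dtype=np.uint8)
    importance = np.zeros(p, dtype=np.float64)
    idx = np.empty(n, dtype=np.int64)
    cap = 2 * n + 64
    stack_s = np.empty(cap, dtype=np.int64)
    stack_e = np.empty(cap, dtype=np.int64)
    stack_d = np.empty(cap, dtype=np.int64)
    feat_perm = np.arange(p)
    kc = k_cand if k_cand < p else p
    cand = np.empty(kc, dtype=np.int64)

    for _tree in range(n_trees):
        for i in range(n):
            idx[i] = i
        stack_s[0] = 0
        stack_e[0] = n
        stack_d[0] = 0
        top = 1
        while top > 0:
            top -= 1
            s = stack_s[top]
            e = stack_e[top]
            depth = stack_d[top]
            wp = 0.0
            wn = 0.0
            for i in range(s, e):
                if y[idx[i]] == 1:
                    wp += w[idx[i]]
                else:
                    wn += w[idx[i]]
            W = wp + wn
            if e - s < min_node or wp == 0.0 or wn == 0.0:
                continue
            if max_depth >= 0 and depth >= max_depth:
                continue
            node_imp = W - (wp * wp + wn * wn) / W

            # sample kc distinct candidate features (partial Fisher-Yates),
            # then sort so ties break on the lowest feature index
            for j in range(kc):
                r = j + np.random.randint(0, p - j)
                tmp = feat_perm[j]
                feat_perm[j] = feat_perm[r]
                feat_perm[r] = tmp
                cand[j] = feat_perm[j]
            cand.sort()

            best_pen = 1e-12
            best_f = -1
            best_raw = 0.0
            for j in range(kc):
                f = cand[j]
                lwp = 0.0
                lwn = 0.0
                for i in range(s, e):
                    if X[idx[i], f] == 1:
                        if y[idx[i]] == 1:
                            lwp += w[idx[i]]
                        else:
                            lwn += w[idx[i]]
                WL = lwp + lwn
                WR = W - WL
                if WL == 0.0 or WR == 0.0:
                    continue
                rwp = wp - lwp
                rwn = wn - lwn
                imp_l = WL - (lwp * lwp + lwn * lwn) / WL
                imp_r = WR - (rwp * rwp + rwn * rwn) / WR
                raw = node_imp - (imp_l + imp_r)
                if raw <= 0.0:
                    continue
                pen = raw if selected[f] == 1 else coef_reg * raw
                if pen > best_pen:
                    best_pen = pen
                    best_f = f
                    best_raw = raw
            if best_f < 0:
                continue
            selected[best_f] = 1
            importance[best_f] += best_raw

            i = s
            j2 = e - 1
            while i <= j2:
                if X[idx[i], best_f] == 1:
                    i += 1
                else:
                    tmp = idx[i]
                    idx[i] = idx[j2]
                    idx[j2] = tmp
                    j2 -= 1
            stack_s[top] = s
            stack_e[top] = i
            stack_d[top] = depth + 1
            top += 1
            stack_s[top] = i
            stack_e[top] = e
            stack_d[top] = depth + 1
            top += 1
    return selected, importance


def fit_rrf(features: np.ndarray, labels, cfg: RRFConfig) -> RRFFit:
    """Fit one regularized random forest on a binary feature matrix.

    ``features`` is samples × pairs (0/1); ``labels`` holds RD/pCR per
    sample. A feature counts as selected when it is used in at least one
    split anywhere in the forest.
    """
    X = np.ascontiguousarray(features, dtype=np.uint8)
    if X.ndim != 2 or X.shape[1] == 0:
        raise KTSPError("feature matrix must be 2-D with >= 1 feature")
    y = response_indicator(labels)
    if y.size != X.shape[0]:
        raise KTSPError("labels must align with feature rows")
    if y.sum() == 0 or y.sum() == y.size:
        raise KTSPError("both classes must be present")
    w = np.where(
        y == 1, cfg.class_weights["RD"], cfg.class_weights["pCR"]
    ).astype(np.float64)
    k_cand = int(math.ceil(cfg.feature_fraction * X.shape[1]))
    max_depth = -1 if cfg.max_depth is None else int(cfg.max_depth)
    selected, importance = _grow_forest(
        X,
        y.astype(np.int8),
        w,
        float(cfg.coef_reg),
        k_cand,
        int(cfg.n_trees),
        max_depth,
        int(cfg.min_node),
        int(cfg.seed) % (2**32),
    )
    return RRFFit(selected=selected.astype(bool), importance=importance)


def _bootstrap_seed(master_seed: int, b: int) -> np.random.SeedSequence:
    # counter-based derivation: bootstrap b is reproducible in isolation
    return np.random.SeedSequence(entropy=(int(master_seed) & 0x7FFFFFFF, b))


def bootstrap_frequency(
    features: np.ndarray,
    labels,
    cfg: RRFConfig,
    pairs: Sequence[ScoredPair],
    B: int = 100,
    top_k: int = 5,
) -> tuple[pd.DataFrame, TSPSignature]:
    """Rank pairs by RRF selection frequency over B bootstraps; keep top-k.

    Each bootstrap draws n samples with replacement, stratified by class so
    both classes are always present, and refits the RRF. Pairs are ranked
    by times selected (desc), then mean importance (desc), then input pair
    order. The top-k pairs become a :class:`TSPSignature` with
    vote_threshold = ceil(0.4 × top_k) — two votes for the published k=5.

    Returns the frequency table (gene_up, gene_down, times_selected,
    mean_importance, rank) and the signature.
    """
    if B < 1:
        raise KTSPError("B must be >= 1")
    if not 1 <= top_k <= len(pairs):
        raise KTSPError("top_k must be in 1..n_pairs")
    if len(pairs) != features.shape[1]:
        raise KTSPError("pairs must align with feature columns")
    y = response_indicator(labels)
    labels_arr = np.asarray(labels)
    idx_by_class = [np.flatnonzero(y == c) for c in (0, 1)]
    if any(ix.size == 0 for ix in idx_by_class):
        raise KTSPError("both classes must be present")

    times = np.zeros(len(pairs), dtype=int)
    imp_sum = np.zeros(len(pairs), dtype=float)
    for b in range(B):
        ss = _bootstrap_seed(cfg.seed, b)
        rng = np.random.default_rng(ss)
        for _attempt in range(100):
            rows = np.concatenate(
                [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_class]
            )
            if 0 < y[rows].sum() < rows.size:
                break
        else:
            raise KTSPError(f"bootstrap {b} could not realize both classes")
        sub_cfg = RRFConfig(
            coef_reg=cfg.coef_reg,
            feature_fraction=cfg.feature_fraction,
            class_weights=cfg.class_weights,
            n_trees=cfg.n_trees,
            max_depth=cfg.max_depth,
            min_node=cfg.min_node,
            seed=int(ss.generate_state(1)[0]),
        )
        fit = fit_rrf(features[rows], labels_arr[rows], sub_cfg)
        times += fit.selected
        imp_sum += fit.importance

    mean_imp = imp_sum / B
    order = np.lexsort((np.arange(len(pairs)), -mean_imp, -times))
    freq = pd.DataFrame(
        {
            "gene_up": [pairs[i].gene_up for i in order],
            "gene_down": [pairs[i].gene_down for i in order],
            "times_selected": times[order],
            "mean_importance": mean_imp[order],
            "rank": np.arange(1, len(pairs) + 1),
        }
    )
    sig = TSPSignature(
        [pairs[i] for i in order[:top_k]],
        vote_threshold=int(math.ceil(0.4 * top_k)),
    )
    return freq, sig
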