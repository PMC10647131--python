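import numpy as np
import pandas as pd
import pytest

import notchtsp as nt


@pytest.fixture(scope="session")
def default_sim():
    """One cohort at the default study conditions, shared across tests."""
    cfg = nt.SimConfig(seed=42)
    cohort, pheno, truth = nt.simulate_cohort(cfg)
    return cfg, cohort, pheno, truth


@pytest.fixture
def tiny_cohort():
    """A 4-gene × 6-sample cohort with hand-checkable orderings."""
    expr = pd.DataFrame(
        {
            "s1": [5.0, 1.0, 2.0, 3.0],
            "s2": [4.0, 2.0, 1.0, 3.0],
            "s3": [1.0, 5.0, 2.0, 3.0],
            "s4": [2.0, 4.0, 1.0, 3.0],
            "s5": [3.0, 3.0, 2.0, 1.0],
            "s6": [1.0, 2.0, 3.0, 4.0],
        },
        index=["A", "B", "C", "D"],
    )
    return nt.ExpressionCohort(expr)


def brute_force_delta(up, down, labels):
    """Per-sample counting oracle for the TSP switch score."""
    up = np.asarray(up, dtype=float)
    down = np.asarray(down, dtype=float)
    y = np.asarray(labels)
    n_rd = n_pcr = rd_hits = pcr_hits = 0
    for u, d, lab in zip(up, down, y):
        if lab == "RD":
            n_rd += 1
            rd_hits += 1 if u > d else 0
        else:
            n_pcr += 1
            pcr_hits += 1 if u > d else 0
    return rd_hits / n_rd - pcr_hits / n_pcr


def mann_whitney_auc(scores, y):
    """Pairwise-comparison oracle for the tie-corrected AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
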