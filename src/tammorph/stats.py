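"""Small statistical utilities shared by the cohort and spatial modules.

Two things live here because no installed library provides them in the exact
form the analyses require:

* an exact two-sided Mann-Whitney U test computed by full enumeration of the
  group-label permutations (scipy's ``method="exact"`` does not enumerate the
  permutation distribution in the presence of ties);
* a DeLong variance estimate for the AUC of an empirical ROC curve.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["mannwhitney_u", "mann_whitney_test", "delong_auc_ci"]

# above this many pooled observations the enumeration is pointless
_EXACT_MAX_PER_GROUP = 8


def mannwhitney_u(x, y) -> float:
    """U statistic for group ``x`` against ``y`` with ties counted 1/2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by enumerating all C(n1+n2, n1) group assignments.

    The permutation distribution of U is symmetric about n1*n2/2 under
    exchangeability, so the two-sided p counts arrangements at least as far
    from the centre as the observed U.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    centre = n1 * len(y) / 2.0
    obs_dev = abs(mannwhitney_u(x, y) - centre)
    idx = np.arange(len(pooled))
    hits = 0
    total = comb(len(pooled), n1)
    for chosen in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(chosen)] = True
        u = mannwhitney_u(pooled[mask], pooled[~mask])
        if abs(u - centre) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_test(x, y, exact_max: int = _EXACT_MAX_PER_GROUP):
    """Two-sided Mann-Whitney U test.

    Exact by full enumeration when both groups have at most ``exact_max``
    observations, otherwise the tie-corrected normal approximation.

    Returns ``(U, p)`` with U counted for the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = mannwhitney_u(x, y)
    if len(x) <= exact_max and len(y) <= exact_max:
        return u, _exact_two_sided_p(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


# ---------------------------------------------------------------------------
# DeLong AUC variance


def _midrank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def delong_auc_ci(scores, labels, alpha: float = 0.05):
    """AUC with DeLong standard error and Wald ``1 - alpha`` CI.

    ``labels`` is boolean (True = positive class); higher scores are assumed
    to indicate the positive class. The CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need at least one positive and one negative")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components (placements)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), se, (lo, hi)
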