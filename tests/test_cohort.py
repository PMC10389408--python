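"""ROC/cutoff, classification, Kaplan-Meier, log-rank, Cox, univariate table."""

import numpy as np
import pandas as pd
import pytest

from tammorph import (
    DegenerateCovariateError,
    DegenerateLabelsError,
    RocResult,
    build_roc,
    classify_patients,
    cox_fit,
    km_estimate,
    logrank_test,
    one_se_cutoff,
    optimal_cutoff,
    survival_at,
    univariate_table,
)
from tammorph.stats import mann_whitney_test, mannwhitney_u


def pair_concordance_auc(scores, labels):
    """Brute-force AUC: fraction of concordant (pos, neg) pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# ROC


def test_perfect_separation_gives_auc_one():
    roc = build_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert roc.auc == pytest.approx(1.0)
    # optimal cutoff separates the groups and is the smallest optimal candidate
    assert 3 < roc.optimal_cutoff <= 10


def test_independent_scores_give_auc_near_half(rng):
    scores = rng.uniform(0, 1, 2000)
    events = rng.uniform(0, 1, 2000) < 0.5
    roc = build_roc(scores, events)
    assert roc.auc == pytest.approx(0.5, abs=0.05)


def test_auc_equals_pair_concordance_with_one_swap():
    areas = [100, 120, 140, 200, 220, 240]
    events = [0, 0, 1, 0, 1, 1]  # one discordant swap
    roc = build_roc(areas, events)
    assert roc.auc == pytest.approx(pair_concordance_auc(areas, events), abs=1e-12)


def test_auc_equals_pair_concordance_random(rng):
    for _ in range(50):
        n = int(rng.integers(6, 40))
        scores = rng.choice(np.arange(10, 30), size=n).astype(float)  # force ties
        events = rng.uniform(size=n) < 0.5
        if events.all() or not events.any():
            continue
        roc = build_roc(scores, events)
        assert roc.auc == pytest.approx(pair_concordance_auc(scores, events), abs=1e-12)


def test_degenerate_labels_rejected():
    with pytest.raises(DegenerateLabelsError):
        build_roc([1, 2, 3], [1, 1, 1])
    with pytest.raises(DegenerateLabelsError):
        build_roc([1, 2, 3], [0, 0, 0])


def test_youden_tie_broken_toward_smaller_threshold():
    roc = RocResult(
        thresholds=np.array([1.0, 2.0, 3.0]),
        sensitivity=np.array([1.0, 0.9, 0.7]),
        specificity=np.array([0.2, 0.6, 0.8]),
        auc=0.7, auc_se=0.1, auc_ci=(0.5, 0.9),
    )  # J = {0.2, 0.5, 0.5} at thresholds a < b < c
    assert optimal_cutoff(roc) == 2.0


def test_one_se_cutoff_is_never_above_plain_argmax():
    rng = np.random.default_rng(5)
    areas = np.concatenate([rng.normal(150, 15, 20), rng.normal(220, 20, 40)])
    events = np.concatenate([rng.uniform(size=20) < 0.3, rng.uniform(size=40) < 0.8])
    roc = build_roc(areas, events)
    assert one_se_cutoff(roc, 0.0) == optimal_cutoff(roc)
    assert one_se_cutoff(roc, 1.0) <= optimal_cutoff(roc)


def test_auc_ci_contains_auc_and_is_proper():
    rng = np.random.default_rng(3)
    areas = np.concatenate([rng.normal(150, 30, 30), rng.normal(210, 30, 50)])
    events = np.repeat([False, True], [30, 50])
    for method in ("delong", "bootstrap"):
        roc = build_roc(areas, events, ci_method=method, n_boot=500, seed=1)
        lo, hi = roc.auc_ci
        assert 0 <= lo <= roc.auc <= hi <= 1


# ---------------------------------------------------------------------------
# classification


def _cohort(areas):
    return pd.DataFrame(
        dict(patient_id=[f"P{i}" for i in range(len(areas))], mean_tam_area=areas)
    )


def test_classification_boundary_and_paper_cutoff():
    df = classify_patients(_cohort([151.38, 100.0, 300.0]), 151.38)
    assert list(df["tam_class"]) == ["L-TAM", "S-TAM", "L-TAM"]
    assert (classify_patients(_cohort([1.0, 2.0]), 0.0)["tam_class"] == "L-TAM").all()


def test_classification_missing_area_reports_patient_ids():
    df = _cohort([100.0, np.nan, 200.0])
    with pytest.raises(ValueError, match="P1"):
        classify_patients(df, 151.38)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_without_censoring_is_empirical_survivor_function():
    curve = km_estimate([1, 2, 3], [1, 1, 1])
    assert curve.at(0.5) == pytest.approx(1.0)
    assert curve.at(1) == pytest.approx(2 / 3)
    assert curve.at(2) == pytest.approx(1 / 3)
    assert curve.at(3) == pytest.approx(0.0)
    assert curve.at(2.999) == pytest.approx(1 / 3)  # right-continuous step


def test_km_all_censored_stays_at_one():
    curve = km_estimate([5, 10, 20], [0, 0, 0])
    assert curve.at(100) == pytest.approx(1.0)


def test_km_hand_computed_product_limit_with_censoring():
    # times 1,2,3+,4,5+,6 (events at 1,2,4,6): S = prod(1 - d_i/n_i)
    times = [1, 2, 3, 4, 5, 6]
    events = [1, 1, 0, 1, 0, 1]
    curve = km_estimate(times, events)
    assert curve.at(1) == pytest.approx(5 / 6)
    assert curve.at(2) == pytest.approx(5 / 6 * 4 / 5)  # 2/3
    assert curve.at(3.5) == pytest.approx(2 / 3)  # censoring: no step
    assert curve.at(4) == pytest.approx(2 / 3 * 2 / 3)  # 4/9
    assert curve.at(6) == pytest.approx(0.0)
    assert survival_at(curve, 36.0) == pytest.approx(0.0)


def test_km_empty_input_raises():
    with pytest.raises(ValueError):
        km_estimate([], [])


# ---------------------------------------------------------------------------
# log-rank


def logrank_oracle_2group(t1, e1, t2, e2):
    """Hand-built Mantel-Cox: 2x2 hypergeometric table per event time."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O_minus_E, V = 0.0, 0.0
    for t in times:
        n1 = (t1 >= t).sum()
        n2 = (t2 >= t).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        d2 = ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


def test_logrank_identical_groups_is_null():
    t, e = [1, 2, 3, 4], [1, 1, 0, 1]
    chi2, p = logrank_test((t, e), (t, e))
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hypergeometric_hand_computation():
    t1, e1 = [2, 4, 6, 8], [1, 1, 1, 0]
    t2, e2 = [1, 3, 5, 7], [1, 1, 1, 1]
    chi2, _ = logrank_test((t1, e1), (t2, e2))
    assert chi2 == pytest.approx(logrank_oracle_2group(t1, e1, t2, e2), rel=1e-8)


def test_logrank_invariant_to_group_swap_and_detects_contrast(rng):
    t1 = rng.exponential(50, 40)
    t2 = rng.exponential(5, 40)
    e = np.ones(40)
    chi2a, pa = logrank_test((t1, e), (t2, e))
    chi2b, pb = logrank_test((t2, e), (t1, e))
    assert chi2a == pytest.approx(chi2b, rel=1e-10)
    assert pa < 0.05  # strong hazard contrast at modest n
    with pytest.raises(ValueError):
        logrank_test((t1, e), ([], []))


# ---------------------------------------------------------------------------
# Cox


def _ph_data(rng, n=200, hr=5.0, h0=0.02, censor=60.0):
    x = (rng.uniform(size=n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (h0 * hr**x))
    c = rng.uniform(0, censor, n)
    return pd.DataFrame(
        dict(dfs_time=np.minimum(t, c), dfs_event=(t <= c).astype(int), x=x)
    )


def test_cox_recovers_true_hazard_ratio():
    df = _ph_data(np.random.default_rng(11), n=200, hr=5.0)
    res = cox_fit(df, ["x"], n_bootstrap=200, seed=1)
    lo, hi = res.summary.loc["x", ["ci_low", "ci_high"]]
    assert lo < 5.0 < hi
    assert res.summary.loc["x", "hr"] == pytest.approx(5.0, rel=0.5)
    # bootstrap percentile CI brackets the point estimate
    b = res.bootstrap.loc["x"]
    assert b["hr_ci_low"] < res.summary.loc["x", "hr"] < b["hr_ci_high"]
    assert np.isfinite(res.concordance_corrected)


def test_cox_constant_covariate_flagged_as_degenerate():
    df = _ph_data(np.random.default_rng(1))
    df["x"] = 1.0
    with pytest.raises(DegenerateCovariateError):
        cox_fit(df, ["x"], n_bootstrap=0)


def test_cox_no_events_is_degenerate():
    df = _ph_data(np.random.default_rng(1))
    df["dfs_event"] = 0
    with pytest.raises(DegenerateLabelsError):
        cox_fit(df, ["x"], n_bootstrap=0)


# ---------------------------------------------------------------------------
# Mann-Whitney and the univariate table


def test_mann_whitney_exact_small_sample():
    u, p = mann_whitney_test([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)


def test_mann_whitney_u_counts_ties_half():
    assert mannwhitney_u([1, 2], [2, 3]) == 0.5


def _uni_records(g0, g1, flag0, flag1):
    return pd.DataFrame(
        dict(
            dfs_event=[0] * len(g0) + [1] * len(g1),
            value=list(g0) + list(g1),
            flag=list(flag0) + list(flag1),
        )
    )


def test_univariate_identical_groups_all_null():
    df = _uni_records([1, 2, 3], [1, 2, 3], [0, 1, 1], [0, 1, 1])
    out = univariate_table(df, {"value": "continuous", "flag": "binary"})
    assert out.loc["value", "p"] == pytest.approx(1.0)
    assert out.loc["flag", "p"] == pytest.approx(1.0)


def test_univariate_perfect_association_is_significant():
    df = _uni_records(range(10), range(10), [0] * 10, [1] * 10)
    out = univariate_table(df, {"flag": "binary"})
    assert out.loc["flag", "p"] < 0.001


def test_univariate_unknown_type_rejected():
    df = _uni_records([1], [2], [0], [1])
    with pytest.raises(ValueError):
        univariate_table(df, {"value": "ordinal"})
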