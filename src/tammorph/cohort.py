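"""Cohort-level statistics: ROC cutoff, S-TAM/L-TAM classification, survival.

The prognostic construct is simple: each patient carries a slide-mean
macrophage area; a ROC curve of that area against recurrence yields an
optimal cutoff (Youden's J); patients at or above the cutoff are L-TAM
(large-TAM) and below it S-TAM. Survival is then compared between classes
with Kaplan-Meier / log-rank, and the class enters a multivariable Cox
proportional-hazards model alongside the clinically significant covariates,
with patient-level bootstrap resampling as an overfitting control.

Kaplan-Meier, log-rank and the Cox partial likelihood (Efron ties) are
delegated to lifelines; this module owns the ROC/cutoff logic, the bootstrap
layer and the univariate screening table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergence
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConvergenceError, DegenerateCovariateError, DegenerateLabelsError
from .stats import delong_auc_ci, mann_whitney_test

__all__ = [
    "RocResult",
    "SurvivalCurve",
    "CoxResult",
    "build_roc",
    "optimal_cutoff",
    "one_se_cutoff",
    "classify_patients",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "univariate_table",
    "PAPER_CUTOFF_UM2",
]

#: published reference cutoff (um^2) separating S-TAMs from L-TAMs, usable
#: directly when a cohort-specific ROC derivation is not wanted
PAPER_CUTOFF_UM2 = 151.38

S_TAM = "S-TAM"
L_TAM = "L-TAM"


# ---------------------------------------------------------------------------
# ROC and classification


@dataclass
class RocResult:
    """Empirical ROC of mean TAM area against recurrence.

    Test-positive means area >= threshold; thresholds are the observed
    areas, sorted ascending.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    n_events: int = 0
    n_nonevents: int = 0
    optimal_cutoff: float = field(init=False, default=float("nan"))
    sens_at_cutoff: float = field(init=False, default=float("nan"))
    spec_at_cutoff: float = field(init=False, default=float("nan"))

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def build_roc(
    mean_areas,
    events,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RocResult:
    """ROC of per-patient mean area against the recurrence flag.

    AUC is the trapezoidal area under the empirical curve, identical to the
    tie-corrected Mann-Whitney concordance U/(n1*n0). The AUC confidence
    interval uses DeLong's variance by default, or a patient-level bootstrap
    (``ci_method="bootstrap"``).
    """
    areas = np.asarray(mean_areas, dtype=float)
    ev = np.asarray(events, dtype=bool)
    if ev.all() or (~ev).all():
        raise DegenerateLabelsError("need at least one event and one non-event")

    fpr, tpr, thr = roc_curve(ev, areas)
    finite = np.isfinite(thr)
    # ascending thresholds; roc_curve emits them descending with a +inf head
    order = np.argsort(thr[finite])
    thresholds = thr[finite][order]
    sens = tpr[finite][order]
    spec = 1.0 - fpr[finite][order]
    auc = float(roc_auc_score(ev, areas))

    if ci_method == "delong":
        _, se, ci = delong_auc_ci(areas, ev, alpha=alpha)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(areas)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if ev[idx].all() or (~ev[idx]).all():
                continue
            reps.append(roc_auc_score(ev[idx], areas[idx]))
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        se = float(np.std(reps, ddof=1))
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    roc = RocResult(
        thresholds, sens, spec, auc, se, ci,
        n_events=int(ev.sum()), n_nonevents=int((~ev).sum()),
    )
    roc.optimal_cutoff = optimal_cutoff(roc)
    at = int(np.searchsorted(roc.thresholds, roc.optimal_cutoff))
    roc.sens_at_cutoff = float(roc.sensitivity[at])
    roc.spec_at_cutoff = float(roc.specificity[at])
    return roc


def optimal_cutoff(roc: RocResult) -> float:
    """Threshold maximizing Youden's J = sens + spec - 1.

    Ties are broken toward the smaller threshold, i.e. the more sensitive
    operating point.
    """
    j = roc.youden()
    best = j.max()
    # thresholds are ascending, so the first maximiser is the smallest
    return float(roc.thresholds[int(np.argmax(j >= best - 1e-12))])


def one_se_cutoff(roc: RocResult, se_factor: float = 1.0) -> float:
    """Sensitivity-favoring cutoff: smallest threshold whose Youden J lies
    within ``se_factor`` binomial standard errors of the maximum.

    The empirical Youden argmax is erratic when non-events are few: a single
    high-area censored patient buys 1/n_nonevents of specificity against
    only 1/n_events of sensitivity, so the argmax random-walks into the
    large-area population and strips high-risk patients out of the L-TAM
    class. Among operating points statistically indistinguishable from the
    maximum (one-SE rule, as used for model selection in CART/lasso), this
    rule prefers the most sensitive one — the trade-off direction the
    clinical application wants, where missing a high-risk patient costs more
    than over-calling one. ``se_factor=0`` reduces to :func:`optimal_cutoff`.
    """
    if se_factor < 0:
        raise ValueError("se_factor must be >= 0")
    j = roc.youden()
    i = int(np.argmax(j >= j.max() - 1e-12))
    s, p = roc.sensitivity[i], roc.specificity[i]
    se = np.sqrt(
        s * (1 - s) / max(roc.n_events, 1) + p * (1 - p) / max(roc.n_nonevents, 1)
    )
    eligible = j >= j.max() - se_factor * se - 1e-12
    # trivial operating points (everyone positive / everyone negative) are
    # never useful cutoffs, however close their J comes to the maximum
    eligible &= (roc.sensitivity > 0) & (roc.specificity > 0)
    if not eligible.any():
        return optimal_cutoff(roc)
    return float(roc.thresholds[int(np.argmax(eligible))])


def classify_patients(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Set ``tam_class`` from ``mean_tam_area``: >= cutoff -> L-TAM else S-TAM.

    The boundary value itself is assigned to L-TAM. Raises ``ValueError``
    naming the patients whose mean area is missing.
    """
    out = records.copy()
    missing = out.index[out["mean_tam_area"].isna()].tolist()
    if missing:
        ids = out.loc[missing, "patient_id"].tolist() if "patient_id" in out else missing
        raise ValueError(f"mean_tam_area missing for patients: {ids}")
    out["tam_class"] = np.where(out["mean_tam_area"] >= cutoff, L_TAM, S_TAM)
    return out


# ---------------------------------------------------------------------------
# Survival


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve with at-risk counts."""

    times: np.ndarray  # event-time grid (0 included)
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """Right-continuous step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[~events]),
    )


def survival_at(curve: SurvivalCurve, t: float = 36.0) -> float:
    """KM survival probability at time ``t`` (months); default the 3-year mark."""
    return curve.at(t)


def logrank_test(*groups) -> tuple[float, float]:
    """Mantel-Cox log-rank test across two or more (times, events) groups.

    Returns the chi-square statistic and its p-value on k-1 df.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    durs, evs, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if len(t) == 0:
            raise ValueError(f"group {gi} is empty")
        durs.append(t)
        evs.append(e)
        labels.append(np.full(len(t), gi))
    res = multivariate_logrank_test(
        np.concatenate(durs), np.concatenate(labels), np.concatenate(evs)
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards with bootstrap overfitting control


@dataclass
class CoxResult:
    summary: pd.DataFrame  # index covariate; hr, ci_low, ci_high, p, coef, se
    log_likelihood: float
    concordance: float
    n: int
    n_events: int
    bootstrap: pd.DataFrame | None = None  # percentile CIs per covariate
    n_bootstrap_failed: int = 0
    optimism: float = float("nan")
    concordance_corrected: float = float("nan")

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(
    records: pd.DataFrame,
    covariate_names,
    duration_col: str = "dfs_time",
    event_col: str = "dfs_event",
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CoxResult:
    """Multivariable Cox PH fit (Efron ties) with patient-level bootstrap.

    Reports per-covariate hazard ratios with Wald CIs and p-values; when
    ``n_bootstrap > 0``, adds percentile CIs from resampling patients with
    replacement and an optimism estimate of the concordance index (mean of
    bootstrap-apparent minus bootstrap-model-on-original concordance), the
    classic internal-validation correction for overfitting.

    Raises :class:`DegenerateCovariateError` for constant covariates and
    :class:`ConvergenceError` if the partial-likelihood optimiser fails.
    """
    covariate_names = list(covariate_names)
    cols = [duration_col, event_col] + covariate_names
    df = records[cols].dropna()
    n_dropped = len(records) - len(df)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} records with missing covariates")
    if not np.asarray(df[event_col], dtype=bool).any():
        raise DegenerateLabelsError("no events observed")
    for c in covariate_names:
        if df[c].nunique() < 2:
            raise DegenerateCovariateError(f"covariate {c!r} is constant")

    def _fit(frame):
        cph = CoxPHFitter()  # lifelines handles ties with Efron's method
        cph.fit(frame, duration_col=duration_col, event_col=event_col)
        return cph

    separation_flag = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph = _fit(df)
        except _LLConvergence as exc:
            raise ConvergenceError(str(exc)) from exc
        separation_flag = any("convergence" in str(w.message).lower() or "separation" in str(w.message).lower() for w in caught)

    z = sps.norm.ppf(1 - alpha / 2)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - z * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + z * s["se(coef)"]),
            "p": s["p"],
        }
    )
    summary.index = s.index
    if separation_flag:
        summary["flagged"] = True

    result = CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        concordance=float(cph.concordance_index_),
        n=len(df),
        n_events=int(np.asarray(df[event_col], dtype=bool).sum()),
    )

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        coefs, optimisms = [], []
        failed = 0
        risk_orig = None
        for _ in range(n_bootstrap):
            bs = df.iloc[rng.integers(0, len(df), len(df))]
            if not np.asarray(bs[event_col], dtype=bool).any() or any(
                bs[c].nunique() < 2 for c in covariate_names
            ):
                failed += 1
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bcph = _fit(bs)
            except _LLConvergence:
                failed += 1
                continue
            coefs.append(bcph.summary["coef"].reindex(summary.index).to_numpy())
            c_boot = float(bcph.concordance_index_)
            risk_orig = -bcph.predict_partial_hazard(df).to_numpy().ravel()
            c_orig = concordance_index(df[duration_col], risk_orig, df[event_col])
            optimisms.append(c_boot - c_orig)
        if coefs:
            arr = np.vstack(coefs)
            lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
            result.bootstrap = pd.DataFrame(
                {
                    "hr_ci_low": np.exp(lo),
                    "hr_ci_high": np.exp(hi),
                    "n_resamples": len(arr),
                },
                index=summary.index,
            )
            result.optimism = float(np.mean(optimisms))
            result.concordance_corrected = result.concordance - result.optimism
        result.n_bootstrap_failed = failed
    return result


# ---------------------------------------------------------------------------
# Univariate screening table


def univariate_table(
    records: pd.DataFrame,
    variables: dict[str, str],
    group_col: str = "dfs_event",
) -> pd.DataFrame:
    """Per-variable comparison between outcome groups.

    ``variables`` maps column name -> "binary" or "continuous". Binary
    variables get an (uncorrected) chi-square test on the 2xk table, falling
    back to Fisher's exact test when any expected cell count is below 5;
    continuous variables get a two-sided Mann-Whitney U test. Summaries are
    n (%) for binary and median (range) for continuous, per group. P-values
    are reported raw (no multiplicity correction).
    """
    groups = records[group_col].astype(bool)
    g0 = records[~groups]
    g1 = records[groups]
    rows = []
    for name, kind in variables.items():
        if kind == "binary":
            x0 = g0[name].astype(int)
            x1 = g1[name].astype(int)
            table = np.array(
                [
                    [(x0 == 0).sum(), (x0 == 1).sum()],
                    [(x1 == 0).sum(), (x1 == 1).sum()],
                ]
            )
            if (table.sum(axis=0) == 0).any():
                p = 1.0
            else:
                chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
                if (expected < 5).any() and table.shape == (2, 2):
                    _, p = sps.fisher_exact(table)
            fmt = lambda x: f"{int(x.sum())} ({100 * x.mean():.0f})" if len(x) else "0 (0)"
            s0, s1 = fmt(x0), fmt(x1)
        elif kind == "continuous":
            x0 = g0[name].astype(float).dropna()
            x1 = g1[name].astype(float).dropna()
            _, p = mann_whitney_test(x0, x1)
            fmt = lambda x: f"{np.median(x):.1f} ({x.min():.1f}-{x.max():.1f})"
            s0, s1 = fmt(x0), fmt(x1)
        else:
            raise ValueError(f"unknown variable type {kind!r} for {name!r}")
        rows.append(dict(variable=name, type=kind, no_event=s0, event=s1, p=float(p)))
    return pd.DataFrame(rows).set_index("variable")
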