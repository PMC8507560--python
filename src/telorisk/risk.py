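"""Combined-marker metastatic-risk modeling.

Covers the patient-level statistics of the pipeline: cohort construction
under the published inclusion rules, univariate and stepwise logistic
regression of metastatic status on dichotomous markers, ROC/AUC with a
Hanley–McNeil confidence interval, and time-to-progression analysis
(Kaplan–Meier, log-rank, Cox proportional-hazards hazard ratio).

Time to progression (TTP) is the number of days between surgery of the
primary tumor and the first confirmed metastasis; non-metastatic patients
are censored at last follow-up. The classification cohort keeps primary
metastatic tumors plus non-metastatic tumors with >= 8 years of follow-up;
the TTP cohort keeps primaries with confirmed metastasis or >= 2 years of
follow-up, excluding metastasis specimens and clinically aggressive cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


def followup_years(days: float) -> float:
    """Convert follow-up days to years (365.25 days/year); rounding is the caller's."""
    if days < 0:
        raise ValueError("follow-up days must be non-negative")
    return days / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# cohort construction


def build_cohorts(
    annotation: pd.DataFrame,
    events: pd.DataFrame,
    classification_min_followup_years: float = 8.0,
    ttp_min_followup_years: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion rules for the two analysis cohorts.

    ``annotation`` is indexed by sample with columns ``status``
    (metastatic | aggressive | non-metastatic), ``tissue`` (primary |
    metastasis), ``follow_up_days`` and ``ttp_days``; ``events`` is the
    integrated event table indexed by the same samples.

    Returns (classification cohort, TTP cohort, exclusion log). Both
    cohorts are annotation rows joined with the event flags; the exclusion
    log records every sample excluded from either cohort with the rule.
    """
    ann = annotation.join(events, how="left")
    orphans = ann.index.difference(events.index)
    if len(orphans):
        raise ValueError(f"samples missing from event table: {list(orphans[:5])}")
    bad = ann[(ann["status"] == "non-metastatic") & ann["ttp_days"].notna()]
    if len(bad):
        raise ValueError(
            f"non-metastatic samples with a time-to-progression: {list(bad.index[:5])}"
        )

    exclusions = []

    def _note(sample, cohort, rule):
        exclusions.append({"sample": sample, "cohort": cohort, "rule": rule})

    fu_years = ann["follow_up_days"] / DAYS_PER_YEAR

    cls_keep, ttp_keep = [], []
    for sample, row in ann.iterrows():
        fy = fu_years[sample]
        is_primary = row["tissue"] == "primary"
        if not is_primary:
            _note(sample, "both", "metastasis_specimen")
            continue
        if row["status"] == "aggressive":
            _note(sample, "both", "clinically_aggressive")
            continue
        if row["status"] == "metastatic":
            cls_keep.append(sample)
            ttp_keep.append(sample)
            continue
        # non-metastatic primaries: follow-up rules
        if pd.isna(fy):
            _note(sample, "both", "unknown_followup")
            continue
        if fy >= classification_min_followup_years:
            cls_keep.append(sample)
        else:
            _note(sample, "classification", "followup_lt_8y")
        if fy >= ttp_min_followup_years:
            ttp_keep.append(sample)
        else:
            _note(sample, "ttp", "followup_lt_2y")

    classification = ann.loc[cls_keep]
    ttp = ann.loc[ttp_keep]
    log = pd.DataFrame(exclusions, columns=["sample", "cohort", "rule"])
    return classification, ttp, log


def survival_records(cohort: pd.DataFrame, group: pd.Series) -> pd.DataFrame:
    """Build (time, event, group) TTP records from a TTP-cohort table.

    Metastatic samples contribute their TTP as an event (synchronous
    metastases at day 0 are nudged to half a day so all times are
    positive); non-metastatic samples are censored at last follow-up.
    """
    times, evts = [], []
    for sample, row in cohort.iterrows():
        if row["status"] == "metastatic":
            t = float(row["ttp_days"])
            times.append(max(t, 0.5))
            evts.append(True)
        else:
            times.append(max(float(row["follow_up_days"]), 0.5))
            evts.append(False)
    out = pd.DataFrame(
        {"time": times, "event": evts, "group": group.reindex(cohort.index).astype(bool)},
        index=cohort.index,
    )
    return out


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """Univariate (or multivariable) logistic fit summary."""

    params: pd.DataFrame  # index = variable; coef, odds_ratio, ci_low, ci_high, p
    llf: float
    converged: bool
    separation: bool
    n: int
    fallback_or: float | None = None


def _haldane_or(a: int, b: int, c: int, d: int) -> float:
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def logistic_fit(X: pd.DataFrame, y: pd.Series) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS via statsmodels)."""
    y = y.astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.Logit(y, Xd)
    separation = False
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
        if np.abs(res.params.drop("const")).max() > 15:
            separation = True
    except Exception:  # PerfectSeparationError and numerical failures
        separation = True
        converged = False
        res = None
    if res is None:
        params = pd.DataFrame(
            index=X.columns, columns=["coef", "odds_ratio", "ci_low", "ci_high", "p"], dtype=float
        )
        return LogisticFit(params, np.nan, False, True, len(y))
    conf = res.conf_int()
    params = pd.DataFrame(
        {
            "coef": res.params,
            "odds_ratio": np.exp(res.params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p": res.pvalues,
        }
    ).drop(index="const")
    return LogisticFit(params, float(res.llf), converged, separation, len(y))


def logistic_fit_univariate(x: pd.Series, y: pd.Series) -> LogisticFit:
    """Single dichotomous marker vs metastatic label.

    For a 2×2 design the fitted odds ratio equals the contingency-table
    cross-ratio ad/bc. Complete separation (an empty table cell) is
    flagged and a Haldane-corrected table OR reported as fallback.
    """
    x = x.astype(bool)
    y = y.astype(bool)
    a = int((x & y).sum())
    b = int((~x & y).sum())
    c = int((x & ~y).sum())
    d = int((~x & ~y).sum())
    fit = logistic_fit(x.astype(float).to_frame(x.name or "marker"), y)
    if min(a, b, c, d) == 0:
        fit.separation = True
    if fit.separation:
        fit.fallback_or = _haldane_or(a, b, c, d)
        logger.warning("separation in univariate logistic fit; Haldane OR %.3f", fit.fallback_or)
    return fit


@dataclass
class StepwiseResult:
    selected: list[str]
    trace: list[str]
    fit: LogisticFit | None


def stepwise_select(
    X: pd.DataFrame,
    y: pd.Series,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_steps: int = 50,
) -> StepwiseResult:
    """Stepwise logistic selection with likelihood-ratio tests.

    Forward entry at ``alpha_enter`` and backward removal at
    ``alpha_remove`` ("conditional" stepwise in the classic statistical-
    package sense), iterated to a fixed point. Deterministic given the
    data; ties break by column order. Returns the selected variables, a
    human-readable trace, and the final fit (None if nothing entered).
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate variable")
    y = y.astype(float)

    def _llf(cols: list[str]) -> float:
        Xd = sm.add_constant(X[cols].astype(float), has_constant="add") if cols else (
            pd.DataFrame({"const": np.ones(len(y))}, index=X.index)
        )
        with np.errstate(all="ignore"):
            return float(sm.Logit(y, Xd).fit(disp=0, maxiter=100).llf)

    selected: list[str] = []
    trace: list[str] = []
    ll_current = _llf(selected)
    for _ in range(max_steps):
        changed = False
        # forward step: best candidate by LR p-value
        best_p, best_var, best_ll = None, None, None
        for var in X.columns:
            if var in selected:
                continue
            try:
                ll1 = _llf(selected + [var])
            except Exception:
                continue
            lr = max(0.0, 2.0 * (ll1 - ll_current))
            p = stats.chi2.sf(lr, df=1)
            if best_p is None or p < best_p:
                best_p, best_var, best_ll = p, var, ll1
        if best_var is not None and best_p < alpha_enter:
            selected.append(best_var)
            ll_current = best_ll
            trace.append(f"enter {best_var} (LR p={best_p:.3g})")
            changed = True
        # backward step: worst retained variable by LR p-value
        while len(selected) > 0:
            worst_p, worst_var, worst_ll = None, None, None
            for var in selected:
                rest = [v for v in selected if v != var]
                ll0 = _llf(rest)
                lr = max(0.0, 2.0 * (ll_current - ll0))
                p = stats.chi2.sf(lr, df=1)
                if worst_p is None or p > worst_p:
                    worst_p, worst_var, worst_ll = p, var, ll0
            if worst_p is not None and worst_p > alpha_remove:
                selected.remove(worst_var)
                ll_current = worst_ll
                trace.append(f"remove {worst_var} (LR p={worst_p:.3g})")
                changed = True
            else:
                break
        if not changed:
            break
    fit = logistic_fit(X[selected], y) if selected else None
    return StepwiseResult(selected, trace, fit)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_pos: int
    n_neg: int


def roc_auc(marker, labels) -> RocResult:
    """AUC by the Mann–Whitney statistic with ties counted 1/2.

    For a dichotomous marker this equals (sensitivity + specificity)/2.
    The standard error follows Hanley & McNeil's nonparametric formula;
    the 95% CI is AUC ± 1.96·SE truncated to [0, 1], and the p-value
    tests AUC = 0.5 with the null-variance version of the same formula.
    """
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = marker[labels]
    neg = marker[~labels]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    # null variance: AUC = 0.5 gives Q1 = Q2 = 1/3
    var0 = (0.25 + (n1 + n0 - 2) / 12.0) / (n1 * n0)
    z = (auc - 0.5) / np.sqrt(var0)
    p = float(2 * stats.norm.sf(abs(z)))
    return RocResult(
        auc=float(auc),
        se=se,
        ci_low=float(max(0.0, auc - 1.96 * se)),
        ci_high=float(min(1.0, auc + 1.96 * se)),
        p=p,
        n_pos=n1,
        n_neg=n0,
    )


def roc_curve_points(marker, labels) -> pd.DataFrame:
    """ROC coordinates (1-specificity, sensitivity) over all thresholds."""
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = np.unique(marker)[::-1]
    rows = [{"fpr": 0.0, "tpr": 0.0, "threshold": np.inf}]
    for t in thresholds:
        pred = marker >= t
        tpr = (pred & labels).sum() / labels.sum()
        fpr = (pred & ~labels).sum() / (~labels).sum()
        rows.append({"fpr": float(fpr), "tpr": float(tpr), "threshold": float(t)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time to progression


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival estimate.

    Returns a step-function table (time, survival) including the implicit
    S(0) = 1 row. With no censoring this equals the empirical survival
    function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no records")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=bool)
    if groups.all() or (~groups).all():
        raise ValueError("two non-empty groups required")
    if not events.any():
        raise ValueError("log-rank undefined with no events")
    res = _lifelines_logrank(
        times[groups], times[~groups], event_observed_A=events[groups], event_observed_B=events[~groups]
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    converged: bool
    method: str  # "cox_breslow" or "oe_ratio"


def _cox_binary_breslow(times, events, groups, max_iter=50, tol=1e-10):
    """Newton-Raphson Cox PH fit for a single binary covariate, Breslow ties."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = groups[order].astype(float)
    # risk-set counts at each event time (counting from the tail)
    n1_tail = np.cumsum(g[::-1])[::-1]  # group-1 subjects with time >= t[i]
    n_tail = np.arange(len(t), 0, -1, dtype=float)
    event_times = np.unique(t[e])
    d_j = np.empty(len(event_times))
    s_j = np.empty(len(event_times))
    n1_j = np.empty(len(event_times))
    n_j = np.empty(len(event_times))
    for k, et in enumerate(event_times):
        at = (t == et) & e
        d_j[k] = at.sum()
        s_j[k] = g[at].sum()
        first = np.searchsorted(t, et, side="left")
        n1_j[k] = n1_tail[first]
        n_j[k] = n_tail[first]
    n0_j = n_j - n1_j

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        eb = np.exp(beta)
        denom = n0_j + n1_j * eb
        pi = n1_j * eb / denom
        score = float(np.sum(s_j - d_j * pi))
        info = float(np.sum(d_j * pi * (1 - pi)))
        if info <= 1e-12:
            break
        step = score / info
        beta += np.clip(step, -5, 5)
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 15:  # monotone likelihood
            break
    eb = np.exp(beta)
    pi = n1_j * eb / (n0_j + n1_j * eb)
    info = float(np.sum(d_j * pi * (1 - pi)))
    se = float(np.sqrt(1.0 / info)) if info > 0 else np.inf
    return beta, se, converged and abs(beta) <= 15


def hazard_ratio(times, events, groups) -> HazardRatioResult:
    """Hazard ratio of the event-positive group from a Cox PH fit.

    Single binary covariate, Newton's method with Breslow tie handling;
    HR = exp(beta) with a Wald 95% CI and p-value. On non-convergence or
    monotone likelihood the observed/expected ratio from the log-rank
    table is reported instead (flagged via ``method``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=bool)
    if groups.all() or (~groups).all():
        raise ValueError("two non-empty groups required")
    if not events.any():
        raise ValueError("hazard ratio undefined with no events")
    beta, se, converged = _cox_binary_breslow(times, events, groups)
    if converged and np.isfinite(se):
        z = beta / se
        return HazardRatioResult(
            hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
            p=float(2 * stats.norm.sf(abs(z))),
            coef=float(beta),
            se=se,
            converged=True,
            method="cox_breslow",
        )
    logger.warning("Cox fit did not converge; reporting O/E hazard-ratio fallback")
    hr = _oe_hazard_ratio(times, events, groups)
    return HazardRatioResult(hr, np.nan, np.nan, np.nan, np.log(hr), np.nan, False, "oe_ratio")


def _oe_hazard_ratio(times, events, groups) -> float:
    """(O1/E1)/(O0/E0) from the log-rank observed/expected decomposition."""
    event_times = np.unique(times[events])
    o1 = e1 = o0 = e0 = 0.0
    for et in event_times:
        at_risk = times >= et
        d = float((events & (times == et)).sum())
        d1 = float((events & (times == et) & groups).sum())
        n = float(at_risk.sum())
        n1 = float((at_risk & groups).sum())
        o1 += d1
        o0 += d - d1
        e1 += d * n1 / n
        e0 += d * (n - n1) / n
    if e1 == 0 or e0 == 0 or o0 == 0:
        return np.inf if o1 > 0 else np.nan
    return (o1 / e1) / (o0 / e0)
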