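"""Cohort-level statistics for indicator-based survival analysis.

Association testing (Fisher's exact), log-transformed group comparisons
(ANOVA + Bonferroni, Welch), optimal log-rank cutoff determination,
Kaplan-Meier / log-rank stratification, Cox proportional-hazards models with
stepwise likelihood-ratio selection, and leave-one-out cross-validation.

The cutoff scan returns the raw minimum p over all admissible splits — no
multiplicity correction is applied, so results carry an ``exploratory``
flag.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .errors import DegenerateTableError, NoCutoffError, ParameterError

logger = logging.getLogger(__name__)

# Case-exclusion reasons applied before analysis. Any true flag excludes the
# case; insufficient tumor area additionally falls out of tissue-area QC.
EXCLUSION_REASONS = (
    "preoperative_treatment",
    "unresected_metastasis",
    "mucinous",
    "appendiceal",
    "insufficient_tumor_area",
)


def filter_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop cases flagged with any exclusion reason.

    Returns the analyzable cohort and a summary dict with per-reason counts
    (a case is tallied under its first applicable reason).
    """
    remaining = df
    summary: dict = {"n_retrieved": len(df)}
    for reason in EXCLUSION_REASONS:
        if reason in remaining.columns:
            flagged = remaining[reason].astype(bool)
            summary[f"excluded_{reason}"] = int(flagged.sum())
            remaining = remaining.loc[~flagged]
        else:
            summary[f"excluded_{reason}"] = 0
    summary["n_analyzed"] = len(remaining)
    return remaining.copy(), summary


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns the sample (cross-product) odds ratio and the exact two-sided p
    obtained by summing hypergeometric probabilities not exceeding that of
    the observed table.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("2x2 table has a zero margin")
    odds_ratio, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds_ratio), float(p)


def compare_groups(
    groups: dict[str, np.ndarray],
    log_transform: bool = False,
    log_offset: float = 1.0,
) -> dict:
    """Compare a continuous indicator across >= 2 groups.

    With ``log_transform`` values are mapped through ln(x + offset) first
    (cell densities are left-skewed with exact zeros, hence the +1 offset).
    Reports one-way ANOVA, Bonferroni-adjusted pairwise Welch t-tests, and a
    per-group Kolmogorov-Smirnov normality note. Degenerate (zero-variance)
    data yields p = 1 with a flag rather than an error.
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrs = {}
    for name, v in groups.items():
        a = np.asarray(v, float)
        if a.size < 2:
            raise ParameterError(f"group {name!r} has fewer than 2 values")
        if log_transform:
            if (a + log_offset <= 0).any():
                raise ParameterError("log transform undefined for x + offset <= 0")
            a = np.log(a + log_offset)
        arrs[name] = a

    pooled = np.concatenate(list(arrs.values()))
    degenerate = all(np.var(a) == 0 for a in arrs.values())
    report: dict = {
        "log_transform": log_transform,
        "degenerate_variance": degenerate,
        "normality_ks": {},
    }
    for name, a in arrs.items():
        sd = a.std(ddof=1)
        if sd > 0:
            report["normality_ks"][name] = float(
                stats.kstest((a - a.mean()) / sd, "norm").pvalue
            )
        else:
            report["normality_ks"][name] = np.nan

    if degenerate:
        identical = np.allclose(pooled, pooled[0])
        report["anova"] = {"F": 0.0, "p": 1.0 if identical else np.nan}
        report["pairwise"] = {
            f"{a}|{b}": {"t": 0.0, "p_raw": 1.0, "p_bonferroni": 1.0}
            for a, b in itertools.combinations(arrs, 2)
        }
        return report

    f, p = stats.f_oneway(*arrs.values())
    report["anova"] = {"F": float(f), "p": float(p)}
    pairs = list(itertools.combinations(arrs, 2))
    k = len(pairs)
    pairwise = {}
    for a, b in pairs:
        if np.var(arrs[a]) == 0 and np.var(arrs[b]) == 0:
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat, p_raw = stats.ttest_ind(arrs[a], arrs[b], equal_var=False)
        pairwise[f"{a}|{b}"] = {
            "t": float(t_stat),
            "p_raw": float(p_raw),
            "p_bonferroni": float(min(1.0, k * p_raw)),
        }
    report["pairwise"] = pairwise
    return report


@dataclass
class CutoffResult:
    """Optimal log-rank cutoff for one indicator."""

    indicator: str
    cutoff: float
    n_low: int
    n_high: int
    logrank_statistic: float
    p_value: float
    high_is_favorable: bool
    exploratory: bool = True  # raw minimum p over the scan; no correction
    n_candidates: int = 0


def optimal_cutoff(
    values,
    durations,
    events,
    min_group_frac: float = 0.10,
    indicator: str = "",
) -> CutoffResult:
    """Scan all admissible cutoffs and return the one minimizing log-rank p.

    Candidates are midpoints between consecutive distinct indicator values
    whose split leaves both groups at least ``min_group_frac`` of the
    cohort. Ties in p resolve to the smaller cutoff. The returned p is the
    raw minimum over the scan (flagged exploratory).
    """
    v = np.asarray(values, float)
    t = np.asarray(durations, float)
    e = np.asarray(events, int)
    ok = np.isfinite(v) & np.isfinite(t)
    v, t, e = v[ok], t[ok], e[ok]
    n = len(v)
    if n == 0:
        raise NoCutoffError("no finite indicator values")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise NoCutoffError("indicator is constant; no admissible cutoff")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_n = min_group_frac * n

    best: CutoffResult | None = None
    n_cand = 0
    for c in candidates:
        high = v > c
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < min_n or n_low < min_n:
            continue
        n_cand += 1
        res = logrank_test(t[high], t[~high], e[high], e[~high])
        p = float(res.p_value)
        if best is None or p < best.p_value - 1e-15:
            km_high = _km_at(t[high], e[high])
            km_low = _km_at(t[~high], e[~high])
            best = CutoffResult(
                indicator=indicator,
                cutoff=float(c),
                n_low=n_low,
                n_high=n_high,
                logrank_statistic=float(res.test_statistic),
                p_value=p,
                high_is_favorable=bool(km_high >= km_low),
            )
    if best is None:
        raise NoCutoffError("no split leaves both groups above the minimum fraction")
    best.n_candidates = n_cand
    return best


def _km_at(durations, events, time: float | None = None) -> float:
    """KM survival probability at ``time`` (default: last observed time)."""
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    if time is None:
        time = float(np.max(durations))
    return float(kmf.predict(time))


def km_logrank(
    strata,
    durations,
    events,
    t_months: float = 60.0,
) -> dict:
    """Kaplan-Meier curves per stratum, t-month OS and the k-group log-rank p.

    The t-month survival is read off the right-continuous KM step function
    (the default of 60 months is the conventional 5-year overall survival).
    Empty strata are dropped with a warning.
    """
    s = pd.Series(strata).reset_index(drop=True)
    t = pd.Series(np.asarray(durations, float))
    e = pd.Series(np.asarray(events, int))
    out: dict = {"strata": {}, "t_months": t_months}
    kept = []
    for level in pd.unique(s.dropna()):
        sel = (s == level).to_numpy()
        if sel.sum() == 0:
            logger.warning("stratum %r empty; dropped", level)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(level))
        out["strata"][level] = {
            "n": int(sel.sum()),
            "events": int(e[sel].sum()),
            f"os_{int(t_months)}m": float(kmf.predict(t_months)),
            "km": kmf,
        }
        kept.append(level)
    if len(kept) >= 2:
        sel = s.isin(kept).to_numpy()
        res = multivariate_logrank_test(t[sel], s[sel], e[sel])
        out["logrank_statistic"] = float(res.test_statistic)
        out["logrank_p"] = float(res.p_value)
    else:
        out["logrank_statistic"] = 0.0
        out["logrank_p"] = np.nan
    return out


@dataclass
class SurvivalModelResult:
    """Cox proportional-hazards fit (Efron ties) with optional stepwise trace."""

    terms: pd.DataFrame  # index: covariate; columns HR, CI_lower, CI_upper, p
    lr_statistic: float
    lr_p: float
    log_likelihood: float
    selected: list = field(default_factory=list)
    trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def _fit_cox(df, duration_col, event_col, covariates) -> CoxPHFitter:
    cph = CoxPHFitter()
    cols = [duration_col, event_col, *covariates]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[cols], duration_col=duration_col, event_col=event_col)
    return cph


def _null_log_likelihood(df, duration_col, event_col) -> float:
    """Partial log-likelihood of the empty Cox model (beta = 0, Efron ties).

    At beta = 0 every relative hazard is 1, so the Efron contribution of an
    event time with d tied events and risk-set size n is
    -sum_{l=0}^{d-1} log(n - l).
    """
    t = df[duration_col].to_numpy(float)
    e = df[event_col].to_numpy(int)
    ll = 0.0
    for tj in np.unique(t[e == 1]):
        n_risk = int(np.sum(t >= tj))
        d = int(np.sum((t == tj) & (e == 1)))
        ll -= float(np.sum(np.log(n_risk - np.arange(d))))
    return ll


def cox_model(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    stepwise: bool = False,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
) -> SurvivalModelResult:
    """Cox proportional-hazards model with Efron tie handling.

    With ``stepwise``, covariates enter by forward likelihood-ratio
    selection (best LR p < ``alpha_enter``) with backward LR removal
    (p > ``alpha_remove``) after each entry, until the selection is stable.
    Zero-variance covariates are excluded with a warning.
    """
    warn: list[str] = []
    usable = []
    for c in covariates:
        if df[c].isna().any():
            raise ParameterError(f"covariate {c!r} has missing values")
        if np.var(df[c].to_numpy(float)) == 0:
            warn.append(f"covariate {c!r} has zero variance; excluded")
            logger.warning(warn[-1])
        else:
            usable.append(c)
    n_events = int(df[event_col].sum())
    if n_events < 5 * max(len(usable), 1):
        warn.append(
            f"only {n_events} events for {len(usable)} candidate terms "
            "(< 5 events per term)"
        )
    ll_null = _null_log_likelihood(df, duration_col, event_col)

    trace: list[str] = []
    if not stepwise:
        selected = list(usable)
    else:
        selected = []
        changed = True
        while changed:
            changed = False
            ll_cur = (
                ll_null
                if not selected
                else float(_fit_cox(df, duration_col, event_col, selected).log_likelihood_)
            )
            # Forward step: add the candidate with the best LR p.
            best_p, best_c, best_ll = 1.0, None, None
            for c in usable:
                if c in selected:
                    continue
                ll_new = float(
                    _fit_cox(df, duration_col, event_col, selected + [c]).log_likelihood_
                )
                p = stats.chi2.sf(2 * (ll_new - ll_cur), df=1)
                if p < best_p:
                    best_p, best_c, best_ll = p, c, ll_new
            if best_c is not None and best_p < alpha_enter:
                selected.append(best_c)
                trace.append(f"add {best_c} (LR p={best_p:.4g})")
                ll_cur = best_ll
                changed = True
            # Backward step: drop any term whose LR p exceeds the threshold.
            dropped = True
            while dropped and len(selected) > 1:
                dropped = False
                worst_p, worst_c = 0.0, None
                for c in selected:
                    rest = [x for x in selected if x != c]
                    ll_red = float(
                        _fit_cox(df, duration_col, event_col, rest).log_likelihood_
                    )
                    p = stats.chi2.sf(2 * (ll_cur - ll_red), df=1)
                    if p > worst_p:
                        worst_p, worst_c = p, c
                if worst_c is not None and worst_p > alpha_remove:
                    selected.remove(worst_c)
                    trace.append(f"remove {worst_c} (LR p={worst_p:.4g})")
                    ll_cur = float(
                        _fit_cox(df, duration_col, event_col, selected).log_likelihood_
                    )
                    dropped = True
                    changed = True

    if not selected:
        terms = pd.DataFrame(columns=["HR", "CI_lower", "CI_upper", "p"])
        return SurvivalModelResult(
            terms=terms,
            lr_statistic=0.0,
            lr_p=1.0,
            log_likelihood=ll_null,
            selected=[],
            trace=trace,
            warnings=warn,
        )

    cph = _fit_cox(df, duration_col, event_col, selected)
    summ = cph.summary
    terms = pd.DataFrame(
        {
            "HR": summ["exp(coef)"],
            "CI_lower": summ["exp(coef) lower 95%"],
            "CI_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    ll = float(cph.log_likelihood_)
    lr = max(0.0, 2 * (ll - ll_null))
    lr_p = float(stats.chi2.sf(lr, df=len(selected)))
    return SurvivalModelResult(
        terms=terms,
        lr_statistic=float(lr),
        lr_p=lr_p,
        log_likelihood=ll,
        selected=selected,
        trace=trace,
        warnings=warn,
    )


def _breslow_partial_loglik(eta, durations, events) -> float:
    """Breslow partial log-likelihood for fixed linear predictors."""
    order = np.argsort(-np.asarray(durations, float), kind="stable")
    eta = np.asarray(eta, float)[order]
    t = np.asarray(durations, float)[order]
    e = np.asarray(events, int)[order]
    # Risk sets: cumulative sums over descending time; ties share a risk set.
    exp_eta = np.exp(eta - eta.max())
    csum = np.cumsum(exp_eta)
    # For tied times the risk set is everyone with time >= t_i.
    risk = np.empty_like(csum)
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        risk[i : j + 1] = csum[j]
        i = j + 1
    ll = float(np.sum(e * ((eta - eta.max()) - np.log(risk))))
    return ll


def loo_cross_validate(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> dict:
    """Leave-one-out cross-validation of a Cox model specification.

    Each patient's linear predictor is computed from the model fit on the
    other n-1; reported are the cross-validated concordance index over the
    held-out predictors and the out-of-sample Breslow partial
    log-likelihood evaluated with those predictors (Verweij-van Houwelingen
    style). Refit failures flag the case and lower the completion fraction.
    """
    n = len(df)
    eta = np.full(n, np.nan)
    failures = []
    X = df[covariates].to_numpy(float)
    for i in range(n):
        rest = df.drop(df.index[i])
        try:
            cph = _fit_cox(rest, duration_col, event_col, covariates)
            beta = cph.params_.reindex(covariates).to_numpy(float)
            eta[i] = float(X[i] @ beta)
        except Exception as exc:  # noqa: BLE001 - any refit failure flags the case
            failures.append((df.index[i], str(exc)))
    ok = np.isfinite(eta)
    t = df[duration_col].to_numpy(float)
    e = df[event_col].to_numpy(int)
    result = {
        "completion_fraction": float(ok.mean()),
        "failed_cases": [i for i, _ in failures],
    }
    if ok.sum() >= 2:
        result["cv_concordance"] = float(concordance_index(t[ok], -eta[ok], e[ok]))
        result["cv_partial_loglik"] = _breslow_partial_loglik(eta[ok], t[ok], e[ok])
    else:
        result["cv_concordance"] = np.nan
        result["cv_partial_loglik"] = np.nan
    return result
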