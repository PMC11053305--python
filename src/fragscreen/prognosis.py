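"""Score-based prognosis: group comparisons, Kaplan–Meier, log-rank, Cox.

Overall survival runs from diagnosis to death or administrative censoring
at 36 months.  The fragmentation score is dichotomized at the median over
all cases (high: score >= median) and its association with survival is
assessed by Kaplan–Meier curves, the two-group log-rank test (optionally
stratified, e.g. by BCLC stage) and a Cox proportional-hazards model
adjusted for age, sex, BCLC stage and AFP status.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FOLLOWUP_CAP_MONTHS = 36.0
AGE_CUT_YEARS = 55.0


def cap_followup(
    df: pd.DataFrame,
    time_col: str = "time_months",
    event_col: str = "event",
    cap: float = FOLLOWUP_CAP_MONTHS,
) -> pd.DataFrame:
    """Administratively censor follow-up beyond ``cap`` months."""
    out = df.copy()
    over = out[time_col] > cap
    out.loc[over, event_col] = 0
    out.loc[over, time_col] = cap
    return out


def group_compare(
    scores: Sequence[float], grouping: Sequence, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of scores between two groups.

    Exact null distribution when both groups have at most ``exact_max_n``
    observations and no ties; otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(grouping)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {len(levels)}")
    a, b = s[g == levels[0]], s[g == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    use_exact = (
        len(a) <= exact_max_n and len(b) <= exact_max_n and len(np.unique(s)) == len(s)
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def dichotomize(
    scores: Sequence[float], rule: str = "median"
) -> tuple[np.ndarray, float]:
    """High/low labels at the median score (high iff score >= median).

    Returns the boolean high-group indicator and the threshold used.  On
    odd n with a uniquely attained median this yields the (n+1)/2 high vs
    (n-1)/2 low split.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 scores to dichotomize")
    if rule != "median":
        raise ValueError(f"unknown dichotomization rule: {rule!r}")
    threshold = float(np.median(s))
    return s >= threshold, threshold


@dataclass
class KMEstimate:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # risk-set size just before each event time
    n_events: np.ndarray    # events at each time
    median: float           # earliest t with S(t) <= 0.5; NaN if never reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan–Meier product-limit estimator.

    The median is the earliest observed event time with S(t) <= 0.5 and is
    NaN when the curve never drops that far.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("no survival records")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    surv_arr = np.array(surv)
    median = math.nan
    below = np.nonzero(surv_arr <= 0.5)[0] if len(surv_arr) else []
    if len(below):
        median = float(event_times[below[0]])
    return KMEstimate(
        times=event_times,
        survival=surv_arr,
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
        median=median,
    )


def _logrank_components(
    t: np.ndarray, e: np.ndarray, g: np.ndarray
) -> tuple[float, float]:
    """Observed-minus-expected events in group 1 and hypergeometric variance,
    summed over event times."""
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & g).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
    strata: Sequence | None = None,
) -> tuple[float, float]:
    """Two-group log-rank test; optionally stratified.

    Returns the chi-square statistic (1 df) and its p-value.  With strata,
    observed-minus-expected and variance are summed across strata before
    forming the statistic.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    garr = np.asarray(groups)
    levels = pd.unique(garr)
    if len(levels) != 2:
        raise ValueError("log-rank test requires exactly 2 groups")
    if e.sum() == 0:
        raise ValueError("no events observed")
    g = garr == levels[1]
    if strata is None:
        o_minus_e, var = _logrank_components(t, e, g)
    else:
        sarr = np.asarray(strata)
        o_minus_e = var = 0.0
        for lvl in pd.unique(sarr):
            mask = sarr == lvl
            ome, v = _logrank_components(t[mask], e[mask], g[mask])
            o_minus_e += ome
            var += v
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def prepare_survival_frame(
    df: pd.DataFrame,
    score_col: str = "score",
    dichotomize_score: bool = True,
    cap: float = FOLLOWUP_CAP_MONTHS,
) -> pd.DataFrame:
    """Standardize a survival table for modeling.

    Expects columns ``time_months``, ``event``, the score, and optionally
    ``age`` (years, dichotomized at 55), ``sex``, ``bclc`` (0/A vs B/C)
    and ``afp_status``.  Adds ``score_high`` from the median split and
    caps follow-up.
    """
    out = cap_followup(df, cap=cap)
    if dichotomize_score:
        high, threshold = dichotomize(out[score_col].to_numpy())
        out["score_high"] = high.astype(int)
        out.attrs["score_threshold"] = threshold
    if "age" in out.columns and not np.issubdtype(out["age"].dtype, np.integer):
        out["age_ge55"] = (out["age"] >= AGE_CUT_YEARS).astype(int)
    return out


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    covariates: Sequence[str] = ("score_high", "age_ge55", "sex", "bclc", "afp_status"),
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron tie handling, via lifelines).

    Returns a table with one row per covariate: hazard ratio, Wald 95% CI
    and p-value.  Warns when events are fewer than covariates; complete
    separation falls back to a ridge-penalized fit with a warning.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = [duration_col, event_col, *covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns for Cox model: {missing}")
    data = df[cols].dropna()
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        logger.warning(
            "only %d events for %d covariates; estimates may be unstable",
            n_events, len(covariates),
        )
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError:
        logger.warning("Cox fit failed to converge; retrying with ridge penalty 0.1")
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    summary = cph.summary
    return pd.DataFrame(
        {
            "covariate": summary.index,
            "hr": summary["exp(coef)"].to_numpy(),
            "hr_ci_lo": summary["exp(coef) lower 95%"].to_numpy(),
            "hr_ci_hi": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)
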