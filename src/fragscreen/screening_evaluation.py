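"""Diagnostic and screening performance metrics.

Covers confusion metrics with exact (Clopper–Pearson) binomial confidence
intervals, ROC AUC with a DeLong-style asymptotic CI, time-windowed
sensitivity for pre-diagnosis samples, incidence rates, and
incidence-based PPV/NPV for a screening scenario.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# time windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeWindow:
    """Years-before-diagnosis interval ``(lower, upper]``.

    A sample exactly on a boundary belongs to the narrower window (closer
    to diagnosis).
    """

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window {self.label}: lower must be < upper")

    def contains(self, years_before_dx: float) -> bool:
        return self.lower < years_before_dx <= self.upper


#: the pre-diagnosis windows used throughout: 0–1, 1–2, 2–3, 3–4 and >4 years
DEFAULT_WINDOWS: tuple[TimeWindow, ...] = (
    TimeWindow("0-1y", 0.0, 1.0),
    TimeWindow("1-2y", 1.0, 2.0),
    TimeWindow("2-3y", 2.0, 3.0),
    TimeWindow("3-4y", 3.0, 4.0),
    TimeWindow(">4y", 4.0, math.inf),
)


def assign_window(
    years_before_dx: float, windows: Sequence[TimeWindow] = DEFAULT_WINDOWS
) -> str | None:
    """Window label for a sampling time, or None if outside every window.

    A time of exactly 0 (sample at diagnosis) is placed in the first
    window.
    """
    labels = [w.label for w in windows]
    if len(set(labels)) != len(labels):
        raise ValueError("window labels not unique")
    if years_before_dx == 0.0:
        return windows[0].label
    for w in windows:
        if w.contains(years_before_dx):
            return w.label
    return None


# ---------------------------------------------------------------------------
# confusion metrics and exact intervals
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan


def confusion_metrics(
    truth: Sequence[int | bool], predicted: Sequence[int | bool]
) -> ConfusionMetrics:
    """2x2 confusion counts; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    y = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if y.shape != p.shape:
        raise ValueError("truth and predicted have different lengths")
    return ConfusionMetrics(
        tp=int((y & p).sum()),
        fp=int((~y & p).sum()),
        tn=int((~y & ~p).sum()),
        fn=int((y & ~p).sum()),
    )


def exact_binomial_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson exact interval for a binomial proportion.

    Endpoints satisfy the tail conditions P(X >= x | p = lower) = alpha/2
    and P(X <= x | p = upper) = alpha/2; lower is 0 when x = 0 and upper
    is 1 when x = n.
    """
    if not (0 <= successes <= trials) or trials < 1:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lower, upper


def wilson_ci(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (alternative to the exact interval)."""
    if not (0 <= successes <= trials) or trials < 1:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    p = successes / trials
    denom = 1 + z**2 / trials
    center = (p + z**2 / (2 * trials)) / denom
    half = z * math.sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def binomial_ci(
    successes: int, trials: int, confidence: float = 0.95, method: str = "exact"
) -> tuple[float, float]:
    if method == "exact":
        return exact_binomial_ci(successes, trials, confidence)
    if method == "wilson":
        return wilson_ci(successes, trials, confidence)
    raise ValueError(f"unknown CI method: {method!r}")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(
    scores: Sequence[float], truth: Sequence[int | bool], confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC as the Mann–Whitney concordance probability, with DeLong CI.

    Ties between a case and a control score count 1/2.  The CI uses the
    DeLong structural-component variance estimate on the logit-free scale,
    clipped to [0, 1]; it degenerates to a point at AUC exactly 0 or 1.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and truth have different lengths")
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for AUC")
    all_ranks = _midrank(s)
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[y].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[y] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[~y] - neg_ranks) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n if m > 1 and n > 1 else 0.0
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    half = z * math.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


def roc_curve_points(scores: Sequence[float], truth: Sequence[int | bool]) -> pd.DataFrame:
    """ROC coordinates (fpr, tpr, threshold) over the distinct scores."""
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, thr = _sk_roc(np.asarray(truth, dtype=int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# screening arithmetic
# ---------------------------------------------------------------------------

def incidence_rate(n_events: int, person_years: float, per: float = 100_000.0) -> float:
    """Events per ``per`` person-years; rounding is left to the reporter."""
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    return n_events / person_years * per


def ppv_npv(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Bayes-rule predictive values at a given prevalence.

    ppv = sens*p / (sens*p + (1-spec)*(1-p));
    npv = spec*(1-p) / (spec*(1-p) + (1-sens)*p).
    For a rare annual outcome the prevalence is approximated by the annual
    incidence rate.  A zero denominator returns NaN with a warning.
    """
    for name, v in [("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    p = prevalence
    ppv_den = sensitivity * p + (1 - specificity) * (1 - p)
    npv_den = specificity * (1 - p) + (1 - sensitivity) * p
    if ppv_den == 0:
        logger.warning("PPV undefined (no positives expected); returning NaN")
        ppv = math.nan
    else:
        ppv = sensitivity * p / ppv_den
    if npv_den == 0:
        logger.warning("NPV undefined (no negatives expected); returning NaN")
        npv = math.nan
    else:
        npv = specificity * (1 - p) / npv_den
    return ppv, npv


# ---------------------------------------------------------------------------
# windowed evaluation report
# ---------------------------------------------------------------------------

@dataclass
class WindowResult:
    window: str
    n: int
    detected: int
    sensitivity: float
    ci: tuple[float, float]
    ppv: float = math.nan
    npv: float = math.nan
    ppv_ci: tuple[float, float] = (math.nan, math.nan)
    npv_ci: tuple[float, float] = (math.nan, math.nan)


@dataclass
class ScreeningReport:
    """Per-window sensitivities with exact CIs plus overall specificity,
    AUC and incidence-based predictive values."""

    windows: list[WindowResult]
    specificity: float
    specificity_ci: tuple[float, float]
    n_controls: int
    n_controls_negative: int
    cutoff: float
    incidence_per_100k: float | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": [w.window for w in self.windows],
                "n": [w.n for w in self.windows],
                "detected": [w.detected for w in self.windows],
                "sensitivity": [w.sensitivity for w in self.windows],
                "ci_lo": [w.ci[0] for w in self.windows],
                "ci_hi": [w.ci[1] for w in self.windows],
                "ppv": [w.ppv for w in self.windows],
                "npv": [w.npv for w in self.windows],
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cutoff": self.cutoff,
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "n_controls": self.n_controls,
            "n_controls_negative": self.n_controls_negative,
            "incidence_per_100k": self.incidence_per_100k,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "windows": [
                {
                    "window": w.window,
                    "n": w.n,
                    "detected": w.detected,
                    "sensitivity": w.sensitivity,
                    "ci": list(w.ci),
                    "ppv": w.ppv,
                    "npv": w.npv,
                    "ppv_ci": list(w.ppv_ci),
                    "npv_ci": list(w.npv_ci),
                }
                for w in self.windows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def window_sensitivity(
    case_scores: pd.DataFrame,
    cutoff: float,
    windows: Sequence[TimeWindow] = DEFAULT_WINDOWS,
    ci_method: str = "exact",
) -> list[WindowResult]:
    """Per-window sensitivity over case subjects with a sample in each window.

    ``case_scores`` holds one aggregated score per (subject, window)
    (columns ``subject_id``, ``window``, ``score``).  A subject with
    samples in several windows contributes once to each.  Windows with no
    eligible subjects are reported with NaN sensitivity and a warning.
    """
    results: list[WindowResult] = []
    for w in windows:
        sub = case_scores[case_scores["window"] == w.label]
        n = len(sub)
        if n == 0:
            logger.warning("window %s: no eligible case subjects", w.label)
            results.append(
                WindowResult(w.label, 0, 0, math.nan, (math.nan, math.nan))
            )
            continue
        detected = int((sub["score"] >= cutoff).sum())
        sens = detected / n
        ci = binomial_ci(detected, n, method=ci_method)
        results.append(WindowResult(w.label, n, detected, sens, ci))
    return results


def ppv_npv_by_window(
    window_results: Sequence[WindowResult],
    specificity: float,
    prevalence: float,
    sensitivity_cis: bool = True,
) -> list[WindowResult]:
    """Attach predictive values to each window result.

    PPV/NPV intervals are obtained by propagating the sensitivity CI
    endpoints through the Bayes formula at fixed specificity and
    prevalence (the specificity uncertainty is not propagated; the method
    is labelled as such in reports).
    """
    out: list[WindowResult] = []
    for w in window_results:
        if math.isnan(w.sensitivity):
            out.append(w)
            continue
        ppv, npv = ppv_npv(w.sensitivity, specificity, prevalence)
        ppv_ci = npv_ci = (math.nan, math.nan)
        if sensitivity_cis and not any(math.isnan(c) for c in w.ci):
            lo_p, lo_n = ppv_npv(w.ci[0], specificity, prevalence)
            hi_p, hi_n = ppv_npv(w.ci[1], specificity, prevalence)
            ppv_ci = (min(lo_p, hi_p), max(lo_p, hi_p))
            npv_ci = (min(lo_n, hi_n), max(lo_n, hi_n))
        out.append(
            WindowResult(
                w.window, w.n, w.detected, w.sensitivity, w.ci,
                ppv=ppv, npv=npv, ppv_ci=ppv_ci, npv_ci=npv_ci,
            )
        )
    return out


def evaluate_screening(
    case_scores: pd.DataFrame,
    control_scores: Sequence[float],
    cutoff: float,
    incidence_per_100k: float | None = None,
    windows: Sequence[TimeWindow] = DEFAULT_WINDOWS,
    ci_method: str = "exact",
) -> ScreeningReport:
    """Full screening evaluation for aggregated case scores and one score
    per control subject.

    Controls contribute to specificity once each (their per-subject mean
    score thresholded at the cutoff).  When an incidence rate is supplied,
    the per-window PPV/NPV use prevalence = incidence_per_100k / 100,000.
    """
    ctrl = np.asarray(control_scores, dtype=float)
    n_ctrl = len(ctrl)
    if n_ctrl == 0:
        raise ValueError("no control scores")
    fp = int((ctrl >= cutoff).sum())
    tn = n_ctrl - fp
    spec = tn / n_ctrl
    spec_ci = binomial_ci(tn, n_ctrl, method=ci_method)

    wres = window_sensitivity(case_scores, cutoff, windows, ci_method)
    if incidence_per_100k is not None:
        prevalence = incidence_per_100k / 100_000.0
        wres = ppv_npv_by_window(wres, spec, prevalence)

    auc = auc_ci = None
    if len(case_scores):
        all_scores = np.concatenate([case_scores["score"].to_numpy(dtype=float), ctrl])
        truth = np.concatenate([np.ones(len(case_scores), bool), np.zeros(n_ctrl, bool)])
        auc, auc_ci = roc_auc(all_scores, truth)

    return ScreeningReport(
        windows=wres,
        specificity=spec,
        specificity_ci=spec_ci,
        n_controls=n_ctrl,
        n_controls_negative=tn,
        cutoff=cutoff,
        incidence_per_100k=incidence_per_100k,
        auc=auc,
        auc_ci=auc_ci,
    )
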