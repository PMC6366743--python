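"""Discrimination and calibration metrics for probabilistic risk models.

Discrimination is summarized by the concordance (C) statistic — the
probability that a randomly chosen event receives a higher predicted risk
than a randomly chosen non-event, ties counted one half — with an
asymptotic DeLong-type confidence interval.  Calibration is summarized by
the expected/observed events ratio E/O (sum of predicted probabilities
over the event count) with a Poisson-approximation confidence interval,
and by grouped calibration curves.  The Brier score (mean squared error
of the predicted probability) and the Yates slope (mean predicted risk in
events minus non-events) complete the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerformanceReport",
    "CalibrationCurve",
    "c_statistic",
    "eo_ratio",
    "eo_confidence_interval",
    "brier_score",
    "yates_slope",
    "calibration_curve",
    "evaluate",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _validate(probs, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probs and outcomes must be equal-length 1-d arrays")
    if np.isnan(p).any() or np.isnan(y).any():
        raise ValueError("probs/outcomes contain missing values")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcomes must be 0/1")
    return p, y


@dataclass(frozen=True)
class CStatistic:
    estimate: float
    ci_low: float
    ci_high: float
    se: float


def c_statistic(probs, outcomes, ci: bool = True) -> CStatistic:
    """Concordance statistic with a DeLong-type asymptotic 95% CI.

    Computed from midranks (equivalent to counting concordant event /
    non-event pairs with ties scored one half); the variance uses the
    DeLong structural components of the two groups.
    """
    p, y = _validate(probs, outcomes)
    cases = p[y == 1]
    controls = p[y == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    # placement values: fraction of the other group below each observation
    v10 = (all_ranks[:m] - case_ranks) / n        # per-case components
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m  # per-control components
    auc = float(np.mean(v10))
    if not ci:
        return CStatistic(auc, np.nan, np.nan, np.nan)
    if m > 1 and n > 1:
        var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    else:
        var = np.nan
    se = float(np.sqrt(var))
    lo = max(0.0, auc - _Z95 * se)
    hi = min(1.0, auc + _Z95 * se)
    return CStatistic(auc, lo, hi, se)


def eo_ratio(probs, outcomes) -> float:
    """Expected over observed events: sum(probs) / sum(outcomes)."""
    p, y = _validate(probs, outcomes)
    observed = float(np.sum(y))
    if observed == 0:
        raise ValueError("no observed events; E/O undefined")
    return float(np.sum(p)) / observed


def eo_confidence_interval(
    ratio: float, observed: int, exact: bool = False
) -> tuple[float, float]:
    """95% CI for an E/O ratio assuming Poisson-distributed observed events.

    The default log-scale normal approximation,
    ``ratio * exp(-+ 1.96 / sqrt(O))``, is the form that standardized-ratio
    reports conventionally print; ``exact=True`` uses the chi-square
    (exact Poisson) bounds for the observed count instead.
    """
    if observed < 1:
        raise ValueError("need at least one observed event")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if exact:
        o_lo = 0.5 * stats.chi2.ppf(0.025, 2 * observed)
        o_hi = 0.5 * stats.chi2.ppf(0.975, 2 * (observed + 1))
        return ratio * observed / o_hi, ratio * observed / o_lo
    half = _Z95 / np.sqrt(observed)
    return float(ratio * np.exp(-half)), float(ratio * np.exp(half))


def brier_score(probs, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p, y = _validate(probs, outcomes)
    return float(np.mean((p - y) ** 2))


def yates_slope(probs, outcomes) -> float:
    """Mean predicted risk among events minus among non-events."""
    p, y = _validate(probs, outcomes)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both outcome classes must be present")
    return float(np.mean(p[y == 1]) - np.mean(p[y == 0]))


@dataclass
class CalibrationCurve:
    """Grouped calibration data: mean predicted vs observed rate per bin."""

    mean_predicted: np.ndarray
    observed_rate: np.ndarray
    counts: np.ndarray
    n_bins: int


def calibration_curve(probs, outcomes, n_bins: int = 10) -> CalibrationCurve:
    """Quantile-binned calibration curve (deciles of predicted risk).

    Bins with too few distinct probabilities are merged (with a warning),
    mirroring how grouped calibration plots behave with granular scores.
    """
    p, y = _validate(probs, outcomes)
    if len(p) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bins = pd.qcut(p, q=n_bins, duplicates="drop")
    if len(bins.categories) == 0:
        # constant predictions: a single all-encompassing bin
        warnings.warn("constant predictions; bins merged into one")
        return CalibrationCurve(
            mean_predicted=np.array([float(np.mean(p))]),
            observed_rate=np.array([float(np.mean(y))]),
            counts=np.array([len(p)]),
            n_bins=1,
        )
    if len(bins.categories) < n_bins:
        warnings.warn(
            f"only {len(bins.categories)} distinct bins (requested {n_bins}); merged"
        )
    frame = pd.DataFrame({"p": p, "y": y, "bin": bins})
    grouped = frame.groupby("bin", observed=True)
    agg = grouped.agg(mean_predicted=("p", "mean"), observed_rate=("y", "mean"),
                      counts=("y", "size"))
    return CalibrationCurve(
        mean_predicted=agg["mean_predicted"].to_numpy(),
        observed_rate=agg["observed_rate"].to_numpy(),
        counts=agg["counts"].to_numpy(dtype=int),
        n_bins=len(agg),
    )


@dataclass
class PerformanceReport:
    """All headline metrics for one model on one dataset."""

    n: int
    events: int
    expected_events: float
    c_statistic: float
    c_ci_low: float
    c_ci_high: float
    eo_ratio: float
    eo_ci_low: float
    eo_ci_high: float
    brier: float
    yates_slope: float


def evaluate(probs, outcomes) -> PerformanceReport:
    """Compute the full discrimination/calibration report."""
    p, y = _validate(probs, outcomes)
    events = int(np.sum(y))
    ratio = eo_ratio(p, y)
    eo_lo, eo_hi = eo_confidence_interval(ratio, events)
    c = c_statistic(p, y)
    return PerformanceReport(
        n=len(p),
        events=events,
        expected_events=float(np.sum(p)),
        c_statistic=c.estimate,
        c_ci_low=c.ci_low,
        c_ci_high=c.ci_high,
        eo_ratio=ratio,
        eo_ci_low=eo_lo,
        eo_ci_high=eo_hi,
        brier=brier_score(p, y),
        yates_slope=yates_slope(p, y),
    )
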