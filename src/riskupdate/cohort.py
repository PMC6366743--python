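"""Synthetic cohort generator emulating a community diabetes-screening survey.

Emulates a community diabetes-screening survey: ``n_recruited``
participants, of whom ``n_previously_diagnosed`` carry a prior diabetes
diagnosis (they are flagged and never receive an OGTT outcome).  Among the
remainder, undiagnosed diabetes is simulated from a known "true" logistic
risk model whose intercept is calibrated so the expected prevalence hits a
target (15% by default).

Continuous covariates (age, BMI, waist circumference, systolic and
diastolic blood pressure) are drawn from truncated-normal marginals
coupled by a Gaussian copula: BMI-waist and SBP-DBP are correlated
(0.8 and 0.6 by default), everything else independent.  Binary and
categorical fields are independent draws at the configured prevalences.
Missing data are injected MCAR, field by field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .registry import RiskModel, design_matrix, load_model_registry

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "inject_missingness",
    "calibrate_true_intercept",
    "CONTINUOUS_FIELDS",
    "BINARY_FIELDS",
    "CATEGORICAL_FIELDS",
]

CONTINUOUS_FIELDS = ("age", "bmi", "waist", "sbp", "dbp")
BINARY_FIELDS = (
    "antihypertensive_meds",
    "lipid_lowering_meds",
    "corticosteroids",
    "mother_diabetes",
    "father_diabetes",
    "sister_diabetes",
    "brother_diabetes",
)
CATEGORICAL_FIELDS = ("sex", "smoking", "drinking", "education")

#: physiologic truncation ranges for the continuous marginals
_BOUNDS = {
    "age": (20.0, 90.0),
    "bmi": (14.0, 60.0),
    "waist": (50.0, 160.0),
    "sbp": (80.0, 220.0),
    "dbp": (40.0, 130.0),
}

_DEFAULT_CONTINUOUS = {
    "age": (51.9, 14.9),
    "bmi": (29.7, 7.0),
    "waist": (95.8, 15.3),
    "sbp": (124.3, 20.0),
    "dbp": (76.0, 12.7),
}

_DEFAULT_BINARY = {
    "male": 0.232,
    "antihypertensive_meds": 0.345,
    "lipid_lowering_meds": 0.037,
    "corticosteroids": 0.011,
    "mother_diabetes": 0.115,
    "father_diabetes": 0.056,
    "sister_diabetes": 0.095,
    "brother_diabetes": 0.062,
    "current_alcohol": 0.251,
    "current_smoking": 0.400,
}

# The survey reports only the "current" fraction for smoking and alcohol
# and the high-school fraction for education; the remaining level splits
# are package choices (see docs/methods.md).
_SMOKING_LEVELS = ("never", "ex", "current")
_DRINKING_LEVELS = ("never", "ex", "current")
_EDUCATION_LEVELS = ("primary", "high_school", "university")
_EX_SMOKING = 0.15
_EX_DRINKING = 0.15
_EDUCATION_PROBS = {"high_school": 0.121, "university": 0.059}

_DEFAULT_MISSINGNESS = {
    "mother_diabetes": 0.251,
    "father_diabetes": 0.249,
    "sister_diabetes": 0.250,
    "brother_diabetes": 0.251,
    "smoking": 0.061,
    "age": 0.03,
    "bmi": 0.03,
    "waist": 0.03,
    "sbp": 0.03,
    "dbp": 0.03,
    "antihypertensive_meds": 0.03,
    "lipid_lowering_meds": 0.03,
    "corticosteroids": 0.03,
    "drinking": 0.03,
    "education": 0.03,
}


@dataclass
class CohortConfig:
    """All generator parameters; defaults emulate the published sample."""

    n_recruited: int = 1256
    n_previously_diagnosed: int = 173
    continuous_marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CONTINUOUS)
    )
    binary_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BINARY)
    )
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    wc_bmi_correlation: float = 0.8
    sbp_dbp_correlation: float = 0.6
    true_model: RiskModel | None = None  # None -> recalibrated Omani model
    #: expected outcome prevalence among non-excluded records; ``None`` keeps
    #: the true model's own intercept (no recalibration)
    target_prevalence: float | None = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_previously_diagnosed < self.n_recruited:
            raise ValueError("need 0 <= n_previously_diagnosed < n_recruited")
        if self.target_prevalence is None and self.true_model is None:
            raise ValueError("target_prevalence=None requires an explicit true_model")
        if self.target_prevalence is not None and not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        for f, (m, s) in self.continuous_marginals.items():
            if s <= 0:
                raise ValueError(f"sd for {f!r} must be positive")
        for f, p in {**self.binary_prevalences, **self.missingness_rates}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {f!r} must be in [0, 1]")


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _draw_continuous(cfg: CohortConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    order = list(CONTINUOUS_FIELDS)
    k = len(order)
    corr = np.eye(k)
    i_bmi, i_wc = order.index("bmi"), order.index("waist")
    i_sbp, i_dbp = order.index("sbp"), order.index("dbp")
    corr[i_bmi, i_wc] = corr[i_wc, i_bmi] = cfg.wc_bmi_correlation
    corr[i_sbp, i_dbp] = corr[i_dbp, i_sbp] = cfg.sbp_dbp_correlation
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((cfg.n_recruited, k)) @ chol.T
    u = stats.norm.cdf(z)
    # keep quantiles strictly inside (0, 1) for the inverse-cdf transform
    u = np.clip(u, 1e-12, 1 - 1e-12)
    out = {}
    for j, f in enumerate(order):
        mean, sd = cfg.continuous_marginals[f]
        lo, hi = _BOUNDS[f]
        out[f] = _truncnorm(mean, sd, lo, hi).ppf(u[:, j])
    return out


def _draw_categorical(
    rng: np.random.Generator, n: int, levels: tuple[str, ...], probs: np.ndarray
) -> np.ndarray:
    return rng.choice(np.array(levels, dtype=object), size=n, p=probs)


def calibrate_true_intercept(
    model: RiskModel, covariate_sample: pd.DataFrame, target_prevalence: float
) -> float:
    """Intercept making the model's mean predicted risk equal the target.

    Solves ``mean(expit(c + lp0)) = target_prevalence`` for ``c`` by
    monotone root-finding, where ``lp0`` is the intercept-free linear
    predictor over the supplied covariate sample.
    """
    if len(covariate_sample) == 0:
        raise ValueError("covariate sample is empty")
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    dm = design_matrix(covariate_sample, model)
    beta = np.array([model.coefficients[t] for t in model.terms])
    lp0 = dm.to_numpy(dtype=float) @ beta

    def gap(c: float) -> float:
        return float(np.mean(expit(c + lp0))) - target_prevalence

    try:
        return float(optimize.brentq(gap, -40.0, 40.0, xtol=1e-12, maxiter=200))
    except ValueError as exc:
        raise RuntimeError(f"intercept calibration did not converge: {exc}") from exc


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort; fully reproducible given ``config.seed``.

    Returns a frame with one row per recruited participant.  Records
    flagged ``previously_diagnosed`` have a missing ``outcome`` (they are
    never screened by OGTT); all other records carry a simulated 0/1
    undiagnosed-diabetes outcome.  The calibrated true-model intercept is
    stored in ``frame.attrs["true_intercept"]``.
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_recruited

    data = {"id": np.arange(n)}
    p = cfg.binary_prevalences
    data["sex"] = np.where(rng.random(n) < p["male"], "M", "F").astype(object)
    data.update(_draw_continuous(cfg, rng))
    for f in BINARY_FIELDS:
        data[f] = (rng.random(n) < p[f]).astype(int)
    cur_s = p["current_smoking"]
    data["smoking"] = _draw_categorical(
        rng, n, _SMOKING_LEVELS,
        np.array([1.0 - cur_s - _EX_SMOKING, _EX_SMOKING, cur_s]),
    )
    cur_a = p["current_alcohol"]
    data["drinking"] = _draw_categorical(
        rng, n, _DRINKING_LEVELS,
        np.array([1.0 - cur_a - _EX_DRINKING, _EX_DRINKING, cur_a]),
    )
    hs, uni = _EDUCATION_PROBS["high_school"], _EDUCATION_PROBS["university"]
    data["education"] = _draw_categorical(
        rng, n, _EDUCATION_LEVELS, np.array([1.0 - hs - uni, hs, uni])
    )

    frame = pd.DataFrame(data)
    flagged = rng.choice(n, size=cfg.n_previously_diagnosed, replace=False)
    prev = np.zeros(n, dtype=bool)
    prev[flagged] = True
    frame["previously_diagnosed"] = prev.astype(int)

    true_model = cfg.true_model
    if true_model is None:
        true_model = load_model_registry()["omani"]
    if cfg.target_prevalence is not None:
        eligible = frame.loc[~prev]
        c = calibrate_true_intercept(true_model, eligible, cfg.target_prevalence)
        true_model = true_model.with_updates(intercept=c, name=f"{true_model.name}_true")

    dm = design_matrix(frame, true_model)
    beta = np.array([true_model.coefficients[t] for t in true_model.terms])
    risk = expit(true_model.intercept + dm.to_numpy(dtype=float) @ beta)
    outcome = (rng.random(n) < risk).astype(float)
    outcome[prev] = np.nan
    frame["outcome"] = outcome
    frame.attrs["true_intercept"] = true_model.intercept
    frame.attrs["true_model_name"] = true_model.name
    frame.attrs["seed"] = cfg.seed
    return frame


def inject_missingness(
    cohort: pd.DataFrame, rates: Mapping[str, float] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Mask each field independently MCAR at its configured rate.

    ``outcome`` and ``previously_diagnosed`` are never maskable; a rate for
    a nonexistent (or protected) field raises ``ValueError``.
    """
    rates = dict(_DEFAULT_MISSINGNESS) if rates is None else dict(rates)
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    protected = {"outcome", "previously_diagnosed", "id"}
    for fieldname, rate in rates.items():
        if fieldname in protected:
            raise ValueError(f"field {fieldname!r} may not be masked")
        if fieldname not in out.columns:
            raise ValueError(f"missingness rate given for unknown field {fieldname!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {fieldname!r} must be in [0, 1]")
        mask = rng.random(len(out)) < rate
        if mask.any():
            if out[fieldname].dtype.kind in "iu":
                out[fieldname] = out[fieldname].astype(float)
            out.loc[mask, fieldname] = np.nan
    return out
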