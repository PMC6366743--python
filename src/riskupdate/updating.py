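"""Sequential updating of logistic risk models in a validation cohort.

The updating hierarchy, from least to most invasive:

Method 1, intercept adjustment
    Shift the intercept by the prevalence correction factor
    ``logit(observed prevalence) - logit(mean predicted risk)``.
Method 2, logistic calibration
    Maximum-likelihood fit of ``outcome ~ a + b * LP``; the calibration
    intercept ``a`` and slope ``b`` rescale the whole model.
Method 3, revision
    After logistic calibration, each original predictor is screened for a
    deviation from its recalibrated coefficient: the Method-2 fit is held
    fixed as an offset and a free per-term coefficient is likelihood-ratio
    tested.  Significant deviations enter a final joint refit
    ``outcome ~ alpha + beta * LP + sum(gamma_j x_j)``.
Method 4, re-estimation
    Full ML refit of the original predictor set, discarding the published
    coefficients.
Method 5, extension
    As Method 3 but screening *new* candidate predictors; selected terms
    are added to the recalibrated model.

Methods 3-5 (and de novo development) are followed by parameterwise
bootstrap shrinkage: each freely estimated coefficient is multiplied by
a resampling-based calibration factor and the intercept is re-estimated
by ML so the training expected/observed ratio returns to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .registry import (
    PredictorSpec,
    RiskModel,
    design_matrix,
    encode_terms,
    linear_predictor,
)

__all__ = [
    "FitError",
    "SeparationError",
    "LRTestResult",
    "UpdateResult",
    "CandidateBlock",
    "lr_test",
    "log_likelihood",
    "method1_intercept_adjustment",
    "method2_logistic_calibration",
    "method3_revision",
    "method4_reestimation",
    "method5_extension",
    "parameterwise_shrinkage",
    "develop_model",
    "method5_candidates",
    "development_candidates",
]

#: name of the base-model linear-predictor term in joint refits
LP_TERM = "linear_predictor"

_SEPARATION_BOUND = 15.0  # |coef| beyond this on an indicator term => separation
_MAX_ITER = 100
_TOL = 1e-8


class FitError(RuntimeError):
    """A maximum-likelihood fit failed to converge."""


class SeparationError(FitError):
    """(Quasi-)complete separation detected in a logistic fit."""

    def __init__(self, message: str, terms: Sequence[str] = ()) -> None:
        super().__init__(message)
        self.terms = list(terms)


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio test of nested logistic models."""

    statistic: float
    df: int
    p_value: float


def lr_test(loglik_null: float, loglik_alt: float, df: int) -> LRTestResult:
    """Chi-square likelihood-ratio test; statistic clamped at zero."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if loglik_alt < loglik_null - 1e-6:
        raise ValueError(
            f"alternative log-likelihood {loglik_alt} below null {loglik_null}"
        )
    stat = max(0.0, 2.0 * (loglik_alt - loglik_null))
    return LRTestResult(stat, df, float(stats.chi2.sf(stat, df)))


@dataclass
class _Fit:
    params: np.ndarray
    bse: np.ndarray
    loglik: float
    cov: np.ndarray


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    add_intercept: bool = True,
    term_names: Sequence[str] | None = None,
) -> _Fit:
    """IRLS maximum-likelihood logistic fit (thin wrapper over GLM/Binomial).

    ``X`` holds the free covariate columns (may have zero columns); the
    offset enters the linear predictor with coefficient fixed at 1.
    Raises :class:`SeparationError` when an indicator-term coefficient
    exceeds 15 in magnitude, and :class:`FitError` on non-convergence.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    names = list(term_names) if term_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    if add_intercept:
        Xd = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    else:
        Xd = X
    if Xd.shape[1] == 0:
        eta = offset if offset is not None else np.zeros(len(y))
        return _Fit(np.empty(0), np.empty(0), _bernoulli_loglik(y, eta), np.empty((0, 0)))
    glm = sm.GLM(y, Xd, family=sm.families.Binomial(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = glm.fit(maxiter=_MAX_ITER, tol=_TOL)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise FitError("logistic fit produced non-finite coefficients")
    is_indicator = [
        bool(np.all(np.isin(np.unique(Xd[:, j]), (0.0, 1.0)))) for j in range(Xd.shape[1])
    ]
    bad = [
        names[j]
        for j in range(Xd.shape[1])
        if is_indicator[j] and abs(params[j]) > _SEPARATION_BOUND
    ]
    if bad:
        raise SeparationError(f"separation suspected on terms: {bad}", terms=bad)
    return _Fit(params, np.asarray(res.bse, dtype=float), float(res.llf),
                np.asarray(res.cov_params(), dtype=float))


def log_likelihood(model: RiskModel, data: pd.DataFrame) -> float:
    """Bernoulli log-likelihood of a risk model on an outcome-bearing cohort."""
    y = _outcome(data)
    return _bernoulli_loglik(y, np.asarray(linear_predictor(data, model)))


def _outcome(data: pd.DataFrame) -> np.ndarray:
    y = data["outcome"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values; exclude/impute first")
    return y


@dataclass(frozen=True)
class CandidateBlock:
    """A candidate predictor tested (and selected) as one block.

    Multi-level categorical candidates carry one spec per non-reference
    level and a block likelihood-ratio test with df = number of levels - 1.
    """

    name: str
    specs: tuple[PredictorSpec, ...]

    @property
    def df(self) -> int:
        return len(self.specs)


@dataclass
class UpdateResult:
    """An updated model plus the estimated correction parameters.

    ``final_model`` is always materialized and usable with
    :func:`riskupdate.registry.predict_risk`; the remaining fields are
    populated per method (correction factor for Method 1, calibration
    intercept/slope for Methods 2-3, per-term deviations for Method 3,
    added terms for Method 5, the full refit coefficient map for Method 4
    and the developed model, bootstrap shrinkage factors where applied).
    """

    method: str
    base_model: RiskModel | None
    final_model: RiskModel
    n: int
    correction_factor: float | None = None
    calibration_intercept: float | None = None
    calibration_slope: float | None = None
    deviations: dict[str, float] = field(default_factory=dict)
    added_terms: dict[str, float] = field(default_factory=dict)
    refit_coefficients: dict[str, float] = field(default_factory=dict)
    shrinkage_factors: dict[str, float] = field(default_factory=dict)
    screening: dict[str, LRTestResult] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)
    loglik: float | None = None  # training log-likelihood, pre-shrinkage
    # free (ML-estimated) slope coefficients, the substrate for shrinkage
    free_intercept: float | None = None
    free_coefficients: dict[str, float] = field(default_factory=dict)
    free_specs: dict[str, PredictorSpec] = field(default_factory=dict)
    free_ses: dict[str, float] = field(default_factory=dict)


def _compose_final(result: UpdateResult) -> RiskModel:
    """Materialize ``final_model`` from the method's composition formula."""
    m = result.method
    base = result.base_model
    alpha = result.free_intercept
    free = result.free_coefficients
    if m in ("4", "developed"):
        specs = [result.free_specs[t] for t in free]
        model_name = (base.name + "_refit") if base is not None else "developed"
        return RiskModel(
            name=model_name,
            intercept=float(alpha),
            coefficients={t: float(c) for t, c in free.items()},
            predictors=specs,
            fixed_zero_terms=list(base.fixed_zero_terms) if base else [],
            label=(base.label if base else "Developed model"),
        )
    beta = free[LP_TERM]
    new_coefs = {t: beta * c for t, c in base.coefficients.items()}
    if m == "3":
        for t, g in free.items():
            if t != LP_TERM:
                new_coefs[t] = new_coefs[t] + g
        return base.with_updates(
            intercept=alpha + beta * base.intercept,
            coefficients=new_coefs,
            name=f"{base.name}_m3",
        )
    if m == "5":
        extra_specs = [result.free_specs[t] for t in free if t != LP_TERM]
        extra_coefs = {t: g for t, g in free.items() if t != LP_TERM}
        return base.with_updates(
            intercept=alpha + beta * base.intercept,
            coefficients=new_coefs,
            extra_predictors=extra_specs,
            extra_coefficients=extra_coefs,
            name=f"{base.name}_m5",
        )
    raise ValueError(f"no composition rule for method {m!r}")


def method1_intercept_adjustment(model: RiskModel, data: pd.DataFrame) -> UpdateResult:
    """Prevalence correction factor added to the intercept (Method 1)."""
    y = _outcome(data)
    prev = float(np.mean(y))
    if prev in (0.0, 1.0):
        raise ValueError("observed prevalence is 0 or 1; logit undefined")
    p = expit(np.asarray(linear_predictor(data, model)))
    cf = float(logit(prev) - logit(np.mean(p)))
    final = model.with_updates(intercept=model.intercept + cf, name=f"{model.name}_m1")
    return UpdateResult(
        method="1",
        base_model=model,
        final_model=final,
        n=len(data),
        correction_factor=cf,
        loglik=log_likelihood(final, data),
    )


def method2_logistic_calibration(model: RiskModel, data: pd.DataFrame) -> UpdateResult:
    """ML fit of ``outcome ~ a + b * LP`` (Method 2, logistic calibration)."""
    y = _outcome(data)
    lp = np.asarray(linear_predictor(data, model))
    if np.var(lp) == 0:
        raise FitError("linear predictor has zero variance; slope not identifiable")
    fit = fit_logistic(lp[:, None], y, term_names=[LP_TERM])
    a, b = float(fit.params[0]), float(fit.params[1])
    final = model.with_updates(
        intercept=a + b * model.intercept,
        coefficients={t: b * c for t, c in model.coefficients.items()},
        name=f"{model.name}_m2",
    )
    return UpdateResult(
        method="2",
        base_model=model,
        final_model=final,
        n=len(data),
        calibration_intercept=a,
        calibration_slope=b,
        loglik=fit.loglik,
    )


def _screen_offset_terms(
    y: np.ndarray,
    offset: np.ndarray,
    blocks: Sequence[CandidateBlock],
    columns: pd.DataFrame,
    alpha: float,
) -> tuple[dict[str, LRTestResult], list[str], dict[str, str]]:
    """Offset-held LR screening shared by Methods 3 and 5.

    The recalibrated fit (Method 2) stays fixed inside the offset; each
    candidate block gets a free coefficient per column and is tested with
    df = number of columns.
    """
    ll0 = _bernoulli_loglik(y, offset)
    tests: dict[str, LRTestResult] = {}
    selected: list[str] = []
    failures: dict[str, str] = {}
    for block in blocks:
        cols = columns[[s.name for s in block.specs]].to_numpy(dtype=float)
        if np.any(np.ptp(cols, axis=0) == 0):
            failures[block.name] = "constant in data"
            continue
        try:
            fit = fit_logistic(
                cols, y, offset=offset, add_intercept=False,
                term_names=[s.name for s in block.specs],
            )
        except FitError as exc:
            failures[block.name] = str(exc)
            warnings.warn(f"screening fit failed for {block.name!r}: {exc}")
            continue
        res = lr_test(ll0, fit.loglik, df=block.df)
        tests[block.name] = res
        if res.p_value < alpha:
            selected.append(block.name)
    return tests, selected, failures


def method3_revision(
    model: RiskModel,
    data: pd.DataFrame,
    alpha: float = 0.05,
    shrink: bool = True,
    B: int = 200,
    seed: int = 0,
) -> UpdateResult:
    """Model revision (Method 3): per-term deviations after recalibration.

    Each original term is screened with the Method-2 fit held fixed as an
    offset; terms with a significant deviation enter a joint ML refit of
    intercept, calibration slope and the selected deviations, followed by
    parameterwise shrinkage.  With nothing selected the result collapses
    to the Method-2 model.
    """
    m2 = method2_logistic_calibration(model, data)
    y = _outcome(data)
    lp = np.asarray(linear_predictor(data, model))
    offset = m2.calibration_intercept + m2.calibration_slope * lp
    dm = design_matrix(data, model)
    blocks = [
        CandidateBlock(p.name, (p,))
        for p in model.predictors
        if p.rule.get("type") != "fixed_zero"
    ]
    tests, selected, failures = _screen_offset_terms(y, offset, blocks, dm, alpha)

    if not selected:
        return replace(
            m2,
            method="3",
            screening=tests,
            failures=failures,
            final_model=m2.final_model.with_updates(name=f"{model.name}_m3"),
        )

    X = np.column_stack([lp] + [dm[t].to_numpy(dtype=float) for t in selected])
    names = [LP_TERM] + selected
    fit = fit_logistic(X, y, term_names=names)
    spec_by_name = {p.name: p for p in model.predictors}
    result = UpdateResult(
        method="3",
        base_model=model,
        final_model=model,  # recomposed below
        n=len(data),
        calibration_intercept=float(fit.params[0]),
        calibration_slope=float(fit.params[1]),
        deviations={t: float(c) for t, c in zip(selected, fit.params[2:])},
        screening=tests,
        selected=selected,
        failures=failures,
        loglik=fit.loglik,
        free_intercept=float(fit.params[0]),
        free_coefficients={t: float(c) for t, c in zip(names, fit.params[1:])},
        free_specs={t: spec_by_name[t] for t in selected},
        free_ses={t: float(s) for t, s in zip(names, fit.bse[1:])},
    )
    result.final_model = _compose_final(result)
    if shrink:
        result = parameterwise_shrinkage(result, data, B=B, seed=seed)
    return result


def method4_reestimation(
    model: RiskModel,
    data: pd.DataFrame,
    shrink: bool = True,
    B: int = 200,
    seed: int = 0,
) -> UpdateResult:
    """Complete re-estimation of intercept and coefficients (Method 4)."""
    y = _outcome(data)
    dm = design_matrix(data, model)
    X = dm.to_numpy(dtype=float)
    const = [t for t, r in zip(model.terms, np.ptp(X, axis=0)) if r == 0]
    if const:
        raise FitError(f"terms constant in data (collinear with intercept): {const}")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
        raise FitError(f"design matrix for terms {model.terms} is rank deficient")
    fit = fit_logistic(X, y, term_names=model.terms)
    spec_by_name = {p.name: p for p in model.predictors}
    result = UpdateResult(
        method="4",
        base_model=model,
        final_model=model,
        n=len(data),
        refit_coefficients={t: float(c) for t, c in zip(model.terms, fit.params[1:])},
        loglik=fit.loglik,
        free_intercept=float(fit.params[0]),
        free_coefficients={t: float(c) for t, c in zip(model.terms, fit.params[1:])},
        free_specs=spec_by_name,
        free_ses={t: float(s) for t, s in zip(model.terms, fit.bse[1:])},
    )
    result.final_model = _compose_final(result)
    if shrink:
        result = parameterwise_shrinkage(result, data, B=B, seed=seed)
    return result


def method5_extension(
    model: RiskModel,
    data: pd.DataFrame,
    candidates: Sequence[CandidateBlock] | None = None,
    alpha: float = 0.05,
    shrink: bool = True,
    B: int = 200,
    seed: int = 0,
) -> UpdateResult:
    """Extension with new predictors (Method 5), screened as in Method 3."""
    if candidates is None:
        candidates = method5_candidates(model.name)
    existing = set(model.terms)
    for block in candidates:
        clash = [s.name for s in block.specs if s.name in existing]
        if clash:
            raise ValueError(
                f"candidate block {block.name!r} collides with model terms {clash}"
            )
    m2 = method2_logistic_calibration(model, data)
    y = _outcome(data)
    lp = np.asarray(linear_predictor(data, model))
    offset = m2.calibration_intercept + m2.calibration_slope * lp
    cols = encode_terms(data, [s for b in candidates for s in b.specs])
    tests, selected, failures = _screen_offset_terms(y, offset, candidates, cols, alpha)

    if not selected:
        return replace(
            m2,
            method="5",
            screening=tests,
            failures=failures,
            final_model=m2.final_model.with_updates(name=f"{model.name}_m5"),
        )

    by_name = {b.name: b for b in candidates}
    sel_specs = [s for b in selected for s in by_name[b].specs]
    names = [LP_TERM] + [s.name for s in sel_specs]
    X = np.column_stack([lp] + [cols[s.name].to_numpy(dtype=float) for s in sel_specs])
    fit = fit_logistic(X, y, term_names=names)
    result = UpdateResult(
        method="5",
        base_model=model,
        final_model=model,
        n=len(data),
        calibration_intercept=float(fit.params[0]),
        calibration_slope=float(fit.params[1]),
        added_terms={t: float(c) for t, c in zip(names[1:], fit.params[2:])},
        screening=tests,
        selected=selected,
        failures=failures,
        loglik=fit.loglik,
        free_intercept=float(fit.params[0]),
        free_coefficients={t: float(c) for t, c in zip(names, fit.params[1:])},
        free_specs={s.name: s for s in sel_specs},
        free_ses={t: float(s) for t, s in zip(names, fit.bse[1:])},
    )
    result.final_model = _compose_final(result)
    if shrink:
        result = parameterwise_shrinkage(result, data, B=B, seed=seed)
    return result


def _free_design(result: UpdateResult, data: pd.DataFrame) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    spec_list = [result.free_specs[t] for t in result.free_coefficients if t != LP_TERM]
    encoded = encode_terms(data, spec_list) if spec_list else pd.DataFrame(index=data.index)
    for t in result.free_coefficients:
        if t == LP_TERM:
            cols[t] = np.asarray(linear_predictor(data, result.base_model))
        else:
            cols[t] = encoded[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def parameterwise_shrinkage(
    fit: UpdateResult, data: pd.DataFrame, B: int = 200, seed: int = 0
) -> UpdateResult:
    """Bootstrap parameterwise shrinkage of freely estimated coefficients.

    For each of ``B`` bootstrap resamples the free model is refit; the
    original-sample outcome is then regressed (logistic, free intercept)
    on the per-term linear-predictor contributions of the resample fit,
    and the per-term calibration slopes are averaged over resamples to
    give shrinkage factors (clipped to [0, 1.5]).  Coefficients are
    multiplied by their factors and the intercept is re-estimated by ML
    with the shrunk terms as offset, restoring a training E/O of 1.
    """
    if not fit.free_coefficients:
        raise ValueError(f"method {fit.method!r} result has no free coefficients")
    if B < 50:
        warnings.warn(f"B={B} bootstrap replicates is small; factors will be noisy")
    y = _outcome(data)
    Xf = _free_design(fit, data)
    names = list(fit.free_coefficients)
    X = Xf[names].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    slopes: list[np.ndarray] = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            bfit = fit_logistic(X[idx], y[idx], term_names=names)
            b_r = bfit.params[1:]
            if np.any(np.abs(b_r) < 1e-10):
                raise FitError("degenerate resample coefficient")
            contrib = X * b_r  # per-term LP contributions on the original sample
            cal = fit_logistic(contrib, y, term_names=names)
            slopes.append(cal.params[1:])
        except FitError:
            n_failed += 1
    if not slopes:
        raise FitError(f"all {B} shrinkage resamples failed")
    if n_failed:
        warnings.warn(f"{n_failed}/{B} shrinkage resamples failed and were skipped")
    factors = np.clip(np.mean(slopes, axis=0), 0.0, 1.5)
    shrunk = {t: f * c for t, f, c in zip(names, factors, fit.free_coefficients.values())}
    offset = X @ np.array([shrunk[t] for t in names])
    icp = fit_logistic(np.empty((n, 0)), y, offset=offset, term_names=[])
    result = replace(
        fit,
        shrinkage_factors={t: float(f) for t, f in zip(names, factors)},
        free_intercept=float(icp.params[0]),
        free_coefficients=shrunk,
    )
    if result.method == "3":
        result.calibration_intercept = result.free_intercept
        result.calibration_slope = shrunk[LP_TERM]
        result.deviations = {t: c for t, c in shrunk.items() if t != LP_TERM}
    elif result.method == "5":
        result.calibration_intercept = result.free_intercept
        result.calibration_slope = shrunk[LP_TERM]
        result.added_terms = {t: c for t, c in shrunk.items() if t != LP_TERM}
    elif result.method in ("4", "developed"):
        result.refit_coefficients = dict(shrunk)
    result.final_model = _compose_final(result)
    return result


def develop_model(
    data: pd.DataFrame,
    candidates: Sequence[CandidateBlock] | None = None,
    alpha: float = 0.05,
    shrink: bool = True,
    B: int = 200,
    seed: int = 0,
) -> UpdateResult:
    """De novo development: backward stepwise selection plus shrinkage.

    Starts from the full candidate model and repeatedly removes the block
    with the largest likelihood-ratio p-value >= ``alpha`` (ties broken
    toward the smaller maximum |coefficient/SE|) until every remaining
    block is significant.  If nothing survives, an intercept-only model
    is returned with a warning.
    """
    if candidates is None:
        candidates = development_candidates()
    y = _outcome(data)
    all_specs = [s for b in candidates for s in b.specs]
    cols = encode_terms(data, all_specs)
    failures: dict[str, str] = {}
    blocks = []
    for b in candidates:
        sub = cols[[s.name for s in b.specs]].to_numpy(dtype=float)
        if np.any(np.ptp(sub, axis=0) == 0):
            failures[b.name] = "constant in data"
        else:
            blocks.append(b)

    def fit_blocks(active: list[CandidateBlock]) -> tuple[_Fit, list[str]]:
        names = [s.name for b in active for s in b.specs]
        X = cols[names].to_numpy(dtype=float) if names else np.empty((len(y), 0))
        return fit_logistic(X, y, term_names=names), names

    current = list(blocks)
    while current:
        try:
            full_fit, names = fit_blocks(current)
        except SeparationError as exc:
            # drop the offending blocks (too sparse to fit) and carry on
            owners = [b for b in current
                      if any(s.name in exc.terms for s in b.specs)]
            if not owners:
                raise
            for b in owners:
                failures[b.name] = f"separation in full model: {exc}"
                current.remove(b)
            continue
        drop_stats = []
        for j, b in enumerate(current):
            reduced = current[:j] + current[j + 1 :]
            try:
                red_fit, _ = fit_blocks(reduced)
            except FitError as exc:
                failures[b.name] = f"reduced fit failed: {exc}"
                continue
            p = lr_test(red_fit.loglik, full_fit.loglik, df=b.df).p_value
            idx = [names.index(s.name) for s in b.specs]
            zmax = max(
                abs(full_fit.params[1 + i] / full_fit.bse[1 + i]) if full_fit.bse[1 + i] > 0 else np.inf
                for i in idx
            )
            drop_stats.append((p, -zmax, j))
        if not drop_stats:
            break
        p_worst, _, j_worst = max(drop_stats)
        if p_worst < alpha:
            break
        current.pop(j_worst)

    if not current:
        warnings.warn("no candidate survived backward selection; intercept-only model")
        # ML intercept-only fit: the intercept is the logit of the event rate
        icp = fit_logistic(np.empty((len(y), 0)), y, term_names=[])
        final = RiskModel(
            name="developed",
            intercept=float(icp.params[0]),
            coefficients={},
            predictors=[],
            label="Developed model",
        )
        return UpdateResult(
            method="developed",
            base_model=None,
            final_model=final,
            n=len(y),
            loglik=icp.loglik,
            free_intercept=final.intercept,
            failures=failures,
        )

    fit, names = fit_blocks(current)
    spec_by_name = {s.name: s for b in current for s in b.specs}
    result = UpdateResult(
        method="developed",
        base_model=None,
        final_model=None,  # type: ignore[arg-type]  (recomposed below)
        n=len(y),
        refit_coefficients={t: float(c) for t, c in zip(names, fit.params[1:])},
        selected=[b.name for b in current],
        failures=failures,
        loglik=fit.loglik,
        free_intercept=float(fit.params[0]),
        free_coefficients={t: float(c) for t, c in zip(names, fit.params[1:])},
        free_specs=spec_by_name,
        free_ses={t: float(s) for t, s in zip(names, fit.bse[1:])},
    )
    result.final_model = _compose_final(result)
    if shrink and names:
        result = parameterwise_shrinkage(result, data, B=B, seed=seed)
    return result


# ---------------------------------------------------------------------------
# Default candidate predictors

def _spec(name: str, kind: str, rule: Mapping, family: str | None = None) -> PredictorSpec:
    return PredictorSpec(name=name, kind=kind, rule=rule, family=family)


def _single(name: str, spec: PredictorSpec) -> CandidateBlock:
    return CandidateBlock(name, (spec,))


def _candidate_pool() -> dict[str, CandidateBlock]:
    return {
        "sex": _single("sex", _spec("male", "derived-binary",
                                    {"type": "equals", "field": "sex", "value": "M"})),
        "age": _single("age", _spec("age", "continuous",
                                    {"type": "linear", "field": "age"})),
        "sbp": _single("sbp", _spec("sbp", "continuous",
                                    {"type": "linear", "field": "sbp"})),
        "dbp": _single("dbp", _spec("dbp", "continuous",
                                    {"type": "linear", "field": "dbp"})),
        "bmi": CandidateBlock("bmi", (
            _spec("bmi_25_to_30", "categorical",
                  {"type": "range", "field": "bmi", "lo": 25.0, "hi": 30.0}, "bmi_band"),
            _spec("bmi_30_plus", "categorical",
                  {"type": "range", "field": "bmi", "lo": 30.0, "hi": None}, "bmi_band"),
        )),
        "waist_cutoff": _single("waist_cutoff", _spec(
            "wc_sex_cutoff", "derived-binary",
            {"type": "sex_range", "field": "waist",
             "male": {"lo": 94.0, "hi": None}, "female": {"lo": 80.0, "hi": None}})),
        "education": CandidateBlock("education", (
            _spec("education_high_school", "categorical",
                  {"type": "equals", "field": "education", "value": "high_school"},
                  "education"),
            _spec("education_university", "categorical",
                  {"type": "equals", "field": "education", "value": "university"},
                  "education"),
        )),
        "antihypertensive": _single("antihypertensive", _spec(
            "antihypertensive_meds", "binary",
            {"type": "flag", "field": "antihypertensive_meds"})),
        "lipid_lowering": _single("lipid_lowering", _spec(
            "lipid_lowering_meds", "binary",
            {"type": "flag", "field": "lipid_lowering_meds"})),
        "corticosteroids": _single("corticosteroids", _spec(
            "corticosteroids", "binary", {"type": "flag", "field": "corticosteroids"})),
        "family_history": CandidateBlock("family_history", (
            _spec("fh_parent_or_sibling", "derived-binary",
                  {"type": "family", "combine": "parent_or_sibling_exclusive"},
                  "family_history"),
            _spec("fh_parent_and_sibling", "derived-binary",
                  {"type": "family", "combine": "parent_and_sibling"},
                  "family_history"),
        )),
        "smoking": CandidateBlock("smoking", (
            _spec("ex_smoker", "categorical",
                  {"type": "equals", "field": "smoking", "value": "ex"}, "smoking"),
            _spec("current_smoker", "categorical",
                  {"type": "equals", "field": "smoking", "value": "current"}, "smoking"),
        )),
        "drinking": CandidateBlock("drinking", (
            _spec("ex_drinker", "categorical",
                  {"type": "equals", "field": "drinking", "value": "ex"}, "drinking"),
            _spec("current_drinker", "categorical",
                  {"type": "equals", "field": "drinking", "value": "current"}, "drinking"),
        )),
    }


#: per-model Method-5 candidate predictors (those not already in the model)
_METHOD5_CANDIDATES = {
    "cambridge": ["sbp", "dbp", "education", "lipid_lowering", "drinking",
                  "waist_cutoff"],
    "kuwaiti": ["sex", "bmi", "sbp", "dbp", "education", "lipid_lowering",
                "corticosteroids", "drinking"],
    "omani": ["sex", "education", "lipid_lowering", "corticosteroids",
              "smoking", "drinking"],
    "rotterdam": ["sbp", "dbp", "education", "lipid_lowering", "corticosteroids",
                  "family_history", "smoking", "drinking", "waist_cutoff"],
    "finnish": ["sex", "sbp", "dbp", "education", "lipid_lowering",
                "corticosteroids", "family_history", "smoking", "drinking"],
}


def method5_candidates(model_name: str) -> list[CandidateBlock]:
    """Default new-predictor candidates offered to each bundled model."""
    pool = _candidate_pool()
    try:
        keys = _METHOD5_CANDIDATES[model_name]
    except KeyError:
        raise KeyError(f"no default Method-5 candidate list for model {model_name!r}")
    return [pool[k] for k in keys]


def development_candidates() -> list[CandidateBlock]:
    """Full candidate pool for de novo backward-stepwise development."""
    pool = _candidate_pool()
    order = ["sex", "age", "bmi", "sbp", "dbp", "waist_cutoff", "education",
             "antihypertensive", "lipid_lowering", "corticosteroids",
             "family_history", "smoking", "drinking"]
    return [pool[k] for k in order]
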