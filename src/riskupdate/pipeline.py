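"""End-to-end study replica: cohort -> preprocessing -> updating -> evaluation.

One experiment run generates (or loads) a cohort, excludes previously
diagnosed participants, imputes, splits two-thirds/one-third, then for
every requested registry model evaluates the original formula on the full
dataset (external validation, "Method 0") and fits Methods 1-5 on the
training set with evaluation on both splits.  A de novo developed model
is fit on the training set as the comparator.  Everything is
deterministic given the configured seeds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import updating
from .cohort import CohortConfig, generate_cohort, inject_missingness
from .performance import PerformanceReport, calibration_curve, evaluate
from .preprocessing import exclude_diagnosed, simple_impute, split_cohort
from .registry import RiskModel, linear_predictor, load_model_registry, predict_risk
from .updating import UpdateResult

__all__ = ["ExperimentConfig", "CellResult", "ReportBundle", "run_experiment",
           "render_tables", "render_calibration_grid"]

_ALL_METHODS = ("0", "1", "2", "3", "4", "5")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    cohort_csv: str | Path | None = None  # overrides the synthetic generator
    models: tuple[str, ...] = ("cambridge", "kuwaiti", "omani", "rotterdam", "finnish")
    methods: tuple[str, ...] = _ALL_METHODS
    develop: bool = True
    alpha: float = 0.05
    split_fraction: float = 2 / 3
    shrinkage_B: int = 200
    split_seed: int = 1
    bootstrap_seed: int = 2
    missingness_seed: int = 3
    inject_missing: bool = True

    def digest(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class CellResult:
    """One model x method cell: fitted update, metrics, retained probabilities."""

    model: str
    method: str
    update: UpdateResult | None = None
    train: PerformanceReport | None = None
    test: PerformanceReport | None = None
    full: PerformanceReport | None = None
    probs: dict[str, np.ndarray] = field(default_factory=dict)
    outcomes: dict[str, np.ndarray] = field(default_factory=dict)
    failure: str | None = None


@dataclass
class ReportBundle:
    """All cells of one experiment plus the data splits and provenance."""

    config: ExperimentConfig
    cells: dict[tuple[str, str], CellResult]
    n_recruited: int
    n_excluded: int
    n_train: int
    n_test: int

    def cell(self, model: str, method: str) -> CellResult:
        return self.cells[(model, method)]


def _score(model: RiskModel, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    probs = predict_risk(np.asarray(linear_predictor(data, model)))
    y = data["outcome"].to_numpy(dtype=float)
    return probs, y


def _evaluate_model(cell: CellResult, model: RiskModel, label: str, data: pd.DataFrame) -> None:
    probs, y = _score(model, data)
    cell.probs[label] = probs
    cell.outcomes[label] = y
    setattr(cell, label if label != "full" else "full", evaluate(probs, y))


def prepare_cohort(config: ExperimentConfig):
    """Generate/load, exclude, impute and split; returns (full, train, test)."""
    if config.cohort_csv is not None:
        raw = pd.read_csv(config.cohort_csv)
    else:
        raw = generate_cohort(config.cohort_config)
        if config.inject_missing:
            raw = inject_missingness(
                raw, config.cohort_config.missingness_rates, seed=config.missingness_seed
            )
    analyzable = exclude_diagnosed(raw)
    imputed = simple_impute(analyzable)
    split = split_cohort(imputed, fraction=config.split_fraction, seed=config.split_seed)
    return raw, imputed, split.train, split.test


def run_experiment(config: ExperimentConfig | None = None) -> ReportBundle:
    """Run the full updating study; per-cell failures are recorded, not fatal."""
    cfg = config if config is not None else ExperimentConfig()
    registry = load_model_registry()
    unknown = [m for m in cfg.models if m not in registry]
    if unknown:
        raise KeyError(f"unknown model name(s) in config: {unknown}")

    raw, full, train, test = prepare_cohort(cfg)
    cells: dict[tuple[str, str], CellResult] = {}

    fitters = {
        "1": lambda m: updating.method1_intercept_adjustment(m, train),
        "2": lambda m: updating.method2_logistic_calibration(m, train),
        "3": lambda m: updating.method3_revision(
            m, train, alpha=cfg.alpha, B=cfg.shrinkage_B, seed=cfg.bootstrap_seed),
        "4": lambda m: updating.method4_reestimation(
            m, train, B=cfg.shrinkage_B, seed=cfg.bootstrap_seed),
        "5": lambda m: updating.method5_extension(
            m, train, alpha=cfg.alpha, B=cfg.shrinkage_B, seed=cfg.bootstrap_seed),
    }

    for name in cfg.models:
        base = registry[name]
        for method in cfg.methods:
            cell = CellResult(model=name, method=method)
            cells[(name, method)] = cell
            try:
                if method == "0":
                    cell.full = None
                    _evaluate_model(cell, base, "full", full)
                    _evaluate_model(cell, base, "train", train)
                    _evaluate_model(cell, base, "test", test)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cell.update = fitters[method](base)
                    _evaluate_model(cell, cell.update.final_model, "train", train)
                    _evaluate_model(cell, cell.update.final_model, "test", test)
            except Exception as exc:  # record and continue with the next cell
                cell.failure = f"{type(exc).__name__}: {exc}"

    if cfg.develop:
        cell = CellResult(model="developed", method="developed")
        cells[("developed", "developed")] = cell
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cell.update = updating.develop_model(
                    train, alpha=cfg.alpha, B=cfg.shrinkage_B, seed=cfg.bootstrap_seed)
            _evaluate_model(cell, cell.update.final_model, "train", train)
            _evaluate_model(cell, cell.update.final_model, "test", test)
        except Exception as exc:
            cell.failure = f"{type(exc).__name__}: {exc}"

    return ReportBundle(
        config=cfg,
        cells=cells,
        n_recruited=len(raw),
        n_excluded=len(raw) - len(full),
        n_train=len(train),
        n_test=len(test),
    )


# ---------------------------------------------------------------------------
# Rendering

def _provenance(cfg: ExperimentConfig) -> str:
    return (
        f"# config_hash={cfg.digest()} cohort_seed={cfg.cohort_config.seed} "
        f"split_seed={cfg.split_seed} bootstrap_seed={cfg.bootstrap_seed} "
        f"missingness_seed={cfg.missingness_seed}"
    )


def _write_csv(frame: pd.DataFrame, path: Path, cfg: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg) + "\n")
        frame.to_csv(fh, index=False)


def render_tables(bundle: ReportBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four analysis tables as CSV; returns the paths.

    ``updating_parameters.csv``: correction factors, calibration
    intercepts/slopes and deviations of Methods 1-3.
    ``coefficients.csv``: full coefficient maps of every materialized model.
    ``performance_methods_0_3.csv`` / ``performance_methods_4_5.csv``:
    the metric grids, one row per model x method x dataset x metric.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config

    param_rows = []
    for (model, method), cell in bundle.cells.items():
        u = cell.update
        if u is None or method not in ("1", "2", "3"):
            continue
        row = {
            "model": model, "method": method,
            "correction_factor": u.correction_factor,
            "calibration_intercept": u.calibration_intercept,
            "calibration_slope": u.calibration_slope,
        }
        for term, dev in u.deviations.items():
            param_rows.append({**row, "deviation_term": term, "deviation": dev})
        if not u.deviations:
            param_rows.append({**row, "deviation_term": None, "deviation": None})
    params = pd.DataFrame(param_rows)

    coef_rows = []
    for (model, method), cell in bundle.cells.items():
        if cell.failure:
            continue
        final = cell.update.final_model if cell.update else None
        if method == "0":
            final = load_model_registry()[model] if model != "developed" else None
        if final is None:
            continue
        coef_rows.append({"model": model, "method": method,
                          "term": "intercept", "coefficient": final.intercept})
        for term, c in final.coefficients.items():
            coef_rows.append({"model": model, "method": method,
                              "term": term, "coefficient": c})
    coefs = pd.DataFrame(coef_rows)

    perf_rows = []
    for (model, method), cell in bundle.cells.items():
        if cell.failure:
            perf_rows.append({"model": model, "method": method, "dataset": None,
                              "metric": "failure", "estimate": None,
                              "ci_low": None, "ci_high": None, "note": cell.failure})
            continue
        for ds in ("full", "train", "test"):
            rep: PerformanceReport | None = getattr(cell, ds)
            if rep is None:
                continue
            perf_rows.extend([
                {"model": model, "method": method, "dataset": ds, "metric": "eo_ratio",
                 "estimate": rep.eo_ratio, "ci_low": rep.eo_ci_low,
                 "ci_high": rep.eo_ci_high, "note": None},
                {"model": model, "method": method, "dataset": ds, "metric": "brier",
                 "estimate": rep.brier, "ci_low": None, "ci_high": None, "note": None},
                {"model": model, "method": method, "dataset": ds, "metric": "yates_slope",
                 "estimate": rep.yates_slope, "ci_low": None, "ci_high": None, "note": None},
                {"model": model, "method": method, "dataset": ds, "metric": "c_statistic",
                 "estimate": rep.c_statistic, "ci_low": rep.c_ci_low,
                 "ci_high": rep.c_ci_high, "note": None},
            ])
    perf = pd.DataFrame(perf_rows)
    early = perf[perf["method"].isin(["0", "1", "2", "3"])]
    late = perf[~perf["method"].isin(["0", "1", "2", "3"])]

    paths = {}
    for name, frame in [
        ("updating_parameters", params),
        ("coefficients", coefs),
        ("performance_methods_0_3", early),
        ("performance_methods_4_5", late),
    ]:
        path = outdir / f"{name}.csv"
        _write_csv(frame, path, cfg)
        paths[name] = path
    return paths


def render_calibration_grid(bundle: ReportBundle, outdir: str | Path,
                            dataset: str = "test", n_bins: int = 10) -> Path:
    """Multi-panel calibration plot: rows = methods, columns = models."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = [m for m in bundle.config.models]
    methods = [m for m in bundle.config.methods]
    if bundle.config.develop:
        models_grid = models + ["developed"]
    else:
        models_grid = models
    fig, axes = plt.subplots(
        len(methods), len(models_grid),
        figsize=(2.6 * len(models_grid), 2.4 * len(methods)),
        squeeze=False,
    )
    for i, method in enumerate(methods):
        for j, model in enumerate(models_grid):
            ax = axes[i][j]
            key = (model, "developed" if model == "developed" else method)
            cell = bundle.cells.get(key)
            ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
            if cell is None or cell.failure or dataset not in cell.probs:
                ax.annotate("n/a", (0.5, 0.5), ha="center")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    curve = calibration_curve(
                        cell.probs[dataset], cell.outcomes[dataset], n_bins=n_bins)
                ax.plot(curve.mean_predicted, curve.observed_rate, "o-", ms=3)
            lim = 0.8
            ax.set_xlim(0, lim)
            ax.set_ylim(0, lim)
            if i == 0:
                ax.set_title(model, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"method {method}\nobserved", fontsize=8)
            if i == len(methods) - 1:
                ax.set_xlabel("predicted", fontsize=8)
    fig.suptitle(f"Calibration ({dataset} set), {_provenance(bundle.config)[2:]}",
                 fontsize=8)
    fig.tight_layout()
    path = outdir / f"calibration_grid_{dataset}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
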