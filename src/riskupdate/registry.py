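"""Declarative registry of published prevalent-diabetes logistic risk models.

Each model is a logistic regression on the log-odds scale,

    logit P(undiagnosed diabetes) = alpha + sum_j beta_j x_j,

where the design terms ``x_j`` (indicators for age/BMI/waist bands,
medication and family-history flags, or continuous fields) are derived
from raw participant fields by small pure rules declared in the bundled
JSON registry.  The five bundled models are the Cambridge, Kuwaiti,
Omani, Rotterdam and simplified Finnish diabetes risk models, with
their originally published intercepts and coefficients.

Derivation-rule vocabulary (the ``rule`` object of each term):

``linear``
    the raw field itself (continuous).
``flag``
    a 0/1 raw field.
``equals``
    indicator that a categorical raw field equals ``value``.
``range``
    indicator for ``lo <= field < hi`` (``hi`` null means no upper bound).
``threshold``
    indicator for ``field > gt`` or ``field >= ge``.
``sex_range``
    a ``range`` whose bounds depend on sex (waist-circumference cutoffs).
``family``
    composites of the four family-history flags; a "parent" is mother or
    father, a "sibling" is sister or brother.  ``parent_or_sibling`` is
    the inclusive union, ``parent_or_sibling_exclusive`` excludes records
    where both a parent and a sibling are affected (those score on the
    ``parent_and_sibling`` term instead), mirroring the mutually
    exclusive family-history categories of the Cambridge score.
``bp_either``
    indicator for SBP >= ``sbp_ge`` and/or DBP >= ``dbp_ge``.
``age_increments``
    count of completed ``step``-year increments at or above ``start``,
    capped at ``cap`` and 0 below ``start`` (the Rotterdam age score).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PredictorSpec",
    "RiskModel",
    "RegistryError",
    "MissingFieldError",
    "load_model_registry",
    "encode_predictors",
    "encode_terms",
    "design_matrix",
    "linear_predictor",
    "predict_risk",
    "save_model_registry",
]


class RegistryError(ValueError):
    """Malformed model-registry document."""


class MissingFieldError(KeyError):
    """A raw field required by a derivation rule is absent or missing."""


#: raw fields each rule type reads, besides those named in the rule itself
_FAMILY_FIELDS = ("mother_diabetes", "father_diabetes", "sister_diabetes", "brother_diabetes")


@dataclass(frozen=True)
class PredictorSpec:
    """One design term: its name, kind, derivation rule and reference level."""

    name: str
    kind: str  # binary | categorical | continuous | derived-binary
    rule: Mapping
    reference: str = ""
    family: str | None = None  # band family for mutually exclusive indicator sets

    def required_fields(self) -> tuple[str, ...]:
        return _rule_fields(self.rule)


@dataclass
class RiskModel:
    """A logistic risk model: intercept, per-term coefficients, term rules."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    predictors: list[PredictorSpec]
    fixed_zero_terms: list[str] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise RegistryError(f"model {self.name!r}: intercept is not finite")
        spec_names = {p.name for p in self.predictors}
        for term, coef in self.coefficients.items():
            if term not in spec_names:
                raise RegistryError(
                    f"model {self.name!r}: coefficient {term!r} has no predictor spec"
                )
            if not math.isfinite(coef):
                raise RegistryError(f"model {self.name!r}: coefficient {term!r} is not finite")
        for p in self.predictors:
            if p.name not in self.coefficients:
                raise RegistryError(
                    f"model {self.name!r}: predictor {p.name!r} has no coefficient"
                )

    @property
    def terms(self) -> list[str]:
        return [p.name for p in self.predictors]

    def required_fields(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.predictors:
            for f in p.required_fields():
                seen.setdefault(f)
        return tuple(seen)

    def with_updates(
        self,
        *,
        intercept: float | None = None,
        coefficients: Mapping[str, float] | None = None,
        extra_predictors: Iterable[PredictorSpec] = (),
        extra_coefficients: Mapping[str, float] | None = None,
        name: str | None = None,
    ) -> "RiskModel":
        """Return a copy with a new intercept/coefficients and optional new terms."""
        new_coefs = dict(self.coefficients)
        if coefficients is not None:
            new_coefs.update(coefficients)
        preds = list(self.predictors) + list(extra_predictors)
        if extra_coefficients:
            new_coefs.update(extra_coefficients)
        return RiskModel(
            name=name if name is not None else self.name,
            intercept=self.intercept if intercept is None else float(intercept),
            coefficients=new_coefs,
            predictors=preds,
            fixed_zero_terms=list(self.fixed_zero_terms),
            label=self.label,
        )


def _rule_fields(rule: Mapping) -> tuple[str, ...]:
    kind = rule.get("type")
    if kind in ("linear", "flag", "equals", "range", "threshold"):
        return (rule["field"],)
    if kind == "sex_range":
        return ("sex", rule["field"])
    if kind == "family":
        combine = rule.get("combine")
        if combine == "sibling":
            return ("sister_diabetes", "brother_diabetes")
        return _FAMILY_FIELDS
    if kind == "bp_either":
        return ("sbp", "dbp")
    if kind == "age_increments":
        return ("age",)
    if kind == "fixed_zero":
        return ()
    raise RegistryError(f"unknown derivation rule type {kind!r}")


def _eval_rule(rule: Mapping, data: pd.DataFrame) -> np.ndarray:
    """Evaluate one derivation rule on a cohort frame -> float array (n,)."""
    kind = rule["type"]
    if kind == "linear":
        return data[rule["field"]].to_numpy(dtype=float)
    if kind == "flag":
        return data[rule["field"]].to_numpy(dtype=float)
    if kind == "equals":
        return (data[rule["field"]] == rule["value"]).to_numpy(dtype=float)
    if kind == "range":
        x = data[rule["field"]].to_numpy(dtype=float)
        lo, hi = rule.get("lo"), rule.get("hi")
        ok = np.ones_like(x, dtype=bool)
        if lo is not None:
            ok &= x >= lo
        if hi is not None:
            ok &= x < hi
        return ok.astype(float)
    if kind == "threshold":
        x = data[rule["field"]].to_numpy(dtype=float)
        if "gt" in rule:
            return (x > rule["gt"]).astype(float)
        return (x >= rule["ge"]).astype(float)
    if kind == "sex_range":
        x = data[rule["field"]].to_numpy(dtype=float)
        male = (data["sex"] == "M").to_numpy()
        out = np.zeros_like(x)
        for is_male, key in ((True, "male"), (False, "female")):
            b = rule[key]
            ok = male == is_male
            sel = ok & (x >= b["lo"]) if b.get("lo") is not None else ok
            if b.get("hi") is not None:
                sel &= x < b["hi"]
            out[sel] = 1.0
        return out
    if kind == "family":
        parent = (
            (data["mother_diabetes"] == 1) | (data["father_diabetes"] == 1)
        ).to_numpy()
        sibling = (
            (data["sister_diabetes"] == 1) | (data["brother_diabetes"] == 1)
        ).to_numpy()
        combine = rule["combine"]
        if combine == "sibling":
            return sibling.astype(float)
        if combine == "parent_and_sibling":
            return (parent & sibling).astype(float)
        if combine == "parent_or_sibling":
            return (parent | sibling).astype(float)
        if combine == "parent_or_sibling_exclusive":
            return ((parent | sibling) & ~(parent & sibling)).astype(float)
        raise RegistryError(f"unknown family combine {combine!r}")
    if kind == "bp_either":
        sbp = data["sbp"].to_numpy(dtype=float)
        dbp = data["dbp"].to_numpy(dtype=float)
        return ((sbp >= rule["sbp_ge"]) | (dbp >= rule["dbp_ge"])).astype(float)
    if kind == "age_increments":
        age = data["age"].to_numpy(dtype=float)
        inc = np.floor((age - rule["start"]) / rule["step"]) + 1.0
        return np.clip(inc, 0.0, float(rule["cap"]))
    if kind == "fixed_zero":
        return np.zeros(len(data))
    raise RegistryError(f"unknown derivation rule type {kind!r}")


def _check_fields(data: pd.DataFrame, fields: Iterable[str]) -> None:
    for f in fields:
        if f not in data.columns:
            raise MissingFieldError(f"required raw field {f!r} is absent")
        col = data[f]
        if col.isna().any():
            raise MissingFieldError(
                f"required raw field {f!r} has missing values; impute first"
            )


def _bundled_registry_path() -> Path:
    return Path(resources.files("riskupdate").joinpath("data/models.json"))  # type: ignore[arg-type]


def load_model_registry(source: str | Path | None = None) -> dict[str, RiskModel]:
    """Load a model registry document (bundled five-model registry by default).

    Parameters
    ----------
    source
        Path to a JSON registry; ``None`` loads the packaged registry with
        the five published models at their original published coefficients.

    Returns
    -------
    dict mapping model name to :class:`RiskModel`, in document order.
    """
    path = _bundled_registry_path() if source is None else Path(source)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RegistryError(f"registry {path} is not valid JSON: {exc}") from exc

    models: dict[str, RiskModel] = {}
    for name, entry in doc.items():
        try:
            preds = []
            coefs = {}
            for t in entry["terms"]:
                preds.append(
                    PredictorSpec(
                        name=t["name"],
                        kind=t.get("kind", "derived-binary"),
                        rule=t["rule"],
                        reference=t.get("reference", ""),
                        family=t.get("family"),
                    )
                )
                coefs[t["name"]] = float(t["coefficient"])
        except KeyError as exc:
            raise RegistryError(f"model {name!r}: missing field {exc}") from exc
        models[name] = RiskModel(
            name=name,
            intercept=float(entry["intercept"]),
            coefficients=coefs,
            predictors=preds,
            fixed_zero_terms=list(entry.get("fixed_zero_terms", [])),
            label=entry.get("label", name),
        )
    return models


def save_model_registry(models: Mapping[str, RiskModel], path: str | Path) -> None:
    """Serialize a registry back to JSON (round-trips bit-for-bit)."""
    doc = {}
    for name, m in models.items():
        doc[name] = {
            "label": m.label,
            "intercept": m.intercept,
            "terms": [
                {
                    "name": p.name,
                    "kind": p.kind,
                    "coefficient": m.coefficients[p.name],
                    "rule": p.rule,
                    "reference": p.reference,
                    **({"family": p.family} if p.family else {}),
                }
                for p in m.predictors
            ],
            "fixed_zero_terms": m.fixed_zero_terms,
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def design_matrix(data: pd.DataFrame, model: RiskModel) -> pd.DataFrame:
    """Encode a cohort frame into the model's design terms (one column per term).

    Fixed-zero terms are not materialized (they contribute nothing).
    Raises :class:`MissingFieldError` if a required raw field is absent or
    still contains missing values.
    """
    _check_fields(data, model.required_fields())
    cols = {p.name: _eval_rule(p.rule, data) for p in model.predictors}
    return pd.DataFrame(cols, index=data.index)


def encode_terms(data: pd.DataFrame, specs: Iterable[PredictorSpec]) -> pd.DataFrame:
    """Encode an arbitrary list of term specs on a cohort frame."""
    specs = list(specs)
    fields: dict[str, None] = {}
    for s in specs:
        for f in s.required_fields():
            fields.setdefault(f)
    _check_fields(data, fields)
    return pd.DataFrame(
        {s.name: _eval_rule(s.rule, data) for s in specs}, index=data.index
    )


def encode_predictors(record: Mapping | pd.Series, model: RiskModel) -> dict[str, float]:
    """Encode a single participant record into the model's feature vector."""
    if isinstance(record, pd.Series):
        frame = record.to_frame().T
    else:
        frame = pd.DataFrame([record])
    dm = design_matrix(frame, model)
    return {k: float(v) for k, v in dm.iloc[0].items()}


def linear_predictor(features, model: RiskModel):
    """Intercept plus coefficient-weighted sum of encoded terms (log-odds).

    ``features`` may be a per-record dict (from :func:`encode_predictors`),
    a design-matrix DataFrame, or a raw cohort DataFrame (encoded on the fly).
    """
    if isinstance(features, Mapping):
        missing = [t for t in model.terms if t not in features]
        if missing:
            raise KeyError(f"feature vector missing model terms: {missing}")
        lp = model.intercept + sum(
            model.coefficients[t] * float(features[t]) for t in model.terms
        )
        if not math.isfinite(lp):
            raise ValueError("linear predictor is not finite")
        return lp
    if isinstance(features, pd.DataFrame):
        if not set(model.terms).issubset(features.columns):
            features = design_matrix(features, model)
        beta = np.array([model.coefficients[t] for t in model.terms])
        lp = model.intercept + features[model.terms].to_numpy(dtype=float) @ beta
        if not np.all(np.isfinite(lp)):
            raise ValueError("linear predictor contains non-finite values")
        return lp
    raise TypeError(f"unsupported features type {type(features)!r}")


def predict_risk(lp):
    """Logistic transform 1 / (1 + exp(-lp)); strictly inside (0, 1)."""
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    p = expit(lp)
    eps = np.finfo(float).tiny
    p = np.clip(p, eps, 1.0 - np.finfo(float).epsneg)
    return float(p) if p.ndim == 0 else p
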