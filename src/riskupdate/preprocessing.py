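"""Data preparation mirroring the study flow.

Participants with previously diagnosed diabetes are excluded (they never
underwent the OGTT), remaining missing values are filled by simple
imputation (mean substitution for continuous fields, mode substitution
for binary/categorical fields, fit on the full post-exclusion cohort),
and the cohort is split two-thirds/one-third into an updating (training)
set and an internal-validation (test) set by simple, unstratified random
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BINARY_FIELDS, CATEGORICAL_FIELDS, CONTINUOUS_FIELDS

__all__ = ["SplitCohort", "exclude_diagnosed", "simple_impute", "split_cohort"]

# mode ties are broken toward the reference level, listed first here
_LEVEL_PRIORITY = {
    "sex": ["F", "M"],
    "smoking": ["never", "ex", "current"],
    "drinking": ["never", "ex", "current"],
    "education": ["primary", "high_school", "university"],
}


@dataclass
class SplitCohort:
    """A disjoint train/test partition of a cohort."""

    train: pd.DataFrame
    test: pd.DataFrame
    fraction: float
    seed: int


def exclude_diagnosed(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop records flagged as previously diagnosed; order preserved."""
    if "previously_diagnosed" not in cohort.columns:
        raise KeyError("cohort has no 'previously_diagnosed' column")
    flag = cohort["previously_diagnosed"]
    if flag.isna().any():
        raise ValueError("'previously_diagnosed' contains missing values")
    return cohort.loc[flag.astype(int) == 0].copy()


def _mode(series: pd.Series, priority: list | None) -> object:
    counts = series.value_counts()
    top = counts.max()
    tied = list(counts[counts == top].index)
    if len(tied) == 1:
        return tied[0]
    if priority is not None:
        for level in priority:
            if level in tied:
                return level
    return sorted(tied, key=str)[0]


def simple_impute(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean (continuous) / mode (binary, categorical) substitution.

    Observed values are left untouched; a field that is entirely missing
    raises ``ValueError`` naming it.  The imputed continuous fields keep
    the observed mean exactly.
    """
    out = cohort.copy()
    for f in out.columns:
        if f in ("outcome", "previously_diagnosed", "id"):
            continue  # never fabricate outcomes or identifiers
        col = out[f]
        n_miss = int(col.isna().sum())
        if n_miss == 0:
            continue
        observed = col.dropna()
        if observed.empty:
            raise ValueError(f"field {f!r} is entirely missing; cannot impute")
        if f in CONTINUOUS_FIELDS:
            fill = float(observed.mean())
        elif f in BINARY_FIELDS:
            fill = _mode(observed, [0, 1])
        else:
            fill = _mode(observed, _LEVEL_PRIORITY.get(f))
        out[f] = col.fillna(fill)
        if f in BINARY_FIELDS:
            out[f] = out[f].astype(int)
    return out


def split_cohort(cohort: pd.DataFrame, fraction: float = 2 / 3, seed: int = 0) -> SplitCohort:
    """Simple random split; ``|train| = round(fraction * n)``; seeded."""
    n = len(cohort)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(round(fraction * n))
    if n < 2 or n_train == 0 or n_train == n:
        raise ValueError(f"degenerate split: n={n}, train size {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return SplitCohort(
        train=cohort.iloc[train_idx].copy(),
        test=cohort.iloc[test_idx].copy(),
        fraction=fraction,
        seed=seed,
    )
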