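"""Record cleaning, factor encoding and data splitting for the
expenditure model.

The influencing-factor model regresses per-admission hospitalization
expenditure on eight encounter factors: length of stay, institution type,
insurance type, surgery, gender, institution level, age and admission
season.  This module turns validated discharge records into a numeric
design matrix:

* records with missing mandatory fields, malformed ICD-10 codes or
  inconsistent setting/stay are excluded up front (neural nets cannot use
  incomplete rows), with a per-reason exclusion report;
* categorical factors are one-hot encoded by default (a tanh network has no
  ordinal semantics); an ordinal scheme is available for ablation;
* continuous columns are z-scored, ``(x - mean)/std`` with the sample
  (n-1) standard deviation;
* the outcome defaults to log expenditure — cost data are right-skewed;
* a 90/10 train/test split with 5-fold cross-validation folds inside the
  training set, all deterministic under a seed.

Standardization statistics for model fitting are computed on the training
rows only and applied unchanged to test rows (see :mod:`ccekit.ann_model`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dimensions import ICD10_PATTERN
from .errors import (
    ConfigError,
    ConstantColumnError,
    EmptyDatasetError,
    UnknownCategoryError,
)
from .synthetic_data import FACTORS, RECORD_COLUMNS

CONTINUOUS_FACTORS = ("length_of_stay", "age")
CATEGORICAL_FACTORS = tuple(f for f in FACTORS if f not in CONTINUOUS_FACTORS)

# Category order fixed so encodings (and therefore weight matrices) are
# stable across runs regardless of which categories appear first.
_ORDINAL_LEVELS = {
    "institution_type": (
        "ambulatory",
        "public_health",
        "basic_medical",
        "tcm_hospital",
        "special_hospital",
        "general_hospital",
    ),
    "institution_level": ("primary", "secondary", "tertiary"),
    "insurance_type": ("self_pay", "rural_cooperative", "urban_resident", "urban_employee"),
    "gender": ("male", "female"),
    "admission_season": ("spring", "summer", "autumn", "winter"),
    "surgery": (0, 1),
}


@dataclass
class ModelMatrix:
    """Encoded design matrix: X (n x p), outcome y, and a total, invertible
    map from encoded column name to source factor."""

    X: np.ndarray
    y: np.ndarray
    feature_map: dict[str, str]
    columns: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint 90/10 train/test indices plus 5 CV folds partitioning the
    training set."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    cv_folds: tuple[np.ndarray, ...]
    seed: int


def exclude_invalid(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records the model cannot use; report counts by reason.

    Reasons: missing_field, bad_icd10, inpatient_zero_stay,
    outpatient_nonzero_stay, negative_amount.  Idempotent.
    """
    report = {
        "missing_field": 0,
        "bad_icd10": 0,
        "inpatient_zero_stay": 0,
        "outpatient_nonzero_stay": 0,
        "negative_amount": 0,
    }
    frame = records.copy()
    mandatory = [c for c in RECORD_COLUMNS if c in frame.columns]
    bad = frame[mandatory].isna().any(axis=1)
    report["missing_field"] = int(bad.sum())
    frame = frame.loc[~bad]

    ok_icd = frame["icd10"].astype(str).str.match(ICD10_PATTERN)
    report["bad_icd10"] = int((~ok_icd).sum())
    frame = frame.loc[ok_icd]

    inp_zero = (frame["setting"] == "inpatient") & (frame["length_of_stay"] < 1)
    report["inpatient_zero_stay"] = int(inp_zero.sum())
    frame = frame.loc[~inp_zero]

    out_stay = (frame["setting"] == "outpatient") & (frame["length_of_stay"] != 0)
    report["outpatient_nonzero_stay"] = int(out_stay.sum())
    frame = frame.loc[~out_stay]

    neg = (frame["curative_income"] < 0) | (frame["length_of_stay"] < 0)
    report["negative_amount"] = int(neg.sum())
    frame = frame.loc[~neg]

    if frame.empty:
        raise EmptyDatasetError("all records excluded during cleaning")
    report = {k: v for k, v in report.items() if v}
    return frame.reset_index(drop=True), report


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 using the sample (n-1) SD."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ConfigError("zscore needs a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConstantColumnError("constant column cannot be standardized")
    return (x - x.mean()) / sd


def encode(
    records: pd.DataFrame,
    scheme: str = "one_hot",
    outcome: str = "log",
    standardize: bool = True,
) -> ModelMatrix:
    """Build the model matrix for the eight factors.

    ``scheme`` is ``one_hot`` (default; k indicator columns per categorical
    factor) or ``ordinal`` (one integer-coded column per factor, exactly 8
    columns).  ``outcome`` is ``log`` (natural log of curative income) or
    ``raw``.  Continuous columns are z-scored when ``standardize`` is true;
    indicator columns are left 0/1.
    """
    if scheme not in ("one_hot", "ordinal"):
        raise ConfigError(f"unknown encoding scheme {scheme!r}")
    if outcome not in ("log", "raw"):
        raise ConfigError(f"unknown outcome transform {outcome!r}")
    for factor in CATEGORICAL_FACTORS:
        levels = set(_ORDINAL_LEVELS[factor])
        seen = set(records[factor].unique())
        unknown = seen - levels
        if unknown:
            raise UnknownCategoryError(
                f"factor {factor!r} has unknown categories {sorted(map(str, unknown))}"
            )

    columns: list[str] = []
    feature_map: dict[str, str] = {}
    parts: list[np.ndarray] = []

    def add_numeric(factor: str, col: np.ndarray) -> None:
        if standardize:
            try:
                col = zscore(col)
            except ConstantColumnError:
                warnings.warn(
                    f"factor {factor!r} is constant in this data and was dropped",
                    stacklevel=3,
                )
                return
        parts.append(col[:, None])
        columns.append(factor)
        feature_map[factor] = factor

    for factor in FACTORS:
        if factor in CONTINUOUS_FACTORS:
            add_numeric(factor, records[factor].to_numpy(dtype=float))
        elif scheme == "ordinal":
            levels = _ORDINAL_LEVELS[factor]
            codes = records[factor].map({v: i for i, v in enumerate(levels)})
            add_numeric(factor, codes.to_numpy(dtype=float))
        else:
            for level in _ORDINAL_LEVELS[factor]:
                name = f"{factor}={level}"
                indicator = (records[factor] == level).to_numpy(dtype=float)
                if indicator.any():  # absent levels contribute no column
                    parts.append(indicator[:, None])
                    columns.append(name)
                    feature_map[name] = factor

    X = np.hstack(parts)
    income = records["curative_income"].to_numpy(dtype=float)
    y = np.log(income) if outcome == "log" else income
    return ModelMatrix(X=X, y=y, feature_map=feature_map, columns=columns)


def make_splits(n: int, seed: int, test_fraction: float = 0.1, n_folds: int = 5) -> SplitPlan:
    """Deterministic shuffled 90/10 split with ``n_folds`` CV folds over the
    training indices; fold sizes differ by at most 1."""
    if n < 4 * n_folds:
        raise ConfigError(f"n={n} too small for a {n_folds}-fold plan")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = round(test_fraction * n)
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])
    fold_order = rng.permutation(train_idx)
    folds = tuple(np.sort(f) for f in np.array_split(fold_order, n_folds))
    return SplitPlan(train_idx=train_idx, test_idx=test_idx, cv_folds=folds, seed=seed)
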