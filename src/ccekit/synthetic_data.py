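"""Synthetic hospital discharge records, institution ledgers and population
tables.

Real Chinese provincial discharge databases are not publicly deposited, so
this module generates data with the statistical structure the downstream
analysis assumes, with known ground truth for parameter-recovery tests:

* one row per admission, carrying the eight encounter factors used by the
  expenditure model (length of stay, institution type and level, insurance
  type, surgery, gender, age, admission season) plus an ICD-10 code,
  care setting and billed curative income;
* per-admission curative income that is log-normal conditional on the
  factors: for inpatient records
  ``log(income) = intercept + sum_f beta_f * z(x_f) + Normal(0, noise_sd)``
  where ``z(x_f)`` is the standardized encoded factor and ``beta_f`` the
  configured standardized effect size, so right-skew and a configurable
  dominance ordering (length of stay first by default) are built in;
* per-institution "yearbook" ledgers whose totals exceed the sampled income
  by a fixed inflation factor (the non-sampled remainder), against which
  the accounting module apportions;
* an age-group population table (thousands of persons).

Outpatient admissions get length_of_stay 0 and a separate, smaller income
intercept; only inpatient records feed the influencing-factor model
downstream.  An optional interaction term (length_of_stay x institution
type) exercises genuinely non-additive structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dimensions import ICD10_PATTERN
from .errors import ConfigError, FormatError, ValidationError

FACTORS = (
    "length_of_stay",
    "institution_type",
    "insurance_type",
    "surgery",
    "gender",
    "institution_level",
    "age",
    "admission_season",
)

INSTITUTION_TYPES = (
    "general_hospital",
    "tcm_hospital",
    "special_hospital",
    "basic_medical",
    "public_health",
    "ambulatory",
)
INSTITUTION_LEVELS = ("tertiary", "secondary", "primary")
INSURANCE_TYPES = ("urban_employee", "urban_resident", "rural_cooperative", "self_pay")
SEASONS = ("spring", "summer", "autumn", "winter")
SETTINGS = ("outpatient", "inpatient")

RECORD_COLUMNS = (
    "record_id",
    "age",
    "gender",
    "icd10",
    "institution_id",
    "institution_type",
    "institution_level",
    "insurance_type",
    "admission_season",
    "surgery",
    "length_of_stay",
    "setting",
    "curative_income",
    "is_preventive",
)
LEDGER_COLUMNS = ("institution_id", "institution_type", "ST_INC", "ST_ALL", "S_P_ALL")
POPULATION_COLUMNS = ("age_group", "population")

# Standardized contributions to log-income, dominance ordering: length of
# stay first, institution type second, insurance type third.
DEFAULT_EFFECT_SIZES = {
    "length_of_stay": 0.8,
    "institution_type": 0.2,
    "insurance_type": 0.15,
    "surgery": 0.12,
    "gender": 0.11,
    "institution_level": 0.10,
    "age": 0.02,
    "admission_season": 0.03,
}

# Ordinal scores used to turn categorical factors into the latent numeric
# drivers of log-income (standardized before applying effect sizes).
_CATEGORY_SCORES = {
    "institution_type": {
        "general_hospital": 1.0,
        "special_hospital": 0.7,
        "tcm_hospital": 0.6,
        "basic_medical": 0.2,
        "public_health": 0.1,
        "ambulatory": 0.0,
    },
    "institution_level": {"tertiary": 1.0, "secondary": 0.5, "primary": 0.0},
    "insurance_type": {
        "urban_employee": 1.0,
        "urban_resident": 0.6,
        "rural_cooperative": 0.3,
        "self_pay": 0.0,
    },
    "gender": {"male": 0.0, "female": 1.0},
    "admission_season": {"spring": 0.3, "summer": 0.0, "autumn": 0.4, "winter": 0.7},
}

_TYPE_SHARE = {  # sampling weight of each institution type among institutions
    "general_hospital": 0.22,
    "tcm_hospital": 0.08,
    "special_hospital": 0.05,
    "basic_medical": 0.35,
    "public_health": 0.10,
    "ambulatory": 0.20,
}
_TYPE_VOLUME = {  # relative patient volume per institution of each type
    "general_hospital": 30.0,
    "tcm_hospital": 8.0,
    "special_hospital": 4.0,
    "basic_medical": 2.0,
    "public_health": 0.5,
    "ambulatory": 0.5,
}

_NON_GU_CODES = (
    "A15 B18 C34 C61 D12 D50 E11 E44 F03 G20 H25 H65 I10 I21 I63 I64 J18 J44 "
    "K29 K80 L03 M17 M54 O80 P07 Q21 R50 S72 T14 V01 W19 X59 Z51"
).split()
_GU_CODES = "N03 N10 N11 N13 N17 N18 N19 N20 N21 N30 N39 N40 N41 N70 N81".split()

_LOG_INCOME_INTERCEPT_IN = 9.0  # exp(9.0) ~ 8100 RMB per hospitalization
_LOG_INCOME_INTERCEPT_OUT = 5.7  # exp(5.7) ~ 300 RMB per outpatient visit
_LEDGER_INFLATION = 1.25  # yearbook ST_INC / sampled income
_ALLOWANCE_RATE = 0.12  # ST_ALL as a share of ST_INC
_PREVENTIVE_ALLOWANCE_SHARE = 0.2  # S_P_ALL as a share of ST_ALL

# 2014 Liaoning resident population by age band, thousands.
DEFAULT_POPULATION = {"0-14": 4469.10, "15-64": 32837.40, ">=65": 5135.50}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the discharge-record simulation.

    ``effect_sizes`` maps each of the eight model factors to its
    standardized contribution to log income; ``noise_sd`` is the residual
    SD on the log scale.  Fractions select the subpopulation mix.
    """

    n_records: int = 1_377_681
    n_institutions: int = 252
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    noise_sd: float = 0.5
    genitourinary_fraction: float = 0.035
    elderly_fraction: float = 0.25
    preventive_fraction: float = 0.02
    outpatient_fraction: float = 0.35
    interaction: float = 0.0  # optional length_of_stay x institution_type term
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_records, (int, np.integer)) or self.n_records < 1:
            raise ConfigError(f"n_records must be a positive integer, got {self.n_records!r}")
        if not isinstance(self.n_institutions, (int, np.integer)) or self.n_institutions < 1:
            raise ConfigError(
                f"n_institutions must be a positive integer, got {self.n_institutions!r}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be nonnegative, got {self.noise_sd!r}")
        for name in (
            "genitourinary_fraction",
            "elderly_fraction",
            "preventive_fraction",
            "outpatient_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        if set(self.effect_sizes) != set(FACTORS):
            raise ConfigError(
                "effect_sizes keys must be exactly the eight model factors "
                f"{sorted(FACTORS)}, got {sorted(self.effect_sizes)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__},
                fh,
                sort_keys=False,
            )


def cohort_config(n_records: int = 5993, seed: int = 0, **overrides) -> SimulationConfig:
    """Preset for the modelled cohort: genitourinary hospitalizations of
    patients aged 65 and over (default size mirrors a provincial study
    population of 5993 such admissions)."""
    base = dict(
        n_records=n_records,
        n_institutions=40,
        genitourinary_fraction=1.0,
        elderly_fraction=1.0,
        outpatient_fraction=0.0,
        preventive_fraction=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _standardize(values: np.ndarray) -> np.ndarray:
    """Population z-score; all-zero when the input is constant."""
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def _score(factor: str, labels: np.ndarray) -> np.ndarray:
    mapping = _CATEGORY_SCORES[factor]
    return np.vectorize(mapping.__getitem__, otypes=[float])(labels)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(records, ledgers, population)`` under ``config``.

    Same config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    m = config.n_institutions

    inst_ids = np.array([f"H{i:04d}" for i in range(m)])
    type_names = np.array(list(_TYPE_SHARE))
    inst_types = rng.choice(type_names, size=m, p=list(_TYPE_SHARE.values()))
    # at least one general hospital so large-volume strata always exist
    inst_types[0] = "general_hospital"
    level_of = np.empty(m, dtype=object)
    for i, t in enumerate(inst_types):
        if t in ("general_hospital", "tcm_hospital", "special_hospital"):
            level_of[i] = rng.choice(["tertiary", "secondary"], p=[0.4, 0.6])
        else:
            level_of[i] = "primary"

    volume = np.array([_TYPE_VOLUME[t] for t in inst_types])
    volume = volume * rng.uniform(0.6, 1.4, size=m)
    inst_idx = rng.choice(m, size=n, p=volume / volume.sum())

    elderly = rng.random(n) < config.elderly_fraction
    age = np.where(
        elderly,
        65 + np.minimum(rng.exponential(8.0, size=n).astype(int), 35),
        np.where(
            rng.random(n) < 0.12,
            rng.integers(0, 15, size=n),
            rng.integers(15, 65, size=n),
        ),
    )
    gender = np.where(rng.random(n) < 0.5, "male", "female")
    gu = rng.random(n) < config.genitourinary_fraction
    icd10 = np.where(
        gu,
        rng.choice(_GU_CODES, size=n),
        rng.choice(_NON_GU_CODES, size=n),
    )
    insurance = rng.choice(INSURANCE_TYPES, size=n, p=[0.35, 0.30, 0.25, 0.10])
    season = rng.choice(SEASONS, size=n, p=[0.24, 0.22, 0.24, 0.30])
    outpatient = rng.random(n) < config.outpatient_fraction
    # ambulatory facilities provide no beds
    if config.outpatient_fraction > 0:
        outpatient |= inst_types[inst_idx] == "ambulatory"
    setting = np.where(outpatient, "outpatient", "inpatient")
    los = np.where(outpatient, 0, 1 + rng.negative_binomial(3, 0.25, size=n))
    surgery = np.where(
        outpatient, rng.random(n) < 0.02, rng.random(n) < 0.35
    ).astype(int)
    preventive = (rng.random(n) < config.preventive_fraction).astype(int)

    inpatient = ~outpatient
    log_income = np.full(n, _LOG_INCOME_INTERCEPT_OUT)
    if inpatient.any():
        z = {}
        z["length_of_stay"] = _standardize(los[inpatient].astype(float))
        z["age"] = _standardize(age[inpatient].astype(float))
        z["surgery"] = _standardize(surgery[inpatient].astype(float))
        for factor in ("institution_type", "institution_level", "insurance_type",
                       "gender", "admission_season"):
            source = {
                "institution_type": inst_types[inst_idx][inpatient],
                "institution_level": level_of[inst_idx][inpatient],
                "insurance_type": insurance[inpatient],
                "gender": gender[inpatient],
                "admission_season": season[inpatient],
            }[factor]
            z[factor] = _standardize(_score(factor, source))
        linpred = _LOG_INCOME_INTERCEPT_IN + sum(
            config.effect_sizes[f] * z[f] for f in FACTORS
        )
        if config.interaction:
            linpred = linpred + config.interaction * z["length_of_stay"] * z[
                "institution_type"
            ]
        log_income_in = linpred + (
            rng.normal(0.0, config.noise_sd, size=int(inpatient.sum()))
            if config.noise_sd > 0
            else 0.0
        )
        log_income[inpatient] = log_income_in
    if outpatient.any() and config.noise_sd > 0:
        log_income[outpatient] = log_income[outpatient] + rng.normal(
            0.0, config.noise_sd, size=int(outpatient.sum())
        )
    income = np.exp(log_income)

    records = pd.DataFrame(
        {
            "record_id": [f"R{i:07d}" for i in range(n)],
            "age": age.astype(int),
            "gender": gender,
            "icd10": icd10,
            "institution_id": inst_ids[inst_idx],
            "institution_type": inst_types[inst_idx],
            "institution_level": level_of[inst_idx].astype(str),
            "insurance_type": insurance,
            "admission_season": season,
            "surgery": surgery,
            "length_of_stay": los.astype(int),
            "setting": setting,
            "curative_income": income,
            "is_preventive": preventive,
        }
    )

    sampled = records.groupby("institution_id")["curative_income"].sum()
    st_inc = sampled.reindex(inst_ids, fill_value=0.0).to_numpy() * _LEDGER_INFLATION
    st_all = st_inc * _ALLOWANCE_RATE
    ledgers = pd.DataFrame(
        {
            "institution_id": inst_ids,
            "institution_type": inst_types,
            "ST_INC": st_inc,
            "ST_ALL": st_all,
            "S_P_ALL": st_all * _PREVENTIVE_ALLOWANCE_SHARE,
        }
    )

    population = pd.DataFrame(
        {
            "age_group": list(DEFAULT_POPULATION),
            "population": list(DEFAULT_POPULATION.values()),
        }
    )
    return records, ledgers, population


# ---------------------------------------------------------------------------
# Delimited I/O: UTF-8, comma-delimited, header row.

_INT_COLUMNS = ("age", "surgery", "length_of_stay", "is_preventive")


def write_records(records: pd.DataFrame, path) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise FormatError(f"records frame missing columns: {sorted(missing)}")
    records.loc[:, RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read and validate a records CSV; malformed rows raise with their
    1-based data row numbers."""
    frame = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {sorted(missing)}")
    frame = frame.loc[:, list(RECORD_COLUMNS)]
    if frame.empty:
        return frame.astype({c: int for c in _INT_COLUMNS} | {"curative_income": float})

    rows = frame.index + 1
    bad_missing = rows[frame.isna().any(axis=1)]
    if len(bad_missing):
        raise ValidationError(
            f"{path}: rows with missing fields: {list(bad_missing[:20])}"
        )
    bad_icd = rows[~frame["icd10"].astype(str).str.match(ICD10_PATTERN)]
    if len(bad_icd):
        raise ValidationError(
            f"{path}: rows with unparseable ICD-10 codes: {list(bad_icd[:20])}"
        )
    neg = rows[(frame["curative_income"] < 0) | (frame["length_of_stay"] < 0)]
    if len(neg):
        raise ValidationError(f"{path}: rows with negative amounts: {list(neg[:20])}")
    return frame.astype({c: int for c in _INT_COLUMNS} | {"curative_income": float})


def write_ledgers(ledgers: pd.DataFrame, path) -> None:
    missing = set(LEDGER_COLUMNS) - set(ledgers.columns)
    if missing:
        raise FormatError(f"ledgers frame missing columns: {sorted(missing)}")
    ledgers.loc[:, LEDGER_COLUMNS].to_csv(path, index=False)


def read_ledgers(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(LEDGER_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {sorted(missing)}")
    return frame.loc[:, list(LEDGER_COLUMNS)]


def write_population(population: pd.DataFrame, path) -> None:
    population.loc[:, list(POPULATION_COLUMNS)].to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {sorted(missing)}")
    return frame.loc[:, list(POPULATION_COLUMNS)]
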