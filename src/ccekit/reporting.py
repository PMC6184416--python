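"""Dimensional expenditure tables.

Turns per-record CCE allocations into the standard reporting tables of a
provincial expenditure study: shares by GBD broad cause group (both the
share-of-total and the within-group outpatient/inpatient views), by ICD-10
chapter, by institution type, by age band, and the disease-of-interest
(genitourinary) breakdown by age band with per-capita figures.

Conventions: all internal arithmetic at full precision; rounding to two
decimals happens only at serialization.  Each serialized CSV starts with a
``# units: ...`` comment line because published tables mix million- and
billion-RMB units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dimensions import GENITOURINARY_CHAPTER, MappingTable, age_band, icd10_chapter
from .errors import UndefinedMetricError, ValidationError

UNIT_SCALE = {"RMB": 1.0, "million": 1e6, "billion": 1e9}


def proportion_table(expenditures: pd.Series | dict) -> pd.DataFrame:
    """Per-group share of the total, in percent (full precision)."""
    series = pd.Series(expenditures, dtype=float)
    if (series < 0).any():
        raise ValidationError("expenditures must be nonnegative")
    total = series.sum()
    if total == 0:
        raise UndefinedMetricError("all expenditures are zero; proportions undefined")
    return pd.DataFrame(
        {"expenditure": series, "proportion_pct": 100.0 * series / total}
    ).rename_axis("group").reset_index()


def per_capita(expenditure: float, population_thousands: float) -> float:
    """RMB per person from total RMB and population in thousands."""
    if population_thousands <= 0:
        raise ValidationError(f"population must be positive, got {population_thousands}")
    return expenditure / (population_thousands * 1000.0)


def setting_split(
    merged: pd.DataFrame, by: str, cce_col: str = "cce"
) -> pd.DataFrame:
    """Per-group CCE with outpatient/inpatient percentage split.

    ``merged`` needs a ``setting`` label on every row; the returned
    percentages sum to 100 per group, and the CCE-weighted mean of
    outpatient percentages equals the overall outpatient share.
    """
    if merged["setting"].isna().any():
        raise ValidationError("every allocation must be labeled outpatient or inpatient")
    bad = set(merged["setting"].unique()) - {"outpatient", "inpatient"}
    if bad:
        raise ValidationError(f"unknown setting labels: {sorted(bad)}")
    pivot = (
        merged.pivot_table(
            index=by, columns="setting", values=cce_col, aggfunc="sum", fill_value=0.0
        )
        .reindex(columns=["outpatient", "inpatient"], fill_value=0.0)
    )
    total = pivot.sum(axis=1)
    out = pd.DataFrame(
        {
            "cce": total,
            "outpatient_pct": 100.0 * pivot["outpatient"] / total.replace(0, np.nan),
            "inpatient_pct": 100.0 * pivot["inpatient"] / total.replace(0, np.nan),
        }
    )
    return out.rename_axis(by).reset_index()


def weighted_overall_share(table: pd.DataFrame, pct_col: str = "outpatient_pct") -> float:
    """CCE-weighted overall percentage from a :func:`setting_split` table
    (the published tables' "Total" row)."""
    w = table["cce"].to_numpy(dtype=float)
    p = table[pct_col].to_numpy(dtype=float)
    if w.sum() == 0:
        raise UndefinedMetricError("zero total CCE")
    return float(np.nansum(w * p) / w.sum())


def _with_dimensions(
    allocations: pd.DataFrame, records: pd.DataFrame, gbd_table: MappingTable | None
) -> pd.DataFrame:
    merged = allocations.merge(records, on="record_id", validate="1:1")
    table = gbd_table or MappingTable.default()
    codes = merged["icd10"].astype(str)
    unique = codes.unique()
    merged["chapter"] = codes.map({c: icd10_chapter(c) for c in unique})
    merged["gbd"] = codes.map({c: table.lookup(c) for c in unique})
    merged["age_group"] = merged["age"].map(age_band)
    return merged


def gbd_share_tables(merged: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two standard GBD views from one contingency array.

    View 1 (column-normalized): each group's share of total, outpatient and
    inpatient expenditure.  View 2 (row-normalized): within each group, the
    outpatient/inpatient split.  Both in percent.
    """
    contingency = merged.pivot_table(
        index="gbd", columns="setting", values="cce", aggfunc="sum", fill_value=0.0
    ).reindex(columns=["outpatient", "inpatient"], fill_value=0.0)
    total = contingency.sum(axis=1)
    col_norm = pd.DataFrame(
        {
            "total_pct": 100.0 * total / total.sum(),
            "outpatient_pct": 100.0 * contingency["outpatient"] / contingency["outpatient"].sum()
            if contingency["outpatient"].sum()
            else 0.0,
            "inpatient_pct": 100.0 * contingency["inpatient"] / contingency["inpatient"].sum()
            if contingency["inpatient"].sum()
            else 0.0,
        }
    ).rename_axis("gbd").reset_index()
    row_norm = pd.DataFrame(
        {
            "total_pct": 100.0 * total / total.sum(),
            "outpatient_pct": 100.0 * contingency["outpatient"] / total.replace(0, np.nan),
            "inpatient_pct": 100.0 * contingency["inpatient"] / total.replace(0, np.nan),
        }
    ).rename_axis("gbd").reset_index()
    return col_norm, row_norm


def age_table(merged: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Expenditure, share, population and per-capita RMB by age band."""
    pop = population.set_index("age_group")["population"]
    missing = set(merged["age_group"].unique()) - set(pop.index)
    if missing:
        raise ValidationError(f"population table missing age groups: {sorted(missing)}")
    table = proportion_table(merged.groupby("age_group")["cce"].sum()).rename(
        columns={"group": "age_group", "expenditure": "cce"}
    )
    table["population_thousand"] = table["age_group"].map(pop)
    table["per_capita_rmb"] = [
        per_capita(e, p) for e, p in zip(table["cce"], table["population_thousand"])
    ]
    return table


def render_tables(
    allocations: pd.DataFrame,
    records: pd.DataFrame,
    population: pd.DataFrame,
    out_dir,
    units: str = "million",
    gbd_table: MappingTable | None = None,
) -> dict[str, pd.DataFrame]:
    """Emit the full table set as CSV files plus a JSON manifest; returns
    the tables (full precision) keyed by name."""
    if units not in UNIT_SCALE:
        raise ValidationError(f"unknown units {units!r}; choose from {sorted(UNIT_SCALE)}")
    merged = _with_dimensions(allocations, records, gbd_table)
    scale = UNIT_SCALE[units]

    gbd_col, gbd_row = gbd_share_tables(merged)
    institution = setting_split(merged, by="institution_type")
    chapter = proportion_table(merged.groupby("chapter")["cce"].sum()).rename(
        columns={"group": "chapter", "expenditure": "cce"}
    )
    ages = age_table(merged, population)

    gu = merged.loc[merged["chapter"] == GENITOURINARY_CHAPTER]
    if gu.empty:
        import warnings

        warnings.warn("no genitourinary records; emitting empty breakdown", stacklevel=2)
        gu_age = pd.DataFrame(
            columns=["age_group", "cce", "proportion_pct", "population_thousand", "per_capita_rmb"]
        )
    else:
        gu_age = age_table(gu, population)
        # share of each band's ALL-disease expenditure spent on this chapter
        all_by_age = merged.groupby("age_group")["cce"].sum()
        gu_age["proportion_pct"] = (
            100.0 * gu_age["cce"] / gu_age["age_group"].map(all_by_age)
        )

    tables = {
        "gbd_share_of_total": gbd_col,
        "gbd_setting_split": gbd_row,
        "institution_setting_split": institution,
        "chapter_share": chapter,
        "age_groups": ages,
        "genitourinary_by_age": gu_age,
    }

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"units": units, "tables": {}}
    for name, table in tables.items():
        serial = table.copy()
        for col in serial.columns:
            if col in ("cce", "expenditure"):
                serial[col] = serial[col] / scale
            if serial[col].dtype.kind == "f":
                serial[col] = serial[col].round(2)
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            money = "cce" in table.columns or "expenditure" in table.columns
            fh.write(f"# units: {units} RMB\n" if money else "# units: percent\n")
            serial.to_csv(fh, index=False)
        manifest["tables"][name] = path.name
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return tables
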