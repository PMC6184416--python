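"""SHA2011 curative-care-expenditure (CCE) apportionment.

The System of Health Accounts 2011 allocates institution-level financial
totals to individual patients through sharing coefficients computed from
sampled billing records.  For one institution with sampled per-patient
curative income ``a_i`` (total ``a``, of which ``a_p`` belongs to admissions
flagged as preventive services):

* sharing coefficient of patient i:  ``a_i / (a - a_p)``
* allocated curative income:         ``ST_INC * (1 - a_p/a) * a_i/(a - a_p)``
* allocated basic-expenditure
  allowance:                         ``(ST_ALL - S_P_ALL) * a_i/(a - a_p)``
* CCE of patient i:                  income share + allowance share

where ``ST_INC`` and ``ST_ALL`` are the institution's yearbook totals of
curative income and government basic-expenditure allowance, and ``S_P_ALL``
the yearbook preventive-service allowance.  Preventive admissions receive
zero.  The preventive share of ``ST_INC`` is scaled by the sampled
preventive fraction ``a_p/a`` (self-consistent with the coefficient's
denominator); the yearbook states no preventive split of its own.

Summing allocations over any dimension (age band, disease chapter,
institution type, ...) yields the dimensional expenditure tables; the sums
are conservative by construction, which the test suite checks to 1e-6 RMB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInstitutionError,
    LedgerError,
    LookupError_,
    UnknownDimensionError,
)

ALLOCATION_COLUMNS = ("record_id", "allocated_income", "allocated_allowance", "cce")


@dataclass(frozen=True)
class SharingContext:
    """Sampled totals of one institution: ``a`` over all records, ``a_p``
    over preventive ones."""

    a: float
    a_p: float

    def __post_init__(self) -> None:
        if not 0 <= self.a_p <= self.a:
            raise LedgerError(f"need a >= a_p >= 0, got a={self.a}, a_p={self.a_p}")


def sharing_coefficient(a_i: float, a: float, a_p: float) -> float:
    """Per-patient sharing coefficient ``a_i / (a - a_p)``.

    Coefficients over an institution's non-preventive records sum to 1.
    """
    if a_i < 0:
        raise LedgerError(f"a_i must be nonnegative, got {a_i}")
    if a_p < 0:
        raise LedgerError(f"a_p must be nonnegative, got {a_p}")
    if a <= a_p:
        raise DegenerateInstitutionError(
            f"all sampled income is preventive (a={a}, a_p={a_p}); "
            "sharing coefficient undefined"
        )
    return a_i / (a - a_p)


def _context(records: pd.DataFrame) -> SharingContext:
    a = float(records["curative_income"].sum())
    a_p = float(
        records.loc[records["is_preventive"].astype(bool), "curative_income"].sum()
    )
    return SharingContext(a=a, a_p=a_p)


def _ledger_row(ledger: pd.DataFrame | pd.Series, institution_id: str) -> pd.Series:
    if isinstance(ledger, pd.Series):
        row = ledger
    else:
        match = ledger.loc[ledger["institution_id"] == institution_id]
        if match.empty:
            raise LookupError_(f"no ledger entry for institution {institution_id!r}")
        row = match.iloc[0]
    if row["S_P_ALL"] > row["ST_ALL"]:
        raise LedgerError(
            f"institution {institution_id!r}: S_P_ALL ({row['S_P_ALL']}) exceeds "
            f"ST_ALL ({row['ST_ALL']})"
        )
    if row["ST_INC"] < 0 or row["ST_ALL"] < 0 or row["S_P_ALL"] < 0:
        raise LedgerError(f"institution {institution_id!r}: negative ledger totals")
    return row


def _shares(records: pd.DataFrame) -> np.ndarray:
    ctx = _context(records)
    if ctx.a <= ctx.a_p:
        raise DegenerateInstitutionError(
            "all sampled income is preventive; allocation undefined"
        )
    coef = records["curative_income"].to_numpy(dtype=float) / (ctx.a - ctx.a_p)
    coef[records["is_preventive"].astype(bool).to_numpy()] = 0.0
    return coef


def allocate_income(records: pd.DataFrame, ledger) -> pd.Series:
    """Apportion the yearbook curative income ``ST_INC`` (net of its
    preventive share) onto one institution's records."""
    institution_id = records["institution_id"].iloc[0]
    row = _ledger_row(ledger, institution_id)
    ctx = _context(records)
    coef = _shares(records)
    curative_st_inc = float(row["ST_INC"]) * (1.0 - ctx.a_p / ctx.a) if ctx.a else 0.0
    return pd.Series(curative_st_inc * coef, index=records.index, name="allocated_income")


def allocate_allowance(records: pd.DataFrame, ledger) -> pd.Series:
    """Apportion the yearbook basic-expenditure allowance net of its
    preventive part, ``ST_ALL - S_P_ALL``, onto one institution's records."""
    institution_id = records["institution_id"].iloc[0]
    row = _ledger_row(ledger, institution_id)
    coef = _shares(records)
    return pd.Series(
        (float(row["ST_ALL"]) - float(row["S_P_ALL"])) * coef,
        index=records.index,
        name="allocated_allowance",
    )


def allocate_cce(
    records: pd.DataFrame, ledgers: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full apportionment over all institutions.

    Returns ``(allocations, unallocated)``: one allocation row per record
    (``cce = allocated_income + allocated_allowance`` exactly), plus a frame
    of ledger money that could not be attributed because an institution had
    no sampled non-preventive income (its net allowance is reported there
    rather than silently dropped).
    """
    known = set(ledgers["institution_id"])
    unknown = set(records["institution_id"]) - known
    if unknown:
        raise LookupError_(f"records reference unknown institutions: {sorted(unknown)[:10]}")

    pieces = []
    degenerate = []
    for institution_id, group in records.groupby("institution_id", sort=True):
        row = _ledger_row(ledgers, institution_id)
        try:
            income = allocate_income(group, row.rename(None))
        except DegenerateInstitutionError:
            degenerate.append(
                {
                    "institution_id": institution_id,
                    "unallocated_allowance": float(row["ST_ALL"]) - float(row["S_P_ALL"]),
                }
            )
            continue
        allowance = allocate_allowance(group, row)
        pieces.append(
            pd.DataFrame(
                {
                    "record_id": group["record_id"],
                    "allocated_income": income,
                    "allocated_allowance": allowance,
                    "cce": income + allowance,
                }
            )
        )
    # ledgers with no sampled records at all are degenerate too
    for institution_id in sorted(known - set(records["institution_id"])):
        row = _ledger_row(ledgers, institution_id)
        net = float(row["ST_ALL"]) - float(row["S_P_ALL"])
        if net or row["ST_INC"]:
            degenerate.append(
                {"institution_id": institution_id, "unallocated_allowance": net}
            )
    allocations = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=list(ALLOCATION_COLUMNS))
    )
    unallocated = pd.DataFrame(
        degenerate, columns=["institution_id", "unallocated_allowance"]
    )
    return allocations, unallocated


def total_cce(
    allocations: pd.DataFrame, records: pd.DataFrame, by: str | list[str]
) -> pd.DataFrame:
    """Aggregate CCE over a record dimension (any column of ``records``,
    e.g. institution_type, setting, or a derived column such as an age
    band added by the caller)."""
    dims = [by] if isinstance(by, str) else list(by)
    valid = [c for c in records.columns if c != "record_id"]
    bad = [d for d in dims if d not in records.columns]
    if bad:
        raise UnknownDimensionError(
            f"unknown dimension(s) {bad}; valid dimensions: {valid}"
        )
    merged = allocations.merge(records, on="record_id", how="left", validate="1:1")
    out = (
        merged.groupby(dims, sort=True, observed=True)["cce"]
        .sum()
        .reset_index()
        .rename(columns={"cce": "cce"})
    )
    return out
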