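"""Domain records, validation and CSV round-trip for ewe survey data.

The survey design interviews smallholder/pastoralist farmers who each pick,
within every breed group they keep, the Best, Average and Poor quality ewe of
their flock.  Each chosen ewe gets objective measurements (body weight, body
length, heart girth, body condition score, daily milk yield, a hypothetical
purchase price) and up to three ordered free-text reasons for its quality
class.  This module defines the two record types, validates rows against the
design invariants, and reads/writes them as plain CSV.

Validation is *quarantine based*: a malformed row never aborts a load; it is
set aside with a reason string and the run continues.  Every input row ends up
either as a record or as a quarantined row, so counts always add up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

QUALITY_CLASSES = ("Best", "Average", "Poor")
DEFAULT_SITES = ("Amboseli", "Isinya")
DEFAULT_BREEDS = ("Red Maasai", "Dorper", "Cross")

EWE_COLUMNS = (
    "ewe_id", "farmer_id", "site", "breed", "quality",
    "body_weight", "body_length", "heart_girth", "bcs", "milk_yield",
    "price", "age", "coat_colour", "across_breed_rank",
)
EWE_MANDATORY = EWE_COLUMNS[:11]
REASON_COLUMNS = ("ewe_id", "order", "phrase", "trait_group")
REASON_MANDATORY = REASON_COLUMNS[:3]


@dataclass(frozen=True)
class EweRecord:
    """One surveyed ewe.

    Measurements are metric: body_weight in kg, body_length and heart_girth in
    cm, milk_yield in litres/day (0 is a real value: no milk left after the
    lamb suckled), price in KES (integer), bcs on the half-point 1-5 grid.
    ``across_breed_rank`` is kept on its *raw* within-farm scale (1..6 or
    1..9); rescaling to the common 1-9 scale is an explicit, separate step.
    """

    ewe_id: str
    farmer_id: str
    site: str
    breed: str
    quality: str
    body_weight: float
    body_length: float
    heart_girth: float
    bcs: float
    milk_yield: float
    price: int
    age: float | None = None
    coat_colour: str | None = None
    across_breed_rank: int | None = None


@dataclass(frozen=True)
class ReasonRecord:
    """One ordered reason (order 1-3) a farmer gave for an ewe's quality class."""

    ewe_id: str
    order: int
    phrase: str
    trait_group: str | None = None


@dataclass
class ValidationReport:
    """Accounting of a load: accepted + quarantined == rows seen."""

    n_rows: int = 0
    n_accepted: int = 0
    quarantined: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantined)

    def balances(self) -> bool:
        return self.n_rows == self.n_accepted + self.n_quarantined


def _is_half_point(x: float) -> bool:
    return abs(x * 2 - round(x * 2)) < 1e-9


def _validate_ewe_row(row: Mapping, farmer_sites: dict[str, str]) -> str | None:
    """Return a rejection reason, or None if the row is a valid ewe record."""
    for col in ("ewe_id", "farmer_id", "site", "breed"):
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
            return f"missing {col}"
    if row["quality"] not in QUALITY_CLASSES:
        return f"quality {row['quality']!r} not in {QUALITY_CLASSES}"
    for col in ("body_weight", "body_length", "heart_girth"):
        v = row[col]
        if v is None or not math.isfinite(v) or v <= 0:
            return f"{col} must be finite and positive, got {v!r}"
    bcs = row["bcs"]
    if bcs is None or not math.isfinite(bcs) or not (1.0 <= bcs <= 5.0) or not _is_half_point(bcs):
        return f"bcs {bcs!r} not on the half-point grid in [1, 5]"
    milk = row["milk_yield"]
    if milk is None or not math.isfinite(milk) or milk < 0:
        return f"milk_yield must be finite and >= 0, got {milk!r}"
    price = row["price"]
    if price is None or not math.isfinite(price) or price <= 0 or price != int(price):
        return f"price must be a positive integer (KES), got {price!r}"
    age = row.get("age")
    if age is not None and not (isinstance(age, float) and math.isnan(age)):
        if not math.isfinite(age) or not (1.0 <= age <= 9.0):
            return f"age {age!r} outside [1, 9] years"
    rank = row.get("across_breed_rank")
    if rank is not None and not (isinstance(rank, float) and math.isnan(rank)):
        if rank != int(rank) or not (1 <= int(rank) <= 9):
            return f"across_breed_rank {rank!r} not an integer in 1..9"
    fid, site = str(row["farmer_id"]), str(row["site"])
    if farmer_sites.setdefault(fid, site) != site:
        return (f"farmer {fid} already assigned to site {farmer_sites[fid]!r}, "
                f"row says {site!r}")
    return None


def _clean_optional(v, as_int: bool = False):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return int(v) if as_int else v


def load_ewe_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[EweRecord], ValidationReport]:
    """Load ewe records from CSV, quarantining invalid rows.

    ``schema`` maps canonical column names to the file's column names, for
    files using a different header vocabulary.  Missing mandatory columns are
    a hard error; everything row-level is quarantined with a reason.
    """
    df = pd.read_csv(path, dtype={"ewe_id": str, "farmer_id": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in EWE_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory column(s) missing from {path}: {missing}")
    for c in EWE_COLUMNS:
        if c not in df.columns:
            df[c] = None

    report = ValidationReport(n_rows=len(df))
    if len(df) == 0:
        report.warnings.append(f"{path}: empty input (header only)")
        warnings.warn(report.warnings[-1], stacklevel=2)
        return [], report

    records: list[EweRecord] = []
    farmer_sites: dict[str, str] = {}
    seen_cell: dict[tuple[str, str, str], int] = {}
    for i, row in enumerate(df.to_dict("records")):
        reason = _validate_ewe_row(row, farmer_sites)
        if reason is None:
            cell = (str(row["farmer_id"]), str(row["breed"]), str(row["quality"]))
            if cell in seen_cell:
                reason = (f"duplicate quality class {cell[2]!r} for farmer "
                          f"{cell[0]!r} breed {cell[1]!r} (first at row {seen_cell[cell]})")
        if reason is not None:
            report.quarantined.append((i, reason))
            continue
        seen_cell[(str(row["farmer_id"]), str(row["breed"]), str(row["quality"]))] = i
        coat = row.get("coat_colour")
        if isinstance(coat, float) and math.isnan(coat):
            coat = None
        records.append(EweRecord(
            ewe_id=str(row["ewe_id"]), farmer_id=str(row["farmer_id"]),
            site=str(row["site"]), breed=str(row["breed"]), quality=str(row["quality"]),
            body_weight=float(row["body_weight"]), body_length=float(row["body_length"]),
            heart_girth=float(row["heart_girth"]), bcs=float(row["bcs"]),
            milk_yield=float(row["milk_yield"]), price=int(row["price"]),
            age=_clean_optional(row.get("age")),
            coat_colour=coat,
            across_breed_rank=_clean_optional(row.get("across_breed_rank"), as_int=True),
        ))
        report.n_accepted += 1
    return records, report


def load_reason_records(
    path: str | Path,
    ewes: Sequence[EweRecord],
) -> tuple[list[ReasonRecord], ValidationReport]:
    """Load ordered reasons; trait groups stay unset (mapped later).

    A reason row is quarantined if its ewe_id does not resolve, its order is
    not an integer, duplicates an order already seen for that ewe, or exceeds
    order 3 (the analysis uses exactly the top three ordered reasons; later
    reasons are rejected, not silently truncated).
    """
    df = pd.read_csv(path, dtype={"ewe_id": str, "phrase": str})
    missing = [c for c in REASON_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory column(s) missing from {path}: {missing}")

    known = {e.ewe_id for e in ewes}
    report = ValidationReport(n_rows=len(df))
    if len(df) == 0:
        report.warnings.append(f"{path}: empty input (header only)")
        warnings.warn(report.warnings[-1], stacklevel=2)
        return [], report

    records: list[ReasonRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.to_dict("records")):
        eid = str(row["ewe_id"])
        if eid not in known:
            report.quarantined.append((i, f"ewe_id {eid!r} not in ewe table"))
            continue
        order = row["order"]
        try:
            order_i = int(order)
            ok = float(order) == order_i
        except (TypeError, ValueError):
            ok = False
        if not ok or order_i < 1:
            report.quarantined.append((i, f"order {order!r} not a positive integer"))
            continue
        if order_i > 3:
            report.quarantined.append((i, f"order beyond 3 (got {order_i})"))
            continue
        if (eid, order_i) in seen:
            report.quarantined.append((i, f"duplicate order {order_i} for ewe {eid!r}"))
            continue
        phrase = row["phrase"]
        if phrase is None or (isinstance(phrase, float) and math.isnan(phrase)) or str(phrase).strip() == "":
            report.quarantined.append((i, "empty phrase"))
            continue
        seen.add((eid, order_i))
        tg = row.get("trait_group")
        if isinstance(tg, float) and math.isnan(tg):
            tg = None
        records.append(ReasonRecord(ewe_id=eid, order=order_i, phrase=str(phrase),
                                    trait_group=tg))
        report.n_accepted += 1
    return records, report


def records_to_frame(records: Iterable[EweRecord | ReasonRecord]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return pd.DataFrame(columns=list(EWE_COLUMNS))
    cols = [f.name for f in fields(records[0])]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_records(records: Sequence[EweRecord] | Sequence[ReasonRecord],
                  path: str | Path, kind: str | None = None) -> None:
    """Write records as CSV such that loading the file recovers them exactly.

    ``kind`` ("ewe" or "reason") fixes the header for an empty collection,
    where the record type cannot be inferred; it defaults to "ewe".
    """
    path = Path(path)
    if records:
        kind = "reason" if isinstance(records[0], ReasonRecord) else "ewe"
        df = records_to_frame(records)
        if kind == "ewe":
            df["across_breed_rank"] = df["across_breed_rank"].astype("Int64")
    else:
        cols = REASON_COLUMNS if kind == "reason" else EWE_COLUMNS
        df = pd.DataFrame(columns=list(cols))
    df.to_csv(path, index=False)


def ewes_to_frame(records: Sequence[EweRecord]) -> pd.DataFrame:
    """Ewe records as a tidy DataFrame (analysis entry point)."""
    df = records_to_frame(records)
    if df.empty:
        df = pd.DataFrame(columns=list(EWE_COLUMNS))
    return df
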