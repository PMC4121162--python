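"""Domain types and CSV readers/writers shared by all pipeline stages.

The tabular interchange formats are plain CSV:

* ``specimens.csv`` — ``specimen_id,capture_date,sex,maturity,preservation,
  total_weight_g,mantle_weight_g``
* ``counts.csv`` — ``specimen_id,count1,count2,count3,pct_uncountable``
  (optional boolean ``unclear`` column for sections whose increments could
  not be followed at all)
* ``env.csv`` — ``year_month,sst_c,chla_mg_m3``
* ``pairs.csv`` — ``pair_id,treatment,fresh_weight_g,preserved_weight_g``

Readers validate row-by-row: rows that violate a type invariant are excluded
and reported with their (1-based, header-exclusive) row number so a dirty
input never silently contaminates the analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SpecimenRecord",
    "IncrementCounts",
    "AgedSpecimen",
    "EnvMonth",
    "SeasonDefinition",
    "DEFAULT_SEASONS",
    "FormatError",
    "RowError",
    "classify_season",
    "backcalculate_hatch",
    "read_specimens",
    "write_specimens",
    "read_counts",
    "write_counts",
    "read_env",
    "write_env",
    "read_pairs",
    "write_pairs",
]

SEXES = {"female", "male", "unknown"}
MATURITIES = {"immature", "mature", "spent", "unknown"}
PRESERVATIONS = {"fresh", "frozen", "ethanol"}


class FormatError(ValueError):
    """A file-level problem: missing column, unreadable file."""


@dataclass(frozen=True)
class RowError:
    """Diagnostic for one rejected input row."""

    row: int  # 1-based data-row index (header not counted)
    message: str


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected animal with its weights and preservation state.

    ``total_weight`` is the eviscerated total wet weight in grams and may be
    missing (arms are often damaged); ``mantle_weight`` (grams) is the size
    measure the growth analysis uses.
    """

    specimen_id: str
    capture_date: _dt.date
    sex: str
    maturity: str
    preservation: str
    mantle_weight: float
    total_weight: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.maturity not in MATURITIES:
            raise ValueError(
                f"maturity must be one of {sorted(MATURITIES)}, got {self.maturity!r}"
            )
        if self.preservation not in PRESERVATIONS:
            raise ValueError(
                f"preservation must be one of {sorted(PRESERVATIONS)}, "
                f"got {self.preservation!r}"
            )
        if not self.mantle_weight > 0:
            raise ValueError("mantle_weight must be > 0")
        if self.total_weight is not None and self.total_weight < self.mantle_weight:
            raise ValueError("total_weight must be >= mantle_weight when present")
        if not isinstance(self.capture_date, _dt.date):
            raise ValueError("capture_date must be a datetime.date")


@dataclass(frozen=True)
class IncrementCounts:
    """Three stylet increment counts for one specimen.

    Two counts come from the first reader, the third from a second reader;
    ``pct_uncountable`` is the fraction of the section that could not be
    counted. ``unclear`` marks a section whose increments were not clear
    along the section at all.
    """

    specimen_id: str
    counts: tuple[float, float, float]
    pct_uncountable: float
    unclear: bool = False

    def __post_init__(self) -> None:
        if len(self.counts) != 3:
            raise ValueError("exactly three counts are required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.pct_uncountable <= 1.0:
            raise ValueError("pct_uncountable must lie in [0, 1]")


@dataclass(frozen=True)
class AgedSpecimen:
    """A QC-passed specimen with its mean age and back-calculated hatch.

    ``age_days`` is the arithmetic mean of the accepted increment counts
    (daily increment periodicity assumed); ``hatch_date`` is capture date
    minus the age rounded to whole days; ``hatch_season`` is the warm/cool
    class of the hatch month.
    """

    specimen_id: str
    age_days: float
    hatch_date: _dt.date
    hatch_season: str

    def __post_init__(self) -> None:
        if not self.age_days > 0:
            raise ValueError("age_days must be > 0")
        if self.hatch_season not in {"warm", "cool"}:
            raise ValueError("hatch_season must be 'warm' or 'cool'")


@dataclass(frozen=True)
class EnvMonth:
    """Monthly environmental record: SST (deg C) and Chl-a (mg m^-3)."""

    year_month: str  # "YYYY-MM"
    sst: float
    chla: float

    def __post_init__(self) -> None:
        try:
            _dt.datetime.strptime(self.year_month, "%Y-%m")
        except ValueError as exc:
            raise ValueError(f"year_month must be YYYY-MM: {self.year_month!r}") from exc
        if not -2.0 < self.sst < 40.0:
            raise ValueError("sst outside plausible ocean range (-2, 40)")
        if self.chla < 0:
            raise ValueError("chla must be >= 0")


@dataclass(frozen=True)
class SeasonDefinition:
    """Partition of the twelve calendar months into a warm and a cool season."""

    warm_months: frozenset[int] = frozenset({12, 1, 2, 3, 4, 5})
    cool_months: frozenset[int] = frozenset({6, 7, 8, 9, 10, 11})

    def __post_init__(self) -> None:
        if self.warm_months | self.cool_months != frozenset(range(1, 13)):
            raise ValueError("warm and cool months must cover months 1..12")
        if self.warm_months & self.cool_months:
            raise ValueError("warm and cool months must be disjoint")


#: Austral seasons used throughout: December–May warm, June–November cool.
DEFAULT_SEASONS = SeasonDefinition()


def classify_season(month: int, season_def: SeasonDefinition = DEFAULT_SEASONS) -> str:
    """Return ``"warm"`` or ``"cool"`` for a calendar month (1..12)."""
    if not (isinstance(month, int) and 1 <= month <= 12):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    return "warm" if month in season_def.warm_months else "cool"


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def backcalculate_hatch(capture_date: _dt.date, age_days: float) -> _dt.date:
    """Back-calculate the hatch date: capture date minus age in whole days.

    The fractional mean age is rounded half-away-from-zero for the calendar
    arithmetic only; model fitting keeps the unrounded value.
    """
    if not age_days > 0:
        raise ValueError("age_days must be > 0")
    return capture_date - _dt.timedelta(days=_round_half_away(age_days))


# ---------------------------------------------------------------------------
# CSV readers / writers

_SPECIMEN_COLS = [
    "specimen_id",
    "capture_date",
    "sex",
    "maturity",
    "preservation",
    "total_weight_g",
    "mantle_weight_g",
]
_COUNT_COLS = ["specimen_id", "count1", "count2", "count3", "pct_uncountable"]
_ENV_COLS = ["year_month", "sst_c", "chla_mg_m3"]
_PAIR_COLS = ["pair_id", "treatment", "fresh_weight_g", "preserved_weight_g"]


def _load_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_specimens(path: str | Path) -> tuple[list[SpecimenRecord], list[RowError]]:
    """Read a specimens CSV.

    Returns the valid records plus row-indexed diagnostics for every row
    that failed to parse or violated an invariant.
    """
    df = _load_frame(path, _SPECIMEN_COLS)
    records: list[SpecimenRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            tw_raw = getattr(row, "total_weight_g")
            total = float(tw_raw) if tw_raw not in ("", "NA") else None
            records.append(
                SpecimenRecord(
                    specimen_id=str(row.specimen_id),
                    capture_date=_dt.date.fromisoformat(row.capture_date),
                    sex=row.sex,
                    maturity=row.maturity,
                    preservation=row.preservation,
                    mantle_weight=float(row.mantle_weight_g),
                    total_weight=total,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return records, errors


def write_specimens(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "capture_date": r.capture_date.isoformat(),
            "sex": r.sex,
            "maturity": r.maturity,
            "preservation": r.preservation,
            "total_weight_g": "" if r.total_weight is None else repr(r.total_weight),
            "mantle_weight_g": repr(r.mantle_weight),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SPECIMEN_COLS).to_csv(path, index=False)


def read_counts(path: str | Path) -> tuple[list[IncrementCounts], list[RowError]]:
    """Read an increment-count CSV (optional ``unclear`` column)."""
    df = _load_frame(path, _COUNT_COLS)
    has_unclear = "unclear" in df.columns
    out: list[IncrementCounts] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                IncrementCounts(
                    specimen_id=str(row.specimen_id),
                    counts=(float(row.count1), float(row.count2), float(row.count3)),
                    pct_uncountable=float(row.pct_uncountable),
                    unclear=(
                        str(getattr(row, "unclear")).strip().lower()
                        in {"1", "true", "yes"}
                        if has_unclear
                        else False
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return out, errors


def write_counts(counts: Iterable[IncrementCounts], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": c.specimen_id,
            "count1": repr(c.counts[0]),
            "count2": repr(c.counts[1]),
            "count3": repr(c.counts[2]),
            "pct_uncountable": repr(c.pct_uncountable),
            "unclear": str(c.unclear).lower(),
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=_COUNT_COLS + ["unclear"]).to_csv(path, index=False)


def read_env(path: str | Path) -> tuple[list[EnvMonth], list[RowError]]:
    df = _load_frame(path, _ENV_COLS)
    out: list[EnvMonth] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                EnvMonth(
                    year_month=str(row.year_month),
                    sst=float(row.sst_c),
                    chla=float(row.chla_mg_m3),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return out, errors


def write_env(months: Iterable[EnvMonth], path: str | Path) -> None:
    rows = [
        {"year_month": m.year_month, "sst_c": repr(m.sst), "chla_mg_m3": repr(m.chla)}
        for m in months
    ]
    pd.DataFrame(rows, columns=_ENV_COLS).to_csv(path, index=False)


@dataclass(frozen=True)
class WeightPair:
    """One fresh-vs-preserved tissue weight pair from the correction experiment."""

    pair_id: str
    treatment: str  # "frozen" | "ethanol"
    fresh_weight: float
    preserved_weight: float

    def __post_init__(self) -> None:
        if self.treatment not in {"frozen", "ethanol"}:
            raise ValueError("treatment must be 'frozen' or 'ethanol'")
        if self.fresh_weight <= 0 or self.preserved_weight <= 0:
            raise ValueError("weights must be > 0")


def read_pairs(path: str | Path) -> tuple[list[WeightPair], list[RowError]]:
    df = _load_frame(path, _PAIR_COLS)
    out: list[WeightPair] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                WeightPair(
                    pair_id=str(row.pair_id),
                    treatment=row.treatment,
                    fresh_weight=float(row.fresh_weight_g),
                    preserved_weight=float(row.preserved_weight_g),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return out, errors


def write_pairs(pairs: Iterable[WeightPair], path: str | Path) -> None:
    rows = [
        {
            "pair_id": p.pair_id,
            "treatment": p.treatment,
            "fresh_weight_g": repr(p.fresh_weight),
            "preserved_weight_g": repr(p.preserved_weight),
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_PAIR_COLS).to_csv(path, index=False)
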