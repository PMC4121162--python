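"""Increment-count quality control and cohort ageing.

Each stylet section carries three increment counts (two by one reader, one
by a second). A section is discarded when its increments were unreadable,
when more than 10% of the section could not be counted, or when the three
counts disagree by more than 10%; otherwise the accepted age is the
arithmetic mean of the counts, assumed to accumulate one increment per day.
Accepted specimens get a hatch date (capture date minus age) and a
warm/cool hatch season from the hatch month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import (
    AgedSpecimen,
    DEFAULT_SEASONS,
    IncrementCounts,
    SeasonDefinition,
    SpecimenRecord,
    backcalculate_hatch,
    classify_season,
)

__all__ = ["AgeQCResult", "QCReport", "qc_counts", "age_cohort"]

DISCARD_STATUSES = (
    "discard_unclear",
    "discard_uncountable",
    "discard_count_disagreement",
)


@dataclass(frozen=True)
class AgeQCResult:
    """Outcome of the three-count quality control for one specimen."""

    specimen_id: str
    status: str  # accepted | discard_unclear | discard_uncountable | discard_count_disagreement
    discrepancy: float
    mean_age_days: float | None = None


@dataclass
class QCReport:
    """Tally of QC outcomes across a cohort."""

    n_input: int = 0
    n_accepted: int = 0
    discards: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in DISCARD_STATUSES}
    )
    unmatched_specimens: list[str] = field(default_factory=list)

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / self.n_input if self.n_input else 0.0


def qc_counts(
    counts: IncrementCounts,
    max_rel_diff: float = 0.10,
    max_uncountable: float = 0.10,
    denominator: str = "mean",
) -> AgeQCResult:
    """Apply the 10% rules to one specimen's three counts.

    The discrepancy is (max - min) / mean of the three counts by default;
    ``denominator="pairwise_max"`` instead uses the largest pairwise
    relative difference max(|ci - cj|) / max(ci, cj). Gates are applied in
    the order unclear -> uncountable -> disagreement, and the first
    triggered is reported.
    """
    c = counts.counts
    if any(x <= 0 for x in c):
        raise ValueError(f"{counts.specimen_id}: counts must be > 0 for QC")
    mean = sum(c) / 3.0
    if denominator == "mean":
        discrepancy = (max(c) - min(c)) / mean
    elif denominator == "pairwise_max":
        discrepancy = (max(c) - min(c)) / max(c)
    else:
        raise ValueError("denominator must be 'mean' or 'pairwise_max'")
    if counts.unclear:
        return AgeQCResult(counts.specimen_id, "discard_unclear", discrepancy)
    if counts.pct_uncountable > max_uncountable:
        return AgeQCResult(counts.specimen_id, "discard_uncountable", discrepancy)
    if discrepancy > max_rel_diff:
        return AgeQCResult(counts.specimen_id, "discard_count_disagreement", discrepancy)
    return AgeQCResult(counts.specimen_id, "accepted", discrepancy, mean_age_days=mean)


def age_cohort(
    records: Sequence[SpecimenRecord],
    counts: Iterable[IncrementCounts],
    season_def: SeasonDefinition = DEFAULT_SEASONS,
    max_rel_diff: float = 0.10,
    max_uncountable: float = 0.10,
    denominator: str = "mean",
) -> tuple[list[AgedSpecimen], QCReport]:
    """Join counts to specimens, run QC, and attach hatch date and season.

    Specimens with no count row are excluded from the aged set and listed
    in the report; accepted specimens carry the unrounded mean age, the
    hatch date from calendar back-calculation and the warm/cool class of
    the hatch month.
    """
    counts_by_id = {c.specimen_id: c for c in counts}
    report = QCReport(n_input=len(records))
    aged: list[AgedSpecimen] = []
    for rec in records:
        c = counts_by_id.get(rec.specimen_id)
        if c is None:
            report.unmatched_specimens.append(rec.specimen_id)
            continue
        qc = qc_counts(
            c,
            max_rel_diff=max_rel_diff,
            max_uncountable=max_uncountable,
            denominator=denominator,
        )
        if qc.status != "accepted":
            report.discards[qc.status] += 1
            continue
        hatch = backcalculate_hatch(rec.capture_date, qc.mean_age_days)
        aged.append(
            AgedSpecimen(
                specimen_id=rec.specimen_id,
                age_days=qc.mean_age_days,
                hatch_date=hatch,
                hatch_season=classify_season(hatch.month, season_def),
            )
        )
        report.n_accepted += 1
    return aged, report
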