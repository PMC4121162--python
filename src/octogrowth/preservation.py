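"""Fresh-weight correction for frozen and ethanol-preserved specimens.

Freezing and ethanol storage change tissue weight; a paired experiment
(same tissue weighed fresh and again after preservation) decides whether a
correction is needed (paired t-test) and, if so, supplies a Model II linear
map from preserved to fresh-equivalent weight.  Model II regression is used
because both the fresh and the preserved weights carry measurement error;
the standardized major axis (geometric-mean) variant is the default, with
major-axis regression available behind ``method=``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import SpecimenRecord, WeightPair

__all__ = [
    "CorrectionModel",
    "paired_t_test",
    "fit_model2_regression",
    "fit_corrections",
    "apply_correction",
]


@dataclass(frozen=True)
class CorrectionModel:
    """A preserved-to-fresh weight map for one treatment.

    ``applied`` is True only when the paired test found a significant
    fresh-vs-preserved difference at the configured alpha; otherwise the
    map is recorded but weights pass through unchanged.
    """

    treatment: str
    slope: float
    intercept: float
    n_pairs: int
    t_statistic: float
    p_value: float
    applied: bool

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ValueError("a fitted correction needs at least 3 pairs")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def paired_t_test(fresh: Sequence[float], preserved: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on fresh-minus-preserved differences.

    Returns (t, two-sided p). Degenerate cases are resolved before scipy is
    consulted: identical pairs give (0, 1); zero-variance differences with a
    non-zero mean give the limit (±inf, 0).
    """
    f = np.asarray(fresh, dtype=float)
    p = np.asarray(preserved, dtype=float)
    if f.shape != p.shape or f.ndim != 1:
        raise ValueError("fresh and preserved must be 1-D and equal length")
    if len(f) < 2:
        raise ValueError("need at least 2 pairs")
    d = f - p
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    res = stats.ttest_rel(f, p)
    return float(res.statistic), float(res.pvalue)


def fit_model2_regression(
    x: Sequence[float], y: Sequence[float], method: str = "sma"
) -> tuple[float, float]:
    """Model II regression of y on x; returns (slope, intercept).

    ``sma`` (standardized major axis): slope = sign(r) * s_y / s_x, the
    geometric mean of the y-on-x and inverted x-on-y OLS slopes.  ``ma``
    (major axis): slope from the first principal axis of the covariance
    matrix.  Both lines pass through the centroid.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    sx = xa.std(ddof=1)
    sy = ya.std(ddof=1)
    if sx == 0.0:
        raise ValueError("zero variance in x: slope undefined")
    if sy == 0.0:
        raise ValueError("zero variance in y: slope undefined")
    r = float(np.corrcoef(xa, ya)[0, 1])
    if r == 0.0:
        raise ValueError("r = 0: sign of the Model II slope is ambiguous")
    if method == "sma":
        slope = math.copysign(sy / sx, r)
    elif method == "ma":
        cov = float(np.cov(xa, ya)[0, 1])
        d = sy**2 - sx**2
        slope = (d + math.sqrt(d * d + 4 * cov * cov)) / (2 * cov)
    else:
        raise ValueError("method must be 'sma' or 'ma'")
    intercept = float(ya.mean() - slope * xa.mean())
    return float(slope), intercept


def fit_corrections(
    pairs: Iterable[WeightPair], alpha: float = 0.05, method: str = "sma"
) -> dict[str, CorrectionModel]:
    """Fit one CorrectionModel per treatment present in the paired data.

    The preserved weight is the predictor and the fresh weight the response,
    so applying the model converts a recorded preserved weight into a
    fresh-weight equivalent. The correction is armed (``applied=True``) only
    when the paired t-test is significant at ``alpha``.
    """
    by_treatment: dict[str, list[WeightPair]] = {}
    for p in pairs:
        by_treatment.setdefault(p.treatment, []).append(p)
    models: dict[str, CorrectionModel] = {}
    for treatment, group in by_treatment.items():
        fresh = [p.fresh_weight for p in group]
        preserved = [p.preserved_weight for p in group]
        t, pv = paired_t_test(fresh, preserved)
        slope, intercept = fit_model2_regression(preserved, fresh, method=method)
        models[treatment] = CorrectionModel(
            treatment=treatment,
            slope=slope,
            intercept=intercept,
            n_pairs=len(group),
            t_statistic=t,
            p_value=pv,
            applied=pv < alpha,
        )
    return models


def apply_correction(
    records: Sequence[SpecimenRecord], models: dict[str, CorrectionModel]
) -> tuple[list[SpecimenRecord], dict[str, str]]:
    """Convert preserved weights to fresh-equivalents.

    Fresh records pass through untouched. Returns the corrected records and
    a per-specimen provenance flag: ``fresh`` / ``corrected`` /
    ``correction_skipped`` (treatment tested non-significant).
    Raises KeyError if a non-fresh treatment present in the data has no
    fitted model.
    """
    present = {r.preservation for r in records if r.preservation != "fresh"}
    missing = present - set(models)
    if missing:
        raise KeyError(f"no correction model for treatment(s): {sorted(missing)}")
    out: list[SpecimenRecord] = []
    flags: dict[str, str] = {}
    from dataclasses import replace

    for r in records:
        if r.preservation == "fresh":
            out.append(r)
            flags[r.specimen_id] = "fresh"
            continue
        model = models[r.preservation]
        if not model.applied:
            out.append(r)
            flags[r.specimen_id] = "correction_skipped"
            continue
        mw = model.slope * r.mantle_weight + model.intercept
        tw = (
            model.slope * r.total_weight + model.intercept
            if r.total_weight is not None
            else None
        )
        if tw is not None and tw < mw:  # corrected TW may not undercut MW
            tw = mw
        out.append(replace(r, mantle_weight=mw, total_weight=tw))
        flags[r.specimen_id] = "corrected"
    return out, flags
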