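"""Monte-Carlo validation harnesses for the growth-analysis pipeline.

These routines measure, under controlled synthetic conditions, the
statistical behaviour the analysis relies on: bootstrap coverage and bias
of the Gompertz rate coefficient, the type-I error of the ARSS
curve-comparison F-test, the reliability of AIC model selection, and the
discard rate produced by the 10% increment-count quality-control rules.
They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy import stats

from . import synth
from .ageing import age_cohort
from .growth import (
    GrowthParams,
    aic_and_weights,
    bootstrap_ci,
    fit_model,
    predict_mass,
)
from .compare import arss_compare

__all__ = [
    "simulate_size_at_age",
    "parameter_recovery",
    "arss_type1_error",
    "model_selection_rates",
    "qc_discard_fraction",
]

#: Gompertz truth used by the recovery and null-comparison harnesses:
#: the whole-cohort curve (asymptote 171.55 g, shape 9.81, rate 0.0137/day).
RECOVERY_TRUTH = GrowthParams(model="gompertz", m_inf=171.55, gamma=9.81, g1=0.0137)

#: Truth for the model-selection harness: same asymptote and shape but a
#: faster rate so the asymptote is effectively reached inside the observed
#: 85-313 day age window (the regime in which the sigmoid is identifiable).
SELECTION_TRUTH = GrowthParams(model="gompertz", m_inf=171.55, gamma=9.81, g1=0.03)


def simulate_size_at_age(
    params: GrowthParams,
    n: int,
    noise_cv: float,
    rng: np.random.Generator,
    age_range: tuple[float, float] = (85.0, 313.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (age, mantle weight) with multiplicative lognormal noise of the
    given CV around the model curve; ages uniform on ``age_range``."""
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    masses = np.asarray(predict_mass(params, ages), dtype=float)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        masses = masses * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
    return ages, masses


def _recovery_cohort_spec(n: int, noise_cv: float, seed: int) -> synth.CohortSpec:
    """A single-truth, fresh-only cohort for parameter-recovery runs."""
    return synth.CohortSpec(
        n_specimens=n,
        gompertz_true={"warm": RECOVERY_TRUTH, "cool": RECOVERY_TRUTH},
        noise_cv=noise_cv,
        preservation_probs={"fresh": 1.0},
        unclear_prob=0.0,
        seed=seed,
    )


def parameter_recovery(
    n_cohorts: int = 100,
    n: int = 200,
    noise_cv: float = 0.15,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Fit the Gompertz model to repeated synthetic cohorts and measure
    bootstrap-CI coverage and point-estimate bias for the rate g1.

    Each cohort comes from the synthetic generator (all hatch seasons share
    one truth, no preservation shrinkage); the fitted age is the mean of
    the three reader counts, as in the real protocol.
    """
    truth_g1 = RECOVERY_TRUTH.g1
    covered = 0
    estimates = []
    for i in range(n_cohorts):
        tables = synth.generate_cohort(_recovery_cohort_spec(n, noise_cv, seed + i))
        by_id = {r.specimen_id: r for r in tables.specimens}
        ages = np.array([sum(c.counts) / 3.0 for c in tables.counts])
        masses = np.array([by_id[c.specimen_id].mantle_weight for c in tables.counts])
        fit = fit_model(ages, masses, model="gompertz", weighting="irls_fit_sq")
        ci, _ = bootstrap_ci(
            ages,
            masses,
            model="gompertz",
            n_boot=n_boot,
            level=level,
            seed=seed + 7919 * (i + 1),
            point_fit=fit,
        )
        lo, hi = ci["g1"]
        covered += lo <= truth_g1 <= hi
        estimates.append(fit.params.g1)
    estimates = np.asarray(estimates)
    return {
        "n_cohorts": n_cohorts,
        "coverage": covered / n_cohorts,
        "n_covered": covered,
        "mean_g1": float(estimates.mean()),
        "true_g1": truth_g1,
        "relative_bias": float((estimates.mean() - truth_g1) / truth_g1),
    }


def arss_type1_error(
    n_reps: int = 500,
    n_per_group: int = 100,
    noise_cv: float = 0.15,
    alpha: float = 0.05,
    seed: int = 0,
    truth: GrowthParams = RECOVERY_TRUTH,
) -> dict:
    """Empirical size of the ARSS F-test under the null (shared curve).

    Both groups are drawn from one Gompertz truth; returns the rejection
    rate at ``alpha`` and a Kolmogorov-Smirnov p-value for uniformity of
    the null p-values.
    """
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        rng = np.random.default_rng(seed + i)
        g1 = simulate_size_at_age(truth, n_per_group, noise_cv, rng)
        g2 = simulate_size_at_age(truth, n_per_group, noise_cv, rng)
        res = arss_compare({"a": g1, "b": g2}, model="gompertz", weighting="data_sq")
        pvals[i] = res.p_value
    ks = stats.kstest(pvals, "uniform")
    return {
        "n_reps": n_reps,
        "rejection_rate": float(np.mean(pvals < alpha)),
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "p_values": pvals,
    }


def model_selection_rates(
    n_reps: int = 100,
    n: int = 200,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> dict:
    """How often AIC selection behaves as it should on known truths.

    (a) Cohorts from a Gompertz truth whose asymptote is reached inside the
    observed ages: count how often the Gompertz model earns wAIC > 0.9.
    (b) Cohorts from a pure exponential at small ages: count how often
    selection wrongly lands on the linear or power model.
    """
    gompertz_wins = 0
    for i in range(n_reps):
        rng = np.random.default_rng(seed + i)
        a, m = simulate_size_at_age(SELECTION_TRUTH, n, noise_cv, rng)
        fits = aic_and_weights(
            [
                fit_model(a, m, model=k, weighting="data_sq")
                for k in ("gompertz", "exponential", "power", "linear")
            ]
        )
        w = {f.params.model: f.waic for f in fits}
        gompertz_wins += w["gompertz"] > 0.9
    exp_truth = GrowthParams(model="exponential", b0=0.05, c=0.04)
    wrong_simple = 0
    for i in range(n_reps):
        rng = np.random.default_rng(seed + 10_000 + i)
        a, m = simulate_size_at_age(exp_truth, n, noise_cv, rng, age_range=(20.0, 120.0))
        fits = aic_and_weights(
            [
                fit_model(a, m, model=k, weighting="data_sq")
                for k in ("gompertz", "exponential", "power", "linear")
            ]
        )
        best = max(fits, key=lambda f: f.waic).params.model
        wrong_simple += best in ("linear", "power")
    return {
        "n_reps": n_reps,
        "gompertz_waic_gt_0.9_rate": gompertz_wins / n_reps,
        "exponential_truth_picked_linear_or_power_rate": wrong_simple / n_reps,
    }


def qc_discard_fraction(n: int = 10_000, seed: int = 0) -> dict:
    """Discard fraction produced by the 10% QC rules on a default cohort.

    Uses the generator's calibrated reader noise and uncountable-section
    law; the study-scale expectation is a discard fraction near 0.59.
    """
    spec = synth.CohortSpec(n_specimens=n, seed=seed)
    tables = synth.generate_cohort(spec)
    _, report = age_cohort(tables.specimens, tables.counts)
    return {
        "n": n,
        "discard_fraction": report.discard_fraction,
        "discards_by_reason": dict(report.discards),
    }
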