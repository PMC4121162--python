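"""End-to-end orchestration: ingest or synthesize -> correct -> age -> fit
-> select -> compare -> report.

Every stage exchanges plain CSV/JSON artifacts so intermediates are
inspectable and diffable; all randomness is seeded through the config (no
wall-clock seeding), so a config reproduces its report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import ageing, compare, growth, preservation, synth
from .io import (
    DEFAULT_SEASONS,
    SeasonDefinition,
    read_counts,
    read_env,
    read_pairs,
    read_specimens,
    write_counts,
    write_env,
    write_pairs,
    write_specimens,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("octogrowth")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either the four input CSV paths are given, or a synthetic cohort is
    generated from ``synth_spec``. Seeds are explicit so a config fully
    determines its outputs.
    """

    out_dir: Path = Path("out")
    specimens: Path | None = None
    counts: Path | None = None
    env: Path | None = None
    pairs: Path | None = None
    synth_spec: synth.CohortSpec | None = None
    season_def: SeasonDefinition = DEFAULT_SEASONS
    qc_max_rel_diff: float = 0.10
    qc_max_uncountable: float = 0.10
    correction_alpha: float = 0.05
    correction_method: str = "sma"
    models: tuple[str, ...] = ("gompertz", "exponential", "power", "linear")
    weighting: str = "data_sq"
    n_boot: int = 200
    boot_seed: int = 42
    min_group_n: int = 12

    def validate(self) -> None:
        paths = {"specimens": self.specimens, "counts": self.counts, "pairs": self.pairs}
        given = {k: v for k, v in paths.items() if v is not None}
        if self.synth_spec is None:
            missing = [k for k in ("specimens", "counts", "pairs") if paths[k] is None]
            if missing:
                raise ValueError(
                    f"configuration error: no synth spec and missing input(s) {missing}"
                )
            for k, v in given.items():
                if not Path(v).exists():
                    raise ValueError(f"configuration error: {k} file not found: {v}")
        for m in self.models:
            if m not in growth.MODEL_KINDS:
                raise ValueError(f"unknown model kind {m!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(out_dir=Path(raw.get("out_dir", "out")))
    inputs = raw.get("inputs") or {}
    for key in ("specimens", "counts", "env", "pairs"):
        if inputs.get(key):
            setattr(cfg, key, Path(inputs[key]))
    if "synth" in raw and raw["synth"] is not None:
        s = dict(raw["synth"])
        if "gompertz_true" in s:
            s["gompertz_true"] = {
                season: growth.GrowthParams(model="gompertz", **p)
                for season, p in s["gompertz_true"].items()
            }
        if "age_range" in s:
            s["age_range"] = tuple(s["age_range"])
        if "hatch_month_weights" in s:
            s["hatch_month_weights"] = tuple(s["hatch_month_weights"])
        cfg.synth_spec = synth.CohortSpec(**s)
    if "season" in raw and raw["season"]:
        warm = frozenset(raw["season"]["warm_months"])
        cfg.season_def = SeasonDefinition(
            warm_months=warm, cool_months=frozenset(range(1, 13)) - warm
        )
    qc = raw.get("qc") or {}
    cfg.qc_max_rel_diff = qc.get("max_rel_diff", cfg.qc_max_rel_diff)
    cfg.qc_max_uncountable = qc.get("max_uncountable", cfg.qc_max_uncountable)
    corr = raw.get("correction") or {}
    cfg.correction_alpha = corr.get("alpha", cfg.correction_alpha)
    cfg.correction_method = corr.get("method", cfg.correction_method)
    fit = raw.get("fit") or {}
    cfg.models = tuple(fit.get("models", cfg.models))
    cfg.weighting = fit.get("weighting", cfg.weighting)
    boot = raw.get("bootstrap") or {}
    cfg.n_boot = boot.get("n_boot", cfg.n_boot)
    cfg.boot_seed = boot.get("seed", cfg.boot_seed)
    return cfg


def _fit_summary(f: growth.ModelFit) -> dict[str, Any]:
    p = f.params
    out: dict[str, Any] = {
        "model": p.model,
        "n": f.n,
        "k": f.k,
        "rss_weighted": f.rss_weighted,
        "aic": f.aic,
        "waic": f.waic,
        "converged": f.converged,
        "se": f.se,
        "params": {name: getattr(p, name) for name in p.names},
    }
    if p.model == "gompertz":
        out["inflection_weight_g"] = p.inflection_weight
        out["inflection_age_days"] = p.inflection_age
        out["G_at_inflection_per_day"] = p.g1
    if f.bootstrap_ci is not None:
        out["bootstrap_ci"] = f.bootstrap_ci
    return out


def _group_fits(
    ages: np.ndarray, masses: np.ndarray, cfg: PipelineConfig
) -> list[growth.ModelFit]:
    fits = [
        growth.fit_model(ages, masses, model=m, weighting=cfg.weighting)
        for m in cfg.models
    ]
    return growth.aic_and_weights(fits)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run all stages in order and write the report under ``cfg.out_dir``.

    Returns the report dict. On a stage failure the exception names the
    stage; artifacts written so far are moved under ``out/failed``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stages": []}
    stage = "ingest"
    try:
        # -- ingest or synthesize -------------------------------------
        if cfg.synth_spec is not None:
            log.info("[synth] generating cohort n=%d seed=%d", cfg.synth_spec.n_specimens, cfg.synth_spec.seed)
            tables = synth.generate_cohort(cfg.synth_spec)
            specimens, counts, env, pairs = (
                tables.specimens,
                tables.counts,
                tables.env,
                tables.pairs,
            )
            write_specimens(specimens, out / "specimens.csv")
            write_counts(counts, out / "counts.csv")
            write_env(env, out / "env.csv")
            write_pairs(pairs, out / "pairs.csv")
            synth.write_truth(cfg.synth_spec, out / "truth.json")
        else:
            specimens, spec_errs = read_specimens(cfg.specimens)
            counts, count_errs = read_counts(cfg.counts)
            pairs, pair_errs = read_pairs(cfg.pairs)
            env = read_env(cfg.env)[0] if cfg.env else []
            report["ingest_row_errors"] = {
                "specimens": [dataclasses.asdict(e) for e in spec_errs],
                "counts": [dataclasses.asdict(e) for e in count_errs],
                "pairs": [dataclasses.asdict(e) for e in pair_errs],
            }
        report["stages"].append("ingest")
        report["n_specimens"] = len(specimens)

        # -- preservation correction ----------------------------------
        stage = "correct"
        models = preservation.fit_corrections(
            pairs, alpha=cfg.correction_alpha, method=cfg.correction_method
        )
        corrected, flags = preservation.apply_correction(specimens, models)
        report["corrections"] = {
            t: dataclasses.asdict(m) for t, m in models.items()
        }
        report["correction_flags"] = {
            flag: sum(1 for v in flags.values() if v == flag)
            for flag in ("fresh", "corrected", "correction_skipped")
        }
        write_specimens(corrected, out / "corrected.csv")
        report["stages"].append("correct")

        # -- ageing ----------------------------------------------------
        stage = "age"
        aged, qc_report = ageing.age_cohort(
            corrected,
            counts,
            season_def=cfg.season_def,
            max_rel_diff=cfg.qc_max_rel_diff,
            max_uncountable=cfg.qc_max_uncountable,
        )
        report["qc"] = {
            "n_input": qc_report.n_input,
            "n_accepted": qc_report.n_accepted,
            "n_discarded": qc_report.n_discarded,
            "discard_fraction": qc_report.discard_fraction,
            "discards_by_reason": qc_report.discards,
            "n_unmatched": len(qc_report.unmatched_specimens),
        }
        (out / "qc.json").write_text(json.dumps(report["qc"], indent=2))
        report["stages"].append("age")

        # -- fit + select ---------------------------------------------
        stage = "fit"
        by_id = {r.specimen_id: r for r in corrected}
        rows = [
            (a.specimen_id, a.age_days, by_id[a.specimen_id].mantle_weight,
             a.hatch_season, by_id[a.specimen_id].sex)
            for a in aged
        ]
        seasons = sorted({r[3] for r in rows})
        aic_matrix: dict[str, Any] = {}
        season_fits: dict[str, list[growth.ModelFit]] = {}
        for season in seasons:
            grp = [(r[1], r[2]) for r in rows if r[3] == season]
            if len(grp) < cfg.min_group_n:
                continue
            ages = np.array([g[0] for g in grp])
            masses = np.array([g[1] for g in grp])
            fits = _group_fits(ages, masses, cfg)
            season_fits[season] = fits
            aic_matrix[season] = {
                f.params.model: {"aic": f.aic, "waic": f.waic} for f in fits
            }
        if not season_fits and len(rows) < cfg.min_group_n:
            raise ValueError(
                f"only {len(rows)} specimens survived QC; no group reaches "
                f"the minimum of {cfg.min_group_n} for model fitting"
            )
        report["aic_matrix"] = aic_matrix
        report["stages"].append("fit")

        # -- bootstrap the best model per season -----------------------
        stage = "bootstrap"
        summary: dict[str, Any] = {}
        mean_G: dict[str, float] = {}
        for season, fits in season_fits.items():
            best = max(fits, key=lambda f: f.waic)
            grp = [(r[1], r[2]) for r in rows if r[3] == season]
            ages = np.array([g[0] for g in grp])
            masses = np.array([g[1] for g in grp])
            if cfg.n_boot > 0:
                ci, failed = growth.bootstrap_ci(
                    ages,
                    masses,
                    model=best.params.model,
                    n_boot=cfg.n_boot,
                    seed=cfg.boot_seed,
                    weighting=cfg.weighting,
                    point_fit=best,
                )
                best = best.with_(bootstrap_ci=ci)
                summary.setdefault("bootstrap_failures", {})[season] = failed
            s = _fit_summary(best)
            s["age_range_days"] = [float(ages.min()), float(ages.max())]
            if best.params.model == "gompertz":
                g_vals = growth.relative_growth_rate(best.params, ages)
                s["mean_G_per_day"] = float(np.mean(g_vals))
                mean_G[season] = s["mean_G_per_day"]
            summary[season] = s
        # pooled (all seasons) summary of the best common model
        all_ages = np.array([r[1] for r in rows])
        all_masses = np.array([r[2] for r in rows])
        if len(all_ages) >= cfg.min_group_n:
            fits = _group_fits(all_ages, all_masses, cfg)
            best = max(fits, key=lambda f: f.waic)
            s = _fit_summary(best)
            s["age_range_days"] = [float(all_ages.min()), float(all_ages.max())]
            if best.params.model == "gompertz":
                g_vals = growth.relative_growth_rate(best.params, all_ages)
                s["mean_G_per_day"] = float(np.mean(g_vals))
            summary["all"] = s
        report["parameter_summary"] = summary
        report["stages"].append("bootstrap")

        # -- between-group comparisons --------------------------------
        stage = "compare"
        comparisons: dict[str, Any] = {}
        if len(season_fits) >= 2:
            data_by_season = {
                season: (
                    [r[1] for r in rows if r[3] == season],
                    [r[2] for r in rows if r[3] == season],
                )
                for season in season_fits
            }
            res = compare.arss_compare(
                data_by_season, model="gompertz", weighting=cfg.weighting
            )
            comparisons["by_hatch_season"] = dataclasses.asdict(res)
        for season in seasons:
            by_sex = {
                sex: (
                    [r[1] for r in rows if r[3] == season and r[4] == sex],
                    [r[2] for r in rows if r[3] == season and r[4] == sex],
                )
                for sex in ("female", "male")
            }
            if all(len(v[0]) >= cfg.min_group_n for v in by_sex.values()):
                res = compare.arss_compare(
                    by_sex, model="gompertz", weighting=cfg.weighting
                )
                comparisons[f"by_sex_{season}"] = dataclasses.asdict(res)
        report["comparisons"] = comparisons
        report["stages"].append("compare")

        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}, indent=2)
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
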