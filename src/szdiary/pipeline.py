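"""End-to-end pipeline: simulate or load a cohort, then run every
analysis stage and write one reproducible report directory.

Identical configuration and seeds yield a byte-identical ``summary.json``
(floats are serialised via ``repr`` and keys sorted), which is the
determinism contract the tests hash.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .circadian import circadian_profile, day_night_duration_test
from .descriptives import natural_history
from .diary import Cohort, load_cohort, rebase_epoch, write_cohort
from .predict import (
    fit_gp_linear,
    enrollment_report,
    threshold_interval,
    training_pairs,
)
from .semiology import duration_histogram, duration_vs_isi, semiology_summary
from .simulate import SimulatorConfig, simulate_cohort
from .temporal import (
    isi_set,
    lilliefors_exponential,
    pacf_analysis,
    peri_seizure_analysis,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    events_path: str | None = None
    meta_path: str | None = None
    simulator: SimulatorConfig | None = None
    out_dir: str = "szdiary_report"
    seed: int = 0
    T_days: float = 30.0
    n_weeks: int = 4
    isi_bin_h: float = 1.5
    peri_bin_days: float = 1.0
    peri_max_lag_days: float = 7.0
    pacf_max_lag: int = 7
    lilliefors_n_mc: int = 10_000
    target_intervals: list[tuple[float, float]] = field(
        default_factory=lambda: [(20.0, 100.0), (20.0, 200.0)])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulator", None)
        cfg = cls(**raw)
        if sim is not None:
            sim["latency_days_range"] = tuple(
                sim.get("latency_days_range", (3, 7)))
            cfg.simulator = SimulatorConfig(**sim)
        if cfg.target_intervals:
            cfg.target_intervals = [tuple(t) for t in cfg.target_intervals]
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage on one cohort and write the report directory.

    Any stage failure aborts with the stage name; partial outputs written
    so far are preserved for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    summary: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config": _jsonable({
                k: v for k, v in dataclasses.asdict(config).items()
                if k not in ("simulator", "out_dir")
            }),
            "simulator": _jsonable(dataclasses.asdict(config.simulator))
            if config.simulator else None,
        }
    }
    timings: list[str] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                timings.append(f"{name}: FAILED ({exc})")
                log_path.write_text("\n".join(timings) + "\n")
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            timings.append(f"{name}: {time.perf_counter() - t0:.2f} s")
        return deco

    holder: dict = {}

    @stage("input")
    def _input():
        if config.simulator is not None:
            cohort = simulate_cohort(config.simulator)
            write_cohort(cohort, out / "events.csv", out / "meta.csv")
        else:
            if not config.events_path:
                raise FileNotFoundError("no events_path and no simulator")
            cohort = load_cohort(config.events_path, config.meta_path)
        holder["cohort"] = cohort
        summary["n_animals"] = len(cohort)
        summary["n_events"] = cohort.n_events

    @stage("describe")
    def _describe():
        cohort = holder["cohort"]
        nh = natural_history(cohort, config.T_days, config.n_weeks)
        nh.daily_counts.to_csv(out / "daily_counts.csv")
        nh.weekly_pct.to_csv(out / "weekly_pct.csv")
        nh.weekly_box.to_csv(out / "weekly_box.csv", index=False)
        nh.cumulative_pct.to_csv(out / "cumulative_pct.csv")
        nh.duration_medians.to_csv(out / "duration_medians.csv")
        nh.latencies.to_csv(out / "latency.csv")
        summary["induction"] = {
            "n_injected": nh.induction.n_injected,
            "n_with_seizures": nh.induction.n_with_seizures,
            "pct": nh.induction.pct,
        }
        summary["weekly_pct_mean"] = _jsonable(
            nh.weekly_pct.mean(axis=0).to_numpy())

    @stage("semiology")
    def _semiology():
        cohort = holder["cohort"]
        labelled = all(
            e.semiology is not None for d in cohort for e in d)
        if labelled and cohort.n_events:
            table = semiology_summary(cohort)
            table.to_frame().to_csv(out / "semiology.csv", index=False)
            summary["semiology_pct"] = table.percentages
        hist = duration_histogram(cohort)
        hist.to_csv(out / "duration_histogram.csv", index=False)
        dvi = duration_vs_isi(cohort, seed=config.seed)
        summary["duration_vs_isi"] = {
            "spearman_rho": dvi.spearman_rho, "p": dvi.p_value}

    @stage("circadian")
    def _circadian():
        cohort = holder["cohort"]
        prof = circadian_profile(cohort)
        prof.per_animal.to_csv(out / "circadian_profile.csv")
        wil = day_night_duration_test(cohort)
        summary["circadian"] = {
            "peak_hour": prof.peak_hour,
            "light_fraction_mean": float(prof.light_fraction.mean()),
            "day_night_wilcoxon": {
                "W": wil.statistic, "p": wil.p_value,
                "n": wil.n_used, "method": wil.method},
        }

    @stage("structure")
    def _structure():
        cohort = holder["cohort"]
        iset = isi_set(cohort, config.isi_bin_h)
        iset.per_animal_hist.to_csv(out / "isi.csv")
        rng = np.random.default_rng(config.seed)
        lil = {}
        for aid, iv in iset.per_animal.items():
            if iv.size >= 5:
                d_stat, p = lilliefors_exponential(
                    iv, config.lilliefors_n_mc, rng)
                lil[aid] = {"D": d_stat, "p": p}
        summary["lilliefors"] = lil
        summary["lilliefors_n_significant_05"] = sum(
            1 for v in lil.values() if v["p"] < 0.05)
        peri = peri_seizure_analysis(
            cohort, config.peri_bin_days, config.T_days,
            config.peri_max_lag_days)
        peri.to_frame().to_csv(out / "periseizure.csv", index=False)
        summary["periseizure"] = _jsonable({
            "mean": peri.mean, "baseline": peri.baseline_mean,
            "p": peri.p_value})
        pac = pacf_analysis(cohort, config.pacf_max_lag, int(config.T_days))
        pac.to_frame().to_csv(out / "pacf.csv", index=False)
        summary["pacf"] = _jsonable({"mean": pac.mean, "p": pac.p_value})

    @stage("predict")
    def _predict():
        cohort = holder["cohort"]
        pairs = training_pairs(cohort, total_days=config.T_days)
        if len(pairs) < 3:
            summary["prediction"] = None
            logger.warning("too few animals with nonzero counts; "
                           "prediction stage skipped")
            return
        model = fit_gp_linear(pairs["x"], pairs["y"],
                              animal_ids=list(pairs["animal_id"]))
        thresholds = {}
        for a, b in config.target_intervals:
            ti = threshold_interval(model, (a, b))
            thresholds[f"{a:g}-{b:g}"] = _jsonable({
                "range": ti.as_range, "contiguous": ti.contiguous})
        report = enrollment_report(model, pairs, config.target_intervals)
        report.to_csv(out / "enrollment.csv", index=False)
        (out / "model.json").write_text(json.dumps(_jsonable({
            "sigma_b2": model.sigma_b2, "sigma_v2": model.sigma_v2,
            "sigma_n2": model.sigma_n2, "pearson_r": model.pearson_r,
            "pairs": {"x": model.x, "y": model.y},
        }), indent=2, sort_keys=True))
        summary["prediction"] = _jsonable({
            "pearson_r": model.pearson_r,
            "hyperparameters": {
                "sigma_b2": model.sigma_b2, "sigma_v2": model.sigma_v2,
                "sigma_n2": model.sigma_n2},
            "thresholds": thresholds,
        })

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
    log_path.write_text("\n".join(timings) + "\n")
    return out
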