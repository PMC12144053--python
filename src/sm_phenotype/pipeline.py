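"""End-to-end orchestration: generate/ingest -> yield -> features -> stats -> report.

A run is described by a :class:`PipelineConfig` (YAML-loadable, flag
overrides in the CLI), executes the full chain on either synthetic or
on-disk sensor logs, and writes a reproducible artifact bundle:

* yield report (per-participant and study data-yield ratios),
* hourly and daily feature tables (long delimited text),
* per-app descriptive table,
* a stats report (summary blocks, variance decompositions,
  between-category repeated-measures correlations, duration-checks
  coupling) as JSON,
* daily time-series figures by category and for the most-used apps,
* a manifest recording config, seed and library versions — enough to
  reproduce the bundle byte-identically.

Structured per-stage log records (events read, episodes built, bins
missing) make data loss visible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import CATEGORIES, CategoryKey, category_members, load_key, reference_key
from .data_yield import STATUS_MISSING, hour_bins, yield_summary
from .features import (
    app_daily_features,
    daily_features,
    day_inclusion,
    hourly_features,
    per_app_table,
)
from .ingest import build_episodes, read_sensor_tables
from .stats import duration_checks_correlation, icc_between_fraction, rm_correlation, summarize
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_key"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on."""

    output_dir: str | Path = "sm_phenotype_run"
    log_paths: list[str] = field(default_factory=list)
    key_path: str | None = None  # None -> packaged reference key
    timezone: str = "America/Phoenix"
    episode_cap_minutes: float = 120.0
    valid_hour_min_minutes: int = 30
    day_missing_max_hours: int = 12
    categories: list[str] = field(default_factory=lambda: list(CATEGORIES))
    synthetic: bool = True
    seed: int = 0
    cohort: CohortConfig | None = None
    make_figures: bool = True

    def validate(self) -> None:
        if not 0 <= self.valid_hour_min_minutes <= 60:
            raise ValueError("valid_hour_min_minutes must be in 0..60")
        if not 0 <= self.day_missing_max_hours <= 24:
            raise ValueError("day_missing_max_hours must be in 0..24")
        if self.episode_cap_minutes <= 0:
            raise ValueError("episode_cap_minutes must be > 0")
        unknown = [c for c in self.categories if c not in CATEGORIES]
        if unknown:
            raise ValueError(f"unknown categories: {unknown}")
        if not self.synthetic and not self.log_paths:
            raise ValueError("log_paths required when synthetic mode is off")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", None)
        config = cls(**raw)
        if cohort_raw:
            config.cohort = CohortConfig(**cohort_raw)
        return config


@dataclass
class PipelineResult:
    """In-memory handles plus the paths of everything written."""

    paths: dict[str, Path]
    bins: pd.DataFrame
    daily: pd.DataFrame
    hourly: pd.DataFrame
    stats_report: dict


def _stage(name: str, **counts) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; every stage error aborts with its stage name."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- acquire logs -----------------------------------------------------
    if config.synthetic:
        cohort = config.cohort or CohortConfig(seed=config.seed)
        if config.cohort is None:
            cohort.seed = config.seed
        logs, truth = generate_cohort(cohort)
        logs_dir = out / "logs"
        written = logs.write_tables(logs_dir)
        paths.update({f"log_{k}": v for k, v in written.items()})
        paths["truth"] = logs_dir / "cohort_truth.json"
        truth.to_json(paths["truth"])
        tables = read_sensor_tables(list(written.values()))
        tz = cohort.timezone
        _stage("simulate", participants=cohort.n_participants, days=cohort.n_days)
    else:
        tables = read_sensor_tables([Path(p) for p in config.log_paths])
        tz = config.timezone
    _stage(
        "ingest",
        foreground_events=len(tables.foreground),
        screen_events=len(tables.screen),
        aux_rows=len(tables.aux),
        duplicates_dropped=tables.n_dropped_duplicates,
    )

    key = load_key(config.key_path) if config.key_path else reference_key()

    # --- episodes ---------------------------------------------------------
    episodes = build_episodes(tables.foreground, tables.screen, config.episode_cap_minutes)
    _stage("episodes", episodes=len(episodes))

    # --- yield ------------------------------------------------------------
    bins = hour_bins(tables.all_row_timestamps(), tz)
    ysum = yield_summary(bins)
    per = ysum.per_participant.copy()
    valid_hours = (
        bins.assign(ok=bins["valid_minutes"] >= config.valid_hour_min_minutes)
        .groupby("participant_id")["ok"].sum().rename("valid_hours")
    )
    per = per.merge(valid_hours, on="participant_id")
    per = per[["participant_id", "enrolled_hours", "valid_hours", "yield_ratio"]]
    paths["yield_report"] = out / "yield_report.csv"
    per.to_csv(paths["yield_report"], index=False)
    _stage(
        "yield",
        enrolled_hours=int(per["enrolled_hours"].sum()),
        study_pooled=round(ysum.study_pooled, 4),
    )

    # --- features ---------------------------------------------------------
    hourly_parts, daily_parts = [], []
    for category in config.categories:
        cells = hourly_features(
            episodes, tables.foreground, key, category, bins, tz,
            config.valid_hour_min_minutes,
        )
        hourly_parts.append(cells)
        daily_parts.append(daily_features(cells, config.day_missing_max_hours))
    hourly = pd.concat(hourly_parts, ignore_index=True)
    daily = pd.concat(daily_parts, ignore_index=True)
    paths["features_hourly"] = out / "features_hourly.csv"
    hourly.drop(columns="hour_index").to_csv(paths["features_hourly"], index=False)
    paths["features_daily"] = out / "features_daily.csv"
    daily.to_csv(paths["features_daily"], index=False)
    _stage(
        "features",
        hourly_cells=len(hourly),
        missing_cells=int((hourly["status"] == STATUS_MISSING).sum()),
        days_excluded=int((~daily["included"]).sum()),
    )

    # --- per-app table ----------------------------------------------------
    app_daily = app_daily_features(episodes, tables.foreground, bins, key, tz)
    days = day_inclusion(bins, config.valid_hour_min_minutes, config.day_missing_max_hours)
    cohort_ids = sorted(bins["participant_id"].unique())
    apps = per_app_table(app_daily, days, cohort_ids, key)
    paths["per_app_table"] = out / "per_app_table.csv"
    apps.to_csv(paths["per_app_table"], index=False)

    # --- stats ------------------------------------------------------------
    stats_report = _stats_report(hourly, daily, config.categories, ysum)
    paths["stats_report"] = out / "stats_report.json"
    paths["stats_report"].write_text(json.dumps(stats_report, indent=1))
    _stage("stats", categories=len(config.categories))

    # --- figures ----------------------------------------------------------
    if config.make_figures:
        paths.update(_figures(out, daily, app_daily, apps, config.categories))

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))

    return PipelineResult(paths=paths, bins=bins, daily=daily, hourly=hourly, stats_report=stats_report)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _stats_report(hourly, daily, categories, ysum) -> dict:
    report: dict = {
        "data_yield": {
            "study_pooled": ysum.study_pooled,
            "study_mean_of_participants": ysum.study_mean_of_participants,
            "participant_range": [
                float(ysum.per_participant["yield_ratio"].min()),
                float(ysum.per_participant["yield_ratio"].max()),
            ],
        },
        "categories": {},
        "between_category_rmcorr": {"daily_sum": {}, "daily_checks": {}},
    }
    included = daily.loc[daily["included"]]
    for cat in categories:
        cat_daily = included.loc[included["scope"] == cat]
        cat_hourly = hourly.loc[hourly["scope"] == cat]
        block = {}
        for col, label in (("daily_sum", "duration"), ("daily_checks", "checks")):
            block[f"between_person_{label}"] = dataclasses.asdict(
                summarize(cat_daily, col, "between_person")
            )
            block[f"daily_{label}"] = dataclasses.asdict(summarize(cat_daily, col, "daily"))
            icc = icc_between_fraction(cat_daily, col)
            block[f"icc_{label}"] = dataclasses.asdict(icc)
        for col, label in (("sum_duration", "duration"), ("count_event", "checks")):
            block[f"hourly_{label}"] = dataclasses.asdict(summarize(cat_hourly, col, "hourly"))
        coupling = duration_checks_correlation(cat_daily)
        block["duration_checks_rmcorr"] = dataclasses.asdict(coupling)
        report["categories"][cat] = block

    for col, slot in (("daily_sum", "daily_sum"), ("daily_checks", "daily_checks")):
        wide = included.pivot_table(
            index=["participant_id", "date"], columns="scope", values=col
        )
        for i, a in enumerate(categories):
            for b in categories[i + 1:]:
                if a in wide and b in wide:
                    res = rm_correlation(wide[a], wide[b], wide.index.get_level_values(0))
                    report["between_category_rmcorr"][slot][f"{a}~{b}"] = dataclasses.asdict(res)
    return report


def _figures(out: Path, daily, app_daily, apps, categories) -> dict[str, Path]:
    paths = {}
    included = daily.loc[daily["included"]]
    for col, label, fname in (
        ("daily_sum", "daily duration (min)", "fig_daily_duration_by_category.png"),
        ("daily_checks", "daily checks", "fig_daily_checks_by_category.png"),
    ):
        fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
        for ax, cat in zip(axes.ravel(), categories):
            sub = included.loc[included["scope"] == cat]
            for _, grp in sub.groupby("participant_id"):
                ax.plot(pd.to_datetime(grp["date"]), grp[col], lw=0.6, alpha=0.4, color="steelblue")
            mean = sub.groupby("date")[col].mean()
            ax.plot(pd.to_datetime(mean.index), mean.values, lw=2.0, color="crimson")
            ax.set_title(cat)
            ax.tick_params(axis="x", rotation=45)
        fig.suptitle(f"{label} by category (thin: participants, bold: cohort mean)")
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths[fname.removesuffix(".png")] = path

    top = apps.head(4)["package_name"].tolist()
    for col, label, fname in (
        ("daily_sum", "daily duration (min)", "fig_popular_apps_duration.png"),
        ("daily_checks", "daily checks", "fig_popular_apps_checks.png"),
    ):
        fig, ax = plt.subplots(figsize=(10, 5))
        for pkg in top:
            sub = app_daily.loc[app_daily["package_name"] == pkg]
            if sub.empty:
                continue
            mean = sub.groupby("date")[col].mean()
            ax.plot(pd.to_datetime(mean.index), mean.values, lw=1.5, label=pkg)
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
        ax.tick_params(axis="x", rotation=45)
        fig.suptitle(f"Most-used apps: cohort mean {label} per day")
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths[fname.removesuffix(".png")] = path
    return paths


def validate_key(path: str | Path | None = None) -> dict:
    """Check a key file's invariants and report member counts per category.

    Returns ``{"counts": {...}, "violations": [...], "n_apps": int}``;
    parse/invariant problems are reported as violation strings rather than
    raised, so a maintenance workflow can list them all.
    """
    violations: list[str] = []
    counts = {c: 0 for c in CATEGORIES}
    n_apps = 0
    try:
        key = load_key(path) if path else reference_key()
    except Exception as exc:
        violations.append(str(exc))
        return {"counts": counts, "violations": violations, "n_apps": 0}
    n_apps = len(key)
    counts = {c: len(category_members(key, c)) for c in CATEGORIES}
    return {"counts": counts, "violations": violations, "n_apps": n_apps}
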