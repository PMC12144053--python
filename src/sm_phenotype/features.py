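"""Behavioral features: sum duration, count event, count episode.

Three features are extracted per app or per category, at hourly and daily
grain:

* **sum duration** — total foreground minutes within a time bin ("screen
  time").  An episode spanning a bin boundary contributes the exact
  interval intersection to each bin, so durations are additive and an
  hourly cell can never exceed 60 minutes across all apps combined.
* **count event** — the number of app launches in a bin ("checking"
  frequency).  A launch is an instantaneous event, counted once, in the
  bin containing its start.
* **count episode** — a 0/1 indicator of any launch in the bin; it is the
  coarser of the two counting features and is dominated by count event.

Category features are computed by summing member-app features cellwise,
which enforces additivity by construction (episodes never overlap, so no
double counting; narrow-scheme cells can never exceed broad-scheme cells).

Hourly cells inherit the three-valued status of the valid-hour rule;
daily features (civil day, 00:00-23:59) sum the non-missing hours and
record how many of the 24 hours were missing, so that days with poor
sensing coverage can be excluded from statistics by a configurable policy
(default: drop a day when more than 12 of its 24 hours are missing,
mirroring the hour-level 50% convention).

Durations are carried in fractional minutes at millisecond precision;
per-app daily means in sparse cohorts can be far below one minute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import CATEGORIES, CategoryKey, category_members
from .data_yield import STATUS_MISSING, STATUS_OBSERVED, STATUS_ZERO_FILLED
from .ingest import wall_clock_ms

__all__ = [
    "resolve_scope",
    "hourly_features",
    "daily_features",
    "day_inclusion",
    "app_daily_features",
    "per_app_table",
]

MS_PER_MIN = 60_000
MS_PER_HOUR = 3_600_000


def resolve_scope(scope: str, key: CategoryKey) -> tuple[str, frozenset[str]]:
    """Map a scope spec to (scope_type, member packages).

    ``scope`` is a category name (``sns``/``broad``/``google_play``/
    ``popular``) or ``app:<package_name>``.
    """
    if scope in CATEGORIES:
        return "category", category_members(key, scope)
    if scope.startswith("app:"):
        return "app", frozenset({scope[4:]})
    raise ValueError(
        f"unknown scope {scope!r}: expected one of {', '.join(CATEGORIES)} or 'app:<package>'"
    )


def _split_episodes_by_hour(
    episodes: pd.DataFrame, tz_name: str
) -> pd.DataFrame:
    """Explode episodes into (participant, hour_index, package, minutes) segments."""
    if episodes.empty:
        return pd.DataFrame(columns=["participant_id", "hour_index", "package_name", "minutes"])
    s = wall_clock_ms(episodes["start"].to_numpy(np.int64), tz_name)
    e = s + (episodes["end"].to_numpy(np.int64) - episodes["start"].to_numpy(np.int64))
    h0 = s // MS_PER_HOUR
    h1 = (e - 1) // MS_PER_HOUR
    n_spans = (h1 - h0 + 1).astype(np.int64)
    rep = np.repeat(np.arange(len(episodes)), n_spans)
    offsets = np.arange(n_spans.sum()) - np.repeat(np.cumsum(n_spans) - n_spans, n_spans)
    hour_idx = h0[rep] + offsets
    seg_start = np.maximum(s[rep], hour_idx * MS_PER_HOUR)
    seg_end = np.minimum(e[rep], (hour_idx + 1) * MS_PER_HOUR)
    return pd.DataFrame(
        {
            "participant_id": episodes["participant_id"].to_numpy()[rep],
            "hour_index": hour_idx,
            "package_name": episodes["package_name"].to_numpy()[rep],
            "minutes": (seg_end - seg_start) / MS_PER_MIN,
        }
    )


def _usage_by_hour(
    episodes: pd.DataFrame,
    launches: pd.DataFrame,
    members: frozenset[str],
    tz_name: str,
    per_package: bool = False,
) -> pd.DataFrame:
    """Aggregate member-app usage to (participant, hour[, package]) cells."""
    keys = ["participant_id", "hour_index"] + (["package_name"] if per_package else [])
    ep = episodes.loc[episodes["package_name"].isin(members)]
    segs = _split_episodes_by_hour(ep, tz_name)
    dur = segs.groupby(keys, sort=False)["minutes"].sum().rename("sum_duration")

    la = launches.loc[launches["package_name"].isin(members)]
    if la.empty:
        cnt = pd.Series(dtype=np.int64, name="count_event")
        cnt.index = pd.MultiIndex.from_arrays([[] for _ in keys], names=keys)
    else:
        la = la.assign(hour_index=wall_clock_ms(la["timestamp"].to_numpy(np.int64), tz_name) // MS_PER_HOUR)
        cnt = la.groupby(keys, sort=False).size().rename("count_event")

    usage = pd.concat([dur, cnt], axis=1).fillna(0.0).reset_index()
    usage["count_event"] = usage["count_event"].astype(np.int64)
    return usage


def hourly_features(
    episodes: pd.DataFrame,
    launches: pd.DataFrame,
    key: CategoryKey,
    scope: str,
    bins: pd.DataFrame,
    tz_name: str,
    min_valid_minutes: int = 30,
) -> pd.DataFrame:
    """Per participant-hour feature cells for one scope.

    ``episodes`` come from :func:`sm_phenotype.ingest.build_episodes`;
    ``launches`` is the raw foreground event table (each row one launch);
    ``bins`` is the enrolled-hour grid from
    :func:`sm_phenotype.data_yield.hour_bins`.  Every enrolled hour yields
    a cell; cells with no captured member-app usage are zero-filled or
    missing according to the valid-hour rule.
    """
    scope_type, members = resolve_scope(scope, key)
    usage = _usage_by_hour(episodes, launches, members, tz_name)

    cells = bins[["participant_id", "hour_index", "date", "hour", "valid_minutes"]].merge(
        usage, on=["participant_id", "hour_index"], how="left"
    )
    for col in ("sum_duration", "count_event"):
        cells[col] = cells[col].astype(float).fillna(0.0)

    observed = (cells["sum_duration"] > 0) | (cells["count_event"] > 0)
    valid = cells["valid_minutes"] >= min_valid_minutes
    cells["status"] = np.select(
        [observed, valid], [STATUS_OBSERVED, STATUS_ZERO_FILLED], default=STATUS_MISSING
    )
    missing = cells["status"] == STATUS_MISSING
    cells.loc[missing, ["sum_duration", "count_event"]] = np.nan
    cells["count_episode"] = (cells["count_event"] > 0).astype(float)
    cells.loc[missing, "count_episode"] = np.nan
    cells["scope_type"] = scope_type
    cells["scope"] = scope
    return cells[
        [
            "participant_id", "date", "hour", "hour_index", "scope_type", "scope",
            "sum_duration", "count_event", "count_episode", "status", "valid_minutes",
        ]
    ]


def daily_features(cells: pd.DataFrame, max_missing_hours: int = 12) -> pd.DataFrame:
    """Aggregate hourly cells to civil days (00:00-23:59).

    Daily sums run over non-missing hours only; hours absent from the
    enrolled grid (partial first/last days) count as missing.  A day is
    flagged ``included=False`` when ``n_missing_hours > max_missing_hours``
    and is then dropped listwise by downstream statistics.
    """
    dupes = cells.duplicated(subset=["participant_id", "date", "hour", "scope"])
    if dupes.any():
        raise ValueError("duplicate (participant, date, hour, scope) cells")
    grouped = cells.groupby(["participant_id", "date", "scope"], sort=True)
    daily = grouped.agg(
        daily_sum=("sum_duration", lambda s: s.sum(skipna=True)),
        daily_checks=("count_event", lambda s: s.sum(skipna=True)),
        n_present=("status", lambda s: int((s != STATUS_MISSING).sum())),
    ).reset_index()
    daily["n_missing_hours"] = 24 - daily["n_present"]
    daily["included"] = daily["n_missing_hours"] <= max_missing_hours
    return daily.drop(columns="n_present")


def day_inclusion(
    bins: pd.DataFrame, min_valid_minutes: int = 30, max_missing_hours: int = 12
) -> pd.DataFrame:
    """Package-independent day-level missingness bookkeeping.

    Counts, per participant-day, the enrolled hours whose sensing coverage
    fell below the valid-hour threshold.  Used for per-app tables, where
    day inclusion should not depend on which app is being tabulated.
    """
    grouped = bins.groupby(["participant_id", "date"], sort=True)
    days = grouped.agg(
        n_hours=("valid_minutes", "size"),
        n_low=("valid_minutes", lambda v: int((v < min_valid_minutes).sum())),
    ).reset_index()
    days["n_missing_hours"] = (24 - days["n_hours"]) + days["n_low"]
    days["included"] = days["n_missing_hours"] <= max_missing_hours
    return days


def app_daily_features(
    episodes: pd.DataFrame,
    launches: pd.DataFrame,
    bins: pd.DataFrame,
    key: CategoryKey,
    tz_name: str,
) -> pd.DataFrame:
    """Daily captured usage per (participant, date, package) for key apps.

    Only days/packages with captured usage appear; zero-usage days are
    implied by the day grid (see :func:`day_inclusion`) and handled in
    :func:`per_app_table`.
    """
    members = category_members(key, "broad") | category_members(key, "google_play")
    usage = _usage_by_hour(episodes, launches, members, tz_name, per_package=True)
    if usage.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", "package_name", "daily_sum", "daily_checks"]
        )
    hour_dates = bins[["participant_id", "hour_index", "date"]].drop_duplicates()
    usage = usage.merge(hour_dates, on=["participant_id", "hour_index"], how="left")
    # usage in hours outside the enrolled grid (shouldn't happen) is dropped
    usage = usage.dropna(subset=["date"])
    daily = (
        usage.groupby(["participant_id", "date", "package_name"], sort=True)
        .agg(daily_sum=("sum_duration", "sum"), daily_checks=("count_event", "sum"))
        .reset_index()
    )
    return daily


def per_app_table(
    app_daily: pd.DataFrame,
    day_table: pd.DataFrame,
    cohort_ids: list[str],
    key: CategoryKey,
) -> pd.DataFrame:
    """Descriptive usage per app, in the cohort's two reporting variants.

    For each app: how many participants ever used it (and the cohort
    percentage), and the mean/SD of person-level mean daily minutes and
    daily checks computed two ways — over *all* participants (non-users
    contributing zero days) and over users only.  Person-level means are
    taken over each participant's included days.
    """
    n_cohort = len(cohort_ids)
    included_days = day_table.loc[day_table["included"], ["participant_id", "date"]]
    n_days_per_person = included_days.groupby("participant_id").size()

    rows = []
    label_names = {"sns": "SNS", "broad": "Broad", "google_play": "GP", "popular": "Popular SM"}
    for _, app in key.table.iterrows():
        pkg = app["package_name"]
        sub = app_daily.loc[app_daily["package_name"] == pkg]
        sub = sub.merge(included_days, on=["participant_id", "date"], how="inner")
        totals = sub.groupby("participant_id")[["daily_sum", "daily_checks"]].sum()
        person_means = totals.div(n_days_per_person.reindex(totals.index), axis=0).dropna()
        users = person_means.index[
            (person_means["daily_sum"] > 0) | (person_means["daily_checks"] > 0)
        ]
        n_users = len(users)
        all_means = person_means.reindex(cohort_ids).fillna(0.0)

        def _stats(frame: pd.DataFrame) -> tuple[float, float, float, float]:
            if frame.empty:
                return (np.nan,) * 4
            m = frame.mean()
            s = frame.std(ddof=1) if len(frame) > 1 else pd.Series(np.nan, index=frame.columns)
            return (
                float(m["daily_sum"]), float(s["daily_sum"]),
                float(m["daily_checks"]), float(s["daily_checks"]),
            )

        a_md, a_sd, a_mc, a_sc = _stats(all_means)
        u_md, u_sd, u_mc, u_sc = _stats(person_means.loc[users])
        cats = ", ".join(label_names[c] for c in CATEGORIES if app[c] == 1)
        rows.append(
            {
                "app_label": app["app_label"],
                "package_name": pkg,
                "n_users": n_users,
                "pct_cohort": 100.0 * n_users / n_cohort,
                "mean_daily_minutes_all": a_md,
                "sd_daily_minutes_all": a_sd,
                "mean_daily_checks_all": a_mc,
                "sd_daily_checks_all": a_sc,
                "mean_daily_minutes_users": u_md,
                "sd_daily_minutes_users": u_sd,
                "mean_daily_checks_users": u_mc,
                "sd_daily_checks_users": u_sc,
                "categories": cats,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["n_users", "mean_daily_minutes_all"], ascending=False, kind="stable"
    ).reset_index(drop=True)
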