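"""Hourly/daily feature extraction: apportioning, statuses, per-app tables."""

import numpy as np
import pandas as pd
import pytest

from sm_phenotype.catalog import reference_key
from sm_phenotype.data_yield import STATUS_ZERO_FILLED, hour_bins
from sm_phenotype.features import (
    daily_features,
    day_inclusion,
    hourly_features,
    per_app_table,
    resolve_scope,
)
from sm_phenotype.ingest import build_episodes

from conftest import brute_hourly_usage, fg_events, minutes, random_episode_set, screen_events

MS_PER_MIN = 60_000


def full_coverage_bins(pids, start_hour, n_hours, tz="UTC"):
    """An hour-bin grid with one aux row per minute (all hours fully valid)."""
    rows = pd.DataFrame(
        [
            (pid, minutes(start_hour * 60 + m))
            for pid in pids
            for m in range(n_hours * 60)
        ],
        columns=["participant_id", "timestamp"],
    )
    return hour_bins(rows, tz)


def episodes_df(*rows):
    """rows: (pid, package, start_minute, end_minute)."""
    return pd.DataFrame(
        {
            "participant_id": [r[0] for r in rows],
            "package_name": [r[1] for r in rows],
            "start": [minutes(r[2]) for r in rows],
            "end": [minutes(r[3]) for r in rows],
        }
    )


@pytest.fixture(scope="module")
def key():
    return reference_key()


class TestHourlyFeatures:
    def test_episode_within_hour(self, key):
        bins = full_coverage_bins(["p"], 10, 2)
        eps = episodes_df(("p", "com.tumblr", 10 * 60 + 15, 10 * 60 + 45))
        launches = fg_events(("p", 10 * 60 + 15, "com.tumblr"))
        cells = hourly_features(eps, launches, key, "broad", bins, "UTC")
        by_hour = cells.set_index("hour")
        assert by_hour.loc[10, "sum_duration"] == pytest.approx(30.0)
        assert by_hour.loc[10, "count_event"] == 1

    def test_boundary_spanning_episode_split_exactly(self, key):
        bins = full_coverage_bins(["p"], 10, 2)
        eps = episodes_df(("p", "com.tumblr", 10 * 60 + 50, 11 * 60 + 10))
        launches = fg_events(("p", 10 * 60 + 50, "com.tumblr"))
        cells = hourly_features(eps, launches, key, "broad", bins, "UTC").set_index("hour")
        assert cells.loc[10, "sum_duration"] == pytest.approx(10.0)
        assert cells.loc[11, "sum_duration"] == pytest.approx(10.0)
        # the launch is counted once, in its start bin only
        assert cells.loc[10, "count_event"] == 1
        assert cells.loc[11, "count_event"] == 0

    def test_valid_hour_without_usage_zero_filled(self, key):
        bins = full_coverage_bins(["p"], 10, 1)
        cells = hourly_features(episodes_df(), fg_events(), key, "broad", bins, "UTC")
        assert cells.loc[0, "status"] == STATUS_ZERO_FILLED
        assert cells.loc[0, "sum_duration"] == 0.0
        assert cells.loc[0, "count_episode"] == 0.0

    def test_unknown_scope_rejected(self, key):
        with pytest.raises(ValueError, match="unknown scope"):
            resolve_scope("gaming", key)

    def test_matches_per_second_oracle(self, key):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            eps, launches = random_episode_set(rng)
            bins = hour_bins(
                pd.DataFrame(
                    {
                        "participant_id": "p",
                        "timestamp": np.arange(
                            eps["start"].min() // 3_600_000 * 3_600_000,
                            (eps["end"].max() // 3_600_000 + 1) * 3_600_000,
                            MS_PER_MIN,
                        ),
                    }
                ),
                "UTC",
            )
            cells = hourly_features(eps, launches, key, "broad", bins, "UTC")
            oracle_dur, oracle_cnt = brute_hourly_usage(eps, launches)
            for row in cells.itertuples():
                k = (row.participant_id, row.hour_index)
                assert row.sum_duration == pytest.approx(oracle_dur.get(k, 0.0), abs=1e-9)
                assert row.count_event == oracle_cnt.get(k, 0)

    def test_category_additivity_and_nesting(self, key, small_cohort):
        config, logs, _ = small_cohort
        eps = build_episodes(logs.foreground, logs.screen)
        rows = pd.concat(
            [logs.foreground[["participant_id", "timestamp"]],
             logs.screen[["participant_id", "timestamp"]],
             logs.aux[["participant_id", "timestamp"]]],
            ignore_index=True,
        )
        bins = hour_bins(rows, config.timezone)
        cells = {
            cat: hourly_features(eps, logs.foreground, key, cat, bins, config.timezone)
            for cat in ("broad", "sns", "popular")
        }
        broad = cells["broad"]["sum_duration"].fillna(0).to_numpy()
        for narrow in ("sns", "popular"):
            vals = cells[narrow]["sum_duration"].fillna(0).to_numpy()
            assert (vals <= broad + 1e-9).all()
        # one app in foreground at a time: all apps combined never exceed the hour
        assert (broad <= 60.0 + 1e-9).all()
        # counting features dominate the episode indicator
        ok = cells["broad"].dropna(subset=["count_event"])
        assert (ok["count_event"] >= ok["count_episode"]).all()

    def test_doubling_durations_leaves_counts_unchanged(self, key):
        bins = full_coverage_bins(["p"], 10, 3)
        eps = episodes_df(("p", "com.tumblr", 10 * 60 + 5, 10 * 60 + 15))
        launches = fg_events(("p", 10 * 60 + 5, "com.tumblr"))
        doubled = eps.assign(end=eps["start"] + 2 * (eps["end"] - eps["start"]))
        a = hourly_features(eps, launches, key, "broad", bins, "UTC")
        b = hourly_features(doubled, launches, key, "broad", bins, "UTC")
        assert a["count_event"].equals(b["count_event"])
        assert b["sum_duration"].sum() == pytest.approx(2 * a["sum_duration"].sum())


class TestDailyFeatures:
    def _cells(self, key, usage_minutes_per_hour=2.0, n_hours=24):
        bins = full_coverage_bins(["p"], 0, n_hours)
        eps = episodes_df(
            *[("p", "com.tumblr", h * 60, h * 60 + usage_minutes_per_hour) for h in range(n_hours)]
        )
        launches = fg_events(*[("p", h * 60, "com.tumblr") for h in range(n_hours)])
        return hourly_features(eps, launches, key, "broad", bins, "UTC")

    def test_additivity_over_full_day(self, key):
        daily = daily_features(self._cells(key))
        assert daily.loc[0, "daily_sum"] == pytest.approx(48.0)
        assert daily.loc[0, "n_missing_hours"] == 0
        assert bool(daily.loc[0, "included"])

    def test_missing_hours_counted_not_summed(self, key):
        cells = self._cells(key, n_hours=23)  # hour 23 never enrolled
        daily = daily_features(cells)
        assert daily.loc[0, "daily_sum"] == pytest.approx(46.0)
        assert daily.loc[0, "n_missing_hours"] == 1

    def test_day_excluded_over_policy_threshold(self, key):
        cells = self._cells(key, n_hours=10)  # 14 missing hours > default 12
        daily = daily_features(cells)
        assert not bool(daily.loc[0, "included"])

    def test_duplicate_cells_rejected(self, key):
        cells = self._cells(key)
        with pytest.raises(ValueError, match="duplicate"):
            daily_features(pd.concat([cells, cells.iloc[:1]], ignore_index=True))

    def test_recovers_generator_ground_truth(self, key, small_cohort):
        config, logs, truth = small_cohort
        eps = build_episodes(logs.foreground, logs.screen)
        rows = pd.concat(
            [logs.foreground[["participant_id", "timestamp"]],
             logs.screen[["participant_id", "timestamp"]],
             logs.aux[["participant_id", "timestamp"]]],
            ignore_index=True,
        )
        bins = hour_bins(rows, config.timezone)
        cells = hourly_features(eps, logs.foreground, key, "broad", bins, config.timezone)
        daily = daily_features(cells)
        merged = daily.merge(truth.daily, on=["participant_id", "date"])
        assert len(merged) == len(truth.daily)
        assert (merged["daily_sum"] - merged["realized_minutes"]).abs().max() < 0.1
        assert (merged["daily_checks"] == merged["n_launches"]).all()


class TestPerAppTable:
    def _day_table(self):
        return pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2", "p2"],
                "date": ["2020-04-01", "2020-04-02"] * 2,
                "n_hours": 24,
                "n_low": 0,
                "n_missing_hours": 0,
                "included": True,
            }
        )

    def test_app_used_by_all(self, key):
        app_daily = pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2", "p2"],
                "date": ["2020-04-01", "2020-04-02"] * 2,
                "package_name": "com.tumblr",
                "daily_sum": 10.0,
                "daily_checks": 4,
            }
        )
        table = per_app_table(app_daily, self._day_table(), ["p1", "p2"], key).set_index("package_name")
        row = table.loc["com.tumblr"]
        assert row["n_users"] == 2 and row["pct_cohort"] == 100.0
        assert row["mean_daily_minutes_all"] == pytest.approx(10.0)
        assert row["mean_daily_minutes_users"] == pytest.approx(10.0)

    def test_nonusers_pull_down_all_participant_mean(self, key):
        app_daily = pd.DataFrame(
            {
                "participant_id": ["p1", "p1"],
                "date": ["2020-04-01", "2020-04-02"],
                "package_name": "com.tumblr",
                "daily_sum": 10.0,
                "daily_checks": 4,
            }
        )
        table = per_app_table(app_daily, self._day_table(), ["p1", "p2"], key).set_index("package_name")
        row = table.loc["com.tumblr"]
        assert row["n_users"] == 1 and row["pct_cohort"] == 50.0
        assert row["mean_daily_minutes_all"] == pytest.approx(5.0)
        assert row["mean_daily_minutes_users"] == pytest.approx(10.0)

    def test_prevalence_follows_generator_app_weights(self, key, small_cohort):
        config, logs, _ = small_cohort
        counts = logs.foreground.groupby("package_name")["participant_id"].nunique()
        # the most-weighted app reaches at least as many participants as the least-weighted
        ordered = sorted(config.app_weights, key=config.app_weights.get, reverse=True)
        assert counts.get(ordered[0], 0) >= counts.get(ordered[-1], 0)
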