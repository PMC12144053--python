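"""Raw sensor-table reading and foreground-episode reconstruction.

The raw "applications foreground" sensor is a stream of launch instants:
one row per time an app comes to the device foreground, with no explicit
end.  Turning launches into usage *episodes* (intervals during which an app
is in the foreground) therefore needs termination rules, and sensing
pipelines rarely document theirs.  The rules used here are explicit:

* a foreground event opens an episode for its package;
* the episode ends at the earliest of (a) the participant's next foreground
  event (a new app replaces the old one), (b) the next screen-off or
  screen-lock event (the display going dark ends use; "lock" is treated
  like "off" and "unlock" does not reopen the prior app's episode), and
  (c) ``start + cap_minutes`` — a hard cap (default 120 min) so a launch
  with no terminator (phone idle with the screen on, missing screen rows)
  cannot produce multi-hour phantom usage;
* consecutive events for the *same* package with no terminator between them
  merge into one episode for duration purposes, but each event still counts
  as a separate launch ("checking") downstream.

All intervals are half-open ``[start, end)`` so durations are exactly
additive across bin boundaries.  Timestamps are carried internally as epoch
milliseconds; conversion to local civil time happens once, at binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from zoneinfo import ZoneInfo
import logging

import numpy as np
import pandas as pd

__all__ = [
    "IngestError",
    "EventTables",
    "read_sensor_tables",
    "build_episodes",
    "localize",
    "delocalize",
]

logger = logging.getLogger(__name__)

MS_PER_MIN = 60_000

DIALECT_COLUMNS = ["participant_id", "timestamp", "sensor", "payload"]
SCREEN_STATES = frozenset({"on", "off", "lock", "unlock"})
FOREGROUND_SENSOR = "applications_foreground"
SCREEN_SENSOR = "screen"


class IngestError(ValueError):
    """Malformed sensor table (bad header, unparseable timestamp, bad state)."""


@dataclass
class EventTables:
    """Typed, per-sensor event collections sorted by (participant, instant)."""

    foreground: pd.DataFrame  # participant_id, timestamp, package_name
    screen: pd.DataFrame      # participant_id, timestamp, state
    aux: pd.DataFrame         # participant_id, timestamp, sensor
    n_dropped_duplicates: int = 0

    def all_row_timestamps(self) -> pd.DataFrame:
        frames = [
            self.foreground[["participant_id", "timestamp"]],
            self.screen[["participant_id", "timestamp"]],
            self.aux[["participant_id", "timestamp"]],
        ]
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=["participant_id", "timestamp"])
        return pd.concat(frames, ignore_index=True)


def _parse_timestamps(raw: pd.Series, path) -> np.ndarray:
    """Accept epoch-milliseconds integers or ISO-8601 strings (UTC if naive).

    Both forms may occur in one file; each row is tried as a number first,
    then as ISO-8601.  A row parseable as neither aborts with its 1-based
    file row number.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    out = numeric.to_numpy(dtype=float)
    need_iso = numeric.isna().to_numpy()
    if need_iso.any():
        parsed = pd.to_datetime(
            raw[need_iso], errors="coerce", utc=True, format="ISO8601"
        )
        bad = parsed.isna().to_numpy()
        if bad.any():
            pos = int(np.flatnonzero(need_iso)[np.flatnonzero(bad)[0]])
            raise IngestError(
                f"{path}: unparseable timestamp at row {pos + 2}: {raw.iloc[pos]!r}"
            )
        out[need_iso] = pd.DatetimeIndex(parsed).asi8 // 10**6
    return out.astype(np.int64)


def read_sensor_tables(paths: list[str | Path]) -> EventTables:
    """Read dialect files (``participant_id,timestamp,sensor,payload``).

    Rows are routed by their ``sensor`` value: ``applications_foreground``
    rows become foreground events (payload = package name), ``screen`` rows
    become screen events (payload = one of on/off/lock/unlock), anything
    else is kept as an auxiliary sensor row for valid-minute computation.
    Events are sorted by (participant, instant); fully identical rows are
    dropped with a logged count.
    """
    frames = []
    for path in paths:
        frame = pd.read_csv(path, dtype={"participant_id": str, "sensor": str, "payload": str})
        unknown = [c for c in frame.columns if c not in DIALECT_COLUMNS]
        if unknown:
            raise IngestError(f"{path}: unknown column(s) {', '.join(unknown)}")
        missing = [c for c in DIALECT_COLUMNS if c not in frame.columns]
        if missing:
            raise IngestError(f"{path}: missing column(s) {', '.join(missing)}")
        frame = frame.copy()
        frame["timestamp"] = _parse_timestamps(frame["timestamp"], path)
        frames.append(frame)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=DIALECT_COLUMNS)
    )

    n_before = len(table)
    table = table.drop_duplicates()
    n_dropped = n_before - len(table)
    if n_dropped:
        logger.info("dropped %d duplicate sensor rows", n_dropped)
    table = table.sort_values(["participant_id", "timestamp"], kind="stable")

    is_fg = table["sensor"] == FOREGROUND_SENSOR
    is_screen = table["sensor"] == SCREEN_SENSOR
    foreground = (
        table.loc[is_fg, ["participant_id", "timestamp", "payload"]]
        .rename(columns={"payload": "package_name"})
        .reset_index(drop=True)
    )
    screen = (
        table.loc[is_screen, ["participant_id", "timestamp", "payload"]]
        .rename(columns={"payload": "state"})
        .reset_index(drop=True)
    )
    bad_states = set(screen["state"].unique()) - SCREEN_STATES
    if bad_states:
        raise IngestError(f"unknown screen state(s): {sorted(bad_states)}")
    aux = (
        table.loc[~is_fg & ~is_screen, ["participant_id", "timestamp", "sensor"]]
        .reset_index(drop=True)
    )
    return EventTables(
        foreground=foreground, screen=screen, aux=aux, n_dropped_duplicates=n_dropped
    )


def build_episodes(
    foreground: pd.DataFrame,
    screen: pd.DataFrame | None = None,
    cap_minutes: float = 120.0,
) -> pd.DataFrame:
    """Reconstruct non-overlapping usage episodes from launch events.

    Parameters
    ----------
    foreground
        Columns ``participant_id, timestamp, package_name`` (epoch ms).
        Input row order is irrelevant; sorting is internal.
    screen
        Optional columns ``participant_id, timestamp, state``; only
        ``off``/``lock`` rows act as terminators.
    cap_minutes
        Hard per-episode duration cap, must be > 0.

    Returns
    -------
    DataFrame with ``participant_id, package_name, start, end, n_events``
    (epoch ms, half-open).  ``n_events`` is the number of launch events
    merged into the episode.  Zero-length episodes (two launches at the
    same instant) are dropped, but their launches remain in the foreground
    table for event counting.
    """
    if cap_minutes <= 0:
        raise ValueError("cap_minutes must be > 0")
    cap_ms = int(round(cap_minutes * MS_PER_MIN))
    cols = ["participant_id", "package_name", "start", "end", "n_events"]
    if foreground.empty:
        return pd.DataFrame(columns=cols)

    fg = foreground.sort_values(["participant_id", "timestamp"], kind="stable")
    if screen is not None and len(screen):
        offs = screen.loc[screen["state"].isin(["off", "lock"])]
    else:
        offs = pd.DataFrame(columns=["participant_id", "timestamp"])

    out = []
    for pid, grp in fg.groupby("participant_id", sort=True):
        ts = grp["timestamp"].to_numpy(np.int64)
        pkg = grp["package_name"].to_numpy(object)
        off_ts = np.sort(
            offs.loc[offs["participant_id"] == pid, "timestamp"].to_numpy(np.int64)
        )
        horizon = np.iinfo(np.int64).max
        next_fg = np.append(ts[1:], horizon)
        if len(off_ts):
            idx = np.searchsorted(off_ts, ts, side="right")
            next_off = np.append(off_ts, horizon)[idx]
        else:
            next_off = np.full(len(ts), horizon)
        end = np.minimum(np.minimum(next_fg, next_off), ts + cap_ms)
        # merge run: same package and the previous episode ran right up to
        # this launch (terminated by it, with no screen-off in between)
        same_pkg = np.concatenate([[False], pkg[1:] == pkg[:-1]])
        continues = np.concatenate([[False], end[:-1] == ts[1:]])
        new_group = ~(same_pkg & continues)
        group_id = np.cumsum(new_group) - 1
        n_groups = int(group_id[-1]) + 1
        first = np.flatnonzero(new_group)
        last = np.append(first[1:], len(ts)) - 1
        g_start = ts[first]
        g_end = end[last]
        g_n = np.bincount(group_id, minlength=n_groups)
        g_pkg = pkg[np.flatnonzero(new_group)]
        out.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "package_name": g_pkg,
                    "start": g_start,
                    "end": g_end,
                    "n_events": g_n,
                }
            )
        )
    episodes = pd.concat(out, ignore_index=True)
    episodes = episodes.loc[episodes["end"] > episodes["start"]].reset_index(drop=True)
    return episodes[cols]


def localize(timestamps_ms, tz_name: str) -> pd.DatetimeIndex:
    """Epoch-ms instants -> timezone-aware local civil times.

    Conversion from an absolute instant to local time is total: DST gaps
    and folds cannot occur in this direction, so downstream date/hour
    assignment is always well defined.  (Naive *local* strings, where folds
    are ambiguous, are resolved at parse time to the earlier UTC offset.)
    """
    try:
        ZoneInfo(tz_name)
    except Exception as exc:
        raise ValueError(f"invalid IANA timezone {tz_name!r}") from exc
    ts = pd.to_datetime(np.asarray(timestamps_ms, dtype=np.int64), unit="ms", utc=True)
    return ts.tz_convert(tz_name)


def delocalize(local_times: pd.DatetimeIndex) -> np.ndarray:
    """Inverse of :func:`localize`: tz-aware local times -> epoch ms."""
    return (local_times.tz_convert("UTC").asi8 // 10**6).astype(np.int64)


def wall_clock_ms(timestamps_ms, tz_name: str) -> np.ndarray:
    """Epoch-ms instants -> local wall-clock milliseconds since 1970-01-01 00:00 local.

    Binning by date/hour/minute is done on this wall-clock axis so bins
    follow local civil time (00:00-23:59) rather than UTC hours.
    """
    local = localize(timestamps_ms, tz_name)
    return (local.tz_localize(None).asi8 // 10**6).astype(np.int64)
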