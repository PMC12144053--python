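"""Valid minutes, data-yield ratios, and the zero-vs-NA valid-hour rule.

Event-based sensing cannot distinguish "the participant used nothing this
hour" from "the sensing app was not running this hour" by the absence of
usage rows alone.  Two constructs resolve this:

* **valid minute** — a clock-aligned 60-second window (hh:mm:00–hh:mm:59)
  in which *any* phone sensor logged at least one row: evidence the sensing
  app was alive during that minute.  Minute windows are aligned rather than
  sliding so the count is well defined and additive across hours.
* **data yield ratio** — valid minutes divided by the minutes in a time
  segment; within hourly bins, ``valid_minutes / 60``.  This is the
  feasibility/compliance metric of a sensing study.

The **valid-hour rule** then assigns each participant-hour one of exactly
three statuses:

* ``observed`` — usage was captured in the hour; the captured value stands
  regardless of yield (usage is direct evidence the app was running);
* ``zero_filled`` — no usage captured but the hour had at least
  ``min_valid_minutes`` (default 30, i.e. >= 50% coverage) of sensing, so
  0.0 minutes is taken to reflect real non-use;
* ``missing`` — no usage captured *and* under-half sensing coverage: the
  hour is NA, because usage could have happened while sensing was down.

The 30-minute threshold is a researcher-set convention, not a law of the
data; it is configurable, and any choice introduces some bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import wall_clock_ms

__all__ = [
    "STATUS_OBSERVED",
    "STATUS_ZERO_FILLED",
    "STATUS_MISSING",
    "valid_minutes",
    "hour_bins",
    "apply_valid_hour_rule",
    "yield_summary",
]

STATUS_OBSERVED = "observed"
STATUS_ZERO_FILLED = "zero_filled"
STATUS_MISSING = "missing"

MS_PER_MIN = 60_000


def valid_minutes(row_timestamps_ms, hour_start_ms: int) -> int:
    """Count valid minutes in the hour starting at ``hour_start_ms``.

    ``row_timestamps_ms`` are pooled rows from all sensors (foreground,
    screen, auxiliary) for one participant; rows outside the hour are
    ignored.  Returns an integer in 0..60.
    """
    ts = np.asarray(row_timestamps_ms, dtype=np.int64)
    in_hour = ts[(ts >= hour_start_ms) & (ts < hour_start_ms + 60 * MS_PER_MIN)]
    if in_hour.size == 0:
        return 0
    return int(np.unique((in_hour - hour_start_ms) // MS_PER_MIN).size)


def hour_bins(
    all_rows: pd.DataFrame,
    tz_name: str,
    enrollment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per participant-hour valid-minute counts over the enrollment window.

    Parameters
    ----------
    all_rows
        Pooled ``participant_id, timestamp`` rows from every sensor.
    tz_name
        IANA zone used to assign rows to local civil dates and hours.
    enrollment
        Optional ``participant_id, start, end`` (epoch ms) windows; by
        default the window is inferred as [first row, last row] per
        participant.  Every enrolled hour appears in the output, including
        hours with zero rows.

    Returns
    -------
    DataFrame ``participant_id, date, hour, valid_minutes, yield_ratio``
    with one row per enrolled participant-hour.
    """
    if all_rows.empty:
        raise ValueError("no sensor rows: cannot build hour bins")
    rows = all_rows.copy()
    if enrollment is None:
        enrollment = (
            rows.groupby("participant_id")["timestamp"]
            .agg(start="min", end="max")
            .reset_index()
        )

    # Work on the local wall-clock axis: bins follow civil dates/hours.
    wall = wall_clock_ms(rows["timestamp"].to_numpy(np.int64), tz_name)
    key = pd.DataFrame(
        {"participant_id": rows["participant_id"].to_numpy(), "minute": wall // MS_PER_MIN}
    ).drop_duplicates()
    key["hour_index"] = key["minute"] // 60
    counts = (
        key.groupby(["participant_id", "hour_index"], sort=False)
        .size()
        .rename("valid_minutes")
        .reset_index()
    )

    # enumerate enrolled hours per participant
    parts = []
    for _, row in enrollment.iterrows():
        bounds = wall_clock_ms([int(row["start"]), int(row["end"])], tz_name)
        h0, h1 = bounds // (60 * MS_PER_MIN)
        hours = np.arange(h0, h1 + 1, dtype=np.int64)
        parts.append(pd.DataFrame({"participant_id": row["participant_id"], "hour_index": hours}))
    grid = pd.concat(parts, ignore_index=True)

    bins = grid.merge(counts, on=["participant_id", "hour_index"], how="left")
    bins["valid_minutes"] = bins["valid_minutes"].fillna(0).astype(int)
    wall_hour = pd.to_datetime(bins["hour_index"].to_numpy(np.int64) * 60 * MS_PER_MIN, unit="ms")
    bins["date"] = wall_hour.strftime("%Y-%m-%d")
    bins["hour"] = wall_hour.hour
    bins["yield_ratio"] = bins["valid_minutes"] / 60.0
    return bins[["participant_id", "hour_index", "date", "hour", "valid_minutes", "yield_ratio"]]


def apply_valid_hour_rule(
    valid_minutes_in_hour: int,
    captured_usage_minutes: float,
    min_valid_minutes: int = 30,
) -> tuple[str, float]:
    """Resolve one participant-hour to (status, usage value).

    Exactly three outcomes are reachable: captured usage is ``observed``
    whatever the yield; otherwise the hour is ``zero_filled`` at or above
    the valid-minute threshold and ``missing`` (value NaN) below it.
    """
    if captured_usage_minutes < 0:
        raise ValueError("captured usage cannot be negative")
    if captured_usage_minutes > 0:
        return STATUS_OBSERVED, float(captured_usage_minutes)
    if valid_minutes_in_hour >= min_valid_minutes:
        return STATUS_ZERO_FILLED, 0.0
    return STATUS_MISSING, float("nan")


@dataclass
class YieldSummary:
    """Study-level data-yield feasibility summary."""

    per_participant: pd.DataFrame  # participant_id, enrolled_hours, valid_minutes, yield_ratio
    study_pooled: float            # hour-weighted: mean yield over all enrolled hours
    study_mean_of_participants: float


def yield_summary(bins: pd.DataFrame) -> YieldSummary:
    """Summarize yield per participant and for the whole study.

    Two study-level numbers are emitted because both conventions are
    defensible: ``study_pooled`` weights every enrolled hour equally, while
    ``study_mean_of_participants`` averages the per-participant ratios.
    """
    if bins.empty:
        raise ValueError("no hour bins to summarize")
    per = (
        bins.groupby("participant_id")
        .agg(enrolled_hours=("yield_ratio", "size"), yield_ratio=("yield_ratio", "mean"))
        .reset_index()
    )
    return YieldSummary(
        per_participant=per,
        study_pooled=float(bins["yield_ratio"].mean()),
        study_mean_of_participants=float(per["yield_ratio"].mean()),
    )
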