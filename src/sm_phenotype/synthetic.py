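"""Synthetic AWARE-like sensing logs for a virtual adolescent cohort.

The generator emits the three raw tables the rest of the pipeline consumes —
app-foreground launch events, screen on/off events, and an auxiliary
always-on sensor row stream — for a cohort with *known* ground truth, so
every downstream stage (episode building, yield computation, feature
extraction, variance decomposition) can be tested against what was put in.

The statistical skeleton is a two-level model of daily usage: participant i
has a true mean daily foreground duration mu_i = mu + b_i with
b_i ~ N(0, between_sd^2), and day t realizes a target
mu_i + e_it with e_it ~ N(0, within_sd^2), truncated at 0.  Daily checking
(launch) counts follow the same structure, and the within-day deviations of
duration and checks are drawn jointly normal with a configurable
correlation, emulating the moderate duration/checking coupling seen in real
cohorts.  The implied between-person variance fraction
between_sd^2 / (between_sd^2 + within_sd^2) is recorded in the truth object
for recovery tests.

Within a day, launches are placed by a 24-hour diurnal weight profile and
session lengths are heavy-tailed (log-normal weights, capped), rescaled so
the day's realized total matches its target.  Sessions of one participant
never overlap (one app in the foreground at a time) and every session emits
a screen-on row at its start and a screen-off row at its end, which makes
episode reconstruction exact.  Sensor outages ("the sensing app crashed")
remove *all* sensor rows inside scheduled intervals, producing the
partial-hour yield patterns the valid-hour rule exists for.

All instants are generated in a single named local timezone with no DST
transitions by default, so calendar pathologies cannot leak into binning
tests; DST behaviour is exercised separately in the ingest module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "CohortConfigError",
    "CohortTruth",
    "SensorLogs",
    "generate_cohort",
    "generate_participant_day",
    "inject_outages",
]

MS_PER_MIN = 60_000
MS_PER_DAY = 86_400_000


class CohortConfigError(ValueError):
    """A cohort configuration field is invalid; the message names the field."""


def _default_app_weights() -> dict[str, float]:
    # Prevalence-ordered weights over commonly observed social apps
    # (most-used platforms first); normalized to sum to 1.
    raw = {
        "com.google.android.youtube": 18.0,
        "com.snapchat.android": 16.0,
        "com.instagram.android": 15.0,
        "com.discord": 12.0,
        "com.zhiliaoapp.musically": 11.0,
        "com.twitter.android": 7.0,
        "com.facebook.katana": 6.0,
        "com.reddit.frontpage": 5.0,
        "tv.twitch.android.app": 4.0,
        "com.pinterest": 3.0,
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _default_diurnal_profile() -> np.ndarray:
    # Low overnight use, daytime ramp, evening peak.
    raw = np.array(
        [0.30, 0.15, 0.10, 0.05, 0.05, 0.10, 0.30, 0.60,
         1.00, 1.20, 1.30, 1.50, 1.70, 1.60, 1.60, 1.80,
         2.20, 2.60, 3.00, 3.30, 3.20, 2.80, 2.00, 1.00]
    )
    return raw / raw.sum()


@dataclass
class CohortConfig:
    """Parameters of the virtual cohort.

    Defaults emulate a one-month adolescent sensing study: 19 participants
    enrolled ~31 days, a grand mean of 95 foreground minutes and 160
    launches of broad social media per day, between/within person SDs that
    imply a between-person variance fraction of ~0.6 for duration and ~0.67
    for checking, and occasional multi-hour sensor outages.
    """

    n_participants: int = 19
    n_days: int = 31
    seed: int = 0
    start_date: str = "2020-04-01"
    timezone: str = "America/Phoenix"  # fixed-offset in practice: no DST

    mean_daily_minutes: float = 95.0
    between_sd: float = 62.0
    within_sd: float = 50.0
    mean_daily_checks: float = 160.0
    check_between_sd: float = 120.0
    check_within_sd: float = 85.0
    #: within-person correlation between daily duration and daily checks
    duration_checks_rho: float = 0.55

    app_weights: dict[str, float] = field(default_factory=_default_app_weights)
    diurnal_profile: np.ndarray = field(default_factory=_default_diurnal_profile)

    #: expected outage episodes per participant per day; with the default
    #: length distribution (mean ~148 min) this yields ~25% downtime and a
    #: study data-yield ratio in the mid-70% range
    outage_rate: float = 2.5
    #: log-normal parameters (log-minutes) of outage length
    outage_log_mean: float = np.log(90.0)
    outage_log_sd: float = 1.0

    aux_sensor_rows_per_min: float = 1.0
    #: log-normal shape of within-day session-length weights
    session_sigma: float = 1.0
    session_cap_minutes: float = 120.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise CohortConfigError("n_participants must be >= 1")
        if self.n_days < 1:
            raise CohortConfigError("n_days must be >= 1")
        for name in ("between_sd", "within_sd", "check_between_sd", "check_within_sd"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        if self.mean_daily_minutes < 0:
            raise CohortConfigError("mean_daily_minutes must be >= 0")
        if self.mean_daily_checks < 0:
            raise CohortConfigError("mean_daily_checks must be >= 0")
        if not -1.0 <= self.duration_checks_rho <= 1.0:
            raise CohortConfigError("duration_checks_rho must be in [-1, 1]")
        if not self.app_weights:
            raise CohortConfigError("app_weights must be non-empty")
        if any(w < 0 for w in self.app_weights.values()):
            raise CohortConfigError("app_weights must be nonnegative")
        if abs(sum(self.app_weights.values()) - 1.0) > 1e-9:
            raise CohortConfigError("app_weights must sum to 1")
        profile = np.asarray(self.diurnal_profile, dtype=float)
        if profile.shape != (24,):
            raise CohortConfigError("diurnal_profile must have 24 entries")
        if (profile < 0).any():
            raise CohortConfigError("diurnal_profile must be nonnegative")
        if abs(profile.sum() - 1.0) > 1e-9:
            raise CohortConfigError("diurnal_profile must sum to 1")
        if self.outage_rate < 0:
            raise CohortConfigError("outage_rate must be >= 0")
        if self.aux_sensor_rows_per_min < 1:
            raise CohortConfigError("aux_sensor_rows_per_min must be >= 1")
        if self.session_cap_minutes <= 0:
            raise CohortConfigError("session_cap_minutes must be > 0")
        try:
            ZoneInfo(self.timezone)
        except Exception as exc:  # pragma: no cover - zoneinfo raises KeyError variants
            raise CohortConfigError(f"timezone {self.timezone!r} is not a valid IANA zone") from exc

    @property
    def between_fraction_minutes(self) -> float:
        denom = self.between_sd**2 + self.within_sd**2
        return float(self.between_sd**2 / denom) if denom else 0.0

    @property
    def between_fraction_checks(self) -> float:
        denom = self.check_between_sd**2 + self.check_within_sd**2
        return float(self.check_between_sd**2 / denom) if denom else 0.0


@dataclass
class SensorLogs:
    """The three raw sensing tables, timestamps as epoch milliseconds."""

    foreground: pd.DataFrame  # participant_id, timestamp, package_name
    screen: pd.DataFrame      # participant_id, timestamp, state
    aux: pd.DataFrame         # participant_id, timestamp, sensor

    def all_row_timestamps(self) -> pd.DataFrame:
        """Pooled (participant_id, timestamp) rows across every sensor."""
        frames = [
            self.foreground[["participant_id", "timestamp"]],
            self.screen[["participant_id", "timestamp"]],
            self.aux[["participant_id", "timestamp"]],
        ]
        return pd.concat(frames, ignore_index=True)

    def write_tables(self, directory: str | Path) -> dict[str, Path]:
        """Write the ingest dialect: ``participant_id,timestamp,sensor,payload``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = {}
        fg = self.foreground.assign(sensor="applications_foreground")
        fg = fg.rename(columns={"package_name": "payload"})
        out["foreground"] = directory / "applications_foreground.csv"
        fg[["participant_id", "timestamp", "sensor", "payload"]].to_csv(
            out["foreground"], index=False
        )
        sc = self.screen.assign(sensor="screen").rename(columns={"state": "payload"})
        out["screen"] = directory / "screen.csv"
        sc[["participant_id", "timestamp", "sensor", "payload"]].to_csv(
            out["screen"], index=False
        )
        aux = self.aux.assign(payload="1")
        out["aux"] = directory / "aux_sensors.csv"
        aux[["participant_id", "timestamp", "sensor", "payload"]].to_csv(
            out["aux"], index=False
        )
        return out


@dataclass
class CohortTruth:
    """Ground truth the generator committed to; the oracle for recovery tests."""

    participants: pd.DataFrame  # participant_id, true_mean_daily_minutes, true_mean_daily_checks
    daily: pd.DataFrame         # participant_id, date, target_minutes, realized_minutes, n_launches
    outages: pd.DataFrame       # participant_id, start, end (epoch ms, half-open)
    between_fraction_minutes: float
    between_fraction_checks: float
    timezone: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "between_fraction_minutes": self.between_fraction_minutes,
            "between_fraction_checks": self.between_fraction_checks,
            "timezone": self.timezone,
            "participants": self.participants.to_dict(orient="records"),
            "daily": self.daily.to_dict(orient="records"),
            "outages": self.outages.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _waterfill(weights: np.ndarray, caps: np.ndarray, total: float) -> np.ndarray:
    """Allocate ``total`` across slots proportionally to ``weights`` under caps."""
    n = len(weights)
    alloc = np.zeros(n)
    active = np.ones(n, dtype=bool)
    remaining = float(min(total, caps.sum()))
    # Each pass pins at least one slot at its cap, so n passes suffice.
    for _ in range(n + 1):
        if remaining <= 1e-12 or not active.any():
            break
        w = np.where(active, weights, 0.0)
        share = remaining * w / w.sum()
        target = alloc + share
        over = active & (target > caps)
        if over.any():
            remaining -= float((caps - alloc)[over].sum())
            alloc[over] = caps[over]
            active &= ~over
        else:
            alloc = np.where(active, target, alloc)
            remaining = 0.0
    return alloc


def generate_participant_day(
    rng: np.random.Generator,
    n_sessions: int,
    target_minutes: float,
    config: CohortConfig,
):
    """Place one participant-day of sessions on the 1440-minute clock.

    Returns ``(start_minutes, duration_minutes, package_names)`` with
    sessions sorted, pairwise non-overlapping, start hours drawn from the
    diurnal profile, and total duration equal to ``target_minutes`` up to
    capacity constraints (a ~0.3 s guard gap separates back-to-back
    sessions so start/end instants never coincide).
    """
    if n_sessions <= 0 or target_minutes <= 0:
        empty = np.empty(0)
        return empty, empty, np.empty(0, dtype=object)
    profile = np.asarray(config.diurnal_profile, dtype=float)
    hours = rng.choice(24, size=n_sessions, p=profile)
    starts = np.sort(hours + rng.random(n_sessions)) * 60.0
    gap_eps = 0.005  # minutes; keeps a session's end strictly before the next start
    next_start = np.append(starts[1:], 1440.0)
    caps = np.minimum(next_start - starts - gap_eps, config.session_cap_minutes)
    caps = np.maximum(caps, 1e-4)
    weights = rng.lognormal(mean=0.0, sigma=config.session_sigma, size=n_sessions)
    durations = _waterfill(weights, caps, target_minutes)
    keep = durations > 1e-6
    packages = np.array(list(config.app_weights), dtype=object)
    probs = np.fromiter(config.app_weights.values(), dtype=float)
    apps = rng.choice(packages, size=n_sessions, p=probs)
    return starts[keep], durations[keep], apps[keep]


def _draw_daily_targets(
    rng: np.random.Generator, config: CohortConfig, mu_min: float, mu_chk: float
) -> tuple[np.ndarray, np.ndarray]:
    """Realized (minutes, launch-count) targets for each enrolled day."""
    rho = config.duration_checks_rho
    cov = np.array(
        [
            [config.within_sd**2, rho * config.within_sd * config.check_within_sd],
            [rho * config.within_sd * config.check_within_sd, config.check_within_sd**2],
        ]
    )
    # svd method tolerates the singular cov of zero-SD (degenerate) configs
    devs = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_days, method="svd")
    minutes = np.maximum(mu_min + devs[:, 0], 0.0)
    checks = np.rint(np.maximum(mu_chk + devs[:, 1], 0.0)).astype(int)
    # positive usage implies at least one launch; no usage implies none
    checks = np.where(minutes > 0, np.maximum(checks, 1), 0)
    minutes = np.where(checks == 0, 0.0, minutes)
    return minutes, checks


def _draw_outages(
    rng: np.random.Generator, config: CohortConfig, study_start_ms: int, study_end_ms: int
) -> list[tuple[int, int]]:
    n = rng.poisson(config.outage_rate * config.n_days)
    if n == 0:
        return []
    starts = rng.integers(study_start_ms, study_end_ms, size=n)
    lengths = rng.lognormal(config.outage_log_mean, config.outage_log_sd, size=n)
    ends = np.minimum(starts + (lengths * MS_PER_MIN).astype(np.int64), study_end_ms)
    intervals = sorted(zip(starts.tolist(), ends.tolist()))
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e > s]


def inject_outages(logs: SensorLogs, schedule: pd.DataFrame) -> SensorLogs:
    """Delete every sensor row falling inside an outage interval.

    ``schedule`` has columns ``participant_id, start, end`` (epoch ms,
    half-open intervals).  Foreground events inside an outage are removed
    too: usage during an outage is unobserved, exactly as when the sensing
    app is not running.  Overlapping intervals for one participant are a
    schedule error.
    """
    if schedule.empty:
        return logs
    for pid, grp in schedule.groupby("participant_id"):
        grp = grp.sort_values("start")
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping outage intervals for participant {pid!r}")

    def _filter(frame: pd.DataFrame) -> pd.DataFrame:
        keep = np.ones(len(frame), dtype=bool)
        for pid, grp in schedule.groupby("participant_id"):
            mask = frame["participant_id"].to_numpy() == pid
            if not mask.any():
                continue
            ts = frame.loc[mask, "timestamp"].to_numpy()
            starts = np.sort(grp["start"].to_numpy())
            ends = np.sort(grp["end"].to_numpy())
            inside = (
                np.searchsorted(starts, ts, side="right")
                - np.searchsorted(ends, ts, side="right")
            ) == 1
            keep[np.flatnonzero(mask)[inside]] = False
        return frame.loc[keep].reset_index(drop=True)

    return SensorLogs(
        foreground=_filter(logs.foreground),
        screen=_filter(logs.screen),
        aux=_filter(logs.aux),
    )


def generate_cohort(config: CohortConfig) -> tuple[SensorLogs, CohortTruth]:
    """Generate the full cohort's sensing logs plus ground truth.

    Deterministic given ``config.seed``: one root seed spawns an
    independent child stream per participant, so the output is reproducible
    even if participants were generated in parallel.
    """
    config.validate()
    tz = ZoneInfo(config.timezone)
    day_starts = [
        int(pd.Timestamp(config.start_date, tz=tz).value // 10**6) + d * MS_PER_DAY
        for d in range(config.n_days + 1)
    ]
    # America/Phoenix has a fixed offset, so civil days are exactly 24 h;
    # recompute from the calendar anyway so other zones stay correct.
    stamps = pd.date_range(
        pd.Timestamp(config.start_date, tz=tz), periods=config.n_days + 1, freq="D"
    )
    day_starts = (stamps.asi8 // 10**6).tolist()
    dates = [str(stamps[d].date()) for d in range(config.n_days)]
    study_start, study_end = day_starts[0], day_starts[-1]

    width = max(2, len(str(config.n_participants)))
    pids = [f"p{i + 1:0{width}d}" for i in range(config.n_participants)]
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)

    fg_parts, screen_parts, aux_parts = [], [], []
    person_rows, daily_rows, outage_rows = [], [], []

    n_extra_aux = int(round((config.aux_sensor_rows_per_min - 1.0) * 1440))

    for pid, child in zip(pids, children):
        rng = np.random.default_rng(child)
        mu_min = max(config.mean_daily_minutes + rng.normal(0.0, config.between_sd), 0.0)
        mu_chk = max(config.mean_daily_checks + rng.normal(0.0, config.check_between_sd), 0.0)
        person_rows.append((pid, mu_min, mu_chk))
        target_minutes, target_checks = _draw_daily_targets(rng, config, mu_min, mu_chk)

        for d in range(config.n_days):
            day0 = day_starts[d]
            day_ms = day_starts[d + 1] - day0
            starts, durs, apps = generate_participant_day(
                rng, int(target_checks[d]), float(target_minutes[d]), config
            )
            start_ms = day0 + np.rint(starts * MS_PER_MIN).astype(np.int64)
            end_ms = start_ms + np.rint(durs * MS_PER_MIN).astype(np.int64)
            fg_parts.append((pid, start_ms, apps))
            screen_parts.append((pid, start_ms, end_ms))
            daily_rows.append(
                (pid, dates[d], float(target_minutes[d]), float(durs.sum()), int(len(starts)))
            )
            # one aux row per clock minute (jittered inside the minute) ...
            n_min = day_ms // MS_PER_MIN
            lattice = day0 + np.arange(n_min, dtype=np.int64) * MS_PER_MIN
            jitter = rng.integers(0, MS_PER_MIN, size=n_min)
            aux_ts = lattice + jitter
            if n_extra_aux > 0:  # ... plus optional extra rows anywhere in the day
                extra = day0 + rng.integers(0, day_ms, size=n_extra_aux)
                aux_ts = np.sort(np.concatenate([aux_ts, extra]))
            aux_parts.append((pid, aux_ts))

        for s, e in _draw_outages(rng, config, study_start, study_end):
            outage_rows.append((pid, s, e))

    def _concat(parts, maker):
        frames = [maker(*p) for p in parts]
        return pd.concat(frames, ignore_index=True)

    foreground = _concat(
        fg_parts,
        lambda pid, ts, apps: pd.DataFrame(
            {"participant_id": pid, "timestamp": ts, "package_name": apps}
        ),
    )
    screen = _concat(
        screen_parts,
        lambda pid, s, e: pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp": np.concatenate([s, e]),
                "state": np.array(["on"] * len(s) + ["off"] * len(e), dtype=object),
            }
        ),
    )
    aux = _concat(
        aux_parts,
        lambda pid, ts: pd.DataFrame(
            {"participant_id": pid, "timestamp": ts, "sensor": "battery"}
        ),
    )
    for frame in (foreground, screen, aux):
        frame.sort_values(["participant_id", "timestamp"], inplace=True, kind="stable")
        frame.reset_index(drop=True, inplace=True)

    logs = SensorLogs(foreground=foreground, screen=screen, aux=aux)
    outages = pd.DataFrame(outage_rows, columns=["participant_id", "start", "end"])
    truth = CohortTruth(
        participants=pd.DataFrame(
            person_rows,
            columns=["participant_id", "true_mean_daily_minutes", "true_mean_daily_checks"],
        ),
        daily=pd.DataFrame(
            daily_rows,
            columns=["participant_id", "date", "target_minutes", "realized_minutes", "n_launches"],
        ),
        outages=outages,
        between_fraction_minutes=config.between_fraction_minutes,
        between_fraction_checks=config.between_fraction_checks,
        timezone=config.timezone,
    )
    logs = inject_outages(logs, outages)
    return logs, truth
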