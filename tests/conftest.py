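import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sm_phenotype.catalog import reference_key
from sm_phenotype.synthetic import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MS_PER_MIN = 60_000


@pytest.fixture(scope="session")
def key():
    return reference_key()


@pytest.fixture(scope="session")
def small_cohort():
    """3 participants x 6 days, no outages: exact-recovery playground."""
    config = CohortConfig(n_participants=3, n_days=6, seed=11, outage_rate=0.0)
    logs, truth = generate_cohort(config)
    return config, logs, truth


def minutes(m: float) -> int:
    """Minutes-from-epoch -> epoch ms, for hand-built event fixtures."""
    return int(round(m * MS_PER_MIN))


def fg_events(*rows) -> pd.DataFrame:
    """rows: (participant_id, start_minute, package)."""
    return pd.DataFrame(
        {
            "participant_id": [r[0] for r in rows],
            "timestamp": [minutes(r[1]) for r in rows],
            "package_name": [r[2] for r in rows],
        }
    )


def screen_events(*rows) -> pd.DataFrame:
    """rows: (participant_id, minute, state)."""
    return pd.DataFrame(
        {
            "participant_id": [r[0] for r in rows],
            "timestamp": [minutes(r[1]) for r in rows],
            "state": [r[2] for r in rows],
        }
    )


def brute_hourly_usage(episodes: pd.DataFrame, launches: pd.DataFrame):
    """Independent per-second accumulation oracle (UTC wall clock).

    Requires integer-second episode boundaries.  Returns two dicts keyed by
    (participant_id, hour_index): duration minutes and launch counts.
    """
    dur: dict = {}
    for row in episodes.itertuples():
        s, e = row.start // 1000, row.end // 1000
        secs = np.arange(s, e)
        hours, counts = np.unique(secs // 3600, return_counts=True)
        for h, c in zip(hours, counts):
            k = (row.participant_id, int(h))
            dur[k] = dur.get(k, 0) + int(c)
    cnt: dict = {}
    for row in launches.itertuples():
        k = (row.participant_id, int(row.timestamp // 3_600_000))
        cnt[k] = cnt.get(k, 0) + 1
    return {k: v / 60.0 for k, v in dur.items()}, cnt


def random_episode_set(rng: np.random.Generator, package="com.tumblr"):
    """A small random episode/launch set with integer-second boundaries."""
    n = rng.integers(1, 6)
    base = int(rng.integers(0, 10_000)) * 3_600  # some hour, in seconds
    starts = np.sort(rng.integers(0, 3 * 3600, size=n)) + base
    durs = rng.integers(1, 1800, size=n)
    episodes = pd.DataFrame(
        {
            "participant_id": "p",
            "package_name": package,
            "start": starts * 1000,
            "end": (starts + durs) * 1000,
        }
    )
    launches = pd.DataFrame(
        {"participant_id": "p", "timestamp": starts * 1000, "package_name": package}
    )
    return episodes, launches
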