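"""Calibration runs: known-truth cohorts pushed through the full pipeline.

These routines exercise the complete chain (generate -> ingest -> episodes
-> bins -> features -> statistics) on cohorts whose ground truth is known
by construction, and report how well the pipeline recovers it.  They are
the package's evidence that the estimators measure what they claim to
measure.

The recovery cohort is 40 participants x 200 days with a configured
between-person variance fraction of exactly 0.60 for daily duration and a
within-person duration/checks coupling of 0.55.  Its grand means sit more
than four standard deviations above zero so that the generator's
truncation-at-zero leaves the configured variance components essentially
intact; event volume (60 launches/day) is kept moderate so the run stays
fast.  The yield calibration deletes a known fraction of sensor rows from
a usage-free month-long cohort and checks the recovered study yield ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import reference_key
from .data_yield import hour_bins, yield_summary
from .features import daily_features, hourly_features
from .ingest import build_episodes
from .stats import duration_checks_correlation, icc_between_fraction
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "recovery_cohort_config",
    "run_parameter_recovery",
    "run_yield_recovery",
]


def recovery_cohort_config(seed: int) -> CohortConfig:
    """The 40 x 200 parameter-recovery cohort (between fraction 0.60, coupling 0.55)."""
    return CohortConfig(
        n_participants=40,
        n_days=200,
        seed=seed,
        outage_rate=0.0,
        mean_daily_minutes=300.0,
        within_sd=50.0,
        between_sd=50.0 * float(np.sqrt(1.5)),  # fraction = 1.5/(1.5+1) = 0.60
        mean_daily_checks=60.0,
        check_within_sd=12.0,
        check_between_sd=12.0 * float(np.sqrt(1.5)),
        duration_checks_rho=0.55,
    )


def run_parameter_recovery(seed: int) -> dict:
    """Full-pipeline recovery of the ICC fraction and duration/checks coupling.

    Returns the recovered between-person variance fraction of daily
    duration, the recovered repeated-measures duration/checks correlation
    with its 3-standard-error band, and the configured truths.
    """
    config = recovery_cohort_config(seed)
    logs, truth = generate_cohort(config)
    episodes = build_episodes(logs.foreground, logs.screen)
    bins = hour_bins(
        pd.concat(
            [
                logs.foreground[["participant_id", "timestamp"]],
                logs.screen[["participant_id", "timestamp"]],
                logs.aux[["participant_id", "timestamp"]],
            ],
            ignore_index=True,
        ),
        config.timezone,
    )
    cells = hourly_features(
        episodes, logs.foreground, reference_key(), "broad", bins, config.timezone
    )
    daily = daily_features(cells)
    included = daily.loc[daily["included"]]
    icc = icc_between_fraction(included, "daily_sum")
    coupling = duration_checks_correlation(included)
    coupling_se = float(np.sqrt((1.0 - coupling.r**2) / coupling.df))
    return {
        "icc_between_fraction": icc.between_fraction,
        "icc_true_fraction": truth.between_fraction_minutes,
        "coupling_r": coupling.r,
        "coupling_se": coupling_se,
        "coupling_true_rho": config.duration_checks_rho,
        "n_days_analyzed": int(len(included)),
    }


def run_yield_recovery(seed: int, deletion_rate: float = 0.25) -> dict:
    """Recover the study yield ratio after uniform random sensor-row deletion.

    A usage-free 19 x 31 cohort emits exactly one auxiliary row per clock
    minute; deleting each row independently with probability ``p`` makes
    every minute invalid with probability ``p``, so the expected study
    yield ratio is ``1 - p`` with a binomial standard error.
    """
    config = CohortConfig(
        n_participants=19,
        n_days=31,
        seed=seed,
        outage_rate=0.0,
        mean_daily_minutes=0.0,
        between_sd=0.0,
        within_sd=0.0,
        mean_daily_checks=0.0,
        check_between_sd=0.0,
        check_within_sd=0.0,
    )
    logs, _ = generate_cohort(config)
    rng = np.random.default_rng(seed + 1)
    keep = rng.random(len(logs.aux)) >= deletion_rate
    surviving = logs.aux.loc[keep, ["participant_id", "timestamp"]]
    bins = hour_bins(surviving, config.timezone)
    summary = yield_summary(bins)
    n_minutes = len(logs.aux)
    se = float(np.sqrt(deletion_rate * (1 - deletion_rate) / n_minutes))
    return {
        "study_yield": summary.study_pooled,
        "expected_yield": 1.0 - deletion_rate,
        "se": se,
        "n_minutes": n_minutes,
    }
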