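"""Between/within-person statistics for repeated daily measures.

Repeatedly measured usage (a value per participant-day) mixes two sources
of variation: stable differences *between* adolescents and day-to-day
fluctuation *within* each adolescent.  This module provides the three
statistical surfaces used to describe such data:

* descriptive summary blocks at three grains (between-person, daily,
  hourly);
* a one-way random-effects variance decomposition (the ICC's
  between-person variance fraction);
* the repeated-measures correlation: the common within-person association
  between two repeatedly measured variables after removing participant
  means (equivalently, the ANCOVA common-slope formulation with
  participant as a factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryBlock",
    "VarianceDecomposition",
    "RmCorrResult",
    "summarize",
    "icc_between_fraction",
    "rm_correlation",
    "duration_checks_correlation",
]

GRAINS = ("between_person", "daily", "hourly")


@dataclass(frozen=True)
class SummaryBlock:
    """Mean/SD/range of a feature at one reporting grain.

    At the hourly grain the block includes zero-filled bins, i.e. it does
    not exclude hours when participants were asleep or simply not using
    their phone; ``includes_idle_hours`` carries that caveat.
    """

    grain: str
    mean: float
    sd: float
    min: float
    max: float
    n: int
    includes_idle_hours: bool = False


@dataclass(frozen=True)
class VarianceDecomposition:
    """One-way random-effects split of total variance.

    ``between_fraction`` is the intraclass correlation: the share of total
    variance attributable to stable participant differences.
    """

    between_variance: float
    within_variance: float
    between_fraction: float


@dataclass(frozen=True)
class RmCorrResult:
    """Repeated-measures correlation with its degrees of freedom and p-value."""

    r: float
    df: int
    p: float


def summarize(
    values: pd.DataFrame,
    value_col: str,
    grain: str,
    participant_col: str = "participant_id",
) -> SummaryBlock:
    """Summary block for one feature at one grain.

    ``between_person`` first averages within participant (one number per
    adolescent) and summarizes those person means; ``daily`` and ``hourly``
    summarize the rows directly.  Missing values are dropped.
    """
    if grain not in GRAINS:
        raise ValueError(f"grain must be one of {GRAINS}, got {grain!r}")
    data = values[[participant_col, value_col]].dropna(subset=[value_col])
    if data.empty:
        raise ValueError("no non-missing values to summarize")
    if grain == "between_person":
        series = data.groupby(participant_col)[value_col].mean()
    else:
        series = data[value_col]
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return SummaryBlock(
        grain=grain,
        mean=float(series.mean()),
        sd=sd,
        min=float(series.min()),
        max=float(series.max()),
        n=int(len(series)),
        includes_idle_hours=(grain == "hourly"),
    )


def icc_between_fraction(
    values: pd.DataFrame,
    value_col: str,
    participant_col: str = "participant_id",
) -> VarianceDecomposition:
    """Between-person variance fraction from one-way random-effects ANOVA.

    With k participants, group sizes n_i, grand total N and mean squares
    MSB (between) and MSW (within), the variance components are

        sigma_b^2 = (MSB - MSW) / k_bar,   sigma_w^2 = MSW,

    where the unbalanced-design group-size correction is
    k_bar = (N - sum n_i^2 / N) / (k - 1).  A negative between-component
    estimate is truncated to 0, the standard ANOVA-estimator convention.
    The fraction is sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """
    data = values[[participant_col, value_col]].dropna(subset=[value_col])
    groups = data.groupby(participant_col)[value_col]
    k = groups.ngroups
    if k < 2:
        raise ValueError("variance decomposition requires at least 2 participants")
    n_i = groups.size().to_numpy(dtype=float)
    if (n_i < 2).all():
        raise ValueError("variance decomposition requires repeated measures")
    N = n_i.sum()
    grand = data[value_col].mean()
    means = groups.mean().to_numpy()
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(((data[value_col] - data.groupby(participant_col)[value_col].transform("mean")) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    k_bar = (N - np.sum(n_i**2) / N) / (k - 1)
    between = max((msb - msw) / k_bar, 0.0)
    within = msw
    total = between + within
    fraction = between / total if total > 0 else 0.0
    return VarianceDecomposition(
        between_variance=float(between),
        within_variance=float(within),
        between_fraction=float(fraction),
    )


def rm_correlation(
    x, y, participants, *, min_pairs_per_participant: int = 2
) -> RmCorrResult:
    """Repeated-measures (within-person) correlation.

    Center x and y within participant and correlate the centered values:

        r = sum(x_c y_c) / sqrt(sum(x_c^2) sum(y_c^2)),

    over all complete pairs from participants contributing at least
    ``min_pairs_per_participant`` pairs.  Degrees of freedom are
    df = N - k - 1 (N pairs, k participants), matching the ANCOVA
    common-slope formulation; the p-value comes from the t transform
    t = r sqrt(df / (1 - r^2)).

    Participants with zero within-person variance in x or y contribute
    nothing to the sums; if no within-person variation remains at all the
    correlation is undefined and an error is raised.
    """
    frame = pd.DataFrame({"x": x, "y": y, "g": participants}).dropna()
    frame = frame.groupby("g").filter(lambda d: len(d) >= min_pairs_per_participant)
    k = frame["g"].nunique()
    if k < 2:
        raise ValueError("repeated-measures correlation requires >= 2 participants with >= 2 pairs")
    xc = frame["x"] - frame.groupby("g")["x"].transform("mean")
    yc = frame["y"] - frame.groupby("g")["y"].transform("mean")
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("no within-person variation: correlation undefined")
    r = float((xc * yc).sum() / np.sqrt(sxx * syy))
    r = max(min(r, 1.0), -1.0)
    df = int(len(frame) - k - 1)
    if df <= 0:
        raise ValueError("not enough pairs for inference (df <= 0)")
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmCorrResult(r=r, df=df, p=p)


def duration_checks_correlation(
    daily: pd.DataFrame,
    duration_col: str = "daily_sum",
    checks_col: str = "daily_checks",
    participant_col: str = "participant_id",
) -> RmCorrResult:
    """Within-person coupling of daily duration and daily checking."""
    return rm_correlation(
        daily[duration_col], daily[checks_col], daily[participant_col]
    )
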