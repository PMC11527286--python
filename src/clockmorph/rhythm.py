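"""χ²-periodogram analysis and rhythmic/arrhythmic classification.

The statistic is the Sokolove–Bushell Qp: the activity series (DD portion,
30-min bins by default) is folded at every candidate period of P bins,

    Qp(P) = sum_h n_h (M_h - M)^2 / s^2,

where M_h are the column means of the fold, n_h the column counts, M the
grand mean and s^2 the population variance of all N points.  Under the null
of no periodicity Qp is approximately chi-square with P-1 degrees of
freedom, giving the per-period significance line at quantile 1-alpha
(alpha = 0.01 by default).  Candidate periods are integer bin multiples
within the 14–34 h window; partial final cycles are kept (unequal n_h)
rather than truncated.

A fly is called rhythmic when some local Qp maximum exceeds its significance
line by at least the power threshold (default 10 Qp units); the reported
period and rhythmic power (Qp minus significance) come from the predominant
peak — the candidate with the largest power.  Arrhythmic flies contribute
to n but are excluded from period/power summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dam import ActivityRecord, resample

__all__ = [
    "PeriodogramConfig",
    "Periodogram",
    "RhythmCall",
    "RhythmSummary",
    "chi_square_periodogram",
    "classify",
    "summarize",
    "analyze_records",
    "percent_rhythmic",
    "summary_table",
]


@dataclass(frozen=True)
class PeriodogramConfig:
    period_min_h: float = 14.0
    period_max_h: float = 34.0
    alpha: float = 0.01
    analysis_bin: int = 30  # minutes
    power_threshold: float = 10.0
    dd_days: tuple[int, int] = (1, 7)  # 1-based inclusive range within DD

    def __post_init__(self) -> None:
        if not self.period_min_h < self.period_max_h:
            raise ValueError("period_min_h must be < period_max_h")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.power_threshold < 0:
            raise ValueError("power_threshold must be >= 0")


@dataclass
class Periodogram:
    """Per-fly Qp spectrum with its chi-square significance line."""

    fly_id: str
    periods_h: np.ndarray
    qp: np.ndarray
    significance: np.ndarray
    config: PeriodogramConfig

    def __post_init__(self) -> None:
        if not (len(self.periods_h) == len(self.qp) == len(self.significance)):
            raise ValueError("spectrum arrays must have equal length")
        if np.any(np.diff(self.periods_h) <= 0):
            raise ValueError("periods must be strictly increasing")


@dataclass
class RhythmCall:
    fly_id: str
    rhythmic: bool
    period_h: float | None = None
    power: float | None = None
    peak_qp: float | None = None


@dataclass
class RhythmSummary:
    """Per-genotype free-running summary (n, nR, %, period and power ± SEM)."""

    genotype: str
    n: int
    n_rhythmic: int
    percent_rhythmic: float
    period_mean: float | None = None
    period_sem: float | None = None
    power_mean: float | None = None
    power_sem: float | None = None


def percent_rhythmic(n: int, n_rhythmic: int) -> float:
    """Percent rhythmic flies, rounded half-up to 2 decimals.

    Half-up (not banker's) rounding matches the convention of published
    summary tables, e.g. 1/32 -> 3.13.
    """
    if not 0 <= n_rhythmic <= n:
        raise ValueError("need 0 <= n_rhythmic <= n")
    return math.floor(100.0 * n_rhythmic / n * 100.0 + 0.5) / 100.0


def _dd_slice(record: ActivityRecord, config: PeriodogramConfig) -> np.ndarray:
    sched = record.schedule
    dd_offset = sched.phase_day_offset("DD")
    n_dd = sched.phase_n_days("DD")
    lo, hi = config.dd_days
    if not (1 <= lo <= hi <= n_dd):
        raise ValueError(
            f"dd_days {config.dd_days} outside the DD phase (1..{n_dd})"
        )
    return record.day_slice(dd_offset + lo - 1, dd_offset + hi - 1)


def chi_square_periodogram(
    record: ActivityRecord, config: PeriodogramConfig | None = None
) -> Periodogram:
    """Sokolove–Bushell Qp spectrum over the configured period window."""
    config = config or PeriodogramConfig()
    if record.bin_width != config.analysis_bin:
        record = resample(record, config.analysis_bin)
    x = _dd_slice(record, config).astype(float)
    N = len(x)
    p_min = math.ceil(config.period_min_h * 60.0 / config.analysis_bin)
    p_max = math.floor(config.period_max_h * 60.0 / config.analysis_bin)
    if N < 2 * p_max:
        raise ValueError(
            f"series too short: {N} bins < 2 cycles at the longest period"
        )
    M = x.mean()
    s2 = float(np.mean((x - M) ** 2))
    if s2 == 0.0:
        raise ValueError("degenerate constant series (zero variance)")

    periods = np.arange(p_min, p_max + 1)
    qp = np.empty(len(periods))
    idx = np.arange(N)
    for j, P in enumerate(periods):
        cols = idx % P
        n_h = np.bincount(cols, minlength=P)
        m_h = np.bincount(cols, weights=x, minlength=P) / n_h
        qp[j] = float(np.sum(n_h * (m_h - M) ** 2) / s2)
    significance = stats.chi2.ppf(1.0 - config.alpha, periods - 1)
    return Periodogram(
        fly_id=record.fly_id,
        periods_h=periods * config.analysis_bin / 60.0,
        qp=qp,
        significance=significance,
        config=config,
    )


def classify(periodogram: Periodogram,
             config: PeriodogramConfig | None = None) -> RhythmCall:
    """Rhythmic/arrhythmic decision from the predominant periodogram peak."""
    config = config or periodogram.config
    qp = periodogram.qp
    sig = periodogram.significance
    n = len(qp)
    # local maxima (one-sided at the window edges) above the significance line
    candidates = []
    for i in range(n):
        left_ok = i == 0 or qp[i] >= qp[i - 1]
        right_ok = i == n - 1 or qp[i] >= qp[i + 1]
        if left_ok and right_ok and qp[i] > sig[i]:
            candidates.append(i)
    if not candidates:
        return RhythmCall(periodogram.fly_id, rhythmic=False)
    best = max(candidates, key=lambda i: qp[i] - sig[i])
    power = float(qp[best] - sig[best])
    if power < config.power_threshold:
        return RhythmCall(periodogram.fly_id, rhythmic=False,
                          peak_qp=float(qp[best]))
    return RhythmCall(
        periodogram.fly_id,
        rhythmic=True,
        period_h=float(periodogram.periods_h[best]),
        power=power,
        peak_qp=float(qp[best]),
    )


def summarize(
    calls: Iterable[RhythmCall], genotype_map: Mapping[str, str]
) -> list[RhythmSummary]:
    """Per-genotype n, nR, percent (2 dp) and period/power mean ± SEM.

    Period and power statistics cover rhythmic flies only; SEM uses n−1 and
    is absent when fewer than two flies are rhythmic.
    """
    groups: dict[str, list[RhythmCall]] = {}
    for call in calls:
        if call.fly_id not in genotype_map:
            raise KeyError(f"fly {call.fly_id!r} has no genotype mapping")
        groups.setdefault(genotype_map[call.fly_id], []).append(call)

    out = []
    for genotype in sorted(groups):
        gcalls = groups[genotype]
        n = len(gcalls)
        rhythmic = [c for c in gcalls if c.rhythmic]
        nr = len(rhythmic)
        summary = RhythmSummary(genotype, n, nr, percent_rhythmic(n, nr))
        if nr >= 1:
            periods = np.array([c.period_h for c in rhythmic])
            powers = np.array([c.power for c in rhythmic])
            summary.period_mean = float(periods.mean())
            summary.power_mean = float(powers.mean())
            if nr >= 2:
                summary.period_sem = float(periods.std(ddof=1) / math.sqrt(nr))
                summary.power_sem = float(powers.std(ddof=1) / math.sqrt(nr))
        out.append(summary)
    return out


def analyze_records(
    records: Sequence[ActivityRecord],
    genotype_map: Mapping[str, str],
    config: PeriodogramConfig | None = None,
) -> tuple[list[RhythmCall], list[RhythmSummary]]:
    """Periodogram + classification per fly, then per-genotype summaries."""
    config = config or PeriodogramConfig()
    calls = [classify(chi_square_periodogram(r, config), config) for r in records]
    return calls, summarize(calls, genotype_map)


def summary_table(summaries: Iterable[RhythmSummary]) -> pd.DataFrame:
    rows = [s.__dict__ for s in summaries]
    return pd.DataFrame(rows)
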