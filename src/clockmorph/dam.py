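"""TriKinetics DAM2 activity-monitor I/O and activity time series.

A DAM2 monitor file is tab-delimited with 42 columns per reading: reading
index, date (``D Mon YY``), time (``HH:MM:SS``), a status integer (1 = valid
reading), six device fields, then 32 beam-crossing counts — one per channel.
Readings with status != 1 are dropped (monitor-error semantics), not zeroed.

The light schedule is supplied externally (the monitor's optional light
sensor column is not trusted): an ordered list of LD/DD phases with day
counts and lights-on/off clock times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LightSchedule",
    "ActivityRecord",
    "read_dam",
    "write_dam",
    "resample",
    "population_profile",
]

logger = logging.getLogger(__name__)

_DAM_COLUMNS = 42
_DATE_FORMAT = "%d %b %y"


@dataclass(frozen=True)
class LightSchedule:
    """Ordered LD/DD phases; the standard protocol is 12:12 LD then DD."""

    phases: tuple[tuple[str, int, time, time], ...] = (
        ("LD", 5, time(8, 0), time(20, 0)),
        ("DD", 8, time(8, 0), time(20, 0)),
    )
    start_datetime: datetime = datetime(2024, 1, 1, 8, 0)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("phase list must be non-empty")
        for regime, n_days, on, off in self.phases:
            if regime not in ("LD", "DD"):
                raise ValueError(f"unknown regime {regime!r}")
            if n_days < 1:
                raise ValueError("each phase needs n_days >= 1")
            if regime == "LD" and on == off:
                raise ValueError("LD phase needs lights_on != lights_off")

    @property
    def total_days(self) -> int:
        return sum(p[1] for p in self.phases)

    def phase_day_offset(self, regime: str) -> int:
        """Day index (0-based from start) at which the first ``regime``
        phase begins."""
        day = 0
        for r, n_days, _, _ in self.phases:
            if r == regime:
                return day
            day += n_days
        raise ValueError(f"schedule has no {regime} phase")

    def phase_n_days(self, regime: str) -> int:
        for r, n_days, _, _ in self.phases:
            if r == regime:
                return n_days
        raise ValueError(f"schedule has no {regime} phase")

    def lights_on_hour(self) -> float:
        on = self.phases[0][2]
        return on.hour + on.minute / 60.0


@dataclass
class ActivityRecord:
    """One fly's binned beam-crossing counts under a light schedule."""

    fly_id: str
    channel: int
    genotype: str
    bin_width: int  # minutes
    start: datetime
    counts: np.ndarray
    schedule: LightSchedule

    def __post_init__(self) -> None:
        if not 1 <= self.channel <= 32:
            raise ValueError(f"channel must be 1..32, got {self.channel}")
        if self.bin_width < 1 or 60 % self.bin_width != 0:
            raise ValueError("bin_width must divide 60")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        span_min = len(self.counts) * self.bin_width
        if span_min > self.schedule.total_days * 1440:
            raise ValueError("counts extend past the light schedule")

    def day_slice(self, day_from: int, day_to: int) -> np.ndarray:
        """Counts for 0-based days [day_from, day_to] inclusive."""
        per_day = 1440 // self.bin_width
        lo, hi = day_from * per_day, (day_to + 1) * per_day
        if lo < 0 or hi > len(self.counts):
            raise ValueError(
                f"day range {day_from}..{day_to} outside recorded span"
            )
        return self.counts[lo:hi]


# ---------------------------------------------------------------------------
# DAM2 file I/O
# ---------------------------------------------------------------------------

def read_dam(path: str | Path, schedule: LightSchedule) -> list[ActivityRecord]:
    """Read one DAM2 monitor file into 32 per-channel records.

    Rows with status != 1 are dropped (with a logged count); the bin width
    is inferred from consecutive timestamps; interior gaps are zero-filled
    and logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != _DAM_COLUMNS:
        raise ValueError(
            f"{path.name}: expected {_DAM_COLUMNS} tab-separated columns, "
            f"got {df.shape[1]} (line 1)"
        )
    try:
        stamps = pd.to_datetime(
            df[1] + " " + df[2], format=f"{_DATE_FORMAT} %H:%M:%S"
        )
    except ValueError as exc:
        raise ValueError(f"{path.name}: bad date/time field: {exc}") from None
    status = df[3].astype(int)
    counts = df.iloc[:, 10:].astype(int).to_numpy()

    dropped = int((status != 1).sum())
    if dropped:
        logger.info("%s: dropped %d readings with status != 1", path.name, dropped)
    keep = status == 1
    stamps = stamps[keep].reset_index(drop=True)
    counts = counts[keep.to_numpy()]
    if len(stamps) == 0:
        raise ValueError(f"{path.name}: no valid readings")
    diffs = stamps.diff().dropna()
    if len(diffs) and (diffs <= pd.Timedelta(0)).any():
        raise ValueError(f"{path.name}: non-monotone timestamps")
    if len(diffs):
        bin_width = int(diffs.min().total_seconds() // 60)
    else:
        bin_width = 1
    if bin_width < 1:
        raise ValueError(f"{path.name}: sub-minute sampling is unsupported")

    # zero-fill interior gaps on the regular grid
    n_bins = int(
        (stamps.iloc[-1] - stamps.iloc[0]).total_seconds() // 60 // bin_width
    ) + 1
    grid = np.zeros((n_bins, counts.shape[1]), dtype=np.int64)
    idx = (
        (stamps - stamps.iloc[0]).dt.total_seconds() // 60 // bin_width
    ).astype(int)
    if idx.duplicated().any():
        raise ValueError(f"{path.name}: duplicate timestamps")
    grid[idx.to_numpy()] = counts
    if n_bins != len(stamps):
        logger.info("%s: zero-filled %d missing readings", path.name,
                    n_bins - len(stamps))

    start = stamps.iloc[0].to_pydatetime()
    stem = path.stem
    return [
        ActivityRecord(
            fly_id=f"{stem}#{ch:02d}",
            channel=ch,
            genotype="",
            bin_width=bin_width,
            start=start,
            counts=grid[:, ch - 1],
            schedule=schedule,
        )
        for ch in range(1, 33)
    ]


def write_dam(records: Sequence[ActivityRecord], path: str | Path) -> None:
    """Write 32 aligned records as a DAM2 monitor file (all statuses 1)."""
    if len(records) != 32:
        raise ValueError(f"a DAM2 file holds exactly 32 channels, got {len(records)}")
    first = records[0]
    if len(first.counts) == 0:
        raise ValueError("cannot write a monitor file with no readings")
    for rec in records[1:]:
        if (
            rec.bin_width != first.bin_width
            or rec.start != first.start
            or len(rec.counts) != len(first.counts)
        ):
            raise ValueError("records are misaligned (start/bin_width/length)")
    n = len(first.counts)
    stamps = [
        first.start + timedelta(minutes=i * first.bin_width) for i in range(n)
    ]
    mat = np.stack([rec.counts for rec in records], axis=1)
    lines = []
    for i, ts in enumerate(stamps):
        date = ts.strftime(_DATE_FORMAT).lstrip("0")
        head = [str(i + 1), date, ts.strftime("%H:%M:%S"), "1",
                "0", "0", "0", "0", "0", "0"]
        lines.append("\t".join(head + [str(v) for v in mat[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# binning and profiles
# ---------------------------------------------------------------------------

def resample(record: ActivityRecord, new_bin_width: int) -> ActivityRecord:
    """Sum counts into wider bins; a trailing partial group is dropped."""
    if new_bin_width % record.bin_width != 0:
        raise ValueError(
            f"new bin width {new_bin_width} is not a multiple of "
            f"{record.bin_width}"
        )
    k = new_bin_width // record.bin_width
    if k == 1:
        return ActivityRecord(
            record.fly_id, record.channel, record.genotype, record.bin_width,
            record.start, record.counts.copy(), record.schedule,
        )
    n = (len(record.counts) // k) * k
    summed = record.counts[:n].reshape(-1, k).sum(axis=1)
    return ActivityRecord(
        record.fly_id, record.channel, record.genotype, new_bin_width,
        record.start, summed, record.schedule,
    )


def population_profile(
    records: Sequence[ActivityRecord],
    day_from: int,
    day_to: int,
    profile_bin: int = 30,
) -> pd.DataFrame:
    """Mean ± SEM activity per clock-time bin over LD days.

    ``day_from``/``day_to`` are 1-based days within the LD phase.  Activity
    is averaged across the selected days within each fly first, then across
    flies, so flies contribute equally.  SEM uses n−1; with a single fly it
    is reported as missing.
    """
    if not records:
        raise ValueError("no records")
    profiles = []
    for rec in records:
        ld_offset = rec.schedule.phase_day_offset("LD")
        n_ld = rec.schedule.phase_n_days("LD")
        if not (1 <= day_from <= day_to <= n_ld):
            raise ValueError(
                f"day range {day_from}..{day_to} outside the LD phase "
                f"(1..{n_ld})"
            )
        binned = resample(rec, profile_bin) if profile_bin != rec.bin_width else rec
        days = binned.day_slice(ld_offset + day_from - 1, ld_offset + day_to - 1)
        per_day = 1440 // profile_bin
        profiles.append(days.reshape(-1, per_day).mean(axis=0))
    mat = np.stack(profiles)
    mean = mat.mean(axis=0)
    if len(records) > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(len(records))
    else:
        sem = np.full(mat.shape[1], np.nan)
    clock = np.arange(mat.shape[1]) * profile_bin / 60.0
    return pd.DataFrame(
        {"clock_time": clock, "mean": mean, "sem": sem, "n": len(records)}
    )
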