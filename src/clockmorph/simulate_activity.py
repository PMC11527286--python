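"""Synthetic fly locomotor-activity generator (LD entrainment then DD).

Counts are drawn per bin from an inhomogeneous Poisson law whose rate traces
a bimodal daily waveform: two wrapped-Gaussian bumps at a morning and an
evening peak phase.  During LD the waveform is locked to the 24 h zeitgeber;
at the LD→DD transition the internal cycle continues from the entrained
phase but advances at the fly's free-running period.  LD masking is modelled
as entrainment of phase only — no lights-on startle or lights-off suppression
transients — which keeps the generator minimal.

The waveform is normalised so the mean rate over a cycle equals the baseline
rate regardless of amplitude, decoupling rhythm strength from total
activity.  Arrhythmic flies emit a homogeneous Poisson stream at the
baseline rate.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dam import ActivityRecord, LightSchedule, write_dam

__all__ = ["ActivityGenParams", "generate_fly", "generate_cohort", "save_cohort"]


@dataclass(frozen=True)
class ActivityGenParams:
    """Controls for one genotype's activity cohort.

    ``amplitude`` scales the bimodal waveform (0 = flat); peak phases are in
    hours after lights-on within the (possibly non-24 h) cycle.  The first
    ``ceil(arrhythmic_fraction * n_flies)`` fly indices are constant-rate.
    """

    n_flies: int = 32
    schedule: LightSchedule = field(default_factory=LightSchedule)
    period_h: float = 24.0
    baseline_rate: float = 1.0  # counts per minute
    amplitude: float = 2.0
    morning_peak_phase: float = 0.5
    evening_peak_phase: float = 11.5
    peak_width_h: float = 1.5
    arrhythmic_fraction: float = 0.0
    bin_width: int = 1
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_flies < 1:
            bad.append("n_flies >= 1")
        if self.baseline_rate < 0:
            bad.append("baseline_rate >= 0")
        if self.amplitude < 0:
            bad.append("amplitude >= 0")
        if not 4.0 <= self.period_h <= 48.0:
            bad.append("period_h in [4, 48]")
        if not 0.0 <= self.arrhythmic_fraction <= 1.0:
            bad.append("0 <= arrhythmic_fraction <= 1")
        if self.peak_width_h <= 0:
            bad.append("peak_width_h > 0")
        if self.bin_width < 1 or 60 % self.bin_width != 0:
            bad.append("bin_width divides 60")
        if bad:
            raise ValueError("invalid ActivityGenParams: " + "; ".join(bad))

    def n_arrhythmic(self) -> int:
        return math.ceil(self.arrhythmic_fraction * self.n_flies)


def _bimodal_template(phase_h: np.ndarray, params: ActivityGenParams) -> np.ndarray:
    """Non-negative bimodal waveform g(phase) of circular phase in hours."""
    g = np.zeros_like(phase_h)
    for peak in (params.morning_peak_phase, params.evening_peak_phase):
        delta = (phase_h - peak + 12.0) % 24.0 - 12.0  # wrapped difference
        g += np.exp(-0.5 * (delta / params.peak_width_h) ** 2)
    return g


def _rate_profile(params: ActivityGenParams) -> np.ndarray:
    """Expected counts per bin over the whole schedule."""
    sched = params.schedule
    n_bins = sched.total_days * 1440 // params.bin_width
    t_h = (np.arange(n_bins) + 0.5) * params.bin_width / 60.0  # hours from start

    # circadian phase in "cycle hours" after lights-on
    phase = np.empty(n_bins)
    t0 = 0.0  # hours elapsed at the start of the current schedule phase
    phi0 = 0.0  # cycle phase at that moment
    for regime, n_days, _, _ in sched.phases:
        span = n_days * 24.0
        sel = (t_h >= t0) & (t_h < t0 + span + 1e-9)
        speed = 1.0 if regime == "LD" else 24.0 / params.period_h
        phase[sel] = (phi0 + (t_h[sel] - t0) * speed) % 24.0
        phi0 = (phi0 + span * speed) % 24.0
        t0 += span

    g = _bimodal_template(phase, params)
    # normalise so the cycle-mean rate equals the baseline whatever the
    # amplitude: lam = base * (1 + a*g) / (1 + a*mean(g))
    dense = _bimodal_template(np.linspace(0.0, 24.0, 2881)[:-1], params)
    scale = 1.0 + params.amplitude * float(dense.mean())
    lam = params.baseline_rate * (1.0 + params.amplitude * g) / scale
    return lam * params.bin_width


def generate_fly(params: ActivityGenParams, fly_index: int,
                 genotype: str = "") -> ActivityRecord:
    """One fly's ActivityRecord; reproducible from (seed, fly_index)."""
    params.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence((int(params.seed), int(fly_index)))
    )
    arrhythmic = fly_index < params.n_arrhythmic()
    sched = params.schedule
    n_bins = sched.total_days * 1440 // params.bin_width
    if arrhythmic:
        lam = np.full(n_bins, params.baseline_rate * params.bin_width)
    else:
        lam = _rate_profile(params)
    counts = rng.poisson(lam)
    return ActivityRecord(
        fly_id=f"{genotype or 'fly'}#{fly_index:03d}",
        channel=fly_index % 32 + 1,
        genotype=genotype,
        bin_width=params.bin_width,
        start=sched.start_datetime,
        counts=counts,
        schedule=sched,
    )


def generate_cohort(
    params_by_genotype: Mapping[str, ActivityGenParams], seed: int = 0
) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Per-genotype cohorts plus a ground-truth manifest.

    Each fly's RNG stream is derived counter-style from (seed, genotype,
    fly index), so generation order is irrelevant.  The manifest records the
    programmed ground truth (rhythmic flag and period) per fly.
    """
    records: list[ActivityRecord] = []
    rows = []
    for genotype, params in params_by_genotype.items():
        params.validate()
        gen_key = zlib.crc32(genotype.encode())
        for i in range(params.n_flies):
            sub = np.random.SeedSequence((int(seed), gen_key, i))
            fly_params = ActivityGenParams(
                **{**params.__dict__, "seed": int(sub.generate_state(1)[0] % 2**31)}
            )
            rec = generate_fly(fly_params, i, genotype=genotype)
            records.append(rec)
            rows.append(
                {
                    "fly_id": rec.fly_id,
                    "genotype": genotype,
                    "rhythmic": i >= params.n_arrhythmic(),
                    "period_h": params.period_h if i >= params.n_arrhythmic() else np.nan,
                }
            )
    manifest = pd.DataFrame(rows)
    return records, manifest


def save_cohort(
    records: list[ActivityRecord], manifest: pd.DataFrame, out_dir: str | Path
) -> list[Path]:
    """Write records into DAM2 monitor files (32 channels each) + manifest.

    The final monitor is padded with silent dummy channels when the cohort
    size is not a multiple of 32; dummies are absent from the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = manifest.copy()
    manifest["monitor"] = ""
    manifest["channel"] = 0
    for m, lo in enumerate(range(0, len(records), 32)):
        chunk = list(records[lo:lo + 32])
        template = chunk[0]
        aligned = []
        for ch, rec in enumerate(chunk, start=1):
            aligned.append(
                ActivityRecord(rec.fly_id, ch, rec.genotype, rec.bin_width,
                               rec.start, rec.counts, rec.schedule)
            )
        while len(aligned) < 32:
            aligned.append(
                ActivityRecord(
                    f"empty#{len(aligned) + 1:02d}", len(aligned) + 1, "",
                    template.bin_width, template.start,
                    np.zeros_like(template.counts), template.schedule,
                )
            )
        name = f"Monitor{m + 1}.txt"
        write_dam(aligned, out_dir / name)
        paths.append(out_dir / name)
        for ch, rec in enumerate(chunk, start=1):
            manifest.loc[manifest["fly_id"] == rec.fly_id, ["monitor", "channel"]] = [
                name, ch,
            ]
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return paths
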