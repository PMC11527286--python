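"""End-to-end pipeline orchestration: simulate → measure → analyze → report.

A single YAML config drives the run.  Sections (all optional, at least one
required):

``simulate_morph``
    genotypes: mapping genotype → MorphGenParams overrides (or the name of a
    documented preset: control_adult, defasciculated_adult, misrouted_adult,
    control_l3); n_brains; seed.
``simulate_activity``
    genotypes: mapping genotype → ActivityGenParams overrides; seed.
``rhythm``
    PeriodogramConfig overrides.
``per_quant``
    IntensityGenParams overrides (with genotype_effects); stat.
``stats``
    measure: which morphometry column to compare across genotypes
    (default ventral_sholl); alpha; posthoc_adjust.

Outputs are TSV tables plus a run log with seeds, written into the output
directory; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .intensity import (
    IntensityGenParams,
    brain_cluster_average,
    generate_intensity_dataset,
    write_cells_tsv,
)
from .morphometry import measure_cohort
from .rhythm import PeriodogramConfig, analyze_records, summary_table
from .simulate_activity import ActivityGenParams, generate_cohort as gen_activity
from .simulate_activity import save_cohort as save_activity
from .simulate_morphology import (
    CONTROL_ADULT,
    CONTROL_L3,
    DEFASCICULATED_ADULT,
    MISROUTED_ADULT,
    MorphGenParams,
    generate_cohort as gen_morph,
)
from .stats import GroupData, compare_groups, significance_stars
from .traces import save_cohort as save_brains

logger = logging.getLogger(__name__)

_MORPH_PRESETS = {
    "control_adult": CONTROL_ADULT,
    "defasciculated_adult": DEFASCICULATED_ADULT,
    "misrouted_adult": MISROUTED_ADULT,
    "control_l3": CONTROL_L3,
}

_SECTIONS = {"simulate_morph", "simulate_activity", "rhythm", "per_quant", "stats"}


class ConfigError(ValueError):
    """All config schema violations, collected."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid config:\n  " + "\n  ".join(problems))


def _morph_params(spec: Any, problems: list[str], where: str) -> MorphGenParams | None:
    if isinstance(spec, str):
        if spec not in _MORPH_PRESETS:
            problems.append(f"{where}: unknown preset {spec!r}")
            return None
        return _MORPH_PRESETS[spec]
    if isinstance(spec, Mapping):
        base = _MORPH_PRESETS.get(spec.get("preset", "control_adult"))
        if base is None:
            problems.append(f"{where}: unknown preset {spec.get('preset')!r}")
            return None
        overrides = {k: v for k, v in spec.items() if k != "preset"}
        known = {f.name for f in dataclasses.fields(MorphGenParams)}
        bad = set(overrides) - known
        if bad:
            problems.append(f"{where}: unknown fields {sorted(bad)}")
            return None
        for key in ("path_waypoints", "optic_tract_span"):
            if key in overrides:
                overrides[key] = tuple(tuple(p) for p in overrides[key])
        try:
            params = dataclasses.replace(base, **overrides)
            params.validate()
            return params
        except (TypeError, ValueError) as exc:
            problems.append(f"{where}: {exc}")
            return None
    problems.append(f"{where}: expected preset name or mapping")
    return None


def _activity_params(spec: Any, problems: list[str], where: str
                     ) -> ActivityGenParams | None:
    if not isinstance(spec, Mapping):
        problems.append(f"{where}: expected a mapping")
        return None
    known = {f.name for f in dataclasses.fields(ActivityGenParams)}
    bad = set(spec) - known
    if bad:
        problems.append(f"{where}: unknown fields {sorted(bad)}")
        return None
    try:
        params = ActivityGenParams(**spec)
        params.validate()
        return params
    except (TypeError, ValueError) as exc:
        problems.append(f"{where}: {exc}")
        return None


def load_config(path: str | Path) -> dict:
    """Parse and validate a pipeline config; raises ConfigError collectively."""
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw)


def validate_config(raw: Any) -> dict:
    problems: list[str] = []
    if not isinstance(raw, Mapping):
        raise ConfigError(["top level must be a mapping"])
    unknown = set(raw) - _SECTIONS - {"seed", "out_dir"}
    if unknown:
        problems.append(f"unknown sections {sorted(unknown)}")
    if not (_SECTIONS & set(raw)):
        problems.append(f"need at least one of {sorted(_SECTIONS)}")

    cfg: dict = {"seed": int(raw.get("seed", 0))}
    if "simulate_morph" in raw:
        sec = raw["simulate_morph"]
        genotypes = {}
        for name, spec in (sec.get("genotypes") or {}).items():
            p = _morph_params(spec, problems, f"simulate_morph.genotypes.{name}")
            if p is not None:
                genotypes[name] = p
        if not genotypes:
            problems.append("simulate_morph: no valid genotypes")
        cfg["simulate_morph"] = {
            "genotypes": genotypes,
            "n_brains": int(sec.get("n_brains", 15)),
        }
    if "simulate_activity" in raw:
        sec = raw["simulate_activity"]
        genotypes = {}
        for name, spec in (sec.get("genotypes") or {}).items():
            p = _activity_params(spec, problems,
                                 f"simulate_activity.genotypes.{name}")
            if p is not None:
                genotypes[name] = p
        if not genotypes:
            problems.append("simulate_activity: no valid genotypes")
        cfg["simulate_activity"] = {"genotypes": genotypes}
    if "rhythm" in raw:
        try:
            cfg["rhythm"] = PeriodogramConfig(**(raw["rhythm"] or {}))
        except (TypeError, ValueError) as exc:
            problems.append(f"rhythm: {exc}")
    if "per_quant" in raw:
        sec = dict(raw["per_quant"] or {})
        stat = sec.pop("stat", "normalized")
        try:
            cfg["per_quant"] = {
                "params": IntensityGenParams(**sec),
                "stat": stat,
            }
        except (TypeError, ValueError) as exc:
            problems.append(f"per_quant: {exc}")
    if "stats" in raw:
        sec = raw["stats"] or {}
        cfg["stats"] = {
            "measure": sec.get("measure", "ventral_sholl"),
            "alpha": float(sec.get("alpha", 0.05)),
            "posthoc_adjust": sec.get("posthoc_adjust", "bonferroni"),
        }
    if problems:
        raise ConfigError(problems)
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns a dict of output paths."""
    if not isinstance(config, dict) or "seed" not in config:
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    outputs: dict[str, Path] = {}
    log_lines = [f"clockmorph {__version__}", f"seed {seed}"]

    measures = None
    if "simulate_morph" in config:
        sec = config["simulate_morph"]
        brains = gen_morph(sec["genotypes"], sec["n_brains"], seed=seed)
        save_brains(brains, out_dir / "brains")
        measures = measure_cohort(brains)
        path = out_dir / "morphometry.tsv"
        measures.to_csv(path, sep="\t", index=False)
        outputs["morphometry"] = path
        log_lines.append(
            f"simulate_morph: {len(brains)} brains, "
            f"{len(sec['genotypes'])} genotypes"
        )

    if "simulate_activity" in config:
        sec = config["simulate_activity"]
        records, manifest = gen_activity(sec["genotypes"], seed=seed)
        save_activity(records, manifest, out_dir / "activity")
        rcfg = config.get("rhythm", PeriodogramConfig())
        genotype_map = dict(zip(manifest["fly_id"], manifest["genotype"]))
        calls, summaries = analyze_records(records, genotype_map, rcfg)
        calls_df = pd.DataFrame([c.__dict__ for c in calls])
        calls_path = out_dir / "rhythm_calls.tsv"
        calls_df.to_csv(calls_path, sep="\t", index=False)
        summary_path = out_dir / "rhythm_summary.tsv"
        summary_table(summaries).to_csv(summary_path, sep="\t", index=False)
        outputs["rhythm_calls"] = calls_path
        outputs["rhythm_summary"] = summary_path
        log_lines.append(f"simulate_activity: {len(records)} flies")

    if "per_quant" in config:
        sec = config["per_quant"]
        cells = generate_intensity_dataset(sec["params"])
        write_cells_tsv(cells, out_dir / "cells.tsv")
        brains_df = brain_cluster_average(cells, stat=sec["stat"])
        path = out_dir / "per_brain_intensity.tsv"
        brains_df.to_csv(path, sep="\t", index=False)
        outputs["per_brain_intensity"] = path
        log_lines.append(f"per_quant: {len(cells)} cells")

    if "stats" in config and measures is not None:
        sec = config["stats"]
        col = sec["measure"]
        groups = [
            GroupData(genotype, tuple(sub[col].dropna()))
            for genotype, sub in measures.groupby("genotype")
        ]
        # groups too small for the omnibus normality screen fall back to
        # the nonparametric branch
        override = (
            "nonparametric" if any(len(g.values) < 8 for g in groups) else None
        )
        report = compare_groups(groups, gate_override=override,
                                alpha=sec["alpha"],
                                posthoc_adjust=sec["posthoc_adjust"])
        path = out_dir / "stats_report.json"
        payload = {
            "measure": col,
            "chosen_test": report.chosen_test,
            "gate": report.gate,
            "statistic": report.statistic,
            "p_value": report.p_value,
            "stars": significance_stars(report.p_value),
            "posthoc": [
                {"pair": list(pp.pair), "p_raw": pp.p_raw,
                 "p_adjusted": pp.p_adjusted}
                for pp in report.posthoc
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        outputs["stats_report"] = path
        log_lines.append(f"stats: {col} via {report.chosen_test}")

    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    outputs["log"] = out_dir / "run.log"
    return outputs
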