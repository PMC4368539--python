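"""End-to-end orchestration: simulate -> preprocess -> compare -> classify -> report.

Every stage's output is persisted as TSV in the output directory and the
run is deterministic given the seed.  A ``classify_only`` run skips the
simulation and statistics and classifies the packaged published-table
fixture instead.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comparisons, fixtures, preprocess, reporting, simulate
from .patterns import ClassifierConfig, PatternCode, classify_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    design: simulate.DesignSpec = field(default_factory=simulate.DesignSpec)
    noise: simulate.NoiseSpec = field(default_factory=simulate.NoiseSpec)
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    stats: comparisons.StatsConfig = field(default_factory=comparisons.StatsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    # (protein, region, fraction) -> (archetype, nl_magnitude, baseline_magnitude)
    archetypes: dict = field(default_factory=dict)
    classify_only: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs: dict = {}
        sections = {
            "design": simulate.DesignSpec,
            "noise": simulate.NoiseSpec,
            "preprocess": preprocess.PreprocessConfig,
            "stats": comparisons.StatsConfig,
            "classifier": ClassifierConfig,
        }
        for name, typ in sections.items():
            if name in raw:
                try:
                    kwargs[name] = typ(**raw[name])
                except TypeError as exc:
                    raise KeyError(f"bad configuration in section {name!r}: {exc}") from None
        if "archetypes" in raw:
            arch = {}
            for entry in raw["archetypes"]:
                key = (entry["protein"], entry["region"], entry["fraction"])
                arch[key] = (
                    entry["archetype"],
                    float(entry.get("nl_magnitude", 20.0)),
                    entry.get("baseline_magnitude"),
                )
            kwargs["archetypes"] = arch
        for name in ("classify_only", "seed"):
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)


def _stage(log: list[str], name: str, func, *args, **kwargs):
    log.append(f"{datetime.datetime.now().isoformat()} start {name}")
    try:
        out = func(*args, **kwargs)
    except Exception as exc:
        log.append(f"{datetime.datetime.now().isoformat()} FAILED {name}: {exc}")
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.append(f"{datetime.datetime.now().isoformat()} done {name}")
    return out


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns the stage outputs and writes them to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    log: list[str] = [f"{datetime.datetime.now().isoformat()} pipeline seed={seed}"]
    outputs: dict[str, pd.DataFrame] = {}

    if config.classify_only:
        results = _stage(log, "load-fixture", fixtures.table3_results)
    else:
        effect_map = {
            key: simulate.archetype_to_effects(arch, nl, base)
            for key, (arch, nl, base) in config.archetypes.items()
        }
        effects = _stage(
            log, "effects", simulate.effects_table, config.design, effect_map or None
        )
        measurements = _stage(
            log, "simulate", simulate.simulate_measurements,
            config.design, effects, config.noise, seed,
        )
        outputs["measurements"] = measurements
        measurements.to_csv(out_dir / "measurements.tsv", sep="\t", index=False)

        normalized = _stage(log, "preprocess", preprocess.preprocess, measurements, config.preprocess)
        outputs["normalized"] = normalized
        normalized.to_csv(out_dir / "normalized.tsv", sep="\t", index=False)
        n_flagged = int((~preprocess.usable_mask(normalized)).sum())
        log.append(f"  excluded spots: {n_flagged} of {len(normalized)}")

        results = _stage(log, "compare", comparisons.fit_battery, normalized, config.stats)
        n_fallback = int((results["method"] == "nested_means").sum())
        log.append(f"  nested-means fallbacks: {n_fallback} of {len(results)} fits")
        for (reg, frac), sub in results.groupby(["region", "fraction"]):
            log.append(f"  family {reg}/{frac}: m={int(sub['m_tests'].max())} proteins")
    outputs["results"] = results
    results.to_csv(out_dir / "results.tsv", sep="\t", index=False)

    assignments = _stage(log, "classify", classify_all, results, config.classifier)
    outputs["assignments"] = assignments
    assignments.to_csv(out_dir / "assignments.tsv", sep="\t", index=False)

    counts = _stage(log, "report-counts", reporting.summarize_counts, results)
    outputs["counts"] = counts
    counts.to_csv(out_dir / "counts.tsv", sep="\t", index=False)

    roster = _stage(log, "report-roster", reporting.build_roster, assignments)
    roster_out = roster.copy()
    roster_out["protein"] = roster_out["protein"].map(",".join)
    outputs["roster"] = roster
    roster_out.to_csv(out_dir / "roster.tsv", sep="\t", index=False)

    totals = _stage(log, "report-totals", reporting.family_totals, assignments)
    outputs["family_totals"] = totals
    totals.to_csv(out_dir / "family_totals.tsv", sep="\t", index=False)

    (out_dir / "log.txt").write_text("\n".join(log) + "\n")
    return outputs
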