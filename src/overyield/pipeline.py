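"""Reproducible simulate -> effects -> analyze pipeline with a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .effects import BASELINES, effects_table
from .inference import ModelSpec, analyze
from .schema import (accumulate_annual, read_harvest_table,
                     validate_harvest_frame, write_table)
from .simulate import SyntheticConfig, scenario_presets, simulate

log = logging.getLogger("overyield")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (structured text / YAML).

    ``simulate`` either names a preset, embeds a generator config, or is
    None when ``harvests`` points at an existing harvest table (the simulate
    stage is then skipped).  ``analyses`` lists model specifications for the
    analyze stage.
    """

    simulate: dict | None = field(default_factory=lambda: {"preset": "null"})
    harvests: str | None = None
    baselines: tuple = tuple(BASELINES)
    clover_ryc_n1: bool = False
    strict_harvests: bool = True
    analyses: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
        if "baselines" in raw:
            raw["baselines"] = tuple(raw["baselines"])
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baselines"] = list(self.baselines)
        d["analyses"] = [dict(a) for a in self.analyses]
        return d


def resolve_generator_config(section: dict | None, seed: int) -> SyntheticConfig:
    """Turn the ``simulate`` config section into a SyntheticConfig."""
    section = dict(section or {})
    preset = section.pop("preset", None)
    if preset is not None:
        cfg = scenario_presets()[preset]
        if section:
            cfg = cfg.replace(**section)
    else:
        cfg = SyntheticConfig.from_dict(section)
    return cfg.replace(seed=seed)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    tool_version: str
    config_hash: str
    seed: int
    started: str
    finished: str = ""
    status: str = "running"
    failed_stage: str | None = None
    outputs: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    flagged_counts: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def _config_hash(config: PipelineConfig) -> str:
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_pipeline(config: PipelineConfig, outdir, seed: int = 0) -> RunManifest:
    """Execute the pipeline stages in order, writing all tables and a manifest.

    Stages: simulate (skipped when ``config.harvests`` is given), effects
    (both baselines by default), analyze (one sequential-test table and
    selection path per requested analysis).  Any stage is re-runnable from
    its predecessor's output file.  On stage failure the manifest records
    the failed stage and the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_config_hash(config),
        seed=seed,
        started=_now(),
    )
    mpath = outdir / "manifest.json"
    stage = "simulate"
    try:
        if config.harvests:
            log.info("reading harvest table %s", config.harvests)
            harvests = read_harvest_table(config.harvests)
        else:
            gcfg = resolve_generator_config(config.simulate, seed)
            log.info("simulating harvest data (seed=%d)", seed)
            harvests = simulate(gcfg)
            hpath = outdir / "harvests.csv"
            write_table(harvests, hpath)
            manifest.outputs["harvests"] = str(hpath)
            manifest.row_counts["harvests"] = len(harvests)
            harvests = validate_harvest_frame(harvests)

        stage = "effects"
        annual = accumulate_annual(harvests, strict=config.strict_harvests)
        apath = outdir / "annual.csv"
        write_table(annual, apath)
        manifest.outputs["annual"] = str(apath)
        manifest.row_counts["annual"] = len(annual)

        effects, species = effects_table(
            annual,
            baselines=tuple(config.baselines),
            clover_ryc_n1=config.clover_ryc_n1,
        )
        epath, spath = outdir / "effects.csv", outdir / "species.csv"
        write_table(effects, epath)
        write_table(species, spath)
        manifest.outputs["effects"] = str(epath)
        manifest.outputs["species"] = str(spath)
        manifest.row_counts["effects"] = len(effects)
        manifest.row_counts["species"] = len(species)
        manifest.flagged_counts["effects"] = int((effects["flags"] != "").sum())
        manifest.flagged_counts["species"] = int((species["flags"] != "").sum())

        stage = "analyze"
        for a in config.analyses:
            a = dict(a)
            spec = ModelSpec(
                response=a["response"],
                baseline=a.get("baseline", "N0"),
                species=a.get("species"),
                transform=a.get("transform", "auto"),
            )
            table = species if spec.response == "RY_C" else effects
            tag = spec.response + (f"_{spec.species}" if spec.species else "")
            tag = f"{tag}_{spec.baseline}"
            log.info("analyzing %s", tag)
            sel, tests = analyze(table, spec)
            tpath = outdir / f"anova_{tag}.csv"
            ppath = outdir / f"selection_{tag}.csv"
            tests.to_csv(tpath, index=False)
            sel.path_table().to_csv(ppath, index=False)
            manifest.outputs[f"anova_{tag}"] = str(tpath)
            manifest.row_counts[f"anova_{tag}"] = len(tests)
            manifest.outputs[f"selection_{tag}"] = str(ppath)
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.finished = _now()
        manifest.write(mpath)
        raise
    manifest.status = "ok"
    manifest.finished = _now()
    manifest.outputs["manifest"] = str(mpath)
    manifest.write(mpath)
    return manifest
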