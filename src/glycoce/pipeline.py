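"""Pipeline orchestration: simulate -> ingest -> fit-curves -> features ->
model -> evaluate-gain, with schema-checked YAML config, derived per-stage
seeds, checksummed outputs, and resumable re-runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import ce_model, curve_opt, modeling, report_io, smart_ce, synth_data
from .ce_model import CECalibration, CESweepGrid
from .curve_opt import EligibilityPolicy
from .glyco_chem import (
    GlycopeptideSpecies,
    PeptideBackbone,
    parse_glycan_composition,
    feature_table,
)
from .synth_data import DEFAULT_PERSONAS, PersonaParams

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "StageError",
    "validate_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration; message names the offending key."""


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 1
    n_species: int = 300
    out_dir: str = "glycoce_run"
    calibration: CECalibration = field(default_factory=CECalibration)
    grid: CESweepGrid = field(default_factory=ce_model.sweep_grid)
    policy: EligibilityPolicy = field(default_factory=EligibilityPolicy)
    personas: Mapping[str, PersonaParams] = field(default_factory=lambda: dict(DEFAULT_PERSONAS))
    delta_r2: float = 0.01
    alpha_interaction: float = 0.05
    gain_mode: str = "loo"
    gain_channel: str = "byonic"
    p_duplicate: float = 0.05


_KNOWN_TOP_KEYS = {"seed", "n_species", "out_dir", "ce", "eligibility",
                   "personas", "modeling", "smart_ce"}
_KNOWN_CE_KEYS = {"anchor_low", "anchor_high", "ceiling", "grid"}
_KNOWN_GRID_KEYS = {"start", "stop", "step"}
_KNOWN_ELIG_KEYS = {"min_score", "min_consecutive", "min_points"}
_KNOWN_MODELING_KEYS = {"delta_r2", "alpha"}
_KNOWN_SMART_KEYS = {"mode", "channel"}
_PERSONA_FIELDS = {f.name for f in dataclasses.fields(PersonaParams)}


def _reject_unknown(mapping: Mapping, known: set, prefix: str) -> None:
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(f'{prefix}{k}' for k in unknown)}")


def _build_config(raw: Mapping[str, Any]) -> PipelineConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _KNOWN_TOP_KEYS, "")
    kwargs: dict[str, Any] = {}
    for key in ("seed", "n_species", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]

    ce_raw = raw.get("ce", {})
    _reject_unknown(ce_raw, _KNOWN_CE_KEYS, "ce.")
    cal_kwargs = {}
    for key, name in (("anchor_low", "anchor_low"), ("anchor_high", "anchor_high")):
        if key in ce_raw:
            pair = ce_raw[key]
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise ConfigError(f"ce.{key} must be a [m/z, eV] pair")
            cal_kwargs[name] = (float(pair[0]), float(pair[1]))
    if "ceiling" in ce_raw:
        ceiling = ce_raw["ceiling"]
        if not isinstance(ceiling, (int, float)) or ceiling <= 0:
            raise ConfigError("ce.ceiling must be a positive number")
        cal_kwargs["ceiling"] = float(ceiling)
    try:
        kwargs["calibration"] = CECalibration(**cal_kwargs)
    except ValueError as exc:
        raise ConfigError(f"ce: {exc}") from exc
    grid_raw = ce_raw.get("grid", {})
    _reject_unknown(grid_raw, _KNOWN_GRID_KEYS, "ce.grid.")
    try:
        kwargs["grid"] = ce_model.sweep_grid(
            grid_raw.get("start", 6.25), grid_raw.get("stop", 175.0),
            grid_raw.get("step", 6.25))
    except ValueError as exc:
        raise ConfigError(f"ce.grid: {exc}") from exc

    elig_raw = raw.get("eligibility", {})
    _reject_unknown(elig_raw, _KNOWN_ELIG_KEYS, "eligibility.")
    policy_kwargs = {}
    if "min_score" in elig_raw:
        policy_kwargs["min_score"] = {str(k): float(v)
                                      for k, v in elig_raw["min_score"].items()}
    for key in ("min_consecutive", "min_points"):
        if key in elig_raw:
            value = elig_raw[key]
            if not isinstance(value, int) or value < 1:
                raise ConfigError(f"eligibility.{key} must be a positive integer")
            policy_kwargs[key] = value
    kwargs["policy"] = EligibilityPolicy(**policy_kwargs)

    personas_raw = raw.get("personas")
    if personas_raw is not None:
        personas = {}
        for channel, spec_map in personas_raw.items():
            if channel not in report_io.CHANNELS:
                raise ConfigError(f"personas.{channel}: unknown score channel")
            _reject_unknown(spec_map, _PERSONA_FIELDS, f"personas.{channel}.")
            base = dict(DEFAULT_PERSONAS.get(channel, synth_data.PEPTIDE_CENTRIC).__dict__)
            base.update(spec_map)
            try:
                personas[channel] = PersonaParams(**base)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"personas.{channel}: {exc}") from exc
        kwargs["personas"] = personas

    modeling_raw = raw.get("modeling", {})
    _reject_unknown(modeling_raw, _KNOWN_MODELING_KEYS, "modeling.")
    if "delta_r2" in modeling_raw:
        kwargs["delta_r2"] = float(modeling_raw["delta_r2"])
    if "alpha" in modeling_raw:
        kwargs["alpha_interaction"] = float(modeling_raw["alpha"])

    smart_raw = raw.get("smart_ce", {})
    _reject_unknown(smart_raw, _KNOWN_SMART_KEYS, "smart_ce.")
    if "mode" in smart_raw:
        if smart_raw["mode"] not in ("loo", "insample"):
            raise ConfigError("smart_ce.mode must be 'loo' or 'insample'")
        kwargs["gain_mode"] = smart_raw["mode"]
    if "channel" in smart_raw:
        if smart_raw["channel"] not in report_io.CHANNELS:
            raise ConfigError("smart_ce.channel: unknown score channel")
        kwargs["gain_channel"] = smart_raw["channel"]
    return PipelineConfig(**kwargs)


def validate_config(path) -> PipelineConfig:
    """Load, default, and schema-check a YAML pipeline config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    return _build_config(raw)


# ---------------------------------------------------------------------------
# checksums, seeds, resumability

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a stable per-stage sub-seed from the root seed."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _config_hash(config: PipelineConfig) -> str:
    text = repr(dataclasses.asdict(config) if not dataclasses.is_dataclass(config)
                else config)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


class _Meta:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except json.JSONDecodeError:
                pass
        self.data.setdefault("stages", {})

    def stage_fresh(self, stage: str, outputs: list[Path]) -> bool:
        recorded = self.data["stages"].get(stage)
        if recorded is None:
            return False
        if set(recorded) != {str(p) for p in outputs}:
            return False
        return all(Path(p).exists() and _checksum(Path(p)) == digest
                   for p, digest in recorded.items())

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {str(p): _checksum(p) for p in outputs}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages

def _species_from_frame(frame: pd.DataFrame) -> list[GlycopeptideSpecies]:
    species = []
    for row in frame.itertuples(index=False):
        species.append(GlycopeptideSpecies(
            peptide=PeptideBackbone(sequence=row.sequence),
            glycan=parse_glycan_composition(row.glycan_composition),
            charge=int(row.charge)))
    return species


def _unique_species(table: report_io.ScoreTable) -> list[GlycopeptideSpecies]:
    seen: dict[tuple, GlycopeptideSpecies] = {}
    for rec in table.records:
        seen.setdefault(rec.species.key, rec.species)
    return [seen[k] for k in sorted(seen)]


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Execute all stages in order; completed stages whose outputs still match
    their recorded checksums are skipped.  Returns the run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = _Meta(out_dir / "meta.json")
    meta.data["config_hash"] = _config_hash(config)
    meta.data["seed"] = config.seed
    counts: dict[str, int] = {}

    reports_dir = out_dir / "reports"
    manifest_path = reports_dir / "manifest.tsv"
    table_path = out_dir / "score_table.tsv"
    optima_path = out_dir / "optima.tsv"
    features_path = out_dir / "features.tsv"
    model_path = out_dir / "model.json"
    gain_path = out_dir / "gain.json"

    def _stage(name, outputs, fn):
        if not force and meta.stage_fresh(name, outputs):
            logger.info("stage %s: up to date, skipped", name)
            return
        try:
            fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        meta.record(name, outputs)
        logger.info("stage %s: done", name)

    # --- simulate ---------------------------------------------------------
    def _simulate():
        species = synth_data.sample_species(
            config.n_species, stage_seed(config.seed, "sample"))
        records, _truth = synth_data.simulate_sweep(
            species, config.grid, config.personas,
            seed=stage_seed(config.seed, "sweep"), cal=config.calibration,
            p_duplicate=config.p_duplicate)
        synth_data.emit_reports(records, reports_dir, config.grid)
        counts["species_in"] = len(species)

    sim_outputs = [reports_dir / f"run_{i:02d}.tsv"
                   for i in range(len(config.grid.scale_percents))] + [manifest_path]
    _stage("simulate", sim_outputs, _simulate)

    # --- ingest -----------------------------------------------------------
    def _ingest():
        result = report_io.read_report_dir(reports_dir, manifest_path)
        table = report_io.aggregate_best_per_run(result.records)
        report_io.write_normalized(table.records, table_path)
        counts["records"] = len(table)

    _stage("ingest", [table_path], _ingest)

    # --- fit-curves -------------------------------------------------------
    def _fit_curves():
        result = report_io.read_report(table_path)
        table = report_io.aggregate_best_per_run(result.records)
        curves = curve_opt.build_curves(table, config.calibration, config.grid)
        optima = curve_opt.fit_optima(curves, config.policy)
        optima.to_csv(optima_path, sep="\t", index=False)
        counts["curves"] = len(curves)
        counts["fitted"] = len(optima)

    _stage("fit_curves", [optima_path], _fit_curves)

    # --- features ---------------------------------------------------------
    def _features():
        result = report_io.read_report(table_path)
        table = report_io.aggregate_best_per_run(result.records)
        species = _unique_species(table)
        feature_table(species).to_csv(features_path, sep="\t", index=False)

    _stage("features", [features_path], _features)

    # --- model ------------------------------------------------------------
    def _model():
        optima = pd.read_csv(optima_path, sep="\t")
        features = pd.read_csv(features_path, sep="\t")
        merged = optima.merge(features, on=["sequence", "glycan_composition", "charge"],
                              how="inner")
        report: dict[str, Any] = {"trendlines": {}, "glm": {}, "lasso": {}}
        for channel, sub in merged.groupby("channel"):
            if len(sub) < 3:
                continue
            tl = modeling.fit_trendline(sub["mz"], sub["optimal_ce_ev"], channel)
            report["trendlines"][channel] = dataclasses.asdict(tl)
            if len(sub) >= 20:
                glm = modeling.ancova(sub["optimal_ce_ev"], sub["hydrophobicity"].to_numpy(),
                                      sub["mz"], is_factor=False,
                                      alpha_interaction=config.alpha_interaction)
                report["glm"][channel] = {
                    "formula": glm.formula,
                    "interaction_p": glm.interaction_p,
                    "hydrophobicity_p": glm.covariate_p,
                }
                candidates = sub[list(modeling_feature_columns(features))]
                path = modeling.lasso_path(candidates, sub["optimal_ce_ev"].to_numpy())
                selected = modeling.select_features(path, config.delta_r2)
                report["lasso"][channel] = {
                    "selected_features": list(selected),
                    "full_r2": float(np.max(path.r_squared)),
                }
        model_path.write_text(json.dumps(report, indent=2, sort_keys=True))

    _stage("model", [model_path], _model)

    # --- evaluate-gain ----------------------------------------------------
    def _gain():
        channel = config.gain_channel
        optima = pd.read_csv(optima_path, sep="\t")
        optima = optima[optima["channel"] == channel]
        features = pd.read_csv(features_path, sep="\t")
        merged = optima.merge(features, on=["sequence", "glycan_composition", "charge"],
                              how="inner")
        result = report_io.read_report(table_path)
        table = report_io.aggregate_best_per_run(result.records)
        curves = curve_opt.build_curves(table, config.calibration, config.grid)
        curve_index = {(c.species.key, c.channel): c for c in curves}
        aligned_curves, keep = [], []
        for i, row in merged.iterrows():
            sp_key = ((row["sequence"]),
                      tuple(parse_glycan_composition(row["glycan_composition"]).counts().values()),
                      int(row["charge"]))
            curve = curve_index.get((sp_key, channel))
            if curve is not None:
                aligned_curves.append(curve)
                keep.append(i)
        merged = merged.loc[keep].reset_index(drop=True)
        report = smart_ce.evaluate_gain(
            aligned_curves, merged["optimal_ce_ev"].to_numpy(), merged,
            channel=channel, mode=config.gain_mode, cal=config.calibration)
        payload = {
            "channel": report.channel, "mode": report.mode, "n": report.n,
            "mean_gain_pct": report.mean_gain_pct,
            "bottom_quintile_mean_gain_pct": report.bottom_quintile_mean_gain_pct,
        }
        gain_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    _stage("evaluate_gain", [gain_path], _gain)

    meta.data["counts"] = counts
    meta.path.write_text(json.dumps(meta.data, indent=2, sort_keys=True))
    return out_dir


def modeling_feature_columns(features: pd.DataFrame) -> list[str]:
    """Numeric candidate columns for the lasso stage."""
    skip = {"sequence", "glycan_composition"}
    return [c for c in features.columns if c not in skip]
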