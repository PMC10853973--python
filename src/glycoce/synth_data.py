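"""Synthetic glycopeptide cohorts and CE-sweep report simulation.

Generates tryptic-like peptide backbones, a catalog of realistic N-glycan
compositions, and per-channel Gaussian score-vs-CE responses whose centers
depend linearly on m/z plus structural covariates.  Two engine personas are
provided: a peptide-centric one and a glycan-centric one whose mean optimum
is about half of the peptide-centric optimum at matched m/z.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ce_model import CECalibration, CESweepGrid, DEFAULT_CALIBRATION, DEFAULT_GRID, applied_ce
from .glyco_chem import (
    GlycanComposition,
    GlycopeptideSpecies,
    PeptideBackbone,
    feature_table,
)
from .report_io import IdentificationRecord, write_normalized, write_run_manifest

__all__ = [
    "PersonaParams",
    "SyntheticTruth",
    "CohortConfig",
    "PEPTIDE_CENTRIC",
    "GLYCAN_CENTRIC",
    "DEFAULT_PERSONAS",
    "weak_covariate_variant",
    "glycan_catalog",
    "sample_species",
    "true_optimum",
    "simulate_sweep",
    "emit_reports",
]

#: amino-acid background frequencies (rounded database averages); internal
#: K/R are excluded when sampling tryptic interiors, so they carry no weight
_AA_BACKGROUND = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9, "S": 6.6,
    "T": 5.3, "V": 6.9, "W": 1.1, "Y": 2.9,
}


@dataclass(frozen=True)
class PersonaParams:
    """Generator parameters for one search-engine score channel."""

    name: str
    intercept: float
    slope_mz: float
    coef_hydrophobicity: float
    coef_mobile_protons: float
    coef_glycan_mass: float
    optimum_noise_sd: float
    curve_sigma_mean: float
    peak_score_log_mean: float
    peak_score_log_sd: float
    detection_threshold: float
    multiplicative_score_noise_sd: float

    def __post_init__(self) -> None:
        if self.slope_mz <= 0:
            raise ValueError("slope_mz must be positive")
        if self.curve_sigma_mean <= 0:
            raise ValueError("curve_sigma_mean must be positive")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")


# peptide-backbone-focused engine: steep m/z slope, strong hydrophobicity
# effect, mild mobile-proton effect
PEPTIDE_CENTRIC = PersonaParams(
    name="peptide_centric",
    intercept=13.57,
    slope_mz=0.0607,
    coef_hydrophobicity=0.40,
    coef_mobile_protons=-1.5,
    coef_glycan_mass=-0.0025,
    optimum_noise_sd=2.0,
    curve_sigma_mean=16.0,
    peak_score_log_mean=math.log(500.0),
    peak_score_log_sd=0.6,
    detection_threshold=50.0,
    multiplicative_score_noise_sd=0.05,
)

# glycan-focused engine: optima roughly half of the peptide-centric ones at
# matched m/z, strong mobile-proton and glycan-mass effects, weak
# hydrophobicity effect
GLYCAN_CENTRIC = PersonaParams(
    name="glycan_centric",
    intercept=8.0,
    slope_mz=0.030,
    coef_hydrophobicity=0.05,
    coef_mobile_protons=-3.0,
    coef_glycan_mass=-0.003,
    optimum_noise_sd=2.0,
    curve_sigma_mean=12.0,
    peak_score_log_mean=math.log(60.0),
    peak_score_log_sd=0.6,
    detection_threshold=5.0,
    multiplicative_score_noise_sd=0.05,
)

#: default channel -> persona mapping used by the pipeline
DEFAULT_PERSONAS: Mapping[str, PersonaParams] = {
    "byonic": PEPTIDE_CENTRIC,
    "glycoquest": GLYCAN_CENTRIC,
}


def weak_covariate_variant(persona: PersonaParams) -> PersonaParams:
    """Copy of a persona with all structural covariate effects switched off
    (optimum depends on m/z only)."""
    return dataclasses.replace(
        persona,
        name=persona.name + "_weak",
        coef_hydrophobicity=0.0,
        coef_mobile_protons=0.0,
        coef_glycan_mass=0.0,
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated sweep, for recovery checks."""

    species: tuple[GlycopeptideSpecies, ...]
    features: pd.DataFrame
    true_mu: Mapping[str, np.ndarray]
    amplitudes: Mapping[str, np.ndarray]
    sigmas: Mapping[str, np.ndarray]
    personas: Mapping[str, PersonaParams]
    seed: int


@dataclass(frozen=True)
class CohortConfig:
    min_length: int = 7
    max_length: int = 25
    charges: tuple[int, ...] = (2, 3, 4)
    sequon: bool = True          # splice an N-X-S/T motif into each peptide
    p_duplicate: float = 0.05    # probability of a duplicate record per run


def glycan_catalog() -> tuple[GlycanComposition, ...]:
    """Built-in composition catalog: high-mannose Man5-Man9 plus complex
    bi/tri/tetra-antennary glycans with 0..n sialic acids and 0-1 fucose."""
    catalog = [GlycanComposition(hexnac=2, hex=h) for h in range(5, 10)]
    for antennae in (2, 3, 4):
        for n_sa in range(antennae + 1):
            for fuc in (0, 1):
                catalog.append(GlycanComposition(
                    hexnac=2 + antennae, hex=3 + antennae, neuac=n_sa, fuc=fuc))
    return tuple(catalog)


def _sample_peptide(rng: np.random.Generator, config: CohortConfig) -> str:
    letters = list(_AA_BACKGROUND)
    weights = np.array([_AA_BACKGROUND[a] for a in letters])
    weights = weights / weights.sum()
    length = int(rng.integers(config.min_length, config.max_length + 1))
    interior = rng.choice(letters, size=length - 1, p=weights)
    cterm = "K" if rng.random() < 0.5 else "R"
    seq = list(interior) + [cterm]
    if config.sequon and length >= 4:
        # overwrite three interior residues with an N-X-S/T sequon
        pos = int(rng.integers(0, length - 3))
        x = rng.choice([a for a in letters if a != "P"])
        seq[pos] = "N"
        seq[pos + 1] = x
        seq[pos + 2] = "S" if rng.random() < 0.5 else "T"
    return "".join(seq)


def sample_species(n: int, seed: int, config: CohortConfig = CohortConfig()
                   ) -> list[GlycopeptideSpecies]:
    """Sample a reproducible cohort of glycopeptide species.

    Peptides are tryptic-like (C-terminal K/R, no internal K/R) with lengths
    ``min_length..max_length``; glycans come from the built-in catalog;
    charges 2-4 are weighted by total mass (heavier species charge higher).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    catalog = glycan_catalog()
    species: list[GlycopeptideSpecies] = []
    from .glyco_chem import glycan_mass, peptide_mass  # local to avoid cycle noise
    for _ in range(n):
        seq = _sample_peptide(rng, config)
        glycan = catalog[int(rng.integers(0, len(catalog)))]
        pep = PeptideBackbone(sequence=seq)
        total = peptide_mass(pep) + glycan_mass(glycan)
        expected_z = np.clip(total / 1300.0, min(config.charges), max(config.charges))
        z = int(np.clip(round(expected_z + rng.normal(0.0, 0.7)),
                        min(config.charges), max(config.charges)))
        species.append(GlycopeptideSpecies(peptide=pep, glycan=glycan, charge=z))
    return species


def true_optimum(features_row: Mapping[str, float], persona: PersonaParams,
                 rng: np.random.Generator | None = None,
                 ceiling: float = 200.0) -> float:
    """Ground-truth optimal CE for one species under a persona.

    Linear in m/z, hydrophobicity, mobile protons and glycan mass, plus
    Gaussian noise when an ``rng`` is supplied; clipped to [5, ceiling].
    """
    mu = (persona.intercept
          + persona.slope_mz * float(features_row["mz"])
          + persona.coef_hydrophobicity * float(features_row["hydrophobicity"])
          + persona.coef_mobile_protons * float(features_row["mobile_protons"])
          + persona.coef_glycan_mass * float(features_row["glycan_mass"]))
    if rng is not None and persona.optimum_noise_sd > 0:
        mu += rng.normal(0.0, persona.optimum_noise_sd)
    return float(np.clip(mu, 5.0, ceiling))


def _run_id(grid_index: int) -> str:
    return f"run_{grid_index:02d}"


def simulate_sweep(species: Sequence[GlycopeptideSpecies],
                   grid: CESweepGrid = DEFAULT_GRID,
                   personas: Mapping[str, PersonaParams] = DEFAULT_PERSONAS,
                   seed: int = 0,
                   cal: CECalibration = DEFAULT_CALIBRATION,
                   p_duplicate: float = 0.05,
                   ) -> tuple[tuple[IdentificationRecord, ...], SyntheticTruth]:
    """Simulate the CE sweep for every species and score channel.

    Scores follow ``A * exp(-(CE - mu)^2 / (2 sigma^2)) * (1 + eps)`` with
    multiplicative Gaussian noise; records are emitted only above each
    persona's detection threshold, and duplicate within-run identifications
    are injected with probability ``p_duplicate`` to exercise deduplication.
    """
    rng = np.random.default_rng(seed)
    features = feature_table(species)
    mzs = features["mz"].to_numpy()
    hydro = features["hydrophobicity"].to_numpy()
    rts = np.clip(60.0 + 1.2 * hydro + rng.normal(0.0, 2.0, len(species)), 1.0, None)

    true_mu: dict[str, np.ndarray] = {}
    amplitudes: dict[str, np.ndarray] = {}
    sigmas: dict[str, np.ndarray] = {}
    records: list[IdentificationRecord] = []

    for channel in sorted(personas):
        persona = personas[channel]
        mu = np.array([true_optimum(features.iloc[i], persona, rng, cal.ceiling)
                       for i in range(len(species))])
        amp = rng.lognormal(persona.peak_score_log_mean, persona.peak_score_log_sd,
                            len(species))
        sig = np.clip(rng.normal(persona.curve_sigma_mean,
                                 0.15 * persona.curve_sigma_mean, len(species)),
                      3.0, None)
        true_mu[channel] = mu
        amplitudes[channel] = amp
        sigmas[channel] = sig
        for grid_index, scale in enumerate(grid.scale_percents):
            run_id = _run_id(grid_index)
            ce = applied_ce(mzs, scale, cal)
            noise = rng.normal(0.0, persona.multiplicative_score_noise_sd,
                               len(species)) if persona.multiplicative_score_noise_sd > 0 \
                else np.zeros(len(species))
            scores = amp * np.exp(-((ce - mu) ** 2) / (2.0 * sig ** 2)) * (1.0 + noise)
            scores = np.clip(scores, 0.0, None)
            dup_draws = rng.random(len(species))
            dup_factors = rng.uniform(0.6, 0.95, len(species))
            for i, sp in enumerate(species):
                if scores[i] > persona.detection_threshold:
                    records.append(IdentificationRecord(
                        run_id=run_id, scale_pct=scale, species=sp,
                        channel=channel, score=float(scores[i]),
                        retention_time=float(rts[i])))
                    dup_score = scores[i] * dup_factors[i]
                    if dup_draws[i] < p_duplicate and dup_score > persona.detection_threshold:
                        records.append(IdentificationRecord(
                            run_id=run_id, scale_pct=scale, species=sp,
                            channel=channel, score=float(dup_score),
                            retention_time=float(rts[i] + 0.3)))
    truth = SyntheticTruth(
        species=tuple(species), features=features, true_mu=true_mu,
        amplitudes=amplitudes, sigmas=sigmas, personas=dict(personas), seed=seed)
    return tuple(records), truth


def emit_reports(records: Sequence[IdentificationRecord], out_dir,
                 grid: CESweepGrid = DEFAULT_GRID, dialect: str = "normalized") -> list[Path]:
    """Write one normalized TSV per sweep setting plus a run manifest.

    Settings with no surviving records get a header-only file.  Output is
    byte-identical for identical inputs.
    """
    if dialect != "normalized":
        raise ValueError(f"only the 'normalized' dialect is emitted, got {dialect!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_run: dict[str, list[IdentificationRecord]] = {
        _run_id(i): [] for i in range(len(grid.scale_percents))}
    for rec in records:
        by_run.setdefault(rec.run_id, []).append(rec)
    manifest = {_run_id(i): scale for i, scale in enumerate(grid.scale_percents)}
    paths = []
    for run_id in sorted(by_run):
        path = out_dir / f"{run_id}.tsv"
        write_normalized(by_run[run_id], path)
        paths.append(path)
    manifest_path = out_dir / "manifest.tsv"
    write_run_manifest(manifest, manifest_path)
    paths.append(manifest_path)
    return paths
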