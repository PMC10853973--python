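"""Reading search-engine report tables into a normalized long-format score
table keyed by (species, run, channel).

Vendor exports (Byonic/pGlyco/GlycoQuest) are abstracted as delimited-text
dialects with documented column maps; the normalized tab-separated schema is
the contract:

    run_id  scale_pct  sequence  glycan_composition  charge  channel  score
    retention_time_min
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glyco_chem import (
    GlycanComposition,
    GlycanParseError,
    GlycopeptideSpecies,
    PeptideBackbone,
    format_glycan_composition,
    parse_glycan_composition,
    peptide_mass,
)

__all__ = [
    "CHANNELS",
    "IdentificationRecord",
    "ScoreTable",
    "ReportReadResult",
    "SchemaError",
    "read_report",
    "read_report_dir",
    "read_run_manifest",
    "write_run_manifest",
    "aggregate_best_per_run",
    "write_normalized",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

CHANNELS = ("byonic", "pglyco_peptide", "pglyco_glycan", "pglyco_total", "glycoquest")

NORMALIZED_COLUMNS = (
    "run_id", "scale_pct", "sequence", "glycan_composition", "charge",
    "channel", "score", "retention_time_min",
)


class SchemaError(ValueError):
    """A report file does not match its dialect's required columns."""


@dataclass(frozen=True)
class IdentificationRecord:
    """One accepted identification of a species in one run for one score channel."""

    run_id: str
    scale_pct: float
    species: GlycopeptideSpecies
    channel: str
    score: float
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown score channel {self.channel!r}")
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")

    @property
    def key(self) -> tuple:
        return (self.species.key, self.run_id, self.channel)


@dataclass(frozen=True)
class ScoreTable:
    """Deduplicated records: at most one per (species, run, channel)."""

    records: tuple[IdentificationRecord, ...]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ReportReadResult:
    records: tuple[IdentificationRecord, ...]
    n_skipped: int


# ---------------------------------------------------------------------------
# dialect column maps (tab-separated re-expressions of the vendor exports)

BYONIC_COLUMNS = {
    "sequence": "Peptide",
    "glycan_composition": "Glycans",
    "charge": "z",
    "score": "Score",
    "retention_time_min": "Scan Time",
}

PGLYCO_COLUMNS = {
    "sequence": "Peptide",
    "glycan_composition": "GlycanComposition",
    "charge": "Charge",
    "peptide_score": "PepScore",
    "glycan_score": "GlyScore",
    "total_score": "TotalScore",
    "retention_time_min": "RT",
}

GLYCOQUEST_COLUMNS = {
    "peptide_mass": "PeptideMass",
    "glycan_composition": "GlycanComposition",
    "charge": "Charge",
    "score": "Score",
    "retention_time_min": "RT",
}

#: tolerance for matching GlycoQuest peptide masses against a species list
GLYCOQUEST_MASS_TOL_DA = 0.02


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty report file") from None
    return frame


def _optional_float(text: str) -> float | None:
    return float(text) if text not in ("", "NA", "nan") else None


def read_report(path, dialect: str = "normalized", *,
                run_id: str | None = None,
                scale_pct: float | None = None,
                species_list: Sequence[GlycopeptideSpecies] | None = None,
                ) -> ReportReadResult:
    """Read one report file into identification records.

    ``normalized`` files carry run_id and scale_pct columns themselves; the
    vendor dialects describe a single run, whose ``run_id``/``scale_pct`` must
    be supplied (typically from the run manifest).  Rows whose glycan text
    cannot be parsed are skipped with a warning and counted in ``n_skipped``.
    """
    frame = _read_tsv(path)
    if dialect == "normalized":
        return _read_normalized(frame, path)
    if run_id is None or scale_pct is None:
        raise ValueError(f"dialect {dialect!r} requires run_id and scale_pct")
    if dialect == "byonic":
        return _read_byonic(frame, path, run_id, scale_pct)
    if dialect == "pglyco":
        return _read_pglyco(frame, path, run_id, scale_pct)
    if dialect == "glycoquest":
        if species_list is None:
            raise ValueError("glycoquest dialect requires a species list for peptide-mass matching")
        return _read_glycoquest(frame, path, run_id, scale_pct, species_list)
    raise ValueError(f"unknown dialect {dialect!r}")


def _make_species(sequence: str, glycan_text: str, charge: int) -> GlycopeptideSpecies:
    return GlycopeptideSpecies(
        peptide=PeptideBackbone(sequence=sequence),
        glycan=parse_glycan_composition(glycan_text),
        charge=charge,
    )


def _read_normalized(frame: pd.DataFrame, path) -> ReportReadResult:
    _require_columns(frame, NORMALIZED_COLUMNS, path)
    records: list[IdentificationRecord] = []
    n_skipped = 0
    for row in frame.itertuples(index=False):
        try:
            species = _make_species(row.sequence, row.glycan_composition, int(row.charge))
        except (GlycanParseError, ValueError) as exc:
            logger.warning("%s: skipping row (%s)", path, exc)
            n_skipped += 1
            continue
        records.append(IdentificationRecord(
            run_id=str(row.run_id),
            scale_pct=float(row.scale_pct),
            species=species,
            channel=str(row.channel),
            score=float(row.score),
            retention_time=_optional_float(row.retention_time_min),
        ))
    return ReportReadResult(tuple(records), n_skipped)


def _read_byonic(frame, path, run_id, scale_pct) -> ReportReadResult:
    cols = BYONIC_COLUMNS
    _require_columns(frame, cols.values(), path)
    records, n_skipped = [], 0
    for _, row in frame.iterrows():
        try:
            species = _make_species(row[cols["sequence"]],
                                    row[cols["glycan_composition"]],
                                    int(row[cols["charge"]]))
        except (GlycanParseError, ValueError) as exc:
            logger.warning("%s: skipping row (%s)", path, exc)
            n_skipped += 1
            continue
        records.append(IdentificationRecord(
            run_id=run_id, scale_pct=scale_pct, species=species,
            channel="byonic", score=float(row[cols["score"]]),
            retention_time=_optional_float(row[cols["retention_time_min"]]),
        ))
    return ReportReadResult(tuple(records), n_skipped)


def _read_pglyco(frame, path, run_id, scale_pct) -> ReportReadResult:
    cols = PGLYCO_COLUMNS
    _require_columns(frame, cols.values(), path)
    records, n_skipped = [], 0
    score_channels = (("peptide_score", "pglyco_peptide"),
                      ("glycan_score", "pglyco_glycan"),
                      ("total_score", "pglyco_total"))
    for _, row in frame.iterrows():
        try:
            species = _make_species(row[cols["sequence"]],
                                    row[cols["glycan_composition"]],
                                    int(row[cols["charge"]]))
        except (GlycanParseError, ValueError) as exc:
            logger.warning("%s: skipping row (%s)", path, exc)
            n_skipped += 1
            continue
        rt = _optional_float(row[cols["retention_time_min"]])
        for score_key, channel in score_channels:
            records.append(IdentificationRecord(
                run_id=run_id, scale_pct=scale_pct, species=species,
                channel=channel, score=float(row[cols[score_key]]),
                retention_time=rt,
            ))
    return ReportReadResult(tuple(records), n_skipped)


def _read_glycoquest(frame, path, run_id, scale_pct, species_list) -> ReportReadResult:
    """GlycoQuest reports carry no sequence, only a peptide mass; match each
    row against the supplied species list by (peptide mass within tolerance,
    glycan composition, charge)."""
    cols = GLYCOQUEST_COLUMNS
    _require_columns(frame, cols.values(), path)
    index: dict[tuple, list[tuple[float, GlycopeptideSpecies]]] = {}
    for sp in species_list:
        key = (format_glycan_composition(sp.glycan), sp.charge)
        index.setdefault(key, []).append((peptide_mass(sp.peptide), sp))
    records, n_skipped = [], 0
    for _, row in frame.iterrows():
        try:
            comp = parse_glycan_composition(row[cols["glycan_composition"]])
        except GlycanParseError as exc:
            logger.warning("%s: skipping row (%s)", path, exc)
            n_skipped += 1
            continue
        charge = int(row[cols["charge"]])
        mass = float(row[cols["peptide_mass"]])
        candidates = index.get((format_glycan_composition(comp), charge), [])
        best = None
        for cand_mass, sp in candidates:
            delta = abs(cand_mass - mass)
            if delta <= GLYCOQUEST_MASS_TOL_DA and (best is None or delta < best[0]):
                best = (delta, sp)
        if best is None:
            logger.warning("%s: no species-list match for peptide mass %.4f", path, mass)
            n_skipped += 1
            continue
        records.append(IdentificationRecord(
            run_id=run_id, scale_pct=scale_pct, species=best[1],
            channel="glycoquest", score=float(row[cols["score"]]),
            retention_time=_optional_float(row[cols["retention_time_min"]]),
        ))
    return ReportReadResult(tuple(records), n_skipped)


# ---------------------------------------------------------------------------
# run manifest

def read_run_manifest(path) -> dict[str, float]:
    """Run manifest TSV (run_id, scale_pct) -> mapping."""
    frame = _read_tsv(path)
    _require_columns(frame, ("run_id", "scale_pct"), path)
    return {str(r.run_id): float(r.scale_pct) for r in frame.itertuples(index=False)}


def write_run_manifest(mapping: dict[str, float], path) -> None:
    frame = pd.DataFrame(
        {"run_id": list(mapping), "scale_pct": [mapping[k] for k in mapping]}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_report_dir(report_dir, manifest_path, dialect: str = "normalized",
                    species_list=None) -> ReportReadResult:
    """Read every report file listed in the manifest from a directory.

    Files are expected to be named ``<run_id>.tsv``.
    """
    manifest = read_run_manifest(manifest_path)
    report_dir = Path(report_dir)
    all_records: list[IdentificationRecord] = []
    n_skipped = 0
    for run_id in sorted(manifest):
        result = read_report(report_dir / f"{run_id}.tsv", dialect,
                             run_id=run_id, scale_pct=manifest[run_id],
                             species_list=species_list)
        all_records.extend(result.records)
        n_skipped += result.n_skipped
    return ReportReadResult(tuple(all_records), n_skipped)


# ---------------------------------------------------------------------------
# deduplication

def aggregate_best_per_run(records: Iterable[IdentificationRecord]) -> ScoreTable:
    """Keep the best-scoring match per (species, run, channel).

    Ties broken by earliest retention time, then by input order; records with
    no retention time sort after those with one.
    """
    best: dict[tuple, tuple[tuple, IdentificationRecord]] = {}
    for order, rec in enumerate(records):
        rt = rec.retention_time if rec.retention_time is not None else np.inf
        # sort key: maximize score, then minimize RT, then earliest input
        rank = (-rec.score, rt, order)
        current = best.get(rec.key)
        if current is None or rank < current[0]:
            best[rec.key] = (rank, rec)
    ordered = sorted(best.values(), key=lambda item: item[0][2])
    return ScoreTable(records=tuple(rec for _, rec in ordered))


# ---------------------------------------------------------------------------
# normalized output

def records_to_frame(records: Iterable[IdentificationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "run_id": rec.run_id,
            "scale_pct": rec.scale_pct,
            "sequence": rec.species.peptide.sequence,
            "glycan_composition": format_glycan_composition(rec.species.glycan),
            "charge": rec.species.charge,
            "channel": rec.channel,
            "score": rec.score,
            "retention_time_min": "" if rec.retention_time is None else rec.retention_time,
        })
    return pd.DataFrame(rows, columns=list(NORMALIZED_COLUMNS))


def write_normalized(records: Iterable[IdentificationRecord], path) -> None:
    """Write records in the normalized TSV schema (round-trips via read_report)."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)
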