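"""Glycan composition parsing, peptide chemistry, and structural features.

All masses are monoisotopic.  The unit of analysis throughout the package is
a glycopeptide *species*: a peptide backbone plus a glycan composition plus a
charge state.  Different charge states of the same glycoform are distinct
species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GlycanComposition",
    "PeptideBackbone",
    "GlycopeptideSpecies",
    "FeatureVector",
    "GlycanParseError",
    "parse_glycan_composition",
    "format_glycan_composition",
    "glycan_mass",
    "peptide_mass",
    "theoretical_mz",
    "basic_site_count",
    "mobile_proton_count",
    "hydrophobicity",
    "glycan_features",
    "compute_features",
    "feature_table",
    "KYTE_DOOLITTLE",
    "PROTON_MASS",
    "WATER_MASS",
]

PROTON_MASS = 1.00727646
WATER_MASS = 18.010565

#: monoisotopic residue masses (monosaccharide minus water)
MONOSACCHARIDE_RESIDUE_MASS = {
    "hexnac": 203.07937,
    "hex": 162.05282,
    "neuac": 291.09542,
    "neugc": 307.09033,
    "fuc": 146.05791,
}

#: monoisotopic amino-acid residue masses, 20 canonical letters
AMINO_ACID_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

CANONICAL_RESIDUES = frozenset(AMINO_ACID_RESIDUE_MASS)

#: Kyte-Doolittle hydropathy index, summed over residues as the default
#: hydrophobicity proxy.  Only the ordering of peptides matters downstream.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: default fixed modification: carbamidomethylation of cysteine
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": 57.02146}

_BASIC_RESIDUES = frozenset("KRH")

_MONO_TOKEN_NAMES = {
    "HexNAc": "hexnac",
    "Hex": "hex",
    "NeuAc": "neuac",
    "NeuGc": "neugc",
    "Fuc": "fuc",
    "dHex": "fuc",  # alias
}

_TOKEN_RE = re.compile(r"([A-Za-z]+)\((-?\d+(?:\.\d+)?)\)")


class GlycanParseError(ValueError):
    """Raised when a glycan composition string cannot be parsed."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of a glycan; no linkage/topology information."""

    hexnac: int = 0
    hex: int = 0
    neuac: int = 0
    neugc: int = 0
    fuc: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "neuac", "neugc", "fuc"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise GlycanParseError(f"count for {name!r} must be an integer, got {value!r}")
            if value < 0:
                raise GlycanParseError(f"count for {name!r} must be >= 0, got {value}")

    def counts(self) -> dict[str, int]:
        return {
            "hexnac": self.hexnac, "hex": self.hex, "neuac": self.neuac,
            "neugc": self.neugc, "fuc": self.fuc,
        }

    @property
    def total_residues(self) -> int:
        return self.hexnac + self.hex + self.neuac + self.neugc + self.fuc

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            hexnac=self.hexnac + other.hexnac,
            hex=self.hex + other.hex,
            neuac=self.neuac + other.neuac,
            neugc=self.neugc + other.neugc,
            fuc=self.fuc + other.fuc,
        )


def parse_glycan_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``"HexNAc(4)Hex(5)NeuAc(2)"``.

    Recognized monosaccharide names are HexNAc, Hex, NeuAc, NeuGc and Fuc
    (case-sensitive); ``dHex`` is accepted as an alias of Fuc.  Absent
    monosaccharides default to 0.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError("empty glycan composition string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(text):
        if match.start() != pos:
            raise GlycanParseError(
                f"malformed composition {text!r} near {text[pos:match.start()]!r}"
            )
        name, count_text = match.group(1), match.group(2)
        if name not in _MONO_TOKEN_NAMES:
            raise GlycanParseError(f"unrecognized monosaccharide {name!r} in {text!r}")
        try:
            count = int(count_text)
        except ValueError:
            raise GlycanParseError(
                f"non-integer count {count_text!r} for {name!r} in {text!r}"
            ) from None
        if count < 0:
            raise GlycanParseError(f"negative count {count} for {name!r} in {text!r}")
        key = _MONO_TOKEN_NAMES[name]
        counts[key] = counts.get(key, 0) + count
        pos = match.end()
    if pos != len(text):
        raise GlycanParseError(f"malformed composition {text!r} near {text[pos:]!r}")
    if not counts:
        raise GlycanParseError(f"no monosaccharide tokens found in {text!r}")
    return GlycanComposition(**counts)


def format_glycan_composition(comp: GlycanComposition) -> str:
    """Canonical text form; inverse of :func:`parse_glycan_composition`."""
    parts = []
    for name, key in (("HexNAc", "hexnac"), ("Hex", "hex"), ("NeuAc", "neuac"),
                      ("NeuGc", "neugc"), ("Fuc", "fuc")):
        count = getattr(comp, key)
        if count:
            parts.append(f"{name}({count})")
    return "".join(parts)


@dataclass(frozen=True)
class PeptideBackbone:
    """Amino-acid sequence plus fixed modification offsets per residue letter."""

    sequence: str
    fixed_modifications: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residue(s) {sorted(bad)} in {self.sequence!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GlycopeptideSpecies:
    """Peptide + glycan + charge; the unit of all per-species analysis."""

    peptide: PeptideBackbone
    glycan: GlycanComposition
    charge: int
    retention_time: float | None = None
    observed_mz: float | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")

    @property
    def key(self) -> tuple:
        """Species identity: (sequence, composition counts, charge)."""
        g = self.glycan
        return (self.peptide.sequence, (g.hexnac, g.hex, g.neuac, g.neugc, g.fuc), self.charge)


def glycan_mass(comp: GlycanComposition) -> float:
    """Monoisotopic glycan mass in Da (sum of residue masses; additive in counts)."""
    return sum(MONOSACCHARIDE_RESIDUE_MASS[name] * count
               for name, count in comp.counts().items())


def peptide_mass(pep: PeptideBackbone) -> float:
    """Monoisotopic peptide mass in Da, including water and fixed modifications."""
    mass = WATER_MASS
    for letter in pep.sequence:
        mass += AMINO_ACID_RESIDUE_MASS[letter]
        mass += pep.fixed_modifications.get(letter, 0.0)
    return mass


def theoretical_mz(species: GlycopeptideSpecies) -> float:
    """Theoretical m/z of the protonated species."""
    if species.charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = peptide_mass(species.peptide) + glycan_mass(species.glycan)
    return (neutral + species.charge * PROTON_MASS) / species.charge


def basic_site_count(pep: PeptideBackbone) -> int:
    """Number of basic sites: Lys + Arg + His residues + the N-terminus."""
    return sum(1 for letter in pep.sequence if letter in _BASIC_RESIDUES) + 1


def mobile_proton_count(species: GlycopeptideSpecies) -> int:
    """Charge minus the number of basic sites (K, R, H, N-terminus); may be negative."""
    return species.charge - basic_site_count(species.peptide)


def hydrophobicity(pep: PeptideBackbone, scale: Mapping[str, float] = KYTE_DOOLITTLE) -> float:
    """Residue-additive hydrophobicity index (default: Kyte-Doolittle sum).

    Only ordering is meaningful across scales; the value is the plain sum of
    per-residue scale values, hence permutation-invariant.
    """
    if not pep.sequence:
        raise ValueError("empty peptide sequence")
    missing = set(pep.sequence) - set(scale)
    if missing:
        raise ValueError(f"hydrophobicity scale lacks residues {sorted(missing)}")
    return sum(scale[letter] for letter in pep.sequence)


def glycan_features(comp: GlycanComposition) -> dict:
    """Derived glycan descriptors.

    ``n_antennae`` uses the ``hexnac - 2`` heuristic for non-high-mannose
    compositions (ignores bisecting GlcNAc); high-mannose glycans are
    HexNAc(2)Hex(>=5) without fucose or sialic acid.
    """
    n_sialic = comp.neuac + comp.neugc
    is_high_mannose = (comp.hexnac == 2 and comp.hex >= 5
                       and n_sialic == 0 and comp.fuc == 0)
    n_antennae = 0 if is_high_mannose else max(0, comp.hexnac - 2)
    return {
        "n_sialic": n_sialic,
        "n_fucose": comp.fuc,
        "n_antennae": n_antennae,
        "is_high_mannose": is_high_mannose,
    }


_SEQUON_RE = re.compile(r"N[^P][ST]")


def _glycosite_position_fraction(sequence: str) -> float:
    """Fractional position (0-1] of the first N-X-S/T sequon N, else of the
    first Asn, else 0.5 when no Asn is present."""
    match = _SEQUON_RE.search(sequence)
    if match is not None:
        return (match.start() + 1) / len(sequence)
    idx = sequence.find("N")
    if idx >= 0:
        return (idx + 1) / len(sequence)
    return 0.5


@dataclass(frozen=True)
class FeatureVector:
    """Structural covariates of one species, feeding GLM/lasso/smart-CE."""

    mz: float
    total_mass: float
    peptide_mass: float
    glycan_mass: float
    peptide_only_mz: float
    hydrophobicity: float
    charge: int
    mobile_protons: int
    n_sialic: int
    n_fucose: int
    n_antennae: int
    glycosite_position_fraction: float
    peptide_length: int
    amino_acid_counts: tuple[int, ...]
    monosaccharide_counts: tuple[int, ...]


AA_ORDER = tuple(sorted(AMINO_ACID_RESIDUE_MASS))
MONO_ORDER = ("hexnac", "hex", "neuac", "neugc", "fuc")


def compute_features(species: GlycopeptideSpecies,
                     scale: Mapping[str, float] = KYTE_DOOLITTLE) -> FeatureVector:
    """Compute the full covariate vector for one species."""
    pep_mass = peptide_mass(species.peptide)
    gly_mass = glycan_mass(species.glycan)
    z = species.charge
    seq = species.peptide.sequence
    gf = glycan_features(species.glycan)
    return FeatureVector(
        mz=(pep_mass + gly_mass + z * PROTON_MASS) / z,
        total_mass=pep_mass + gly_mass,
        peptide_mass=pep_mass,
        glycan_mass=gly_mass,
        peptide_only_mz=(pep_mass + z * PROTON_MASS) / z,
        hydrophobicity=hydrophobicity(species.peptide, scale),
        charge=z,
        mobile_protons=mobile_proton_count(species),
        n_sialic=gf["n_sialic"],
        n_fucose=gf["n_fucose"],
        n_antennae=gf["n_antennae"],
        glycosite_position_fraction=_glycosite_position_fraction(seq),
        peptide_length=len(seq),
        amino_acid_counts=tuple(seq.count(a) for a in AA_ORDER),
        monosaccharide_counts=tuple(getattr(species.glycan, m) for m in MONO_ORDER),
    )


#: numeric feature columns excluding the raw composition counts
CORE_FEATURE_COLUMNS = (
    "mz", "total_mass", "peptide_mass", "glycan_mass", "peptide_only_mz",
    "hydrophobicity", "charge", "mobile_protons", "n_sialic", "n_fucose",
    "n_antennae", "glycosite_position_fraction", "peptide_length",
)


def feature_table(species_list: Sequence[GlycopeptideSpecies],
                  scale: Mapping[str, float] = KYTE_DOOLITTLE,
                  include_counts: bool = True) -> pd.DataFrame:
    """Feature matrix for a list of species, indexed positionally.

    Adds identity columns (sequence, glycan_composition, charge) so the table
    can be joined against fitted optima.
    """
    rows = []
    for sp in species_list:
        fv = compute_features(sp, scale)
        row = {
            "sequence": sp.peptide.sequence,
            "glycan_composition": format_glycan_composition(sp.glycan),
        }
        for col in CORE_FEATURE_COLUMNS:
            row[col] = getattr(fv, col)
        if include_counts:
            for a, c in zip(AA_ORDER, fv.amino_acid_counts):
                row[f"aa_{a}"] = c
            for m, c in zip(MONO_ORDER, fv.monosaccharide_counts):
                row[f"mono_{m}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
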