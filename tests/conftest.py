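import numpy as np
import pytest

from glycoce.ce_model import DEFAULT_GRID, applied_ce
from glycoce.curve_opt import ScoreCurve
from glycoce.glyco_chem import (
    GlycanComposition,
    GlycopeptideSpecies,
    PeptideBackbone,
)


@pytest.fixture
def species():
    return GlycopeptideSpecies(
        peptide=PeptideBackbone("ENGTISR"),
        glycan=GlycanComposition(hexnac=2, hex=5),
        charge=2,
    )


def make_curve(ce, scores, species=None, channel="byonic", grid_indices=None):
    """Build a ScoreCurve directly from (CE, score) arrays for fit tests."""
    if species is None:
        species = GlycopeptideSpecies(
            peptide=PeptideBackbone("ENGTISR"),
            glycan=GlycanComposition(hexnac=2, hex=5),
            charge=2,
        )
    ce = np.asarray(ce, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if grid_indices is None:
        grid_indices = tuple(range(len(ce)))
    return ScoreCurve(species=species, channel=channel, ce=ce, scores=scores,
                      grid_indices=tuple(grid_indices),
                      grid_scales=tuple(float(i) for i in grid_indices))


def default_grid_ce(mz=1200.0):
    """Applied CE values of the default sweep at one m/z, duplicates removed."""
    ce = np.array([applied_ce(mz, s) for s in DEFAULT_GRID.scale_percents])
    return np.unique(ce)
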