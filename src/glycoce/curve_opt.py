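"""Score-vs-CE curves, eligibility filtering, and Gaussian optimum extraction.

For each (species, score channel) pair the sweep produces score values at a
set of applied collision energies; the optimal CE is the center of a Gaussian
fitted to those points by damped nonlinear least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ce_model import CECalibration, CESweepGrid, DEFAULT_CALIBRATION, DEFAULT_GRID, applied_ce
from .glyco_chem import GlycopeptideSpecies, format_glycan_composition, theoretical_mz
from .report_io import ScoreTable

__all__ = [
    "ScoreCurve",
    "GaussianFitResult",
    "EligibilityPolicy",
    "CurveFitError",
    "DEFAULT_MIN_SCORES",
    "build_curves",
    "is_eligible",
    "fit_gaussian",
    "optimal_ce",
    "fit_optima",
]

logger = logging.getLogger(__name__)

#: per-channel acceptance score thresholds; the pGlyco sub-scores have no
#: published acceptance threshold, presence suffices
DEFAULT_MIN_SCORES: Mapping[str, float] = {
    "byonic": 300.0,
    "pglyco_total": 15.0,
    "glycoquest": 30.0,
    "pglyco_peptide": 0.0,
    "pglyco_glycan": 0.0,
}


class CurveFitError(RuntimeError):
    """Raised when a species must be excluded because its fit is unusable."""


@dataclass(frozen=True)
class ScoreCurve:
    """Score-vs-applied-CE points for one species and one score channel."""

    species: GlycopeptideSpecies
    channel: str
    ce: np.ndarray          # applied CE in eV, strictly increasing
    scores: np.ndarray      # same length as ce
    grid_indices: tuple[int, ...]   # sweep-grid index of each point
    grid_scales: tuple[float, ...]  # sweep scales at which the species was seen

    def __post_init__(self) -> None:
        if len(self.ce) != len(self.scores):
            raise ValueError("ce and scores must have equal length")
        if np.any(np.diff(self.ce) <= 0):
            raise ValueError("CE values must be strictly increasing")
        if np.any(np.asarray(self.scores) < 0):
            raise ValueError("scores must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.ce)


@dataclass(frozen=True)
class GaussianFitResult:
    amplitude: float
    center_ce: float
    width_sigma: float
    residual_sum_squares: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class EligibilityPolicy:
    """Requirements a curve must meet before its optimum is trusted.

    ``min_score`` is per channel; a curve qualifies when its best score
    exceeds the threshold, at least ``min_consecutive`` adjacent sweep
    settings score above the threshold, and it has at least ``min_points``
    points overall.
    """

    min_score: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIN_SCORES))
    min_consecutive: int = 4
    min_points: int = 5

    def threshold(self, channel: str) -> float:
        return self.min_score.get(channel, 0.0)


def build_curves(table: ScoreTable,
                 cal: CECalibration = DEFAULT_CALIBRATION,
                 grid: CESweepGrid = DEFAULT_GRID) -> list[ScoreCurve]:
    """One curve per (species, channel); CE coordinate is the energy applied
    at the species' theoretical m/z for each sweep setting.

    Sweep settings that saturate at the instrument ceiling map to the same
    applied CE; such duplicate abscissae are collapsed keeping the best score.
    """
    groups: dict[tuple, list] = {}
    species_by_key: dict[tuple, GlycopeptideSpecies] = {}
    for rec in table.records:
        key = (rec.species.key, rec.channel)
        groups.setdefault(key, []).append(rec)
        species_by_key[rec.species.key] = rec.species

    curves: list[ScoreCurve] = []
    for (species_key, channel), recs in groups.items():
        species = species_by_key[species_key]
        try:
            mz = theoretical_mz(species)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping species %s: %s", species_key, exc)
            continue
        points = []
        for rec in recs:
            idx = grid.index_of(rec.scale_pct)
            ce = applied_ce(mz, rec.scale_pct, cal)
            points.append((ce, idx, rec.scale_pct, rec.score))
        points.sort(key=lambda p: (p[0], p[1]))
        # collapse ceiling-saturated duplicates (same applied CE)
        collapsed: list[list] = []
        for ce, idx, scale, score in points:
            if collapsed and abs(ce - collapsed[-1][0]) < 1e-9:
                collapsed[-1][3] = max(collapsed[-1][3], score)
            else:
                collapsed.append([ce, idx, scale, score])
        curves.append(ScoreCurve(
            species=species,
            channel=channel,
            ce=np.array([p[0] for p in collapsed]),
            scores=np.array([p[3] for p in collapsed]),
            grid_indices=tuple(p[1] for p in collapsed),
            grid_scales=tuple(s for _, _, s, _ in points),
        ))
    return curves


def _longest_consecutive_run(indices: Sequence[int]) -> int:
    if not indices:
        return 0
    ordered = sorted(set(indices))
    best = run = 1
    for prev, cur in zip(ordered, ordered[1:]):
        run = run + 1 if cur == prev + 1 else 1
        best = max(best, run)
    return best


def is_eligible(curve: ScoreCurve, policy: EligibilityPolicy = EligibilityPolicy()
                ) -> tuple[bool, str]:
    """Check a curve against the eligibility policy; returns (flag, reason)."""
    threshold = policy.threshold(curve.channel)
    if curve.n_points < policy.min_points:
        return False, "too few points"
    if not np.any(curve.scores > threshold):
        return False, "below score threshold"
    above = [idx for idx, s in zip(curve.grid_indices, curve.scores) if s > threshold]
    if _longest_consecutive_run(above) < policy.min_consecutive:
        return False, "consecutive-run requirement"
    return True, "eligible"


def fit_gaussian(curve: ScoreCurve) -> GaussianFitResult:
    """Fit ``s(CE) = A * exp(-(CE - mu)^2 / (2 sigma^2))`` to the curve points.

    Initialization: A = max score, mu = CE at the max score, sigma = a quarter
    of the probed CE span.  The ``converged`` flag is false when the optimizer
    fails or the fitted center escapes the probed CE range by more than two
    fitted widths; a singular fit yields a non-converged result rather than an
    exception.
    """
    if curve.n_points < 4:
        raise ValueError(f"need >= 4 points to fit, got {curve.n_points}")
    ce = np.asarray(curve.ce, dtype=float)
    scores = np.asarray(curve.scores, dtype=float)
    span = ce[-1] - ce[0]
    a0 = float(scores.max())
    mu0 = float(ce[int(np.argmax(scores))])
    sigma0 = max(span / 4.0, 1e-3)

    def residuals(params):
        a, mu, sigma = params
        return a * np.exp(-((ce - mu) ** 2) / (2.0 * sigma ** 2)) - scores

    try:
        result = least_squares(
            residuals,
            x0=[a0 if a0 > 0 else 1.0, mu0, sigma0],
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=200 * 10,
        )
    except Exception:
        return GaussianFitResult(a0, mu0, sigma0, float(np.sum(residuals([a0, mu0, sigma0]) ** 2)),
                                 curve.n_points, converged=False)
    a, mu, sigma = result.x
    sigma = abs(float(sigma))
    rss = float(np.sum(result.fun ** 2))
    in_range = (ce[0] - 2 * sigma) <= mu <= (ce[-1] + 2 * sigma)
    converged = bool(result.success) and sigma > 0 and np.isfinite(mu) and in_range
    return GaussianFitResult(float(a), float(mu), sigma, rss, curve.n_points, converged)


def optimal_ce(fit: GaussianFitResult) -> float:
    """The optimal CE is the fitted Gaussian center; a non-converged fit means
    the species is excluded from downstream analysis."""
    if not fit.converged:
        raise CurveFitError("fit did not converge; species excluded")
    return fit.center_ce


def fit_optima(curves: Iterable[ScoreCurve],
               policy: EligibilityPolicy = EligibilityPolicy()) -> pd.DataFrame:
    """Fit every eligible curve and tabulate the optima.

    Returns one row per eligible, converged curve with columns: sequence,
    glycan_composition, charge, channel, optimal_ce_ev, sigma_ev, amplitude,
    n_points, converged.
    """
    rows = []
    for curve in curves:
        ok, _reason = is_eligible(curve, policy)
        if not ok or curve.n_points < 4:
            continue
        fit = fit_gaussian(curve)
        if not fit.converged:
            continue
        rows.append({
            "sequence": curve.species.peptide.sequence,
            "glycan_composition": format_glycan_composition(curve.species.glycan),
            "charge": curve.species.charge,
            "channel": curve.channel,
            "optimal_ce_ev": fit.center_ce,
            "sigma_ev": fit.width_sigma,
            "amplitude": fit.amplitude,
            "n_points": fit.n_points,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows, columns=[
        "sequence", "glycan_composition", "charge", "channel", "optimal_ce_ev",
        "sigma_ev", "amplitude", "n_points", "converged"])
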