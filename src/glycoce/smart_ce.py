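"""Smart collision-energy selection: quantify the identification-score gain
of a multivariate CE predictor over the classical m/z-only choice.

Given per-species fitted optima and the measured score curves, both a
baseline (m/z-only) and a multivariate regression (m/z, total mass, glycan
mass, peptide-only m/z, hydrophobicity) are trained to predict the optimal
CE; each species is then "re-acquired" at the measured sweep point closest to
the predicted CE and the resulting scores compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ce_model import CECalibration, CE_FLOOR_EV, DEFAULT_CALIBRATION
from .curve_opt import ScoreCurve

__all__ = [
    "MZ_ONLY_COVARIATES",
    "MULTIVARIATE_COVARIATES",
    "CEPredictor",
    "GainReport",
    "fit_predictor",
    "predict_ce",
    "nearest_measured_score",
    "evaluate_gain",
]

MZ_ONLY_COVARIATES = ("mz",)
MULTIVARIATE_COVARIATES = ("mz", "total_mass", "glycan_mass", "peptide_only_mz",
                           "hydrophobicity")

_COVARIATE_SETS = {"mz_only": MZ_ONLY_COVARIATES, "multivariate": MULTIVARIATE_COVARIATES}


@dataclass(frozen=True)
class CEPredictor:
    kind: str
    covariates: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    channel: str

    def __post_init__(self) -> None:
        if self.kind not in _COVARIATE_SETS:
            raise ValueError(f"unknown predictor kind {self.kind!r}")


@dataclass(frozen=True)
class GainReport:
    channel: str
    mode: str
    per_species: pd.DataFrame   # baseline_score, smart_score, gain_fraction
    mean_gain_pct: float
    bottom_quintile_mean_gain_pct: float
    n: int


def _design(features: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    missing = [c for c in covariates if c not in features.columns]
    if missing:
        raise KeyError(f"missing covariate column(s) {missing}")
    block = features.loc[:, list(covariates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(block)):
        raise ValueError("non-finite covariate values")
    return np.column_stack([np.ones(len(block)), block])


def fit_predictor(features: pd.DataFrame, optima: Sequence[float], kind: str,
                  channel: str = "") -> CEPredictor:
    """Ordinary least squares on the stated covariate set; needs >= 10 species."""
    covariates = _COVARIATE_SETS[kind]
    y = np.asarray(optima, dtype=float)
    if len(y) < 10:
        raise ValueError(f"need >= 10 training species, got {len(y)}")
    # constant covariates carry no information and would only break the rank
    # check; they are absorbed by the intercept
    covariates = tuple(
        c for c in covariates
        if np.std(features[c].to_numpy(dtype=float)) > 1e-12)
    if not covariates:
        raise ValueError("all covariates are constant")
    X = _design(features, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design for covariates "
                         f"{list(covariates)} (rank {rank} < {X.shape[1]})")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return CEPredictor(kind=kind, covariates=covariates,
                       intercept=float(beta[0]),
                       coefficients=tuple(float(b) for b in beta[1:]),
                       channel=channel)


def predict_ce(pred: CEPredictor, features: Mapping[str, float] | pd.Series,
               cal: CECalibration = DEFAULT_CALIBRATION) -> float:
    """Linear prediction clipped to the instrument floor and ceiling."""
    value = pred.intercept
    for name, coef in zip(pred.covariates, pred.coefficients):
        if name not in features:
            raise KeyError(f"missing covariate {name!r}")
        x = float(features[name])
        if not np.isfinite(x):
            raise ValueError(f"non-finite covariate {name!r}")
        value += coef * x
    return float(np.clip(value, CE_FLOOR_EV, cal.ceiling))


def nearest_measured_score(curve: ScoreCurve, desired_ce: float) -> float:
    """Score at the measured CE point closest to the desired CE; ties broken
    toward the lower CE."""
    if curve.n_points == 0:
        raise ValueError("empty curve")
    deltas = np.abs(np.asarray(curve.ce, dtype=float) - desired_ce)
    # argmin returns the first (lowest-CE) index on ties since ce is ascending
    return float(curve.scores[int(np.argmin(deltas))])


def evaluate_gain(curves: Sequence[ScoreCurve], optima: Sequence[float],
                  features: pd.DataFrame, channel: str, mode: str = "loo",
                  cal: CECalibration = DEFAULT_CALIBRATION) -> GainReport:
    """Score gain of the multivariate CE choice over the m/z-only choice.

    ``curves``, ``optima`` and ``features`` rows must be aligned per species.
    ``mode="loo"`` (default) refits both predictors without the evaluated
    species; ``mode="insample"`` trains once on everything.  The bottom
    quintile is defined on the baseline score (empirical 20th percentile,
    ties assigned to the bottom group).
    """
    if mode not in ("loo", "insample"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(curves)
    if not (n == len(optima) == len(features)):
        raise ValueError("curves, optima and features must be aligned")
    if n < 10:
        raise ValueError(f"need >= 10 species, got {n}")
    features = features.reset_index(drop=True)
    optima = np.asarray(optima, dtype=float)

    if mode == "insample":
        base = fit_predictor(features, optima, "mz_only", channel)
        smart = fit_predictor(features, optima, "multivariate", channel)

    rows = []
    for i, curve in enumerate(curves):
        if mode == "loo":
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            train_feats = features.loc[mask]
            base = fit_predictor(train_feats, optima[mask], "mz_only", channel)
            smart = fit_predictor(train_feats, optima[mask], "multivariate", channel)
        feat_row = features.iloc[i]
        baseline_score = nearest_measured_score(curve, predict_ce(base, feat_row, cal))
        smart_score = nearest_measured_score(curve, predict_ce(smart, feat_row, cal))
        rows.append({"baseline_score": baseline_score, "smart_score": smart_score})
    frame = pd.DataFrame(rows)
    if (frame["baseline_score"] <= 0).any():
        # species never detected near the baseline CE cannot define a relative
        # gain; exclude them rather than divide by zero
        frame = frame[frame["baseline_score"] > 0].reset_index(drop=True)
    frame["gain_fraction"] = (frame["smart_score"] - frame["baseline_score"]) / frame["baseline_score"]

    cutoff = np.quantile(frame["baseline_score"], 0.2)
    bottom = frame[frame["baseline_score"] <= cutoff]
    return GainReport(
        channel=channel, mode=mode, per_species=frame,
        mean_gain_pct=float(frame["gain_fraction"].mean() * 100.0),
        bottom_quintile_mean_gain_pct=float(bottom["gain_fraction"].mean() * 100.0),
        n=len(frame),
    )
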