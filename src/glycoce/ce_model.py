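"""Instrument collision-energy model: m/z-linear calibration, sweep scaling,
and the hardware ceiling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CECalibration",
    "CESweepGrid",
    "DEFAULT_CALIBRATION",
    "DEFAULT_GRID",
    "CE_FLOOR_EV",
    "reference_ce",
    "applied_ce",
    "sweep_grid",
]

#: lower bound on any applied energy; linear extrapolation to very small m/z
#: would otherwise produce non-physical values
CE_FLOOR_EV = 1.0


@dataclass(frozen=True)
class CECalibration:
    """Two-anchor linear CE(m/z) calibration plus the maximum settable energy."""

    anchor_low: tuple[float, float] = (600.0, 50.0)
    anchor_high: tuple[float, float] = (2000.0, 135.0)
    ceiling: float = 200.0

    def __post_init__(self) -> None:
        (mz_lo, e_lo), (mz_hi, e_hi) = self.anchor_low, self.anchor_high
        if not mz_lo < mz_hi:
            raise ValueError("anchor_low m/z must be below anchor_high m/z")
        if e_lo <= 0 or e_hi <= 0:
            raise ValueError("anchor energies must be positive")
        if self.ceiling < e_hi:
            raise ValueError("ceiling must be >= the high-anchor energy")

    @property
    def slope(self) -> float:
        (mz_lo, e_lo), (mz_hi, e_hi) = self.anchor_low, self.anchor_high
        return (e_hi - e_lo) / (mz_hi - mz_lo)

    @property
    def intercept(self) -> float:
        mz_lo, e_lo = self.anchor_low
        return e_lo - self.slope * mz_lo


DEFAULT_CALIBRATION = CECalibration()


@dataclass(frozen=True)
class CESweepGrid:
    """Ordered sweep-scale settings in percent of the reference energy."""

    scale_percents: tuple[float, ...]

    def __post_init__(self) -> None:
        scales = self.scale_percents
        if len(scales) == 0:
            raise ValueError("empty sweep grid")
        if any(s <= 0 for s in scales):
            raise ValueError("sweep scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("sweep scales must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scale_percents)

    def index_of(self, scale_pct: float, tol: float = 1e-9) -> int:
        """Grid index of a scale setting (within tolerance); raises if absent."""
        arr = np.asarray(self.scale_percents)
        idx = int(np.argmin(np.abs(arr - scale_pct)))
        if abs(arr[idx] - scale_pct) > tol:
            raise KeyError(f"scale {scale_pct} not on the sweep grid")
        return idx


def sweep_grid(start_pct: float = 6.25, stop_pct: float = 175.0,
               step_pct: float = 6.25) -> CESweepGrid:
    """Arithmetic progression of sweep scales, inclusive of the stop when hit
    exactly (1e-9 tolerance on the grid arithmetic)."""
    if not (0 < start_pct <= stop_pct):
        raise ValueError("require 0 < start <= stop")
    if step_pct <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((stop_pct - start_pct) / step_pct + 1e-9)) + 1
    values = tuple(start_pct + i * step_pct for i in range(n))
    return CESweepGrid(scale_percents=values)


DEFAULT_GRID = sweep_grid()


def reference_ce(mz, cal: CECalibration = DEFAULT_CALIBRATION):
    """Reference ("100%") collision energy at a given m/z.

    Linear through the two anchors, extended linearly outside them and floored
    at :data:`CE_FLOOR_EV`; the instrument ceiling is *not* applied here.
    Accepts scalars or arrays.
    """
    mz_arr = np.asarray(mz, dtype=float)
    if np.any(mz_arr <= 0):
        raise ValueError("m/z must be positive")
    energy = np.maximum(cal.intercept + cal.slope * mz_arr, CE_FLOOR_EV)
    return float(energy) if np.isscalar(mz) else energy


def applied_ce(mz, scale_pct, cal: CECalibration = DEFAULT_CALIBRATION):
    """Energy actually applied at a sweep setting: the scaled reference energy
    truncated at the instrument ceiling.  Accepts scalars or arrays."""
    scale_arr = np.asarray(scale_pct, dtype=float)
    if np.any(scale_arr <= 0):
        raise ValueError("sweep scale must be positive")
    energy = np.minimum(cal.ceiling, scale_arr / 100.0 * reference_ce(mz, cal))
    if np.isscalar(mz) and np.isscalar(scale_pct):
        return float(energy)
    return energy
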