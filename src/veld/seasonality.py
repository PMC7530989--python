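"""Circular statistics of monthly series: seasonal concentration and phase.

Each calendar month ``m`` (1..12) is treated as a unit direction
``theta_m = 2*pi*(m-1)/12`` with January at angle zero, increasing
through the year.  A monthly magnitude series ``v_m >= 0`` (e.g.
precipitation in mm/month) defines a mean vector

    x = sum_m v_m cos(theta_m),    y = sum_m v_m sin(theta_m)

whose normalised length is the seasonal concentration

    C = sqrt(x**2 + y**2) / sum_m v_m          (0 uniform .. 1 single month)

and whose direction is the seasonal phase P.  C is 1 when the variable
falls entirely in one month, 0 (with P undefined) when it is spread
evenly over the year.  P is reported both as an angle in [0, 2*pi) and
as the nearest month index.

All functions accept either a single 12-vector or an array whose first
axis is the month axis (shape ``(12, ...)``), in which case they return
arrays of the trailing shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Number of months in the climatological year.
N_MONTHS = 12

#: Month angles, January = 0, increasing through the year (radians).
THETA = 2.0 * np.pi * np.arange(N_MONTHS) / N_MONTHS

#: Concentration below which the phase is flagged undefined.
PHASE_TOL = 1e-9


@dataclass(frozen=True)
class SeasonalStats:
    """First circular moment of a monthly series (possibly gridded)."""

    x: np.ndarray | float
    y: np.ndarray | float
    concentration: np.ndarray | float      # C in [0, 1]; NaN where annual sum is 0
    phase_angle: np.ndarray | float        # radians in [0, 2*pi); NaN where undefined
    phase_month: np.ndarray | int          # nearest month 1..12; 0 where undefined
    defined: np.ndarray | bool             # phase defined iff C > PHASE_TOL


def _as_monthly(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[0] != N_MONTHS:
        raise ValueError(f"monthly series must have 12 entries on axis 0, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("monthly series contains non-finite values")
    return v


def monthly_vectors(v) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Mean-vector components (x, y) of a monthly series.

    ``x`` points at January, ``y`` at April (a quarter year later).
    """
    v = _as_monthly(v)
    shape = (N_MONTHS,) + (1,) * (v.ndim - 1)
    x = np.sum(v * np.cos(THETA).reshape(shape), axis=0)
    y = np.sum(v * np.sin(THETA).reshape(shape), axis=0)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def concentration(v) -> np.ndarray | float:
    """Seasonal concentration C = |mean vector| / annual sum, in [0, 1].

    NaN where the annual sum is zero (C undefined).
    """
    v = _as_monthly(v)
    if np.any(v < 0):
        raise ValueError("concentration requires non-negative magnitudes")
    x, y = monthly_vectors(v)
    total = np.sum(v, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(total > 0, np.hypot(x, y) / np.where(total > 0, total, 1.0), np.nan)
    # guard against rounding pushing C infinitesimally past 1
    c = np.clip(c, 0.0, 1.0, out=None)
    return float(c) if np.ndim(c) == 0 else c


def phase(v) -> SeasonalStats:
    """Full seasonal statistics including the quadrant-correct phase."""
    return seasonal_stats(v)


def seasonal_stats(v) -> SeasonalStats:
    """Concentration and phase of a monthly series (scalar or gridded)."""
    v = _as_monthly(v)
    x, y = monthly_vectors(v)
    c = concentration(v)
    defined = np.asarray(c) > PHASE_TOL
    ang = np.mod(np.arctan2(np.asarray(y), np.asarray(x)), 2.0 * np.pi)
    safe_ang = np.where(defined, ang, 0.0)
    ang = np.where(defined, ang, np.nan)
    month = np.where(
        defined,
        (np.rint(safe_ang / (2.0 * np.pi / N_MONTHS)).astype(int) % N_MONTHS) + 1,
        0,
    )
    if np.ndim(c) == 0:
        return SeasonalStats(float(x), float(y), float(c), float(ang), int(month), bool(defined))
    return SeasonalStats(x, y, c, ang, month, defined)


def phase_month_of(pre: np.ndarray) -> np.ndarray:
    """Nearest calendar month (1..12, 0 undefined) of the precipitation phase.

    Convenience wrapper for gridded fields with a leading month axis.
    """
    return np.asarray(seasonal_stats(pre).phase_month)
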