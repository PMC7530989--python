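"""Lightning-fire occurrence, flame height and crown-scorch mortality.

A strongly reduced fire scheme: the full spread-rate system is replaced
by a single calibrated dryness x spread factor.  Fires start from a
constant climatological lightning-ignition rate; the probability that
an ignition becomes a fire falls to zero as fuel moisture approaches a
moisture of extinction, and no fire occurs below a minimum fuel load
(200 g C/m², a common savanna-model convention).  The annual burned
fraction is ignitions x p(fire|ignition) x mean spread area.

Fuel moisture is proxied by the wet-day fraction over a running
three-month window; the fire season is the driest such window of the
climatological year.  Flame height grows concavely with fire intensity
(fuel consumed x dryness); the probability of death by crown scorch
rises smoothly once flames reach a PFT's canopy height, so the 0.5 m
grass canopies burn off almost completely while 8 m trees mostly escape
scorch but suffer an additional cambial-damage loss.  Grasses
nevertheless dominate post-fire landscapes because they re-establish
within a couple of years (see :mod:`veld.vegetation`), which is why
fire moves tree cover far more than it moves the C3:C4 grass balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import ClimateGrid, DAYS_IN_MONTH
from .vegetation import C3G, C4G, TREE, PFTDef, VegState, DEFAULT_PFTS

__all__ = [
    "FireParams", "fire_environment", "fire_occurrence", "flame_height",
    "crown_scorch_mortality", "apply_fire", "make_fire_fn",
]


@dataclass(frozen=True)
class FireParams:
    """Constants of the reduced fire scheme."""

    ignitions: float = 1.0             # expected lightning fires/cell/year
    moisture_of_extinction: float = 0.35   # wet-day fraction killing all fire
    fuel_threshold: float = 200.0      # g C/m² below which nothing burns
    spread_factor: float = 0.45        # mean burned area per fire at dryness 1
    consume_frac: float = 0.5          # fraction of fuel consumed in the flame
    flame_coef: float = 0.15           # m per sqrt(intensity unit)
    scorch_steepness: float = 3.0      # logistic steepness of crown scorch
    cambial_mortality: float = 0.35    # extra tree loss fraction per burned area
    litter_frac_tree: float = 0.2      # tree biomass contributing to fine fuel


DEFAULT_FIRE = FireParams()


def fire_environment(grid: ClimateGrid, params: FireParams = DEFAULT_FIRE) -> np.ndarray:
    """Climatological dryness of the fire season, per cell in [0, 1].

    Wet-day fraction smoothed over a circular three-month window; the
    annual minimum, scaled against the moisture of extinction, gives the
    dryness factor (0: too moist to burn, 1: bone dry).
    """
    wet_frac = grid.wet / DAYS_IN_MONTH[:, None, None]
    window = (wet_frac + np.roll(wet_frac, 1, axis=0) + np.roll(wet_frac, 2, axis=0)) / 3.0
    moisture = window.min(axis=0)
    return np.clip(1.0 - moisture / params.moisture_of_extinction, 0.0, 1.0)


def fire_occurrence(fuel_load, dryness, params: FireParams = DEFAULT_FIRE):
    """Annual burned fraction of the cell, in [0, 1].

    ignitions x p(fire|ignition) x mean spread, with p = dryness² and
    spread proportional to dryness; zero below the fuel threshold.
    """
    fuel_load = np.asarray(fuel_load, dtype=float)
    dryness = np.clip(np.asarray(dryness, dtype=float), 0.0, 1.0)
    p_fire = dryness ** 2
    spread = params.spread_factor * dryness
    burned = params.ignitions * p_fire * spread
    burned = np.where(fuel_load >= params.fuel_threshold, burned, 0.0)
    burned = np.clip(burned, 0.0, 1.0)
    return float(burned) if np.ndim(burned) == 0 else burned


def flame_height(intensity, params: FireParams = DEFAULT_FIRE):
    """Flame height (m): concave (square-root) in fire intensity."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    h = params.flame_coef * np.sqrt(intensity)
    return float(h) if np.ndim(h) == 0 else h


def crown_scorch_mortality(fh, pft: PFTDef, params: FireParams = DEFAULT_FIRE):
    """Probability of death by crown scorch within the burned area.

    Logistic in flame height relative to canopy height, rebased so that
    zero flames give exactly zero mortality; ~0.48 when flames reach the
    canopy top, saturating to 1 well above it.
    """
    fh = np.asarray(fh, dtype=float)
    k = params.scorch_steepness
    base = 1.0 / (1.0 + np.exp(k))                      # logistic at fh = 0
    raw = 1.0 / (1.0 + np.exp(-k * (fh / pft.canopy_height - 1.0)))
    mort = np.clip((raw - base) / (1.0 - base), 0.0, 1.0)
    return float(mort) if np.ndim(mort) == 0 else mort


def apply_fire(state: VegState, burned_frac, mortality: np.ndarray,
               params: FireParams = DEFAULT_FIRE, pfts=DEFAULT_PFTS) -> VegState:
    """Remove burned biomass: per-PFT scorch loss plus tree cambial damage.

    ``mortality`` has shape (3, n) (or (3,) broadcastable).  With zero
    burned fraction this is the identity.
    """
    burned = np.clip(np.asarray(burned_frac, dtype=float), 0.0, 1.0)
    for i, p in enumerate(pfts):
        loss = burned * np.asarray(mortality)[i]
        if p.form == "tree":
            loss = np.clip(loss + burned * params.cambial_mortality, 0.0, 1.0)
        state.biomass[i] *= 1.0 - loss
    return state


def make_fire_fn(dryness: np.ndarray, params: FireParams = DEFAULT_FIRE,
                 pfts=DEFAULT_PFTS, diagnostics: dict | None = None):
    """Build the annual fire step for :func:`veld.vegetation.annual_update`.

    ``dryness`` is the per-cell climatological fire-season dryness from
    :func:`fire_environment`.  If ``diagnostics`` is given, the burned
    fraction of the last call is stored under ``"burned_frac"``.
    """

    def fire_fn(state: VegState) -> None:
        fuel = (state.biomass[C3G] + state.biomass[C4G]
                + params.litter_frac_tree * state.biomass[TREE])
        burned = fire_occurrence(fuel, dryness, params)
        intensity = params.consume_frac * fuel * dryness
        fh = flame_height(intensity, params)
        mort = np.stack([crown_scorch_mortality(fh, p, params) for p in pfts])
        apply_fire(state, burned, mort, params, pfts)
        if diagnostics is not None:
            diagnostics["burned_frac"] = np.asarray(burned)
    return fire_fn
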