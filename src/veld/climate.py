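"""Synthetic southern-African monthly climatology and LGM-like variants.

The generator builds a regular cell-centre lat–lon grid (default 1°,
10–35°S x 10–35°E) carrying twelve climatological months of near-surface
temperature, precipitation, wet-day frequency and sunshine fraction.
Its spatial structure mimics the region's three rainfall regimes:

* a summer-rainfall (DJF-peaking) zone over the north-east and interior,
* a winter-rainfall (JJA-peaking) zone in the south-west corner,
* a weakly seasonal year-round zone along the south coast,

with mean annual temperature falling poleward (plus a weak warm-east
gradient) and mean annual precipitation rising toward the north-east.
Monthly rainfall is a mix of a summer-peaking mode, a winter-peaking
mode and a uniform mode, weighted by position; seeded multiplicative
noise roughens the fields.  The seasonal temperature half-amplitude is
small (~1.2 °C) in the tropical north and grows toward the subtropical
south, so the grid spans both near-aseasonal and strongly seasonal
thermal regimes.

Four fixed "LGM variant" parameter sets (labels A–D) stand in for four
independent glacial climate reconstructions: each applies a distinct
uniform cooling, precipitation scaling and an expansion of the
winter-rainfall margin toward the north-east, emulating inter-model
disagreement.  Variant "none" is the identity (for testing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .seasonality import THETA, seasonal_stats

__all__ = [
    "DAYS_IN_MONTH", "ClimateConfig", "ClimateGrid", "ClimateSummaries",
    "VariantParams", "LGM_VARIANTS", "generate_grid", "lgm_perturb",
    "summarize_climate",
]

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)


class ConfigurationError(ValueError):
    """Invalid domain extent, resolution or variant label."""


@dataclass(frozen=True)
class ClimateConfig:
    """Domain extent, resolution and generator parameters.

    Latitudes are signed degrees north (the default domain is on the
    southern hemisphere).  Structural parameters are documented where a
    scientist might plausibly retune them; all are plain numbers so a
    config file can override any of them.
    """

    lat_min: float = -35.0
    lat_max: float = -10.0
    lon_min: float = 10.0
    lon_max: float = 35.0
    resolution: float = 1.0
    seed: int = 0

    # mean annual temperature: equatorward value, poleward lapse (°C/deg),
    # west-east contrast (°C across the domain)
    mat_north: float = 30.0
    mat_lapse: float = 0.9
    mat_east_gain: float = 3.0
    # seasonal temperature half-amplitude: tropical floor, subtropical
    # rise beyond `amp_lat0` degrees of latitude
    amp_floor: float = 1.2
    amp_rise: float = 4.3
    amp_lat0: float = 26.0
    # precipitation: MAP ramp toward NE, winter-corner supplement
    map_min: float = 60.0
    map_range: float = 1050.0
    map_winter_bonus: float = 200.0
    # seasonal-mode sharpness and zone geometry
    mode_power: float = 2.0
    winter_weight: float = 0.9
    winter_spread: float = 0.35
    uniform_weight: float = 0.85
    uniform_spread: float = 0.15
    # noise (multiplicative lognormal sigma on precip, additive °C on tas)
    noise_pre: float = 0.10
    noise_tas: float = 0.2

    def __post_init__(self):
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ConfigurationError("extent is empty")
        if self.lat_max - self.lat_min < 5 or self.lon_max - self.lon_min < 5:
            raise ConfigurationError("extent too small to contain the rainfall zones")


@dataclass
class ClimateGrid:
    """Gridded 12-month climatology.

    Monthly fields have shape ``(12, nlat, nlon)``; ``lat`` is stored
    descending (north to south) and ``lon`` ascending, both at cell
    centres.
    """

    lat: np.ndarray
    lon: np.ndarray
    tas: np.ndarray   # °C
    pre: np.ndarray   # mm/month
    wet: np.ndarray   # wet days/month
    sun: np.ndarray   # sunshine fraction [0, 1]
    variant_id: str = "modern"
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lat), len(self.lon)

    @property
    def n_cells(self) -> int:
        return len(self.lat) * len(self.lon)

    def validate(self) -> None:
        expect = (12, *self.shape)
        for name in ("tas", "pre", "wet", "sun"):
            f = getattr(self, name)
            if f.shape != expect:
                raise ValueError(f"{name} has shape {f.shape}, expected {expect}")
        if np.any(self.pre < 0):
            raise ValueError("negative precipitation")
        if np.any((self.wet < 0) | (self.wet > 31)):
            raise ValueError("wet days outside [0, 31]")
        if np.any((self.sun < 0) | (self.sun > 1)):
            raise ValueError("sunshine fraction outside [0, 1]")

    def copy(self) -> "ClimateGrid":
        return ClimateGrid(self.lat.copy(), self.lon.copy(), self.tas.copy(),
                           self.pre.copy(), self.wet.copy(), self.sun.copy(),
                           self.variant_id, self.seed)

    def to_dataset(self):
        from .io import grid_to_dataset    # local import: io pulls in xarray
        return grid_to_dataset(self)


@dataclass
class ClimateSummaries:
    """Per-cell annual summaries (arrays of the grid shape).

    ``t_peak_rain`` is the temperature of the precipitation-phase month
    and is NaN where the phase is undefined (e.g. zero or perfectly
    uniform rainfall).
    """

    mat: np.ndarray          # °C
    map_: np.ndarray         # mm/year
    t_coldest: np.ndarray    # °C
    t_warmest: np.ndarray    # °C
    t_peak_rain: np.ndarray  # °C, NaN where undefined
    concentration: np.ndarray
    phase_month: np.ndarray  # 1..12, 0 undefined


@dataclass(frozen=True)
class VariantParams:
    """One LGM-like perturbation: cooling, drying, winter-margin shift."""

    label: str
    d_tas: float           # uniform cooling, °C (positive = colder)
    pre_scale: float       # multiplicative precipitation scaling
    winter_gain: float     # strength of winter-mode admixture (0 = none)
    winter_spread: float   # spatial reach of the expanded winter margin

    def __post_init__(self):
        if self.pre_scale < 0:
            raise ValueError("pre_scale must be non-negative")


#: Four fixed glacial variants (distinct cooling 2–5.5 °C, drying and
#: winter-rainfall expansion) plus an identity variant for testing.
LGM_VARIANTS: dict[str, VariantParams] = {
    "A": VariantParams("A", d_tas=2.0, pre_scale=0.90, winter_gain=0.25, winter_spread=0.45),
    "B": VariantParams("B", d_tas=3.5, pre_scale=0.85, winter_gain=0.45, winter_spread=0.55),
    "C": VariantParams("C", d_tas=2.5, pre_scale=1.00, winter_gain=0.60, winter_spread=0.65),
    "D": VariantParams("D", d_tas=5.5, pre_scale=0.75, winter_gain=0.15, winter_spread=0.40),
    "none": VariantParams("none", d_tas=0.0, pre_scale=1.0, winter_gain=0.0, winter_spread=0.5),
}


def _cell_centres(lo: float, hi: float, res: float) -> np.ndarray:
    n = int(round((hi - lo) / res))
    return lo + res * (np.arange(n) + 0.5)


def _seasonal_modes(power: float):
    """Normalised (mean 1) summer- and winter-peaking monthly shapes."""
    summer = (1.0 + np.cos(THETA)) ** power
    winter = (1.0 + np.cos(THETA - np.pi)) ** power
    return 12.0 * summer / summer.sum(), 12.0 * winter / winter.sum()


def _winter_weight(u, v, gain, spread):
    """Weight of the winter-peaking mode: strongest at the SW corner."""
    return gain * np.exp(-((u / spread) ** 2 + (v / spread) ** 2))


def generate_grid(config: ClimateConfig | None = None, seed: int | None = None,
                  variant: str = "modern") -> ClimateGrid:
    """Generate the synthetic climatology (deterministic under seed).

    ``variant`` here is only a label; LGM perturbations are applied with
    :func:`lgm_perturb`.
    """
    cfg = config or ClimateConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    lat = _cell_centres(cfg.lat_min, cfg.lat_max, cfg.resolution)[::-1]  # descending
    lon = _cell_centres(cfg.lon_min, cfg.lon_max, cfg.resolution)

    # u: 0 west .. 1 east; v: 0 south .. 1 north (per cell)
    uu, vv = np.meshgrid((lon - cfg.lon_min) / (cfg.lon_max - cfg.lon_min),
                         (lat - cfg.lat_min) / (cfg.lat_max - cfg.lat_min))
    abslat = -np.meshgrid(lon, lat)[1]          # positive degrees south

    rng = np.random.default_rng(cfg.seed)

    # --- temperature ------------------------------------------------
    mat = (cfg.mat_north - cfg.mat_lapse * (abslat - (-cfg.lat_max))
           + cfg.mat_east_gain * (uu - 0.5))
    amp = cfg.amp_floor + cfg.amp_rise * np.clip(abslat - cfg.amp_lat0, 0.0, None) / (
        -cfg.lat_min - cfg.amp_lat0 if -cfg.lat_min > cfg.amp_lat0 else 1.0)
    # austral seasons: January (theta=0) is the warmest month
    tas = mat[None, :, :] + amp[None, :, :] * np.cos(THETA)[:, None, None]
    tas = tas + rng.normal(0.0, cfg.noise_tas, size=tas.shape)

    # --- precipitation ----------------------------------------------
    s_ne = np.clip((uu + vv) / 2.0, 0.0, 1.0)              # NE-ness
    w_w = _winter_weight(uu, vv, cfg.winter_weight, cfg.winter_spread)
    w_u = (cfg.uniform_weight * np.exp(-((vv / cfg.uniform_spread) ** 2))
           * (1.0 / (1.0 + np.exp(-(uu - 0.35) / 0.08))) * (1.0 - w_w))
    w_s = np.clip(1.0 - w_w - w_u, 0.0, 1.0)

    map_total = (cfg.map_min + cfg.map_range * s_ne ** 2.2
                 + cfg.map_winter_bonus * (w_w / max(cfg.winter_weight, 1e-9)))
    summer_mode, winter_mode = _seasonal_modes(cfg.mode_power)
    shape = (w_s[None] * summer_mode[:, None, None]
             + w_w[None] * winter_mode[:, None, None]
             + w_u[None] * 1.0)
    pre = (map_total[None] / 12.0) * shape
    pre = pre * rng.lognormal(mean=0.0, sigma=cfg.noise_pre, size=pre.shape)
    pre = np.clip(pre, 0.0, None)

    wet = wet_days_from_precip(pre)
    sun = sunshine_from_precip(pre)

    grid = ClimateGrid(lat, lon, tas, pre, wet, sun, variant_id=variant, seed=cfg.seed)
    grid.validate()
    return grid


def wet_days_from_precip(pre: np.ndarray) -> np.ndarray:
    """Saturating wet-day proxy: bounded [1, days-in-month] where pre > 0."""
    days = DAYS_IN_MONTH[:, None, None] if pre.ndim == 3 else DAYS_IN_MONTH.reshape(
        (12,) + (1,) * (pre.ndim - 1))
    wet = days * (1.0 - np.exp(-pre / 80.0))
    return np.where(pre > 0, np.clip(wet, 1.0, days), 0.0)


def sunshine_from_precip(pre: np.ndarray) -> np.ndarray:
    """Cloudier in wetter months: sun = 0.92 - 0.45 * pre/(pre+40)."""
    return np.clip(0.92 - 0.45 * pre / (pre + 40.0), 0.05, 0.95)


def lgm_perturb(grid: ClimateGrid, variant: str) -> ClimateGrid:
    """Apply one of the fixed LGM-like perturbations to a grid.

    Cooling is a uniform offset, drying a uniform scaling; the
    winter-rainfall expansion blends each cell's monthly rainfall shape
    toward the winter-peaking mode with a weight that decays away from
    the SW corner (reaching further for larger ``winter_spread``).
    Wet days and sunshine are recomputed from the perturbed rainfall.
    """
    try:
        vp = LGM_VARIANTS[variant]
    except KeyError:
        raise ConfigurationError(
            f"unknown variant {variant!r}; choose from {sorted(LGM_VARIANTS)}") from None

    uu = (grid.lon - grid.lon.min()) / max(np.ptp(grid.lon), 1e-9)
    vv = (grid.lat - grid.lat.min()) / max(np.ptp(grid.lat), 1e-9)
    uu, vv = np.meshgrid(uu, vv)

    tas = grid.tas - vp.d_tas
    pre = grid.pre * vp.pre_scale
    if vp.winter_gain > 0:
        beta = _winter_weight(uu, vv, vp.winter_gain, vp.winter_spread)
        _, winter_mode = _seasonal_modes(2.0)
        cell_map = pre.sum(axis=0)
        pre = (1.0 - beta[None]) * pre + beta[None] * (cell_map[None] / 12.0) * winter_mode[:, None, None]
    pre = np.clip(pre, 0.0, None)

    out = ClimateGrid(grid.lat.copy(), grid.lon.copy(), tas, pre,
                      wet_days_from_precip(pre), sunshine_from_precip(pre),
                      variant_id=vp.label if vp.label != "none" else grid.variant_id,
                      seed=grid.seed)
    out.validate()
    return out


def summarize_climate(grid: ClimateGrid) -> ClimateSummaries:
    """Per-cell MAT, MAP, coldest/warmest month and peak-rain temperature.

    The peak-rainfall month is the (nearest-month) phase of the monthly
    precipitation series; cells with undefined phase get NaN.
    """
    grid.validate()
    stats = seasonal_stats(grid.pre)
    mat = grid.tas.mean(axis=0)
    map_ = grid.pre.sum(axis=0)
    t_cold = grid.tas.min(axis=0)
    t_warm = grid.tas.max(axis=0)

    month = np.asarray(stats.phase_month)
    t_peak = np.full(grid.shape, np.nan)
    defined = month > 0
    if np.any(defined):
        idx = np.clip(month - 1, 0, 11)
        gathered = np.take_along_axis(grid.tas, idx[None, :, :], axis=0)[0]
        t_peak = np.where(defined, gathered, np.nan)

    return ClimateSummaries(mat=mat, map_=map_, t_coldest=t_cold, t_warmest=t_warm,
                            t_peak_rain=t_peak, concentration=np.asarray(stats.concentration),
                            phase_month=month)
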