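"""Annual per-cell population dynamics of three competing plant types.

The plant functional types (PFTs) are a tropical raingreen tree, a C3
grass and a C4 grass — a deliberate reduction of the nine-PFT scheme of
full LPJ-family models to the minimum needed to study the grass layer
and its interaction with tree shading and fire.

Structure is annual, fluxes monthly: each simulated year loops over the
twelve climatological months, keeping a single-layer soil-water bucket
and accumulating water-limited GPP per PFT (see
:mod:`veld.photosynthesis`); the annual carbon balance is then allocated
to biomass, converted to leaf area (LAI) and foliage projective cover
(FPC, Lambert–Beer: FPC = 1 - exp(-0.5 LAI)), and reduced by background
turnover.  Trees shade grasses (grass light scales with 1 - tree FPC);
total cover is capped at 0.95 with grasses scaled back before trees.

Bioclimatic limits act on the coldest-month mean temperature of the
climatology: the C4 grass cannot survive a coldest month below 15.5 °C,
the C3 grass has no lower survival limit, and the tropical tree drops
out below 5.5 °C.  Ineligible PFTs decay rapidly; eligible ones
re-establish from a small seed biomass, which makes grasses recover
from disturbance within a couple of years while trees take decades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import photosynthesis as ps

__all__ = [
    "PFTDef", "DEFAULT_PFTS", "VegState", "SoilParams", "DEFAULT_SOIL",
    "TREE", "C3G", "C4G",
    "establishment_filter", "fpc_from_lai", "light_competition", "annual_update",
    "update_structure",
]

# PFT indices used throughout the package.
TREE, C3G, C4G = 0, 1, 2

#: Lambert–Beer light-extinction coefficient for FPC.
K_BEER = 0.5
#: Total-cover cap; the remainder is bare ground.
FPC_CAP = 0.95
#: Seed biomass (g C/m²) from which an eligible PFT can (re)establish.
SEED_BIOMASS = 2.0
#: Annual survival of an ineligible PFT's biomass (rapid die-off).
INELIGIBLE_SURVIVAL = 0.1
#: NPP as a fraction of GPP before maintenance costs (growth respiration).
NPP_FRAC = 0.5
#: Daytime = monthly mean + fixed diurnal half-amplitude (°C).
DIURNAL_OFFSET = 2.5


def par_from_sunshine(sun):
    """Daily PAR (mol photons m-2 day-1) from sunshine fraction."""
    return 18.0 + 30.0 * np.asarray(sun, dtype=float)


@dataclass(frozen=True)
class PFTDef:
    """Static traits of one plant functional type."""

    name: str
    form: str                      # "tree" | "grass"
    pathway: ps.PathwayParams
    t_coldest_min: float | None    # °C survival limit on coldest month, None = none
    canopy_height: float           # m, for fire crown scorch
    turnover_rate: float           # fraction of biomass lost per year
    sla: float                     # specific leaf area, m² leaf per g C
    leaf_frac: float               # fraction of biomass in leaves
    resp_maint: float              # maintenance respiration, /year on biomass

    def __post_init__(self):
        if self.form not in ("tree", "grass"):
            raise ValueError("form must be 'tree' or 'grass'")


DEFAULT_PFTS: tuple[PFTDef, PFTDef, PFTDef] = (
    PFTDef("tropical_tree", "tree", ps.TREE_C3, t_coldest_min=5.5,
           canopy_height=8.0, turnover_rate=0.05, sla=0.010, leaf_frac=0.25,
           resp_maint=0.35),
    PFTDef("C3_grass", "grass", ps.C3, t_coldest_min=None,
           canopy_height=0.5, turnover_rate=0.5, sla=0.012, leaf_frac=1.0,
           resp_maint=0.8),
    PFTDef("C4_grass", "grass", ps.C4, t_coldest_min=15.5,
           canopy_height=0.5, turnover_rate=0.5, sla=0.012, leaf_frac=1.0,
           resp_maint=0.8),
)


@dataclass(frozen=True)
class SoilParams:
    """Single-layer bucket hydrology constants."""

    capacity: float = 150.0        # mm of plant-available water
    infiltration: float = 0.8      # fraction of monthly rain entering the bucket
    evap_rate: float = 1.8         # bare-soil evaporation, mm/day at saturation


DEFAULT_SOIL = SoilParams()


@dataclass
class VegState:
    """Per-cell vegetation state, vectorised over ``n`` cells.

    ``biomass``/``lai``/``fpc`` have shape ``(3, n)`` in PFT order
    (tree, C3 grass, C4 grass); ``soil_w`` is the bucket content (mm).
    """

    biomass: np.ndarray
    lai: np.ndarray
    fpc: np.ndarray
    soil_w: np.ndarray
    gpp: np.ndarray        # last annual GPP per PFT, g C/m²/yr
    npp: np.ndarray

    @classmethod
    def bare(cls, n: int, soil: SoilParams = DEFAULT_SOIL) -> "VegState":
        z = lambda: np.zeros((3, n))
        return cls(z(), z(), z(), np.full(n, 0.5 * soil.capacity), z(), z())

    def copy(self) -> "VegState":
        return VegState(*(getattr(self, f).copy()
                          for f in ("biomass", "lai", "fpc", "soil_w", "gpp", "npp")))

    def established_fpc(self, pfts=None) -> np.ndarray:
        """FPC net of the seed-recolonisation floor, shape (3, n).

        The small seed biomass every eligible PFT is held at is a
        modelling device for recolonisation, not real cover; reported
        cover (maps, shares, binned summaries) excludes it.
        """
        if pfts is None:
            pfts = DEFAULT_PFTS
        b = np.clip(self.biomass - SEED_BIOMASS, 0.0, None)
        lai = np.array([p.sla * p.leaf_frac for p in pfts])[:, None] * b
        return light_competition(fpc_from_lai(lai))

    def grass_share_c4(self, min_grass: float = 0.01, pfts=None) -> np.ndarray:
        """C4 fraction of the established grass layer; NaN below min_grass."""
        f = self.established_fpc(pfts)
        tot = f[C3G] + f[C4G]
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(tot >= min_grass, f[C4G] / np.where(tot > 0, tot, 1.0), np.nan)
        return share


def establishment_filter(pft: PFTDef, t_coldest) -> np.ndarray | bool:
    """Survival/establishment flag from the coldest-month mean temperature.

    The C4 grass fails strictly below 15.5 °C; the C3 grass never fails.
    """
    t = np.asarray(t_coldest, dtype=float)
    if pft.t_coldest_min is None:
        out = np.ones_like(t, dtype=bool)
    else:
        out = t >= pft.t_coldest_min
    return bool(out) if out.ndim == 0 else out


def fpc_from_lai(lai) -> np.ndarray | float:
    """Foliage projective cover from LAI (Lambert–Beer, k = 0.5)."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    out = 1.0 - np.exp(-K_BEER * lai)
    return float(out) if out.ndim == 0 else out


def light_competition(fpc: np.ndarray, cap: float = FPC_CAP) -> np.ndarray:
    """Cap total cover, reducing grasses (proportionally) before trees.

    ``fpc`` has shape (3, n); returns the adjusted copy.
    """
    fpc = np.clip(np.asarray(fpc, dtype=float), 0.0, 1.0).copy()
    total = fpc.sum(axis=0)
    over = total > cap
    if not np.any(over):
        return fpc
    grass = fpc[C3G] + fpc[C4G]
    excess = np.where(over, total - cap, 0.0)
    take = np.minimum(excess, grass)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(grass > 0, (grass - take) / np.where(grass > 0, grass, 1.0), 1.0)
    fpc[C3G] *= scale
    fpc[C4G] *= scale
    fpc[TREE] = np.minimum(fpc[TREE], cap)    # residual excess falls on trees
    return fpc


def update_structure(state: VegState, pfts=DEFAULT_PFTS) -> None:
    """Recompute LAI and (capped) FPC from biomass.

    Call after any direct edit of ``state.biomass`` so the cover fields
    the next annual update sees are consistent.
    """
    for i, p in enumerate(pfts):
        state.lai[i] = p.sla * p.leaf_frac * state.biomass[i]
    state.fpc = light_competition(fpc_from_lai(state.lai))


def annual_update(state: VegState, tas: np.ndarray, pre: np.ndarray, sun: np.ndarray,
                  ca: float, eligible: np.ndarray,
                  pfts=DEFAULT_PFTS, soil: SoilParams = DEFAULT_SOIL,
                  fire_fn=None) -> VegState:
    """Advance the vegetation state by one year (in place; also returned).

    Parameters
    ----------
    tas, pre, sun
        Monthly climatology for the cells, shape ``(12, n)``.
    ca
        Ambient CO2, ppm.
    eligible
        Boolean (3, n) establishment/survival mask (from
        :func:`establishment_filter` on the cell summaries).
    fire_fn
        Optional callable ``fire_fn(state) -> None`` applied after the
        growth step and before turnover (growth -> fire -> turnover).
    """
    n = state.biomass.shape[1]
    gpp_y = np.zeros((3, n))
    fpc_tree = state.fpc[TREE]

    for m in range(12):
        days = _DAYS[m]
        t_day = tas[m] + DIURNAL_OFFSET
        par = par_from_sunshine(sun[m])
        soil_frac = state.soil_w / soil.capacity
        aet = np.zeros(n)
        for i, p in enumerate(pfts):
            gpp_pd, aet_pd = ps.daily_gpp(p.pathway, t_day, par, soil_frac, ca,
                                          return_aet=True)
            light = np.ones(n) if p.form == "tree" else 1.0 - fpc_tree
            area = state.fpc[i] * light
            gpp_y[i] += gpp_pd * days * area
            aet += np.asarray(aet_pd) * days * area
        evap = soil.evap_rate * days * soil_frac * (1.0 - state.fpc.sum(axis=0))
        state.soil_w = np.clip(state.soil_w + soil.infiltration * pre[m] - aet - evap,
                               0.0, soil.capacity)

    npp = np.empty((3, n))
    for i, p in enumerate(pfts):
        npp[i] = NPP_FRAC * gpp_y[i] - p.resp_maint * state.biomass[i]
        state.biomass[i] = np.clip(state.biomass[i] + npp[i], 0.0, None)
        # establishment: eligible PFTs never fall below seed biomass
        state.biomass[i] = np.where(eligible[i],
                                    np.maximum(state.biomass[i], SEED_BIOMASS),
                                    state.biomass[i] * INELIGIBLE_SURVIVAL)
    state.gpp, state.npp = gpp_y, npp

    if fire_fn is not None:
        update_structure(state, pfts)
        fire_fn(state)

    for i, p in enumerate(pfts):
        state.biomass[i] *= (1.0 - p.turnover_rate)
        state.biomass[i] = np.where(eligible[i],
                                    np.maximum(state.biomass[i], SEED_BIOMASS),
                                    state.biomass[i])
    update_structure(state, pfts)
    return state


_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
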