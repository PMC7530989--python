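"""C3 and C4 gross assimilation with explicit CO2–water coupling.

A simplified Collatz-style scheme: gross assimilation is the minimum of a
light-limited and a Rubisco-limited rate.  For the C3 pathway the
quantum yield declines with temperature through the CO2 compensation
point Gamma* (photorespiration), and the Rubisco-limited rate carries
the same Gamma* penalty; for the C4 pathway the quantum yield is
temperature-independent and the carboxylation term is nearly saturated
in CO2 (the CO2-concentrating mechanism), so C4 productivity is far
less sensitive to lowered ambient CO2.

Water coupling follows the supply/demand logic of LPJ-family models:
the canopy conductance required to realise unstressed assimilation,

    gcMax = gmin + k * Amax / (ca * (1 - lambda)),

falls with rising ambient CO2 ``ca`` (CO2 fertilisation acts through
water use), and rises steeply for the C3 pathway whose optimal
internal-to-ambient CO2 ratio ``lambda`` is high.  Transpirational
demand saturates in conductance, D(gc) = Emax*(1 - exp(-gc/gm))
(an empirical Monteith-type form); when demand at gcMax exceeds the
soil-limited supply S, conductance — and with it assimilation — is
down-regulated so that realised demand equals S.

Units: assimilation in g C m-2 day-1, PAR in mol photons m-2 day-1,
CO2 concentrations and compensation points in ppm (µmol mol-1),
conductances in mm s-1, water fluxes in mm day-1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PathwayParams", "C3", "C4", "TREE_C3",
    "gamma_star", "gross_assimilation", "gc_max", "transpiration_demand",
    "water_limited_conductance", "daily_gpp", "crossover_temperature",
]

#: Atmospheric O2 mixing ratio, ppm — sets the CO2 compensation point.
O2_PPM = 209_000.0
#: CO2/O2 specificity of Rubisco at 25 °C and its Q10 (declines with T).
TAU25, TAU_Q10 = 2600.0, 0.57

#: Maximum transpiration rate at wide-open stomata, mm/day.
E_MAX = 5.0
#: Conductance scale of the saturating demand curve, mm/s.
G_M = 2.5
#: Maximum soil-water supply rate at saturation, mm/day.  Slightly above
#: E_MAX so that saturated soil never down-regulates conductance.
S_MAX = 6.0
#: Conductance units constant in gcMax (mm/s per (gC m-2 d-1 / ppm)).
K_GC = 24.0
#: Grams of carbon per mole of CO2.
GC_PER_MOL = 12.0


@dataclass(frozen=True)
class PathwayParams:
    """Photosynthetic-pathway parameter set."""

    pathway: str                 # "C3" or "C4"
    lambda_opt: float            # optimal ci/ca ratio (C4 < C3)
    b_resp: float                # leaf respiration as fraction of Vmax (C4 > C3)
    alpha: float                 # intrinsic quantum yield, mol CO2 / mol photons
    vmax25: float                # Rubisco-limited rate at 25 °C, g C m-2 day-1
    k_co2: float                 # Michaelis constant of the carboxylation term, ppm
    t_low: float                 # low-T inhibition midpoint, °C
    t_high: float                # high-T inhibition midpoint, °C
    t_min_photo: float           # no assimilation below, °C
    t_max_photo: float           # no assimilation above, °C
    gmin: float = 0.5            # minimum canopy conductance, mm/s

    def __post_init__(self):
        if not 0.0 < self.lambda_opt < 1.0:
            raise ValueError("lambda_opt must lie in (0, 1)")


# Pathway defaults.  lambda and b_resp orderings (C4 lower lambda, higher
# leaf respiration) are the core C3/C4 contrast; alpha/vmax values are
# calibrated so that under wet soil and 360 ppm the C4 GPP overtakes C3
# near 20 °C, with the crossover falling as CO2 or soil moisture drops.
# alpha here is a whole-day effective quantum yield (daylight-averaged),
# hence smaller than instantaneous leaf-level values.
C3 = PathwayParams("C3", lambda_opt=0.8, b_resp=0.015, alpha=0.040, vmax25=60.0,
                   k_co2=450.0, t_low=4.0, t_high=36.0,
                   t_min_photo=-4.0, t_max_photo=45.0)
C4 = PathwayParams("C4", lambda_opt=0.4, b_resp=0.02, alpha=0.030, vmax25=22.0,
                   k_co2=12.0, t_low=12.0, t_high=48.0,
                   t_min_photo=2.0, t_max_photo=55.0)
#: Tropical tree leaves use C3 biochemistry with a slightly lower capacity.
TREE_C3 = replace(C3, vmax25=54.0)


def gamma_star(t: np.ndarray | float) -> np.ndarray | float:
    """CO2 compensation point Gamma* (ppm); rises with temperature."""
    tau = TAU25 * TAU_Q10 ** ((np.asarray(t, dtype=float) - 25.0) / 10.0)
    return O2_PPM / (2.0 * tau)


def _temp_inhibition(p: PathwayParams, t) -> np.ndarray:
    """Peaked temperature response of the carboxylation capacity (0..1)."""
    t = np.asarray(t, dtype=float)
    q10 = 2.0 ** ((t - 25.0) / 10.0)
    inhib = (1.0 + np.exp(0.3 * (p.t_low - t))) * (1.0 + np.exp(0.3 * (t - p.t_high)))
    return q10 / inhib


def _vmax(p: PathwayParams, t) -> np.ndarray:
    return p.vmax25 * _temp_inhibition(p, t) / _temp_inhibition(p, 25.0)


def leaf_respiration(p: PathwayParams, t) -> np.ndarray:
    """Leaf (dark) respiration, b_resp fraction of Rubisco capacity."""
    return p.b_resp * _vmax(p, t)


def gross_assimilation(p: PathwayParams, t_day, par, ca, lam: float | None = None):
    """Gross assimilation A (g C m-2 day-1) before water down-regulation.

    Minimum of the light-limited and Rubisco-limited rates.  Zero
    outside the pathway's photosynthetic temperature range and at zero
    light; strictly increasing in ca for C3 over the glacial range,
    near-saturated for C4.
    """
    t_day = np.asarray(t_day, dtype=float)
    par = np.asarray(par, dtype=float)
    if np.any(np.asarray(ca) <= 0):
        raise ValueError("ambient CO2 must be positive")
    lam = p.lambda_opt if lam is None else lam
    ci = lam * np.asarray(ca, dtype=float)

    if p.pathway == "C3":
        gs = gamma_star(t_day)
        light = p.alpha * np.clip((ci - gs) / (ci + 2.0 * gs), 0.0, None) * par * GC_PER_MOL
        rub = _vmax(p, t_day) * np.clip((ci - gs) / (ci + p.k_co2), 0.0, None)
    else:
        light = p.alpha * par * GC_PER_MOL
        rub = _vmax(p, t_day) * ci / (ci + p.k_co2)

    a = np.minimum(light, rub)
    in_range = (t_day > p.t_min_photo) & (t_day < p.t_max_photo)
    a = np.where(in_range, np.clip(a, 0.0, None), 0.0)
    return float(a) if a.ndim == 0 else a


def gc_max(a_max, ca, p: PathwayParams):
    """Maximum potential canopy conductance (mm/s) when water is unlimited.

    gcMax = gmin + k * Amax / (ca * (1 - lambda)).  Decreases with ca at
    fixed Amax — the water-use-efficiency side of CO2 fertilisation.
    """
    if p.lambda_opt >= 1.0:
        raise ValueError("lambda_opt >= 1 gives an unbounded conductance")
    a_max = np.asarray(a_max, dtype=float)
    if np.any(a_max < 0):
        raise ValueError("a_max must be non-negative")
    g = p.gmin + K_GC * a_max / (np.asarray(ca, dtype=float) * (1.0 - p.lambda_opt))
    return float(g) if np.ndim(g) == 0 else g


def transpiration_demand(gc):
    """Transpirational demand D(gc) = Emax*(1 - exp(-gc/gm)), mm/day."""
    d = E_MAX * (1.0 - np.exp(-np.asarray(gc, dtype=float) / G_M))
    return float(d) if np.ndim(d) == 0 else d


def supply_rate(soil_frac):
    """Soil water supply S = s_max * relative soil water content, mm/day."""
    return S_MAX * np.clip(np.asarray(soil_frac, dtype=float), 0.0, 1.0)


def water_limited_conductance(gcmax, d_pot, s):
    """Down-regulate conductance so realised demand does not exceed supply.

    Returns ``(gc, factor)`` with ``factor = gc/gcmax`` in (0, 1].  When
    demand at gcMax is within supply, gc = gcMax exactly (continuous at
    the stress onset).  The saturating demand curve inverts in closed
    form: gc = -gm * ln(1 - S/Emax).
    """
    gcmax = np.asarray(gcmax, dtype=float)
    d_pot = np.asarray(d_pot, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(d_pot < 0):
        raise ValueError("supply and demand must be non-negative")
    stressed = d_pot > s
    frac = np.clip(s / E_MAX, 0.0, 1.0 - 1e-12)
    gc_stress = -G_M * np.log(1.0 - frac)
    gc = np.where(stressed, np.minimum(gc_stress, gcmax), gcmax)
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(gcmax > 0, gc / np.where(gcmax > 0, gcmax, 1.0), 1.0)
    factor = np.clip(factor, 0.0, 1.0)
    if np.ndim(gc) == 0:
        return float(gc), float(factor)
    return gc, factor


def daily_gpp(p: PathwayParams, t_day, par, soil_frac, ca, return_aet: bool = False):
    """Daily GPP (g C m-2 day-1 of foliage) after water down-regulation.

    Chains gross assimilation -> gcMax -> demand -> water-limited
    conductance -> down-regulated assimilation minus leaf respiration.
    Optionally also returns the realised transpiration (mm/day).
    """
    a = gross_assimilation(p, t_day, par, ca)
    gcmax = gc_max(a, ca, p)
    d_pot = transpiration_demand(gcmax)
    s = supply_rate(soil_frac)
    gc, factor = water_limited_conductance(gcmax, d_pot, s)
    gpp = np.clip(np.asarray(factor) * np.asarray(a) - leaf_respiration(p, t_day), 0.0, None)
    gpp = np.where(np.asarray(a) > 0, gpp, 0.0)
    if np.ndim(gpp) == 0:
        gpp = float(gpp)
    if not return_aet:
        return gpp
    aet = np.where(np.asarray(a) > 0, np.minimum(transpiration_demand(gc), s), 0.0)
    return gpp, (float(aet) if np.ndim(aet) == 0 else aet)


#: PAR used for crossover diagnostics (saturating light), mol m-2 day-1.
PAR_REF = 40.0


def crossover_temperature(ca: float, soil_frac: float = 1.0,
                          par: float = PAR_REF, tol: float = 0.05) -> float:
    """Lowest daytime temperature at which C4 GPP first matches C3 GPP.

    Scan of [0, 45] °C followed by bisection to ``tol`` °C.  Returns NaN
    when no crossover exists in range (one pathway dominant throughout).
    Under wet soil and present-day CO2 (360 ppm) the crossover sits near
    20 °C and moves downward as CO2 or soil moisture falls.
    """
    if not 100.0 <= ca <= 1000.0:
        raise ValueError("ca outside the supported 100–1000 ppm range")
    if not 0.0 < soil_frac <= 1.0:
        raise ValueError("soil_frac must lie in (0, 1]")

    def margin(t):
        g4 = daily_gpp(C4, t, par, soil_frac, ca)
        g3 = daily_gpp(C3, t, par, soil_frac, ca)
        return g4 - g3, g4

    ts = np.arange(0.0, 45.0 + 1e-9, 0.25)
    lo = None
    for t in ts:
        m, g4 = margin(t)
        if m >= 0 and g4 > 0:
            hi = t
            break
        lo = t
    else:
        return float("nan")
    if lo is None:      # C4 already ahead at the low end of the scan
        return float(ts[0])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        m, g4 = margin(mid)
        if m >= 0 and g4 > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
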