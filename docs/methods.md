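# Methods

This note documents the model equations, parameter choices and known
limitations of `veld`, in the spirit of a model-description paper for a
strongly reduced savanna DGVM.

## Scope and reduction strategy

The package isolates one question: how do atmospheric CO₂, rainfall
seasonality and fire jointly set the balance of C₃ grass, C₄ grass and
tree cover over a southern-African domain under glacial boundary
conditions?  Everything not needed for that question is cut: the PFT
set is reduced from the nine of full LPJ-family models to three
(tropical raingreen tree, C₃ grass, C₄ grass), hydrology to a
single-layer bucket, fire to a one-parameter spread model, and the
forcing to a 12-month climatology recycled every year.  The reduction
is deliberate and documented per module below; the trade-offs it buys
are second-scale runtimes and exact reproducibility.

## Synthetic climate generator

The generator (`veld.climate`) produces monthly temperature,
precipitation, wet-day and sunshine fields on a regular cell-centre
grid (default 1°, 10–35°S × 10–35°E) with the structure that matters
for the experiment:

* **Rainfall zones.** Monthly rainfall at each cell is a mix of a
  summer-peaking mode ∝ (1 + cos θ_m)², a winter-peaking mode (the same
  shape six months out of phase) and a uniform mode.  The winter mode
  is weighted by a Gaussian centred on the south-west corner, the
  uniform mode by a south-coast band, and the summer mode carries the
  remainder — giving winter-rainfall, year-round and summer-rainfall
  regions like the real subcontinent.
* **Temperature.** MAT falls poleward at 0.9 °C/degree from 30 °C at
  10°S, with a +3 °C west→east contrast.  The seasonal half-amplitude
  is ~1.2 °C equatorward of 26°S, rising to ~5.5 °C at 35°S.  The low
  tropical amplitude matters: it supplies near-aseasonal cells across
  the MAT 14–20 °C range, which is what lets a 25°-wide grid emulate
  the continental climate space in which the C₄ region's MAT boundary
  is expressed (in an all-Africa map those cells are the tropical
  highlands).
* **Precipitation amount.** MAP ramps from <150 mm in the SW interior
  to >1000 mm at the NE corner (a quadratic-in-NE-ness ramp), plus a
  200 mm supplement in the winter-rain corner.
* **Noise.** Multiplicative lognormal noise (σ = 0.10) on monthly
  rainfall and additive noise (σ = 0.2 °C) on temperature, from a
  seeded generator; regeneration with the same seed is bit-identical.
* **Derived fields.** Wet days follow a saturating map of monthly
  rainfall, bounded [1, days-in-month] where rain falls; sunshine
  fraction declines with monthly rainfall.

Four fixed LGM-like variants (A–D) emulate disagreeing glacial
reconstructions: uniform cooling of 2.0/3.5/2.5/5.5 °C, precipitation
scaling of 0.90/0.85/1.00/0.75, and a winter-rainfall expansion of
distinct strength and reach (implemented as a positional blend of each
cell's monthly shape toward the winter mode).  The values are package
choices — no public anomaly tables exist at this reduction level — and
are fixed in `LGM_VARIANTS`.

## Seasonality statistics

Concentration and phase are the length and direction of the mean
monthly vector with θ_m = 2π(m−1)/12, January at angle 0, increasing
through the year (an explicit convention; the phase quadrant is resolved
with the two-argument arctangent).  Months are equally weighted — no
day-count weighting — and the phase is flagged undefined when
C < 1e−9.  Scale invariance, the rotation property and the [0, 1]
bound are enforced by property tests.

## Photosynthesis and the CO₂–water coupling

Gross assimilation per unit foliage is

    A = min(A_light, A_rub)

with, for C₃: A_light = α₃ · (c_i − Γ*)/(c_i + 2Γ*) · PAR and
A_rub = Vmax(T) · (c_i − Γ*)/(c_i + K_C3); for C₄:
A_light = α₄ · PAR and A_rub = Vmax(T) · c_i/(c_i + K_C4) with a small
K_C4 (CO₂-concentrating mechanism).  c_i = λ·c_a with λ = 0.8 (C₃) and
0.4 (C₄); Γ* follows the standard O₂/(2τ) form with τ(25 °C) = 2600 and
Q10 = 0.57; Vmax has a Q10 = 2 response damped by low- and high-
temperature logistic inhibitions.  Leaf respiration is b·Vmax(T) with
b = 0.015 (C₃) < 0.02 (C₄).  The quantum yields are whole-day effective
values (α₃ = 0.040, α₄ = 0.030 mol CO₂/mol photons), hence below
instantaneous leaf-level numbers.

Water enters through the conductance budget: gcMax = gmin +
k·Amax/(c_a(1−λ)) (k = 24, gmin = 0.5 mm/s), demand
D(gc) = E_max(1 − e^(−gc/g_m)) (E_max = 5 mm/day, g_m = 2.5 mm/s), and
supply S = s_max · soil_fraction (s_max = 6 mm/day, chosen slightly
above E_max so saturated soil never limits).  When D(gcMax) > S the
conductance is the closed-form inversion gc = −g_m·ln(1 − S/E_max) and
assimilation is scaled by gc/gcMax; the scheme is continuous at the
stress onset and is checked against a brute-force scan oracle.

The α/Vmax set was calibrated jointly so the wet-soil, 360 ppm GPP
crossover emerges near 20 °C — the behaviour the scheme is meant to
reproduce — giving 20.3 °C, with 16.4 °C at 250 ppm, 12.1 °C at
150 ppm and 9.9 °C at 360 ppm over dry soil (soil fraction 0.3).
"Present-day CO₂" is taken as 360 ppm.  The calibration was done on
the crossover scan alone, before any factorial-level quantity was
evaluated.

## Vegetation dynamics

Annual structure, monthly fluxes.  Each month: daytime temperature =
monthly mean + 2.5 °C; PAR = 18 + 30·sunshine (mol photons/m²/day);
per-PFT GPP = daily GPP × days × own FPC × light factor (1 for trees,
1 − tree FPC for grasses); transpiration of all PFTs and bare-soil
evaporation (1.8 mm/day × soil fraction × bare fraction) drain the
150 mm bucket, infiltration captures 80% of rainfall.  Annually:
NPP = 0.5·GPP − r_m·biomass (maintenance r_m: tree 0.35/yr, grass
0.8/yr), allocation to a single biomass pool, LAI = SLA · leaf-fraction
· biomass (tree 0.010 m²/gC and 0.25; grass 0.012 and 1.0), FPC by
Lambert–Beer with k = 0.5, total cover capped at 0.95 with grasses
scaled back proportionally before trees, and background turnover (tree
0.05/yr, grass 0.5/yr).

Bioclimatic limits act on the coldest climatological month: C₄ grass
< 15.5 °C fails, tree < 5.5 °C fails, C₃ grass never.  Ineligible PFTs
retain 10% of biomass per year (rapid die-off); eligible PFTs are held
at a 2 g C/m² seed pool, from which grasses regain half their cover in
1–2 years and trees in decades.  **Reported cover is net of this seed
pool**: the seed is a recolonisation device, and including it would
pollute cover maps and grass-share statistics with a constant floor.

The grass maintenance rate and bare-soil evaporation were set so that
equilibrium C₄ cover over a warm summer-rain cell rises realistically
with rainfall (roughly 0.2/0.45/0.65 cover at 300/500/800 mm/yr at
150 ppm with fire), i.e. a savanna-like cover–rainfall ramp; tree
parameters so that trees dominate only wet (>700 mm) warm cells and
thin out under fire.

## Fire

Fuel is grass biomass plus 20% of tree biomass.  Fire-season dryness is
1 − m/m_ext (m_ext = 0.35), where m is the minimum three-month running
wet-day fraction of the climatological year.  The annual burned
fraction is ignitions (1/cell/yr) × dryness² (probability an ignition
takes) × 0.45·dryness (mean spread), zero below 200 g C/m² fuel —
replacing the full Rothermel spread system with a single calibrated
dryness×spread term.  Flame height is 0.15·√(consumed fuel × dryness)
metres (concave); crown-scorch mortality is a rebased logistic in
flame-height/canopy-height (≈0.48 at the canopy top), and trees take an
additional cambial loss of 0.35 × burned fraction.  The fire step runs
between growth and turnover (growth → fire → turnover).  With fire off
the step is skipped entirely, and fire-off runs are bit-identical to
runs without the fire module.

Fire parameters were tuned against a single qualitative constraint —
fire must restructure tree cover much more than the C₃:C₄ composition
of the grass layer (both grass types share one canopy height, so scorch
hits them symmetrically while the asymmetry comes from slow tree
recovery) — since no burned-area climatology exists for this reduced
configuration.

## Experiments and analysis

Defaults: 200-year spin-up from bare ground (with early exit once
per-cell FPC drift < 1e−4/yr over 10-year windows; non-converged cells
are flagged, ~3% of cells in fire-on runs sit on fuel-threshold limit
cycles), then a 50-year averaging run.  Doubling the spin-up changes
mean cover by <1%: the climatological forcing makes the fixed point
fast.  The full-scale protocol values (4000/1380 years) remain
selectable in the config.

Climate-space binning uses 1 °C MAT × 100 mm MAP bins (and 0.2-wide
concentration × month-phase polar bins); cells with established grass
cover below 0.01 are excluded from share statistics.  MAT×MAP panels
report C₄ FPC as a fraction of land, polar panels the C₄ share of
grass.  The "boundary" diagnostic is the lowest bin edge at which
binned mean C₄ FPC over summer-rainfall cells first exceeds half its
maximum across bins.

## Behaviour of the reduced model, and honest caveats

* The low-CO₂ C₄ advantage is expressed primarily in the *share* of the
  grass layer and in C₄ taking space freed by retreating trees.  Raw C₄
  foliage density in already-grass-dominated wet cells can *fall*
  slightly at 150 ppm (C₄ too pays a water cost at low CO₂); the C₄
  expansion signal is the share and the tree-retreat cells.
* The association of winter-rainfall climate with C₃ grass runs through
  the coldest-month survival filter (winter-rain cells are also
  cold-winter cells) rather than through within-year growth timing: at
  250 ppm the crossover (16.4 °C) sits below the wet-season daytime
  temperature of any cell warm enough to pass the 15.5 °C filter.  A
  C₄ exclusion south of the winter margin "regardless of CO₂" is the
  corresponding behaviour of the full-scale model this emulates.
* The synthetic grid reproduces climate-space *structure*, not
  geography: cell counts per climate bin differ from any real map, so
  binned boundaries are robust but areal statistics are not
  transferable.
* No interannual variability: fire and drought act as identical annual
  pulses, which removes rare-event dynamics (fire escapes, droughts)
  and makes all equilibria deterministic fixed points.
* No nitrogen limitation, acclimation, canopy layering, soil carbon,
  dispersal between cells, or human ignitions.
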