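# Methods

## Model overview

`planktos` simulates a protist community whose members span the
trophic spectrum: two phytoplankton types (diatoms with an obligate
silica requirement, and silica-free "green" flagellates), pure
phagotrophic protozooplankton, constitutive mixoplankton (CM: innate
photosystem plus phagotrophy) and non-constitutive mixoplankton (NCM:
primarily phagotrophic, photosynthesizing only with chloroplasts
stolen from phototrophic prey).  Every type carries carbon, nitrogen
and phosphorus state variables; diatoms add silica and all
photosynthesizing types add chlorophyll-a, so stoichiometry is fully
variable.  Physiology is quota-regulated in the Droop tradition: the
internal N:C, P:C and Si:C ratios, mapped onto dimensionless statuses
in [0, 1], control nutrient uptake, chlorophyll synthesis and (through
prey quality) assimilation efficiency.  Liebig's law of the minimum
selects the limiting status.

### Status functions

* Nitrogen status: linear ramp from 0 at `NCmin` to 1 at `NCopt`
  (nitrogen is not stored in an inactive form).
* Phosphorus status: cubic smoothstep sigmoid between `PCmin` and
  `PCopt` with zero slope at both ends — the near-1 plateau below the
  optimum represents polyphosphate storage.
* Silica status: Michaelis–Menten in *external* dissolved Si
  (incorporated frustule silica is inaccessible), half-saturation
  `KtSi`.

The smoothstep `x²(3−2x)` is the package's single normalized sigmoid;
it is used wherever a curve must switch smoothly between regimes
(uptake regulation, kleptoplast shut-down, capture/satiation blending
is the analytic Holling form instead).  Its flat ends keep every
regulated rate continuously differentiable across the quota
thresholds, which the fixed-step integrator repays with smaller
splitting error.

### Uptake regulation

Optimal uptake is `UmT · QCopt · S/(S+Kt)`.  Below the optimal quota,
uptake is enhanced by up to `Qmax/Qopt` (i.e. at most the flux that
would fill the *maximum* quota at maximum growth); above it, ammonium
and phosphate uptake are repressed sigmoidally to zero at the maximum
quota, while nitrate (with its own, slightly lower quota pair
`NO3Copt`/`NO3Cmax`) and silica (at `SCopt`) shut off hard.  All
curves equal the optimal-quota uptake exactly at the optimum.
Nitrogen uptake is additionally ceiling-coupled to the phosphorus
status: under full P stress it stops once N:C exceeds `PCminNCmax`
and is unhindered below `PCminNCmin`, so N:C relaxes toward the
P-limited band.  Ammonium–nitrate preference is emergent: the lower
nitrate ceiling quotas plus the respiratory reduction cost `redco`
favour ammonium without an explicit inhibition term.

### Phototrophy

Gross fixation follows the Smith P–I curve
`Cfix = PSqm·a/√(PSqm²+a²)`, `a = αChl·(Chl:C)·PFD`.  The capacity
`PSqm = relPS·NCu·UmT·(1+NCopt·(redco+AR))/(1−PSDOC) + BR` covers
growth, the carbon cost of acquiring the nitrogen that growth needs,
and pre-pays the fixed leakage fraction `PSDOC`; basal respiration is
the only term not modulated by nitrogen status.  `relPS = 2` gives the
primarily phototrophic types their photosynthetic overcapacity.
Chlorophyll synthesis is proportional to
`NPCu·(1−Cfix/PSqm)·(1−ChlC/ChlCmax)` — repressed by nutrient
limitation, light saturation and the quota ceiling, hence enhanced
under low light (photoacclimation); degradation is linear in the
nitrogen-stress signal `(1−NCu)` with maximum rate 0.5 d⁻¹.  NCMs
acquire chlorophyll from ingested phototrophic prey through a
smoothstep shut-down at their `ChlCmax` and lose it linearly at
`lossChl_rate`; without phototrophic prey an NCM relaxes to pure
heterotrophy on the analytic exponential.

A known idealization: synthesis is not energy-gated, so a dark,
nutrient-replete cell will still pigment up to its quota ceiling.
This does not affect carbon or nutrient budgets (chlorophyll is a
pigment proxy outside the element books) and is irrelevant once any
light is present, but dark-incubation chlorophyll dynamics should not
be interpreted quantitatively.

### Phagotrophy

Swimming speed is a log-log allometry of equivalent spherical
diameter (ESD), `log10(v/µm s⁻¹) = 0.36 + 0.75·log10(ESD/µm)` —
roughly half a body length per second at 10 µm.  Encounters follow
the Gerritsen–Strickler random-swimmer kernel with capture radius
equal to the sum of the two cell radii; prey density is prey carbon
divided by the per-cell carbon content (Menden-Deuer–Lessard volume
regressions).  Captures are discounted by the predator's optimum
capture rate `optCR`, the handling matrix `PR` (diagonal zero; CM rows
zero for prey larger than the predator; phototroph rows zero), and a
light-inhibition sigmoid with dark asymptote `relPhag` (half-saturation
10 µmol photons m⁻² s⁻¹) for mixoplankton.

Prey quality compares the captured-prey N:C and P:C mix against the
predator's optimal quotas and maps the scarcer ratio onto an
assimilation efficiency in [`AEo`, `AEm`].  The satiation asymptote is
`maxIng = (UmT+BR)/(opAE·(1−SDA))`, so poorer prey raises the
ingestion the predator attempts (compensatory feeding).  Realized
ingestion is the smooth Holling-II blend
`ingC = maxIng·sumCP/(maxIng+sumCP)`, which is capture-limited at low
and satiation-limited at high prey density with a continuous
derivative (a hard minimum is available via `smooth_ingestion=False`).
Assimilated N and P are referenced to carbon assimilation and the
predator's optimal quotas, capped by what was ingested; the remainder
leaves as particulate organics.  Ingested prey silica goes entirely to
the opal pool; ingested prey chlorophyll is destroyed except for the
NCM-acquired fraction.

### Conservation equations and numerics

All process rates are assembled flux-wise: every transfer has a source
and a destination (dissolved pools, labile DOC, particulate detritus,
opal) or an explicit budget (DIC sink, burial, boundary in/outflow,
denitrification), so carbon, nitrogen, phosphorus and silica are
conserved to machine rounding; the tests require < 1e-9 relative
drift over 1000 steps and observe ~1e-13.  Respired carbon goes to a
tracked DIC sink (inorganic carbon is not a limiting resource).
Mortality is linear (`mrt·C`) for diatom, green and CM and quadratic
(`mrt·C²`) for protozooplankton — the implicit higher-trophic-level
closure — routed to particulate detritus at the organism's current
stoichiometry.

Integration is fixed-step explicit Euler.  Positivity is guarded by a
per-pool limiter: if a step would remove more than 90% of a pool, all
outgoing fluxes of that pool *and their linked gains* are scaled by a
common factor, so the guard never violates conservation.  Quota caps
are enforced at the end of each step: N and P above their maximum
quotas are voided to the dissolved pools, carbon below the minimum
N:C is voided to labile DOC, Chl:C is clipped at `ChlCmax` (silica is
never voided).  Predator respiration uses the pre-limiter
assimilation rates; when the limiter engages, respiration lags the
scaled flux by one step without affecting the element budgets.
Dormancy: pools below 1e-10 gC m⁻³ freeze all physiological rates,
avoiding 0/0 quota arithmetic; boundary seeding keeps populations
revivable.

### Column schematization

Scenario columns have two equal cells.  Horizontal through-flow
relaxes every pool toward the boundary concentration with a 30-day
residence time; vertical diffusion (100 m² d⁻¹ mixed, 2 m² d⁻¹ during
stratified months, April–August) exchanges the cells; diatoms settle
at a Stokes velocity precomputed from their ESD (20 kg m⁻³ excess
density, ~0.5 m d⁻¹) and detritus at 1 m d⁻¹, with bottom export
logged to the burial budget.  Light decays by Lambert–Beer extinction
(background 0.12 m⁻¹, 0.03 m² g⁻¹ for suspended sediment, 16 m² g⁻¹
chlorophyll self-shading, 0.1 m² g⁻¹ POC); each cell sees its
*within-cell average* irradiance — the mid-depth value would starve
optically thick 5–20 m cells and misrepresent what a homogenised
population experiences.  First-order, Q10-scaled closures recycle
organic matter (decomposition 0.05 d⁻¹, DOC decay 0.1 d⁻¹, opal
dissolution 0.02 d⁻¹, nitrification 0.1 d⁻¹ at 20 °C; denitrification
off by default).  These rate constants stand in for the host
framework's standard water-quality modules and are config-exposed.

### Default parameterization

All five types share `UmRT = 0.81 d⁻¹` (no type starts with a growth
advantage), `Q10 = 2`, `Tref = 20 °C`.  Nitrogen quotas bracket the
Redfield mass ratio (0.07/0.15/0.20 gN gC⁻¹); phosphorus 0.005/0.02/
0.04 gP gC⁻¹ with luxury storage; diatom silica 0.10/0.25/0.35
gSi gC⁻¹.  Nitrate quota ceilings sit slightly below the ammonium
ones (0.14/0.19).  Sizes are group-typical medians (diatom 24 µm,
green 6 µm, protozoo 30 µm, CM 12 µm, NCM 60 µm).  Diatoms carry the
strongest light-harvesting apparatus (αChl 0.9, ChlCmax 0.06) — the
trait that wins them the spring bloom — and pay for it with frustule
ballast (settling).  Greens are the mid-field competitor (αChl 0.5,
ChlCmax 0.035).  CMs are parameterized as oligotrophy specialists:
a weaker photosystem (αChl 0.35, ChlCmax 0.025), high nutrient
affinity (KtN 0.005, KtP 0.001 g m⁻³), low phosphorus quotas
(0.002/0.008/0.02 gP gC⁻¹) and a moderate capture rate (optCR 0.4) on
prey no larger than themselves.  This is the trait syndrome reported
for mixotrophic flagellates — supplementing nutrients by ingestion
decouples them from dissolved phosphorus — and it is what produces
their competitive release when nutrient forcing is reduced.
Protozooplankton capture at optCR 0.5 with quadratic closure
(0.007 d⁻¹); mixoplankton dark-capture fractions are `relPhag` 0.05
(CM) and 0.5 (NCM).  Respiration costs: `redco` 1.71 gC gN⁻¹ (nitrate
reduction), `AR` 0.5 gC gN⁻¹, `SDA` 0.3, basal fraction 0.05.

### Synthetic forcings

The forcing generator emulates a monitored estuary→coast→offshore
gradient with four environmental systems (ES, CS, AS, OS).  Winter
maxima (g m⁻³): total N 1.2/0.5/0.9/0.12, PO₄ 0.09/0.035/0.06/0.02,
Si 0.8/0.45/0.5/0.12, SPM 80/25/6/4 for ES/CS/AS/OS, cosine
seasonality with system-specific summer troughs, and seeded lognormal
(σ = 0.15) year-to-year factors.  Total N is split 5:1 into
NO₃⁻:NH₄⁺ at every time point.  Temperature (3–18 °C, minimum
mid-February) and daily-mean irradiance (50–450 µmol m⁻² s⁻¹,
solstice-phased) are shared by all scenarios.  Eleven location
classes map onto the systems (2 ES, 4 CS, 2 AS, 3 OS; four of them
stratified) with synthetic depths of 8–40 m; every column uses the
same 30-day residence time and a 1e-4 gC m⁻³ boundary inoculum per
type.  What the generator does *not* emulate: tidal dynamics and
lateral biomass import (which dominate real estuaries — the ES
columns are expected to stay near-empty), observed interannual
weather, within-day light cycles, and salinity.  Passing tests on
these forcings demonstrate internally consistent mechanism, not a
validated hindcast of any monitored station.

### Problem sizes used in tests and checks

The operational configuration (3-minute step, 2-hourly output, decade
runs) is available but deliberately not used in the automated checks.
The test suite runs scenario columns for 3 simulated years (first
year spin-up) at a 30–60 minute Euler step — all specific rates are
O(1 d⁻¹), so these steps resolve the dynamics; halving the step
changes trajectories by well under 1% RMS (verified in the suite).
The box equilibrium test integrates up to 20 years at a 30-minute
step with steady state declared when every state variable changes by
less than 1e-6 (relative) over 30 days.

### Known limitations

* Two vertical cells cannot represent subsurface chlorophyll maxima
  or sharp pycnoclines; stratification is a diffusion switch.
* The quadratic protozoo closure, read volumetrically in gC m⁻³, is
  weak at typical biomass; grazer control is mostly bottom-up.
* No colony formation, no DOC/amino-acid osmotrophy, no dissolved
  oxygen, no salinity, no variable diatom density.
* NCMs are exercised in the box test only; the column scenarios run
  the four better-constrained types.
* One fixed size per type: prey-size windows are static, and the
  handling matrix must be revisited if sizes are changed.
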