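# planktos

A variable-stoichiometry simulator of marine protist communities that
span the trophic spectrum: diatoms, green algae, protozooplankton,
constitutive mixoplankton (CM — cells with their own photosystem that
also ingest prey) and non-constitutive mixoplankton (NCM — phagotrophs
that run photosynthesis on chloroplasts stolen from their prey).  It
is written for plankton ecologists and biogeochemical modellers who
want to ask how trophic strategies sort along environmental gradients
— in particular why constitutive mixoplankton occupy clear,
nutrient-poor, stratified waters while eutrophied, turbid, mixed
waters are dominated by pure phototrophs and their grazers.

## The model in brief

Each protist functional type (PFT) carries C, N and P state variables
(plus Si for diatoms and chlorophyll-a for all photosynthesizing
types).  Internal quotas regulate physiology in the Droop tradition:

* **Cellular status.** Quotas map to statuses in [0, 1]: nitrogen is a
  linear ramp NCu = (N:C − NCmin)/(NCopt − NCmin); phosphorus a
  sigmoid (polyphosphate storage); silica follows the *external*
  concentration, SCu = Si/(Si + KtSi).  Liebig's minimum selects the
  limiting resource.  Rates scale with temperature as Q10^((T−Tref)/10).
* **Uptake.** Optimal uptake UmT·QCopt·S/(S+Kt) is enhanced below the
  optimal quota (up to Qmax/Qopt) and repressed above it — sigmoidally
  for NH4+ and PO4^3−, with a hard stop for NO3− and Si.  N uptake is
  additionally capped by the phosphorus status.
* **Phototrophy.** Gross fixation follows the Smith P–I curve,
  Cfix = PSqm·a/√(PSqm² + a²) with a = αChl·(Chl:C)·PFD; PSqm covers
  growth, N-reduction costs and DOC leakage, scaled by the
  overcapacity relPS = 2 for primarily phototrophic types.
  Chlorophyll synthesis photoacclimates; NCMs acquire and lose
  kleptochloroplasts instead.
* **Phagotrophy.** Gerritsen–Strickler encounters from size-based
  swimming speeds, a predator×prey handling matrix (CMs cannot take
  prey larger than themselves), light-inhibited capture for
  mixoplankton, stoichiometric prey quality setting assimilation
  efficiency in [AEo, AEm], and a Holling type II satiation whose
  asymptote (UmT+BR)/(opAE·(1−SDA)) rises for poor prey.
* **Environment.** Two-cell vertical columns with 30-day through-flow,
  stratification as a vertical-diffusion switch, Beer–Lambert light
  with sediment and self-shading extinction, Stokes-settling diatoms,
  and first-order remineralization closures.  Element budgets close to
  machine precision; every loss flux is a source somewhere else or an
  explicit budget term.

A synthetic forcing generator emulates an estuary→coast→offshore
gradient (four systems: ES, CS, AS, OS; eleven named location
classes) so every scenario runs with no external data, and a
sensitivity driver perturbs single boundary factors by ±10%.

## Worked example

Three simulated years of the stratified offshore column (first year
spin-up, 30-minute step):

```python
from planktos import make_scenario, run, trophic_fractions

scen = make_scenario("Doggerbank", years=3, seed=1)
res = run(scen, years=3.0, spinup_years=1.0, dt_minutes=30.0)
print(trophic_fractions(res.post_spinup,
                        ("diatom", "green", "protozoo", "CM")).round(2))
```

prints (`examples/column_scenario.py`):

```
Doggerbank (OS, depth 28.0 m, stratified=True)
  diatom    peak   0.3745 gC m-3   mean  0.05789
  green     peak  0.01307 gC m-3   mean   0.0012
  protozoo  peak   0.1302 gC m-3   mean   0.0337
  CM        peak   0.2332 gC m-3   mean  0.06855

monthly biomass fractions (rows: month)
       diatom  green  protozoo    CM
month
1        0.79   0.00      0.15  0.05
2        0.65   0.00      0.33  0.02
3        0.43   0.01      0.56  0.01
4        0.49   0.03      0.45  0.03
5        0.23   0.05      0.42  0.30
6        0.08   0.01      0.27  0.64
7        0.06   0.00      0.13  0.81
8        0.03   0.00      0.04  0.93
9        0.02   0.00      0.01  0.97
10       0.01   0.00      0.01  0.98
11       0.14   0.00      0.03  0.83
12       0.63   0.00      0.06  0.31
```

The numbers are column-mean carbon concentrations and monthly shares
of total protist carbon: a diatom-dominated winter/spring gives way to
constitutive mixoplankton through the stratified, nutrient-depleted
summer — the offshore succession this package exists to reproduce.
The same run for a turbid coastal column ("Noordwijk") keeps the CM
share below 1% year-round, reproducing the coast→offshore mixoplankton
gradient.

Other entry points, each with a narrative script under `examples/`:

* `run_box_equilibrium` — closed five-type competition box
  (`examples/box_competition.py`),
* `run_sensitivity` — ±10% boundary perturbations of one forcing
  factor (`examples/sensitivity_analysis.py`); lowering phosphate or
  silica *raises* integrated CM carbon (competitive release), while
  the suspended-sediment perturbation matters less,
* `target_stats` — target-diagram skill coordinates
  (`examples/skill_metrics.py`).

A thin CLI wraps the same calls: `planktos run Doggerbank`,
`planktos box`, `planktos sensitivity Doggerbank --factor PO4 --delta
-0.1`, `planktos validate-params examples/default_params.yaml`.

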