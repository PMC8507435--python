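"""Synthetic boundary and meteorological forcings.

The scenario columns emulate the biogeochemical gradient of a shallow
shelf sea monitored along an estuary -> coast -> offshore transect.
Four environmental systems are distinguished:

``ES``  unstratified estuary: high dissolved nutrients, high suspended
        sediment;
``CS``  unstratified coast: lower nutrients and sediment than ES;
``AS``  anthropogenically modified basins: high nutrients, low sediment,
        stratified;
``OS``  offshore: low nutrients and low sediment year-round, partly
        stratified.

Boundary series are monthly climatologies (winter maximum, summer
minimum) with seeded multiplicative lognormal year-to-year variability.
Total nitrogen is split 5:1 into nitrate and ammonium.  Absolute scales
are synthetic round numbers consistent with winter-nutrient ranges of
temperate eutrophied shelf seas and are config-overridable so real
monitoring series can be substituted.  The same temperature and
irradiance series is used for every scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .environment import ColumnConfig

__all__ = [
    "SystemForcing",
    "MetForcing",
    "Scenario",
    "make_system_forcing",
    "make_met_forcing",
    "make_scenario",
    "SYSTEMS",
    "SCENARIOS",
    "NO3_NH4_RATIO",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365          # no-leap calendar, nominal dates
NO3_NH4_RATIO = 5.0          # total N split 5:1 into NO3 : NH4

# winter-maximum boundary concentrations (g m-3) and seasonal trough
# fractions per environmental system; synthetic defaults.
SYSTEMS: Dict[str, Dict[str, float]] = {
    "ES": dict(DIN=1.20, PO4=0.090, Si=0.80, SPM=80.0,
               trough=0.30, spm_trough=0.75),
    "CS": dict(DIN=0.50, PO4=0.035, Si=0.45, SPM=25.0,
               trough=0.20, spm_trough=0.70),
    "AS": dict(DIN=0.90, PO4=0.060, Si=0.50, SPM=6.0,
               trough=0.25, spm_trough=0.80),
    "OS": dict(DIN=0.12, PO4=0.020, Si=0.12, SPM=4.0,
               trough=0.15, spm_trough=0.85),
}

#: location class -> (system, depth m, stratified); the class list and
#: depths are synthetic defaults for an 11-member transect.
SCENARIOS: Dict[str, tuple] = {
    "Westerschelde":     ("ES", 12.0, False),
    "Waddensea":         ("ES",  8.0, False),
    "Oosterschelde":     ("CS", 15.0, False),
    "Walcheren":         ("CS", 14.0, False),
    "Noordwijk":         ("CS", 18.0, False),
    "Coastal Waddensea": ("CS", 12.0, False),
    "Veerse Meer":       ("AS", 14.0, True),
    "Grevelingen":       ("AS", 25.0, True),
    "Offshore Mixed":    ("OS", 30.0, False),
    "Offshore":          ("OS", 40.0, True),
    "Doggerbank":        ("OS", 28.0, True),
}

#: year-to-year lognormal perturbation (sigma of log)
YEAR_SIGMA = 0.15


@dataclass
class SystemForcing:
    """Monthly boundary series (length years*12), g m-3."""
    system: str
    years: int
    NH4: np.ndarray
    NO3: np.ndarray
    PO4: np.ndarray
    Si: np.ndarray
    SPM: np.ndarray

    def monthly(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def at_day(self, name: str, day: float) -> float:
        """Linear interpolation of the monthly series to a model day
        (month values anchored at month centres)."""
        series = getattr(self, name)
        return _interp_monthly(series, day)

    def scaled(self, factors: Dict[str, float]) -> "SystemForcing":
        """A copy with named series multiplied by the given factors
        (sensitivity perturbations)."""
        kw = {}
        for name in ("NH4", "NO3", "PO4", "Si", "SPM"):
            kw[name] = getattr(self, name) * factors.get(name, 1.0)
        return SystemForcing(system=self.system, years=self.years, **kw)


@dataclass
class MetForcing:
    """Daily temperature (degC) and surface irradiance (umol m-2 s-1)."""
    years: int
    T: np.ndarray
    I0: np.ndarray


@dataclass
class Scenario:
    """A runnable scenario: column config + boundary + meteorology."""
    name: str
    system: str
    config: ColumnConfig
    boundary: SystemForcing
    met: MetForcing
    seed: int


def _interp_monthly(series: np.ndarray, day: float) -> float:
    """Piecewise-linear interpolation of a monthly series, values at
    month centres (month length 365/12 d), clamped at the ends."""
    mlen = DAYS_PER_YEAR / 12.0
    x = day / mlen - 0.5
    n = len(series)
    if x <= 0:
        return float(series[0])
    if x >= n - 1:
        return float(series[-1])
    i = int(math.floor(x))
    w = x - i
    return float((1.0 - w) * series[i] + w * series[i + 1])


def _seasonal_months(peak: float, trough: float) -> np.ndarray:
    """12 monthly values: cosine seasonality, max in January."""
    m = np.arange(12)
    shape = 0.5 * (1.0 + np.cos(2.0 * np.pi * (m + 0.5) / 12.0))
    return trough * peak + (1.0 - trough) * peak * shape


def make_system_forcing(system: str, years: int, seed: int) -> SystemForcing:
    """Synthetic monthly boundary series for one environmental system.

    Winter-high / summer-low nutrient seasonality with system-ordered
    amplitudes (nutrients ES > AS > CS > OS; sediment ES > CS > AS ~ OS),
    seeded lognormal year-to-year perturbations, and the 5:1 NO3:NH4
    split of total nitrogen applied exactly at every time point.
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown environmental system {system!r}")
    spec = SYSTEMS[system]
    rng = np.random.default_rng(seed)
    din_clim = _seasonal_months(spec["DIN"], spec["trough"])
    po4_clim = _seasonal_months(spec["PO4"], spec["trough"])
    si_clim = _seasonal_months(spec["Si"], spec["trough"])
    spm_clim = _seasonal_months(spec["SPM"], spec["spm_trough"])
    din, po4, si, spm = [], [], [], []
    for _ in range(years):
        pert = np.exp(rng.normal(0.0, YEAR_SIGMA, size=4))
        din.append(din_clim * pert[0])
        po4.append(po4_clim * pert[1])
        si.append(si_clim * pert[2])
        spm.append(spm_clim * pert[3])
    din = np.concatenate(din)
    po4 = np.concatenate(po4)
    si = np.concatenate(si)
    spm = np.concatenate(spm)
    no3 = din * (NO3_NH4_RATIO / (NO3_NH4_RATIO + 1.0))
    nh4 = din * (1.0 / (NO3_NH4_RATIO + 1.0))
    return SystemForcing(system=system, years=years,
                         NH4=nh4, NO3=no3, PO4=po4, Si=si, SPM=spm)


def make_met_forcing(years: int,
                     T_mean: float = 10.5, T_amp: float = 7.5,
                     I_mean: float = 250.0, I_amp: float = 200.0) -> MetForcing:
    """Daily temperature and irradiance series, identical for all
    scenarios.

    Temperature: sinusoid, minimum in mid February, maximum in mid
    August.  Irradiance (daily-mean photosynthetically active photon
    flux): solstice-phased sinusoid.
    """
    d = np.arange(years * DAYS_PER_YEAR, dtype=float)
    doy = d % DAYS_PER_YEAR
    T = T_mean - T_amp * np.cos(2.0 * np.pi * (doy - 46.0) / DAYS_PER_YEAR)
    I0 = I_mean + I_amp * np.cos(2.0 * np.pi * (doy - 172.0) / DAYS_PER_YEAR)
    return MetForcing(years=years, T=T, I0=np.maximum(I0, 0.0))


def make_scenario(location_class: str, years: int = 11,
                  seed: int = 0,
                  depth: Optional[float] = None) -> Scenario:
    """A full runnable scenario for one of the 11 location classes.

    All scenarios share the 30-day residence time, the seeding boundary
    biomass and the meteorological series; they differ in system
    forcing, depth and stratification.
    """
    if location_class not in SCENARIOS:
        raise ValueError(f"unknown location class {location_class!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    system, d0, strat = SCENARIOS[location_class]
    config = ColumnConfig(depth=depth if depth is not None else d0,
                          stratified=strat)
    # per-class stream so different classes of the same system see
    # different year-to-year realisations
    sub = seed * 131 + sorted(SCENARIOS).index(location_class)
    boundary = make_system_forcing(system, years, sub)
    met = make_met_forcing(years)
    return Scenario(name=location_class, system=system, config=config,
                    boundary=boundary, met=met, seed=seed)
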