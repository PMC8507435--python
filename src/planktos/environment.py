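"""Abiotic support processes and the two-cell vertical column scheme.

The water column is schematized as two stacked, equal-thickness cells.
Horizontal through-flow replaces each cell's volume on the configured
residence time with boundary water (which carries dissolved nutrients,
suspended sediment and a small seeding biomass of every PFT);
vertical exchange between the cells is diffusive, with a reduced
coefficient during stratified months.  Light decays with depth by
Lambert-Beer extinction from background, suspended sediment,
chlorophyll self-shading and particulate organic carbon.  Organic
matter cycles through first-order, Q10-scaled closures: POM
decomposition to dissolved nutrients, opal dissolution, labile-DOC
decay and nitrification (plus an optional denitrification sink).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

__all__ = [
    "AbioticState",
    "ColumnConfig",
    "ReminRates",
    "LightCoefficients",
    "light_profile",
    "transport_rates",
    "settling_rates",
    "remineralization_rates",
]

DISSOLVED = ("NH4", "NO3", "PO4", "Si")
PARTICULATE = ("DOClab", "POC", "PON", "POP", "opal")
ABIOTIC_POOLS = DISSOLVED + PARTICULATE


@dataclass
class LightCoefficients:
    """Additive extinction coefficients (m-1 per g m-3, background m-1)."""
    k_background: float = 0.12
    k_SPM: float = 0.03
    k_Chl: float = 16.0
    k_POC: float = 0.10


@dataclass
class ReminRates:
    """First-order abiotic rate constants (d-1 at Tref), Q10-scaled."""
    decomposition: float = 0.05   # POC/PON/POP -> DIC/NH4/PO4
    doc_decay: float = 0.10       # DOClab -> DIC
    opal_dissolution: float = 0.02  # opal -> dissolved Si
    nitrification: float = 0.10   # NH4 -> NO3
    denitrification: float = 0.0  # NO3 -> N2 sink (optional)
    Q10: float = 2.0
    Tref: float = 20.0
    pom_settling: float = 1.0     # m d-1, POC/PON/POP/opal


@dataclass
class AbioticState:
    """Dissolved and detrital pools per cell (g m-3, arrays of n_cells)."""
    NH4: np.ndarray
    NO3: np.ndarray
    PO4: np.ndarray
    Si: np.ndarray
    DOClab: np.ndarray
    POC: np.ndarray
    PON: np.ndarray
    POP: np.ndarray
    opal: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int) -> "AbioticState":
        return cls(**{k: np.zeros(n_cells) for k in ABIOTIC_POOLS})


@dataclass
class ColumnConfig:
    """Physical schematization of one scenario column."""
    depth: float                       # m, total
    n_cells: int = 2
    stratified: bool = False
    strat_months: Sequence[int] = (4, 5, 6, 7, 8)  # calendar months
    diffusion_mixed: float = 100.0     # m2 d-1
    diffusion_stratified: float = 2.0  # m2 d-1
    residence_time: float = 30.0       # d
    seed_biomass: float = 1e-4         # gC m-3 per PFT at the boundary
    closed: bool = False               # no transport / settling (box mode)

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.residence_time <= 0:
            raise ValueError("residence_time must be positive")
        if self.diffusion_stratified >= self.diffusion_mixed:
            raise ValueError("stratified diffusion must be below mixed")

    @property
    def cell_thickness(self) -> float:
        return self.depth / self.n_cells

    def diffusion(self, month: int) -> float:
        if self.stratified and month in self.strat_months:
            return self.diffusion_stratified
        return self.diffusion_mixed


def light_profile(I0, k_per_cell, cell_thickness):
    """Mean photon flux density within each cell (umol m-2 s-1).

    Lambert-Beer decay through the overlying cells, then the analytic
    within-cell average I_top * (1 - exp(-k h)) / (k h).  The average
    (rather than the mid-depth value) is what the cell's biomass
    experiences under instantaneous vertical homogenisation, and avoids
    starving optically thick cells.
    """
    k = np.asarray(k_per_cell, dtype=float)
    h = cell_thickness
    tau = k * h
    above = np.concatenate(([0.0], np.cumsum(tau)[:-1]))
    mean_fac = np.where(tau > 1e-12, (1.0 - np.exp(-tau)) / np.where(
        tau > 0, tau, 1.0), 1.0)
    return I0 * np.exp(-above) * mean_fac


def extinction(SPM, Chl, POC, coeffs: LightCoefficients):
    """Per-cell extinction coefficient (m-1)."""
    return (coeffs.k_background + coeffs.k_SPM * np.asarray(SPM, dtype=float)
            + coeffs.k_Chl * np.asarray(Chl, dtype=float)
            + coeffs.k_POC * np.asarray(POC, dtype=float))


def transport_rates(conc, boundary, config: ColumnConfig, month: int):
    """Tendency (g m-3 d-1) from through-flow and vertical diffusion.

    Through-flow relaxes every cell toward the boundary concentration
    with e-folding time equal to the residence time; vertical exchange
    mixes the two cells with rate D/(dz*h) where dz is the mid-point
    distance and h the cell thickness.  Flux-form and mass-conservative
    for equal-thickness cells.  Returns (tendency, inflow, outflow)
    where inflow/outflow are depth-integrated boundary fluxes
    (g m-2 d-1) for budget closure.
    """
    c = np.asarray(conc, dtype=float)
    b = float(boundary)
    h = config.cell_thickness
    flow = (b - c) / config.residence_time
    inflow = b / config.residence_time * h * config.n_cells
    outflow = float(np.sum(c)) / config.residence_time * h
    tend = flow.copy()
    if config.n_cells == 2:
        D = config.diffusion(month)
        dz = h  # mid-point distance of equal cells
        ex = D * (c[1] - c[0]) / (dz * h)
        tend[0] += ex
        tend[1] -= ex
    return tend, inflow, outflow


def settling_rates(conc, velocity, config: ColumnConfig):
    """Tendency (g m-3 d-1) from downward settling, plus bottom export.

    Downward-only flux velocity*concentration across the cell
    interface; export from the bottom cell is returned as a
    depth-integrated burial flux (g m-2 d-1).
    """
    c = np.maximum(np.asarray(conc, dtype=float), 0.0)
    h = config.cell_thickness
    tend = np.zeros_like(c)
    if velocity <= 0.0:
        return tend, 0.0
    if config.n_cells == 2:
        f01 = velocity * c[0]          # g m-2 d-1 across the interface
        tend[0] -= f01 / h
        tend[1] += f01 / h
        export = velocity * c[1]
        tend[1] -= export / h
    else:
        export = velocity * c[0]
        tend[0] -= export / h
    return tend, float(export)


def remineralization_rates(ab: AbioticState, T, rates: ReminRates):
    """First-order decomposition / dissolution / nitrification fluxes.

    Returns a dict of volumetric fluxes (g m-3 d-1, arrays per cell):
    ``poc_dic, pon_nh4, pop_po4, doc_dic, opal_si, nh4_no3, no3_n2``.
    Each transfer conserves its element (N released by PON decay
    appears 1:1 in NH4; nitrification moves N between NH4 and NO3).
    """
    f = rates.Q10 ** ((np.asarray(T, dtype=float) - rates.Tref) / 10.0)
    return {
        "poc_dic": rates.decomposition * f * ab.POC,
        "pon_nh4": rates.decomposition * f * ab.PON,
        "pop_po4": rates.decomposition * f * ab.POP,
        "doc_dic": rates.doc_decay * f * ab.DOClab,
        "opal_si": rates.opal_dissolution * f * ab.opal,
        "nh4_no3": rates.nitrification * f * ab.NH4,
        "no3_n2": rates.denitrification * f * ab.NO3,
    }
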