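"""Phototrophy: photosynthesis, photosynthate leakage, chlorophyll-a
synthesis/degradation, and kleptoplastic chloroplast turnover.

Gross carbon fixation follows the Smith photosynthesis-irradiance
curve, Cfix = PSqm * a / sqrt(PSqm^2 + a^2) with light-harvesting slope
a = alphaChl * Chl:C * PFD.  The maximum photosynthetic rate PSqm
covers growth, leakage and nitrogen-reduction costs, all modulated by
the nitrogen status except basal respiration, and is scaled by the
overcapacity factor relPS.  Constitutive phototrophs (diatom, green,
CM) regulate chlorophyll synthesis against both nutrient status and the
realized fixation fraction (photoacclimation); non-constitutive
mixoplankton acquire chloroplasts from phototrophic prey instead and
lose them at a fixed linear rate.
"""

from __future__ import annotations

import numpy as np

from .status import smoothstep

__all__ = [
    "max_photo_rate",
    "gross_fixation",
    "net_photosynthesis",
    "chlorophyll_synthesis",
    "chlorophyll_degradation",
    "chloroplast_acquisition",
    "chloroplast_loss",
    "DEGCHL_MAX",
]

#: maximum specific chlorophyll degradation rate (d-1) reached at full
#: nitrogen starvation (NCu = 0); degradation is linear in (1 - NCu).
DEGCHL_MAX = 0.5


def max_photo_rate(NCu, UmT, BR, params):
    """Maximum photosynthetic rate PSqm (gC gC-1 d-1).

    PSqm = relPS * NCu * UmT * (1 + NCopt*(redco + AR)) / (1 - PSDOC) + BR

    The bracket converts the carbon demand of growth plus the carbon
    costs of reducing and assimilating the nitrogen that growth at the
    optimal quota requires; dividing by (1 - PSDOC) pre-pays the leakage
    loss.  All of it is modulated by the nitrogen status NCu; the basal
    term is not, so at NCu = 0 photosynthesis retains a BR-driven floor.
    """
    NCu = np.asarray(NCu, dtype=float)
    costs = 1.0 + params.NCopt * (params.redco + params.AR)
    return params.relPS * NCu * UmT * costs / (1.0 - params.PSDOC) + BR


def gross_fixation(PSqm, alphaChl, ChlC, PFD):
    """Gross photosynthesis Cfix (gC gC-1 d-1) via the Smith equation.

    Cfix = PSqm * a / sqrt(PSqm^2 + a^2),  a = alphaChl * ChlC * PFD.
    Zero in darkness; saturates monotonically toward PSqm.
    """
    PSqm = np.asarray(PSqm, dtype=float)
    a = alphaChl * np.asarray(ChlC, dtype=float) * np.asarray(PFD, dtype=float)
    denom = np.sqrt(PSqm * PSqm + a * a)
    return np.where(denom > 0.0, PSqm * a / np.where(denom > 0, denom, 1.0),
                    0.0)


def net_photosynthesis(Cfix, PSDOC):
    """Net photosynthesis and DOC leakage: (netPS, Cleak).

    Cleak = PSDOC * Cfix is leaked as labile DOC; netPS = Cfix - Cleak.
    """
    Cfix = np.asarray(Cfix, dtype=float)
    Cleak = PSDOC * Cfix
    return Cfix - Cleak, Cleak


def chlorophyll_synthesis(NPCu, Cfix, PSqm, ChlC, UmT, params):
    """Chlorophyll-a synthesis synChl (gChl gC-1 d-1).

    synChl = UmT * ChlCmax * NPCu * (1 - Cfix/PSqm) * (1 - ChlC/ChlCmax)

    Repressed when the cell is nutrient limited (NPCu), when fixation
    already runs near capacity (light saturation), and as the Chl:C
    quota approaches its maximum; conversely enhanced under low light
    (photoacclimation).  The engine additionally clips Chl:C at
    ChlCmax at the end of each step.
    """
    NPCu = np.asarray(NPCu, dtype=float)
    PSqm = np.asarray(PSqm, dtype=float)
    sat = np.where(PSqm > 0.0,
                   np.asarray(Cfix, dtype=float) / np.where(PSqm > 0, PSqm, 1.0),
                   1.0)
    headroom = np.clip(1.0 - np.asarray(ChlC, dtype=float) / params.ChlCmax,
                       0.0, 1.0)
    return np.maximum(UmT * params.ChlCmax * NPCu * (1.0 - sat) * headroom,
                      0.0)


def chlorophyll_degradation(NCu, ChlC, deg_max=DEGCHL_MAX):
    """Chlorophyll-a degradation degChl (gChl gC-1 d-1).

    Linear in the nitrogen-stress signal (1 - NCu): zero for a replete
    cell, ``deg_max * ChlC`` at full starvation.
    """
    return deg_max * (1.0 - np.asarray(NCu, dtype=float)) \
        * np.asarray(ChlC, dtype=float)


def chloroplast_acquisition(ingested_prey_Chl, ChlC, ChlCmax):
    """Kleptoplastic chloroplast uptake upChl (gChl gC-1 d-1).

    The acquirable fraction of the chlorophyll flux in ingested
    phototrophic prey shuts down sigmoidally as the predator's own
    Chl:C quota approaches its maximum: upChl = flux * (1 - S(ChlC/
    ChlCmax)) with the smooth sigmoid S.  Never exceeds the available
    prey chlorophyll.
    """
    frac = 1.0 - smoothstep(np.asarray(ChlC, dtype=float) / ChlCmax)
    return np.maximum(np.asarray(ingested_prey_Chl, dtype=float), 0.0) * frac


def chloroplast_loss(ChlC, lossChl_rate):
    """Linear kleptochloroplast loss lossChl (gChl gC-1 d-1)."""
    return lossChl_rate * np.asarray(ChlC, dtype=float)
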