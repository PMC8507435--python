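"""Phagotrophy: prey encounter, capture, quality, ingestion and
assimilation.

Capture is encounter-based: swimming speeds follow an allometric
(log-log linear) regression on equivalent spherical diameter, prey
density derives from the prey carbon pool and its per-cell carbon
content, and the encounter rate follows the Gerritsen-Strickler /
Rothschild random-swimmer kernel.  Encounters are discounted by the
predator's optimum capture rate, the per-prey handling index and — for
mixoplankton — a sigmoidal light-inhibition factor (mixoplankton ingest
only a fraction relPhag of their capacity in darkness).

Ingestion is the smaller of captured prey and a Holling type II
satiation curve whose asymptote covers maximum growth plus basal
respiration at the realized assimilation efficiency; poorer prey
quality lowers the assimilation efficiency and therefore *raises* the
satiated ingestion rate ("compensatory feeding").  Non-assimilated
material is voided as particulate organics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "motility",
    "encounter_rate",
    "light_inhibition",
    "prey_quality",
    "max_ingestion",
    "satiation_ingestion",
    "ingestion",
    "assimilation",
    "MOT_LOG10_INTERCEPT",
    "MOT_LOG10_SLOPE",
    "PFD_INHIBITION_K",
]

# log10(speed um/s) = a + b*log10(ESD um): allometric swimming-speed
# regression, roughly half a body length per second at 10 um rising to
# ~50 um/s at 60 um.
MOT_LOG10_INTERCEPT = 0.36
MOT_LOG10_SLOPE = 0.75

#: half-saturation photon flux density (umol m-2 s-1) of the
#: light-inhibition sigmoid on mixoplankton prey capture.
PFD_INHIBITION_K = 10.0

_UMS_TO_MD = 0.0864  # um s-1  ->  m d-1


def motility(ESD):
    """Swimming speed (m d-1) from equivalent spherical diameter (um).

    Log-log linear regression; 0 for non-positive ESD.
    """
    ESD = np.asarray(ESD, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = 10.0 ** (MOT_LOG10_INTERCEPT
                     + MOT_LOG10_SLOPE * np.log10(np.maximum(ESD, 1e-300)))
    return np.where(ESD > 0.0, v * _UMS_TO_MD, 0.0)


def encounter_rate(mot_pred, mot_prey, nr_prey, ESD_pred, ESD_prey):
    """Encounters (prey predator-1 d-1), Gerritsen-Strickler kernel.

    enc = pi R^2 N (u^2 + 3 v^2) / (3 v) with v the faster and u the
    slower of the two swimming speeds (m d-1), R the capture radius
    (sum of the two cell radii, m) and N the prey density (cells m-3).
    Zero if both parties are immotile or no prey is present.
    """
    u = np.minimum(np.asarray(mot_pred, dtype=float),
                   np.asarray(mot_prey, dtype=float))
    v = np.maximum(np.asarray(mot_pred, dtype=float),
                   np.asarray(mot_prey, dtype=float))
    R = 0.5 * (np.asarray(ESD_pred, dtype=float)
               + np.asarray(ESD_prey, dtype=float)) * 1e-6
    N = np.maximum(np.asarray(nr_prey, dtype=float), 0.0)
    vsafe = np.where(v > 0.0, v, 1.0)
    enc = np.pi * R * R * N * (u * u + 3.0 * v * v) / (3.0 * vsafe)
    return np.where(v > 0.0, enc, 0.0)


def light_inhibition(PFD, relPhag, k=PFD_INHIBITION_K):
    """Light-dependent capture factor in [relPhag, 1].

    Sigmoid in photon flux density with dark asymptote ``relPhag`` (the
    fraction of maximal capture feasible in darkness) and light
    asymptote 1.  Pure heterotrophs use relPhag = 1 (no inhibition).
    """
    PFD = np.maximum(np.asarray(PFD, dtype=float), 0.0)
    s = PFD * PFD / (PFD * PFD + k * k)
    return relPhag + (1.0 - relPhag) * s


def prey_quality(NC_prey, PC_prey, params):
    """Assimilation efficiency opAE in [AEo, AEm] from prey stoichiometry.

    The captured-prey N:C and P:C mix is compared against the
    predator's optimal quotas; the scarcer element sets the quality.
    Prey at (or above) the predator optimum assimilates at AEm, fully
    depleted prey at AEo.
    """
    nq = np.clip(np.asarray(NC_prey, dtype=float) / params.NCopt, 0.0, 1.0)
    pq = np.clip(np.asarray(PC_prey, dtype=float) / params.PCopt, 0.0, 1.0)
    q = np.minimum(nq, pq)
    return params.AEo + (params.AEm - params.AEo) * q


def max_ingestion(UmT, BR, opAE, SDA):
    """Maximum ingestion rate maxIng (gC gC-1 d-1).

    Covers maximum growth and basal respiration given the quality of
    the captured prey: maxIng = (UmT + BR) / (opAE * (1 - SDA)).  Poorer
    prey (lower opAE) raises the required ingestion.
    """
    return (UmT + BR) / (np.asarray(opAE, dtype=float) * (1.0 - SDA))


def satiation_ingestion(sumCP, maxIng):
    """Holling type II satiation curve scaled to maxIng."""
    s = np.maximum(np.asarray(sumCP, dtype=float), 0.0)
    return maxIng * s / (maxIng + s)


def ingestion(sumCP, maxIng, smooth=True):
    """Realized carbon ingestion ingC (gC gC-1 d-1).

    Limited by captured prey at low density and by satiation at high
    density.  The default smooth blend ingC = maxIng*sumCP/(maxIng+
    sumCP) realizes both limits with a continuous derivative; the hard
    alternative takes min(sumCP, satiation).
    """
    s = np.maximum(np.asarray(sumCP, dtype=float), 0.0)
    if smooth:
        return maxIng * s / (maxIng + s)
    return np.minimum(s, satiation_ingestion(s, maxIng))


def assimilation(ingC, ingN, ingP, opAE, params):
    """Assimilated vs voided fractions of ingested prey.

    assC = opAE * ingC; assN and assP are referenced to the carbon
    assimilation and the predator's *optimal* quota, capped by what was
    ingested.  The remainder is voided as particulate organics:
    returns (assC, assN, assP, POCout, PONout, POPout) with exact
    per-element balance ing = ass + out.
    """
    ingC = np.asarray(ingC, dtype=float)
    ingN = np.asarray(ingN, dtype=float)
    ingP = np.asarray(ingP, dtype=float)
    assC = np.asarray(opAE, dtype=float) * ingC
    assN = np.minimum(ingN, assC * params.NCopt)
    assP = np.minimum(ingP, assC * params.PCopt)
    return assC, assN, assP, ingC - assC, ingN - assN, ingP - assP
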