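"""Cellular status: quotas, temperature scaling, nutrient statuses,
respiration and excess voiding.

The internal elemental ratios (N:C, P:C, Si:C quotas) regulate every
physiological rate in the model.  Nutrient status functions map a quota
onto [0, 1]: 0 when the cell is severely deprived, 1 at (or above) the
optimal quota.  Nitrogen is not stored in a physiologically inactive
form, so its status falls linearly as soon as the quota drops below the
optimum; phosphate can be stored as polyphosphate, so its status is a
sigmoid that stays near 1 well below the optimum; silica status tracks
*external* dissolved silica (incorporated frustule silica is
inaccessible).  The limiting status follows Liebig's law of the minimum.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "C_FLOOR",
    "quotas",
    "temperature_scaled_rate",
    "nitrogen_status",
    "phosphorus_status",
    "silica_status",
    "limiting_status",
    "basal_respiration",
    "total_respiration",
    "void_excess",
    "smoothstep",
]

#: biomass floor (gC m-3) below which a PFT is dormant: quotas are not
#: computed and all physiological rates are frozen at zero.
C_FLOOR = 1e-10


def smoothstep(x):
    """Cubic sigmoid on [0, 1] with zero slope at both ends.

    Clipped outside [0, 1].  Used as the generic normalized sigmoid for
    quota-regulation curves; its flat ends keep the regulated rates
    differentiable across the quota thresholds.
    """
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def quotas(C, N, P, Si=None):
    """Elemental quotas N:C, P:C (and Si:C) in g gC-1.

    Pools with ``C <= C_FLOOR`` are dormant: their quotas are reported
    as 0 and no division is performed.
    """
    C = np.asarray(C, dtype=float)
    active = C > C_FLOOR
    Csafe = np.where(active, C, 1.0)
    NC = np.where(active, np.asarray(N, dtype=float) / Csafe, 0.0)
    PC = np.where(active, np.asarray(P, dtype=float) / Csafe, 0.0)
    if Si is None:
        return NC, PC
    SC = np.where(active, np.asarray(Si, dtype=float) / Csafe, 0.0)
    return NC, PC, SC


def temperature_scaled_rate(ref_rate, T, Q10, Tref):
    """Q10 temperature correction: rate = ref * Q10**((T - Tref)/10)."""
    return ref_rate * np.power(Q10, (np.asarray(T, dtype=float) - Tref) / 10.0)


def nitrogen_status(NC, NCmin, NCopt):
    """Nitrogen status NCu in [0, 1].

    Linear ramp from 0 at the minimum quota to 1 at the optimal quota,
    saturated at 1 above it.
    """
    return np.clip((np.asarray(NC, dtype=float) - NCmin) / (NCopt - NCmin),
                   0.0, 1.0)


def phosphorus_status(PC, PCmin, PCopt):
    """Phosphorus status PCu in [0, 1].

    Sigmoid (near-zero slope at both ends): ~1 just below the optimal
    quota — polyphosphate stores keep the cell replete — dropping to 0
    only near the minimum quota.
    """
    x = (np.asarray(PC, dtype=float) - PCmin) / (PCopt - PCmin)
    return smoothstep(x)


def silica_status(Si_ext, KtSi):
    """Silica status SCu in [0, 1] from *external* dissolved Si.

    Michaelis-Menten saturation: 0 with no external silica, 0.5 at
    ``Si_ext = KtSi``, 1 in the saturation limit.
    """
    s = np.maximum(np.asarray(Si_ext, dtype=float), 0.0)
    return s / (s + KtSi)


def limiting_status(NCu, PCu, SCu=None):
    """Liebig's law of the minimum over the component statuses."""
    m = np.minimum(NCu, PCu)
    if SCu is not None:
        m = np.minimum(m, SCu)
    return m


def basal_respiration(UmT, BRfrac):
    """Basal respiration BR (d-1) as a fraction of maximum growth."""
    return BRfrac * UmT


def total_respiration(upNO3, upNH4, assN, assC, BR, redco, AR, SDA):
    """Total respiration (d-1).

    totR = redco*upNO3 + AR*(upNH4 + assN) + SDA*assC + BR:
    the metabolic cost of nitrate reduction, the anabolic cost of
    nitrogen utilisation, the foraging cost of prey processing, and
    basal respiration.
    """
    return redco * upNO3 + AR * (upNH4 + assN) + SDA * assC + BR


def void_excess(C, N, P, params):
    """End-of-step voiding enforcing the quota caps.

    Returns ``(C', N', P', Cvoid, Nout, Pout)`` where the primed pools
    satisfy ``NCmin <= N'/C' <= NCmax`` and ``P'/C' <= PCmax``.  Voided
    carbon (quota below the N:C minimum) is destined for labile DOC,
    voided N and P for the dissolved ammonium and phosphate pools; the
    caller routes the returned masses.  Silica is never voided.  Dormant
    pools are left untouched.
    """
    C = float(C)
    N = float(N)
    P = float(P)
    if C <= C_FLOOR:
        return C, N, P, 0.0, 0.0, 0.0
    Cvoid = 0.0
    # below-minimum N:C -> void carbon down to N/NCmin
    if N / C < params.NCmin:
        target = N / params.NCmin
        Cvoid = C - target
        C = target
    Nout = 0.0
    if C > C_FLOOR and N / C > params.NCmax:
        Nout = N - params.NCmax * C
        N -= Nout
    Pout = 0.0
    if C > C_FLOOR and P / C > params.PCmax:
        Pout = P - params.PCmax * C
        P -= Pout
    return C, N, P, Cvoid, Nout, Pout
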