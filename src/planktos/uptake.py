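"""Dissolved inorganic nutrient uptake (NH4+, NO3-, PO4 3-, Si).

Uptake combines external availability (Michaelis-Menten in the ambient
concentration) with the cell's acquisition capability, which depends on
the internal quota.  Below the optimal quota uptake is *enhanced* up to
a ceiling set by the maximum quota (at most the flux that would fill
the maximum quota at maximum growth, i.e. an enhancement factor
Qmax/Qopt); above the optimum it is *repressed*: sigmoidally toward
zero at the maximum quota for ammonium and phosphate, and shut off
entirely for nitrate (beyond its own, slightly lower quota pair) and
for silica (beyond the optimal Si:C quota).  All regulation curves are
continuous with continuous first derivative, and cross the value 1
exactly at the optimal quota.

Nitrogen uptake is additionally coupled to the phosphorus status: under
P stress the attainable N:C ceiling interpolates down to the
``PCminNCmin``–``PCminNCmax`` band, so N:C relaxes toward a reduced
ceiling while phosphate is scarce.
"""

from __future__ import annotations

import numpy as np

from .status import smoothstep

__all__ = [
    "optimal_uptake",
    "quota_regulation_soft",
    "quota_regulation_hard",
    "quota_regulation_si",
    "regulated_uptake_NH4",
    "regulated_uptake_NO3",
    "regulated_uptake_P",
    "regulated_uptake_Si",
    "n_uptake_p_coupling",
]


def optimal_uptake(conc, Kt, UmT, QCopt):
    """Uptake at the optimal quota: UmT * QCopt * conc/(conc + Kt).

    g(element) gC-1 d-1; Michaelis-Menten in the ambient concentration,
    scaled to maximum growth and the optimal quota.
    """
    c = np.maximum(np.asarray(conc, dtype=float), 0.0)
    return UmT * QCopt * c / (c + Kt)


def quota_regulation_soft(Q, Qmin, Qopt, Qmax):
    """Regulation factor for ammonium / phosphate style uptake.

    1 exactly at ``Qopt``; rises smoothly to ``Qmax/Qopt`` at ``Qmin``
    (enhancement toward the maximum uptake); falls sigmoidally to 0 at
    ``Qmax`` (repression once the optimum is passed).
    """
    Q = np.asarray(Q, dtype=float)
    fmax = Qmax / Qopt
    below = 1.0 + (fmax - 1.0) * smoothstep((Qopt - Q) / (Qopt - Qmin))
    above = 1.0 - smoothstep((Q - Qopt) / (Qmax - Qopt))
    return np.where(Q <= Qopt, below, above)


def quota_regulation_hard(Q, Qmin, Qopt, Qmax):
    """Regulation factor for nitrate-style uptake.

    As the soft form below the optimum, but the repression branch is
    squared so uptake dies off sharply once the optimum quota is passed
    and is exactly 0 at and above ``Qmax``.
    """
    Q = np.asarray(Q, dtype=float)
    fmax = Qmax / Qopt
    below = 1.0 + (fmax - 1.0) * smoothstep((Qopt - Q) / (Qopt - Qmin))
    above = (1.0 - smoothstep((Q - Qopt) / (Qmax - Qopt))) ** 2
    return np.where(Q <= Qopt, below, above)


def quota_regulation_si(SC, SCmin, SCopt, SCmax):
    """Regulation factor for silica uptake.

    Uptake stops altogether at the optimal Si:C quota (frustule silica
    cannot be dispelled, so overshoot must be prevented at the source):
    smooth ramp from ``SCmax/SCopt`` at ``SCmin`` to exactly 0 at and
    above ``SCopt``.
    """
    SC = np.asarray(SC, dtype=float)
    fmax = SCmax / SCopt
    return fmax * smoothstep((SCopt - SC) / (SCopt - SCmin))


def regulated_uptake_NH4(opt_up, NC, params):
    """Ammonium uptake, quota-regulated (gN gC-1 d-1)."""
    return opt_up * quota_regulation_soft(NC, params.NCmin, params.NCopt,
                                          params.NCmax)


def regulated_uptake_NO3(opt_up, NC, params):
    """Nitrate uptake, quota-regulated with a hard stop (gN gC-1 d-1).

    Uses the nitrate-specific quota pair (``NO3Copt``/``NO3Cmax``),
    slightly lower than the ammonium quotas, so nitrate uptake stops
    earlier than ammonium uptake as the cell fills up.
    """
    return opt_up * quota_regulation_hard(NC, params.NCmin, params.NO3Copt,
                                          params.NO3Cmax)


def regulated_uptake_P(opt_up, PC, params):
    """Phosphate uptake, quota-regulated (gP gC-1 d-1)."""
    return opt_up * quota_regulation_soft(PC, params.PCmin, params.PCopt,
                                          params.PCmax)


def regulated_uptake_Si(opt_up, SC, params):
    """Silica uptake (gSi gC-1 d-1); 0 for non-diatoms."""
    if not params.uses_silica:
        return np.zeros_like(np.asarray(opt_up, dtype=float)) * 0.0
    return opt_up * quota_regulation_si(SC, params.SCmin, params.SCopt,
                                        params.SCmax)


def n_uptake_p_coupling(upN_raw, NC, PCu, PCminNCmin, PCminNCmax):
    """Scale nitrogen uptake down under phosphorus stress.

    At ``PCu = 1`` the raw uptake passes unchanged.  At full P stress
    (``PCu = 0``) nitrogen uptake proceeds unhindered below the
    P-limited N:C floor ``PCminNCmin`` and is shut off above the
    P-limited ceiling ``PCminNCmax``, so the attainable N:C quota
    interpolates between the two bounds with the P status.
    """
    h = smoothstep((np.asarray(NC, dtype=float) - PCminNCmin)
                   / (PCminNCmax - PCminNCmin))
    return upN_raw * (1.0 - (1.0 - np.asarray(PCu, dtype=float)) * h)
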