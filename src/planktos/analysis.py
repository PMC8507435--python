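"""Model-skill statistics and trophic-composition summaries.

The target diagram plots the normalized bias against the signed,
normalized unbiased root-mean-square difference of a model/observation
pair; points inside the unity circle perform better than the
observation variance.  Trophic compositions are monthly per-type
fractions of total protist carbon.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "target_stats",
    "yearly_max_extraction",
    "trophic_fractions",
    "pft_carbon",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """Observation series has zero variance: skill is undefined."""


def target_stats(model, obs) -> Tuple[float, float, bool]:
    """Target-diagram coordinates (nuBIAS, nuRMSD) and unity-circle flag.

    nuBIAS = (mean(m) - mean(o)) / sd(o)
    nuRMSD = sign(sd(m) - sd(o)) * RMSD' / sd(o)

    with RMSD' the unbiased (centred-pattern) root-mean-square
    difference.  ``inside`` is true when nuBIAS^2 + nuRMSD^2 <= 1.
    Requires paired series of at least 3 points with nonzero
    observation variance.
    """
    m = np.asarray(model, dtype=float)
    o = np.asarray(obs, dtype=float)
    if m.shape != o.shape:
        raise ValueError("model and observation series must be paired")
    if m.size < 3:
        raise ValueError("need at least 3 paired points")
    sdo = float(np.std(o))
    if sdo == 0.0:
        raise UndefinedStatisticError("observation variance is zero")
    sdm = float(np.std(m))
    nubias = (float(np.mean(m)) - float(np.mean(o))) / sdo
    anom = (m - np.mean(m)) - (o - np.mean(o))
    rmsd_u = float(np.sqrt(np.mean(anom * anom)))
    nurmsd = float(np.sign(sdm - sdo)) * rmsd_u / sdo
    inside = bool(nubias * nubias + nurmsd * nurmsd <= 1.0)
    return nubias, nurmsd, inside


def yearly_max_extraction(df: pd.DataFrame, columns: Sequence[str],
                          days_per_year: int = 365) -> pd.DataFrame:
    """Annual maxima per column, spin-up rows excluded.

    ``df`` must carry ``time`` (days) and ``spinup`` columns as written
    by the engine.  Returns one row per simulation year.
    """
    d = df[~df["spinup"]].copy()
    year = (d["time"] // days_per_year).astype(int)
    out = d.groupby(year)[list(columns)].max()
    out.index.name = "year"
    return out


def pft_carbon(df: pd.DataFrame, pft: str, n_cells: int = 2) -> pd.Series:
    """Column-mean carbon concentration (gC m-3) of one PFT."""
    cols = [f"{pft}_C_{k}" for k in range(n_cells)]
    return df[cols].mean(axis=1)


def trophic_fractions(df: pd.DataFrame, pfts: Sequence[str],
                      n_cells: int = 2,
                      days_per_year: int = 365) -> pd.DataFrame:
    """Monthly biomass fractions per PFT of total protist carbon.

    Spin-up rows are excluded; rows are calendar months (1-12, pooled
    over years), columns PFTs.  Fractions sum to 1 whenever the total
    is positive.
    """
    d = df[~df["spinup"]].copy()
    mlen = days_per_year / 12.0
    month = ((d["time"] % days_per_year) // mlen).astype(int) % 12 + 1
    carbon = pd.DataFrame({p: pft_carbon(d, p, n_cells) for p in pfts})
    monthly = carbon.groupby(month).mean()
    total = monthly.sum(axis=1)
    frac = monthly.div(total.where(total > 0), axis=0).fillna(0.0)
    frac.index.name = "month"
    return frac
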