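"""Community tendencies: the conservation equations of the full model.

Every state variable's time derivative is assembled from the process
rates of the physiology modules plus mortality, predation routing,
abiotic cycling and (for column runs) transport and settling.  The
assembly is strictly flux-based: each physical transfer is written once
with a source and a destination, so every loss appears as a gain
elsewhere (dissolved pools, labile DOC, particulate detritus, opal) or
in an explicit budget (DIC sink, burial, boundary in/outflow,
denitrification).  Chlorophyll-a is a pigment proxy, synthesized and
destroyed, and is deliberately outside the element budgets.

Positivity guard: before applying a step of length ``dt`` every pool's
total outgoing flux is capped so at most 90% of the pool can leave
within the step; the cap scales each outgoing transfer and its linked
gains by the same factor, so element conservation is exact even when
the guard engages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from . import phagotrophy as phag
from . import phototrophy as photo
from . import status as st
from . import uptake as up
from .environment import (AbioticState, ColumnConfig, LightCoefficients,
                          ReminRates, extinction, light_profile,
                          remineralization_rates)
from .params import ParameterSet, prey_handling_matrix

__all__ = [
    "Community",
    "CommunityState",
    "VectorParams",
    "IntegrationError",
    "mortality_flux",
    "element_totals",
]

BUDGETS = ("DIC", "burial_C", "burial_N", "burial_P", "burial_Si",
           "denit_N",
           "inflow_C", "inflow_N", "inflow_P", "inflow_Si",
           "outflow_C", "outflow_N", "outflow_P", "outflow_Si")


class IntegrationError(RuntimeError):
    """Raised when a non-finite tendency is detected."""


def mortality_flux(C, mrtRT, order, T=None, Q10=2.0, Tref=20.0):
    """Mortality loss flux (gC m-3 d-1).

    linear:    flux = mrt * C
    quadratic: flux = mrt * C**2   (implicit closure by higher trophic
    levels).  ``mrt`` is the Q10-corrected reference rate when a
    temperature is supplied.
    """
    mrt = mrtRT if T is None else st.temperature_scaled_rate(mrtRT, T, Q10,
                                                             Tref)
    C = np.maximum(np.asarray(C, dtype=float), 0.0)
    if order == "quadratic":
        return mrt * C * C
    if order == "linear":
        return mrt * C
    raise ValueError(f"unknown mortality order {order!r}")


class _ArrayView:
    """Attribute bag of per-PFT numpy arrays; lets the scalar physiology
    functions run vectorized over the whole community."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


@dataclass
class VectorParams:
    """Parameter set flattened to per-PFT arrays plus derived matrices."""

    names: List[str]
    A: _ArrayView                 # numeric fields as arrays
    quad_mort: np.ndarray         # bool
    up_mask: np.ndarray           # dissolved-nutrient uptake capable
    photo_mask: np.ndarray        # fixes carbon (incl. NCM on stolen Chl)
    constit_mask: np.ndarray      # synthesizes own chlorophyll
    graz_mask: np.ndarray
    diatom_mask: np.ndarray
    ncm_mask: np.ndarray
    PR: np.ndarray                # (npft, npft) predator x prey
    geom: np.ndarray              # encounter kernel / prey density

    @classmethod
    def from_set(cls, pset: ParameterSet) -> "VectorParams":
        n = len(pset)

        def arr(fieldname, fill=0.0):
            out = np.empty(n)
            for i, p in enumerate(pset):
                v = getattr(p, fieldname)
                out[i] = fill if v is None else v
            return out

        A = _ArrayView(
            UmRT=arr("UmRT"), Q10=arr("Q10"), Tref=arr("Tref"),
            mrtRT=arr("mrtRT"), BRfrac=arr("BRfrac"),
            redco=arr("redco"), AR=arr("AR"), SDA=arr("SDA"),
            NCmin=arr("NCmin"), NCopt=arr("NCopt"), NCmax=arr("NCmax"),
            PCmin=arr("PCmin"), PCopt=arr("PCopt"), PCmax=arr("PCmax"),
            KtN=arr("KtN", 1.0), KtP=arr("KtP", 1.0), KtSi=arr("KtSi", 1.0),
            ChlCmax=arr("ChlCmax", 1.0), alphaChl=arr("alphaChl", 0.0),
            relPS=arr("relPS", 1.0), PSDOC=arr("PSDOC", 0.0),
            lossChl_rate=arr("lossChl_rate", 0.0),
            ESD=arr("ESD"), Ccell=arr("Ccell", 1.0),
            optCR=arr("optCR"), relPhag=arr("relPhag", 1.0),
            AEo=arr("AEo"), AEm=arr("AEm"), sed=arr("sed"),
            NO3Copt=np.empty(n), NO3Cmax=np.empty(n),
            PCminNCmin=np.empty(n), PCminNCmax=np.empty(n),
            SCmin=arr("SCmin", 0.5), SCopt=arr("SCopt", 1.0),
            SCmax=arr("SCmax", 2.0),
        )
        for i, p in enumerate(pset):
            A.NO3Copt[i] = p.NO3Copt if p.NO3Copt is not None else p.NCopt
            A.NO3Cmax[i] = p.NO3Cmax if p.NO3Cmax is not None else p.NCmax
            A.PCminNCmin[i] = (p.PCminNCmin if p.PCminNCmin is not None
                               else p.NCmin)
            A.PCminNCmax[i] = (p.PCminNCmax if p.PCminNCmax is not None
                               else p.NCmax)

        cls_of = [p.trophic_class for p in pset]
        quad = np.array([p.mortality_order == "quadratic" for p in pset])
        up_mask = np.array([p.has_uptake for p in pset])
        constit = np.array([p.is_phototroph for p in pset])
        photo_mask = np.array([p.is_phototroph or p.is_kleptoplastic
                               for p in pset])
        graz = np.array([p.is_phagotroph for p in pset])
        diat = np.array([c == "diatom" for c in cls_of])
        ncm = np.array([c == "NCM" for c in cls_of])
        PR = prey_handling_matrix(pset)

        # encounter geometry: pi R^2 (u^2 + 3 v^2)/(3 v) per predator/prey
        # pair (m3 d-1 per prey cell per predator cell); prey density and
        # behavioural factors are applied at run time.
        mot = phag.motility(A.ESD)
        u = np.minimum.outer(mot, mot)
        v = np.maximum.outer(mot, mot)
        R = 0.5 * (A.ESD[:, None] + A.ESD[None, :]) * 1e-6
        vsafe = np.where(v > 0, v, 1.0)
        geom = np.where(v > 0,
                        np.pi * R * R * (u * u + 3.0 * v * v) / (3.0 * vsafe),
                        0.0)

        return cls(names=list(pset.names), A=A, quad_mort=quad,
                   up_mask=up_mask, photo_mask=photo_mask,
                   constit_mask=constit, graz_mask=graz, diatom_mask=diat,
                   ncm_mask=ncm, PR=PR, geom=geom)


@dataclass
class CommunityState:
    """Full model state: protist pools (n_cells x n_pft) + abiotic."""

    C: np.ndarray
    N: np.ndarray
    P: np.ndarray
    Si: np.ndarray
    Chl: np.ndarray
    ab: AbioticState
    budgets: Dict[str, float]

    def copy(self) -> "CommunityState":
        return CommunityState(
            C=self.C.copy(), N=self.N.copy(), P=self.P.copy(),
            Si=self.Si.copy(), Chl=self.Chl.copy(),
            ab=AbioticState(**{k: getattr(self.ab, k).copy()
                               for k in self.ab.__dataclass_fields__}),
            budgets=dict(self.budgets))


def _limiter(pool, loss, dt):
    """Scale factor in (0, 1] capping losses at 90% of the pool per step."""
    loss = np.asarray(loss, dtype=float)
    pool = np.asarray(pool, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 0.9 * pool / (dt * loss)
    return np.where((loss > 0) & (dt * loss > 0.9 * pool),
                    np.maximum(f, 0.0), 1.0)


class Community:
    """Binds a parameter set to the tendency assembly.

    Parameters
    ----------
    pset : ParameterSet
    light : LightCoefficients
    remin : ReminRates
    smooth_ingestion : bool
        Smooth capture-vs-satiation blend (default) or hard minimum.
    """

    def __init__(self, pset: ParameterSet,
                 light: Optional[LightCoefficients] = None,
                 remin: Optional[ReminRates] = None,
                 smooth_ingestion: bool = True):
        self.pset = pset
        self.vp = VectorParams.from_set(pset)
        self.light = light if light is not None else LightCoefficients()
        self.remin = remin if remin is not None else ReminRates()
        self.smooth_ingestion = smooth_ingestion

    @property
    def n_pft(self) -> int:
        return len(self.vp.names)

    # ------------------------------------------------------------------
    def init_state(self, config: ColumnConfig, nutrients: Dict[str, float],
                   biomass: float = 1e-3) -> CommunityState:
        """Uniform initial state: given dissolved nutrients, equal small
        biomass per PFT at optimal quotas, empty detritus."""
        nc, n = config.n_cells, self.n_pft
        A = self.vp.A
        C = np.full((nc, n), biomass)
        state = CommunityState(
            C=C,
            N=C * A.NCopt, P=C * A.PCopt,
            Si=C * np.where(self.vp.diatom_mask, A.SCopt, 0.0),
            Chl=C * np.where(self.vp.photo_mask, 0.5 * A.ChlCmax, 0.0)
            * np.where(self.vp.ncm_mask, 0.0, 1.0),
            ab=AbioticState.zeros(nc),
            budgets={k: 0.0 for k in BUDGETS},
        )
        for k, v in nutrients.items():
            getattr(state.ab, k)[:] = v
        return state

    def boundary_protist(self, config: ColumnConfig):
        """Boundary (seeding) concentrations per protist pool."""
        A = self.vp.A
        bC = np.full(self.n_pft, config.seed_biomass)
        return {
            "C": bC,
            "N": bC * A.NCopt,
            "P": bC * A.PCopt,
            "Si": bC * np.where(self.vp.diatom_mask, A.SCopt, 0.0),
            "Chl": bC * np.where(self.vp.photo_mask & ~self.vp.ncm_mask,
                                 0.5 * A.ChlCmax, 0.0),
        }

    # ------------------------------------------------------------------
    def tendencies(self, state: CommunityState, config: ColumnConfig,
                   T: float, I0: float, SPM: float,
                   boundary: Optional[Dict[str, float]] = None,
                   month: int = 1, dt: float = 1.0 / 480.0,
                   want_diag: bool = False):
        """Time derivative of every pool plus budget increments.

        Returns ``(dstate, dbudgets, diag)`` with ``dstate`` mirroring
        the state arrays (g m-3 d-1), ``dbudgets`` in g m-2 d-1 and
        ``diag`` a dict of per-PFT specific rates (only filled when
        ``want_diag``).
        """
        vp, A = self.vp, self.vp.A
        nc, npft = state.C.shape
        h = config.cell_thickness
        ab = state.ab
        transport_on = not config.closed

        C, N, P, Si, Chl = state.C, state.N, state.P, state.Si, state.Chl
        active = C > st.C_FLOOR
        Csafe = np.where(active, C, 1.0)
        NC = np.where(active, N / Csafe, 0.0)
        PC = np.where(active, P / Csafe, 0.0)
        SC = np.where(active, Si / Csafe, 0.0)
        ChlC = np.where(active, Chl / Csafe, 0.0)

        UmT = st.temperature_scaled_rate(A.UmRT, T, A.Q10, A.Tref)
        mrt = st.temperature_scaled_rate(A.mrtRT, T, A.Q10, A.Tref)
        BR = st.basal_respiration(UmT, A.BRfrac)

        NCu = st.nitrogen_status(NC, A.NCmin, A.NCopt)
        PCu = st.phosphorus_status(PC, A.PCmin, A.PCopt)
        SCu = np.where(vp.diatom_mask,
                       st.silica_status(ab.Si[:, None], A.KtSi), 1.0)
        NPCu = st.limiting_status(NCu, PCu,
                                  np.where(vp.diatom_mask, SCu, 1.0))

        # ---- light ----------------------------------------------------
        k_ext = extinction(SPM, Chl.sum(axis=1), ab.POC, self.light)
        PFD = light_profile(I0, k_ext, h)

        # ---- dissolved-nutrient uptake (specific, g gC-1 d-1) ---------
        upmask = vp.up_mask & active
        optNH4 = up.optimal_uptake(ab.NH4[:, None], A.KtN, UmT, A.NCopt)
        optNO3 = up.optimal_uptake(ab.NO3[:, None], A.KtN, UmT, A.NO3Copt)
        optP = up.optimal_uptake(ab.PO4[:, None], A.KtP, UmT, A.PCopt)
        upNH4 = np.where(upmask, up.regulated_uptake_NH4(optNH4, NC, A), 0.0)
        upNO3 = np.where(upmask, up.regulated_uptake_NO3(optNO3, NC, A), 0.0)
        upNH4 = up.n_uptake_p_coupling(upNH4, NC, PCu, A.PCminNCmin,
                                       A.PCminNCmax)
        upNO3 = up.n_uptake_p_coupling(upNO3, NC, PCu, A.PCminNCmin,
                                       A.PCminNCmax)
        upP = np.where(upmask, up.regulated_uptake_P(optP, PC, A), 0.0)
        simask = vp.diatom_mask & active
        optSi = up.optimal_uptake(ab.Si[:, None], A.KtSi, UmT, A.SCopt)
        upSi = np.where(simask,
                        optSi * up.quota_regulation_si(SC, A.SCmin, A.SCopt,
                                                       A.SCmax), 0.0)

        # ---- phototrophy (specific) -----------------------------------
        pmask = vp.photo_mask & active
        PSqm = np.where(pmask, photo.max_photo_rate(NCu, UmT, BR, A), 0.0)
        Cfix = np.where(pmask,
                        photo.gross_fixation(PSqm, A.alphaChl, ChlC,
                                             PFD[:, None]), 0.0)
        netPS, Cleak = photo.net_photosynthesis(Cfix, A.PSDOC)
        cmask = vp.constit_mask & active
        synChl = np.where(cmask,
                          photo.chlorophyll_synthesis(NPCu, Cfix, PSqm, ChlC,
                                                      UmT, A), 0.0)
        degChl = np.where(cmask, photo.chlorophyll_degradation(NCu, ChlC),
                          0.0)
        lossChl = np.where(vp.ncm_mask & active,
                           photo.chloroplast_loss(ChlC, A.lossChl_rate), 0.0)

        # ---- phagotrophy ----------------------------------------------
        gmask = vp.graz_mask & active
        inh = phag.light_inhibition(PFD[:, None], A.relPhag)  # (nc, npft)
        Gmats = []
        sumCP = np.zeros((nc, npft))
        opAE = np.full((nc, npft), 0.5)
        NCcp = np.zeros((nc, npft))
        PCcp = np.zeros((nc, npft))
        ingC = np.zeros((nc, npft))
        for kcell in range(nc):
            nr = np.where(active[kcell], C[kcell] / A.Ccell, 0.0)
            CP = (vp.geom * nr[None, :] * vp.PR
                  * A.optCR[:, None] * inh[kcell][:, None]
                  * (A.Ccell[None, :] / A.Ccell[:, None]))
            CP[~gmask[kcell]] = 0.0
            sCP = CP.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(sCP[:, None] > 0, CP / np.where(sCP > 0,
                                                             sCP, 1.0)[:, None],
                             0.0)
            nccp = w @ NC[kcell]
            pccp = w @ PC[kcell]
            ae = phag.prey_quality(nccp, pccp, A)
            maxIng = phag.max_ingestion(UmT, BR, ae, A.SDA)
            ing = np.where(gmask[kcell],
                           phag.ingestion(sCP, maxIng,
                                          smooth=self.smooth_ingestion), 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                fI = np.where(sCP > 0, ing / np.where(sCP > 0, sCP, 1.0), 0.0)
            # volumetric prey-carbon capture, g m-3 d-1
            G = CP * (fI * C[kcell])[:, None]
            Gmats.append(G)
            sumCP[kcell] = sCP
            opAE[kcell] = ae
            NCcp[kcell] = nccp
            PCcp[kcell] = pccp
            ingC[kcell] = ing

        ingN = ingC * NCcp
        ingP = ingC * PCcp
        assC, assN, assP, POCout, PONout, POPout = phag.assimilation(
            ingC, ingN, ingP, opAE, A)

        totR = np.where(active,
                        st.total_respiration(upNO3, upNH4, assN, assC, BR,
                                             A.redco, A.AR, A.SDA), 0.0)

        # ---- raw volumetric fluxes (g m-3 d-1) ------------------------
        leak_v = Cleak * C
        resp_v = totR * C
        fix_v = Cfix * C
        syn_v = synChl * C
        deg_v = degChl * C
        lossChl_v = lossChl * C
        mort_v = np.where(active,
                          np.where(vp.quad_mort, mrt * C * C, mrt * C), 0.0)
        predC_raw = np.stack([G.sum(axis=0) for G in Gmats])  # prey C loss
        uNH4_v = upNH4 * C
        uNO3_v = upNO3 * C
        uP_v = upP * C
        uSi_v = upSi * C

        rem = remineralization_rates(ab, T, self.remin)

        # ---- transport / settling losses (vectorized) -----------------
        tau = config.residence_time
        D = config.diffusion(month) if transport_on else 0.0
        prot_bnd = self.boundary_protist(config)
        pom_v = self.remin.pom_settling
        sedv = np.where(vp.diatom_mask, A.sed, 0.0)

        def trans_loss(X, vset):
            """Outgoing transport+settling rate per cell (g m-3 d-1)
            and the signed diffusive gain ``exg`` to the top cell."""
            if not transport_on:
                return np.zeros_like(X), 0.0
            Xp = np.maximum(X, 0.0)
            loss = Xp / tau
            exg = 0.0
            if nc == 2:
                if D > 0:
                    exg = D * (Xp[1] - Xp[0]) / (h * h)
                    loss[1] = loss[1] + np.maximum(exg, 0.0)
                    loss[0] = loss[0] + np.maximum(-exg, 0.0)
                loss[0] = loss[0] + vset * Xp[0] / h
                loss[1] = loss[1] + vset * Xp[1] / h
            else:
                loss[0] = loss[0] + vset * Xp[0] / h
            return loss, exg

        tlC, exC = trans_loss(C, sedv)
        tlN, exN = trans_loss(N, sedv)
        tlP, exP = trans_loss(P, sedv)
        tlSi, exSi = trans_loss(Si, sedv)
        tlChl, exChl = trans_loss(Chl, sedv)

        ab_vset = {"NH4": 0.0, "NO3": 0.0, "PO4": 0.0, "Si": 0.0,
                   "DOClab": 0.0, "POC": pom_v, "PON": pom_v, "POP": pom_v,
                   "opal": pom_v}
        ab_tl = {}
        ab_ex = {}
        for name, vset in ab_vset.items():
            ab_tl[name], ab_ex[name] = trans_loss(getattr(ab, name), vset)

        # ---- loss sums and limiter factors ----------------------------
        lossC = leak_v + resp_v + mort_v + predC_raw + tlC
        lossN = (mort_v + predC_raw) * NC + tlN
        lossP = (mort_v + predC_raw) * PC + tlP
        lossSi = (mort_v + predC_raw) * SC + tlSi
        lossChl_pool = (deg_v + lossChl_v + (mort_v + predC_raw) * ChlC
                        + tlChl)

        fC = _limiter(C, lossC, dt)
        fN = _limiter(N, lossN, dt)
        fP = _limiter(P, lossP, dt)
        fSi = _limiter(Si, lossSi, dt)
        fChl = _limiter(Chl, lossChl_pool, dt)

        ab_bio_loss = {
            "NH4": uNH4_v.sum(axis=1) + rem["nh4_no3"],
            "NO3": uNO3_v.sum(axis=1) + rem["no3_n2"],
            "PO4": uP_v.sum(axis=1),
            "Si": uSi_v.sum(axis=1),
            "DOClab": rem["doc_dic"],
            "POC": rem["poc_dic"],
            "PON": rem["pon_nh4"],
            "POP": rem["pop_po4"],
            "opal": rem["opal_si"],
        }
        fab = {}
        for name in ab_vset:
            loss = ab_bio_loss[name] + ab_tl[name]
            fab[name] = _limiter(getattr(ab, name), loss, dt)

        # ---- assemble tendencies --------------------------------------
        dC = np.zeros((nc, npft))
        dN = np.zeros((nc, npft))
        dP = np.zeros((nc, npft))
        dSi = np.zeros((nc, npft))
        dChl = np.zeros((nc, npft))
        dab = {k: np.zeros(nc) for k in ab_vset}
        dbud = {k: 0.0 for k in BUDGETS}

        # photosynthesis: DIC -> protist C (source unlimited)
        dC += fix_v
        dbud["DIC"] -= fix_v.sum() * h
        # leakage: protist C -> DOC
        amt = leak_v * fC
        dC -= amt
        dab["DOClab"] += amt.sum(axis=1)
        # respiration: protist C -> DIC budget
        amt = resp_v * fC
        dC -= amt
        dbud["DIC"] += amt.sum() * h
        # mortality: protist -> particulate detritus at current quotas
        mC = mort_v * fC
        dC -= mC
        dab["POC"] += mC.sum(axis=1)
        mN = mort_v * NC * fN
        dN -= mN
        dab["PON"] += mN.sum(axis=1)
        mP = mort_v * PC * fP
        dP -= mP
        dab["POP"] += mP.sum(axis=1)
        mSi = mort_v * SC * fSi
        dSi -= mSi
        dab["opal"] += mSi.sum(axis=1)
        dChl -= mort_v * ChlC * fChl  # pigment destroyed

        # chlorophyll synthesis / degradation / kleptoplast loss
        dChl += syn_v - deg_v * fChl - lossChl_v * fChl

        # predation: prey pools -> predator + particulates, per cell
        klepto_frac = 1.0 - st.smoothstep(ChlC / A.ChlCmax)  # (nc, npft)
        for kcell in range(nc):
            G = Gmats[kcell] * fC[kcell][None, :]        # scaled prey C
            ingC_s = G.sum(axis=1)
            assC_s = opAE[kcell] * ingC_s
            dC[kcell] -= G.sum(axis=0)
            dC[kcell] += assC_s
            dab["POC"][kcell] += (ingC_s - assC_s).sum()

            GN = Gmats[kcell] * (NC[kcell] * fN[kcell])[None, :]
            ingN_s = GN.sum(axis=1)
            assN_s = np.minimum(ingN_s, assC_s * A.NCopt)
            dN[kcell] -= GN.sum(axis=0)
            dN[kcell] += assN_s
            dab["PON"][kcell] += (ingN_s - assN_s).sum()

            GP = Gmats[kcell] * (PC[kcell] * fP[kcell])[None, :]
            ingP_s = GP.sum(axis=1)
            assP_s = np.minimum(ingP_s, assC_s * A.PCopt)
            dP[kcell] -= GP.sum(axis=0)
            dP[kcell] += assP_s
            dab["POP"][kcell] += (ingP_s - assP_s).sum()

            GSi = Gmats[kcell] * (SC[kcell] * fSi[kcell])[None, :]
            dSi[kcell] -= GSi.sum(axis=0)
            dab["opal"][kcell] += GSi.sum()  # frustules -> opal detritus

            GChl = Gmats[kcell] * (ChlC[kcell] * fChl[kcell])[None, :]
            dChl[kcell] -= GChl.sum(axis=0)
            # NCM predators acquire a fraction of ingested chlorophyll
            upChl_s = np.where(vp.ncm_mask,
                               klepto_frac[kcell] * GChl.sum(axis=1), 0.0)
            dChl[kcell] += upChl_s  # rest of the pigment is destroyed

        # dissolved-nutrient uptake
        for pool, flux, target in (("NH4", uNH4_v, dN), ("NO3", uNO3_v, dN),
                                   ("PO4", uP_v, dP), ("Si", uSi_v, dSi)):
            amt = flux * fab[pool][:, None]
            target += amt
            dab[pool] -= amt.sum(axis=1)

        # abiotic first-order cycling
        amt = rem["poc_dic"] * fab["POC"]
        dab["POC"] -= amt
        dbud["DIC"] += amt.sum() * h
        amt = rem["pon_nh4"] * fab["PON"]
        dab["PON"] -= amt
        dab["NH4"] += amt
        amt = rem["pop_po4"] * fab["POP"]
        dab["POP"] -= amt
        dab["PO4"] += amt
        amt = rem["doc_dic"] * fab["DOClab"]
        dab["DOClab"] -= amt
        dbud["DIC"] += amt.sum() * h
        amt = rem["opal_si"] * fab["opal"]
        dab["opal"] -= amt
        dab["Si"] += amt
        amt = rem["nh4_no3"] * fab["NH4"]
        dab["NH4"] -= amt
        dab["NO3"] += amt
        amt = rem["no3_n2"] * fab["NO3"]
        dab["NO3"] -= amt
        dbud["denit_N"] += amt.sum() * h

        # transport + settling, with budget closure
        elem_of_ab = {"NH4": "N", "NO3": "N", "PO4": "P", "Si": "Si",
                      "DOClab": "C", "POC": "C", "PON": "N", "POP": "P",
                      "opal": "Si"}

        def apply_transport(X, b, vset, f, dX, elem, exg):
            if not transport_on:
                return
            Xp = np.maximum(X, 0.0)
            amt_out = Xp / tau * f
            dX -= amt_out
            dX += np.asarray(b) / tau
            if elem is not None:
                dbud[f"outflow_{elem}"] += float(np.sum(amt_out)) * h
                dbud[f"inflow_{elem}"] += float(np.sum(b)) / tau * h * nc
            if nc == 2:
                if D > 0:
                    ex_s = np.where(exg > 0, exg * f[1], exg * f[0])
                    dX[0] += ex_s
                    dX[1] -= ex_s
                a01 = vset * Xp[0] / h * f[0]
                dX[0] -= a01
                dX[1] += a01
                aexp = vset * Xp[1] / h * f[1]
                dX[1] -= aexp
            else:
                aexp = vset * Xp[0] / h * f[0]
                dX[0] -= aexp
            if elem is not None:
                dbud[f"burial_{elem}"] += float(np.sum(aexp)) * h

        if transport_on:
            apply_transport(C, prot_bnd["C"], sedv, fC, dC, "C", exC)
            apply_transport(N, prot_bnd["N"], sedv, fN, dN, "N", exN)
            apply_transport(P, prot_bnd["P"], sedv, fP, dP, "P", exP)
            apply_transport(Si, prot_bnd["Si"], sedv, fSi, dSi, "Si", exSi)
            apply_transport(Chl, prot_bnd["Chl"], sedv, fChl, dChl, None,
                            exChl)
            bnd = boundary if boundary else {}
            for name in ab_vset:
                b = bnd.get(name, 0.0)
                apply_transport(getattr(ab, name), b, ab_vset[name],
                                fab[name], dab[name], elem_of_ab[name],
                                ab_ex[name])

        # ---- sanity ---------------------------------------------------
        for label, arrs in (("protist", (dC, dN, dP, dSi, dChl)),
                            ("abiotic", tuple(dab.values()))):
            for a_ in arrs:
                if not np.all(np.isfinite(a_)):
                    raise IntegrationError(
                        f"non-finite tendency in {label} pools "
                        f"(T={T}, I0={I0}, month={month})")

        dstate = {"C": dC, "N": dN, "P": dP, "Si": dSi, "Chl": dChl,
                  "ab": dab}
        diag = {}
        if want_diag:
            diag = {"NC": NC, "PC": PC, "SC": SC, "ChlC": ChlC,
                    "NCu": NCu, "PCu": PCu, "SCu": SCu, "NPCu": NPCu,
                    "UmT": UmT, "BR": BR, "totR": totR, "mrt": mrt,
                    "upNH4": upNH4, "upNO3": upNO3, "upP": upP, "upSi": upSi,
                    "PSqm": PSqm, "Cfix": Cfix, "netPS": netPS,
                    "Cleak": Cleak, "synChl": synChl, "degChl": degChl,
                    "sumCP": sumCP, "ingC": ingC, "assC": assC,
                    "opAE": opAE, "PFD": PFD, "mort_flux": mort_v}
        return dstate, dbud, diag

    # ------------------------------------------------------------------
    def apply_voiding(self, state: CommunityState):
        """End-of-step quota enforcement (voiding + Chl:C clip).

        Voided N and P go to the dissolved pools, voided C to labile
        DOC; chlorophyll above ChlCmax is destroyed.  Mass conservative.
        """
        A = self.vp.A
        C, N, P = state.C, state.N, state.P
        active = C > st.C_FLOOR
        Csafe = np.where(active, C, 1.0)
        # carbon voiding: N:C below minimum
        nc_q = np.where(active, N / Csafe, A.NCmin)
        low = active & (nc_q < A.NCmin)
        target = np.where(low, N / A.NCmin, C)
        cvoid = np.where(low, C - target, 0.0)
        state.C = C = np.where(low, target, C)
        state.ab.DOClab += cvoid.sum(axis=1)
        # N voiding above max quota
        active = C > st.C_FLOOR
        Csafe = np.where(active, C, 1.0)
        nout = np.where(active & (N / Csafe > A.NCmax), N - A.NCmax * C, 0.0)
        state.N = N - nout
        state.ab.NH4 += nout.sum(axis=1)
        # P voiding above max quota
        pout = np.where(active & (P / Csafe > A.PCmax), P - A.PCmax * C, 0.0)
        state.P = P - pout
        state.ab.PO4 += pout.sum(axis=1)
        # chlorophyll cap (pigment, destroyed)
        cap = A.ChlCmax * C
        state.Chl = np.where(active & vp_photo(self.vp),
                             np.minimum(state.Chl, cap), state.Chl)
        return cvoid, nout, pout


def vp_photo(vp: VectorParams):
    return vp.photo_mask


def element_totals(state: CommunityState, config: ColumnConfig):
    """Whole-system element inventories (g m-2), budgets included.

    In a closed run each total is invariant; in an open run the
    boundary/burial budgets close the balance, so the totals net of
    (inflow - outflow - burial - sinks) remain invariant.
    """
    h = config.cell_thickness
    b = state.budgets
    ab = state.ab
    C = (state.C.sum() + ab.POC.sum() + ab.DOClab.sum()) * h \
        + b["DIC"] + b["burial_C"] + b["outflow_C"] - b["inflow_C"]
    N = (state.N.sum() + ab.PON.sum() + ab.NH4.sum() + ab.NO3.sum()) * h \
        + b["denit_N"] + b["burial_N"] + b["outflow_N"] - b["inflow_N"]
    P = (state.P.sum() + ab.POP.sum() + ab.PO4.sum()) * h \
        + b["burial_P"] + b["outflow_P"] - b["inflow_P"]
    Si = (state.Si.sum() + ab.opal.sum() + ab.Si.sum()) * h \
        + b["burial_Si"] + b["outflow_Si"] - b["inflow_Si"]
    return {"C": C, "N": N, "P": P, "Si": Si}
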