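"""Protist functional type (PFT) parameter sets.

Five trophic classes are distinguished:

``diatom``
    phototroph with an obligate silica requirement (frustule).
``green``
    phototroph without silica (flagellates, *Phaeocystis*-like cells).
``protozoo``
    pure phagotroph, closed with a quadratic mortality term.
``CM``
    constitutive mixoplankton: innate photosystem plus phagotrophy.
``NCM``
    non-constitutive mixoplankton: primarily phagotrophic, runs
    photosynthesis only on chloroplasts stolen from phototrophic prey
    (kleptoplasty).

A :class:`PFTParams` instance carries the full physiological trait set of
one type (quotas, rates, size, trophic capabilities); a
:class:`ParameterSet` is an ordered collection of them plus the
predator x prey handling matrix.  Capability flags are derived from the
trophic class, never stored, so hybrid mis-configurations cannot arise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Dict, List, Optional

import yaml

__all__ = [
    "PFTParams",
    "ParameterSet",
    "ConfigurationError",
    "ValidationError",
    "load_parameter_set",
    "default_parameters",
    "prey_handling_matrix",
    "carbon_per_cell",
    "stokes_velocity",
    "TROPHIC_CLASSES",
]

TROPHIC_CLASSES = ("diatom", "green", "protozoo", "CM", "NCM")

PHOTOTROPH_CLASSES = ("diatom", "green", "CM")       # synthesize own Chl
PHAGOTROPH_CLASSES = ("protozoo", "CM", "NCM")       # capture prey
UPTAKE_CLASSES = ("diatom", "green", "CM")           # dissolved-nutrient uptake


class ConfigurationError(ValueError):
    """A mandatory field is missing or a PFT entry is malformed."""


class ValidationError(ValueError):
    """A parameter invariant is violated."""


def carbon_per_cell(esd_um: float, diatom: bool = False) -> float:
    """Carbon content of one cell (gC) from equivalent spherical diameter.

    Uses the Menden-Deuer & Lessard (2000) volume-to-carbon regressions
    (pgC = 0.288 V^0.811 for diatoms, 0.216 V^0.939 otherwise, V in um^3).
    """
    if esd_um <= 0:
        raise ValueError("ESD must be positive")
    vol = math.pi / 6.0 * esd_um**3
    if diatom:
        pg = 0.288 * vol**0.811
    else:
        pg = 0.216 * vol**0.939
    return pg * 1e-12


def stokes_velocity(esd_um: float, excess_density: float = 35.0,
                    viscosity: float = 1.07e-3) -> float:
    """Stokes settling velocity (m d-1) for a sphere of given ESD.

    excess_density : cell minus seawater density, kg m-3
    viscosity      : dynamic viscosity of seawater, Pa s

    Precomputed once per parameter set; no in-run density dependence.
    """
    d = esd_um * 1e-6
    v_ms = 9.81 * excess_density * d * d / (18.0 * viscosity)
    return v_ms * 86400.0


# fields that every PFT must provide
_MANDATORY = ("name", "trophic_class", "UmRT", "Q10", "Tref", "mrtRT",
              "mortality_order", "BRfrac", "ESD")

# class-specific mandatory fields
_CLASS_MANDATORY = {
    "diatom": ("NCmin", "NCopt", "NCmax", "NO3Copt", "NO3Cmax",
               "PCmin", "PCopt", "PCmax", "SCmin", "SCopt", "SCmax",
               "KtN", "KtP", "KtSi", "ChlCmax", "alphaChl", "relPS"),
    "green": ("NCmin", "NCopt", "NCmax", "NO3Copt", "NO3Cmax",
              "PCmin", "PCopt", "PCmax", "KtN", "KtP",
              "ChlCmax", "alphaChl", "relPS"),
    "protozoo": ("NCmin", "NCopt", "NCmax", "PCmin", "PCopt", "PCmax",
                 "Ccell", "optCR", "AEo", "AEm"),
    "CM": ("NCmin", "NCopt", "NCmax", "NO3Copt", "NO3Cmax",
           "PCmin", "PCopt", "PCmax", "KtN", "KtP",
           "ChlCmax", "alphaChl", "relPS",
           "Ccell", "optCR", "AEo", "AEm", "relPhag"),
    "NCM": ("NCmin", "NCopt", "NCmax", "PCmin", "PCopt", "PCmax",
            "ChlCmax", "alphaChl", "lossChl_rate",
            "Ccell", "optCR", "AEo", "AEm", "relPhag"),
}


@dataclass
class PFTParams:
    """Physiological trait set of one protist functional type.

    Rates are d-1, quotas g(element) gC-1, concentrations g m-3,
    sizes um, carbon-per-cell gC cell-1, velocities m d-1.
    """

    name: str
    trophic_class: str
    # growth / mortality / respiration
    UmRT: float = 0.81          # reference max growth rate, d-1
    Q10: float = 2.0
    Tref: float = 20.0          # degC
    mrtRT: float = 0.07         # reference mortality, d-1 (or d-1 (gC m-3)-1)
    mortality_order: str = "linear"   # "linear" | "quadratic"
    BRfrac: float = 0.05        # basal respiration as fraction of UmT
    redco: float = 0.0          # C cost of NO3 reduction, gC gN-1
    AR: float = 0.5             # anabolic cost of N utilisation, gC gN-1
    SDA: float = 0.0            # specific dynamic action fraction
    # nitrogen quotas
    NCmin: float = 0.05
    NCopt: float = 0.15
    NCmax: float = 0.20
    NO3Copt: Optional[float] = None
    NO3Cmax: Optional[float] = None
    PCminNCmin: Optional[float] = None   # N:C floor under full P stress
    PCminNCmax: Optional[float] = None   # N:C ceiling under full P stress
    # phosphorus quotas
    PCmin: float = 0.005
    PCopt: float = 0.02
    PCmax: float = 0.04
    # silica quotas (diatom only)
    SCmin: Optional[float] = None
    SCopt: Optional[float] = None
    SCmax: Optional[float] = None
    # uptake half-saturations, g m-3
    KtN: Optional[float] = None
    KtP: Optional[float] = None
    KtSi: Optional[float] = None
    # phototrophy
    ChlCmax: Optional[float] = None      # gChl gC-1
    alphaChl: Optional[float] = None     # gC gChl-1 (umol m-2 s-1)-1 d-1
    relPS: float = 1.0
    PSDOC: float = 0.06
    lossChl_rate: Optional[float] = None  # d-1, NCM kleptochloroplast loss
    # size / phagotrophy
    ESD: float = 10.0            # um
    Ccell: Optional[float] = None
    optCR: float = 0.0           # optimum capture rate, dimensionless
    PR: Dict[str, float] = field(default_factory=dict)  # prey handling index
    relPhag: float = 1.0         # dark ingestion fraction
    AEo: float = 0.25
    AEm: float = 0.75
    # settling (diatom only)
    sed: float = 0.0             # m d-1

    def __post_init__(self):
        # every PFT may appear as prey, so a per-cell carbon content is
        # always needed; fill from the size regression when absent
        if self.Ccell is None and self.ESD > 0:
            self.Ccell = carbon_per_cell(
                self.ESD, diatom=self.trophic_class == "diatom")

    # ----- derived capability flags -------------------------------------
    @property
    def is_phototroph(self) -> bool:
        return self.trophic_class in PHOTOTROPH_CLASSES

    @property
    def is_phagotroph(self) -> bool:
        return self.trophic_class in PHAGOTROPH_CLASSES

    @property
    def has_uptake(self) -> bool:
        return self.trophic_class in UPTAKE_CLASSES

    @property
    def uses_silica(self) -> bool:
        return self.trophic_class == "diatom"

    @property
    def is_kleptoplastic(self) -> bool:
        return self.trophic_class == "NCM"

    # ----- validation ---------------------------------------------------
    def validate(self) -> None:
        p = self
        if p.trophic_class not in TROPHIC_CLASSES:
            raise ConfigurationError(
                f"{p.name}: unknown trophic_class {p.trophic_class!r}")
        for f in _CLASS_MANDATORY[p.trophic_class]:
            if getattr(p, f) is None:
                raise ConfigurationError(
                    f"{p.name}: mandatory field {f!r} missing for "
                    f"trophic class {p.trophic_class}")
        if p.mortality_order not in ("linear", "quadratic"):
            raise ConfigurationError(
                f"{p.name}: mortality_order must be linear or quadratic")

        def _chain(lo, opt, hi, label):
            if not (lo < opt <= hi):
                raise ValidationError(
                    f"{p.name}: require {label}min < {label}opt <= {label}max "
                    f"(got {lo}, {opt}, {hi})")

        _chain(p.NCmin, p.NCopt, p.NCmax, "NC")
        _chain(p.PCmin, p.PCopt, p.PCmax, "PC")
        if p.uses_silica:
            _chain(p.SCmin, p.SCopt, p.SCmax, "SC")
        if p.has_uptake:
            if p.NO3Copt > p.NCopt or p.NO3Cmax > p.NCmax:
                raise ValidationError(
                    f"{p.name}: nitrate quotas must satisfy "
                    "NO3Copt <= NCopt and NO3Cmax <= NCmax")
        nonneg = ("UmRT", "Q10", "mrtRT", "BRfrac", "redco", "AR", "SDA",
                  "NCmin", "PCmin", "ESD", "relPS", "PSDOC", "optCR", "sed")
        for f in nonneg:
            v = getattr(p, f)
            if v is not None and v < 0:
                raise ValidationError(f"{p.name}: {f} must be nonnegative")
        if p.is_phagotroph:
            if not (0.0 <= p.AEo <= p.AEm <= 1.0):
                raise ValidationError(
                    f"{p.name}: require 0 <= AEo <= AEm <= 1")
            if not (0.0 <= p.relPhag <= 1.0):
                raise ValidationError(f"{p.name}: relPhag must lie in [0,1]")
        else:
            if any(v > 0 for v in p.PR.values()):
                raise ValidationError(
                    f"{p.name}: phototrophs cannot carry prey-handling "
                    "entries > 0")
            if p.optCR > 0:
                raise ValidationError(
                    f"{p.name}: optCR > 0 on a non-phagotroph")
        for prey, v in p.PR.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"{p.name}: PR[{prey}] must lie in [0,1]")


class ParameterSet:
    """Ordered, validated collection of :class:`PFTParams`."""

    def __init__(self, pfts: List[PFTParams]):
        self.pfts = list(pfts)
        names = [p.name for p in self.pfts]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate PFT names")
        self.validate()

    def __iter__(self):
        return iter(self.pfts)

    def __len__(self):
        return len(self.pfts)

    def __getitem__(self, name: str) -> PFTParams:
        for p in self.pfts:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> List[str]:
        return [p.name for p in self.pfts]

    def subset(self, names) -> "ParameterSet":
        """A new set restricted to ``names`` (prey-handling entries for
        removed types are dropped)."""
        keep = [self[n] for n in names]
        out = []
        for p in keep:
            q = PFTParams(**asdict(p))
            q.PR = {k: v for k, v in p.PR.items() if k in names}
            out.append(q)
        return ParameterSet(out)

    def validate(self) -> None:
        for p in self.pfts:
            p.validate()
        # cross-PFT rules
        for p in self.pfts:
            for prey_name, v in p.PR.items():
                if prey_name not in self.names:
                    raise ConfigurationError(
                        f"{p.name}: PR refers to unknown prey {prey_name!r}")
                prey = self[prey_name]
                if prey_name == p.name and v > 0:
                    raise ValidationError(
                        f"{p.name}: self-predation is excluded")
                if p.trophic_class == "CM" and prey.ESD > p.ESD and v > 0:
                    raise ValidationError(
                        f"{p.name}: CM cannot capture prey larger than "
                        f"itself (prey {prey_name}, ESD {prey.ESD} um)")

    # ----- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for p in self.pfts:
            d = {k: v for k, v in asdict(p).items()
                 if v is not None and k != "name"}
            out[p.name] = d
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "ParameterSet":
        pfts = []
        valid_fields = {f.name for f in fields(PFTParams)}
        for name, entry in doc.items():
            if not isinstance(entry, dict):
                raise ConfigurationError(f"{name}: entry must be a mapping")
            unknown = set(entry) - valid_fields
            if unknown:
                raise ConfigurationError(
                    f"{name}: unknown fields {sorted(unknown)}")
            if "trophic_class" not in entry:
                raise ConfigurationError(
                    f"{name}: mandatory field 'trophic_class' missing")
            pfts.append(PFTParams(name=name, **entry))
        return cls(pfts)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError("parameter document must be a mapping")
        return cls.from_dict(doc)


def load_parameter_set(source) -> ParameterSet:
    """Load and validate a parameter set.

    ``source`` may be a path to a YAML document (one mapping per PFT) or a
    plain dict of the same structure.
    """
    if isinstance(source, dict):
        return ParameterSet.from_dict(source)
    return ParameterSet.from_yaml(source)


def prey_handling_matrix(params: ParameterSet):
    """Square predator x prey handling-index matrix over the set's PFTs.

    Rows are predators, columns prey, entries in [0, 1].  Phototroph rows
    and the diagonal are identically zero; CM rows are zero for prey
    larger than the predator.
    """
    import numpy as np
    n = len(params)
    M = np.zeros((n, n))
    for i, pred in enumerate(params):
        if not pred.is_phagotroph:
            continue
        for j, prey in enumerate(params):
            v = pred.PR.get(prey.name, 0.0)
            if i == j:
                v = 0.0
            if pred.trophic_class == "CM" and prey.ESD > pred.ESD:
                v = 0.0
            M[i, j] = v
    return M


def default_parameters() -> ParameterSet:
    """The default five-type Southern-North-Sea-style parameterization.

    Shared choices: identical reference maximum growth rate (0.81 d-1) so
    no type starts with a growth advantage; linear mortality 0.07 d-1 for
    diatom, green and CM; quadratic closure 0.007 d-1 for protozoo-
    plankton; photosynthetic overcapacity relPS = 2 for the primarily
    phototrophic types.  Quotas follow Redfield-anchored trait-table
    ranges (gN gC-1 ~0.07-0.20, gP gC-1 ~0.005-0.04, gSi gC-1 up to
    ~0.35 for diatoms); CMs carry a weaker photosystem (lower alphaChl,
    ChlCmax) and a modest capture rate, trading peak growth for
    flexibility.  Sizes are medians typical of the respective groups.
    """
    n_common = dict(NCmin=0.07, NCopt=0.15, NCmax=0.20,
                    NO3Copt=0.14, NO3Cmax=0.19,
                    PCminNCmin=0.10, PCminNCmax=0.16)
    p_common = dict(PCmin=0.005, PCopt=0.02, PCmax=0.04)
    kt = dict(KtN=0.014, KtP=0.0031)

    diatom = PFTParams(
        name="diatom", trophic_class="diatom",
        UmRT=0.81, Q10=2.0, Tref=20.0, mrtRT=0.07, mortality_order="linear",
        BRfrac=0.05, redco=1.71, AR=0.5,
        **n_common, **p_common, **kt,
        SCmin=0.10, SCopt=0.25, SCmax=0.35, KtSi=0.028,
        ChlCmax=0.060, alphaChl=0.90, relPS=2.0, PSDOC=0.06,
        ESD=24.0, Ccell=carbon_per_cell(24.0, diatom=True),
        sed=stokes_velocity(24.0, excess_density=20.0),
    )
    green = PFTParams(
        name="green", trophic_class="green",
        UmRT=0.81, Q10=2.0, Tref=20.0, mrtRT=0.07, mortality_order="linear",
        BRfrac=0.05, redco=1.71, AR=0.5,
        **n_common, **p_common, **kt,
        ChlCmax=0.035, alphaChl=0.50, relPS=2.0, PSDOC=0.06,
        ESD=6.0, Ccell=carbon_per_cell(6.0),
    )
    protozoo = PFTParams(
        name="protozoo", trophic_class="protozoo",
        UmRT=0.81, Q10=2.0, Tref=20.0, mrtRT=0.007,
        mortality_order="quadratic",
        BRfrac=0.05, AR=0.5, SDA=0.3,
        NCmin=0.07, NCopt=0.16, NCmax=0.22,
        PCmin=0.006, PCopt=0.022, PCmax=0.045,
        ESD=30.0, Ccell=carbon_per_cell(30.0),
        optCR=0.50, relPhag=1.0, AEo=0.25, AEm=0.75,
        PR={"diatom": 0.75, "green": 1.0, "CM": 1.0},
    )
    # CMs are parameterized as oligotrophy specialists: weak photosystem,
    # high nutrient affinity, low phosphorus quotas (prey ingestion
    # decouples them from dissolved phosphate)
    cm = PFTParams(
        name="CM", trophic_class="CM",
        UmRT=0.81, Q10=2.0, Tref=20.0, mrtRT=0.07, mortality_order="linear",
        BRfrac=0.05, redco=1.71, AR=0.5, SDA=0.3,
        **n_common,
        PCmin=0.002, PCopt=0.008, PCmax=0.02,
        KtN=0.005, KtP=0.001,
        ChlCmax=0.025, alphaChl=0.35, relPS=2.0, PSDOC=0.06,
        ESD=12.0, Ccell=carbon_per_cell(12.0),
        optCR=0.40, relPhag=0.05, AEo=0.25, AEm=0.75,
        PR={"green": 1.0},
    )
    ncm = PFTParams(
        name="NCM", trophic_class="NCM",
        UmRT=0.81, Q10=2.0, Tref=20.0, mrtRT=0.07, mortality_order="linear",
        BRfrac=0.05, AR=0.5, SDA=0.3,
        NCmin=0.07, NCopt=0.16, NCmax=0.22,
        PCmin=0.006, PCopt=0.022, PCmax=0.045,
        ChlCmax=0.02, alphaChl=0.30, relPS=1.0, PSDOC=0.06,
        lossChl_rate=0.15,
        ESD=60.0, Ccell=carbon_per_cell(60.0),
        optCR=0.20, relPhag=0.5, AEo=0.25, AEm=0.75,
        PR={"diatom": 1.0, "green": 0.5, "CM": 1.0, "protozoo": 0.5},
    )
    return ParameterSet([diatom, green, protozoo, cm, ncm])
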