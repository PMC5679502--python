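"""Stoichiometric network representation, biomass adjustment, knockouts, and
the bundled toy network.

The toy network is a deliberately small (23-reaction) stand-in for a
genome-scale fungal reconstruction: a single C1 carbon currency, external and
stored phosphate pools, a biomass reaction built from a documented
composition, secretion + dissociation reaction pairs for seven organic acids,
an extracellular glucose-oxidase route to gluconate, and an external-proton
output reaction used as the proton-production objective.  See
``data/toy_network.md`` for the full derivation of every coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .acids import acid_table, protons_released

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "BiomassAdjustment",
    "Tag",
    "BIOMASS_CLASS_PROPS",
    "TOY_BIOMASS_COMPOSITION",
    "TOY_RESPIRATION_CC",
    "apply_biomass_adjustment",
    "apply_knockout",
    "make_toy_network",
    "carbon_imbalances",
]

C_MOLAR_MASS = 12.011
P_MOLAR_MASS = 30.974


class Tag:
    """Role markers for special reactions."""

    BIOMASS = "BIOMASS"
    PROTON_OUT = "PROTON_OUT"
    STORED_P_IN = "STORED_P_IN"
    EXTERNAL_P_IN = "EXTERNAL_P_IN"
    GLUCOSE_EX = "GLUCOSE_EX"
    XYLOSE_EX = "XYLOSE_EX"
    ACID_SECRETION = "ACID_SECRETION"
    ACID_DISSOCIATION = "ACID_DISSOCIATION"
    GOX = "GOX"
    OAH = "OAH"
    OTHER = "OTHER"

    #: tags that may appear at most once per network (per acid for ACID_*)
    UNIQUE = (
        BIOMASS,
        PROTON_OUT,
        STORED_P_IN,
        EXTERNAL_P_IN,
        GLUCOSE_EX,
        XYLOSE_EX,
        GOX,
        OAH,
    )


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    carbon_count: int = 0
    phosphorus_count: int = 0
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.carbon_count < 0 or self.phosphorus_count < 0:
            raise ValueError(f"{self.id}: element counts must be non-negative")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    reversible: bool = False
    tag: str = Tag.OTHER
    acid: str | None = None

    def __post_init__(self) -> None:
        self.lower_bound = float(self.lower_bound)
        self.upper_bound = float(self.upper_bound)
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items()}
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"{self.id}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ValueError(f"{self.id}: irreversible reaction with negative lower bound")
        if self.tag in (Tag.ACID_SECRETION, Tag.ACID_DISSOCIATION) and not self.acid:
            raise ValueError(f"{self.id}: acid tag requires an acid name")

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            reversible=self.reversible,
            tag=self.tag,
            acid=self.acid,
        )


@dataclass(frozen=True)
class BiomassAdjustment:
    """Multipliers on the nucleic-acid and phospholipid biomass components."""

    nucleic_acid_scale: float = 1.0
    phospholipid_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.nucleic_acid_scale <= 0 or self.phospholipid_scale <= 0:
            raise ValueError("biomass adjustment scales must be positive")


#: (g carbon per g, g phosphorus per g) of each biomass component class.
BIOMASS_CLASS_PROPS: dict[str, tuple[float, float]] = {
    "protein": (0.53, 0.0),
    "carbohydrate": (0.444, 0.0),
    "phospholipid": (0.65, 0.031),
    "nucleic_acid": (0.34, 0.094),
    "glycerol": (0.391, 0.0),
    "other": (0.0, 0.0),
}

#: Baseline toy biomass composition, mass fractions per gDW (sums to 1).
TOY_BIOMASS_COMPOSITION: dict[str, float] = {
    "protein": 0.45,
    "carbohydrate": 0.26,
    "phospholipid": 0.05,
    "nucleic_acid": 0.04,
    "glycerol": 0.10,
    "other": 0.10,
}

#: Growth-associated respiration: mmol of carbon currency oxidised to CO2
#: per gDW of biomass formed.  Sets the toy network's carbon-limited growth
#: rate; derivation in data/toy_network.md.
TOY_RESPIRATION_CC = 213.0


def biomass_coefficients(
    composition: Mapping[str, float], respiration_cc: float
) -> tuple[float, float, float]:
    """(carbon currency demand, phosphate demand, CO2 release) per gDW.

    Carbon demand is structural carbon (from the composition and per-class
    carbon contents) plus the respiration overhead, in mmol; phosphate demand
    comes from the phosphorus contents of the nucleic-acid and phospholipid
    classes.
    """
    carbon_g = sum(
        m * BIOMASS_CLASS_PROPS[cls][0] for cls, m in composition.items()
    )
    phosphorus_g = sum(
        m * BIOMASS_CLASS_PROPS[cls][1] for cls, m in composition.items()
    )
    cc = carbon_g * 1000.0 / C_MOLAR_MASS + respiration_cc
    pi = phosphorus_g * 1000.0 / P_MOLAR_MASS
    return cc, pi, respiration_cc


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_composition: dict[str, float] = field(default_factory=dict)
    respiration_cc: float = 0.0
    gox_forcing_disabled: bool = False

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ValueError(f"{rxn.id}: unknown metabolite {met_id}")
        seen: set[tuple[str, str | None]] = set()
        for rxn in self.reactions:
            if rxn.tag == Tag.OTHER:
                continue
            key = (rxn.tag, rxn.acid)
            if rxn.tag in Tag.UNIQUE or rxn.tag in (
                Tag.ACID_SECRETION,
                Tag.ACID_DISSOCIATION,
            ):
                if key in seen:
                    raise ValueError(f"duplicate tagged reaction {key}")
                seen.add(key)
        if self.biomass_composition:
            total = sum(self.biomass_composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"biomass composition mass fractions sum to {total}, not 1"
                )

    # -- lookups ---------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reactions_by_tag(self, tag: str) -> list[Reaction]:
        return [r for r in self.reactions if r.tag == tag]

    def tagged(self, tag: str, acid: str | None = None) -> Reaction:
        """The unique reaction carrying *tag* (and *acid* for ACID_* tags)."""
        matches = [
            r
            for r in self.reactions
            if r.tag == tag and (acid is None or r.acid == acid)
        ]
        if not matches:
            raise KeyError(f"no reaction tagged {tag}" + (f"({acid})" if acid else ""))
        if len(matches) > 1:
            raise KeyError(f"tag {tag} is not unique")
        return matches[0]

    # -- matrices --------------------------------------------------------

    @property
    def balanced_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.boundary]

    def stoichiometric_matrix(self, include_boundary: bool = False) -> np.ndarray:
        """Dense S (metabolites x reactions); boundary rows excluded by default."""
        mets = self.metabolites if include_boundary else self.balanced_metabolites
        row = {m.id: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                if met_id in row:
                    S[row[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_composition=dict(self.biomass_composition),
            respiration_cc=self.respiration_cc,
            gox_forcing_disabled=self.gox_forcing_disabled,
        )

    def summary(self) -> dict:
        """JSON-ready structural summary (counts, tags, composition)."""
        tags: dict[str, int] = {}
        for rxn in self.reactions:
            tags[rxn.tag] = tags.get(rxn.tag, 0) + 1
        return {
            "n_metabolites": len(self.metabolites),
            "n_reactions": len(self.reactions),
            "n_boundary_metabolites": sum(m.boundary for m in self.metabolites),
            "tags": tags,
            "acids_with_dissociation": sorted(
                r.acid for r in self.reactions_by_tag(Tag.ACID_DISSOCIATION)
            ),
            "biomass_composition": dict(self.biomass_composition),
            "respiration_cc": self.respiration_cc,
        }


def carbon_imbalances(net: MetabolicNetwork) -> dict[str, float]:
    """Per-reaction net carbon change, counting boundary metabolites.

    Exchange-style reactions (a single metabolite), the biomass reaction and
    the proton output are excluded: their carbon crosses the system boundary
    without an explicit partner species.
    """
    carbon = {m.id: m.carbon_count for m in net.metabolites}
    out: dict[str, float] = {}
    for rxn in net.reactions:
        if rxn.tag in (Tag.BIOMASS, Tag.PROTON_OUT) or len(rxn.stoichiometry) < 2:
            continue
        out[rxn.id] = sum(
            coeff * carbon[met] for met, coeff in rxn.stoichiometry.items()
        )
    return out


def apply_biomass_adjustment(
    net: MetabolicNetwork, adj: BiomassAdjustment
) -> MetabolicNetwork:
    """Rescale the nucleic-acid and phospholipid biomass components.

    Internal component ratios are untouched (each class is scaled as a
    whole); the glycerol component absorbs the mass difference so total
    biomass mass per gDW is unchanged.  The biomass reaction's carbon and
    phosphate coefficients are recomputed from the adjusted composition.
    """
    if not net.biomass_composition:
        raise ValueError("network carries no biomass composition to adjust")
    comp = dict(net.biomass_composition)
    delta = comp["nucleic_acid"] * (adj.nucleic_acid_scale - 1.0) + comp[
        "phospholipid"
    ] * (adj.phospholipid_scale - 1.0)
    new_glycerol = comp["glycerol"] - delta
    if new_glycerol < 0:
        raise ValueError(
            "biomass adjustment would drive the glycerol fraction negative "
            f"({new_glycerol:.4f})"
        )
    comp["nucleic_acid"] *= adj.nucleic_acid_scale
    comp["phospholipid"] *= adj.phospholipid_scale
    comp["glycerol"] = new_glycerol

    out = net.copy()
    out.biomass_composition = comp
    cc, pi, co2 = biomass_coefficients(comp, net.respiration_cc)
    biomass = out.tagged(Tag.BIOMASS)
    for met_id in list(biomass.stoichiometry):
        met = out.metabolite(met_id)
        if met.phosphorus_count and biomass.stoichiometry[met_id] < 0:
            biomass.stoichiometry[met_id] = -pi
        elif met.carbon_count and biomass.stoichiometry[met_id] < 0:
            biomass.stoichiometry[met_id] = -cc
    return out


SUPPORTED_KNOCKOUTS = frozenset({"oah", "gox"})


def apply_knockout(net: MetabolicNetwork, genes: Iterable[str]) -> MetabolicNetwork:
    """Return a copy with the given gene deletions applied.

    ``oah`` pins the oxalate-producing reaction to zero flux; ``gox``
    disables the forced extracellular glucose-oxidase flux (the engine then
    sees a zero GOX rate) and pins the reaction to zero.
    """
    genes = set(genes)
    unknown = genes - SUPPORTED_KNOCKOUTS
    if unknown:
        raise ValueError(
            f"unknown knockout(s) {sorted(unknown)}; "
            f"supported: {sorted(SUPPORTED_KNOCKOUTS)}"
        )
    out = net.copy()
    if "oah" in genes:
        rxn = out.tagged(Tag.OAH)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    if "gox" in genes:
        rxn = out.tagged(Tag.GOX)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
        out.gox_forcing_disabled = True
    return out


# ---------------------------------------------------------------------------
# toy network fixture
# ---------------------------------------------------------------------------

_ACID_MET_PREFIX = {
    "citric": "cit",
    "oxalic": "oxa",
    "gluconic": "glcn",
    "acetic": "ace",
    "malic": "mal",
    "succinic": "suc",
    "lactic": "lac",
}


def make_toy_network(dissociation_ph: float = 2.0) -> MetabolicNetwork:
    """Deterministic 23-reaction fermentation network.

    ``dissociation_ph`` sets the initial proton coefficient on the
    dissociation reactions; the simulation engine rewrites these every step
    from the ambient pH.
    """
    acids = acid_table()
    mets: list[Metabolite] = [
        Metabolite("glc_e", "glucose (external)", "external", 6, boundary=True),
        Metabolite("xyl_e", "xylose (external)", "external", 5, boundary=True),
        Metabolite("pi_e", "phosphate (external)", "external", 0, 1, boundary=True),
        Metabolite("polyp", "stored phosphate pool", "cytosol", 0, 1, boundary=True),
        Metabolite("co2_e", "carbon dioxide (external)", "external", 1, boundary=True),
        Metabolite("cc", "carbon currency (C1)", "cytosol", 1),
        Metabolite("pi_c", "phosphate (cytosol)", "cytosol", 0, 1),
        Metabolite("h_e", "proton (external)", "external", 0),
        Metabolite("sec_cap", "acid secretion capacity", "cytosol", 0),
    ]
    for name, prefix in _ACID_MET_PREFIX.items():
        n_c = acids[name].carbon_count
        mets.append(Metabolite(f"{prefix}_c", f"{name} acid (cytosol)", "cytosol", n_c))
        mets.append(
            Metabolite(f"{prefix}_s", f"{name} acid (secreted, undissociated)", "external", n_c)
        )
        mets.append(
            Metabolite(f"{prefix}_e", f"{name} acid (external pool)", "external", n_c, boundary=True)
        )

    cc_coeff, pi_coeff, co2_coeff = biomass_coefficients(
        TOY_BIOMASS_COMPOSITION, TOY_RESPIRATION_CC
    )

    rxns: list[Reaction] = [
        Reaction("T_GLC", {"glc_e": -1, "cc": 6}, 0, 1000, tag=Tag.GLUCOSE_EX),
        Reaction("T_XYL", {"xyl_e": -1, "cc": 5}, 0, 1000, tag=Tag.XYLOSE_EX),
        # phosphate transport is deliberately carbon-free: under the
        # two-stage optimisation any carbon cost would let the growth LP
        # starve the storage objective in carbon-limited phases and kill
        # the rapid-uptake-then-store behaviour
        Reaction("T_PIE", {"pi_e": -1, "pi_c": 1}, 0, 1000, tag=Tag.EXTERNAL_P_IN),
        # forward flux = release of stored phosphate; reverse = storage
        Reaction(
            "PI", {"polyp": -1, "pi_c": 1}, -1000, 1000, reversible=True, tag=Tag.STORED_P_IN
        ),
        # forced per step from GOX kinetics; zero when not forced
        Reaction("GOX_E", {"glc_e": -1, "glcn_s": 1}, 0, 0, tag=Tag.GOX),
        Reaction(
            "BIOMASS",
            {"cc": -cc_coeff, "pi_c": -pi_coeff, "co2_e": co2_coeff},
            0,
            1000,
            tag=Tag.BIOMASS,
        ),
        Reaction("SYN_CIT", {"cc": -6, "cit_c": 1}, 0, 1000),
        Reaction("SYN_OXA", {"cc": -2, "oxa_c": 1}, 0, 1000, tag=Tag.OAH),
        # citrate and oxalate secretion share one transport-capacity pool
        # (they act as a single proton-production response); the engine sizes
        # it with the citrate output cap each step
        Reaction("SEC_BUDGET", {"sec_cap": 1}, 0, 0.12),
        Reaction("HPE", {"h_e": -1}, 0, 1000, tag=Tag.PROTON_OUT),
    ]
    h_e0 = 10.0 ** (-dissociation_ph)
    for name, prefix in _ACID_MET_PREFIX.items():
        stoich = {f"{prefix}_c": -1, f"{prefix}_s": 1}
        if name in ("citric", "oxalic"):
            stoich["sec_cap"] = -1
        rxns.append(
            Reaction(
                f"SEC_{prefix.upper()}",
                stoich,
                0,
                1000,
                tag=Tag.ACID_SECRETION,
                acid=name,
            )
        )
        rxns.append(
            Reaction(
                f"DISS_{prefix.upper()}",
                {
                    f"{prefix}_s": -1,
                    f"{prefix}_e": 1,
                    "h_e": protons_released(acids[name], h_e0),
                },
                0,
                1000,
                tag=Tag.ACID_DISSOCIATION,
                acid=name,
            )
        )

    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        biomass_composition=dict(TOY_BIOMASS_COMPOSITION),
        respiration_cc=TOY_RESPIRATION_CC,
    )


def acid_metabolite_prefix(acid_name: str) -> str:
    return _ACID_MET_PREFIX[acid_name]
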