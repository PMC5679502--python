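"""SBML import/export (Level 3 + fbc, Level 2 tolerated on read).

Round-trips through :func:`save_sbml`/:func:`load_sbml` preserve the
stoichiometric matrix, bounds, element counts and role tags exactly; tags and
element counts ride in SBML notes.  Foreign models without tag notes are
tagged by configurable id patterns plus an explicit override map.
"""

from __future__ import annotations

import re
from typing import Mapping

import libsbml

from .network import MetabolicNetwork, Metabolite, Reaction, Tag

__all__ = ["load_sbml", "save_sbml", "SBMLParseError", "DEFAULT_TAG_PATTERNS"]


class SBMLParseError(ValueError):
    pass


#: id patterns used to tag special reactions in foreign models (the naming
#: follows the conventions of published fungal reconstructions, e.g. DGLCe /
#: XYLe / PIe / PI / Hpe); override per call for anything else.
DEFAULT_TAG_PATTERNS: dict[str, str] = {
    Tag.BIOMASS: r"(?i)biomass|growth",
    Tag.PROTON_OUT: r"(?i)^hpe",
    Tag.EXTERNAL_P_IN: r"(?i)^pie",
    Tag.STORED_P_IN: r"(?i)^pi$",
    Tag.GLUCOSE_EX: r"(?i)^(dglce|t_glc|ex_glc)",
    Tag.XYLOSE_EX: r"(?i)^(xyle|t_xyl|ex_xyl)",
    Tag.GOX: r"(?i)gox",
    Tag.OAH: r"(?i)oah",
}

_NOTE_RE = re.compile(r"<p>\s*([\w.]+)\s*:\s*(.*?)\s*</p>", re.S)


def _notes_dict(node) -> dict[str, str]:
    notes = node.getNotesString() if node.isSetNotes() else ""
    return dict(_NOTE_RE.findall(notes))


def _set_notes(node, pairs: Mapping[str, object]) -> None:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    node.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def save_sbml(net: MetabolicNetwork, path: str) -> None:
    """Write the network as SBML Level 3 Version 1 with the fbc extension."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId("acidflux_model")
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)
    if net.biomass_composition:
        encoded = ";".join(
            f"{cls}={frac!r}" for cls, frac in net.biomass_composition.items()
        )
        _set_notes(
            model,
            {
                "biomass_composition": encoded,
                "respiration_cc": net.respiration_cc,
            },
        )

    for comp_id in sorted({m.compartment for m in net.metabolites}):
        comp = model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in net.metabolites:
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(met.boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        _set_notes(
            sp,
            {"carbon_count": met.carbon_count, "phosphorus_count": met.phosphorus_count},
        )

    def _bound_param(value: float, which: str, rxn_id: str) -> str:
        pid = f"{which}_{rxn_id}"
        par = model.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        return pid

    for rxn in net.reactions:
        rx = model.createReaction()
        rx.setId(rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound, "lb", rxn.id))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound, "ub", rxn.id))
        notes = {"tag": rxn.tag}
        if rxn.acid:
            notes["acid"] = rxn.acid
        # exact coefficients (XML doubles are truncated to ~15 digits)
        notes["stoich"] = ";".join(
            f"{met}={coeff!r}" for met, coeff in rxn.stoichiometry.items()
        )
        notes["bounds"] = f"{rxn.lower_bound!r},{rxn.upper_bound!r}"
        _set_notes(rx, notes)

    libsbml.writeSBMLToFile(doc, path)


def _tag_from_patterns(
    rxn_id: str,
    patterns: Mapping[str, str],
    overrides: Mapping[str, str],
) -> str:
    if rxn_id in overrides:
        return overrides[rxn_id]
    for tag, pattern in patterns.items():
        if re.search(pattern, rxn_id):
            return tag
    return Tag.OTHER


def load_sbml(
    path: str,
    tag_patterns: Mapping[str, str] | None = None,
    tag_overrides: Mapping[str, str] | None = None,
) -> MetabolicNetwork:
    """Read an SBML file into a :class:`MetabolicNetwork`.

    Reactions without explicit bounds get (-1000, 1000) if reversible, else
    (0, 1000).  Special-reaction tags come from notes written by
    :func:`save_sbml` when present, otherwise from ``tag_patterns`` /
    ``tag_overrides``.  A missing biomass reaction is an error.
    """
    doc = libsbml.readSBMLFromFile(path)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    model = doc.getModel()
    if model is None:
        raise SBMLParseError("SBML document contains no model")

    model_notes = _notes_dict(model)
    composition = {}
    if "biomass_composition" in model_notes:
        for item in model_notes["biomass_composition"].split(";"):
            cls, _, frac = item.partition("=")
            composition[cls.strip()] = float(frac)
    respiration = float(model_notes.get("respiration_cc", 0.0))

    metabolites = []
    for sp in model.getListOfSpecies():
        notes = _notes_dict(sp)
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "cytosol",
                carbon_count=int(notes.get("carbon_count", 0)),
                phosphorus_count=int(notes.get("phosphorus_count", 0)),
                boundary=sp.getBoundaryCondition(),
            )
        )

    patterns = DEFAULT_TAG_PATTERNS if tag_patterns is None else tag_patterns
    overrides = tag_overrides or {}
    params = {
        p.getId(): p.getValue() for p in model.getListOfParameters()
    }

    reactions = []
    for rx in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        reversible = rx.getReversible()
        lb, ub = (-1000.0, 1000.0) if reversible else (0.0, 1000.0)
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound() and rplug.getLowerFluxBound() in params:
                lb = params[rplug.getLowerFluxBound()]
            if rplug.isSetUpperFluxBound() and rplug.getUpperFluxBound() in params:
                ub = params[rplug.getUpperFluxBound()]
        notes = _notes_dict(rx)
        if "stoich" in notes:  # exact values written by save_sbml
            stoich = {}
            for item in notes["stoich"].split(";"):
                met, _, coeff = item.partition("=")
                stoich[met.strip()] = float(coeff)
        if "bounds" in notes:
            lb, ub = (float(x) for x in notes["bounds"].split(","))
        tag = notes.get("tag") or _tag_from_patterns(rx.getId(), patterns, overrides)
        try:
            reactions.append(
                Reaction(
                    id=rx.getId(),
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    reversible=reversible,
                    tag=tag,
                    acid=notes.get("acid"),
                )
            )
        except ValueError as exc:
            raise SBMLParseError(f"reaction {rx.getId()}: {exc}") from exc

    net = MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        biomass_composition=composition,
        respiration_cc=respiration,
    )
    if not net.reactions_by_tag(Tag.BIOMASS):
        raise SBMLParseError(
            "no biomass reaction found (tag notes, id patterns and overrides "
            "all failed to identify one)"
        )
    return net
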