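"""Minimal SBML Level 3 (core + fbc) reader.

Covers the subset needed to ingest constraint-based models: species
with compartments, reactions with stoichiometries and reversibility,
fbc flux bounds (via referenced parameters) and fbc gene-product
associations.  Species ids of the form ``M_<base>_<tag>`` or
``<base>[tag]`` are mapped onto the package's eight-compartment tag
scheme; the SBML ``compartment`` attribute is used as a fallback when
its id (or first letter) is one of the known tags.
"""

from __future__ import annotations

import math
from pathlib import Path

from lxml import etree

from .model import (
    COMPARTMENTS,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = ["read_sbml_model"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"


def _tag(name: str, ns: str = _SBML_NS) -> str:
    return f"{{{ns}}}{name}"


def _species_to_met_id(sid: str, compartment: str) -> str:
    sid = sid.removeprefix("M_")
    if sid.endswith("]") and "[" in sid:
        return sid
    for tag in COMPARTMENTS:
        if sid.endswith(f"_{tag}"):
            return f"{sid[:-2]}[{tag}]"
    comp = compartment[:1].lower()
    if comp not in COMPARTMENTS:
        raise ModelError(
            f"species {sid!r}: cannot map compartment {compartment!r} to a tag"
        )
    return f"{sid}[{comp}]"


def _gpr_from_association(node) -> str:
    tag = etree.QName(node).localname
    if tag == "geneProductRef":
        ref = node.get(_tag("geneProduct", _FBC_NS)) or node.get("geneProduct")
        return (ref or "").removeprefix("G_")
    children = [_gpr_from_association(ch) for ch in node]
    joiner = " and " if tag == "and" else " or "
    return "(" + joiner.join(children) + ")"


def read_sbml_model(
    path: str | Path, objective_id: str | None = None
) -> MetabolicModel:
    """Read an SBML L3 (core + fbc v2) file into a MetabolicModel."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    model_el = root.find(_tag("model"))
    if model_el is None:
        raise ModelError(f"{path}: no <model> element")

    parameters: dict[str, float] = {}
    for par in model_el.iterfind(f"{_tag('listOfParameters')}/{_tag('parameter')}"):
        parameters[par.get("id")] = float(par.get("value", "nan"))

    species_map: dict[str, str] = {}
    metabolites: list[Metabolite] = []
    seen_mets: set[str] = set()
    for sp in model_el.iterfind(f"{_tag('listOfSpecies')}/{_tag('species')}"):
        if sp.get("boundaryCondition") == "true":
            continue
        met_id = _species_to_met_id(sp.get("id"), sp.get("compartment", ""))
        species_map[sp.get("id")] = met_id
        if met_id not in seen_mets:
            seen_mets.add(met_id)
            formula = sp.get(_tag("chemicalFormula", _FBC_NS))
            metabolites.append(
                Metabolite(met_id, name=sp.get("name", ""), formula=formula)
            )

    reactions: list[Reaction] = []
    for rx in model_el.iterfind(f"{_tag('listOfReactions')}/{_tag('reaction')}"):
        rid = rx.get("id").removeprefix("R_")
        stoich: dict[str, float] = {}
        for ref in rx.iterfind(
            f"{_tag('listOfReactants')}/{_tag('speciesReference')}"
        ):
            sid = ref.get("species")
            if sid in species_map:
                stoich[species_map[sid]] = stoich.get(
                    species_map[sid], 0.0
                ) - float(ref.get("stoichiometry", "1"))
        for ref in rx.iterfind(
            f"{_tag('listOfProducts')}/{_tag('speciesReference')}"
        ):
            sid = ref.get("species")
            if sid in species_map:
                stoich[species_map[sid]] = stoich.get(
                    species_map[sid], 0.0
                ) + float(ref.get("stoichiometry", "1"))
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        if not stoich:
            continue
        reversible = rx.get("reversible", "false") == "true"
        lb_ref = rx.get(_tag("lowerFluxBound", _FBC_NS))
        ub_ref = rx.get(_tag("upperFluxBound", _FBC_NS))
        lb = parameters.get(lb_ref) if lb_ref else None
        ub = parameters.get(ub_ref) if ub_ref else None
        if lb is not None and lb <= -1e30:
            lb = -math.inf
        if ub is not None and ub >= 1e30:
            ub = math.inf
        gpr = ""
        assoc = rx.find(_tag("geneProductAssociation", _FBC_NS))
        if assoc is not None and len(assoc):
            gpr = _gpr_from_association(assoc[0])
        reactions.append(
            Reaction(
                rid,
                stoich,
                reversible,
                name=rx.get("name", ""),
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
            )
        )

    if objective_id is None:
        candidates = [
            r.id for r in reactions if "biomass" in (r.id + r.name).lower()
        ]
        if not candidates:
            raise ModelError(f"{path}: no biomass reaction found for objective")
        objective_id = candidates[0]
    return MetabolicModel(
        metabolites, reactions, objective_id, name=Path(path).stem
    )
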