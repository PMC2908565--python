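"""Compartmentalized metabolic models: parsing, validation, statistics.

A model is a stoichiometric network over metabolites tagged with one of
eight sub-cellular compartments (cytosol, extracellular, ER, Golgi,
mitochondria, nucleus, peroxisome, vacuole), written ``base[tag]`` as in
``pyr[c]`` / ``pyr[m]``.  Reactions carry flux bounds in mmol/gDCW-hr,
optional boolean gene--protein--reaction (GPR) associations and a
free-text subsystem.  The on-disk format is a TSV dialect with columns
``id, name, equation, gpr, subsystem, lb, ub``; a subset of SBML Level 3
(core + fbc) can also be read.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "COMPARTMENTS",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelStats",
    "ModelError",
    "EquationParseError",
    "GPRParseError",
    "parse_equation",
    "parse_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "load_model",
    "write_model",
    "model_stats",
    "decompartmentalize",
    "carbon_count",
]

#: compartment tag -> human name
COMPARTMENTS = {
    "c": "cytosol",
    "e": "extracellular",
    "r": "endoplasmic reticulum",
    "g": "Golgi apparatus",
    "m": "mitochondria",
    "n": "nucleus",
    "x": "peroxisome",
    "v": "vacuole",
}

EXCHANGE_PREFIX = "EX_"

#: solver-facing stand-in for an unbounded flux (mmol/gDCW-hr)
BIG_M = 1000.0


class ModelError(ValueError):
    """Raised when a model violates a structural invariant."""


class EquationParseError(ModelError):
    """Raised for malformed reaction equation strings."""


class GPRParseError(ModelError):
    """Raised for malformed gene--protein--reaction expressions."""


# ---------------------------------------------------------------------------
# elemental formulas

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``C6H12O6`` into ``{'C': 6, 'H': 12, 'O': 6}``."""
    out: dict[str, int] = {}
    pos = 0
    for m in _ELEMENT_RE.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"malformed formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ModelError(f"malformed formula {formula!r}")
    return out


def carbon_count(formula: str | None) -> int | None:
    """Carbon atoms in an elemental formula, or None when unknown."""
    if not formula:
        return None
    return parse_formula(formula).get("C", 0)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Metabolite:
    """A compartment-tagged chemical species, e.g. ``pyr[c]``."""

    id: str
    name: str = ""
    formula: str | None = None
    n_carbon: int | None = None

    def __post_init__(self) -> None:
        base, comp = split_met_id(self.id)
        self.base_id = base
        self.compartment = comp
        if not self.name:
            self.name = base
        if self.formula and self.n_carbon is None:
            self.n_carbon = carbon_count(self.formula)
        if self.formula and self.n_carbon is not None:
            if self.n_carbon != carbon_count(self.formula):
                raise ModelError(
                    f"{self.id}: n_carbon={self.n_carbon} contradicts "
                    f"formula {self.formula}"
                )
        if self.n_carbon is not None and self.n_carbon < 0:
            raise ModelError(f"{self.id}: negative carbon count")


def split_met_id(met_id: str) -> tuple[str, str]:
    """Split ``pyr[c]`` into ``('pyr', 'c')``; validate the tag."""
    m = re.fullmatch(r"(.+)\[([a-z])\]", met_id)
    if not m:
        raise ModelError(f"metabolite id {met_id!r} lacks a [tag] compartment")
    base, comp = m.group(1), m.group(2)
    if comp not in COMPARTMENTS:
        raise ModelError(
            f"metabolite id {met_id!r}: unknown compartment tag [{comp}]"
        )
    return base, comp


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and optional GPR.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  Bounds default from reversibility:
    irreversible reactions have a lower bound of 0, reversible -inf.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    name: str = ""
    lower_bound: float | None = None
    upper_bound: float | None = None
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        if not self.name:
            self.name = self.id
        if self.lower_bound is None:
            self.lower_bound = -math.inf if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = math.inf
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.gpr:
            parse_gpr(self.gpr)  # validate eagerly

    @property
    def kind(self) -> str:
        return "exchange" if self.id.startswith(EXCHANGE_PREFIX) else "internal"

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.stoichiometry)

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    def equation(self) -> str:
        """Render the stoichiometry back into the TSV equation dialect."""

        def side(items: list[tuple[str, float]]) -> str:
            parts = []
            for met, coef in items:
                c = abs(coef)
                frac = Fraction(c).limit_denominator(10**6)
                txt = str(frac) if frac.denominator == 1 else f"{c:g}"
                parts.append(f"{txt} {met}" if txt != "1" else met)
            return " + ".join(parts)

        subs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = "<=>" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class ModelStats:
    """Count summary of a metabolic reconstruction."""

    n_genes: int
    n_reactions: int
    n_metabolites: int
    n_unique_metabolites: int
    n_internal: int
    n_exchange: int
    n_intra_compartment: int
    n_inter_compartment: int
    n_gene_associated: int
    metabolites_per_compartment: dict[str, int]
    reactions_per_compartment: dict[str, int]
    reactions_per_subsystem: dict[str, int]

    def __post_init__(self) -> None:
        assert self.n_internal + self.n_exchange == self.n_reactions
        assert self.n_unique_metabolites <= self.n_metabolites

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, indent=2, **kwargs)


class MetabolicModel:
    """A compartmentalized stoichiometric network.

    Parameters
    ----------
    metabolites, reactions :
        The network content.  Every metabolite referenced by a reaction
        must be declared; reaction ids must be unique.
    objective_id :
        Reaction whose flux is maximized by default (the biomass
        pseudo-reaction for growth simulations).
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: str,
        name: str = "",
    ) -> None:
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {met.id}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelError(f"duplicate reaction id {rxn.id}")
            self.reactions[rxn.id] = rxn
        self.objective_id = objective_id
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.objective_id not in self.reactions:
            raise ModelError(f"objective reaction {self.objective_id!r} missing")
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown metabolite "
                        f"{met_id!r}"
                    )
            if rxn.kind == "exchange":
                mets = rxn.metabolite_ids
                if len(mets) != 1 or self.metabolites[mets[0]].compartment != "e":
                    raise ModelError(
                        f"exchange reaction {rxn.id} must touch exactly one "
                        "extracellular metabolite"
                    )

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def reactions_of(self, met_id: str) -> list[Reaction]:
        if met_id not in self.metabolites:
            raise ModelError(f"unknown metabolite {met_id!r}")
        return [
            r for r in self.reactions.values() if met_id in r.stoichiometry
        ]

    def copy(self) -> "MetabolicModel":
        mets = [
            Metabolite(m.id, m.name, m.formula, m.n_carbon)
            for m in self.metabolites.values()
        ]
        rxns = [
            Reaction(
                r.id,
                dict(r.stoichiometry),
                r.reversible,
                r.name,
                r.lower_bound,
                r.upper_bound,
                r.gpr,
                r.subsystem,
            )
            for r in self.reactions.values()
        ]
        return MetabolicModel(mets, rxns, self.objective_id, self.name)

    def stoichiometric_matrix(self):
        """Dense S matrix plus row/column id orderings."""
        import numpy as np

        met_ids = self.metabolite_ids
        rxn_ids = self.reaction_ids
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[met], j] = coef
        return S, met_ids, rxn_ids

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.name or 'unnamed'}: "
            f"{len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


# ---------------------------------------------------------------------------
# equation grammar

_ARROW_RE = re.compile(r"(<=>|->)")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:/\d+)?)\s+)?(\S+)\[([a-z])\]$")


def _parse_side(text: str, sign: int, stoich: dict[str, float]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise EquationParseError(f"empty term near {text!r}")
        m = _TERM_RE.match(term)
        if not m:
            raise EquationParseError(f"malformed term {term!r}")
        coef_txt, base, comp = m.groups()
        if comp not in COMPARTMENTS:
            raise EquationParseError(
                f"unknown compartment tag [{comp}] in term {term!r}"
            )
        coef = float(Fraction(coef_txt)) if coef_txt else 1.0
        met_id = f"{base}[{comp}]"
        stoich[met_id] = stoich.get(met_id, 0.0) + sign * coef


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse a reaction equation string.

    Grammar: ``coef? met_id '[' tag ']' ('+' term)* ('->'|'<=>') rhs``
    where coefficients default to 1 and either side may be empty
    (drain/source pseudo-reactions).  Consumed species get negative
    coefficients; a metabolite appearing on both sides is net-summed and
    dropped if the net coefficient is zero.

    Returns
    -------
    (stoichiometry, reversible)
    """
    parts = _ARROW_RE.split(text)
    if len(parts) != 3:
        raise EquationParseError(
            f"equation must contain exactly one '->' or '<=>': {text!r}"
        )
    lhs, arrow, rhs = parts
    reversible = arrow == "<=>"
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1, stoich)
    _parse_side(rhs, +1, stoich)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise EquationParseError(
            f"all species cancel to zero net coefficient in {text!r}"
        )
    return stoich, reversible


# ---------------------------------------------------------------------------
# GPR boolean expressions (and/or over gene ids, with parentheses)

_GPR_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize_gpr(text: str) -> list[str]:
    return _GPR_TOKEN_RE.findall(text)


def parse_gpr(text: str):
    """Parse a GPR string into an AST of nested tuples.

    Returns ``None`` for an empty expression, a gene id string for a
    leaf, or ``('and'|'or', child, child, ...)`` for an operator node.
    """
    tokens = _tokenize_gpr(text)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_atom():
        tok = peek()
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR {text!r}")
            take()
            return node
        if tok is None or tok in (")", "and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR {text!r}")
        return take()

    def parse_and():
        children = [parse_atom()]
        while peek() == "and":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", *children)

    def parse_or():
        children = [parse_and()]
        while peek() == "or":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", *children)

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR {text!r}")
    return node


def gpr_genes(text: str) -> set[str]:
    """All gene ids appearing in a GPR expression."""

    def walk(node) -> set[str]:
        if node is None:
            return set()
        if isinstance(node, str):
            return {node}
        op, *children = node
        out: set[str] = set()
        for ch in children:
            out |= walk(ch)
        return out

    return walk(parse_gpr(text))


def evaluate_gpr(gpr: str, deleted_genes: set[str] | frozenset[str]) -> bool:
    """Evaluate a GPR with the listed genes deleted (set to false).

    An empty or absent GPR evaluates true (the reaction is retained):
    reactions with no gene association are spontaneous or unannotated
    and cannot be knocked out.
    """

    def walk(node) -> bool:
        if isinstance(node, str):
            return node not in deleted_genes
        op, *children = node
        results = (walk(ch) for ch in children)
        return all(results) if op == "and" else any(results)

    ast = parse_gpr(gpr)
    if ast is None:
        return True
    return walk(ast)


# ---------------------------------------------------------------------------
# tabular I/O

_TSV_COLUMNS = ["id", "name", "equation", "gpr", "subsystem", "lb", "ub"]


def load_model(
    path: str | Path,
    format: str = "tabular",
    objective_id: str | None = None,
    formulas: Mapping[str, str] | None = None,
) -> MetabolicModel:
    """Load a model from the TSV dialect or from SBML.

    Parameters
    ----------
    path :
        File to read.
    format :
        ``"tabular"`` (TSV with columns id, name, equation, gpr,
        subsystem, lb, ub) or ``"sbml"``.
    objective_id :
        Objective reaction; defaults to a reaction whose id or name
        contains "biomass" (case-insensitive), else an error.
    formulas :
        Optional base-id -> elemental formula map attached to
        metabolites after parsing (tabular only).
    """
    path = Path(path)
    if format == "sbml":
        from .sbml import read_sbml_model

        return read_sbml_model(path, objective_id=objective_id)
    if format != "tabular":
        raise ValueError(f"unknown format {format!r}")

    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"id", "equation", "gpr", "subsystem"} - set(df.columns)
    if missing:
        raise ModelError(f"{path}: missing required columns {sorted(missing)}")

    reactions: list[Reaction] = []
    seen: set[str] = set()
    met_ids: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rid = row.id.strip()
        if not rid:
            raise ModelError(f"{path}:{row_no}: blank reaction id")
        if rid in seen:
            raise ModelError(f"{path}:{row_no}: duplicate reaction id {rid!r}")
        seen.add(rid)
        try:
            stoich, reversible = parse_equation(row.equation)
        except EquationParseError as exc:
            raise ModelError(f"{path}:{row_no}: {exc}") from exc
        lb = float(row.lb) if getattr(row, "lb", "") else None
        ub = float(row.ub) if getattr(row, "ub", "") else None
        reactions.append(
            Reaction(
                rid,
                stoich,
                reversible,
                name=getattr(row, "name", "") or rid,
                lower_bound=lb,
                upper_bound=ub,
                gpr=row.gpr,
                subsystem=row.subsystem,
            )
        )
        met_ids |= set(stoich)

    formulas = dict(formulas or {})
    metabolites = [
        Metabolite(mid, formula=formulas.get(split_met_id(mid)[0]))
        for mid in sorted(met_ids)
    ]
    if objective_id is None:
        candidates = [
            r.id for r in reactions if "biomass" in (r.id + r.name).lower()
        ]
        if not candidates:
            raise ModelError(f"{path}: no biomass reaction found for objective")
        objective_id = candidates[0]
    return MetabolicModel(metabolites, reactions, objective_id, name=path.stem)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the TSV dialect (inverse of :func:`load_model`)."""
    import pandas as pd

    rows = []
    for rxn in model.reactions.values():
        default_lb = -math.inf if rxn.reversible else 0.0
        rows.append(
            {
                "id": rxn.id,
                "name": rxn.name,
                "equation": rxn.equation(),
                "gpr": rxn.gpr,
                "subsystem": rxn.subsystem,
                "lb": "" if rxn.lower_bound == default_lb else rxn.lower_bound,
                "ub": "" if rxn.upper_bound == math.inf else rxn.upper_bound,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# statistics and decompartmentalization


def model_stats(model: MetabolicModel) -> ModelStats:
    """Summary counts of a reconstruction.

    Internal reactions whose metabolites share a single compartment are
    intra-compartment; the remaining internal reactions (transport or
    multi-compartment conversions) are inter-compartment.  Unique
    metabolites are distinct compartment-stripped base ids.
    """
    mets_per_comp: dict[str, int] = {}
    for met in model.metabolites.values():
        mets_per_comp[met.compartment] = mets_per_comp.get(met.compartment, 0) + 1

    n_exchange = n_intra = n_inter = n_gene = 0
    rxns_per_comp: dict[str, int] = {}
    rxns_per_subsys: dict[str, int] = {}
    for rxn in model.reactions.values():
        subsys = rxn.subsystem or "(unassigned)"
        rxns_per_subsys[subsys] = rxns_per_subsys.get(subsys, 0) + 1
        if rxn.gpr:
            n_gene += 1
        comps = {model.metabolites[m].compartment for m in rxn.stoichiometry}
        for comp in comps:
            rxns_per_comp[comp] = rxns_per_comp.get(comp, 0) + 1
        if rxn.kind == "exchange":
            n_exchange += 1
        elif len(comps) == 1:
            n_intra += 1
        else:
            n_inter += 1

    return ModelStats(
        n_genes=len(model.genes),
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_unique_metabolites=len(
            {m.base_id for m in model.metabolites.values()}
        ),
        n_internal=n_intra + n_inter,
        n_exchange=n_exchange,
        n_intra_compartment=n_intra,
        n_inter_compartment=n_inter,
        n_gene_associated=n_gene,
        metabolites_per_compartment=dict(sorted(mets_per_comp.items())),
        reactions_per_compartment=dict(sorted(rxns_per_comp.items())),
        reactions_per_subsystem=dict(sorted(rxns_per_subsys.items())),
    )


def _base_stoichiometry(
    model: MetabolicModel, rxn: Reaction
) -> dict[str, float]:
    """Net stoichiometry after stripping compartment tags."""
    out: dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        base = model.metabolites[met_id].base_id
        out[base] = out.get(base, 0.0) + coef
    return {m: c for m, c in out.items() if abs(c) > 1e-12}


def _canonical_signature(stoich: dict[str, float], reversible: bool):
    fwd = tuple(sorted((m, round(c, 9)) for m, c in stoich.items()))
    if not reversible:
        return fwd
    rev = tuple(sorted((m, round(-c, 9)) for m, c in stoich.items()))
    return min(fwd, rev)


def decompartmentalize(model: MetabolicModel) -> MetabolicModel:
    """Collapse compartments: strip tags, drop pure transports, dedupe.

    Every metabolite is mapped to its base id (all placed in the
    cytosol tag for bookkeeping), reactions whose base stoichiometry
    cancels entirely (pure inter-compartment transport) are removed and
    reactions with identical normalized base stoichiometry are collapsed
    to a single representative.  Used for cross-model comparisons where
    sub-cellular localization is disregarded.  Idempotent.
    """
    seen_sig: dict[tuple, str] = {}
    new_rxns: list[Reaction] = []
    met_bases: set[str] = set()
    formulas = {
        m.base_id: m.formula for m in model.metabolites.values() if m.formula
    }
    objective = None
    for rxn in model.reactions.values():
        base = _base_stoichiometry(model, rxn)
        if not base:  # pure transport
            continue
        # exchange pseudo-reactions keep the extracellular tag so the
        # structural invariants still hold in the collapsed model
        tag = "e" if rxn.kind == "exchange" else "c"
        retagged = {
            (f"{m}[{tag}]" if not m.endswith("]") else m): c
            for m, c in base.items()
        }
        sig = _canonical_signature(retagged, rxn.reversible)
        if sig in seen_sig:
            if rxn.id == model.objective_id:
                objective = seen_sig[sig]
            continue
        seen_sig[sig] = rxn.id
        new_rxns.append(
            Reaction(
                rxn.id,
                retagged,
                rxn.reversible,
                rxn.name,
                rxn.lower_bound,
                rxn.upper_bound,
                rxn.gpr,
                rxn.subsystem,
            )
        )
        met_bases |= set(retagged)
        if rxn.id == model.objective_id:
            objective = rxn.id
    if objective is None:
        objective = new_rxns[0].id if new_rxns else model.objective_id
    mets = [
        Metabolite(mid, formula=formulas.get(mid[:-3]))
        for mid in sorted(met_bases)
    ]
    out = MetabolicModel(
        mets, new_rxns, objective, name=f"{model.name}_decomp"
    )
    return out
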