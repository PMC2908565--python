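"""Constraint-based flux balance analysis (FBA).

Solves max c·v subject to the steady-state mass balance S·v = 0 and flux
bounds alpha_j <= v_j <= beta_j.  Chemostat-style conditions are imposed
as equality bounds: measured substrate uptakes pin the corresponding
exchange fluxes and the non-growth-associated maintenance (NGAM) pins
the ATP-maintenance flux.  Gene deletions disable every reaction whose
GPR evaluates false.

Because FBA optima are usually degenerate, a second stage minimizes the
total absolute flux at the fixed optimal objective so that derived
quantities (P/O ratio, CO2 evolution, O2 uptake, flux-sums) are
deterministic and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .model import BIG_M, MetabolicModel, ModelError, evaluate_gpr

__all__ = [
    "FEASIBILITY_TOL",
    "ReactionConfig",
    "SimulationConditions",
    "FluxSolution",
    "InfeasibleError",
    "maximize_objective",
    "simulate_deletion",
    "compute_po_ratio",
    "set_po_ratio",
    "gaseous_exchange",
    "solve_lp",
    "effective_bounds",
]

#: primal feasibility tolerance requested from the LP solver
FEASIBILITY_TOL = 1e-9


class InfeasibleError(RuntimeError):
    """Raised when a solve required to be optimal is not."""


@dataclass(frozen=True)
class ReactionConfig:
    """Names of the special reactions/metabolites an analysis relies on.

    Defaults match the bundled toy methylotroph network; for another
    model load the ids from a YAML mapping with :meth:`from_yaml`.
    """

    atp_maintenance: str = "ATPM"
    atp_synthase: str = "ATPS3m"
    cytochrome_oxidase: str = "CYOOm"
    co2_exchange: str = "EX_co2"
    o2_exchange: str = "EX_o2"
    pumped_proton: str = "h_i[m]"
    matrix_proton: str = "h[m]"

    @classmethod
    def from_yaml(cls, path) -> "ReactionConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SimulationConditions:
    """Environment and parameter settings for one simulation.

    fixed_uptakes :
        exchange id -> uptake rate (mmol/gDCW-hr, non-negative); imposed
        as the equality v = -rate (chemostat steady state: the measured
        uptake is an input, not a capacity).
    max_uptakes :
        exchange id -> maximal uptake rate; imposed as the lower bound
        v >= -rate (substrate available but not forced to be consumed).
    ngam :
        non-growth-associated maintenance, mmol ATP/gDCW-hr; imposed as
        an equality on the dedicated ATP-maintenance reaction.
    deleted_genes :
        genes knocked out; reactions whose GPR evaluates false get
        alpha = beta = 0.
    """

    fixed_uptakes: dict[str, float] = field(default_factory=dict)
    max_uptakes: dict[str, float] = field(default_factory=dict)
    ngam: float = 0.0
    deleted_genes: set[str] = field(default_factory=set)
    config: ReactionConfig = field(default_factory=ReactionConfig)

    def __post_init__(self) -> None:
        for rates in (self.fixed_uptakes, self.max_uptakes):
            for rid, rate in rates.items():
                if rate < 0:
                    raise ValueError(f"uptake rate for {rid} must be >= 0")
        if self.ngam < 0:
            raise ValueError("ngam must be >= 0")

    def replace(self, **kwargs) -> "SimulationConditions":
        data = {
            "fixed_uptakes": dict(self.fixed_uptakes),
            "max_uptakes": dict(self.max_uptakes),
            "ngam": self.ngam,
            "deleted_genes": set(self.deleted_genes),
            "config": self.config,
        }
        data.update(kwargs)
        return SimulationConditions(**data)


@dataclass
class FluxSolution:
    """Status and flux vector of one constraint-based solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]
    solver_tolerance: float = FEASIBILITY_TOL

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.fluxes, name="flux")


# ---------------------------------------------------------------------------
# bound assembly


def _clip(value: float) -> float:
    """Replace infinities by the solver-facing big-M bound."""
    if value == math.inf:
        return BIG_M
    if value == -math.inf:
        return -BIG_M
    return value


def effective_bounds(
    model: MetabolicModel, conditions: SimulationConditions
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-reaction (lower, upper) bounds after applying conditions."""
    rxn_ids = model.reaction_ids
    lb = np.array([_clip(model.reactions[r].lower_bound) for r in rxn_ids])
    ub = np.array([_clip(model.reactions[r].upper_bound) for r in rxn_ids])
    index = {r: i for i, r in enumerate(rxn_ids)}

    for rid, rate in conditions.fixed_uptakes.items():
        if rid not in index:
            raise ModelError(f"unknown exchange reaction {rid!r}")
        lb[index[rid]] = ub[index[rid]] = -rate
    for rid, rate in conditions.max_uptakes.items():
        if rid not in index:
            raise ModelError(f"unknown exchange reaction {rid!r}")
        lb[index[rid]] = -rate

    atpm = conditions.config.atp_maintenance
    if conditions.ngam > 0 or atpm in index and conditions.ngam == 0.0:
        if atpm not in index:
            raise ModelError(
                f"ATP maintenance reaction {atpm!r} not in model; needed to "
                "impose NGAM"
            )
        lb[index[atpm]] = ub[index[atpm]] = conditions.ngam

    if conditions.deleted_genes:
        unknown = conditions.deleted_genes - model.genes
        if unknown:
            raise ModelError(f"unknown gene ids: {sorted(unknown)}")
        for rid in rxn_ids:
            gpr = model.reactions[rid].gpr
            if gpr and not evaluate_gpr(gpr, conditions.deleted_genes):
                lb[index[rid]] = ub[index[rid]] = 0.0
    return lb, ub, rxn_ids


# ---------------------------------------------------------------------------
# LP solves

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    maximize: bool = True,
):
    """Thin HiGHS wrapper returning (status, objective, x)."""
    res = linprog(
        -c if maximize else c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return status, math.nan, None
    obj = -res.fun if maximize else res.fun
    return status, obj, res.x


def _minimize_total_flux(
    S: np.ndarray,
    obj_row: np.ndarray,
    obj_value: float,
    lb: np.ndarray,
    ub: np.ndarray,
) -> np.ndarray | None:
    """Stage 2: min sum |v_j| with the stage-1 objective pinned.

    Uses auxiliary t_j >= |v_j|; returns the flux part of the solution.
    """
    n = len(lb)
    # variables [v, t]
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    A_eq = np.vstack([A_eq, np.concatenate([obj_row, np.zeros(n)])])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [obj_value]])
    eye = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([eye, -eye]),   # v - t <= 0
            np.hstack([-eye, -eye]),  # -v - t <= 0
        ]
    )
    b_ub = np.zeros(2 * n)
    lb2 = np.concatenate([lb, np.zeros(n)])
    ub2 = np.concatenate([ub, np.full(n, BIG_M)])
    status, _, x = solve_lp(c, A_eq, b_eq, lb2, ub2, A_ub, b_ub, maximize=False)
    if status != "optimal" or x is None:
        return None
    return x[:n]


def maximize_objective(
    model: MetabolicModel,
    conditions: SimulationConditions | None = None,
    objective_id: str | None = None,
    parsimonious: bool = True,
) -> FluxSolution:
    """Maximize the objective flux (biomass by default) under conditions.

    Two-stage solve: the objective is maximized first, then (with the
    optimum pinned) the total absolute flux is minimized, which selects
    a unique, reproducible representative among alternate optima.
    """
    conditions = conditions or SimulationConditions()
    objective_id = objective_id or model.objective_id
    if objective_id not in model.reactions:
        raise ModelError(f"objective reaction {objective_id!r} not in model")

    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub, _ = effective_bounds(model, conditions)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = 1.0

    status, obj, x = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub)
    if status != "optimal":
        return FluxSolution(status, math.nan, {})
    if parsimonious:
        x2 = _minimize_total_flux(S, c, obj, lb, ub)
        if x2 is not None:
            x = x2
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, x)}
    return FluxSolution("optimal", float(obj), fluxes)


def simulate_deletion(
    model: MetabolicModel,
    genes: set[str],
    conditions: SimulationConditions | None = None,
) -> FluxSolution:
    """Knock out genes and re-maximize growth.

    Reactions whose GPR evaluates false with the genes removed get
    alpha = beta = 0; everything else proceeds as in
    :func:`maximize_objective`.
    """
    conditions = (conditions or SimulationConditions()).replace(
        deleted_genes=set(genes)
    )
    return maximize_objective(model, conditions)


# ---------------------------------------------------------------------------
# condition-specific derived quantities


def compute_po_ratio(
    solution: FluxSolution, config: ReactionConfig | None = None
) -> float:
    """Operational P/O ratio: 0.5 * v_ATP-synthase / v_cytochrome-oxidase.

    The oxidase is written per mol O2 (two O atoms), hence the factor
    0.5 converts ATP per oxidase turnover into ATP per O atom reduced.
    """
    config = config or ReactionConfig()
    if not solution.optimal:
        raise InfeasibleError("P/O ratio requires an optimal solution")
    try:
        v_atps = solution[config.atp_synthase]
        v_cyoo = solution[config.cytochrome_oxidase]
    except KeyError as exc:
        raise ModelError(f"reaction {exc} missing from solution") from exc
    if abs(v_cyoo) < 1e-12:
        raise ZeroDivisionError(
            "cytochrome c oxidase carries zero flux; P/O ratio undefined"
        )
    return 0.5 * v_atps / v_cyoo


def set_po_ratio(
    model: MetabolicModel,
    target: float,
    config: ReactionConfig | None = None,
) -> MetabolicModel:
    """Retune the oxidase proton stoichiometry to a target P/O ratio.

    The proton-motive coupling is adjusted by rescaling the number of
    protons translocated per oxidase turnover so that, when the proton
    cycle is the sole route from respiration to ATP synthesis,
    0.5 * v_ATPS / v_CYOO equals ``target``.  With ``n_h`` protons per
    synthase turnover and the oxidase written per mol O2, the required
    pumping stoichiometry is ``2 * n_h * target``.  Returns a modified
    copy; all other coefficients are untouched.
    """
    config = config or ReactionConfig()
    if target <= 0:
        raise ValueError("target P/O ratio must be > 0")
    out = model.copy()
    try:
        oxidase = out.reactions[config.cytochrome_oxidase]
        synthase = out.reactions[config.atp_synthase]
    except KeyError as exc:
        raise ModelError(f"reaction {exc} not in model") from exc
    if config.pumped_proton not in synthase.stoichiometry:
        raise ModelError(
            f"{config.atp_synthase} does not use pumped proton "
            f"{config.pumped_proton!r}"
        )
    n_h = abs(synthase.stoichiometry[config.pumped_proton])
    pumped = 2.0 * n_h * target
    if config.pumped_proton not in oxidase.stoichiometry:
        raise ModelError(
            f"{config.cytochrome_oxidase} does not translocate "
            f"{config.pumped_proton!r}"
        )
    oxidase.stoichiometry[config.pumped_proton] = pumped
    if config.matrix_proton in oxidase.stoichiometry:
        oxidase.stoichiometry[config.matrix_proton] = -pumped
    return out


def gaseous_exchange(
    solution: FluxSolution, config: ReactionConfig | None = None
) -> tuple[float, float]:
    """(CER, OUR): CO2 evolution and O2 uptake rates, mmol/gDCW-hr.

    Secretion is positive flux on an exchange, so CER is the CO2
    exchange flux directly and OUR is the negated O2 exchange flux.
    """
    config = config or ReactionConfig()
    try:
        cer = solution[config.co2_exchange]
        our = -solution[config.o2_exchange]
    except KeyError as exc:
        raise ModelError(f"exchange {exc} missing from solution") from exc
    return cer, our
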