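"""Carbon-source screening at carbon-normalized uptake.

Comparing growth across substrates of different size requires a common
carbon basis: each source is supplied at 1 C-mmol/gDCW-hr, i.e. the
molar uptake is 1/n_C mmol/gDCW-hr (0.167 for glucose, 0.333 for
glycerol, 1 for methanol).  For every source the screen closes all
other carbon exchanges, runs a two-stage FBA on minimal medium and
collects growth, gaseous exchange, respiratory quotient and ATP /
amino-acid flux-sums, plus reaction-by-source flux and
metabolite-by-source flux-sum matrices row-normalized to their maxima
(heat-map form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fba import (
    FluxSolution,
    ReactionConfig,
    SimulationConditions,
    gaseous_exchange,
    maximize_objective,
)
from .fluxsum import flux_sum_base, flux_sum_profile
from .maintenance import respiratory_quotient
from .model import MetabolicModel, ModelError

__all__ = [
    "CarbonSource",
    "ScreenReport",
    "c_normalized_uptake",
    "screen_carbon_sources",
    "carbon_exchanges",
]


@dataclass(frozen=True)
class CarbonSource:
    """A screenable substrate: exchange reaction and carbon count."""

    name: str
    exchange_id: str
    n_carbon: int

    def __post_init__(self) -> None:
        if self.n_carbon < 1:
            raise ValueError(f"{self.name}: n_carbon must be >= 1")


def c_normalized_uptake(source: CarbonSource, c_mmol_rate: float = 1.0) -> float:
    """Molar uptake (mmol/gDCW-hr) equivalent to a C-mmol supply rate."""
    if c_mmol_rate <= 0:
        raise ValueError("c_mmol_rate must be > 0")
    return c_mmol_rate / source.n_carbon


def carbon_exchanges(model: MetabolicModel) -> list[str]:
    """Exchange reactions whose metabolite contains carbon."""
    out = []
    for rxn in model.exchanges():
        met = model.metabolites[rxn.metabolite_ids[0]]
        if met.n_carbon:
            out.append(rxn.id)
    return out


@dataclass
class ScreenReport:
    """Outcome of a carbon-source screen.

    summary :
        One row per source: uptake, growth, CER, OUR, RQ, ATP flux-sum
        and solver status, ranked by growth yield (best first).
    flux_matrix / fluxsum_matrix :
        reactions x sources and metabolites x sources matrices;
        ``*_normalized`` variants divide each row by its maximum (rows
        of zeros stay zero).
    """

    summary: pd.DataFrame
    flux_matrix: pd.DataFrame
    fluxsum_matrix: pd.DataFrame
    solutions: dict[str, FluxSolution] = field(default_factory=dict)

    @property
    def flux_matrix_normalized(self) -> pd.DataFrame:
        return _row_normalize(self.flux_matrix)

    @property
    def fluxsum_matrix_normalized(self) -> pd.DataFrame:
        return _row_normalize(self.fluxsum_matrix)

    @property
    def ranking(self) -> list[str]:
        return list(self.summary.index)


def _row_normalize(df: pd.DataFrame) -> pd.DataFrame:
    peak = df.abs().max(axis=1)
    out = df.abs().div(peak.where(peak > 0, 1.0), axis=0)
    return out


def screen_carbon_sources(
    model: MetabolicModel,
    sources: Sequence[CarbonSource],
    conditions: SimulationConditions | None = None,
    c_mmol_rate: float = 1.0,
    amino_acid_bases: Iterable[str] = ("ala",),
    matrix_reactions: Iterable[str] | None = None,
    matrix_metabolite_bases: Iterable[str] | None = None,
) -> ScreenReport:
    """Screen each source at ``c_mmol_rate`` C-mmol/gDCW-hr.

    All carbon-containing exchanges except the screened source are
    closed for uptake (secretion stays open); non-carbon minimal-medium
    exchanges keep their defaults.  An infeasible source is recorded
    with zero growth and a status flag rather than raising.

    ``amino_acid_bases`` names the compartment-aggregated amino-acid
    pools whose flux-sums are tabulated (the bundled toy network only
    synthesizes alanine; pass the 20 proteinogenic base ids for a full
    reconstruction).
    """
    if not sources:
        raise ModelError("no carbon sources given")
    conditions = conditions or SimulationConditions()
    config: ReactionConfig = conditions.config
    c_exchanges = set(carbon_exchanges(model))

    rows = []
    solutions: dict[str, FluxSolution] = {}
    for src in sources:
        if src.exchange_id not in model.reactions:
            raise ModelError(f"{src.name}: exchange {src.exchange_id} missing")
        uptake = c_normalized_uptake(src, c_mmol_rate)
        # close competing carbon uptakes (lower bound 0) but leave
        # secretion open; the screened source is pinned at its uptake
        closed = {
            rid: 0.0
            for rid in c_exchanges
            if rid not in (src.exchange_id, config.co2_exchange)
        }
        closed.update(conditions.max_uptakes)
        fixed = dict(conditions.fixed_uptakes)
        fixed[src.exchange_id] = uptake
        cond = conditions.replace(fixed_uptakes=fixed, max_uptakes=closed)
        sol = maximize_objective(model, cond)
        row = {
            "source": src.name,
            "uptake": uptake,
            "status": sol.status,
            "growth": sol.objective_value if sol.optimal else 0.0,
        }
        if sol.optimal:
            cer, our = gaseous_exchange(sol, config)
            row["CER"] = cer
            row["OUR"] = our
            row["RQ"] = (
                respiratory_quotient(cer, our) if our > 1e-9 else float("nan")
            )
            row["atp_fluxsum"] = flux_sum_base(model, sol, "atp")
            for aa in amino_acid_bases:
                row[f"fluxsum_{aa}"] = flux_sum_base(model, sol, aa)
            solutions[src.name] = sol
        else:
            row.update({"CER": 0.0, "OUR": 0.0, "RQ": float("nan"),
                        "atp_fluxsum": 0.0})
            for aa in amino_acid_bases:
                row[f"fluxsum_{aa}"] = 0.0
        rows.append(row)

    summary = (
        pd.DataFrame(rows)
        .set_index("source")
        .sort_values("growth", ascending=False)
    )

    rxn_rows = list(matrix_reactions or model.reaction_ids)
    flux_matrix = pd.DataFrame(
        {
            name: [sol.fluxes.get(r, 0.0) for r in rxn_rows]
            for name, sol in solutions.items()
        },
        index=rxn_rows,
    )
    met_rows = list(
        matrix_metabolite_bases
        or sorted({m.base_id for m in model.metabolites.values()})
    )
    if solutions:
        profile = flux_sum_profile(
            model,
            solutions,
            met_rows,
            aggregate=True,
        )
        fluxsum_matrix = profile.to_frame()
    else:
        fluxsum_matrix = pd.DataFrame(index=met_rows)
    return ScreenReport(
        summary=summary,
        flux_matrix=flux_matrix,
        fluxsum_matrix=fluxsum_matrix,
        solutions=solutions,
    )
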