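"""Metabolite turnover rates via the flux-sum statistic.

At steady state the total production rate of a metabolite equals its
total consumption rate, so half the sum of |S_ij v_j| over every
reaction j touching metabolite i measures its turnover:

    Phi_i = 1/2 * sum_j |S_ij * v_j|

Flux-sums are reported per compartmentalized species (atp[c] and
atp[m] separately); an aggregate per base id is also provided, computed
from net base-stoichiometries so that inter-compartment transport does
not double-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .fba import FluxSolution, InfeasibleError
from .model import MetabolicModel, ModelError

__all__ = [
    "FluxSumProfile",
    "flux_sum",
    "flux_sum_base",
    "flux_sum_profile",
]


@dataclass
class FluxSumProfile:
    """Flux-sums for a metabolite set, optionally across conditions.

    ``values`` maps metabolite id -> {condition -> Phi_i}; ``normalized``
    holds each entry divided by that metabolite's maximum over the
    conditions (0 when the whole row is zero), so every non-zero row
    contains at least one 1.
    """

    values: dict[str, dict[str, float]]
    normalized: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self, normalized: bool = False):
        import pandas as pd

        data = self.normalized if normalized else self.values
        return pd.DataFrame(data).T


def flux_sum(
    model: MetabolicModel, solution: FluxSolution, metabolite_id: str
) -> float:
    """Turnover rate Phi_i = 1/2 sum_j |S_ij v_j| of one metabolite."""
    if not solution.optimal:
        raise InfeasibleError("flux-sum requires an optimal solution")
    if metabolite_id not in model.metabolites:
        raise ModelError(f"unknown metabolite {metabolite_id!r}")
    total = 0.0
    for rxn in model.reactions.values():
        coef = rxn.stoichiometry.get(metabolite_id)
        if coef is not None:
            total += abs(coef * solution.fluxes.get(rxn.id, 0.0))
    return 0.5 * total


def flux_sum_base(
    model: MetabolicModel, solution: FluxSolution, base_id: str
) -> float:
    """Aggregate flux-sum of a base id summed over compartments.

    Uses the net base-stoichiometry of each reaction, so a pure
    transport step (e.g. pyr[c] -> pyr[m]) contributes nothing and the
    pools are not double-counted.
    """
    if not solution.optimal:
        raise InfeasibleError("flux-sum requires an optimal solution")
    instances = [
        m.id for m in model.metabolites.values() if m.base_id == base_id
    ]
    if not instances:
        raise ModelError(f"no metabolite with base id {base_id!r}")
    total = 0.0
    for rxn in model.reactions.values():
        net = sum(rxn.stoichiometry.get(mid, 0.0) for mid in instances)
        if net:
            total += abs(net * solution.fluxes.get(rxn.id, 0.0))
    return 0.5 * total


def flux_sum_profile(
    model: MetabolicModel,
    solutions: FluxSolution | Mapping[str, FluxSolution],
    metabolite_ids: Iterable[str],
    aggregate: bool = False,
) -> FluxSumProfile:
    """Flux-sums of a metabolite set under one or several conditions.

    Parameters
    ----------
    solutions :
        Either a single :class:`FluxSolution` or a mapping
        condition-name -> solution (a heat-map column per condition).
    metabolite_ids :
        Species ids, or base ids when ``aggregate`` is true.
    aggregate :
        Sum each metabolite over compartments (see
        :func:`flux_sum_base`).

    Normalization divides each metabolite's value by its maximum over
    the conditions; a metabolite at zero everywhere normalizes to 0.
    """
    mets = list(metabolite_ids)
    if not mets:
        raise ModelError("empty metabolite set")
    if isinstance(solutions, FluxSolution):
        solutions = {"condition": solutions}

    fn = flux_sum_base if aggregate else flux_sum
    values: dict[str, dict[str, float]] = {
        met: {cond: fn(model, sol, met) for cond, sol in solutions.items()}
        for met in mets
    }
    normalized: dict[str, dict[str, float]] = {}
    for met, row in values.items():
        peak = max(row.values())
        normalized[met] = {
            cond: (val / peak if peak > 0 else 0.0)
            for cond, val in row.items()
        }
    return FluxSumProfile(values=values, normalized=normalized)
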