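"""Condition-specific parameter estimation from chemostat data.

In a chemostat at steady state the specific growth rate equals the
dilution rate D, and the linear maintenance model of substrate use is

    q_s = D / Y_max + m_s

so an ordinary least-squares line of substrate uptake q_s on D yields
the maximal biomass yield Y_max (inverse slope) and the maintenance
substrate flux m_s (intercept at D = 0).  The non-growth-associated ATP
maintenance (NGAM) is m_s converted to ATP through the model itself:
Y_ATP, the maximal ATP-maintenance flux per unit substrate at zero
growth, is computed by LP and NGAM = m_s * Y_ATP.  Both the raw m_s and
the converted NGAM are reported, since the conversion route is a
modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fba import (
    SimulationConditions,
    effective_bounds,
    solve_lp,
)
from .model import MetabolicModel, ModelError

__all__ = [
    "ChemostatPoint",
    "ChemostatSeries",
    "MaintenanceEstimate",
    "estimate_ngam",
    "atp_yield_per_substrate",
    "respiratory_quotient",
]


@dataclass(frozen=True)
class ChemostatPoint:
    """One steady state: dilution rate and measured specific rates."""

    dilution_rate: float  # 1/hr
    substrate_uptake: float  # mmol/gDCW-hr
    cer: float = float("nan")  # CO2 evolution, mmol/gDCW-hr
    our: float = float("nan")  # O2 uptake, mmol/gDCW-hr

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be > 0")
        if self.substrate_uptake < 0:
            raise ValueError("substrate uptake must be >= 0")


@dataclass
class ChemostatSeries:
    """Steady-state observations over several dilution rates."""

    points: Sequence[ChemostatPoint]
    substrate_id: str  # exchange reaction id of the carbon source

    @classmethod
    def from_csv(cls, path, substrate_id: str) -> "ChemostatSeries":
        import pandas as pd

        df = pd.read_csv(path)
        pts = [
            ChemostatPoint(
                row["D"],
                row["q_s"],
                row.get("CER", float("nan")),
                row.get("OUR", float("nan")),
            )
            for _, row in df.iterrows()
        ]
        return cls(pts, substrate_id)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "D": [p.dilution_rate for p in self.points],
                "q_s": [p.substrate_uptake for p in self.points],
                "CER": [p.cer for p in self.points],
                "OUR": [p.our for p in self.points],
            }
        )


@dataclass
class MaintenanceEstimate:
    """Maintenance parameters from the q_s-vs-D regression."""

    m_s: float  # substrate maintenance flux at D=0, mmol/gDCW-hr
    slope: float  # 1/Y_max, mmol substrate per gDCW
    r_squared: float
    y_atp: float  # max ATP per unit substrate at zero growth (model LP)
    ngam_atp: float  # m_s * y_atp, mmol ATP/gDCW-hr

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def atp_yield_per_substrate(
    model: MetabolicModel,
    substrate_id: str,
    conditions: SimulationConditions | None = None,
) -> float:
    """Maximal ATP-maintenance flux per unit substrate at zero growth.

    Solves the model LP with the substrate uptake fixed to 1, growth
    fixed to 0 and the ATP-maintenance flux freed and maximized.
    """
    conditions = conditions or SimulationConditions()
    conditions = conditions.replace(
        fixed_uptakes={**conditions.fixed_uptakes, substrate_id: 1.0},
        ngam=0.0,
    )
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub, _ = effective_bounds(model, conditions)
    index = {r: i for i, r in enumerate(rxn_ids)}
    atpm = conditions.config.atp_maintenance
    if atpm not in index:
        raise ModelError(f"ATP maintenance reaction {atpm!r} not in model")
    # free the maintenance flux (effective_bounds pinned it to NGAM=0)
    lb[index[atpm]], ub[index[atpm]] = 0.0, 1000.0
    # pin growth to zero
    j_growth = index[model.objective_id]
    lb[j_growth] = ub[j_growth] = 0.0
    c = np.zeros(len(rxn_ids))
    c[index[atpm]] = 1.0
    status, obj, _ = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub)
    if status != "optimal":
        raise ModelError(
            f"zero-growth LP for Y_ATP is {status}; check medium/conditions"
        )
    return float(obj)


def estimate_ngam(
    series: ChemostatSeries,
    model: MetabolicModel,
    conditions: SimulationConditions | None = None,
) -> MaintenanceEstimate:
    """Estimate maintenance energy from a chemostat uptake-vs-D series.

    OLS of q_s on D gives the intercept m_s (substrate maintenance) and
    slope 1/Y_max; m_s is converted to ATP with the model-derived yield
    Y_ATP (see :func:`atp_yield_per_substrate`).

    Raises when fewer than two distinct dilution rates are present
    (the line is not identifiable).
    """
    d = np.array([p.dilution_rate for p in series.points], dtype=float)
    q = np.array([p.substrate_uptake for p in series.points], dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError(
            "need >= 2 distinct dilution rates to fit the maintenance line"
        )
    fit = stats.linregress(d, q)
    y_atp = atp_yield_per_substrate(model, series.substrate_id, conditions)
    m_s = float(fit.intercept)
    return MaintenanceEstimate(
        m_s=m_s,
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        y_atp=y_atp,
        # a noisy series can put the intercept marginally below zero;
        # maintenance is physically non-negative
        ngam_atp=max(0.0, m_s * y_atp),
    )


def respiratory_quotient(cer: float, our: float) -> float:
    """RQ = CER / OUR (mol CO2 evolved per mol O2 consumed)."""
    if our <= 0:
        raise ZeroDivisionError("OUR must be > 0 for a defined RQ")
    return cer / our
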