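"""Overexpression-target identification via MIP flux-activity scans.

The *flux activity* of reaction j is a_j = |v_j|.  Its range under a
growth requirement (growth >= fraction * mu_max) is found by a mixed
integer program that linearizes the absolute value with a direction
binary y_j and a big-M bound:

    v_j = p_j - n_j,   p_j <= M y_j,   n_j <= M (1 - y_j),
    a_j = p_j + n_j,   M = 1000 mmol/gDCW-hr.

Clamping a_j at a fraction k of its maximum (k in {0, 0.25, 0.5, 0.75,
1}) and re-maximizing a target flux reveals which reactions cap the
target: a reaction is *directionally coupled* to the target when
attenuating its activity proportionally lowers the maximum achievable
target flux, down to zero at k = 0.  Such reactions are bottleneck /
overexpression candidates for the biotransformation of interest (here
modelled after acetoin -> 2,3-butanediol on methanol).

Two clamp modes exist: ``equality`` (a_j = k a_max, the level actually
shown on a k-scan axis) and ``inequality`` (a_j <= k a_max, which is
always feasible for k a_max >= a_min-free problems and makes the scan
monotone in k).  A clamp below the minimum feasible activity is an
empty constraint set; the achievable target flux is then reported as 0
with an ``infeasible`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from .fba import (
    FEASIBILITY_TOL,
    SimulationConditions,
    effective_bounds,
    maximize_objective,
)
from .model import BIG_M, MetabolicModel, ModelError

__all__ = [
    "DEFAULT_K_LEVELS",
    "ActivityBounds",
    "ActivityScanResult",
    "activity_bounds",
    "clamp_and_maximize",
    "scan_targets",
]

DEFAULT_K_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)
_COUPLING_TOL = 1e-6


@dataclass
class ActivityBounds:
    """Feasible activity range of one reaction under a growth floor."""

    reaction_id: str
    a_max: float
    a_min: float
    growth_floor: float

    def __post_init__(self) -> None:
        # clean up solver noise; activities are non-negative by definition
        self.a_min = max(0.0, self.a_min)
        self.a_max = max(self.a_min, self.a_max)


@dataclass
class ActivityScanResult:
    """Per-reaction outcome of the k-scan against one target flux."""

    reaction_id: str
    k_levels: list[float]
    target_max: list[float]  # max target flux at each k (0 if infeasible)
    feasible: list[bool]
    a_max: float
    coupled: bool = False
    slope: float = float("nan")  # d(target_max)/d(activity), per-unit-a
    r_squared: float = float("nan")


class _MilpProblem:
    """Shared scaffolding for the activity MIP.

    Variables are [v (n reactions), p, n, y] with p, n, y attached to a
    single scanned reaction.  Constraints: S v = 0, v_j - p + n = 0,
    p <= M y, n <= M (1 - y), growth >= floor, plus whatever clamp the
    caller adds on a = p + n.
    """

    def __init__(
        self,
        model: MetabolicModel,
        reaction_id: str,
        conditions: SimulationConditions,
        growth_floor: float,
    ) -> None:
        if reaction_id not in model.reactions:
            raise ModelError(f"unknown reaction {reaction_id!r}")
        S, _, rxn_ids = model.stoichiometric_matrix()
        lb, ub, _ = effective_bounds(model, conditions)
        self.rxn_ids = rxn_ids
        self.n = len(rxn_ids)
        self.j = rxn_ids.index(reaction_id)
        nv = self.n + 3  # v..., p, n, y

        rows = []
        # S v = 0
        A = np.zeros((S.shape[0], nv))
        A[:, : self.n] = S
        rows.append(LinearConstraint(A, 0.0, 0.0))
        # v_j - p + n = 0
        r = np.zeros(nv)
        r[self.j], r[self.n], r[self.n + 1] = 1.0, -1.0, 1.0
        rows.append(LinearConstraint(r, 0.0, 0.0))
        # p - M y <= 0
        r = np.zeros(nv)
        r[self.n], r[self.n + 2] = 1.0, -BIG_M
        rows.append(LinearConstraint(r, -np.inf, 0.0))
        # n + M y <= M
        r = np.zeros(nv)
        r[self.n + 1], r[self.n + 2] = 1.0, BIG_M
        rows.append(LinearConstraint(r, -np.inf, BIG_M))
        # growth floor
        r = np.zeros(nv)
        r[rxn_ids.index(model.objective_id)] = 1.0
        rows.append(LinearConstraint(r, growth_floor, np.inf))
        self.base_constraints = rows

        self.lb = np.concatenate([lb, [0.0, 0.0, 0.0]])
        self.ub = np.concatenate([ub, [BIG_M, BIG_M, 1.0]])
        self.integrality = np.zeros(nv)
        self.integrality[self.n + 2] = 1  # y binary
        self.nv = nv

    def activity_row(self) -> np.ndarray:
        r = np.zeros(self.nv)
        r[self.n], r[self.n + 1] = 1.0, 1.0
        return r

    def solve(
        self,
        c: np.ndarray,
        extra: Sequence[LinearConstraint] = (),
        maximize: bool = True,
    ) -> tuple[str, float, np.ndarray | None]:
        res = milp(
            -c if maximize else c,
            constraints=[*self.base_constraints, *extra],
            bounds=OptBounds(self.lb, self.ub),
            integrality=self.integrality,
            options={"mip_rel_gap": 0.0},
        )
        if res.status != 0 or res.x is None:
            return "infeasible", float("nan"), None
        obj = -res.fun if maximize else res.fun
        return "optimal", float(obj), res.x


def _max_growth(
    model: MetabolicModel, conditions: SimulationConditions
) -> float:
    sol = maximize_objective(model, conditions, parsimonious=False)
    if not sol.optimal:
        raise ModelError(f"growth LP under scan conditions is {sol.status}")
    return sol.objective_value


def activity_bounds(
    model: MetabolicModel,
    reaction_id: str,
    conditions: SimulationConditions | None = None,
    growth_fraction: float = 0.5,
    mu_max: float | None = None,
) -> ActivityBounds:
    """Maximum and minimum |v_j| subject to growth >= fraction * mu_max.

    ``mu_max`` is the unconstrained growth optimum under the same
    conditions; it is computed on the fly when not supplied.
    """
    if not 0 < growth_fraction <= 1:
        raise ValueError("growth_fraction must be in (0, 1]")
    conditions = conditions or SimulationConditions()
    if mu_max is None:
        mu_max = _max_growth(model, conditions)
    floor = growth_fraction * mu_max
    prob = _MilpProblem(model, reaction_id, conditions, floor)
    c = prob.activity_row()
    status_hi, a_max, _ = prob.solve(c, maximize=True)
    status_lo, a_min, _ = prob.solve(c, maximize=False)
    if status_hi != "optimal" or status_lo != "optimal":
        raise ModelError(
            f"activity MIP infeasible for {reaction_id} at growth floor "
            f"{floor:g}"
        )
    return ActivityBounds(reaction_id, a_max, a_min, floor)


def clamp_and_maximize(
    model: MetabolicModel,
    reaction_id: str,
    k: float,
    target_id: str,
    conditions: SimulationConditions | None = None,
    growth_fraction: float = 0.5,
    bounds: ActivityBounds | None = None,
    mode: str = "equality",
    mu_max: float | None = None,
) -> tuple[float, bool]:
    """Clamp a_j at k * a_max and maximize the target flux.

    Returns ``(target_max, feasible)``; an infeasible clamp (possible in
    equality mode when k * a_max < a_min) yields ``(0.0, False)``.
    """
    if not 0 <= k <= 1:
        raise ValueError("k must be in [0, 1]")
    if mode not in ("equality", "inequality"):
        raise ValueError("mode must be 'equality' or 'inequality'")
    conditions = conditions or SimulationConditions()
    if target_id not in model.reactions:
        raise ModelError(f"unknown target reaction {target_id!r}")
    if mu_max is None:
        mu_max = _max_growth(model, conditions)
    if bounds is None:
        bounds = activity_bounds(
            model, reaction_id, conditions, growth_fraction, mu_max
        )
    floor = growth_fraction * mu_max
    prob = _MilpProblem(model, reaction_id, conditions, floor)
    level = k * bounds.a_max
    row = prob.activity_row()
    if mode == "equality":
        clamp = LinearConstraint(row, level, level)
    else:
        clamp = LinearConstraint(row, -np.inf, level)
    c = np.zeros(prob.nv)
    c[prob.rxn_ids.index(target_id)] = 1.0
    status, obj, _ = prob.solve(c, extra=[clamp], maximize=True)
    if status != "optimal":
        return 0.0, False
    return obj, True


def scan_targets(
    model: MetabolicModel,
    target_id: str,
    conditions: SimulationConditions | None = None,
    k_levels: Sequence[float] = DEFAULT_K_LEVELS,
    growth_fraction: float = 0.5,
    reaction_ids: Iterable[str] | None = None,
    mode: str = "equality",
) -> list[ActivityScanResult]:
    """Run the k-scan for every reaction and classify directional coupling.

    A reaction is flagged ``coupled`` when the maximum target flux
    (i) vanishes at k = 0 (an infeasible k = 0 clamp counts as 0: no
    target flux is achievable there), (ii) rises by more than the
    tolerance from k = 0 to k = 1, (iii) is non-decreasing in k, and
    (iv) is proportional to the clamp level (least-squares R^2 >= 0.99
    over the feasible points).  Results are sorted by decreasing slope
    (target gained per unit activity).
    """
    conditions = conditions or SimulationConditions()
    ks = sorted(k_levels)
    if not ks or ks[0] < 0 or ks[-1] > 1:
        raise ValueError("k levels must lie in [0, 1]")
    mu_max = _max_growth(model, conditions)
    if reaction_ids is None:
        reaction_ids = [r for r in model.reaction_ids if r != target_id]

    results: list[ActivityScanResult] = []
    for rid in reaction_ids:
        ab = activity_bounds(model, rid, conditions, growth_fraction, mu_max)
        tmax: list[float] = []
        feas: list[bool] = []
        for k in ks:
            val, ok = clamp_and_maximize(
                model,
                rid,
                k,
                target_id,
                conditions,
                growth_fraction,
                bounds=ab,
                mode=mode,
                mu_max=mu_max,
            )
            tmax.append(val)
            feas.append(ok)
        res = ActivityScanResult(
            reaction_id=rid,
            k_levels=list(ks),
            target_max=tmax,
            feasible=feas,
            a_max=ab.a_max,
        )
        _classify(res)
        results.append(res)
    results.sort(key=lambda r: (-(r.slope if np.isfinite(r.slope) else -np.inf)))
    return results


def _classify(res: ActivityScanResult) -> None:
    """Fill coupled/slope/r_squared on a scan result in place."""
    ks = np.array(res.k_levels)
    tm = np.array(res.target_max)
    feas = np.array(res.feasible)
    # infeasible clamps achieve nothing; keep them as 0 for the k=0 test
    # but exclude them from the proportionality fit
    t0 = tm[ks == 0.0][0] if np.any(ks == 0.0) else np.nan
    activities = ks * res.a_max

    # the clamp stops binding once some other resource (e.g. the ketone
    # supply) caps the target; proportionality is judged on the region
    # where the clamp binds: the rising limb plus the first plateau point
    fit_mask = feas.copy()
    if feas.any():
        plateau = tm[feas].max()
        on_plateau = feas & (tm >= plateau - _COUPLING_TOL)
        fit_mask = feas & ~on_plateau
        if on_plateau.any():
            fit_mask[np.argmax(on_plateau)] = True
    if fit_mask.sum() >= 2 and np.ptp(activities[fit_mask]) > 0:
        x, y = activities[fit_mask], tm[fit_mask]
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        pred = A @ coef
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        res.slope = float(coef[0])
        res.r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rises = (
        np.isfinite(t0)
        and tm[-1] - t0 > _COUPLING_TOL
        and np.all(np.diff(tm) >= -_COUPLING_TOL)
    )
    res.coupled = bool(
        rises
        and np.isfinite(t0)
        and t0 <= _COUPLING_TOL
        and np.isfinite(res.r_squared)
        and res.r_squared >= 0.99
        and res.slope > 0
    )
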