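"""Exact fuel-break selection as a mixed integer program.

Decision variables: binary ``x_i`` (treat break *i*) and binary ``y_j``
(fire *j* is contained within its ignition polygon).  The model

    maximize    sum_j V_j y_j
    subject to  sum_i C_i x_i <= B          (one budget row)
                y_j <= (1/M_j) sum_{i in S_j} x_i   for every fire with S_j != empty

selects the subset of breaks that maximizes the total protected value under
the budget.  Containment is all-or-nothing: ``y_j`` can only be 1 when every
break bounding fire *j*'s ignition polygon is treated, so ``y_j`` stays
binary (an LP relaxation would earn fractional credit for partially treated
polygons, which contradicts the containment model).

Fires with ``S_j = empty`` (never containable) are fixed ``y_j = 0`` and
carried for reporting only.  The solver back end is HiGHS via
:func:`scipy.optimize.milp`, run to a 0% relative gap by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import lil_matrix

from .geometry import BreakSegment
from .valuation import ContainmentRecord

__all__ = [
    "ProblemInstance",
    "Solution",
    "MipModel",
    "build_mip",
    "solve",
    "brute_force",
    "evaluate_selection",
]

BRUTE_FORCE_MAX_BREAKS = 20


@dataclass
class ProblemInstance:
    """Everything the optimization needs: breaks, per-fire records, budget.

    ``objective`` picks which per-fire value stands in for ``V_j`` ('afb' or
    'awb').  ``budget_mode`` selects the budget row: 'cost' charges each
    break its cost ``C_i`` (which defaults to its length), 'length' charges
    its geometric length ``L_i``.
    """

    breaks: list[BreakSegment]
    records: list[ContainmentRecord]
    budget: float
    objective: str = "afb"
    budget_mode: str = "cost"

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be nonnegative")
        if self.objective not in ("afb", "awb"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.budget_mode not in ("cost", "length"):
            raise ValueError(f"unknown budget_mode {self.budget_mode!r}")
        ids = [b.id for b in self.breaks]
        if len(set(ids)) != len(ids):
            raise ValueError("break ids must be unique")
        known = set(ids)
        for rec in self.records:
            missing = rec.s.break_ids - known
            if missing:
                raise ValueError(
                    f"fire {rec.fire_id!r} references unknown break ids {sorted(missing)}"
                )

    def unit_cost(self, seg: BreakSegment) -> float:
        return seg.length_m if self.budget_mode == "length" else seg.effective_cost

    def spend(self, selected: set[str]) -> float:
        return float(sum(self.unit_cost(b) for b in self.breaks if b.id in selected))

    @property
    def total_cost(self) -> float:
        return float(sum(self.unit_cost(b) for b in self.breaks))

    def containable_records(self) -> list[ContainmentRecord]:
        return [r for r in self.records if r.containable]

    def value(self, rec: ContainmentRecord) -> float:
        return rec.value(self.objective)


@dataclass
class Solution:
    """Outcome of a solve or evaluation.

    ``contained`` is always recomputed from ``selected`` via set inclusion
    (``S_j`` a subset of the selection), never trusted from solver
    variables.
    """

    selected: set[str]
    contained: set[str]
    objective_value: float
    status: str
    gap: float = 0.0
    spend: float = 0.0
    budget_feasible: bool = True


@dataclass
class MipModel:
    """Matrix form of the selection MIP, solver-agnostic."""

    instance: ProblemInstance
    c: np.ndarray                    # minimization coefficients (negated values)
    constraints: list[LinearConstraint]
    integrality: np.ndarray
    break_ids: list[str] = field(default_factory=list)
    fire_ids: list[str] = field(default_factory=list)  # containable fires only
    obj_scale: float = 1.0           # c is value * obj_scale (see build_mip)

    @property
    def n_vars(self) -> int:
        return len(self.break_ids) + len(self.fire_ids)


def build_mip(instance: ProblemInstance) -> MipModel:
    """Assemble the MIP: one budget row plus one linking row per containable fire."""
    breaks = instance.breaks
    cont = instance.containable_records()
    nb, nf = len(breaks), len(cont)
    n = nb + nf
    bid_index = {b.id: k for k, b in enumerate(breaks)}

    # The HiGHS back end stops at a fixed *absolute* MIP gap (1e-6).  Scaling
    # the objective to magnitude ~1e6 turns that into ~1e-12 relative, so the
    # returned solution is the true optimum for any practically distinguishable
    # instance.
    vmax = max((instance.value(r) for r in cont), default=0.0)
    obj_scale = 1e6 / vmax if vmax > 0 else 1.0
    c = np.zeros(n)
    for j, rec in enumerate(cont):
        c[nb + j] = -instance.value(rec) * obj_scale

    constraints: list[LinearConstraint] = []
    budget_row = np.zeros((1, n))
    for k, b in enumerate(breaks):
        budget_row[0, k] = instance.unit_cost(b)
    constraints.append(LinearConstraint(budget_row, -np.inf, instance.budget))

    if nf:
        link = lil_matrix((nf, n))
        for j, rec in enumerate(cont):
            m = rec.s.m
            for bid in rec.s.break_ids:
                link[j, bid_index[bid]] = -1.0 / m
            link[j, nb + j] = 1.0
        constraints.append(LinearConstraint(link.tocsr(), -np.inf, np.zeros(nf)))

    return MipModel(
        instance=instance,
        c=c,
        constraints=constraints,
        integrality=np.ones(n),
        break_ids=[b.id for b in breaks],
        fire_ids=[r.fire_id for r in cont],
        obj_scale=obj_scale,
    )


def solve(model: MipModel, rel_gap: float = 0.0) -> Solution:
    """Solve the MIP with HiGHS to the requested relative gap (default 0%).

    The contained-fire set and objective are recomputed from the selected
    breaks and cross-checked against the solver objective.
    """
    instance = model.instance
    if model.n_vars == 0 or not model.fire_ids:
        return evaluate_selection(instance, set(), status="optimal")

    res = milp(
        c=model.c,
        constraints=model.constraints,
        integrality=model.integrality,
        bounds=(0, 1),
        options={"mip_rel_gap": rel_gap, "presolve": True},
    )
    if res.status != 0 or res.x is None:
        status = "infeasible" if res.status == 2 else "error"
        return Solution(set(), set(), 0.0, status=status, gap=float("nan"))

    nb = len(model.break_ids)
    selected = {bid for bid, v in zip(model.break_ids, res.x[:nb]) if v > 0.5}
    sol = evaluate_selection(instance, selected, status="optimal")
    solver_obj = -float(res.fun) / model.obj_scale
    scale = max(1.0, abs(solver_obj))
    if abs(sol.objective_value - solver_obj) > 1e-6 * scale:
        raise RuntimeError(
            f"solver objective {solver_obj} disagrees with recomputed "
            f"objective {sol.objective_value}"
        )
    sol.gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    return sol


def brute_force(instance: ProblemInstance) -> Solution:
    """Exact optimum by enumerating every subset of breaks.

    Independent oracle for :func:`solve`; guarded to at most
    ``BRUTE_FORCE_MAX_BREAKS`` breaks.  Ties in objective are broken toward
    the lexicographically smallest sorted id tuple, so the result is fully
    deterministic.
    """
    nb = len(instance.breaks)
    if nb > BRUTE_FORCE_MAX_BREAKS:
        raise ValueError(
            f"brute_force is limited to {BRUTE_FORCE_MAX_BREAKS} breaks (got {nb})"
        )
    ids = sorted(b.id for b in instance.breaks)
    best: Solution | None = None
    best_key: tuple | None = None
    for r in range(nb + 1):
        for combo in itertools.combinations(ids, r):
            sel = set(combo)
            if instance.spend(sel) > instance.budget * (1 + 1e-12):
                continue
            sol = evaluate_selection(instance, sel, status="optimal")
            key = (-sol.objective_value, tuple(sorted(sel)))
            if best_key is None or key < best_key:
                best, best_key = sol, key
    assert best is not None  # empty set is always feasible (budget >= 0)
    return best


def evaluate_selection(
    instance: ProblemInstance, selected: set[str], status: str = "evaluated"
) -> Solution:
    """Score a fixed selection: ``y_j = 1`` iff ``S_j`` is non-empty and fully treated.

    Budget feasibility is reported, not enforced — this is how rule-based
    (pre-determined) selections are evaluated under the same objective.
    """
    known = {b.id for b in instance.breaks}
    unknown = set(selected) - known
    if unknown:
        raise ValueError(f"selection references unknown break ids {sorted(unknown)}")
    contained = {
        rec.fire_id
        for rec in instance.records
        if rec.containable and rec.s.break_ids <= selected
    }
    objective = float(
        sum(
            instance.value(rec)
            for rec in instance.records
            if rec.fire_id in contained
        )
    )
    spend = instance.spend(set(selected))
    return Solution(
        selected=set(selected),
        contained=contained,
        objective_value=objective,
        status=status,
        gap=0.0,
        spend=spend,
        budget_feasible=spend <= instance.budget * (1 + 1e-12),
    )
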