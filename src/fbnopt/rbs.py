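"""Rule-based selection (RBS) baseline.

The heuristic the exact model is benchmarked against: assume the *entire*
network is treated, score each break by its cost effectiveness

    E_i = (sum of V_j over fires contained with break i's participation) / C_i,

then walk the ranking from the highest score down, selecting breaks until
the budget is exhausted.  The resulting fixed selection is evaluated under
the same objective as the exact model, which makes the comparison a provable
dominance: the optimizer can never do worse.

The greedy walk is first-fit by default (a break that does not fit is
skipped and the walk continues down the ranking, landing "close to but not
exceeding" the budget); ``rule='stop'`` halts at the first break that does
not fit, for sensitivity checks.
"""

from __future__ import annotations

import pandas as pd

from .optimize import ProblemInstance, Solution, evaluate_selection

__all__ = ["effectiveness_scores", "greedy_select", "rbs_solve"]


def effectiveness_scores(instance: ProblemInstance) -> pd.DataFrame:
    """Cost-effectiveness table, one row per break.

    Returns a DataFrame indexed by break id with columns ``score`` (E_i),
    ``cost`` and ``rank`` (1 = best; ties ranked by ascending id).  Fires
    with an empty constituent set contribute to no break.
    """
    costs = {b.id: instance.unit_cost(b) for b in instance.breaks}
    zero = [bid for bid, c in costs.items() if c <= 0]
    if zero:
        raise ValueError(f"effectiveness score undefined for zero-cost breaks {sorted(zero)}")

    totals = dict.fromkeys(costs, 0.0)
    for rec in instance.records:
        if not rec.containable:
            continue
        v = instance.value(rec)
        for bid in rec.s.break_ids:
            totals[bid] += v

    table = pd.DataFrame(
        {
            "score": [totals[bid] / costs[bid] for bid in costs],
            "cost": [costs[bid] for bid in costs],
        },
        index=pd.Index(list(costs), name="break_id"),
    )
    order = table.sort_values(
        ["score", "break_id"], ascending=[False, True], kind="mergesort"
    ).index
    table["rank"] = pd.Series(range(1, len(order) + 1), index=order)
    return table


def greedy_select(table: pd.DataFrame, budget: float, rule: str = "first_fit") -> set[str]:
    """Select breaks by descending effectiveness within the budget."""
    if budget < 0:
        raise ValueError("budget must be nonnegative")
    if rule not in ("first_fit", "stop"):
        raise ValueError(f"unknown greedy rule {rule!r}")
    remaining = budget
    chosen: set[str] = set()
    for bid in table.sort_values("rank").index:
        cost = float(table.at[bid, "cost"])
        if cost <= remaining * (1 + 1e-12):
            chosen.add(bid)
            remaining -= cost
        elif rule == "stop":
            break
    return chosen


def rbs_solve(instance: ProblemInstance, rule: str = "first_fit") -> Solution:
    """Full rule-based baseline: score, greedily select, evaluate."""
    table = effectiveness_scores(instance)
    selected = greedy_select(table, instance.budget, rule=rule)
    return evaluate_selection(instance, selected, status="evaluated")
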