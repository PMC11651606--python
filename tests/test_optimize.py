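"""Exact selection MIP, brute-force oracle, and selection evaluation."""

import numpy as np
import pytest

from fbnopt import (
    ProblemInstance,
    brute_force,
    build_mip,
    evaluate_selection,
    solve,
)

from conftest import make_break, make_record, random_instance


class TestBuildMip:
    def test_variable_and_row_counts(self, three_break_instance):
        model = build_mip(three_break_instance)
        assert model.n_vars == 3 + 3  # x per break + y per containable fire
        budget, linking = model.constraints
        assert budget.A.shape[0] == 1
        assert linking.A.shape == (3, 6)

    def test_never_containable_fire_gets_no_row(self):
        breaks = [make_break("b1", 2.0)]
        records = [make_record("f1", {"b1"}, 10.0), make_record("f2", set(), 99.0)]
        inst = ProblemInstance(breaks=breaks, records=records, budget=5.0)
        model = build_mip(inst)
        assert model.fire_ids == ["f1"]
        assert model.n_vars == 2

    def test_unknown_break_id_rejected(self):
        breaks = [make_break("b1", 2.0)]
        records = [make_record("f1", {"bX"}, 1.0)]
        with pytest.raises(ValueError, match="unknown break"):
            ProblemInstance(breaks=breaks, records=records, budget=5.0)

    def test_singleton_set_reduces_to_pairwise_link(self):
        breaks = [make_break("b1", 2.0)]
        records = [make_record("f1", {"b1"}, 10.0)]
        model = build_mip(ProblemInstance(breaks=breaks, records=records, budget=0.0))
        link = model.constraints[1].A.toarray()
        # y <= x  <=>  -x + y <= 0
        np.testing.assert_allclose(link, [[-1.0, 1.0]])


class TestSolve:
    def test_zero_budget_selects_nothing(self, three_break_instance):
        inst = three_break_instance
        inst.budget = 0.0
        sol = solve(build_mip(inst))
        assert sol.selected == set()
        assert sol.objective_value == 0.0
        assert sol.status == "optimal"

    def test_single_fire_single_break(self):
        inst = ProblemInstance(
            breaks=[make_break("b1", 5.0)],
            records=[make_record("f1", {"b1"}, 10.0)],
            budget=5.0,
        )
        sol = solve(build_mip(inst))
        assert sol.selected == {"b1"}
        assert sol.contained == {"f1"}
        assert sol.objective_value == pytest.approx(10.0)

    def test_three_break_coordination(self, three_break_instance):
        """Known optimum computed by enumerating all 8 break subsets."""
        sol = solve(build_mip(three_break_instance))
        assert sol.objective_value == pytest.approx(5.0)
        assert sol.selected == {"b1", "b3"}
        assert sol.contained == {"f3"}
        assert sol.gap == 0.0
        assert sol.spend <= three_break_instance.budget

    def test_solution_consistent_with_evaluation(self, three_break_instance):
        sol = solve(build_mip(three_break_instance))
        ev = evaluate_selection(three_break_instance, sol.selected)
        assert ev.objective_value == pytest.approx(sol.objective_value)
        assert ev.contained == sol.contained


class TestBruteForce:
    def test_matches_enumeration_example(self, three_break_instance):
        sol = brute_force(three_break_instance)
        assert sol.objective_value == pytest.approx(5.0)
        assert sol.selected == {"b1", "b3"}

    def test_full_budget_saturates(self, three_break_instance):
        inst = three_break_instance
        inst.budget = sum(b.effective_cost for b in inst.breaks)
        sol = brute_force(inst)
        assert sol.objective_value == pytest.approx(4 + 3 + 5)

    def test_no_containable_fires_objective_zero(self):
        inst = ProblemInstance(
            breaks=[make_break("b1", 1.0)],
            records=[make_record("f1", set(), 7.0)],
            budget=100.0,
        )
        assert brute_force(inst).objective_value == 0.0

    def test_too_many_breaks_rejected(self):
        breaks = [make_break(f"b{i:02d}", 1.0, row=i) for i in range(21)]
        inst = ProblemInstance(breaks=breaks, records=[], budget=1.0)
        with pytest.raises(ValueError, match="limited"):
            brute_force(inst)

    def test_tie_break_is_lexicographic(self):
        # two equal-value singleton fires: both {b1} and {b2} score 5;
        # the oracle must return the lexicographically smaller set
        inst = ProblemInstance(
            breaks=[make_break("b1", 1.0), make_break("b2", 1.0, row=1)],
            records=[make_record("f1", {"b1"}, 5.0), make_record("f2", {"b2"}, 5.0)],
            budget=1.0,
        )
        assert brute_force(inst).selected == {"b1"}


class TestEvaluateSelection:
    def test_all_breaks_contains_every_containable_fire(self, three_break_instance):
        inst = three_break_instance
        sol = evaluate_selection(inst, {"b1", "b2", "b3"})
        assert sol.contained == {"f1", "f2", "f3"}
        assert not sol.budget_feasible  # spend 7 > budget 5, reported not enforced

    def test_partial_selection(self, three_break_instance):
        sol = evaluate_selection(three_break_instance, {"b1", "b2"})
        assert sol.objective_value == pytest.approx(4.0)
        assert sol.contained == {"f1"}

    def test_empty_selection(self, three_break_instance):
        sol = evaluate_selection(three_break_instance, set())
        assert sol.objective_value == 0.0
        assert sol.contained == set()

    def test_unknown_id_rejected(self, three_break_instance):
        with pytest.raises(ValueError, match="unknown"):
            evaluate_selection(three_break_instance, {"zz"})


class TestSolverProperties:
    """Seeded randomized invariants linking the MIP to the enumeration oracle."""

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            inst = random_instance(rng, max_breaks=10, max_fires=25)
            mip_obj = solve(build_mip(inst)).objective_value
            bf_obj = brute_force(inst).objective_value
            assert mip_obj == pytest.approx(bf_obj, rel=1e-9, abs=1e-9)

    def test_budget_monotonicity(self):
        rng = np.random.default_rng(7)
        inst = random_instance(rng, max_breaks=10, max_fires=25)
        total = sum(b.effective_cost for b in inst.breaks)
        prev = -1.0
        for frac in np.linspace(0, 1, 6):
            inst.budget = frac * total
            obj = solve(build_mip(inst)).objective_value
            assert obj >= prev - 1e-9
            prev = obj

    def test_saturation_closed_form(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            inst = random_instance(rng, max_breaks=8, max_fires=20)
            inst.budget = sum(b.effective_cost for b in inst.breaks)
            expect = sum(inst.value(r) for r in inst.records if r.containable)
            assert solve(build_mip(inst)).objective_value == pytest.approx(expect)

    def test_fire_subset_dominance(self):
        rng = np.random.default_rng(21)
        inst = random_instance(rng, max_breaks=10, max_fires=30)
        sub = ProblemInstance(
            breaks=inst.breaks, records=inst.records[::2], budget=inst.budget,
            objective=inst.objective, budget_mode=inst.budget_mode,
        )
        full_obj = solve(build_mip(inst)).objective_value
        sub_obj = solve(build_mip(sub)).objective_value
        assert sub_obj <= full_obj + 1e-9 * max(1.0, full_obj)
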