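"""Grouped hyperparameter search: spaces, plans, winners, ledger."""

import math

import numpy as np
import pytest

from respforecast.hpo import (
    DEFAULT_BASE_CONFIG,
    GroupUnresolvedError,
    HPOPlan,
    LEARNING_RATE_RAW,
    N_VARIANTS,
    ParamDomain,
    SearchGroup,
    default_plan,
    default_search_space,
    ledger_to_frame,
    run_group,
    run_plan,
    write_ledger,
)


class TestSearchSpace:
    def test_units_domain(self):
        space = {d.name: d for d in default_search_space()}
        assert space["units"].values == (3, 5, 10, 20, 30, 40, 50, 60)

    def test_learning_rate_deduplicated(self):
        space = {d.name: d for d in default_search_space()}
        assert len(LEARNING_RATE_RAW) == 7          # printed with a repeat
        assert space["learning_rate"].values == (
            0.0001, 0.005, 0.001, 0.003, 0.05, 0.01
        )

    def test_variant_count(self):
        space = default_search_space()
        # 13 table rows; hidden+output activation count as one variant
        assert len(space) == 13
        activation_rows = [d for d in space if "activation" in d.name]
        assert len(activation_rows) == 2
        assert len(space) - len(activation_rows) + 1 == N_VARIANTS == 12

    def test_latency_domain(self):
        space = {d.name: d for d in default_search_space()}
        assert space["latency"].values == (1, 5, 10, 15)

    def test_domains_validated(self):
        with pytest.raises(ValueError):
            ParamDomain("x", ())
        with pytest.raises(ValueError):
            ParamDomain("x", (1, 1))


class TestDefaultPlan:
    def test_named_pairings(self):
        plan = default_plan()
        by_name = {g.name: g for g in plan.groups}
        assert by_name["A"].params == ("loss", "optimizer")
        assert by_name["A"].method == "grid"
        assert by_name["B"].params == ("optimizer", "learning_rate")
        assert by_name["B"].method == "random"
        assert by_name["C"].params == ("n_layers", "units")
        assert by_name["C"].method == "grid"

    def test_group_a_cross_product_is_32(self):
        plan = default_plan()
        a = plan.groups[0]
        assert math.prod(len(d.values) for d in a.domains) == 4 * 8 == 32

    def test_repeats_default_ten(self):
        assert default_plan().repeats == 10

    def test_every_parameter_covered(self):
        plan = default_plan()
        in_groups = {d.name for g in plan.groups for d in g.domains}
        assert in_groups <= set(plan.base_config)
        assert set(DEFAULT_BASE_CONFIG) == {
            d.name for d in default_search_space()
        }

    def test_total_trials_far_below_full_factorial(self):
        plan = default_plan()
        full = math.prod(len(d.values) for d in default_search_space())
        grouped = sum(
            (g.budget if g.method == "random"
             else math.prod(len(d.values) for d in g.domains))
            for g in plan.groups
        ) * plan.repeats
        assert full > 100_000_000       # the factorial explosion avoided
        assert grouped < full / 10_000

    def test_plan_validation(self):
        with pytest.raises(ValueError, match="repeats"):
            HPOPlan(groups=default_plan().groups, base_config=DEFAULT_BASE_CONFIG,
                    repeats=0)
        with pytest.raises(ValueError, match="missing"):
            HPOPlan(groups=default_plan().groups, base_config={}, repeats=1)


def _group(name, domains, method="grid", budget=0):
    return SearchGroup(name, tuple(ParamDomain(n, tuple(v))
                                   for n, v in domains), method, budget)


class TestRunGroup:
    def test_grid_evaluates_full_cross_product(self):
        g = _group("G", [("a", [1, 2]), ("b", ["x", "y"])])
        calls = []

        def objective(config, seed):
            calls.append((config["a"], config["b"], seed))
            return 1.0

        run_group(g, {"a": 1, "b": "x"}, objective, seeds=[0, 1])
        assert len(calls) == 8          # 4 configs x 2 seeds
        assert len(set(calls)) == 8     # each exactly once per seed

    def test_rigged_objective_recovers_planted_optimum(self):
        g = _group("C", [("n_layers", [1, 2, 3, 5]),
                         ("units", [3, 5, 10, 20, 30, 40, 50, 60])])

        def objective(config, seed):
            return abs(config["units"] - 10) + abs(config["n_layers"] - 3)

        winner, ledger = run_group(g, dict(DEFAULT_BASE_CONFIG), objective,
                                   seeds=[0])
        assert winner == {"n_layers": 3, "units": 10}
        assert len(ledger) == 32

    def test_random_samples_distinct_and_reproducible(self):
        g = _group("B", [("a", list(range(6))), ("b", list(range(8)))],
                   method="random", budget=5)
        seen = []

        def objective(config, seed):
            seen.append((config["a"], config["b"]))
            return 1.0

        run_group(g, {"a": 0, "b": 0}, objective, seeds=[0], sampler_seed=42)
        first = list(seen)
        assert len(set(first)) == 5
        seen.clear()
        run_group(g, {"a": 0, "b": 0}, objective, seeds=[0], sampler_seed=42)
        assert seen == first

    def test_ties_broken_by_domain_order(self):
        g = _group("T", [("a", [5, 1, 3])])
        winner, _ = run_group(g, {"a": 5}, lambda c, s: 0.0, seeds=[0])
        assert winner == {"a": 5}       # first in domain order

    def test_diverged_trials_scored_infinite(self):
        g = _group("D", [("a", [1, 2])])

        def objective(config, seed):
            if config["a"] == 1:
                raise FloatingPointError("NaN loss")
            return 0.5

        winner, ledger = run_group(g, {"a": 1}, objective, seeds=[0])
        assert winner == {"a": 2}
        statuses = {r.config["a"]: r.status for r in ledger}
        assert statuses == {1: "diverged", 2: "ok"}

    def test_all_diverged_raises_with_ledger_intact(self):
        g = _group("D", [("a", [1, 2])])
        with pytest.raises(GroupUnresolvedError) as err:
            run_group(g, {"a": 1}, lambda c, s: float("nan"), seeds=[0, 1])
        assert len(err.value.ledger) == 4


class TestRunPlan:
    @staticmethod
    def _separable_plan():
        groups = [
            _group("A", [("a", [1, 2, 3])]),
            _group("B", [("b", [10, 20]), ("c", [0.1, 0.2, 0.3])]),
        ]
        base = {"a": 1, "b": 10, "c": 0.1}
        return HPOPlan(groups=groups, base_config=base, repeats=1)

    def test_separable_objective_recovers_global_minimum(self):
        plan = self._separable_plan()

        def objective(config, seed):
            return (
                abs(config["a"] - 2)
                + abs(config["b"] - 20) / 10
                + abs(config["c"] - 0.3)
            )

        best, ledger = run_plan(plan, objective, seeds=[0])
        assert best == {"a": 2, "b": 20, "c": 0.3}
        # exhaustive oracle over the full product confirms global optimality
        import itertools

        full = [
            {"a": a, "b": b, "c": c}
            for a, b, c in itertools.product([1, 2, 3], [10, 20],
                                             [0.1, 0.2, 0.3])
        ]
        oracle = min(full, key=lambda cfg: objective(cfg, 0))
        assert best == oracle

    def test_ledger_counts_match_contract(self):
        plan = self._separable_plan()
        best, ledger = run_plan(plan, lambda c, s: c["a"], seeds=[0, 1, 2])
        assert len(ledger) == (3 + 6) * 3

    def test_frozen_parameters_dropped_from_later_groups(self):
        groups = [
            _group("A", [("a", [1, 2])]),
            _group("B", [("a", [1, 2]), ("b", [5, 6])]),
        ]
        plan = HPOPlan(groups=groups, base_config={"a": 1, "b": 5}, repeats=1)
        best, ledger = run_plan(plan, lambda c, s: c["a"] + c["b"], seeds=[0])
        assert best == {"a": 1, "b": 5}
        b_trials = [r for r in ledger if r.group == "B"]
        assert len(b_trials) == 2       # only the two b values; a is frozen

    def test_identical_inputs_identical_ledger(self):
        plan = self._separable_plan()
        r1 = run_plan(plan, lambda c, s: c["a"] + s, seeds=[0, 1])
        r2 = run_plan(plan, lambda c, s: c["a"] + s, seeds=[0, 1])
        assert r1[0] == r2[0]
        assert [
            (a.config, a.objective, a.seed, a.status) for a in r1[1]
        ] == [(b.config, b.objective, b.seed, b.status) for b in r2[1]]

    def test_ledger_export(self, tmp_path):
        plan = self._separable_plan()
        _, ledger = run_plan(plan, lambda c, s: c["a"], seeds=[0])
        frame = ledger_to_frame(ledger)
        assert {"group", "seed", "objective", "status"} <= set(frame.columns)
        out = tmp_path / "ledger.tsv"
        write_ledger(ledger, out)
        assert out.read_text().count("\n") == len(ledger) + 1
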