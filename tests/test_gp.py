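import numpy as np
import pytest
import sympy

from gpdrivers.gp import (
    GPConfig,
    Individual,
    eval_genome,
    evaluate,
    evolve,
    genome_depth,
    random_individual,
    rmse,
    select_parent,
    sexpr_to_genome,
    subtree_crossover,
    subtree_mutation,
)

from conftest import make_table


class TestRmse:
    def test_perfect_prediction_is_zero(self):
        assert rmse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_unit_offset(self):
        assert rmse(np.array([1.0, 1.0]), np.array([0.0, 0.0])) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert rmse(np.array([3.0, 4.0]), np.array([0.0, 0.0])) == pytest.approx(
            np.sqrt(25.0 / 2.0)
        )

    def test_missing_indices_excluded(self):
        pred = np.array([1.0, 5.0, 2.0])
        obs = np.array([1.0, np.nan, 2.0])
        assert rmse(pred, obs) == 0.0

    def test_no_usable_index_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.array([1.0]), np.array([np.nan]))


class TestEvaluate:
    def test_identity_tree_copies_column(self):
        table = make_table({"x1": [0.1, 0.5, 1.0]}, [0, 0, 0])
        ind = Individual.from_sexpr("x1")
        np.testing.assert_allclose(evaluate(ind, table), [0.1, 0.5, 1.0])

    def test_protected_division_by_zero_is_one(self):
        table = make_table({"x1": [2.0, 3.0]}, [0, 0])
        ind = Individual.from_sexpr("(div x1 0.0)")
        np.testing.assert_allclose(evaluate(ind, table), [1.0, 1.0])

    def test_protected_log_of_zero_is_zero(self):
        out = eval_genome([("log",), ("c", 0.0)], {"_": np.empty(1)})
        assert out[0] == 0.0

    def test_protected_log_uses_absolute_value(self):
        out = eval_genome([("log",), ("c", -np.e)], {"_": np.empty(1)})
        assert out[0] == pytest.approx(1.0)

    def test_addition(self):
        table = make_table({"x1": [1.0, 2.0], "x2": [3.0, 4.0]}, [0, 0])
        ind = Individual.from_sexpr("(add x1 x2)")
        np.testing.assert_allclose(evaluate(ind, table), [4.0, 6.0])

    def test_subtraction_operand_order(self):
        table = make_table({"x1": [1.0], "x2": [3.0]}, [0])
        ind = Individual.from_sexpr("(sub x1 x2)")
        np.testing.assert_allclose(evaluate(ind, table), [-2.0])

    def test_missing_year_propagates(self):
        table = make_table({"x1": [1.0, np.nan]}, [0, 0])
        ind = Individual.from_sexpr("(add x1 1.0)")
        out = evaluate(ind, table)
        assert out[0] == 2.0 and np.isnan(out[1])

    def test_unknown_variable_rejected(self):
        table = make_table({"x1": [1.0]}, [0])
        with pytest.raises(KeyError):
            evaluate(Individual.from_sexpr("zz"), table)


class TestSexpr:
    @pytest.mark.parametrize("text", [
        "x1",
        "(add x1 0.5)",
        "(div (mul x1 x2) (sub x2 -0.25))",
        "(exp (log x1))",
    ])
    def test_round_trip(self, text):
        ind = Individual(sexpr_to_genome(text))
        assert Individual.from_sexpr(ind.to_sexpr()).genome == ind.genome


VARS = ["x1", "x2", "x3"]


class TestRandomIndividual:
    def test_depth_one_is_single_terminal(self):
        cfg = GPConfig(init_depth=(1, 1), max_depth=2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ind = random_individual(VARS, cfg, rng)
            assert ind.size == 1

    def test_invariants_hold(self):
        cfg = GPConfig(init_depth=(2, 6))
        rng = np.random.default_rng(1)
        for _ in range(100):
            ind = random_individual(VARS, cfg, rng)
            assert genome_depth(ind.genome) <= 6
            assert ind.variables() <= set(VARS)
            for node in ind.genome:
                if node[0] == "c":
                    assert np.isfinite(node[1])

    def test_seed_determinism(self):
        cfg = GPConfig()
        a = random_individual(VARS, cfg, np.random.default_rng(7))
        b = random_individual(VARS, cfg, np.random.default_rng(7))
        assert a.genome == b.genome


class TestSelection:
    def _pop(self, fitnesses):
        return [Individual([("v", "x1")], fitness=f) for f in fitnesses]

    def test_full_tournament_returns_global_best(self):
        pop = self._pop([0.5, 0.1, 0.9, 0.3])
        best = select_parent(pop, tournament_size=4, rng=np.random.default_rng(0))
        assert best.fitness == 0.1

    def test_population_of_one(self):
        pop = self._pop([0.4])
        assert select_parent(pop, 4, np.random.default_rng(0)).fitness == 0.4

    def test_two_way_tournament_prefers_lower_rmse(self):
        pop = self._pop([0.1, 0.9])
        assert select_parent(pop, 2, np.random.default_rng(0)).fitness == 0.1

    def test_fitness_tie_broken_by_size(self):
        small = Individual([("v", "x1")], fitness=0.2)
        big = Individual([("add",), ("v", "x1"), ("c", 0.0)], fitness=0.2)
        got = select_parent([big, small], 2, np.random.default_rng(0))
        assert got is small


def _leaf_multiset(genome):
    return sorted(repr(n) for n in genome if n[0] in ("v", "c"))


class TestCrossover:
    def test_identical_single_leaves(self):
        a = Individual([("v", "x1")])
        b = Individual([("v", "x1")])
        ca, cb = subtree_crossover(a, b, np.random.default_rng(0))
        assert ca.genome == cb.genome == [("v", "x1")]

    def test_depth_cap_enforced(self):
        cfg = GPConfig(init_depth=(2, 6), max_depth=8)
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = random_individual(VARS, cfg, rng)
            b = random_individual(VARS, cfg, rng)
            ca, cb = subtree_crossover(a, b, rng, max_depth=8)
            assert genome_depth(ca.genome) <= 8
            assert genome_depth(cb.genome) <= 8

    def test_leaf_conservation_without_depth_rejection(self):
        cfg = GPConfig(init_depth=(2, 4), max_depth=30)
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = random_individual(VARS, cfg, rng)
            b = random_individual(VARS, cfg, rng)
            before = _leaf_multiset(a.genome) + _leaf_multiset(b.genome)
            ca, cb = subtree_crossover(a, b, rng, max_depth=30)
            after = _leaf_multiset(ca.genome) + _leaf_multiset(cb.genome)
            assert sorted(before) == sorted(after)

    def test_parents_unmodified(self):
        cfg = GPConfig(init_depth=(3, 4))
        rng = np.random.default_rng(5)
        a = random_individual(VARS, cfg, rng)
        b = random_individual(VARS, cfg, rng)
        ga, gb = list(a.genome), list(b.genome)
        subtree_crossover(a, b, rng)
        assert a.genome == ga and b.genome == gb


class TestMutation:
    def test_result_valid_and_capped(self):
        cfg = GPConfig(init_depth=(2, 6), max_depth=8)
        rng = np.random.default_rng(6)
        for _ in range(100):
            a = random_individual(VARS, cfg, rng)
            m = subtree_mutation(a, VARS, cfg, rng)
            assert genome_depth(m.genome) <= cfg.max_depth
            assert m.variables() <= set(VARS)

    def test_depth_cap_one_gives_terminal(self):
        cfg = GPConfig(init_depth=(1, 1), max_depth=1)
        rng = np.random.default_rng(7)
        a = Individual([("v", "x1")])
        m = subtree_mutation(a, VARS, cfg, rng)
        assert m.size == 1

    def test_seed_determinism(self):
        cfg = GPConfig()
        a = random_individual(VARS, cfg, np.random.default_rng(8))
        m1 = subtree_mutation(a, VARS, cfg, np.random.default_rng(9))
        m2 = subtree_mutation(a, VARS, cfg, np.random.default_rng(9))
        assert m1.genome == m2.genome


class TestEvolve:
    def _table(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        cols = {f"x{i}": rng.uniform(-1, 1, n) for i in range(1, 6)}
        return cols

    def test_recovers_identity_target(self):
        cols = self._table()
        table = make_table(cols, cols["x3"])
        cfg = GPConfig(population_size=200, max_generations=50, init_depth=(2, 4),
                       max_depth=8, stagnation_window=50)
        best, hist, _ = evolve(table, list(table.years), cfg, np.random.default_rng(0))
        assert best.fitness < 1e-6

    def test_constant_target(self):
        cols = self._table(1)
        table = make_table(cols, np.full(30, 0.5))
        cfg = GPConfig(population_size=200, max_generations=100, init_depth=(2, 4),
                       max_depth=8, stagnation_window=100)
        best, _, _ = evolve(table, list(table.years), cfg, np.random.default_rng(1))
        assert best.fitness < 1e-3

    def test_history_is_monotone_and_bounded(self):
        cols = self._table(2)
        rng = np.random.default_rng(2)
        table = make_table(cols, 0.3 * cols["x1"] + 0.1 * rng.normal(size=30))
        cfg = GPConfig(population_size=80, max_generations=25, init_depth=(2, 4),
                       max_depth=8, stagnation_window=25)
        best, hist, _ = evolve(table, list(table.years), cfg, rng)
        assert len(hist) <= cfg.max_generations
        assert all(hist[i + 1] <= hist[i] + 1e-15 for i in range(len(hist) - 1))

    def test_seed_reproducibility(self):
        cols = self._table(3)
        table = make_table(cols, cols["x2"] + 0.1)
        cfg = GPConfig(population_size=60, max_generations=15, init_depth=(2, 4),
                       max_depth=8, stagnation_window=15)
        b1, h1, _ = evolve(table, list(table.years), cfg, np.random.default_rng(5))
        b2, h2, _ = evolve(table, list(table.years), cfg, np.random.default_rng(5))
        assert b1.genome == b2.genome and h1 == h2

    def test_too_few_training_years_rejected(self):
        cols = self._table(4)
        table = make_table(cols, np.full(30, np.nan))
        cfg = GPConfig(population_size=10, max_generations=2, init_depth=(2, 2),
                       max_depth=4)
        with pytest.raises(ValueError):
            evolve(table, list(table.years), cfg, np.random.default_rng(0))


class TestSymbolicOracle:
    """Tree evaluation agrees with sympy simplify-then-substitute."""

    def _to_sympy(self, genome, syms):
        def build(i):
            node = genome[i]
            if node[0] == "v":
                return syms[node[1]], i + 1
            if node[0] == "c":
                return sympy.Float(node[1]), i + 1
            op = node[0]
            a, j = build(i + 1)
            b, k = build(j)
            return {"add": a + b, "sub": a - b, "mul": a * b}[op], k

        expr, _ = build(0)
        return expr

    def test_agreement_on_random_polynomial_trees(self):
        cfg = GPConfig(primitives=("add", "sub", "mul"), init_depth=(2, 4),
                       max_depth=4)
        rng = np.random.default_rng(11)
        syms = {v: sympy.Symbol(v) for v in VARS}
        for _ in range(100):
            ind = random_individual(VARS, cfg, rng)
            expr = sympy.simplify(self._to_sympy(ind.genome, syms))
            point = {v: rng.uniform(-1, 1) for v in VARS}
            expected = float(expr.subs({syms[v]: point[v] for v in VARS}))
            cols = {v: np.array([point[v]]) for v in ind.variables()} or {"_": np.empty(1)}
            got = float(eval_genome(ind.genome, cols)[0])
            assert got == pytest.approx(expected, abs=1e-9, rel=1e-9)
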