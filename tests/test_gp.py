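"""Genetic-programming feature synthesis: protected evaluation, variation
operators, the evolutionary loop."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from fldscreen import (GPConfig, crossover, evaluate_tree, mutate,
                       normalize_features, parse_expression, random_tree,
                       run_gp, spearman_fitness)
from fldscreen.gp import (BINARY_OPS, UNARY_OPS, Leaf, Node, canonical_key,
                          depth, expression)
from fldscreen.exceptions import EvaluationError, InputError

from oracles import spearman_rho

FEATURES = ["TG", "ALT", "AST", "GGT", "UA", "GLU"]


def valid(tree, max_depth):
    if isinstance(tree, Leaf):
        return tree.name in FEATURES
    arity_ok = (len(tree.children) == 1) if tree.op in UNARY_OPS \
        else (tree.op in BINARY_OPS and len(tree.children) == 2)
    return (arity_ok and depth(tree) <= max_depth
            and all(valid(c, max_depth) for c in tree.children))


def frame(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame({"sex": np.zeros(n, int), "age": np.full(n, 40.0),
                         "fld": np.zeros(n), **cols})


class TestEvaluate:
    def test_leaf_returns_column(self):
        t = frame(TG=[0.1, 0.5, 0.9])
        np.testing.assert_array_equal(evaluate_tree(Leaf("TG"), t),
                                      [0.1, 0.5, 0.9])

    def test_product_plus_arithmetic(self):
        tree = Node("+", (Node("*", (Leaf("TG"), Leaf("AST"))), Leaf("GLU")))
        t = frame(TG=[0.5], AST=[0.4], GLU=[0.2])
        assert evaluate_tree(tree, t)[0] == pytest.approx(0.4)

    def test_protected_division_by_zero(self):
        tree = Node("/", (Leaf("TG"), Leaf("GLU")))
        t = frame(TG=[3.0, 1.0], GLU=[0.0, 2.0])
        np.testing.assert_allclose(evaluate_tree(tree, t), [1.0, 0.5])

    def test_protected_log_and_sqrt(self):
        t = frame(TG=[0.0, -4.0, np.e])
        np.testing.assert_allclose(evaluate_tree(Node("log", (Leaf("TG"),)), t),
                                   [0.0, np.log(4.0), 1.0])
        np.testing.assert_allclose(evaluate_tree(Node("sqrt", (Leaf("TG"),)), t),
                                   [0.0, 2.0, np.sqrt(np.e)])

    def test_unknown_leaf_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate_tree(Leaf("nope"), frame(TG=[1.0]))


class TestExpressions:
    def test_display_matches_canonical_examples(self):
        tree = Node("+", (Node("*", (Leaf("TG"), Leaf("AST"))), Leaf("GLU")))
        assert expression(tree) == "(TG*AST)+GLU"
        assert expression(Node("+", (Leaf("TG"),
                                     Node("log", (Leaf("ALT"),))))) == "TG+log(ALT)"

    def test_roundtrip_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            tree = random_tree(FEATURES, 3, rng)
            again = parse_expression(expression(tree))
            assert canonical_key(again) == canonical_key(tree)

    def test_commutative_canonicalisation(self):
        a = parse_expression("TG+ALT")
        b = parse_expression("ALT+TG")
        assert canonical_key(a) == canonical_key(b)
        assert canonical_key(parse_expression("TG-ALT")) != \
            canonical_key(parse_expression("ALT-TG"))

    def test_malformed_expressions_rejected(self):
        for text in ("TG+", "(TG", "log TG", "TG $ ALT"):
            with pytest.raises(InputError):
                parse_expression(text)


class TestNormalize:
    def test_min_max_formula(self):
        t = frame(TG=[0.0, 5.0, 10.0])
        np.testing.assert_allclose(normalize_features(t)["TG"], [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        t = frame(TG=[4.0, 4.0, 4.0])
        np.testing.assert_array_equal(normalize_features(t)["TG"], [0, 0, 0])

    def test_test_values_clipped_to_unit_interval(self):
        train = frame(TG=[0.0, 10.0])
        test = frame(TG=[-5.0, 20.0])
        np.testing.assert_array_equal(normalize_features(train, test)["TG"],
                                      [0.0, 1.0])

    def test_reserved_columns_untouched(self):
        t = frame(TG=[1.0, 2.0])
        out = normalize_features(t)
        np.testing.assert_array_equal(out["age"], t["age"])


class TestFitness:
    def test_perfect_monotone_association_and_sign_invariance(self):
        y = np.array([0, 0, 0, 1, 1])
        up = spearman_fitness([1, 2, 3, 4, 5], y)
        down = spearman_fitness([5, 4, 3, 2, 1], y)
        assert up == pytest.approx(down)
        assert up == pytest.approx(abs(spearmanr([1, 2, 3, 4, 5], y).statistic))

    def test_matches_rank_formula_oracle(self):
        assert spearman_fitness([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(
            abs(spearman_rho([1, 2, 3, 4], [0, 0, 1, 1])), abs=1e-12)

    def test_oracle_agreement_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 2, n).astype(float)
            if np.all(y == y[0]):
                continue
            assert spearman_fitness(x, y) == pytest.approx(
                abs(spearman_rho(x, y)), abs=1e-12)

    def test_constant_values_score_zero(self):
        assert spearman_fitness([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1]) == 0.0

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.random(50)
        y = rng.integers(0, 2, 50)
        base = spearman_fitness(x, y)
        assert spearman_fitness(np.exp(5 * x), y) == pytest.approx(base)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(InputError):
            spearman_fitness([1.0, 2.0, 3.0], [1, 1, 1])


class TestVariation:
    def test_depth_zero_always_leaf(self):
        rng = np.random.default_rng(1)
        assert all(isinstance(random_tree(FEATURES, 0, rng), Leaf)
                   for _ in range(50))

    def test_random_trees_respect_depth_bound(self):
        rng = np.random.default_rng(2)
        assert all(valid(random_tree(FEATURES, 3, rng), 3)
                   for _ in range(1000))

    def test_seeded_generation_deterministic(self):
        a = random_tree(FEATURES, 3, np.random.default_rng(9))
        b = random_tree(FEATURES, 3, np.random.default_rng(9))
        assert a == b

    def test_crossover_of_leaves_returns_a_leaf(self):
        rng = np.random.default_rng(3)
        child = crossover(Leaf("TG"), Leaf("ALT"), rng)
        assert child in (Leaf("TG"), Leaf("ALT"))

    def test_crossover_closure(self):
        rng = np.random.default_rng(5)
        parents = [random_tree(FEATURES, 3, rng) for _ in range(200)]
        for i in range(2000):
            child = crossover(parents[i % 200], parents[(i * 7 + 3) % 200],
                              rng, max_depth=3)
            assert valid(child, 3)

    def test_mutation_closure(self):
        rng = np.random.default_rng(6)
        tree = random_tree(FEATURES, 3, rng)
        for _ in range(2000):
            tree = mutate(tree, FEATURES, rng, max_depth=3)
            assert valid(tree, 3)

    def test_seeded_variation_deterministic(self):
        a = random_tree(FEATURES, 3, np.random.default_rng(11))
        b = random_tree(FEATURES, 3, np.random.default_rng(12))
        c1 = crossover(a, b, np.random.default_rng(13))
        c2 = crossover(a, b, np.random.default_rng(13))
        assert c1 == c2
        m1 = mutate(a, FEATURES, np.random.default_rng(14))
        m2 = mutate(a, FEATURES, np.random.default_rng(14))
        assert m1 == m2


@pytest.fixture
def gp_cohort():
    """Normalised cohort whose label follows TG + log(ALT)."""
    rng = np.random.default_rng(8)
    n = 600
    tg = np.exp(0.3 + 0.45 * rng.standard_normal(n))
    alt = np.exp(3.0 + 0.5 * rng.standard_normal(n))
    eta = 1.8 * tg + 2.5 * np.log(alt)
    y = (rng.random(n) < 1 / (1 + np.exp(-(eta - np.median(eta))))).astype(float)
    t = frame(TG=tg, ALT=alt,
              noiseA=rng.lognormal(1, 0.4, n), noiseB=rng.lognormal(2, 0.3, n))
    t["fld"] = y
    return normalize_features(t), y


class TestRun:
    def test_zero_generations_matches_direct_evaluation(self, gp_cohort):
        table, y = gp_cohort
        cfg = GPConfig(population_size=100, generations=0, seed=5)
        result = run_gp(table, y, cfg)
        assert len(result.features) == 3
        assert len(result.best_per_generation) == 1
        for feat in result.features:
            direct = spearman_fitness(evaluate_tree(feat.tree, table), y)
            assert feat.fitness == pytest.approx(direct, abs=1e-12)

    def test_best_fitness_monotone_and_sorted_output(self, gp_cohort):
        table, y = gp_cohort
        result = run_gp(table, y, GPConfig(population_size=150, generations=6,
                                           seed=1))
        trace = result.best_per_generation
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        fits = [f.fitness for f in result.features]
        assert fits == sorted(fits, reverse=True)
        assert all(0.0 <= f <= 1.0 for f in fits)

    def test_returned_expressions_distinct(self, gp_cohort):
        table, y = gp_cohort
        result = run_gp(table, y, GPConfig(population_size=150, generations=6,
                                           seed=2))
        keys = [canonical_key(f.tree) for f in result.features]
        assert len(set(keys)) == len(keys)

    def test_seeded_run_reproducible(self, gp_cohort):
        table, y = gp_cohort
        cfg = GPConfig(population_size=120, generations=4, seed=3)
        a, b = run_gp(table, y, cfg), run_gp(table, y, cfg)
        assert [f.expression for f in a.features] == \
            [f.expression for f in b.features]
        assert a.best_per_generation == b.best_per_generation

    def test_composite_beats_best_single_feature(self, gp_cohort):
        table, y = gp_cohort
        best_single = max(spearman_fitness(table[c], y)
                          for c in ("TG", "ALT", "noiseA", "noiseB"))
        result = run_gp(table, y, GPConfig(population_size=300, generations=6,
                                           seed=4))
        assert result.features[0].fitness > best_single

    def test_no_signal_warns_but_returns(self):
        rng = np.random.default_rng(10)
        t = frame(TG=np.ones(100), ALT=np.ones(100))
        y = rng.integers(0, 2, 100).astype(float)
        t["fld"] = y
        with pytest.warns(UserWarning):
            result = run_gp(t, y, GPConfig(population_size=50, generations=1,
                                           seed=0))
        assert len(result.features) == 3
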