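"""Symbolic feature synthesis by genetic programming.

Candidate features are expression trees over the cohort's exam columns:
leaves are feature names, inner nodes are operators from
``{+, -, *, /, log, sqrt}``. A tree's fitness is the absolute Spearman
rank correlation between its evaluated column and the binary label —
exactly the monotone association a tree-based classifier can exploit.
Evolution is the classic loop: evaluate, keep an elite, refill by
subtree crossover and subtree mutation of rank-selected parents.

Operators are *protected* so evaluation is total on any numeric input:
``log(x) = log|x|`` with ``log(0) = 0``, ``sqrt(x) = sqrt|x|``, and
``x / y = 1`` whenever ``|y| < 1e-12``. Features are min-max normalised
to [0, 1] (train-fitted) before the search so operator scales are
comparable.

Depth is counted in edges on the longest root-to-leaf path; the default
bound of 3 allows up to eight leaves per expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigurationError, EvaluationError, InputError
from .tables import RESERVED_COLUMNS, feature_columns

UNARY_OPS = ("log", "sqrt")
BINARY_OPS = ("+", "-", "*", "/")
_COMMUTATIVE = ("+", "*")
_DIV_EPS = 1e-12
_PRECEDENCE = {"+": 1, "-": 1, "*": 2, "/": 2}


# ---------------------------------------------------------------- trees

@dataclass(frozen=True)
class Leaf:
    name: str


@dataclass(frozen=True)
class Node:
    op: str
    children: tuple


Tree = Leaf | Node


def depth(tree: Tree) -> int:
    """Edge count of the longest root-to-leaf path."""
    if isinstance(tree, Leaf):
        return 0
    return 1 + max(depth(c) for c in tree.children)


def expression(tree: Tree) -> str:
    """Infix display string, binary subexpressions parenthesised."""
    def render(t: Tree, top: bool) -> str:
        if isinstance(t, Leaf):
            return t.name
        if t.op in UNARY_OPS:
            return f"{t.op}({render(t.children[0], True)})"
        inner = f"{render(t.children[0], False)}{t.op}{render(t.children[1], False)}"
        return inner if top else f"({inner})"
    return render(tree, True)


def canonical_key(tree: Tree) -> str:
    """Canonical form for distinctness: commutative operands sorted."""
    if isinstance(tree, Leaf):
        return tree.name
    keys = [canonical_key(c) for c in tree.children]
    if tree.op in _COMMUTATIVE:
        keys.sort()
    if tree.op in UNARY_OPS:
        return f"{tree.op}({keys[0]})"
    return f"({keys[0]}{tree.op}{keys[1]})"


def parse_expression(text: str) -> Tree:
    """Parse an infix expression string back into a tree.

    Accepts the output of :func:`expression` (and ordinary infix with
    standard precedence: ``*``/``/`` bind tighter than ``+``/``-``).
    """
    tokens: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "+-*/()":
            tokens.append(ch)
            i += 1
        elif ch.isalnum() or ch == "_":
            j = i
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(text[i:j])
            i = j
        else:
            raise InputError(f"unexpected character {ch!r} in expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise InputError(f"malformed expression {text!r}")
        pos += 1
        return tok

    def atom() -> Tree:
        tok = take()
        if tok == "(":
            node = expr(1)
            take(")")
            return node
        if tok in UNARY_OPS:
            take("(")
            node = expr(1)
            take(")")
            return Node(tok, (node,))
        if tok in "+-*/)":
            raise InputError(f"malformed expression {text!r}")
        return Leaf(tok)

    def expr(min_prec: int) -> Tree:
        node = atom()
        while peek() in BINARY_OPS and _PRECEDENCE[peek()] >= min_prec:
            op = take()
            rhs = expr(_PRECEDENCE[op] + 1)
            node = Node(op, (node, rhs))
        return node

    result = expr(1)
    if pos != len(tokens):
        raise InputError(f"trailing tokens in expression {text!r}")
    return result


def evaluate_tree(tree: Tree, table: pd.DataFrame) -> np.ndarray:
    """Evaluate a tree row-wise with protected operator semantics."""
    if isinstance(tree, Leaf):
        if tree.name not in table.columns:
            raise EvaluationError(f"unknown feature {tree.name!r}")
        return table[tree.name].to_numpy(dtype=float)
    args = [evaluate_tree(c, table) for c in tree.children]
    if tree.op == "log":
        x = np.abs(args[0])
        with np.errstate(divide="ignore"):
            return np.where(x == 0, 0.0, np.log(np.where(x == 0, 1.0, x)))
    if tree.op == "sqrt":
        return np.sqrt(np.abs(args[0]))
    a, b = args
    if tree.op == "+":
        return a + b
    if tree.op == "-":
        return a - b
    if tree.op == "*":
        return a * b
    protected = np.abs(b) < _DIV_EPS
    return np.where(protected, 1.0, a / np.where(protected, 1.0, b))


# --------------------------------------------------------- normalisation

def fit_normalizer(train: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-feature (min, max) over the training table."""
    return {c: (float(train[c].min()), float(train[c].max()))
            for c in feature_columns(train)}


def normalize_features(train: pd.DataFrame,
                       apply_to: pd.DataFrame | None = None) -> pd.DataFrame:
    """Min-max scale feature columns to [0, 1] using training extremes.

    Values outside the training range (possible on a test table) are
    clipped to [0, 1]; constant training columns map to 0 everywhere.
    Reserved columns pass through untouched.
    """
    bounds = fit_normalizer(train)
    target = train if apply_to is None else apply_to
    out = target.copy()
    for col, (lo, hi) in bounds.items():
        if col not in out.columns:
            continue
        x = out[col].to_numpy(dtype=float)
        if hi > lo:
            out[col] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[col] = np.zeros_like(x)
    return out


# --------------------------------------------------------------- fitness

def spearman_fitness(values, labels) -> float:
    """Absolute Spearman rank correlation, average ranks on ties.

    Constant value vectors score 0 (no monotone association, not an
    error). Labels must contain both classes.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need matched vectors of length >= 3")
    if np.all(y == y[0]):
        raise InputError("labels must not all be equal")
    return _fitness_against(x, _center_ranks(y))


def _center_ranks(y: np.ndarray):
    ry = rankdata(y)
    ry = ry - ry.mean()
    return ry, float(np.sqrt(np.sum(ry * ry)))


def _fitness_against(x: np.ndarray, label_ranks) -> float:
    ry_c, ry_norm = label_ranks
    rx = rankdata(x)
    rx = rx - rx.mean()
    rx_norm = np.sqrt(np.sum(rx * rx))
    if rx_norm == 0.0 or ry_norm == 0.0:
        return 0.0
    rho = float(np.dot(rx, ry_c) / (rx_norm * ry_norm))
    return min(abs(rho), 1.0)


# ------------------------------------------------------------ variation

def _positions(tree: Tree, path=()) -> list[tuple]:
    """Pre-order list of subtree paths (tuples of child indices)."""
    out = [path]
    if isinstance(tree, Node):
        for i, c in enumerate(tree.children):
            out.extend(_positions(c, path + (i,)))
    return out


def _subtree(tree: Tree, path) -> Tree:
    for i in path:
        tree = tree.children[i]
    return tree


def _replace(tree: Tree, path, new: Tree) -> Tree:
    if not path:
        return new
    i, rest = path[0], path[1:]
    children = list(tree.children)
    children[i] = _replace(children[i], rest, new)
    return Node(tree.op, tuple(children))


def random_tree(features: Sequence[str], max_depth: int,
                rng: np.random.Generator) -> Tree:
    """Grow-style random tree of depth <= ``max_depth``.

    A node at depth d becomes a leaf with probability ``d/(max_depth+1)``
    (increasing with depth), and always at the depth bound.
    """
    if len(features) == 0:
        raise InputError("need at least one feature name")

    def grow(d: int) -> Tree:
        if d >= max_depth or rng.random() < d / (max_depth + 1):
            return Leaf(str(features[rng.integers(len(features))]))
        ops = UNARY_OPS + BINARY_OPS
        op = ops[rng.integers(len(ops))]
        if op in UNARY_OPS:
            return Node(op, (grow(d + 1),))
        return Node(op, (grow(d + 1), grow(d + 1)))

    return grow(0)


def crossover(a: Tree, b: Tree, rng: np.random.Generator,
              max_depth: int = 3) -> Tree:
    """Replace a uniformly chosen subtree of ``a`` with one of ``b``.

    If the child would exceed the depth bound the draw is retried (up to
    8 attempts), after which a copy of ``a`` is returned; the result is
    always a valid tree.
    """
    pos_a, pos_b = _positions(a), _positions(b)
    for _ in range(8):
        pa = pos_a[rng.integers(len(pos_a))]
        pb = pos_b[rng.integers(len(pos_b))]
        child = _replace(a, pa, _subtree(b, pb))
        if depth(child) <= max_depth:
            return child
    return a


def mutate(tree: Tree, features: Sequence[str], rng: np.random.Generator,
           max_depth: int = 3) -> Tree:
    """Replace a uniformly chosen subtree with a fresh random subtree
    grown to the remaining depth budget."""
    positions = _positions(tree)
    path = positions[rng.integers(len(positions))]
    budget = max_depth - len(path)
    return _replace(tree, path, random_tree(features, budget, rng))


# -------------------------------------------------------------- the run

@dataclass(frozen=True)
class GPConfig:
    population_size: int = 1000
    generations: int = 10
    max_depth: int = 3
    top_k: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    elite_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.top_k < 1 or self.top_k > self.population_size:
            raise ConfigurationError("top_k must lie in [1, population_size]")
        if self.generations < 0 or self.max_depth < 0:
            raise ConfigurationError("generations and max_depth must be >= 0")
        for name in ("crossover_rate", "mutation_rate", "elite_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SymbolicFeature:
    """A synthesised feature: its tree, infix form and Spearman fitness."""

    tree: Tree
    expression: str
    fitness: float


@dataclass
class GPResult:
    """Top features plus the per-generation best-fitness trace."""

    features: list[SymbolicFeature]
    best_per_generation: list[float]
    populations: list[list[Tree]] | None = None

    def __iter__(self):
        return iter(self.features)


def run_gp(train: pd.DataFrame, labels, config: GPConfig,
           track_populations: bool = False) -> GPResult:
    """Evolve expression trees maximising |Spearman| with the label.

    ``train`` must be imputed and normalised; leaves are drawn from its
    feature columns. Truncation selection with elitism: the top
    ``elite_fraction`` of each generation is copied unchanged (so the
    best fitness never decreases) and the rest is refilled from
    rank-weighted parents via crossover then mutation. Returns the
    ``top_k`` best distinct expressions ever evaluated, fitness
    descending. With ``track_populations`` every generation's individuals
    are kept on the result for closure inspection.
    """
    config.validate()
    features = feature_columns(train)
    if not features:
        raise InputError("training table has no feature columns")
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise InputError("labels must contain both classes")
    label_ranks = _center_ranks(y)
    rng = np.random.default_rng(config.seed)

    archive: dict[str, tuple[float, Tree]] = {}

    def fitness_of(tree: Tree) -> float:
        key = canonical_key(tree)
        hit = archive.get(key)
        if hit is None:
            fit = _fitness_against(evaluate_tree(tree, train), label_ranks)
            archive[key] = (fit, tree)
            return fit
        return hit[0]

    population = [random_tree(features, config.max_depth, rng)
                  for _ in range(config.population_size)]
    fits = np.array([fitness_of(t) for t in population])
    best_trace = [float(fits.max())]
    history = [list(population)] if track_populations else None

    n = config.population_size
    n_elite = max(1, int(round(config.elite_fraction * n)))
    rank_w = np.arange(n, 0, -1, dtype=float)
    rank_w /= rank_w.sum()

    for _ in range(config.generations):
        order = np.argsort(-fits, kind="stable")
        population = [population[i] for i in order]
        fits = fits[order]
        next_pop = population[:n_elite]
        parent_idx = rng.choice(n, size=2 * (n - n_elite), p=rank_w)
        u_cross = rng.random(n - n_elite)
        u_mut = rng.random(n - n_elite)
        for j in range(n - n_elite):
            p1 = population[parent_idx[2 * j]]
            if u_cross[j] < config.crossover_rate:
                p2 = population[parent_idx[2 * j + 1]]
                child = crossover(p1, p2, rng, config.max_depth)
            else:
                child = p1
            if u_mut[j] < config.mutation_rate:
                child = mutate(child, features, rng, config.max_depth)
            next_pop.append(child)
        population = next_pop
        fits = np.array([fitness_of(t) for t in population])
        best = float(fits.max())
        assert best >= best_trace[-1] - 1e-12, "elitism violated"
        best_trace.append(best)
        if history is not None:
            history.append(list(population))

    ranked = sorted(archive.items(), key=lambda kv: (-kv[1][0], kv[0]))
    top = [SymbolicFeature(tree=t, expression=expression(t), fitness=f)
           for _, (f, t) in ranked[:config.top_k]]
    if top and top[0].fitness == 0.0:
        warnings.warn("no monotone association found: all fitness values are 0",
                      stacklevel=2)
    return GPResult(features=top, best_per_generation=best_trace,
                    populations=history)


def append_symbolic_columns(table: pd.DataFrame,
                            feats: Sequence[SymbolicFeature],
                            prefix: str = "GA_fea") -> pd.DataFrame:
    """Evaluate synthesised features on a (normalised) table and append
    them as ``GA_fea1``, ``GA_fea2``, ... columns."""
    out = table.copy()
    for i, f in enumerate(feats, start=1):
        name = f"{prefix}{i}"
        if name in RESERVED_COLUMNS:
            raise InputError(f"column name {name!r} is reserved")
        out[name] = evaluate_tree(f.tree, table)
    return out
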