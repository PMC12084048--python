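"""Multi-objective symbolic regression engine.

Evolves a population of expression trees to classify a binary outcome,
minimizing two objectives simultaneously:

* **BCE** — mean binary cross-entropy of the sigmoid-linked tree output,
* **partial AIC** — ``2k + 2·n·BCE`` where ``k`` is the tree's node count,
  i.e. ``2k − 2·lnL`` under the Bernoulli likelihood. The complexity term
  pushes the search toward short, readable formulae.

Selection is NSGA-II style: fast non-dominated sorting plus crowding
distance, with binary tournaments, subtree crossover, and a mixture of
subtree / point / constant-perturbation mutation. An external archive keeps
every non-dominated individual encountered; the champion returned is the
archive member with the best *validation* BCE (ties broken by partial AIC,
then node count, then age).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import expressions as ex
from .expressions import Node

__all__ = [
    "EvolutionConfig",
    "Individual",
    "ParetoArchive",
    "binary_cross_entropy",
    "partial_aic",
    "non_dominated_sort",
    "crowding_distance",
    "evolve",
    "MOSRClassifier",
]


def binary_cross_entropy(probabilities, labels) -> float:
    """Mean of −[y·ln p + (1−y)·ln(1−p)] over the sample.

    Probabilities are clipped into (0, 1) before the logs are taken.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    p = np.clip(p, ex.PROB_EPS, 1.0 - ex.PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def partial_aic(bce: float, n: int, k: int) -> float:
    """Complexity-penalized likelihood criterion: ``2k + 2·n·BCE``.

    ``n·BCE`` is the negative Bernoulli log-likelihood, so this is the AIC
    form ``2k − 2·lnL`` with the tree's node count standing in for the
    parameter count. Strictly increasing in ``k`` at fixed BCE.
    """
    return 2.0 * k + 2.0 * n * bce


@dataclass
class Individual:
    tree: Node
    bce: float
    paic: float
    age: int  # generation at which the individual was created

    @property
    def node_count(self) -> int:
        return ex.complexity(self.tree)

    def objectives(self) -> tuple[float, float]:
        return (self.bce, self.paic)


@dataclass
class EvolutionConfig:
    population_size: int = 300
    generations: int = 500
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    tournament_size: int = 2
    max_depth: int = 8
    max_nodes: int = 48
    init_depth: tuple[int, int] = (2, 5)
    immigrant_fraction: float = 0.05
    functions: tuple[str, ...] = tuple(ex.DEFAULT_FUNCTIONS)
    const_range: tuple[float, float] = (-2.0, 2.0)
    validation_fraction: float = 0.1
    stagnation_generations: int | None = None  # optional early stop
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return (a[0] <= b[0] and a[1] <= b[1]) and (a[0] < b[0] or a[1] < b[1])


def non_dominated_sort(objectives: Sequence[tuple[float, float]]) -> list[list[int]]:
    """Fast non-dominated sort; returns fronts as lists of indices.

    Front 0 is the maximal non-dominated set; each later front is
    non-dominated once earlier fronts are removed.
    """
    n = len(objectives)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(objectives[i], objectives[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif _dominates(objectives[j], objectives[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
        if domination_count[i] == 0:
            fronts[0].append(i)
    current = 0
    while fronts[current]:
        nxt = []
        for i in fronts[current]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        current += 1
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(objectives: Sequence[tuple[float, float]]) -> np.ndarray:
    n = len(objectives)
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
        return dist
    obj = np.asarray(objectives, dtype=float)
    for m in range(obj.shape[1]):
        order = np.argsort(obj[:, m], kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        spread = obj[order[-1], m] - obj[order[0], m]
        if spread == 0:
            continue
        for pos in range(1, n - 1):
            dist[order[pos]] += (obj[order[pos + 1], m] - obj[order[pos - 1], m]) / spread
    return dist


class ParetoArchive:
    """Maintains the non-dominated set of individuals seen so far."""

    def __init__(self):
        self.individuals: list[Individual] = []

    def add(self, candidate: Individual) -> bool:
        obj = candidate.objectives()
        for member in self.individuals:
            if _dominates(member.objectives(), obj) or member.objectives() == obj:
                return False
        self.individuals = [m for m in self.individuals
                            if not _dominates(obj, m.objectives())]
        self.individuals.append(candidate)
        return True

    def best_bce(self) -> float:
        return min(m.bce for m in self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------

def _collect_with_parents(tree: Node):
    out = []  # (node, parent, child_index)
    stack = [(tree, None, 0)]
    while stack:
        node, parent, ci = stack.pop()
        out.append((node, parent, ci))
        for k, child in enumerate(node.children):
            stack.append((child, node, k))
    return out

def _replace_child(parent: Node, index: int, new: Node):
    parent.children = tuple(new if k == index else c
                            for k, c in enumerate(parent.children))

def _random_node_index(rng, n: int) -> int:
    return int(rng.integers(n))


def subtree_crossover(rng: np.random.Generator, a: Node, b: Node) -> Node:
    """Return a copy of ``a`` with a random subtree swapped in from ``b``."""
    child = a.copy()
    nodes = _collect_with_parents(child)
    target, parent, ci = nodes[_random_node_index(rng, len(nodes))]
    donors = [n for n, _, _ in _collect_with_parents(b)]
    donor = donors[_random_node_index(rng, len(donors))].copy()
    if parent is None:
        return donor
    _replace_child(parent, ci, donor)
    return child


def mutate(rng: np.random.Generator, tree: Node, feature_names: Sequence[str],
           config: EvolutionConfig) -> Node:
    """Subtree, point, or constant-perturbation mutation (equal odds)."""
    child = tree.copy()
    nodes = _collect_with_parents(child)
    kind = rng.integers(3)
    if kind == 0:  # subtree replacement
        target, parent, ci = nodes[_random_node_index(rng, len(nodes))]
        new = ex.random_tree(rng, feature_names, max_depth=3,
                             functions=config.functions,
                             const_range=config.const_range)
        if parent is None:
            return new
        _replace_child(parent, ci, new)
        return child
    if kind == 1:  # point mutation: swap operator of same arity, or leaf
        target, parent, ci = nodes[_random_node_index(rng, len(nodes))]
        if target.op in ex.DEFAULT_FUNCTIONS:
            arity = ex.DEFAULT_FUNCTIONS[target.op]
            pool = [op for op in config.functions
                    if ex.DEFAULT_FUNCTIONS[op] == arity and op != target.op]
            if pool:
                new = Node(pool[_random_node_index(rng, len(pool))], target.children)
                if parent is None:
                    return new
                _replace_child(parent, ci, new)
        else:
            lo, hi = config.const_range
            new = (Node.feat(feature_names[_random_node_index(rng, len(feature_names))])
                   if len(feature_names) and rng.random() < 0.5
                   else Node.const(float(rng.uniform(lo, hi))))
            if parent is None:
                return new
            _replace_child(parent, ci, new)
        return child
    # constant perturbation: jitter every constant; no-op on trees without them
    for node, _, _ in nodes:
        if node.op == "const":
            node.value = float(node.value + rng.normal(0.0, 0.1))
    return child


def _within_caps(tree: Node, config: EvolutionConfig) -> bool:
    return (ex.depth(tree) <= config.max_depth
            and ex.complexity(tree) <= config.max_nodes)


# ---------------------------------------------------------------------------
# evolution loop
# ---------------------------------------------------------------------------

def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return pd.DataFrame(data)


def _score(tree: Node, X: dict[str, np.ndarray], y: np.ndarray) -> tuple[float, float]:
    p = ex.sigmoid(np.atleast_1d(np.asarray(ex.evaluate(tree, X), dtype=float)))
    if p.shape != y.shape:
        p = np.broadcast_to(p, y.shape)
    bce = binary_cross_entropy(p, y)
    return bce, partial_aic(bce, len(y), ex.complexity(tree))


def _ramped_population(rng, feature_names, config) -> list[Node]:
    lo, hi = config.init_depth
    trees = []
    depths = list(range(lo, hi + 1))
    for i in range(config.population_size):
        d = depths[i % len(depths)]
        method = "full" if (i // len(depths)) % 2 == 0 else "grow"
        t = ex.random_tree(rng, feature_names, max_depth=d, method=method,
                           functions=config.functions,
                           const_range=config.const_range)
        trees.append(t)
    return trees


def _tournament(rng, ranks, crowd, k: int) -> int:
    best = None
    for _ in range(max(2, k)):
        i = int(rng.integers(len(ranks)))
        if best is None:
            best = i
        elif (ranks[i], -crowd[i]) < (ranks[best], -crowd[best]):
            best = i
    return best


def evolve(train, outcome, config: EvolutionConfig,
           validation=None, validation_outcome=None):
    """Run the evolutionary search.

    Parameters
    ----------
    train : DataFrame of features (no outcome column)
    outcome : binary array aligned with ``train``
    validation, validation_outcome : optional held-out rows used only to pick
        the champion; when omitted a stratified 90:10 split of ``train`` is
        made internally with the config seed.

    Returns
    -------
    (archive, champion, history) where ``history`` is a DataFrame with one
    row per generation (best/median BCE and partial AIC on the fit data).
    """
    X = _as_frame(train)
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome must contain both classes")
    rng = np.random.default_rng(config.seed)

    if validation is None:
        from .evaluation import stratified_split
        idx_fit, idx_val = stratified_split(y, 1.0 - config.validation_fraction,
                                            seed=int(rng.integers(2**31)))
        X_val, y_val = X.iloc[idx_val], y[idx_val]
        X_fit, y_fit = X.iloc[idx_fit], y[idx_fit]
    else:
        X_fit, y_fit = X, y
        X_val = _as_frame(validation)
        y_val = np.asarray(validation_outcome, dtype=float)

    feature_names = list(X.columns)
    cols_fit = {c: X_fit[c].to_numpy(dtype=float) for c in feature_names}
    cols_val = {c: X_val[c].to_numpy(dtype=float) for c in feature_names}

    def make_individual(tree: Node, age: int) -> Individual:
        bce, paic = _score(tree, cols_fit, y_fit)
        return Individual(tree, bce, paic, age)

    population = [make_individual(t, 0)
                  for t in _ramped_population(rng, feature_names, config)]
    archive = ParetoArchive()
    for ind in population:
        archive.add(ind)

    history = []

    def log(gen: int):
        bces = np.array([i.bce for i in population])
        paics = np.array([i.paic for i in population])
        history.append({
            "generation": gen,
            "best_bce": float(bces.min()),
            "median_bce": float(np.median(bces)),
            "best_paic": float(paics.min()),
            "median_paic": float(np.median(paics)),
            "archive_best_bce": archive.best_bce(),
            "archive_size": len(archive),
        })

    log(0)
    stagnant = 0
    last_best = archive.best_bce()
    for gen in range(1, config.generations + 1):
        objs = [i.objectives() for i in population]
        fronts = non_dominated_sort(objs)
        ranks = np.empty(len(population), dtype=int)
        crowd = np.empty(len(population))
        for r, front in enumerate(fronts):
            ranks[front] = r
            front_obj = [objs[i] for i in front]
            cd = crowding_distance(front_obj)
            for pos, i in enumerate(front):
                crowd[i] = cd[pos]

        offspring: list[Individual] = []
        n_immigrants = max(1, int(config.immigrant_fraction
                                  * config.population_size))
        for _ in range(n_immigrants):
            # random immigrants guard against premature convergence
            lo, hi = config.init_depth
            fresh = ex.random_tree(rng, feature_names,
                                   max_depth=int(rng.integers(lo, hi + 1)),
                                   functions=config.functions,
                                   const_range=config.const_range)
            offspring.append(make_individual(fresh, gen))
        while len(offspring) < config.population_size:
            i = _tournament(rng, ranks, crowd, config.tournament_size)
            u = rng.random()
            if u < config.crossover_rate:
                j = _tournament(rng, ranks, crowd, config.tournament_size)
                child = subtree_crossover(rng, population[i].tree,
                                          population[j].tree)
            elif u < config.crossover_rate + config.mutation_rate:
                child = mutate(rng, population[i].tree, feature_names, config)
            else:
                child = population[i].tree.copy()
            if not _within_caps(child, config):
                child = population[i].tree.copy()
            offspring.append(make_individual(child, gen))

        combined = population + offspring
        objs = [i.objectives() for i in combined]
        fronts = non_dominated_sort(objs)
        survivors: list[Individual] = []
        for front in fronts:
            if len(survivors) + len(front) <= config.population_size:
                survivors.extend(combined[i] for i in front)
            else:
                front_obj = [objs[i] for i in front]
                cd = crowding_distance(front_obj)
                order = sorted(range(len(front)), key=lambda p: -cd[p])
                for p in order[: config.population_size - len(survivors)]:
                    survivors.append(combined[front[p]])
                break
        population = survivors
        for ind in offspring:
            archive.add(ind)
        log(gen)

        if config.stagnation_generations is not None:
            best = archive.best_bce()
            stagnant = stagnant + 1 if best >= last_best - 1e-12 else 0
            last_best = min(last_best, best)
            if stagnant >= config.stagnation_generations:
                break

    # champion: best validation BCE; ties -> lower paic, node count, age
    def champion_key(ind: Individual):
        p = ex.sigmoid(np.atleast_1d(np.asarray(
            ex.evaluate(ind.tree, cols_val), dtype=float)))
        if p.shape != y_val.shape:
            p = np.broadcast_to(p, y_val.shape)
        return (binary_cross_entropy(p, y_val), ind.paic, ind.node_count, ind.age)

    champion = min(archive.individuals, key=champion_key)
    return archive, champion, pd.DataFrame(history)


class MOSRClassifier:
    """Thin scikit-learn-style wrapper around :func:`evolve`.

    Lets the symbolic-regression arm flow through the same benchmarking
    harness as the reference classifiers.
    """

    def __init__(self, config: EvolutionConfig | None = None, **overrides):
        base = config or EvolutionConfig()
        if overrides:
            from dataclasses import replace
            base = replace(base, **overrides)
        self.config = base
        self.archive_ = None
        self.champion_ = None
        self.history_ = None

    def get_params(self, deep=False):
        return {"config": self.config}

    def set_params(self, **params):
        if "config" in params:
            self.config = params["config"]
        return self

    def fit(self, X, y):
        self.archive_, self.champion_, self.history_ = evolve(
            X, y, self.config)
        self.feature_names_ = list(_as_frame(X).columns)
        return self

    def predict_proba(self, X):
        X = _as_frame(X)
        cols = {c: X[c].to_numpy(dtype=float) for c in X.columns}
        p = ex.sigmoid(np.atleast_1d(np.asarray(
            ex.evaluate(self.champion_.tree, cols), dtype=float)))
        if p.size == 1 and len(X) > 1:
            p = np.full(len(X), float(p[0]))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    @property
    def formula_(self) -> str:
        return ex.to_formula_text(self.champion_.tree)
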