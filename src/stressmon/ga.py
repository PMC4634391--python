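"""Budget-constrained genetic algorithm for feature selection.

The search minimises the cross-validated mean squared error of a cheap
least-squares linear classifier over feature subsets, subject to the
subset's processing chain costing fewer than ``Nmax`` operations/s.

One run evolves a population of 200 subsets for 100 generations: exact
duplicates are perturbed, over-budget subsets are repaired by random
removal, the best 20 survive and breed the next population by uniform
set-crossover, and each offspring mutates (one member swapped for a
non-member) with probability 10%.  The best individual is never altered
(elitism), so the best fitness is non-increasing over generations.  The
whole run is restarted five times from fresh random populations and the
best final individual wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import linear_fit, one_hot
from .costs import CostModel

__all__ = ["GAConfig", "Individual", "GAResult", "repair", "dedupe",
           "subset_fitness", "evolve"]


class BudgetError(ValueError):
    """The budget admits no single-feature subset."""


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    survivors: int = 20
    mutation_prob: float = 0.10
    generations: int = 100
    restarts: int = 5
    nmax: float = 80_000.0
    init_mean_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.survivors < self.population_size:
            raise ValueError("need 0 < survivors < population_size")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")


@dataclass
class Individual:
    feature_set: frozenset
    fitness: float = float("inf")
    nop: float = float("nan")


@dataclass
class GAResult:
    best: Individual
    fitness_trace: list = field(default_factory=list)   # per restart, per generation
    evaluations: int = 0
    budget_violations: int = 0  # audited after repair; must stay 0


def repair(features: frozenset, cost_model: CostModel, nmax: float,
           catalog_names: list, rng) -> frozenset:
    """Enforce Nop < Nmax by random removal; never return an empty set.

    If removal empties the set, single features are drawn at random until
    one fits the budget.  Raises :class:`BudgetError` when no single
    feature fits.
    """
    fs = set(features)
    while fs and cost_model.total_nop(fs) >= nmax:
        victim = rng.choice(sorted(fs))
        fs.discard(victim)
    if fs:
        return frozenset(fs)
    under = [n for n in catalog_names if cost_model.total_nop([n]) < nmax]
    if not under:
        name, cost = cost_model.cheapest_single()
        raise BudgetError(
            f"budget {nmax} admits no single feature; cheapest is {name} "
            f"at {cost} operations/s")
    return frozenset([rng.choice(under)])


def dedupe(population: list[frozenset], catalog_names: list, rng,
           max_retries: int = 50) -> list[frozenset]:
    """Perturb exact duplicates by swapping one random feature.

    Distinctness is best-effort: if the subset space is too small at the
    current sizes, duplicates may survive after ``max_retries`` attempts.
    """
    seen: set[frozenset] = set()
    out: list[frozenset] = []
    for ind in population:
        cand = ind
        tries = 0
        while cand in seen and tries < max_retries:
            members = sorted(cand)
            non_members = [n for n in catalog_names if n not in cand]
            if not members or not non_members:
                break
            cand = frozenset(set(cand) - {rng.choice(members)}
                             | {rng.choice(non_members)})
            tries += 1
        seen.add(cand)
        out.append(cand)
    return out


def subset_fitness(features, X_cols: dict, labels, subjects, classes,
                   folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Mean over by-subject folds of the linear classifier's held-out MSE."""
    names = sorted(features)
    X = np.column_stack([X_cols[n] for n in names])
    T = one_hot(labels, classes)
    mses = []
    for train_idx, test_idx in folds:
        clf = linear_fit(X[train_idx], T[train_idx], standardize=True)
        mses.append(clf.mse(X[test_idx], T[test_idx]))
    return float(np.mean(mses))


def _make_folds(subjects) -> list[tuple[np.ndarray, np.ndarray]]:
    subjects = np.asarray(subjects)
    folds = []
    for s in np.unique(subjects):
        mask = subjects == s
        folds.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    return folds


def _crossover(a: frozenset, b: frozenset, rng) -> frozenset:
    union = sorted(a | b)
    child = {f for f in union if rng.random() < 0.5}
    if not child:
        child = {rng.choice(union)}
    return frozenset(child)


def _mutate(ind: frozenset, catalog_names: list, rng) -> frozenset:
    members = sorted(ind)
    non_members = [n for n in catalog_names if n not in ind]
    if not members or not non_members:
        return ind
    return frozenset(set(ind) - {rng.choice(members)} | {rng.choice(non_members)})


def evolve(feature_table, labels, subjects, config: GAConfig,
           cost_model: CostModel | None = None,
           catalog_names: list | None = None) -> GAResult:
    """Run the full restarted GA on a feature matrix.

    ``feature_table`` is a DataFrame whose feature columns are catalog
    names; ``labels`` and ``subjects`` align with its rows.  Fitness folds
    (one per design subject) are fixed across generations and fitness
    values are cached per subset.
    """
    cm = cost_model or CostModel()
    if catalog_names is None:
        drop = {"subject_id", "label", "t_start"}
        catalog_names = [c for c in feature_table.columns if c not in drop]
    X_cols = {n: np.asarray(feature_table[n], dtype=float) for n in catalog_names}
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    classes = sorted(set(labels.tolist()))
    folds = _make_folds(subjects)
    if len(folds) < 2:
        raise ValueError("design set must contain at least 2 subjects")

    cache: dict[frozenset, float] = {}
    result = GAResult(best=Individual(frozenset()))
    master = np.random.default_rng(config.seed)

    def evaluate(fs: frozenset) -> float:
        if fs not in cache:
            cache[fs] = subset_fitness(fs, X_cols, labels, subjects, classes, folds)
            result.evaluations += 1
        return cache[fs]

    best_overall: Individual | None = None
    for _ in range(config.restarts):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        pop: list[frozenset] = []
        for _ in range(config.population_size):
            size = max(1, rng.poisson(config.init_mean_size))
            pop.append(frozenset(rng.choice(catalog_names,
                                            size=min(size, len(catalog_names)),
                                            replace=False)))
        trace: list[float] = []
        elite: frozenset | None = None
        for _gen in range(config.generations):
            if elite is not None:
                pop = [elite] + dedupe(pop[1:], catalog_names, rng)
            else:
                pop = dedupe(pop, catalog_names, rng)
            pop = [repair(fs, cm, config.nmax, catalog_names, rng) for fs in pop]
            for fs in pop:
                if cm.total_nop(fs) >= config.nmax:
                    result.budget_violations += 1
            ranked = sorted(pop, key=evaluate)
            survivors = ranked[: config.survivors]
            elite = survivors[0]
            trace.append(cache[elite])
            children = [elite]
            while len(children) < config.population_size:
                pa, pb = rng.choice(config.survivors, size=2)
                child = _crossover(survivors[pa], survivors[pb], rng)
                if rng.random() < config.mutation_prob:
                    child = _mutate(child, catalog_names, rng)
                children.append(child)
            pop = children
        result.fitness_trace.append(trace)
        final_best = Individual(feature_set=elite, fitness=cache[elite],
                                nop=cm.total_nop(elite))
        if best_overall is None or final_best.fitness < best_overall.fitness:
            best_overall = final_best

    result.best = best_overall
    return result
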