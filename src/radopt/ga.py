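"""Simple genetic algorithm over a categorical model-feature space.

The search treats a complete feature assignment (a :class:`Genome`) as an
individual and the ROC AUC of the classifier it specifies as its fitness.
Each generation: every individual is evaluated (cached by genome, so
duplicates cost nothing); the top ``retention_rate`` fraction survives; each
remaining individual is kept anyway with probability ``rejection_keep_prob``
(the "negative rejection" that preserves diversity); the population is then
refilled by breeding — each child copies every axis from one of two distinct
survivor parents with equal probability, and with probability
``mutation_prob`` one uniformly chosen axis is resampled uniformly from the
full axis.

Evaluations are pure functions of ``(genome, eval_seed)`` where the eval seed
derives from the master seed and the genome's stable hash — never from
execution order — so serial and parallel runs produce identical histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .search_space import Genome, SearchSpace, cardinality, random_genome

__all__ = [
    "GAConfig",
    "Individual",
    "GenerationRecord",
    "GAHistory",
    "derive_eval_seed",
    "evaluate_individual",
    "select_survivors",
    "breed",
    "evolve",
    "top_k",
    "explored_fraction",
]

FitnessFn = Callable[[Genome, int], "float | tuple[float, float]"]


@dataclass(frozen=True)
class GAConfig:
    generations: int = 10
    population_size: int = 100
    retention_rate: float = 0.40
    rejection_keep_prob: float = 0.10
    mutation_prob: float = 0.20
    master_seed: int = 0
    max_parallel_evaluations: int = 1
    #: When True, "negative rejection" is read as the probability of dropping
    #: a retained elite instead of keeping a loser (the alternative reading).
    reject_elites: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.retention_rate <= 1:
            raise ValueError("retention_rate must be in (0, 1]")
        for p in (self.rejection_keep_prob, self.mutation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass(frozen=True)
class Individual:
    genome: Genome
    fitness: float
    accuracy: float = float("nan")
    eval_seed: int = 0
    note: str = ""

    def sort_key(self) -> tuple:
        acc = self.accuracy if math.isfinite(self.accuracy) else -1.0
        return (-self.fitness, -acc, self.genome.stable_hash())


@dataclass(frozen=True)
class GenerationRecord:
    index: int
    individuals: tuple[Individual, ...]  # ranked best-first
    best_fitness: float
    mean_fitness: float


@dataclass
class GAHistory:
    records: list[GenerationRecord] = field(default_factory=list)
    evaluations: int = 0  # unique genome evaluations actually performed

    @property
    def best(self) -> Individual:
        return self.records[-1].individuals[0]

    def best_fitness_trace(self) -> list[float]:
        return [r.best_fitness for r in self.records]

    def to_frame(self):
        import pandas as pd

        rows = []
        for rec in self.records:
            for rank, ind in enumerate(rec.individuals):
                row = {
                    "generation": rec.index,
                    "rank": rank,
                    "fitness": ind.fitness,
                    "accuracy": ind.accuracy,
                    "eval_seed": ind.eval_seed,
                }
                row.update(ind.genome.to_dict())
                rows.append(row)
        return pd.DataFrame(rows)


def derive_eval_seed(master_seed: int, genome: Genome) -> int:
    """Per-genome evaluation seed, independent of execution order."""
    return (master_seed * 1_000_003 + genome.stable_hash()) % (2**31)


def evaluate_individual(
    genome: Genome,
    fitness_fn: FitnessFn,
    eval_seed: int,
) -> Individual:
    """Evaluate one genome; a raised evaluation error yields fitness 0 with a
    note rather than aborting the whole search."""
    try:
        result = fitness_fn(genome, eval_seed)
    except Exception as exc:  # noqa: BLE001 - keep the GA alive
        return Individual(
            genome=genome, fitness=0.0, eval_seed=eval_seed, note=f"error: {exc}"
        )
    if isinstance(result, tuple):
        fitness, acc = result
    else:
        fitness, acc = float(result), float("nan")
    if not 0.0 <= fitness <= 1.0:
        raise ValueError(f"fitness must be an AUC in [0, 1], got {fitness}")
    return Individual(genome=genome, fitness=fitness, accuracy=acc, eval_seed=eval_seed)


def select_survivors(
    population: Sequence[Individual],
    retention_rate: float,
    rejection_keep_prob: float,
    rng: np.random.Generator,
    reject_elites: bool = False,
) -> list[Individual]:
    """Ranked survival: keep the top ceil(retention_rate * N); each individual
    below the cut is independently kept with ``rejection_keep_prob``.

    Ties are broken by accuracy then genome hash so the ranking is
    deterministic.  With ``reject_elites`` the probability is instead applied
    to drop individuals above the cut.
    """
    ranked = sorted(population, key=Individual.sort_key)
    n_keep = math.ceil(retention_rate * len(ranked))
    elites, losers = ranked[:n_keep], ranked[n_keep:]
    if reject_elites:
        kept_elites = [e for e in elites if rng.random() >= rejection_keep_prob]
        survivors = kept_elites if kept_elites else elites[:1]
        return survivors + []
    lucky = [l for l in losers if rng.random() < rejection_keep_prob]
    return list(elites) + lucky


def breed(
    mother: Genome,
    father: Genome,
    space: SearchSpace,
    mutation_prob: float,
    rng: np.random.Generator,
) -> Genome:
    """Feature-wise recombination plus optional single-axis mutation."""
    choices = {}
    for ax in space.axes:
        src = mother if rng.random() < 0.5 else father
        choices[ax.name] = src.choices[ax.name]
    if mutation_prob > 0 and rng.random() < mutation_prob:
        ax = space.axes[int(rng.integers(len(space.axes)))]
        choices[ax.name] = ax.labels[int(rng.integers(len(ax)))]
    return Genome(choices)


def _evaluate_population(
    genomes: Sequence[Genome],
    fitness_fn: FitnessFn,
    master_seed: int,
    cache: dict[Genome, Individual],
    n_jobs: int,
) -> list[Individual]:
    todo = []
    seen = set()
    for g in genomes:
        if g not in cache and g not in seen:
            todo.append(g)
            seen.add(g)
    if todo:
        if n_jobs > 1:
            results = Parallel(n_jobs=n_jobs, backend="threading")(
                delayed(evaluate_individual)(
                    g, fitness_fn, derive_eval_seed(master_seed, g)
                )
                for g in todo
            )
        else:
            results = [
                evaluate_individual(g, fitness_fn, derive_eval_seed(master_seed, g))
                for g in todo
            ]
        for ind in results:
            cache[ind.genome] = ind
    return [cache[g] for g in genomes]


def evolve(
    space: SearchSpace,
    config: GAConfig,
    fitness_fn: FitnessFn,
) -> GAHistory:
    """Run the full evolutionary search and return the generation history.

    Generation 0 is sampled uniformly from the space; every later generation
    is survivors plus bred children up to the population size.  Fitness is
    cached by genome, so the number of unique evaluations never exceeds
    generations x population_size.  Best fitness is non-decreasing because the
    ranked elite always survives with its cached fitness.
    """
    rng = np.random.default_rng(config.master_seed)
    population = [
        random_genome(space, rng) for _ in range(config.population_size)
    ]
    cache: dict[Genome, Individual] = {}
    history = GAHistory()

    for gen in range(config.generations):
        individuals = _evaluate_population(
            population,
            fitness_fn,
            config.master_seed,
            cache,
            config.max_parallel_evaluations,
        )
        ranked = tuple(sorted(individuals, key=Individual.sort_key))
        history.records.append(
            GenerationRecord(
                index=gen,
                individuals=ranked,
                best_fitness=ranked[0].fitness,
                mean_fitness=float(np.mean([i.fitness for i in ranked])),
            )
        )
        if gen == config.generations - 1:
            break
        survivors = select_survivors(
            ranked,
            config.retention_rate,
            config.rejection_keep_prob,
            rng,
            reject_elites=config.reject_elites,
        )
        next_pop = [s.genome for s in survivors][: config.population_size]
        while len(next_pop) < config.population_size:
            if len(survivors) >= 2:
                i, j = rng.choice(len(survivors), size=2, replace=False)
                mother, father = survivors[int(i)].genome, survivors[int(j)].genome
            else:
                mother = father = survivors[0].genome
            next_pop.append(
                breed(mother, father, space, config.mutation_prob, rng)
            )
        population = next_pop

    history.evaluations = len(cache)
    return history


def top_k(history: GAHistory, k: int) -> list[Individual]:
    """The k best distinct genomes of the final generation (ties by accuracy,
    then genome hash).  Returns all distinct genomes when fewer than k exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seen: set[Genome] = set()
    distinct = []
    for ind in history.records[-1].individuals:
        if ind.genome not in seen:
            distinct.append(ind)
            seen.add(ind.genome)
    if k > len(distinct):
        import warnings

        warnings.warn(
            f"only {len(distinct)} distinct genomes in the final generation; "
            f"returning all",
            stacklevel=2,
        )
        return distinct
    return distinct[:k]


def explored_fraction(n_evaluations: int, space: SearchSpace) -> float:
    """Fraction of the search space covered by a given evaluation budget."""
    return n_evaluations / cardinality(space)
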