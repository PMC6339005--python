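"""Genetic-algorithm channel selection wrapped around HDCA (GA-HDCA).

Each chromosome is a binary mask over the montage (length 16 by default):
bit i set means channel i enters the classifier.  Fitness is the
cross-validated HDCA accuracy restricted to the masked channels, with the
fold assignment frozen per run so fitness is a deterministic, cacheable
function of the mask.  Evolution uses tournament selection (size 2),
single-point crossover with probability 0.85, per-individual single-bit
mutation with probability 0.1, and one-elite carryover; the loop stops at a
generation cap or after a stall window without fitness improvement.  Ties in
fitness are broken toward fewer selected channels, favouring sparser (more
practical) montages.

Fitness evaluations of distinct masks are independent and may run on worker
processes; results are identical to sequential execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from . import evaluate, hdca
from .preprocess import EpochSet


@dataclass
class Chromosome:
    """Binary channel mask with its (lazily evaluated) CV-accuracy fitness."""

    mask: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 1 or self.mask.size < 1:
            raise ValueError("mask must be a non-empty binary vector")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "Chromosome":
        return Chromosome(self.mask.copy(), self.fitness)


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; population size and operator rates follow the
    protocol (100 individuals, crossover 0.85, mutation 0.1), the rest are
    documented implementation defaults."""

    pop_size: int = 100
    p_crossover: float = 0.85
    p_mutation: float = 0.1
    max_generations: int = 50
    stall_generations: int = 10
    elitism: int = 1
    seed: int = 0
    cv_folds: int = 5
    n_workers: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_crossover <= 1.0 and 0.0 <= self.p_mutation <= 1.0):
            raise ValueError("operator probabilities must lie in [0, 1]")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.elitism < 0 or self.elitism >= self.pop_size:
            raise ValueError("elitism must be in [0, pop_size)")


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All-zero masks are invalid; set one random bit instead of penalising."""
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(0, mask.size)] = True
    return mask


def init_population(config: GAConfig, n_channels: int = 16,
                    rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Random initial population: i.i.d. Bernoulli(0.5) bits, repaired."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [Chromosome(_repair(rng.random(n_channels) < 0.5, rng))
            for _ in range(config.pop_size)]


def fitness(chromosome: Chromosome | np.ndarray, feats: np.ndarray,
            labels: np.ndarray, folds: list,
            cache: dict | None = None) -> float:
    """CV accuracy of HDCA restricted to the masked channels.

    ``feats`` are full-montage window features (trials × windows × channels)
    computed once per run; ``folds`` is the frozen fold assignment shared by
    every chromosome so fitness is deterministic and cacheable by mask.
    """
    mask = chromosome.mask if isinstance(chromosome, Chromosome) else np.asarray(chromosome, bool)
    if not mask.any():
        raise ValueError("empty channel mask")
    key = mask.tobytes()
    if cache is not None and key in cache:
        value = cache[key]
    else:
        value = evaluate.cv_accuracy(feats, labels, folds, mask)
        if cache is not None:
            cache[key] = value
    if isinstance(chromosome, Chromosome):
        chromosome.fitness = value
    return value


def _better(a: Chromosome, b: Chromosome) -> bool:
    """True when ``a`` beats ``b``: higher fitness, ties to fewer channels."""
    if a.fitness != b.fitness:
        return a.fitness > b.fitness
    return a.n_selected < b.n_selected


def select(population: list[Chromosome], rng: np.random.Generator,
           n_parents: int | None = None, tournament_size: int = 2) -> list[Chromosome]:
    """Tournament selection with replacement; the fitter entrant wins."""
    if any(c.fitness is None for c in population):
        raise ValueError("population must be fully evaluated before selection")
    if n_parents is None:
        n_parents = len(population)
    parents = []
    for _ in range(n_parents):
        entrants = rng.integers(0, len(population), size=tournament_size)
        best = population[entrants[0]]
        for j in entrants[1:]:
            if _better(population[j], best):
                best = population[j]
        parents.append(best)
    return parents


def crossover(parent_a: Chromosome, parent_b: Chromosome, p: float = 0.85,
              rng: np.random.Generator | None = None) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover with probability ``p``, else parent copies."""
    if parent_a.mask.size != parent_b.mask.size:
        raise ValueError("parent masks must have equal length")
    if rng is None:
        rng = np.random.default_rng()
    if rng.random() >= p:
        return Chromosome(parent_a.mask.copy()), Chromosome(parent_b.mask.copy())
    cut = int(rng.integers(1, parent_a.mask.size))
    return (_cross_at(parent_a.mask, parent_b.mask, cut),
            _cross_at(parent_b.mask, parent_a.mask, cut))


def _cross_at(head: np.ndarray, tail: np.ndarray, cut: int) -> Chromosome:
    return Chromosome(np.concatenate([head[:cut], tail[cut:]]))


def mutate(chromosome: Chromosome, p: float = 0.1,
           rng: np.random.Generator | None = None) -> Chromosome:
    """With probability ``p`` per individual, flip one uniform bit; repair."""
    if rng is None:
        rng = np.random.default_rng()
    mask = chromosome.mask.copy()
    if rng.random() < p:
        bit = int(rng.integers(0, mask.size))
        mask[bit] = ~mask[bit]
    return Chromosome(_repair(mask, rng))


def _evaluate_population(population: list[Chromosome], feats, labels, folds,
                         cache: dict, n_workers: int) -> None:
    """Fill in missing fitness values, optionally on parallel workers."""
    pending = {}
    for c in population:
        key = c.mask.tobytes()
        if key in cache:
            c.fitness = cache[key]
        elif key not in pending:
            pending[key] = c.mask.copy()
    if pending:
        keys = list(pending)
        if n_workers > 1:
            values = Parallel(n_jobs=n_workers)(
                delayed(evaluate.cv_accuracy)(feats, labels, folds, pending[k])
                for k in keys)
        else:
            values = [evaluate.cv_accuracy(feats, labels, folds, pending[k])
                      for k in keys]
        cache.update(zip(keys, values))
        for c in population:
            if c.fitness is None:
                c.fitness = cache[c.mask.tobytes()]


def run_ga(epochs: EpochSet, labels: np.ndarray | None = None,
           config: GAConfig | None = None,
           windows: hdca.WindowingScheme | None = None,
           ) -> tuple[Chromosome, dict]:
    """Evolve a channel mask maximising cross-validated HDCA accuracy.

    Returns the best-ever chromosome and a history dict with per-generation
    ``best`` and ``mean`` fitness traces (the best trace is non-decreasing
    by elitism) plus the number of distinct masks evaluated.
    """
    if config is None:
        config = GAConfig()
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels, int)
    if windows is None:
        windows = hdca.WindowingScheme.tile(epochs.n_times, epochs.fs)
    feats = hdca.window_features(epochs.data, windows)

    ss = np.random.SeedSequence(config.seed)
    s_pop, s_evo, s_folds = ss.spawn(3)
    rng = np.random.default_rng(s_evo)
    fold_seed = int(s_folds.generate_state(1)[0] % (2**31))
    folds = evaluate.make_folds(labels, config.cv_folds, seed=fold_seed)
    cache: dict = {}

    population = init_population(config, epochs.n_channels,
                                 np.random.default_rng(s_pop))
    best: Chromosome | None = None
    history = {"best": [], "mean": []}
    stall = 0
    for _generation in range(config.max_generations):
        _evaluate_population(population, feats, labels, folds, cache,
                             config.n_workers)
        gen_best = population[0]
        for c in population[1:]:
            if _better(c, gen_best):
                gen_best = c
        if best is None or _better(gen_best, best):
            improved = best is None or gen_best.fitness > best.fitness
            best = gen_best.copy()
            stall = 0 if improved else stall + 1
        else:
            stall += 1
        history["best"].append(best.fitness)
        history["mean"].append(float(np.mean([c.fitness for c in population])))
        assert all(b2 >= b1 for b1, b2 in zip(history["best"], history["best"][1:]))
        if stall >= config.stall_generations:
            break

        offspring: list[Chromosome] = [best.copy() for _ in range(config.elitism)]
        parents = select(population, rng, n_parents=config.pop_size)
        k = 0
        while len(offspring) < config.pop_size:
            pa, pb = parents[k % len(parents)], parents[(k + 1) % len(parents)]
            k += 2
            ca, cb = crossover(pa, pb, config.p_crossover, rng)
            offspring.append(mutate(ca, config.p_mutation, rng))
            if len(offspring) < config.pop_size:
                offspring.append(mutate(cb, config.p_mutation, rng))
        population = offspring

    history["n_masks_evaluated"] = len(cache)
    history["fold_seed"] = fold_seed
    return best, history


def exhaustive_best(epochs: EpochSet, labels: np.ndarray | None = None,
                    cv_folds: int = 5, fold_seed: int = 0,
                    windows: hdca.WindowingScheme | None = None) -> Chromosome:
    """Brute-force optimum over every non-empty mask (small montages only).

    Independent oracle for GA correctness checks; infeasible beyond ~10
    channels.
    """
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels, int)
    if windows is None:
        windows = hdca.WindowingScheme.tile(epochs.n_times, epochs.fs)
    n = epochs.n_channels
    if n > 12:
        raise ValueError("exhaustive search is limited to small montages")
    feats = hdca.window_features(epochs.data, windows)
    folds = evaluate.make_folds(labels, cv_folds, seed=fold_seed)
    best = None
    for code in range(1, 2 ** n):
        mask = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        c = Chromosome(mask, evaluate.cv_accuracy(feats, labels, folds, mask))
        if best is None or _better(c, best):
            best = c
    return best
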