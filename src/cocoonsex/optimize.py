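"""Hyperparameter optimization: grid search, classical GA, and TLBPSGA.

The boosted-tree classifier's seven hyperparameters (learning rate,
n_estimators, max_depth, min_child_weight, gamma, subsample,
colsample_bytree) are searched over a bounded space.  Chromosomes are
vectors of normalized genes in [0, 1]; decoding maps affinely (log-affinely
for the learning rate) into the bounds, rounding integer dimensions half-up.
Fitness is the mean stratified-CV accuracy of the decoded model, memoized
per decoded point.

Three optimizers share the GAResult contract:

* exhaustive grid search over a per-dimension lattice;
* a classical generational GA — fitness-proportional parent selection,
  single-point crossover applied with a probability that rises linearly
  from R_min to R_max over the generations, per-gene uniform mutation
  (gene resampled ~ U[0,1]), and elitism;
* TLBPSGA — the same genetic loop, but the random initial population is
  first refined by a teaching-learning-based optimization (TLBO) pass that
  whittles it down (e.g. 100 -> 50) toward fitter individuals, parents come
  from tournament selection, and one TLBO pass re-refines the population
  each generation.  The TLBO teacher phase moves every learner toward the
  best individual minus a teaching-factor-scaled population mean
  (TF drawn from {1, 2}); the learner phase moves each learner toward a
  fitter random partner or away from a less fit one, accepting updates on
  improvement only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Dim:
    """One bounded search dimension."""

    name: str
    low: float
    high: float
    kind: str = "float"  # "float" | "int"
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError(f"{self.name}: bounds must be finite")
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log scale needs positive bounds")

    def decode(self, gene: float) -> float | int:
        g = min(max(float(gene), 0.0), 1.0)
        if self.scale == "log":
            value = self.low * (self.high / self.low) ** g
        else:
            value = self.low + (self.high - self.low) * g
        if self.kind == "int":
            return int(np.floor(value + 0.5))  # round half-up
        return float(value)

    def encode(self, value: float) -> float:
        if self.scale == "log":
            return float(np.log(value / self.low) / np.log(self.high / self.low))
        return float((value - self.low) / (self.high - self.low))


@dataclass(frozen=True)
class HyperParamSpace:
    dims: tuple[Dim, ...]

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def decode(self, genes: np.ndarray) -> dict:
        genes = np.asarray(genes, dtype=float)
        if np.any(genes < 0) or np.any(genes > 1):
            import warnings

            warnings.warn("genes outside [0,1] clipped during decode", stacklevel=2)
        return {d.name: d.decode(g) for d, g in zip(self.dims, genes)}

    def encode(self, params: dict) -> np.ndarray:
        return np.array([d.encode(params[d.name]) for d in self.dims])


def default_space() -> HyperParamSpace:
    """Standard tuning ranges for the seven boosted-tree hyperparameters."""
    return HyperParamSpace(
        dims=(
            Dim("learning_rate", 0.01, 0.3, "float", "log"),
            Dim("n_estimators", 50, 500, "int"),
            Dim("max_depth", 3, 10, "int"),
            Dim("min_child_weight", 1.0, 10.0, "float"),
            Dim("gamma", 0.0, 5.0, "float"),
            Dim("subsample", 0.5, 1.0, "float"),
            Dim("colsample_bytree", 0.5, 1.0, "float"),
        )
    )


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    refined_size: int = 50
    generations: int = 100
    r_min: float = 0.6
    r_max: float = 0.95
    mutation_rate: float = 0.1
    tournament_k: int = 3
    elitism: int = 1
    stagnation_window: int = 25
    refine_each_generation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refined_size > self.population_size:
            raise ValueError("refined_size must be <= population_size")
        for r in (self.r_min, self.r_max, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class GAResult:
    """Best point found plus the optimizer's trajectory."""

    best_genes: np.ndarray
    best_params: dict
    best_fitness: float
    trajectory: np.ndarray  # best-so-far fitness per generation
    first_attained: int  # generation index where best fitness first reached
    n_evaluations: int


def first_hitting_generation(trajectory: np.ndarray, target: float) -> int | None:
    """First generation whose best-so-far fitness reaches ``target``.

    The convergence-speed comparison between optimizers uses a common target
    level: on continuous fitness landscapes an elitist optimizer keeps
    polishing its best by float-epsilon amounts, so the generation where the
    *final* best value was attained (GAResult.first_attained) measures
    polishing, not convergence.  Returns None when the target is never hit.
    """
    idx = np.nonzero(np.asarray(trajectory) >= target)[0]
    return int(idx[0]) if len(idx) else None


def crossover_rate(g: int, config: GAConfig) -> float:
    """Crossover probability rising linearly with the generation count.

    R(g) = R_min + (R_max - R_min) * g / G: low early to preserve good
    schemata while the population is diverse, high late to recombine the
    converged population.
    """
    if not 0 <= g <= config.generations:
        raise ValueError(f"generation {g} outside [0, {config.generations}]")
    frac = g / config.generations if config.generations else 1.0
    return config.r_min + (config.r_max - config.r_min) * frac


def single_point_crossover(
    a: np.ndarray, b: np.ndarray, point: int
) -> tuple[np.ndarray, np.ndarray]:
    """Swap gene tails after ``point`` (1 <= point <= len-1)."""
    child1 = np.concatenate([a[:point], b[point:]])
    child2 = np.concatenate([b[:point], a[point:]])
    return child1, child2


def _mutate(genes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = genes.copy()
    mask = rng.random(len(genes)) < rate
    out[mask] = rng.random(int(mask.sum()))
    return out


def tournament_select(
    population: np.ndarray, fitnesses: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Return the fittest of k individuals sampled without replacement."""
    if k > len(population):
        raise ValueError(f"tournament size {k} exceeds population {len(population)}")
    idx = rng.choice(len(population), size=k, replace=False)
    return population[idx[np.argmax(fitnesses[idx])]].copy()


def _roulette_select(
    population: np.ndarray, fitnesses: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    # shift so weights are positive even for negative fitness landscapes
    w = fitnesses - fitnesses.min() + 1e-12
    p = w / w.sum()
    return population[rng.choice(len(population), p=p)].copy()


class _CountingFitness:
    def __init__(self, fn):
        self.fn = fn
        self.count = 0

    def __call__(self, genes: np.ndarray) -> float:
        self.count += 1
        return float(self.fn(genes))


def make_cv_fitness(X, y, space: HyperParamSpace, k: int = 10, seed: int = 0):
    """Fitness = mean stratified-CV accuracy of the decoded boosted-tree model.

    Memoized on the decoded hyperparameter tuple, so re-visiting a point is
    free and returns the identical value.  A model-training failure scores 0.
    """
    from .classify import ClassifierSpec, stratified_cv

    cache: dict[tuple, float] = {}

    def fitness(genes: np.ndarray) -> float:
        params = space.decode(genes)
        key = tuple(sorted(params.items()))
        if key not in cache:
            try:
                report, _, _ = stratified_cv(
                    ClassifierSpec("xgboost", params), X, y, k=k, seed=seed
                )
                cache[key] = report.accuracy
            except ValueError:
                raise
            except Exception:  # model-training failure -> worst fitness
                cache[key] = 0.0
        return cache[key]

    return fitness


def grid_search(
    space: HyperParamSpace,
    grid_sizes: list[int] | tuple[int, ...],
    fitness,
    budget: int = 100_000,
) -> GAResult:
    """Exhaustively evaluate the Cartesian product of per-dimension lattices.

    Each dimension gets ``grid_sizes[i]`` equally spaced normalized genes in
    [0, 1].  Ties on fitness resolve to the first cell in lexicographic
    order.  Refuses grids beyond ``budget`` cells.
    """
    if len(grid_sizes) != space.n_dims:
        raise ValueError(
            f"need {space.n_dims} grid sizes, got {len(grid_sizes)}"
        )
    total = int(np.prod(grid_sizes))
    if total > budget:
        raise ValueError(f"grid has {total} cells, exceeding budget {budget}")
    axes = [
        np.linspace(0.0, 1.0, s) if s > 1 else np.array([0.5]) for s in grid_sizes
    ]
    counting = _CountingFitness(fitness)
    best_genes, best_fit = None, -np.inf
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    for genes in points:
        f = counting(genes)
        if f > best_fit:  # strict: first lexicographic cell wins ties
            best_fit, best_genes = f, genes.copy()
    return GAResult(
        best_genes=best_genes,
        best_params=space.decode(best_genes),
        best_fitness=best_fit,
        trajectory=np.array([best_fit]),
        first_attained=0,
        n_evaluations=counting.count,
    )


def _evolve_loop(
    space: HyperParamSpace,
    config: GAConfig,
    population: np.ndarray,
    fitnesses: np.ndarray,
    select,
    counting: _CountingFitness,
    refine: bool,
    rng: np.random.Generator,
) -> GAResult:
    """Shared generational loop for the classical GA and TLBPSGA."""
    pop_size = len(population)
    best_i = int(np.argmax(fitnesses))
    best_genes = population[best_i].copy()
    best_fit = float(fitnesses[best_i])
    trajectory = [best_fit]
    first_attained = 0
    since_improvement = 0
    for g in range(1, config.generations + 1):
        r = crossover_rate(g, config)
        elite_order = np.argsort(-fitnesses)
        next_pop = [population[i].copy() for i in elite_order[: config.elitism]]
        while len(next_pop) < pop_size:
            p1 = select(population, fitnesses, rng)
            p2 = select(population, fitnesses, rng)
            if rng.random() < r and space.n_dims > 1:
                point = int(rng.integers(1, space.n_dims))
                c1, c2 = single_point_crossover(p1, p2, point)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if len(next_pop) < pop_size:
                    next_pop.append(_mutate(child, config.mutation_rate, rng))
        population = np.array(next_pop)
        fitnesses = np.array([counting(ind) for ind in population])
        if refine:
            population, fitnesses = tlbo_refine(
                population, fitnesses, counting, len(population), rng
            )
        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best_fit:
            best_fit = float(fitnesses[gen_best])
            best_genes = population[gen_best].copy()
            first_attained = g
            since_improvement = 0
        else:
            since_improvement += 1
        trajectory.append(best_fit)
        if config.stagnation_window and since_improvement >= config.stagnation_window:
            break
    return GAResult(
        best_genes=best_genes,
        best_params=space.decode(best_genes),
        best_fitness=best_fit,
        trajectory=np.array(trajectory),
        first_attained=first_attained,
        n_evaluations=counting.count,
    )


def classical_ga(space: HyperParamSpace, fitness, config: GAConfig) -> GAResult:
    """Classical generational GA with fitness-proportional selection."""
    rng = np.random.default_rng(config.seed)
    counting = _CountingFitness(fitness)
    population = rng.random((config.population_size, space.n_dims))
    fitnesses = np.array([counting(ind) for ind in population])
    cfg = dataclasses.replace(config, stagnation_window=0)
    return _evolve_loop(
        space, cfg, population, fitnesses,
        _roulette_select, counting, refine=False, rng=rng,
    )


def tlbo_refine(
    population: np.ndarray,
    fitnesses: np.ndarray,
    fitness,
    refined_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One teaching-learning pass, then truncation to the fittest individuals.

    Teaching phase: each learner moves toward the teacher minus a
    TF-scaled population mean (TF = round(1 + U(0,1)) in {1, 2}), the update
    accepted on improvement; a learner that surpasses the teacher becomes
    the teacher.  Learner phase: each learner is paired with a random other
    and moves toward it if fitter, away otherwise, again greedily accepted.
    """
    population = np.asarray(population, dtype=float)
    n, d = population.shape
    if n < 2:
        raise ValueError("population must have at least 2 individuals")
    if refined_size > n:
        raise ValueError(f"refined_size {refined_size} exceeds population {n}")
    pop = population.copy()
    fits = np.asarray(fitnesses, dtype=float).copy()
    teacher = int(np.argmax(fits))
    # teaching phase
    mean = pop.mean(axis=0)
    for i in range(n):
        if i == teacher:
            continue
        tf = int(np.floor(1.0 + rng.random() + 0.5))  # round(1 + U(0,1)) in {1,2}
        new = pop[i] + rng.random(d) * (pop[teacher] - tf * mean)
        new = np.clip(new, 0.0, 1.0)
        f_new = fitness(new)
        if f_new > fits[i]:
            pop[i], fits[i] = new, f_new
            if f_new > fits[teacher]:
                teacher = i
    # learner phase
    for i in range(n):
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1  # a random OTHER learner
        if fits[j] > fits[i]:
            new = pop[i] + rng.random(d) * (pop[j] - pop[i])
        else:
            new = pop[i] + rng.random(d) * (pop[i] - pop[j])
        new = np.clip(new, 0.0, 1.0)
        f_new = fitness(new)
        if f_new > fits[i]:
            pop[i], fits[i] = new, f_new
    keep = np.argsort(-fits)[:refined_size]
    return pop[keep], fits[keep]


def tlbpsga(space: HyperParamSpace, fitness, config: GAConfig) -> GAResult:
    """Teaching-learning-based population selection genetic algorithm.

    A random population of ``population_size`` is TLBO-refined down to
    ``refined_size`` fitter individuals before the genetic loop; parents are
    then drawn by tournament selection, and (by default) each generation's
    population receives one further TLBO pass.  Stops early after
    ``stagnation_window`` generations without improvement.
    """
    rng = np.random.default_rng(config.seed)
    counting = _CountingFitness(fitness)
    population = rng.random((config.population_size, space.n_dims))
    fitnesses = np.array([counting(ind) for ind in population])
    population, fitnesses = tlbo_refine(
        population, fitnesses, counting, config.refined_size, rng
    )

    def select(pop, fits, rng_):
        return tournament_select(pop, fits, config.tournament_k, rng_)

    return _evolve_loop(
        space, config, population, fitnesses,
        select, counting, refine=config.refine_each_generation, rng=rng,
    )
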