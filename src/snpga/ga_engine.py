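"""Steady-state elitist genetic algorithm over SNP-combination models.

Each generation evaluates the population, deterministically selects the two
highest-fitness chromosomes as parents, applies uniform crossover with a
fair per-position binary mask, mutates each offspring position independently
with the configured rate, and lets each offspring replace the current worst
population member when strictly fitter.  Offspring that duplicate a SNP are
kept and scored 0 rather than repaired.  The best-so-far fitness history is
therefore non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_data import GenotypeDataset
from .model_space import FitnessValue, SNPModel, fitness, is_valid_model

__all__ = [
    "GAParams",
    "GAResult",
    "initialize_population",
    "select_parents",
    "uniform_crossover",
    "mutate",
    "replace",
    "run_ga",
]


@dataclass
class GAParams:
    """Search configuration; defaults follow the reference settings
    (population 50, 100 generations, per-position mutation rate 0.1,
    crossover/selection exchange probabilities 1.0)."""

    order: int = 2
    population_size: int = 50
    generations: int = 100
    mutation_rate: float = 0.1
    crossover_exchange_prob: float = 1.0
    selection_exchange_prob: float = 1.0
    top_k: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("mutation_rate", "crossover_exchange_prob",
                     "selection_exchange_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class GAResult:
    best_model: SNPModel
    best_fitness: FitnessValue
    top_k: list[tuple[SNPModel, FitnessValue]]
    history: list[float]
    evaluations: int
    params: GAParams
    seed: int | None = None


def initialize_population(
    params: GAParams,
    n_snps: int,
    n_genotypes: int,
    rng: np.random.Generator,
) -> list[SNPModel]:
    """Uniform random valid models: distinct SNPs drawn without replacement
    (order preserved as drawn), genotype codes uniform."""
    if params.order > n_snps:
        raise ValueError(f"order {params.order} exceeds {n_snps} SNPs")
    population = []
    for _ in range(params.population_size):
        snps = rng.choice(n_snps, size=params.order, replace=False)
        codes = rng.integers(1, n_genotypes + 1, size=params.order)
        population.append(SNPModel(zip(snps, codes)))
    return population


def select_parents(
    population: list[SNPModel], fitnesses: list[FitnessValue]
) -> tuple[SNPModel, SNPModel]:
    """The two highest-fitness chromosomes; ties broken by population index."""
    if len(population) < 2:
        raise ValueError("population must contain at least 2 chromosomes")
    ranked = sorted(range(len(population)), key=lambda i: (-fitnesses[i].value, i))
    return population[ranked[0]], population[ranked[1]]


def uniform_crossover(
    parent1: SNPModel,
    parent2: SNPModel,
    rng: np.random.Generator | None = None,
    *,
    mask=None,
) -> tuple[SNPModel, SNPModel]:
    """Swap elements between parents wherever the binary mask is 1.

    The mask is a fair coin per position unless given explicitly.  Offspring
    may repeat a SNP; such models are legal chromosomes with fitness 0.
    """
    if parent1.order != parent2.order:
        raise ValueError("parents must have equal order")
    if mask is None:
        if rng is None:
            raise ValueError("either rng or mask is required")
        mask = rng.integers(0, 2, size=parent1.order)
    mask = list(mask)
    if len(mask) != parent1.order:
        raise ValueError("mask length must equal parent order")
    e1 = list(parent1.elements)
    e2 = list(parent2.elements)
    for j, bit in enumerate(mask):
        if bit:
            e1[j], e2[j] = e2[j], e1[j]
    return SNPModel(e1), SNPModel(e2)


def mutate(
    offspring: SNPModel,
    rng: np.random.Generator,
    mutation_rate: float,
    n_snps: int,
    n_genotypes: int,
    *,
    mask=None,
) -> SNPModel:
    """One-point mutation applied independently per position.

    A mutating position is replaced by a (SNP, genotype) pair drawn
    uniformly from the pairs whose SNP is unused at every *other* position
    (the position's own current SNP stays eligible).
    """
    if mask is None:
        mask = rng.random(offspring.order) < mutation_rate
    mask = list(mask)
    if len(mask) != offspring.order:
        raise ValueError("mask length must equal chromosome order")
    elements = list(offspring.elements)
    for j, bit in enumerate(mask):
        if not bit:
            continue
        used_elsewhere = {s for i, (s, _) in enumerate(elements) if i != j}
        eligible_snps = [s for s in range(n_snps) if s not in used_elsewhere]
        if not eligible_snps:
            raise ValueError("no eligible replacement element for mutation")
        pool = [(s, g) for s in eligible_snps for g in range(1, n_genotypes + 1)]
        elements[j] = pool[rng.integers(len(pool))]
    return SNPModel(elements)


def replace(
    population: list[SNPModel],
    fitnesses: list[FitnessValue],
    offspring: list[SNPModel],
    offspring_fitnesses: list[FitnessValue],
) -> tuple[list[SNPModel], list[FitnessValue]]:
    """Each offspring in turn replaces the current worst member if strictly
    fitter than it; otherwise the offspring is discarded.  Population size
    is invariant and the best member can never be displaced."""
    population = list(population)
    fitnesses = list(fitnesses)
    for child, child_fit in zip(offspring, offspring_fitnesses):
        worst = min(range(len(population)), key=lambda i: fitnesses[i].value)
        if child_fit.value > fitnesses[worst].value:
            population[worst] = child
            fitnesses[worst] = child_fit
    return population, fitnesses


def run_ga(dataset: GenotypeDataset, params: GAParams) -> GAResult:
    """Run the full search; fully deterministic given ``params.seed``."""
    if params.order > dataset.n_snps:
        raise ValueError(
            f"order {params.order} exceeds dataset's {dataset.n_snps} SNPs"
        )
    rng = np.random.default_rng(params.seed)
    g = dataset.n_genotypes
    evaluations = 0

    def evaluate(model: SNPModel) -> FitnessValue:
        nonlocal evaluations
        evaluations += 1
        return fitness(model, dataset)

    seen: dict[SNPModel, FitnessValue] = {}

    def record(model: SNPModel, fit: FitnessValue) -> None:
        if is_valid_model(model):
            seen.setdefault(model.canonical(), fit)

    population = initialize_population(params, dataset.n_snps, g, rng)
    fitnesses = [evaluate(m) for m in population]
    for m, f in zip(population, fitnesses):
        record(m, f)

    history: list[float] = []
    best = max(f.value for f in fitnesses)
    for _ in range(params.generations):
        p1, p2 = select_parents(population, fitnesses)
        c1, c2 = uniform_crossover(p1, p2, rng)
        children = [
            mutate(c, rng, params.mutation_rate, dataset.n_snps, g)
            for c in (c1, c2)
        ]
        child_fits = [evaluate(c) for c in children]
        for m, f in zip(children, child_fits):
            record(m, f)
        population, fitnesses = replace(population, fitnesses, children, child_fits)
        best = max(best, max(f.value for f in fitnesses))
        history.append(best)

    ranked = sorted(seen.items(), key=lambda kv: -kv[1].value)
    best_model, best_fit = ranked[0]
    return GAResult(
        best_model=best_model,
        best_fitness=best_fit,
        top_k=ranked[: params.top_k],
        history=history,
        evaluations=evaluations,
        params=params,
        seed=params.seed,
    )
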