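"""Genetic-algorithm feature selection with a scatter-based separability fitness.

The fitness of a feature subset is the average squared Euclidean
distance between samples of the (binary) weed/rice classes, which is
algebraically identical to the prior-weighted sum of the within-class
scatter and the squared displacement of each class mean from the grand
mean:

    J(mask) = Σ_i P_i [ (1/n_i) Σ_k ‖x_k − m_i‖² + ‖m_i − m‖² ]

restricted to the masked feature columns, with P_i = n_i/n and
m = Σ_i P_i m_i.  Because squared Euclidean distance is additive over
dimensions, J decomposes into per-feature contributions; the GA
evaluates masks through that decomposition (one moment pass, then O(D)
per chromosome) while the direct pairwise form serves as an independent
oracle in the tests.

The GA itself is the classic binary-chromosome machinery:
fitness-proportional (roulette) parent selection, single-point crossover,
per-bit flip mutation, and one elite carried over each generation.
Repeated runs are aggregated by counting, per feature, the generations
whose best chromosome included it; the most frequently occurring
features form the selected subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .features import FEATURE_LETTERS
from .signals import RICE_CLASSES

__all__ = [
    "GAConfig",
    "GARun",
    "binary_classes",
    "per_feature_contributions",
    "fitness_scatter",
    "fitness_pairwise",
    "run_ga",
    "aggregate_and_select",
    "select_features",
]

N_FEATURES = len(FEATURE_LETTERS)


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters (defaults follow the study's settings)."""

    crossover_probability: float = 0.8
    mutation_probability: float = 0.01
    population_size: int = 500
    generations: int = 500
    runs: int = 5
    elitism: int = 1
    #: Relative parsimony margin used only when naming each generation's
    #: champion: a feature must contribute more than this fraction of the
    #: best raw fitness to justify its inclusion.  The scatter criterion
    #: is monotone under mask growth, so without a margin the occurrence
    #: counts would saturate at the full mask; the margin implements the
    #: subset-selection intent (d < D) without constraining evolution.
    champion_parsimony: float = 1e-3

    def __post_init__(self) -> None:
        for p in (self.crossover_probability, self.mutation_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 1 or self.generations < 1 or self.runs < 1:
            raise ValueError("population, generations and runs must be >= 1")
        if self.elitism < 0 or self.elitism > self.population_size:
            raise ValueError("elitism must lie in [0, population_size]")


@dataclass
class GARun:
    """Trajectory of one GA run.

    ``best_fitness`` tracks the elite (best raw fitness found so far,
    non-decreasing under elitism).  ``best_bits`` holds each
    generation's champion — the fittest chromosome under the
    parsimony-adjusted score — whose per-feature membership is
    accumulated into ``frequency``.  The two are distinguished because
    the raw scatter fitness is monotone under mask inclusion (every
    feature contributes non-negatively), so the elite drifts towards
    the full mask; the champion keeps only the features that earn their
    fitness share, which is what the occurrence counts expose.
    """

    best_bits: np.ndarray          # (generations, D) champion chromosome per generation
    best_fitness: np.ndarray       # (generations,) elite fitness, non-decreasing
    frequency: np.ndarray          # (D,) generations whose champion includes the feature
    elite_bits: np.ndarray = None  # best chromosome found over the whole run

    @property
    def final_best(self) -> np.ndarray:
        return self.best_bits[-1]


def binary_classes(class_labels: Sequence[str]) -> np.ndarray:
    """Collapse contact types A–D to the two task classes (0 weed, 1 rice)."""
    return np.array([1 if c in RICE_CLASSES else 0 for c in class_labels])


def _validate(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2:
        raise ValueError("feature table must be 2-D (samples × features)")
    if len(y) != X.shape[0]:
        raise ValueError("labels and feature table lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("separability fitness needs at least two classes")


def per_feature_contributions(X, class_labels) -> np.ndarray:
    """Per-feature terms of the separability criterion.

    Returns an array ``f`` of length D such that the fitness of any mask
    is ``f[mask].sum()``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(class_labels)
    _validate(X, y)
    n = X.shape[0]
    classes = np.unique(y)
    priors = np.array([(y == c).sum() / n for c in classes])
    class_means = np.stack([X[y == c].mean(axis=0) for c in classes])
    grand_mean = priors @ class_means
    contrib = np.zeros(X.shape[1])
    for c, p, m_i in zip(classes, priors, class_means):
        within = ((X[y == c] - m_i) ** 2).mean(axis=0)
        between = (m_i - grand_mean) ** 2
        contrib += p * (within + between)
    return contrib


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask must select at least one feature")
    return m


def fitness_scatter(X, class_labels, mask) -> float:
    """Within-plus-between scatter fitness of a feature mask."""
    return float(per_feature_contributions(X, class_labels)[_as_mask(mask)].sum())


def fitness_pairwise(X, class_labels, mask) -> float:
    """Direct average-pairwise-squared-distance form of the fitness.

    Quadratic in the number of samples; used as the brute-force oracle
    for :func:`fitness_scatter`.
    """
    X = np.asarray(X, dtype=float)[:, _as_mask(mask)]
    y = np.asarray(class_labels)
    _validate(X, y)
    n = X.shape[0]
    classes = np.unique(y)
    total = 0.0
    for ci in classes:
        Xi = X[y == ci]
        pi = Xi.shape[0] / n
        for cj in classes:
            Xj = X[y == cj]
            pj = Xj.shape[0] / n
            d2 = ((Xi[:, None, :] - Xj[None, :, :]) ** 2).sum(axis=2)
            total += pi * pj * d2.mean()
    return 0.5 * total


# ---------------------------------------------------------------------------
# The GA
# ---------------------------------------------------------------------------

def _repair_empty(pop: np.ndarray, rng: np.random.Generator) -> None:
    empty = ~pop.any(axis=1)
    if empty.any():
        cols = rng.integers(0, pop.shape[1], size=int(empty.sum()))
        pop[np.flatnonzero(empty), cols] = True


def _roulette(fitness: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    total = fitness.sum()
    if total <= 0:
        probs = np.full(fitness.size, 1.0 / fitness.size)
    else:
        probs = fitness / total
    return rng.choice(fitness.size, size=size, p=probs)


def run_ga(
    X,
    class_labels,
    config: GAConfig = GAConfig(),
    seed: int = 0,
) -> GARun:
    """Evolve feature masks for one run and record the trajectory.

    Frequency counts tally, per feature, the number of generations whose
    best chromosome included it (maximum = ``config.generations``).
    """
    contrib = per_feature_contributions(X, class_labels)
    d = contrib.size
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6A]))
    pop = rng.random((config.population_size, d)) < 0.5
    _repair_empty(pop, rng)

    best_bits = np.empty((config.generations, d), dtype=bool)
    best_fit = np.empty(config.generations)
    elite_bits: Optional[np.ndarray] = None
    elite_fit = -np.inf

    for gen in range(config.generations):
        fitness = pop @ contrib
        # Champion: fittest chromosome under the parsimony-adjusted
        # score, which breaks near-ties in favour of smaller subsets.
        margin = config.champion_parsimony * float(fitness.max())
        champion = int(np.argmax(fitness - margin * pop.sum(axis=1)))
        best_bits[gen] = pop[champion]
        if fitness.max() > elite_fit or elite_bits is None:
            elite_fit = float(fitness.max())
            elite_bits = pop[int(np.argmax(fitness))].copy()
        best_fit[gen] = elite_fit

        parents = pop[_roulette(fitness, config.population_size, rng)]
        children = parents.copy()
        n_pairs = config.population_size // 2
        do_cross = rng.random(n_pairs) < config.crossover_probability
        points = rng.integers(1, d, size=n_pairs)
        for pair, (cross, point) in enumerate(zip(do_cross, points)):
            if not cross:
                continue
            a, b = 2 * pair, 2 * pair + 1
            tail = children[a, point:].copy()
            children[a, point:] = children[b, point:]
            children[b, point:] = tail
        flips = rng.random(children.shape) < config.mutation_probability
        children ^= flips
        _repair_empty(children, rng)
        if config.elitism > 0 and elite_bits is not None:
            children[: config.elitism] = elite_bits
        pop = children

    frequency = best_bits.sum(axis=0)
    return GARun(
        best_bits=best_bits,
        best_fitness=best_fit,
        frequency=frequency,
        elite_bits=elite_bits,
    )


def aggregate_and_select(
    runs: Union[Sequence[GARun], np.ndarray], k: int
) -> List[str]:
    """Sum per-feature frequencies over runs and pick the top ``k`` letters.

    Accepts either GARun objects or a raw (runs × D) count array.  Ties
    are broken in letter order.
    """
    if not 1 <= k <= N_FEATURES:
        raise ValueError("k must lie in [1, 13]")
    if isinstance(runs, np.ndarray):
        counts = np.atleast_2d(runs).sum(axis=0)
    else:
        counts = np.sum([r.frequency for r in runs], axis=0)
    if counts.size != N_FEATURES:
        raise ValueError("expected counts for exactly 13 features")
    order = sorted(range(N_FEATURES), key=lambda i: (-counts[i], i))
    return sorted(FEATURE_LETTERS[i] for i in order[:k])


def select_features(
    X,
    class_labels,
    config: GAConfig = GAConfig(),
    k: int = 5,
    seed: int = 0,
) -> tuple[List[str], List[GARun]]:
    """Run the GA ``config.runs`` times and aggregate the selections."""
    runs = [
        run_ga(X, class_labels, config, seed=np.random.SeedSequence([int(seed), r]))
        for r in range(config.runs)
    ]
    return aggregate_and_select(runs, k), runs
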