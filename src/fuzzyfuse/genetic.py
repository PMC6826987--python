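"""Genetic refinement of bias-corrected FCM initial partitions.

The clustering stage seeds a small population of candidate centroid
sets by running BCFCM from distinct seeds, then evolves them with
selection, one-point crossover and Gaussian mutation. The fittest
chromosome (lowest within-cluster dispersion about the cluster gravity
centres) initialises the possibilistic-fuzzy modelling step. Genetic
refinement of an empirically generated population avoids the local
minima a single random initialisation can fall into.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .clustering import BCFCM, ClusterConfig, _as_feature_matrix, _sqdist, \
    _inverse_power_partition

__all__ = ["GaConfig", "Chromosome", "fitness", "init_population", "evolve"]


@dataclasses.dataclass
class GaConfig:
    """Genetic-algorithm parameters.

    Defaults follow the customary small-population setting: 10
    chromosomes, 20 generations, crossover probability 0.8 (>= 0.5) and
    mutation probability 0.01 (inversely proportional to the population
    size).
    """

    pop_size: int = 10
    generations: int = 20
    pc: float = 0.8
    pm: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ValueError("population size must be at least 1")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if not 0.0 <= self.pm <= 1.0:
            raise ValueError("mutation probability must lie in [0, 1]")
        if not 0.0 <= self.pc <= 1.0:
            raise ValueError("crossover probability must lie in [0, 1]")


@dataclasses.dataclass
class Chromosome:
    """Candidate centroid set with its fitness (lower is better)."""

    centers: np.ndarray          # (C, dim)
    fitness: float
    empty_clusters: bool = False


def fitness(X: np.ndarray, centers: np.ndarray,
            weights: np.ndarray | None = None) -> float:
    """Within-cluster dispersion about gravity centres.

    Each observation is assigned to its nearest chromosome centre; per
    cluster the (unweighted) gravity centre g_l is computed and the
    merit is w = sum_l sum_{x in C_l} p_i d^2(x_i, g_l). Empty clusters
    contribute nothing.
    """
    X = _as_feature_matrix(X)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.ndim == 2 and centers.shape[1] != X.shape[1]:
        centers = centers.reshape(-1, X.shape[1])
    p = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    assign = np.argmin(_sqdist(X, centers), axis=0)
    w = 0.0
    for l in range(len(centers)):
        sel = assign == l
        if not sel.any():
            continue
        g = X[sel].mean(axis=0)
        w += float((p[sel] * ((X[sel] - g) ** 2).sum(axis=1)).sum())
    return w


def _has_empty(X: np.ndarray, centers: np.ndarray) -> bool:
    assign = np.argmin(_sqdist(X, np.atleast_2d(centers)), axis=0)
    return len(np.unique(assign)) < len(np.atleast_2d(centers))


def init_population(image: np.ndarray, cfg: ClusterConfig, ga: GaConfig,
                    weights: np.ndarray | None = None) -> list[Chromosome]:
    """Seed the population with BCFCM centroid sets from distinct seeds.

    Each chromosome is the centroid set of one bias-corrected FCM run;
    the master ``ga.seed`` derives the per-run seeds, so a fixed master
    seed reproduces the population exactly.
    """
    image = np.asarray(image, dtype=float)
    X = image.reshape(-1, 1)
    pop = []
    for k in range(ga.pop_size):
        run_cfg = dataclasses.replace(cfg, seed=(ga.seed * 1009 + k) % (2 ** 31))
        res = BCFCM(image, run_cfg).fit()
        centers = np.asarray(res.centroids, dtype=float)
        pop.append(Chromosome(
            centers=centers,
            fitness=fitness(X, centers, weights),
            empty_clusters=_has_empty(X, centers),
        ))
    return pop


def evolve(population: list[Chromosome], X: np.ndarray, ga: GaConfig,
           weights: np.ndarray | None = None, m: float = 2.0):
    """Run the genetic loop and return the best chromosome plus the
    fuzzy partition its centres induce.

    Selection is fitness-proportional on 1/(1+w) with single elitism;
    crossover is one-point at centre boundaries with probability ``pc``;
    mutation perturbs each gene with probability ``pm`` by a Gaussian
    whose scale is 5% of the feature range. Best-so-far fitness is
    monotone non-increasing across generations. Chromosomes with empty
    clusters are re-seeded from a random data point during mutation.
    """
    if not population:
        raise ValueError("population must be non-empty")
    X = _as_feature_matrix(X)
    rng = np.random.default_rng(ga.seed)
    span = np.ptp(X, axis=0)
    sigma = 0.05 * np.where(span > 0, span, 1.0)
    pop = [Chromosome(c.centers.copy(), c.fitness, c.empty_clusters)
           for c in population]
    history = [min(c.fitness for c in pop)]

    for _ in range(ga.generations):
        pop.sort(key=lambda c: c.fitness)
        elite = pop[0]
        probs = np.array([1.0 / (1.0 + c.fitness) for c in pop])
        probs = probs / probs.sum()
        children = [Chromosome(elite.centers.copy(), elite.fitness,
                               elite.empty_clusters)]
        while len(children) < len(pop):
            i, j = rng.choice(len(pop), size=2, p=probs)
            a = pop[i].centers.copy()
            b = pop[j].centers.copy()
            if rng.random() < ga.pc and len(a) > 1:
                cut = int(rng.integers(1, len(a)))   # cut at centre boundary
                a = np.vstack([a[:cut], b[cut:]])
            # per-gene Gaussian mutation
            mut = rng.random(a.shape) < ga.pm
            a = a + mut * rng.normal(0.0, 1.0, size=a.shape) * sigma
            child = Chromosome(a, fitness(X, a, weights), _has_empty(X, a))
            if child.empty_clusters and ga.pm > 0:
                # re-seed empty clusters from random data points
                assign = np.argmin(_sqdist(X, a), axis=0)
                for l in range(len(a)):
                    if not np.any(assign == l):
                        a[l] = X[rng.integers(len(X))]
                child = Chromosome(a, fitness(X, a, weights), _has_empty(X, a))
            children.append(child)
        pop = children
        history.append(min(c.fitness for c in pop))

    best = min(pop, key=lambda c: c.fitness)
    d2 = _sqdist(X, best.centers)
    partition = _inverse_power_partition(d2, 1.0 / (m - 1.0), axis=0)
    return best, partition, np.asarray(history)
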