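"""Genetic algorithm on byte genomes, lineage tracking and robustness.

The GA follows standard digital-evolution practice: a population of 100 byte
genomes (initialized with 5000 random bytes, seeded with six gate start
codons for Markov substrates), tournament selection of size 5, and
generational replacement where every offspring is mutated.  Mutation
operators are per-site point mutations (rate 5e-3, a site is redrawn
uniformly over 0-255), and rare copy-insert / delete events (rate 2e-5 per
site) that move segments of 128-512 sites; genome length is clamped to
[2000, 20000] by skipping violating events.

A :class:`Lineage` records every generation's genomes, fitnesses and parent
pointers so the line of descent of any final individual can be walked back
to generation zero.

Mutational robustness of a genome is R = <B> / B0: the mean fitness of 100
independent mutants (standard per-offspring rates) over the baseline fitness.
For a perfect scorer (B0 = 1) R is simply the average mutant score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .substrates import (
    GENOME_INIT,
    GENOME_MAX,
    GENOME_MIN,
    Genome,
    random_genome,
    seed_start_codons,
)

__all__ = [
    "EvolutionConfig",
    "Lineage",
    "RobustnessResult",
    "mutate",
    "tournament_select",
    "evolve",
    "line_of_descent",
    "mutational_robustness",
]


@dataclass(frozen=True)
class EvolutionConfig:
    population: int = 100
    tournament_k: int = 5
    generations: int = 100
    point_rate: float = 5e-3
    indel_rate: float = 2e-5
    segment_min: int = 128
    segment_max: int = 512
    genome_min: int = GENOME_MIN
    genome_max: int = GENOME_MAX
    init_length: int = GENOME_INIT
    seed_codons: int = 6  # Markov substrates only

    def __post_init__(self) -> None:
        for r in (self.point_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must be in [0, 1]")


def mutate(g: Genome, cfg: EvolutionConfig, rng: np.random.Generator) -> Genome:
    """One offspring's worth of mutations.

    Point mutations hit a Binomial(L, rate) number of sites; insert events
    copy a uniformly chosen segment of length U[seg_min, seg_max] to a
    uniform position, delete events remove one; events that would push the
    genome outside [genome_min, genome_max] are skipped.
    """
    g = np.array(g, dtype=np.uint8, copy=True)
    n_events = rng.binomial(len(g), cfg.indel_rate) if cfg.indel_rate > 0 else 0
    for _ in range(n_events):
        seg = int(rng.integers(cfg.segment_min, cfg.segment_max + 1))
        if rng.random() < 0.5:  # insert (copy)
            if len(g) + seg > cfg.genome_max or seg > len(g):
                continue
            src = int(rng.integers(0, len(g) - seg + 1))
            at = int(rng.integers(0, len(g) + 1))
            g = np.concatenate([g[:at], g[src : src + seg], g[at:]])
        else:  # delete
            if len(g) - seg < cfg.genome_min or seg >= len(g):
                continue
            at = int(rng.integers(0, len(g) - seg + 1))
            g = np.concatenate([g[:at], g[at + seg :]])
    if cfg.point_rate > 0:
        n_pts = rng.binomial(len(g), cfg.point_rate)
        if n_pts:
            sites = rng.choice(len(g), size=n_pts, replace=False)
            g[sites] = rng.integers(0, 256, size=n_pts, dtype=np.uint8)
    return g


def tournament_select(
    fitnesses: Sequence[float], k: int, rng: np.random.Generator
) -> int:
    """Sample k indices with replacement; return the fittest, breaking ties
    uniformly at random."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.size == 0:
        raise ValueError("population must be non-empty")
    contenders = rng.integers(0, fitnesses.size, size=k)
    best = np.max(fitnesses[contenders])
    winners = contenders[fitnesses[contenders] == best]
    return int(winners[rng.integers(0, winners.size)])


@dataclass
class Lineage:
    """Per-generation genomes, fitnesses and parent pointers."""

    genomes: list[list[Genome]] = field(default_factory=list)
    fitnesses: list[np.ndarray] = field(default_factory=list)
    parents: list[np.ndarray] = field(default_factory=list)  # parents[g][i] in gen g-1

    @property
    def n_generations(self) -> int:
        return len(self.genomes)

    def best_final(self) -> tuple[int, float]:
        f = self.fitnesses[-1]
        i = int(np.argmax(f))
        return i, float(f[i])


def evolve(
    evaluate: Callable[[Genome], float],
    cfg: EvolutionConfig,
    rng: np.random.Generator,
    markov: bool = True,
) -> tuple[list[Genome], Lineage]:
    """Generational GA loop: evaluate -> tournament-select -> mutate.

    ``evaluate`` maps a genome to fitness (decode plus task run).  Seeded and
    bit-reproducible: the same rng state yields identical genomes, fitnesses
    and lineage.  Returns the final (evaluated) population and the lineage.
    """
    pop = []
    for _ in range(cfg.population):
        g = random_genome(rng, cfg.init_length)
        if markov:
            g = seed_start_codons(g, cfg.seed_codons)
        pop.append(g)
    lineage = Lineage()
    fits = np.array([evaluate(g) for g in pop])
    lineage.genomes.append(pop)
    lineage.fitnesses.append(fits)
    lineage.parents.append(np.full(cfg.population, -1))

    for _ in range(cfg.generations):
        parents = np.array(
            [tournament_select(fits, cfg.tournament_k, rng) for _ in range(cfg.population)]
        )
        pop = [mutate(lineage.genomes[-1][p], cfg, rng) for p in parents]
        fits = np.array([evaluate(g) for g in pop])
        lineage.genomes.append(pop)
        lineage.fitnesses.append(fits)
        lineage.parents.append(parents)
    return pop, lineage


def line_of_descent(lineage: Lineage, individual: int) -> list[Genome]:
    """Walk parent pointers from a final-generation individual back to
    generation zero; returned oldest-first."""
    if not 0 <= individual < len(lineage.genomes[-1]):
        raise IndexError("individual not in final generation")
    path = []
    i = individual
    for g in range(lineage.n_generations - 1, -1, -1):
        path.append(lineage.genomes[g][i])
        p = int(lineage.parents[g][i])
        if g > 0:
            if not 0 <= p < len(lineage.genomes[g - 1]):
                raise ValueError(f"corrupt lineage: bad parent pointer at gen {g}")
            i = p
    return path[::-1]


@dataclass(frozen=True)
class RobustnessResult:
    baseline: float        # B0
    mean_mutant: float     # <B>
    robustness: float      # R = <B> / B0
    mutant_fitnesses: tuple[float, ...] = ()


def mutational_robustness(
    g: Genome,
    evaluate: Callable[[Genome], float],
    cfg: EvolutionConfig,
    rng: np.random.Generator,
    n_mutants: int = 100,
) -> RobustnessResult:
    """R = <B> / B0 over ``n_mutants`` independent single-offspring mutants."""
    b0 = evaluate(g)
    if b0 == 0:
        raise ValueError("baseline fitness is zero; robustness undefined")
    scores = [evaluate(mutate(g, cfg, rng)) for _ in range(n_mutants)]
    mean = float(np.mean(scores))
    return RobustnessResult(b0, mean, mean / b0, tuple(scores))
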