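"""Non-spatial agent-based model: the finite-population stochastic
realization of the configuration-field dynamics.

Each elementary step draws two independent random groups of N agents
from a well-mixed population of size P, picks one focal player per
group, and plays the pairwise imitation game between the focals; the
loser's slot is overwritten by a (possibly mutated) copy of the winner.
One generation is P/2 such steps, so each agent participates in one
update per generation on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .core import (
    Genotype,
    GroupConfig,
    ModelParams,
    group_member_cost,
    imitation_probability,
    mutate,
    resolve_activation,
)

__all__ = ["Population", "abm_step", "run_generations", "exact_counts"]

GENOTYPE_COLUMNS = [Genotype(g).allele_string for g in range(8)]


def exact_counts(freqs: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of target frequencies to integer
    counts summing exactly to ``total``."""
    freqs = np.asarray(freqs, dtype=float)
    raw = freqs / freqs.sum() * total
    counts = np.floor(raw).astype(np.int64)
    remainder = total - counts.sum()
    if remainder:
        order = np.argsort(raw - counts)[::-1]
        counts[order[:remainder]] += 1
    return counts


@dataclass
class Population:
    """A well-mixed population of P agents with its own RNG stream."""

    agents: np.ndarray
    rng: np.random.Generator
    generation: int = 0

    @classmethod
    def from_frequencies(
        cls,
        freqs: dict[Genotype, float] | np.ndarray,
        P: int,
        seed: int | np.random.Generator = 0,
    ) -> "Population":
        """Build a shuffled population realizing the target frequencies
        by exact-count (largest-remainder) rounding."""
        rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        if isinstance(freqs, dict):
            vec = np.zeros(8)
            for g, f in freqs.items():
                vec[int(Genotype(g))] = f
        else:
            vec = np.asarray(freqs, dtype=float)
            if vec.shape != (8,):
                raise ValueError("frequency vector must cover all 8 genotypes")
        counts = exact_counts(vec, P)
        agents = np.repeat(np.arange(8, dtype=np.int64), counts)
        rng.shuffle(agents)
        return cls(agents=agents, rng=rng)

    @property
    def size(self) -> int:
        return int(self.agents.shape[0])

    def frequencies(self) -> np.ndarray:
        return np.bincount(self.agents, minlength=8) / self.size


def _focal_cost(pop: Population, members: np.ndarray, p: ModelParams) -> float:
    group = GroupConfig(np.bincount(pop.agents[members], minlength=8))
    outcome = resolve_activation(group, p)
    return group_member_cost(Genotype(int(pop.agents[members[0]])), outcome, p)


def abm_step(pop: Population, p: ModelParams,
             rng: np.random.Generator | None = None) -> Population:
    """One elementary interaction step (reference implementation built
    on the elementary core operations; :func:`run_generations` uses the
    compiled kernel for long runs)."""
    if pop.size < 2 * p.N:
        raise ValueError(f"population size {pop.size} < 2N = {2 * p.N}")
    rng = rng or pop.rng
    members_i = rng.choice(pop.size, size=p.N, replace=False)
    members_j = rng.choice(pop.size, size=p.N, replace=False)
    cost_i = _focal_cost(pop, members_i, p)
    cost_j = _focal_cost(pop, members_j, p)
    p_ij = imitation_probability(cost_i, cost_j, p)
    if rng.random() < p_ij:
        winner, loser = members_i[0], members_j[0]
    else:
        winner, loser = members_j[0], members_i[0]
    child = mutate(Genotype(int(pop.agents[winner])), p.mu, rng)
    pop.agents[loser] = int(child)
    return pop


def run_generations(
    pop: Population,
    p: ModelParams,
    n_gen: int,
    record_every: int = 1,
) -> pd.DataFrame:
    """Run ``n_gen`` generations (P/2 steps each) with the compiled
    kernel; returns recorded genotype frequencies (row 0 is the state
    before the run).  Fully reproducible from the population's seed."""
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    if pop.size < 2 * p.N:
        raise ValueError(f"population size {pop.size} < 2N = {2 * p.N}")
    kernel_seed = int(pop.rng.integers(2**31))
    freqs = _kernels.abm_run_kernel(
        pop.agents, n_gen, record_every, p.N, p.Q, p.kappa,
        p.c0, p.c, p.s, p.r, p.b, p.sigma, p.delta_C_max,
        np.asarray(p.mu, dtype=np.float64), kernel_seed,
    )
    gens = np.concatenate(
        [[pop.generation],
         pop.generation + np.arange(1, freqs.shape[0]) * record_every]
    )
    pop.generation += n_gen
    out = pd.DataFrame(freqs, columns=GENOTYPE_COLUMNS)
    out.insert(0, "generation", gens)
    return out
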