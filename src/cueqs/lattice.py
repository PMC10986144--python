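"""Spatially explicit lattice model: toroidal M x M grid of agents with
Moore-neighborhood interaction groups.

This is the headline simulator.  It differs from the shared-pool
configuration-field rules in one key respect: every agent — the focal
player and each conditional cooperator in its group — evaluates the
quorum against its *own* Moore neighborhood, so activation is a local,
per-agent decision.  Competition is between Moore-adjacent site pairs;
the loser's site is overwritten in place by the winner's (possibly
mutated) offspring.  Limited mobility is modeled by Poisson(D) random
swaps of adjacent agents after each game step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .abm import GENOTYPE_COLUMNS, exact_counts
from .core import Genotype, GroupConfig, ModelParams, imitation_probability, mutate

__all__ = [
    "LatticeState",
    "moore_group",
    "site_cost",
    "game_step",
    "diffusion_steps",
    "run",
    "save_snapshot",
    "load_snapshot",
]


@dataclass
class LatticeState:
    """Toroidal grid of genotype codes plus the model's RNG stream.

    Every site is always occupied, so the population is constant at
    M^2 agents.
    """

    grid: np.ndarray
    rng: np.random.Generator
    generation: int = 0
    last_swap_count: int = 0  # swaps performed by the latest diffusion batch

    @classmethod
    def random(
        cls,
        freqs: dict[Genotype, float] | np.ndarray,
        M: int,
        seed: int | np.random.Generator = 0,
    ) -> "LatticeState":
        """Random spatial arrangement realizing the target frequencies
        with exact-count (largest-remainder) rounding to M^2 sites."""
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
        counts = exact_counts(vec, M * M)
        sites = np.repeat(np.arange(8, dtype=np.int64), counts)
        rng.shuffle(sites)
        return cls(grid=sites.reshape(M, M), rng=rng)

    @property
    def M(self) -> int:
        return int(self.grid.shape[0])

    def frequencies(self) -> np.ndarray:
        return np.bincount(self.grid.ravel(), minlength=8) / self.grid.size


def moore_group(state: LatticeState, site: tuple[int, int]) -> GroupConfig:
    """The 9 genotypes of the 3x3 block centered on the site, with
    toroidal wrapping; includes the focal."""
    x, y = site
    M = state.M
    if not (0 <= x < M and 0 <= y < M):
        raise ValueError(f"site {site} outside the {M}x{M} lattice")
    block = state.grid[np.ix_([(x - 1) % M, x, (x + 1) % M],
                              [(y - 1) % M, y, (y + 1) % M])]
    return GroupConfig(np.bincount(block.ravel(), minlength=8))


def site_cost(state: LatticeState, site: tuple[int, int], p: ModelParams) -> float:
    """Realized cost of the agent at ``site`` under the two-stage local
    resolution: each conditional cooperator in the focal's Moore group
    activates against its own neighborhood's signal doses; the benefit
    indicator counts active cooperators within the focal's group.
    Depends only on the 5x5 block around the site."""
    x, y = site
    if not (0 <= x < state.M and 0 <= y < state.M):
        raise ValueError(f"site {site} outside the lattice")
    return float(
        _kernels.site_cost_kernel(
            state.grid, x, y, p.Q, p.kappa, p.c0, p.c, p.s, p.r, p.b
        )
    )


def game_step(state: LatticeState, p: ModelParams,
              rng: np.random.Generator | None = None) -> LatticeState:
    """One elementary competition: a uniform random site against a
    uniform random Moore-adjacent site; the loser's site is overwritten
    with a mutated copy of the winner's genotype."""
    rng = rng or state.rng
    M = state.M
    x1, y1 = int(rng.integers(M)), int(rng.integers(M))
    ox, oy = _kernels.MOORE_OFF[int(rng.integers(8))]
    x2, y2 = (x1 + int(ox)) % M, (y1 + int(oy)) % M
    cost1 = site_cost(state, (x1, y1), p)
    cost2 = site_cost(state, (x2, y2), p)
    if rng.random() < imitation_probability(cost1, cost2, p):
        winner, loser = (x1, y1), (x2, y2)
    else:
        winner, loser = (x2, y2), (x1, y1)
    child = mutate(Genotype(int(state.grid[winner])), p.mu, rng)
    state.grid[loser] = int(child)
    return state


def diffusion_steps(state: LatticeState, p: ModelParams,
                    rng: np.random.Generator | None = None) -> LatticeState:
    """Poisson(D) site swaps between uniform random Moore-adjacent
    pairs, chosen independently of any game pair."""
    if p.D < 0:
        raise ValueError("D must be non-negative")
    rng = rng or state.rng
    if p.D == 0:
        state.last_swap_count = 0
        return state
    M = state.M
    n_swaps = int(rng.poisson(p.D))
    state.last_swap_count = n_swaps
    for _ in range(n_swaps):
        x1, y1 = int(rng.integers(M)), int(rng.integers(M))
        ox, oy = _kernels.MOORE_OFF[int(rng.integers(8))]
        x2, y2 = (x1 + int(ox)) % M, (y1 + int(oy)) % M
        state.grid[x1, y1], state.grid[x2, y2] = (
            state.grid[x2, y2],
            state.grid[x1, y1],
        )
    return state


def run(
    state: LatticeState,
    p: ModelParams,
    n_gen: int,
    record_every: int = 1,
) -> pd.DataFrame:
    """Run ``n_gen`` generations with the compiled kernel.

    One generation is M^2/2 game steps, each followed by its diffusion
    batch.  The grid is updated in place; recorded genotype frequencies
    are returned (row 0 = state before the run).  Seed-deterministic.
    """
    kernel_seed = int(state.rng.integers(2**31))
    freqs = _kernels.lattice_run_kernel(
        state.grid, n_gen, record_every, p.Q, p.kappa,
        p.c0, p.c, p.s, p.r, p.b, p.sigma, p.delta_C_max, p.D,
        np.asarray(p.mu, dtype=np.float64), kernel_seed,
    )
    gens = np.concatenate(
        [[state.generation],
         state.generation + np.arange(1, freqs.shape[0]) * record_every]
    )
    state.generation += n_gen
    out = pd.DataFrame(freqs, columns=GENOTYPE_COLUMNS)
    out.insert(0, "generation", gens)
    return out


def save_snapshot(state: LatticeState, path) -> None:
    """Write the grid as plain text: one lattice row per line,
    whitespace-separated allele strings."""
    lookup = [Genotype(g).allele_string for g in range(8)]
    with open(path, "w") as fh:
        for row in state.grid:
            fh.write(" ".join(lookup[g] for g in row) + "\n")


def load_snapshot(path, seed: int | np.random.Generator = 0) -> LatticeState:
    """Read a plain-text snapshot back into a LatticeState."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([int(Genotype.from_string(tok)) for tok in line.split()])
    grid = np.asarray(rows, dtype=np.int64)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError("snapshot is not a square lattice")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return LatticeState(grid=grid, rng=rng)
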