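"""Numba kernels for the stochastic simulation tiers.

Genotypes are packed into 3-bit codes (C=4, S=2, R=1) so that a lattice
is a small integer array and one elementary game step costs a few dozen
arithmetic operations.  All kernels draw from numba's global NumPy RNG,
seeded once per kernel call, which makes every simulation bitwise
reproducible from its integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dose table indexed by genotype code: [C] + [S].
DOSE_TAB = np.array([0, 0, 1, 1, 1, 1, 2, 2], dtype=np.int64)

# Moore-neighbor offsets (8 candidates, focal excluded).
MOORE_OFF = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

_C = 4
_S = 2
_R = 1


@njit(cache=True)
def _mutate_code(g, mu):
    """Flip each locus with its direction-specific per-replication rate."""
    code = g
    for locus in range(3):
        bit = 4 >> locus  # C, S, R
        if code & bit:
            rate = mu[locus, 0]
        else:
            rate = mu[locus, 1]
        if rate > 0.0 and np.random.random() < rate:
            code ^= bit
    return code


@njit(cache=True)
def _own_doses(grid, x, y):
    """Signal doses an agent at (x, y) senses in its own Moore group."""
    M = grid.shape[0]
    total = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            total += DOSE_TAB[grid[(x + dx) % M, (y + dy) % M]]
    return total


@njit(cache=True)
def site_cost_kernel(grid, x, y, Q, kappa, c0, c, s, r, b):
    """Realized metabolic cost of the agent at (x, y).

    Two-stage local resolution: every conditional cooperator in the
    focal's Moore group activates against its *own* Moore-group doses;
    the benefit indicator then counts active cooperators within the
    focal's group.  Reads at most the 5x5 block around the site.
    """
    M = grid.shape[0]
    g_f = grid[x, y]
    n_active = 0
    gamma_f = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            xm = (x + dx) % M
            ym = (y + dy) % M
            gm = grid[xm, ym]
            gamma = 0
            if gm & _C:
                if gm & _R:
                    if _own_doses(grid, xm, ym) >= Q:
                        gamma = 1
                else:
                    gamma = 1
            n_active += gamma
            if dx == 0 and dy == 0:
                gamma_f = gamma
    theta = 1 if n_active >= kappa else 0
    bracket = c0
    if g_f & _C:
        bracket += c * gamma_f
    if g_f & _S:
        bracket += s
    if g_f & _R:
        bracket += r
    return (1.0 - theta * b) * bracket


@njit(cache=True)
def dose_field(grid):
    """Own-Moore-group signal doses for every site (the quantity each
    conditional cooperator compares against Q)."""
    M = grid.shape[0]
    out = np.empty((M, M), dtype=np.int64)
    for x in range(M):
        for y in range(M):
            out[x, y] = _own_doses(grid, x, y)
    return out


@njit(cache=True)
def _write_site(grid, doses, x, y, new_code):
    """Overwrite a site and propagate the dose change to the 9 own-dose
    sums it participates in."""
    M = grid.shape[0]
    delta = DOSE_TAB[new_code] - DOSE_TAB[grid[x, y]]
    grid[x, y] = new_code
    if delta != 0:
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                doses[(x + dx) % M, (y + dy) % M] += delta


@njit(cache=True)
def _site_cost_cached(grid, doses, x, y, Q, kappa, c0, c, s, r, b):
    """site_cost_kernel with own-group doses read from the maintained
    field instead of being recomputed (same two-stage resolution)."""
    M = grid.shape[0]
    g_f = grid[x, y]
    n_active = 0
    gamma_f = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            xm = (x + dx) % M
            ym = (y + dy) % M
            gm = grid[xm, ym]
            gamma = 0
            if gm & _C:
                if gm & _R:
                    if doses[xm, ym] >= Q:
                        gamma = 1
                else:
                    gamma = 1
            n_active += gamma
            if dx == 0 and dy == 0:
                gamma_f = gamma
    theta = 1 if n_active >= kappa else 0
    bracket = c0
    if g_f & _C:
        bracket += c * gamma_f
    if g_f & _S:
        bracket += s
    if g_f & _R:
        bracket += r
    return (1.0 - theta * b) * bracket


@njit(cache=True)
def _lattice_game_step(grid, doses, Q, kappa, c0, c, s, r, b, sigma, dcmax, mu):
    M = grid.shape[0]
    x1 = np.random.randint(0, M)
    y1 = np.random.randint(0, M)
    k = np.random.randint(0, 8)
    x2 = (x1 + MOORE_OFF[k, 0]) % M
    y2 = (y1 + MOORE_OFF[k, 1]) % M
    cost1 = _site_cost_cached(grid, doses, x1, y1, Q, kappa, c0, c, s, r, b)
    cost2 = _site_cost_cached(grid, doses, x2, y2, Q, kappa, c0, c, s, r, b)
    p12 = 0.5 * (1.0 + sigma * (cost2 - cost1) / dcmax)
    if np.random.random() < p12:
        _write_site(grid, doses, x2, y2, _mutate_code(grid[x1, y1], mu))
    else:
        _write_site(grid, doses, x1, y1, _mutate_code(grid[x2, y2], mu))


@njit(cache=True)
def _lattice_diffuse(grid, doses, D):
    """Poisson(D) random swaps between Moore-adjacent site pairs."""
    if D <= 0.0:
        return
    M = grid.shape[0]
    n_swaps = np.random.poisson(D)
    for _ in range(n_swaps):
        x1 = np.random.randint(0, M)
        y1 = np.random.randint(0, M)
        k = np.random.randint(0, 8)
        x2 = (x1 + MOORE_OFF[k, 0]) % M
        y2 = (y1 + MOORE_OFF[k, 1]) % M
        g1 = grid[x1, y1]
        g2 = grid[x2, y2]
        if g1 != g2:
            _write_site(grid, doses, x1, y1, g2)
            _write_site(grid, doses, x2, y2, g1)


@njit(cache=True)
def _grid_freqs(grid, out):
    M = grid.shape[0]
    for g in range(8):
        out[g] = 0.0
    for x in range(M):
        for y in range(M):
            out[grid[x, y]] += 1.0
    for g in range(8):
        out[g] /= M * M


@njit(cache=True)
def lattice_run_kernel(
    grid, n_gen, record_every, Q, kappa, c0, c, s, r, b, sigma, dcmax, D, mu, seed
):
    """Run n_gen lattice generations in place; returns recorded frequencies.

    One generation is M^2/2 elementary game steps, each followed by a
    Poisson(D) batch of diffusion swaps.  Row 0 of the output is the
    initial state; a row is appended after every ``record_every``
    generations.
    """
    np.random.seed(seed)
    M = grid.shape[0]
    doses = dose_field(grid)
    steps_per_gen = (M * M) // 2
    n_rec = n_gen // record_every + 1
    freqs = np.zeros((n_rec, 8))
    _grid_freqs(grid, freqs[0])
    rec = 1
    for gen in range(1, n_gen + 1):
        for _ in range(steps_per_gen):
            _lattice_game_step(grid, doses, Q, kappa, c0, c, s, r, b, sigma, dcmax, mu)
            _lattice_diffuse(grid, doses, D)
        if gen % record_every == 0:
            _grid_freqs(grid, freqs[rec])
            rec += 1
    return freqs[:rec]


@njit(cache=True)
def _sample_group(idx, start, N, P):
    """Fill idx[start:start+N] with N distinct uniform indices (rejection)."""
    for k in range(N):
        while True:
            cand = np.random.randint(0, P)
            dup = False
            for m in range(k):
                if idx[start + m] == cand:
                    dup = True
                    break
            if not dup:
                break
        idx[start + k] = cand


@njit(cache=True)
def _abm_group_cost(agents, idx, start, N, Q, kappa, c0, c, s, r, b):
    """Cost of the focal agent (first sampled index) of a shared-pool group."""
    doses = 0
    n_unc = 0
    n_cond = 0
    for k in range(N):
        g = agents[idx[start + k]]
        doses += DOSE_TAB[g]
        if g & _C:
            if g & _R:
                n_cond += 1
            else:
                n_unc += 1
    quorum = doses >= Q
    n_active = n_unc + (n_cond if quorum else 0)
    theta = 1 if n_active >= kappa else 0
    g_f = agents[idx[start]]
    gamma_f = 0
    if g_f & _C:
        if (g_f & _R) == 0 or quorum:
            gamma_f = 1
    bracket = c0
    if g_f & _C:
        bracket += c * gamma_f
    if g_f & _S:
        bracket += s
    if g_f & _R:
        bracket += r
    return (1.0 - theta * b) * bracket


@njit(cache=True)
def abm_run_kernel(
    agents, n_gen, record_every, N, Q, kappa, c0, c, s, r, b, sigma, dcmax, mu, seed
):
    """Run n_gen generations of the non-spatial model in place.

    One elementary step: two independent random samples of N agents form
    the interacting groups; the first sampled member of each group is
    its focal player; the focal pair plays the imitation game and the
    loser's slot is overwritten with a (possibly mutated) copy of the
    winner.  One generation is P/2 steps.
    """
    np.random.seed(seed)
    P = agents.shape[0]
    steps_per_gen = P // 2
    n_rec = n_gen // record_every + 1
    freqs = np.zeros((n_rec, 8))
    counts = np.zeros(8)
    for i in range(P):
        counts[agents[i]] += 1.0
    freqs[0] = counts / P
    rec = 1
    idx = np.empty(2 * N, dtype=np.int64)
    for gen in range(1, n_gen + 1):
        for _ in range(steps_per_gen):
            _sample_group(idx, 0, N, P)
            _sample_group(idx, N, N, P)
            cost1 = _abm_group_cost(agents, idx, 0, N, Q, kappa, c0, c, s, r, b)
            cost2 = _abm_group_cost(agents, idx, N, N, Q, kappa, c0, c, s, r, b)
            p12 = 0.5 * (1.0 + sigma * (cost2 - cost1) / dcmax)
            if np.random.random() < p12:
                winner = idx[0]
                loser = idx[N]
            else:
                winner = idx[N]
                loser = idx[0]
            agents[loser] = _mutate_code(agents[winner], mu)
        if gen % record_every == 0:
            for g in range(8):
                counts[g] = 0.0
            for i in range(P):
                counts[agents[i]] += 1.0
            freqs[rec] = counts / P
            rec += 1
    return freqs[:rec]
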