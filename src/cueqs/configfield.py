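"""Configuration-field (CF) dynamics: infinite population, finite random
groups.

Each focal individual interacts in a randomly assembled group of size N
(itself plus N-1 co-members drawn i.i.d. from the population), so its
expected cost is the multinomial-weighted average of its realized cost
over all compositions of the co-members.  The group shares a single
signal pool: every member evaluates the quorum and cooperation
thresholds against the same group of N.  The replicator flow on these
expected costs is an exact polynomial in the frequencies, which makes
fixed-point location and classification straightforward.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.special import gammaln

from .core import (
    DOSES,
    HAS_C,
    HAS_R,
    HAS_S,
    FEASIBLE_3,
    Genotype,
    GroupConfig,
    ModelParams,
    group_member_cost,
    resolve_activation,
)
from .meanfield import simplex_grid

__all__ = [
    "enumerate_compositions",
    "compositions_array",
    "cf_expected_cost",
    "cf_expected_costs",
    "cf_monte_carlo_costs",
    "cf_flow",
    "cf_integrate",
    "cf_vector_field",
    "cf_fixed_points",
    "CFFixedPoint",
    "mutation_matrix",
]


def enumerate_compositions(n_strategies: int, slots: int) -> Iterator[tuple[int, ...]]:
    """Yield every composition of ``slots`` items into ``n_strategies``
    ordered bins exactly once (C(slots + n - 1, slots) of them)."""
    if slots < 0:
        raise ValueError("slots must be non-negative")
    if n_strategies < 1:
        raise ValueError("need at least one strategy")
    # stars and bars over the cut positions
    for cuts in itertools.combinations(range(slots + n_strategies - 1), n_strategies - 1):
        prev = -1
        counts = []
        for cut in cuts:
            counts.append(cut - prev - 1)
            prev = cut
        counts.append(slots + n_strategies - 1 - prev - 1)
        yield tuple(counts)


@lru_cache(maxsize=32)
def compositions_array(n_strategies: int, slots: int) -> np.ndarray:
    """All compositions as an (n_comp, n_strategies) integer array."""
    return np.array(list(enumerate_compositions(n_strategies, slots)), dtype=np.int64)


@lru_cache(maxsize=32)
def _log_multinomial_coefs(n_strategies: int, slots: int) -> np.ndarray:
    comps = compositions_array(n_strategies, slots)
    return gammaln(slots + 1) - gammaln(comps + 1).sum(axis=1)


def composition_weights(x: np.ndarray, slots: int) -> np.ndarray:
    """Multinomial weights of every co-member composition under
    frequencies x; sums to one."""
    x = np.asarray(x, dtype=float)
    comps = compositions_array(len(x), slots)
    logcoef = _log_multinomial_coefs(len(x), slots)
    pos = x > 0
    # compositions that use a zero-frequency strategy have weight zero
    feasible = (comps[:, ~pos] == 0).all(axis=1)
    logx = np.where(pos, np.log(np.where(pos, x, 1.0)), 0.0)
    w = np.exp(logcoef + comps @ logx)
    w[~feasible] = 0.0
    return w


def _params_key(p: ModelParams) -> tuple:
    return (p.c0, p.c, p.s, p.r, p.b, p.kappa, p.Q, p.N)


@lru_cache(maxsize=64)
def _cost_matrix(strategies: tuple[int, ...], key: tuple) -> np.ndarray:
    """(n_strategies, n_comp) realized focal costs: entry [i, k] is the
    cost of a focal of strategy i in a group formed by co-member
    composition k, under the shared signal pool."""
    c0, c, s, r, b, kappa, Q, N = key
    comps = compositions_array(len(strategies), N - 1)
    onehot = np.zeros((len(strategies), 8), dtype=np.int64)
    for i, g in enumerate(strategies):
        onehot[i, g] = 1
    counts8 = comps @ onehot  # (n_comp, 8) co-member counts
    unc = (HAS_C & ~HAS_R).astype(np.int64)
    cond = (HAS_C & HAS_R).astype(np.int64)
    out = np.empty((len(strategies), comps.shape[0]))
    for i, g in enumerate(strategies):
        group8 = counts8.copy()
        group8[:, g] += 1  # focal joins its own group
        doses = group8 @ DOSES
        quorum = doses >= Q
        n_active = group8 @ unc + quorum * (group8 @ cond)
        theta = (n_active >= kappa).astype(float)
        gamma_f = float(HAS_C[g]) * np.where(HAS_R[g], quorum.astype(float), 1.0)
        bracket = c0 + c * gamma_f * HAS_C[g] + s * HAS_S[g] + r * HAS_R[g]
        out[i] = (1.0 - theta * b) * bracket
    return out


def _strategy_codes(strategies: Sequence[Genotype]) -> tuple[int, ...]:
    return tuple(int(Genotype(g)) for g in strategies)


def cf_expected_costs(
    x: np.ndarray, p: ModelParams, strategies: Sequence[Genotype] = FEASIBLE_3
) -> np.ndarray:
    """Expected cost of a focal of each strategy at frequencies x."""
    codes = _strategy_codes(strategies)
    x = np.asarray(x, dtype=float)
    if x.shape != (len(codes),):
        raise ValueError("frequency vector does not match the strategy set")
    if (x < -1e-12).any() or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"not a simplex point: {x}")
    w = composition_weights(np.clip(x, 0.0, None), p.N - 1)
    return _cost_matrix(codes, _params_key(p)) @ w


def cf_expected_cost(
    g: Genotype, x: np.ndarray, p: ModelParams,
    strategies: Sequence[Genotype] = FEASIBLE_3,
) -> float:
    """Expected cost of a focal of strategy g (weighted over all
    multinomial co-member compositions)."""
    codes = _strategy_codes(strategies)
    g = Genotype(g)
    if int(g) in codes:
        return float(cf_expected_costs(x, p, strategies)[codes.index(int(g))])
    # focal strategy absent from the population: same machinery with the
    # focal appended at frequency zero
    ext = tuple(list(codes) + [int(g)])
    x_ext = np.concatenate([np.asarray(x, dtype=float), [0.0]])
    return float(cf_expected_costs(x_ext, p, [Genotype(c) for c in ext])[-1])


def cf_monte_carlo_costs(
    x: np.ndarray,
    p: ModelParams,
    n_samples: int,
    rng: np.random.Generator,
    strategies: Sequence[Genotype] = FEASIBLE_3,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo oracle for the expected costs: draw ``n_samples``
    random co-member groups (N-1 i.i.d. draws from x) and average the
    focal's realized cost, computed through the elementary
    :func:`cueqs.core.resolve_activation` path rather than the
    enumeration machinery.

    Returns (means, standard_errors), one entry per strategy.
    """
    codes = _strategy_codes(strategies)
    x = np.asarray(x, dtype=float)
    draws = rng.multinomial(p.N - 1, x / x.sum(), size=n_samples)
    uniq, freq = np.unique(draws, axis=0, return_counts=True)
    means = np.empty(len(codes))
    ses = np.empty(len(codes))
    for i, code in enumerate(codes):
        costs_k = np.empty(len(uniq))
        for k, comp in enumerate(uniq):
            counts8 = np.zeros(8, dtype=np.int64)
            for j, c in enumerate(codes):
                counts8[c] += comp[j]
            counts8[code] += 1
            outcome = resolve_activation(GroupConfig(counts8), p)
            costs_k[k] = group_member_cost(Genotype(code), outcome, p)
        w = freq / n_samples
        mean = float(w @ costs_k)
        var = float(w @ (costs_k - mean) ** 2)
        means[i] = mean
        ses[i] = np.sqrt(var / n_samples)
    return means, ses


def mutation_matrix(
    p: ModelParams, strategies: Sequence[Genotype]
) -> np.ndarray:
    """Generator matrix of single-locus mutation flips within the
    strategy set: entry [i, j] is the per-replication rate of j -> i
    (i != j); diagonal balances the outflow.  Flips leading outside the
    strategy set are dropped (relevant only for reduced subsets)."""
    codes = _strategy_codes(strategies)
    k = len(codes)
    Qm = np.zeros((k, k))
    for j, gj in enumerate(codes):
        for locus, bit in enumerate((4, 2, 1)):
            gi = gj ^ bit
            if gi in codes:
                i = codes.index(gi)
                rate = p.mu[locus, 0] if gj & bit else p.mu[locus, 1]
                Qm[i, j] += rate
                Qm[j, j] -= rate
    return Qm


def cf_flow(
    x: np.ndarray,
    p: ModelParams,
    strategies: Sequence[Genotype] = FEASIBLE_3,
    include_mutation: bool = True,
) -> np.ndarray:
    """Replicator velocity on negative expected costs, with an optional
    linear mutation mixing term (one single-locus flip opportunity per
    replication per unit time)."""
    x = np.asarray(x, dtype=float)
    costs = cf_expected_costs(x, p, strategies)
    cbar = float(x @ costs)
    v = x * (cbar - costs) * (p.sigma / p.delta_C_max)
    if include_mutation and p.mu is not None and np.any(p.mu > 0):
        v = v + mutation_matrix(p, strategies) @ x
    return v


def cf_integrate(
    x0: np.ndarray,
    p: ModelParams,
    T: float,
    dt: float = 0.05,
    strategies: Sequence[Genotype] = FEASIBLE_3,
    include_mutation: bool = True,
    record_every: int = 1,
) -> pd.DataFrame:
    """Fixed-step RK4 integration of the CF flow (smooth polynomial
    field; no event handling needed)."""
    names = [Genotype(g).allele_string for g in _strategy_codes(strategies)]
    x = np.asarray(x0, dtype=float).copy()

    def f(x):
        return cf_flow(np.clip(x, 0.0, None) / max(np.clip(x, 0.0, None).sum(), 1e-300),
                       p, strategies, include_mutation)

    n_steps = int(round(T / dt))
    times = [0.0]
    states = [x.copy()]
    for step in range(1, n_steps + 1):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        x = np.clip(x, 0.0, None)
        x /= x.sum()
        if step % record_every == 0 or step == n_steps:
            times.append(step * dt)
            states.append(x.copy())
    out = pd.DataFrame(np.asarray(states), columns=[f"x_{n}" for n in names])
    out.insert(0, "t", times)
    return out


def cf_vector_field(
    grid_resolution: int,
    p: ModelParams,
    strategies: Sequence[Genotype] = FEASIBLE_3,
    include_mutation: bool = False,
) -> pd.DataFrame:
    """Sampled CF flow on a barycentric grid (3-strategy sets only)."""
    codes = _strategy_codes(strategies)
    if len(codes) != 3:
        raise ValueError("vector fields are defined on 3-strategy simplices")
    names = [Genotype(g).allele_string for g in codes]
    pts = simplex_grid(grid_resolution)
    vel = np.array([cf_flow(x, p, strategies, include_mutation) for x in pts])
    data = np.hstack([pts, vel])
    cols = [f"x_{n}" for n in names] + [f"v_{n}" for n in names]
    return pd.DataFrame(data, columns=cols)


@dataclass(frozen=True)
class CFFixedPoint:
    """A fixed point of the CF replicator flow with its linear
    stability class (eigenvalues of the reduced Jacobian, transversal
    directions included for boundary points)."""

    location: tuple[float, ...]
    eigenvalues: tuple[complex, ...]
    stability: str

    def to_record(self) -> dict:
        return {
            "location": list(self.location),
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "class": self.stability,
        }


def _reduced_jacobian(
    x: np.ndarray, p: ModelParams, strategies, include_mutation, h=1e-6
) -> np.ndarray:
    """Jacobian of the flow in the (k-1)-dim simplex parametrization
    x -> (x_1 .. x_{k-1}, 1 - sum), by central differences."""
    k = len(x)
    jac = np.empty((k - 1, k - 1))
    for j in range(k - 1):
        e = np.zeros(k)
        e[j] = 1.0
        e[-1] = -1.0  # stay on the simplex
        vp = cf_flow(np.clip(x + h * e, 0, None) / np.clip(x + h * e, 0, None).sum(),
                     p, strategies, include_mutation)
        vm = cf_flow(np.clip(x - h * e, 0, None) / np.clip(x - h * e, 0, None).sum(),
                     p, strategies, include_mutation)
        jac[:, j] = (vp - vm)[: k - 1] / (2 * h)
    return jac


def _classify(eigs: np.ndarray, tol: float = 1e-7) -> str:
    re = eigs.real
    if np.isnan(re).any():
        return "unclassified"
    if (re < -tol).all():
        return "stable"
    if (re > tol).all():
        return "unstable"
    if (re > tol).any() and (re < -tol).any():
        return "saddle"
    return "marginal"


def cf_fixed_points(
    p: ModelParams,
    strategies: Sequence[Genotype] = FEASIBLE_3,
    include_mutation: bool = False,
    grid_resolution: int = 50,
    polish_tol: float = 1e-10,
    merge_tol: float = 1e-6,
) -> list[CFFixedPoint]:
    """Locate and classify the fixed points of the CF flow.

    Vertices and edge zeros (1-D bracketing on each edge) are found
    exactly; interior points come from dense barycentric grid seeding
    (0.02 resolution by default) followed by Newton polish in reduced
    coordinates.  Duplicates are merged within ``merge_tol``; stability
    is the eigenvalue signature of the reduced Jacobian, so transversal
    directions at boundary points are included.
    """
    codes = _strategy_codes(strategies)
    k = len(codes)
    found: list[np.ndarray] = []

    def add(x: np.ndarray) -> None:
        x = np.clip(x, 0.0, None)
        x = x / x.sum()
        for y in found:
            if np.abs(x - y).max() < merge_tol:
                return
        found.append(x)

    if not include_mutation:
        # vertices are always fixed points of the pure replicator flow
        for i in range(k):
            v = np.zeros(k)
            v[i] = 1.0
            add(v)
        # edge zeros: the flow restricted to an edge is 1-D
        for i in range(k):
            for j in range(i + 1, k):
                def g(t, i=i, j=j):
                    x = np.zeros(k)
                    x[i] = 1.0 - t
                    x[j] = t
                    return cf_flow(x, p, strategies, False)[j]
                ts = np.linspace(1e-6, 1 - 1e-6, 201)
                vals = np.array([g(t) for t in ts])
                for a in range(len(ts) - 1):
                    if vals[a] == 0.0:
                        t0 = ts[a]
                    elif vals[a] * vals[a + 1] < 0:
                        t0 = brentq(g, ts[a], ts[a + 1], xtol=polish_tol)
                    else:
                        continue
                    x = np.zeros(k)
                    x[i] = 1.0 - t0
                    x[j] = t0
                    add(x)

    # interior (and, with mutation, global) seeding + Newton polish
    if k == 3:
        seeds = simplex_grid(grid_resolution)
        seeds = seeds[(seeds > 0).all(axis=1)] if not include_mutation else seeds
    else:
        rng = np.random.default_rng(0)
        seeds = rng.dirichlet(np.ones(k), size=400)

    def residual(y: np.ndarray) -> np.ndarray:
        x = np.concatenate([y, [1.0 - y.sum()]])
        if (x < -0.05).any():
            return np.full(k - 1, 1.0)  # push Newton back toward the simplex
        x = np.clip(x, 0.0, None)
        x = x / x.sum()
        return cf_flow(x, p, strategies, include_mutation)[: k - 1]

    speeds = np.array(
        [np.abs(cf_flow(s, p, strategies, include_mutation)).max() for s in seeds]
    )
    order = np.argsort(speeds)
    for idx in order[: max(40, (speeds < 1e-3).sum())]:
        sol = root(residual, seeds[idx][: k - 1], method="hybr",
                   options={"xtol": polish_tol})
        if not sol.success:
            continue
        x = np.concatenate([sol.x, [1.0 - sol.x.sum()]])
        if (x < -1e-8).any():
            continue
        x = np.clip(x, 0.0, None)
        x = x / x.sum()
        if np.abs(cf_flow(x, p, strategies, include_mutation)).max() < 1e-8:
            add(x)

    points = []
    for x in found:
        jac = _reduced_jacobian(x, p, strategies, include_mutation)
        eigs = np.linalg.eigvals(jac)
        points.append(
            CFFixedPoint(tuple(float(v) for v in x),
                         tuple(complex(e) for e in eigs),
                         _classify(eigs))
        )
    return points
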