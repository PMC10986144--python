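"""Strategy space and elementary game operations of the cue-based
quorum-sensing threshold public goods game.

Agents carry three binary functional loci:

* ``C`` — cooperation: when expressed, the agent contributes the public
  good *and*, as an inevitable byproduct, one constitutive dose of the
  quorum signal (the "cue").
* ``S`` — extra signaling: one additional signal dose, paid for at cost
  ``s`` by anyone who carries it.
* ``R`` — signal response: the receptor/transduction machinery that lets
  a ``C``-carrier make its cooperation conditional on the local signal
  level, at maintenance cost ``r``.

The eight genotypes interact in groups of ``N`` (the focal agent is a
member of its own group).  A conditional cooperator (``C`` and ``R``)
switches cooperation on only if the number of signal doses in its group
reaches the quorum threshold ``Q``; the group benefit ``b`` is delivered
to every member of a group containing at least ``kappa`` *active*
cooperators.  Fitness enters the dynamics only through metabolic-cost
differences, via the pairwise imitation kernel
``p_ij = 0.5 * (1 + sigma * (C_j - C_i) / dC_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "ModelParams",
    "GroupConfig",
    "ActivationOutcome",
    "signal_doses",
    "resolve_activation",
    "realized_cost",
    "imitation_probability",
    "mutate",
    "N_GENOTYPES",
    "DOSES",
    "HAS_C",
    "HAS_S",
    "HAS_R",
]

# Bit layout of the genotype code: C = 4, S = 2, R = 1.
_C_BIT = 4
_S_BIT = 2
_R_BIT = 1

N_GENOTYPES = 8


class Genotype(IntEnum):
    """One of the eight strategies, encoded as three binary loci.

    The integer value packs the loci as ``4*C + 2*S + R``.
    """

    LA = 0  # csr — Lazy: does nothing
    VO = 1  # csR — Voyeur: listens, never cooperates
    LI = 2  # cSr — Liar: fakes the signal, never cooperates
    CL = 3  # cSR — Curious liar: fakes the signal and listens
    TR = 4  # Csr — Trusty: unconditional cooperator
    SM = 5  # CsR — Smart: quorum-sensing conditional cooperator
    BO = 6  # CSr — Bouncer: unconditional cooperator, doubles the signal
    NE = 7  # CSR — Nerd: conditional cooperator, doubles the signal

    @property
    def has_C(self) -> bool:
        return bool(self.value & _C_BIT)

    @property
    def has_S(self) -> bool:
        return bool(self.value & _S_BIT)

    @property
    def has_R(self) -> bool:
        return bool(self.value & _R_BIT)

    @property
    def is_conditional_cooperator(self) -> bool:
        """C and R: cooperation gated by the quorum signal (Sm, Ne)."""
        return self.has_C and self.has_R

    @property
    def is_unconditional_cooperator(self) -> bool:
        """C without R: always cooperates (Tr, Bo)."""
        return self.has_C and not self.has_R

    @property
    def doses(self) -> int:
        """Constitutive signal doses emitted: the cue ([C]) plus extra ([S])."""
        return int(self.has_C) + int(self.has_S)

    @property
    def allele_string(self) -> str:
        """Canonical 3-letter serialization, e.g. ``"CsR"`` for Smart."""
        return (
            ("C" if self.has_C else "c")
            + ("S" if self.has_S else "s")
            + ("R" if self.has_R else "r")
        )

    @property
    def strategy_name(self) -> str:
        return _STRATEGY_NAMES[self]

    @classmethod
    def from_string(cls, text: str) -> "Genotype":
        """Parse either an allele string (``"CsR"``) or a strategy name.

        Strategy names are accepted in short (``"Sm"``) or long
        (``"Smart"``) form, case-insensitively; allele strings are
        case-sensitive because case encodes the allele state.
        """
        if len(text) == 3 and set(text.upper()) == {"C", "S", "R"}:
            code = 0
            for char, bit in zip(text, (_C_BIT, _S_BIT, _R_BIT)):
                if char.isupper():
                    code |= bit
            return cls(code)
        key = text.strip().lower()
        if key in _NAME_LOOKUP:
            return _NAME_LOOKUP[key]
        raise ValueError(f"unrecognized genotype {text!r}")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.allele_string


_STRATEGY_NAMES = {
    Genotype.LA: "Lazy",
    Genotype.VO: "Voyeur",
    Genotype.LI: "Liar",
    Genotype.CL: "Curious liar",
    Genotype.TR: "Trusty",
    Genotype.SM: "Smart",
    Genotype.BO: "Bouncer",
    Genotype.NE: "Nerd",
}

_NAME_LOOKUP = {}
for _g, _name in _STRATEGY_NAMES.items():
    _NAME_LOOKUP[_name.lower()] = _g
    _NAME_LOOKUP[_g.name.lower()] = _g  # "la", "vo", ...
_NAME_LOOKUP["curiousliar"] = Genotype.CL
_NAME_LOOKUP["curious_liar"] = Genotype.CL
_NAME_LOOKUP["bouncy"] = Genotype.BO

# Per-genotype lookup tables (indexed by genotype code).
HAS_C = np.array([bool(g & _C_BIT) for g in range(8)])
HAS_S = np.array([bool(g & _S_BIT) for g in range(8)])
HAS_R = np.array([bool(g & _R_BIT) for g in range(8)])
DOSES = (HAS_C.astype(np.int64) + HAS_S.astype(np.int64))

ALL_GENOTYPES = tuple(Genotype(i) for i in range(8))
FEASIBLE_3 = (Genotype.LA, Genotype.TR, Genotype.SM)


def _default_mu() -> np.ndarray:
    return np.zeros((3, 2))


@dataclass
class ModelParams:
    """All cost/benefit/threshold/dynamics parameters of the model family.

    Parameters
    ----------
    c0
        Baseline metabolic cost paid by every agent (dimensionless, 1).
    c, s, r
        Costs of cooperation, extra signaling, and signal response.
    b
        Cooperation benefit in (0, 1): the metabolic cost of a member of
        a quorate group is multiplied by ``1 - b``.
    sigma
        Selection strength of the imitation kernel, in (0, 1].
    kappa
        Cooperation threshold: minimum active cooperators per group for
        the benefit to be delivered (2..N).
    Q
        Quorum signal threshold; defaults to ``kappa`` (the evolutionary
        optimum assumed throughout).
    N
        Interaction-group size (9: the focal agent plus 8 co-members; on
        the lattice, the Moore neighborhood).
    P, M, G
        Population size (non-spatial ABM), lattice side, generations.
        Defaults are desk-scale; the published full scale (P=90,000,
        M=300, G=10,000) is supported via configuration.
    D
        Mean number of diffusion (site-swap) events per game step.
    rho
        Per-locus, per-direction functional mutation rate used to fill
        ``mu`` when ``mu`` is not given explicitly.
    mu
        (3, 2) array of per-replication mutation rates: rows are loci
        (C, S, R), columns are directions (active→inactive,
        inactive→active).
    """

    c0: float = 1.0
    c: float = 0.3
    s: float = 0.01
    r: float = 0.01
    b: float = 0.5
    sigma: float = 1.0
    kappa: int = 3
    Q: int | None = None
    N: int = 9
    P: int = 10_000
    M: int = 100
    G: int = 2_000
    D: float = 0.0
    rho: float = 0.0
    mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.b < 1.0:
            raise ValueError(f"b must be in (0, 1), got {self.b}")
        if not 0.0 < self.sigma <= 1.0:
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")
        if not 2 <= self.kappa <= self.N:
            raise ValueError(f"kappa must be in [2, N={self.N}], got {self.kappa}")
        if self.Q is None:
            self.Q = self.kappa
        if min(self.c0, self.c, self.s, self.r) < 0:
            raise ValueError("costs must be non-negative")
        if self.delta_C_max <= 0:
            raise ValueError("delta_C_max = c + s + r + b*c0 must be positive")
        if self.mu is None:
            self.mu = np.full((3, 2), float(self.rho))
        else:
            self.mu = np.asarray(self.mu, dtype=float)
            if self.mu.shape != (3, 2):
                raise ValueError("mu must have shape (3, 2): loci (C,S,R) x "
                                 "directions (on->off, off->on)")
            if ((self.mu < 0) | (self.mu > 1)).any():
                raise ValueError("mutation rates must lie in [0, 1]")

    @property
    def delta_C_max(self) -> float:
        """Largest possible cost difference between two interacting agents.

        Attained between an agent expressing every functional gene with
        no benefit and one expressing none with the full benefit:
        ``c + s + r + b*c0``.
        """
        return self.c + self.s + self.r + self.b * self.c0

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (Q re-derived
        from kappa unless given)."""
        if "kappa" in kwargs and "Q" not in kwargs:
            kwargs["Q"] = None
        if "rho" in kwargs and "mu" not in kwargs:
            kwargs["mu"] = None
        return replace(self, **kwargs)

    def static_costs(self) -> np.ndarray:
        """Per-genotype unconditional cost component ``c0 + s·[S] + r·[R]``."""
        return self.c0 + self.s * HAS_S + self.r * HAS_R


class GroupConfig:
    """A multiset of genotypes forming one interaction group of size N.

    The focal member is included in the counts.
    """

    __slots__ = ("counts",)

    def __init__(self, counts: Mapping[Genotype, int] | Sequence[int] | np.ndarray):
        if isinstance(counts, Mapping):
            arr = np.zeros(N_GENOTYPES, dtype=np.int64)
            for g, n in counts.items():
                arr[int(Genotype(g))] += int(n)
        else:
            arr = np.asarray(counts, dtype=np.int64).copy()
            if arr.shape != (N_GENOTYPES,):
                raise ValueError("counts must cover all 8 genotypes")
        if (arr < 0).any():
            raise ValueError("negative genotype count")
        self.counts = arr

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[Genotype | str]) -> "GroupConfig":
        arr = np.zeros(N_GENOTYPES, dtype=np.int64)
        for g in genotypes:
            if isinstance(g, str):
                g = Genotype.from_string(g)
            arr[int(g)] += 1
        return cls(arr)

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    def validate(self, N: int) -> None:
        if self.size != N:
            raise ValueError(
                f"interaction group must contain exactly N={N} members, "
                f"got {self.size}"
            )

    def __getitem__(self, g: Genotype) -> int:
        return int(self.counts[int(g)])

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupConfig) and bool(
            (self.counts == other.counts).all()
        )

    def __repr__(self) -> str:  # pragma: no cover
        parts = [
            f"{n}x{Genotype(i).allele_string}"
            for i, n in enumerate(self.counts)
            if n
        ]
        return "GroupConfig(" + " + ".join(parts) + ")"


@dataclass(frozen=True)
class ActivationOutcome:
    """Result of resolving signal doses and conditional activation in a
    group with a shared signal pool."""

    doses: int
    gamma_by_genotype: tuple[int, ...]  # indexed by genotype code
    n_active_cooperators: int
    theta: int

    def gamma(self, g: Genotype) -> int:
        return self.gamma_by_genotype[int(g)]


def signal_doses(group: GroupConfig, N: int = 9) -> int:
    """Total signal doses in the group: cooperators plus extra signalers.

    Every ``C``-carrier contributes one constitutive cue dose whether or
    not its cooperation is switched on, and every ``S``-carrier one
    extra dose (a Bouncer or Nerd therefore counts as two signalers).
    """
    group.validate(N)
    return int((group.counts * DOSES).sum())


def resolve_activation(group: GroupConfig, params: ModelParams) -> ActivationOutcome:
    """Resolve conditional-cooperator activation and the benefit indicator
    for a group sharing a common signal pool.

    Used as-is by the configuration-field and non-spatial agent-based
    models, where all members of a randomly drawn group evaluate the
    same doses.  The lattice model instead evaluates each agent against
    its own Moore neighborhood (see :mod:`cueqs.lattice`).
    """
    doses = signal_doses(group, params.N)
    quorum = doses >= params.Q
    gamma = tuple(
        1 if (HAS_C[g] and (not HAS_R[g] or quorum)) else 0 for g in range(8)
    )
    n_active = int(sum(group.counts[g] for g in range(8) if gamma[g]))
    theta = 1 if n_active >= params.kappa else 0
    return ActivationOutcome(doses, gamma, n_active, theta)


def realized_cost(
    g: Genotype, gamma: int, theta: int, params: ModelParams
) -> float:
    """Metabolic cost of an agent given its activation state.

    ``cost = (1 - theta*b) * (c0 + gamma*c*[C] + s*[S] + r*[R])`` — the
    benefit discounts the whole bracket, including the signaling and
    response costs.
    """
    g = Genotype(g)
    if gamma and not g.has_C:
        raise ValueError(f"gamma=1 is inconsistent with non-cooperator {g!r}")
    bracket = (
        params.c0
        + (params.c * gamma if g.has_C else 0.0)
        + (params.s if g.has_S else 0.0)
        + (params.r if g.has_R else 0.0)
    )
    return (1.0 - theta * params.b) * bracket


def group_member_cost(
    g: Genotype, outcome: ActivationOutcome, params: ModelParams
) -> float:
    """Realized cost of a member of a shared-pool group with the given
    activation outcome."""
    return realized_cost(g, outcome.gamma(g), outcome.theta, params)


def imitation_probability(
    cost_i: float, cost_j: float, params: ModelParams
) -> float:
    """Probability that player i's offspring replaces player j.

    ``p_ij = 0.5 * (1 + sigma * dw_ij)`` with
    ``dw_ij = (C_j - C_i) / dC_max``; the complementary event has
    probability ``p_ji = 1 - p_ij`` exactly.  The result is clamped to
    [0, 1] as a guard for user-supplied ``sigma > 1``; with consistent
    parameters ``|dw| <= 1`` and no clamping occurs.
    """
    dmax = params.delta_C_max
    dw = (cost_j - cost_i) / dmax
    if abs(dw) > 1.0 + 1e-12:
        raise ValueError(
            f"|cost difference| {abs(cost_j - cost_i):g} exceeds "
            f"delta_C_max {dmax:g}; inconsistent parameters"
        )
    return float(min(1.0, max(0.0, 0.5 * (1.0 + params.sigma * dw))))


def mutate(
    g: Genotype, mu: np.ndarray, rng: np.random.Generator
) -> Genotype:
    """Mutate a genotype at replication.

    Each of the three loci flips independently, with a direction-specific
    rate: ``mu[locus, 0]`` is the active→inactive rate and
    ``mu[locus, 1]`` the inactive→active rate, for loci (C, S, R).
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (3, 2):
        raise ValueError("mu must have shape (3, 2)")
    code = int(g)
    for locus, bit in enumerate((_C_BIT, _S_BIT, _R_BIT)):
        active = bool(code & bit)
        rate = mu[locus, 0] if active else mu[locus, 1]
        if rate > 0.0 and rng.random() < rate:
            code ^= bit
    return Genotype(code)
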