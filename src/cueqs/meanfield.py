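"""Mean-field (infinite population, infinite group) dynamics.

In the limit ``N -> inf`` with ``kappa/N -> K``, every interaction group
mirrors the global strategy frequencies, so only three strategies can
persist: Lazy (La), Trusty (Tr), and Smart (Sm).  The state is a point
on the 2-simplex ``x = (x_La, x_Tr, x_Sm)`` and the dynamic is the
replicator flow on negative metabolic costs (the exact mean field of the
pairwise imitation process, in which the baseline fitness cancels).

The flow is piecewise smooth: the conditional cooperator's activation
indicator ``gamma_Sm = [x_C >= K]`` and the benefit indicator
``theta = [a >= K]`` are hard step functions of the state, so the
simplex is partitioned by the two surfaces ``x_C = K`` and ``a = K``.
Integration is event-aware: steps that would jump across a surface are
bisected to land on it.

The optional ``focal_offset`` parameter (``1/N`` in a finite-group
reading, 0 in the pure continuum) lets a cooperator's own contribution
count toward the thresholds of its *own* group, which is what makes the
threshold-pinned La/Tr coexistence point one-sidedly stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "MFParams",
    "MFFixedPoint",
    "mf_costs",
    "mf_flow",
    "mf_integrate",
    "mf_vector_field",
    "mf_fixed_points",
    "STRATEGIES_3",
]

STRATEGIES_3 = ("La", "Tr", "Sm")
_SIMPLEX_TOL = 1e-12


@dataclass
class MFParams:
    """Parameters of the three-strategy mean-field flow.

    ``K`` is the cooperation threshold as a fraction of group size
    (``kappa/N``); cost and benefit parameters are as in
    :class:`cueqs.core.ModelParams`.  ``s`` only enters the time-scale
    normalization ``delta_C_max`` (no extra-signal strategies exist in
    the reduced system).
    """

    K: float = 1.0 / 3.0
    c0: float = 1.0
    c: float = 0.3
    r: float = 0.01
    b: float = 0.5
    sigma: float = 1.0
    s: float = 0.0
    focal_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"K must be in (0, 1), got {self.K}")
        if not 0.0 < self.b < 1.0:
            raise ValueError(f"b must be in (0, 1), got {self.b}")

    @property
    def delta_C_max(self) -> float:
        return self.c + self.s + self.r + self.b * self.c0


def _check_simplex(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValueError("state must be a 3-vector (x_La, x_Tr, x_Sm)")
    if (x < -_SIMPLEX_TOL).any() or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"not a simplex point: {x}")
    return x


def mf_costs(x: np.ndarray, p: MFParams) -> np.ndarray:
    """Per-strategy expected metabolic costs at frequencies x.

    All C-carriers emit the cue, so the signal-dose fraction equals the
    cooperator fraction ``x_C = x_Tr + x_Sm``.  Smart activates iff
    ``x_C >= K``; the active-cooperator fraction is
    ``a = x_Tr + gamma_Sm * x_Sm`` and the benefit is on iff ``a >= K``.
    With ``focal_offset > 0`` a focal cooperator additionally counts its
    own doses/activity toward the thresholds of its own group.
    """
    x = _check_simplex(x)
    off = p.focal_offset
    x_c = x[1] + x[2]
    gamma_sm_global = 1 if x_c >= p.K else 0
    gamma_sm_focal = 1 if x_c + off >= p.K else 0
    a = x[1] + gamma_sm_global * x[2]
    theta_la = 1 if a >= p.K else 0
    theta_tr = 1 if a + off >= p.K else 0
    theta_sm = 1 if a + off * gamma_sm_focal >= p.K else 0
    return np.array(
        [
            (1.0 - theta_la * p.b) * p.c0,
            (1.0 - theta_tr * p.b) * (p.c0 + p.c),
            (1.0 - theta_sm * p.b) * (p.c0 + gamma_sm_focal * p.c + p.r),
        ]
    )


def _regime(x: np.ndarray, p: MFParams) -> tuple[int, int]:
    """Discrete regime labels (gamma_Sm, theta) at a state."""
    x_c = x[1] + x[2]
    gamma = 1 if x_c + p.focal_offset >= p.K else 0
    a = x[1] + (1 if x_c >= p.K else 0) * x[2]
    theta = 1 if a >= p.K else 0
    return gamma, theta


def mf_flow(x: np.ndarray, p: MFParams) -> np.ndarray:
    """Replicator velocity on negative costs, rescaled by sigma/dC_max.

    ``dx_i/dt = x_i * (cbar - cost_i) * sigma / dC_max`` — strategies
    cheaper than the population mean grow.  Velocities sum to zero.
    """
    x = _check_simplex(x)
    costs = mf_costs(x, p)
    cbar = float(x @ costs)
    return x * (cbar - costs) * (p.sigma / p.delta_C_max)


def mf_integrate(
    x0: np.ndarray, p: MFParams, T: float, dt: float = 0.01
) -> pd.DataFrame:
    """Integrate the flow with fixed-step RK4 and event handling at the
    discontinuity surfaces (regime changes trigger step bisection).

    Returns a tidy trajectory with columns t, x_La, x_Tr, x_Sm.
    """
    x = _check_simplex(x0).copy()
    times = [0.0]
    states = [x.copy()]
    t = 0.0

    def rk4(x: np.ndarray, h: float) -> np.ndarray:
        k1 = mf_flow(x, p)
        k2 = mf_flow(_project(x + 0.5 * h * k1), p)
        k3 = mf_flow(_project(x + 0.5 * h * k2), p)
        k4 = mf_flow(_project(x + h * k3), p)
        return _project(x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4))

    while t < T - 1e-12:
        h = min(dt, T - t)
        x_new = rk4(x, h)
        if _regime(x_new, p) != _regime(x, p):
            # bisect the step size to land just past the surface
            lo, hi = 0.0, h
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if _regime(rk4(x, mid), p) == _regime(x, p):
                    lo = mid
                else:
                    hi = mid
            x_new = rk4(x, hi)
            h = hi
        x = x_new
        t += h
        times.append(t)
        states.append(x.copy())
    out = pd.DataFrame(np.asarray(states), columns=[f"x_{s}" for s in STRATEGIES_3])
    out.insert(0, "t", times)
    return out


def _project(x: np.ndarray) -> np.ndarray:
    """Clip tiny negative components and renormalize onto the simplex."""
    x = np.where(x < 0.0, 0.0, x)
    return x / x.sum()


def simplex_grid(resolution: int) -> np.ndarray:
    """All barycentric grid points i/resolution on the 2-simplex."""
    pts = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            k = resolution - i - j
            pts.append((i, j, k))
    return np.asarray(pts, dtype=float) / resolution


def mf_vector_field(grid_resolution: int, p: MFParams) -> pd.DataFrame:
    """Sample the flow on a barycentric grid.

    Returns the CSV schema columns x_La, x_Tr, x_Sm, v_La, v_Tr, v_Sm.
    """
    pts = simplex_grid(grid_resolution)
    vel = np.array([mf_flow(x, p) for x in pts])
    data = np.hstack([pts, vel])
    cols = [f"x_{s}" for s in STRATEGIES_3] + [f"v_{s}" for s in STRATEGIES_3]
    return pd.DataFrame(data, columns=cols)


@dataclass(frozen=True)
class MFFixedPoint:
    """A stationary state of the mean-field flow.

    ``kind`` is "vertex" for monomorphic states or "threshold-pinned"
    for stationary states pinned to a discontinuity surface of the
    piecewise flow (these are stable only one-sidedly: robust to
    fluctuations smaller than the 1/N band, per the finite-group
    reading).
    """

    location: tuple[float, float, float]
    kind: str
    stability: str
    eigenvalues: tuple[float, ...]
    note: str = ""


def mf_fixed_points(p: MFParams, grid_resolution: int = 50) -> list[MFFixedPoint]:
    """Locate and classify the stationary states of the mean-field flow.

    Within each smooth piece the per-strategy costs are constants, so
    the replicator flow can only vanish at the simplex vertices (or on
    non-generic neutral sets where two costs tie exactly).  In addition,
    stationary states can sit pinned on the threshold surfaces.  The
    La/Tr coexistence point at ``x_Tr = K`` is reported when a just-
    quorate Trusty out-competes a sub-quorate Lazy — the cost comparison
    ``(1-b)(c0+c) < c0`` — which is what makes the pinned state
    attracting from within the 1/N band below the threshold.  The
    analogous La/Sm candidate never qualifies: a Smart focal whose own
    cue tips it over the quorum still sits in a group whose *other*
    conditional cooperators are inactive, so it pays ``c0 + c + r``
    without the benefit.
    """
    points: list[MFFixedPoint] = []
    vertices = np.eye(3)
    for i, vertex in enumerate(vertices):
        costs = mf_costs(vertex, p)
        # invader growth rates: lambda_j = (cost_resident - cost_j)*sigma/dCmax
        eigs = tuple(
            (costs[i] - costs[j]) * p.sigma / p.delta_C_max
            for j in range(3)
            if j != i
        )
        if max(eigs) < 0:
            stab = "stable"
        elif min(eigs) > 0:
            stab = "unstable"
        elif max(eigs) <= 0:
            stab = "marginal"
        else:
            stab = "saddle" if min(eigs) < 0 else "unstable"
        points.append(
            MFFixedPoint(tuple(vertex), "vertex", stab, eigs,
                         note=f"{STRATEGIES_3[i]} vertex")
        )

    # Threshold-pinned La/Tr candidate at x_Tr = K on the La-Tr edge.
    # Band argument (focal inclusion): for x_Tr in (K - 1/N, K) a Trusty
    # focal's own group is quorate (theta=1) while a Lazy focal's is not
    # (theta=0); Trusty is then favored iff its discounted cost is lower.
    cost_tr_band = (1.0 - p.b) * (p.c0 + p.c)
    cost_la_band = p.c0
    if cost_tr_band < cost_la_band:
        points.append(
            MFFixedPoint(
                (1.0 - p.K, p.K, 0.0),
                "threshold-pinned",
                "attracting (one-sided)",
                ((cost_la_band - cost_tr_band) * p.sigma / p.delta_C_max,),
                note="La/Tr coexistence pinned at the benefit threshold; "
                "stable only against fluctuations within the 1/N band",
            )
        )
    # La/Sm candidate at x_Sm = K: the Smart focal activates on its own
    # cue but its group's active-cooperator fraction stays below K
    # (co-member conditionals are sub-quorate), so theta=0 and it pays
    # c0 + c + r against the Lazy focal's c0 — never favored.
    cost_sm_band = p.c0 + p.c + p.r
    if cost_sm_band < cost_la_band:  # pragma: no cover - impossible for r,c > 0
        points.append(
            MFFixedPoint(
                (1.0 - p.K, 0.0, p.K),
                "threshold-pinned",
                "attracting (one-sided)",
                ((cost_la_band - cost_sm_band) * p.sigma / p.delta_C_max,),
                note="La/Sm pinned point",
            )
        )

    # Numerical sweep for any residual interior zeros (non-generic cost
    # ties); reported unclassified rather than polished.
    for x in simplex_grid(grid_resolution):
        if (x == 0).sum() >= 2:
            continue  # vertices handled above
        v = mf_flow(x, p)
        if np.abs(v).max() < 1e-14 and not any(
            np.allclose(x, fp.location, atol=1e-9) for fp in points
        ):
            costs = mf_costs(x, p)
            support = x > 0
            if np.ptp(costs[support]) < 1e-14:
                points.append(
                    MFFixedPoint(tuple(x), "neutral", "unclassified", (),
                                 note="cost tie on support (non-generic)")
                )
    return points
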