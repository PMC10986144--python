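"""Reproduction harnesses: simulated vector fields on the 3-strategy
simplex and steady-state genotype-distribution sweeps over
(kappa, s, r, D).

Desk-scale defaults (100 x 100 lattice, 2,000 generations, 3
replicates) keep a full sweep tractable on one CPU; the published full
scale (300 x 300, 10,000 generations) is reachable through
``paper_scale_params`` or the CLI's ``--paper-scale`` flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import GENOTYPE_COLUMNS, Population, exact_counts, run_generations
from .core import FEASIBLE_3, Genotype, ModelParams
from .lattice import LatticeState, run as lattice_run
from .meanfield import simplex_grid

__all__ = [
    "SweepSpec",
    "simulated_vector_field",
    "steady_state_sweep",
    "paper_scale_params",
]

_FEASIBLE_CODES = [int(g) for g in FEASIBLE_3]
_FEASIBLE_NAMES = [Genotype(g).allele_string for g in _FEASIBLE_CODES]


def paper_scale_params(p: ModelParams) -> ModelParams:
    """The published full-scale problem sizes (M=300, G=10,000,
    P=90,000) with all other parameters unchanged."""
    return p.with_(M=300, G=10_000, P=90_000)


def _freqs8(freqs3: np.ndarray) -> np.ndarray:
    vec = np.zeros(8)
    vec[_FEASIBLE_CODES] = freqs3
    return vec


def simulated_vector_field(
    model: str,
    p: ModelParams,
    grid_resolution: int = 5,
    horizon: int = 5,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical drift field of a stochastic model tier on the
    3-strategy (La, Tr, Sm) simplex.

    For every barycentric grid point, populations are initialized at
    those frequencies (exact-count rounding, random arrangement), run
    for ``horizon`` generations, and the mean per-generation frequency
    displacement is reported with its dispersion across replicates.
    """
    if model not in ("lattice", "abm"):
        raise ValueError("model must be 'lattice' or 'abm'")
    pts = simplex_grid(grid_resolution)
    seeds = np.random.SeedSequence(seed).spawn(len(pts) * replicates)
    rows = []
    for i, x0 in enumerate(pts):
        drifts = np.empty((replicates, 3))
        for rep in range(replicates):
            rng = np.random.default_rng(seeds[i * replicates + rep])
            if model == "lattice":
                state = LatticeState.random(_freqs8(x0), p.M, rng)
                start = state.frequencies()[_FEASIBLE_CODES]
                lattice_run(state, p, horizon, record_every=horizon)
                end = state.frequencies()[_FEASIBLE_CODES]
            else:
                pop = Population.from_frequencies(_freqs8(x0), p.P, rng)
                start = pop.frequencies()[_FEASIBLE_CODES]
                run_generations(pop, p, horizon, record_every=horizon)
                end = pop.frequencies()[_FEASIBLE_CODES]
            drifts[rep] = (end - start) / horizon
        mean = drifts.mean(axis=0)
        disp = drifts.std(axis=0, ddof=1) if replicates > 1 else np.zeros(3)
        rows.append([*x0, *mean, *disp])
    cols = (
        [f"x_{n}" for n in _FEASIBLE_NAMES]
        + [f"v_{n}" for n in _FEASIBLE_NAMES]
        + [f"sd_{n}" for n in _FEASIBLE_NAMES]
    )
    return pd.DataFrame(rows, columns=cols)


@dataclass
class SweepSpec:
    """A steady-state parameter sweep over the lattice (or CF) model.

    ``axes`` maps ModelParams field names (kappa, s, r, D, ...) to the
    value lists to scan; every cell starts from even 8-strategy
    frequencies with functional mutation at rate ``base.rho`` and the
    first ``burn_in`` fraction of generations is discarded before
    averaging.
    """

    base: ModelParams
    axes: dict[str, list] = field(default_factory=dict)
    replicates: int = 3
    seed: int = 0
    burn_in: float = 0.5
    record_every: int = 10

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError("burn_in must be in [0, 1)")
        for name, values in self.axes.items():
            for v in values:
                self.base.with_(**{name: v})  # validates each axis value

    def cells(self) -> list[dict]:
        names = sorted(self.axes)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]


def _run_cell(
    cell: dict, spec: SweepSpec, seeds
) -> pd.DataFrame:
    p = spec.base.with_(**cell)
    even8 = np.full(8, 1.0 / 8.0)
    burn_gen = int(spec.burn_in * p.G)
    means = np.zeros((spec.replicates, 8))
    disps = np.zeros((spec.replicates, 8))
    for rep in range(spec.replicates):
        rng = np.random.default_rng(seeds[rep])
        state = LatticeState.random(even8, p.M, rng)
        traj = lattice_run(state, p, p.G, record_every=spec.record_every)
        window = traj[traj["generation"] > burn_gen][GENOTYPE_COLUMNS]
        means[rep] = window.mean(axis=0)
        disps[rep] = window.std(axis=0, ddof=0)
    rows = []
    for g in range(8):
        rows.append(
            {
                **cell,
                "genotype": GENOTYPE_COLUMNS[g],
                "mean_freq": means[:, g].mean(),
                "dispersion": float(
                    np.sqrt((disps[:, g] ** 2).mean() + means[:, g].var())
                ),
            }
        )
    return pd.DataFrame(rows)


def steady_state_sweep(spec: SweepSpec, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the sweep and return a tidy table (one row per cell x
    genotype): per-cell mean and dispersion of the post-burn-in genotype
    frequencies, averaged over replicates.

    With ``out_dir``, each completed cell is written to its own CSV and
    skipped on restart (resumability); failed cells are logged with an
    ``error`` column and the sweep continues.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    cells = spec.cells()
    root_seq = np.random.SeedSequence(spec.seed)
    all_seeds = root_seq.spawn(len(cells))
    frames = []
    for i, cell in enumerate(cells):
        tag = "_".join(f"{k}-{cell[k]}" for k in sorted(cell)) or "base"
        path = out_dir / f"cell_{tag}.csv" if out_dir is not None else None
        if path is not None and path.exists():
            frames.append(pd.read_csv(path))
            continue
        try:
            df = _run_cell(cell, spec, all_seeds[i].spawn(spec.replicates))
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            df = pd.DataFrame([{**cell, "genotype": None, "mean_freq": np.nan,
                                "dispersion": np.nan, "error": str(exc)}])
        if path is not None:
            df.to_csv(path, index=False)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
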