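"""Lattice model: Moore groups, two-stage local activation, diffusion,
and conservation/closure of the update rules."""

import numpy as np
import pytest

from cueqs import _kernels
from cueqs.core import Genotype, ModelParams
from cueqs.lattice import (
    LatticeState,
    diffusion_steps,
    game_step,
    load_snapshot,
    moore_group,
    run,
    save_snapshot,
    site_cost,
)

LA, TR, SM, BO = Genotype.LA, Genotype.TR, Genotype.SM, Genotype.BO


def lattice_of(genotype, M, seed=0):
    return LatticeState.random({genotype: 1.0}, M, seed)


class TestMooreGroup:
    def test_uniform_lattice(self):
        state = lattice_of(TR, 5)
        group = moore_group(state, (2, 2))
        assert group.size == 9 and group[TR] == 9

    def test_corner_wraps_around_the_torus(self):
        state = lattice_of(LA, 5)
        # mark the wrapped rows/cols reachable from (0, 0)
        for x in (4, 0, 1):
            for y in (4, 0, 1):
                state.grid[x, y] = int(TR)
        group = moore_group(state, (0, 0))
        assert group[TR] == 9

    def test_group_size_is_always_nine(self, rng):
        state = LatticeState.random(np.full(8, 1 / 8), 7, rng)
        for site in [(0, 0), (3, 4), (6, 6), (0, 6)]:
            assert moore_group(state, site).size == 9


class TestSiteCost:
    def test_all_trusty_lattice_is_quorate_everywhere(self, params):
        state = lattice_of(TR, 6)
        expected = (1 - params.b) * (params.c0 + params.c)
        assert site_cost(state, (2, 3), params) == pytest.approx(expected)

    def test_all_lazy_lattice_pays_baseline(self, params):
        state = lattice_of(LA, 6)
        assert site_cost(state, (1, 1), params) == params.c0

    def test_lone_smart_stays_silent(self, params):
        state = lattice_of(LA, 8)
        state.grid[4, 4] = int(SM)
        # own doses = 1 < Q=3: gamma=0, no quorum, pays only c0 + r
        assert site_cost(state, (4, 4), params) == pytest.approx(
            params.c0 + params.r
        )

    def test_per_agent_activation_uses_own_neighborhood(self, params):
        # a Smart two steps from a signal cluster activates only if its
        # OWN 3x3 block reaches the quorum
        state = lattice_of(LA, 9)
        state.grid[4, 4] = int(SM)
        state.grid[4, 5] = int(TR)
        state.grid[4, 6] = int(BO)  # two doses, adjacent to the Tr
        # Sm's own group: doses = Sm(1) + Tr(1) + Bo? (4,6) is not in
        # (4,4)'s Moore block -> doses=2 < 3 -> silent
        assert site_cost(state, (4, 4), params) == pytest.approx(
            params.c0 + params.r
        )
        # move the Bouncer adjacent: now doses = 1+1+2 = 4 >= Q
        state.grid[4, 6] = int(LA)
        state.grid[3, 4] = int(BO)
        cost = site_cost(state, (4, 4), params)
        # active (pays c) but n_active = Sm+Tr+Bo = 3 >= kappa: benefit on
        assert cost == pytest.approx(
            (1 - params.b) * (params.c0 + params.c + params.r)
        )

    def test_cost_depends_only_on_5x5_block(self, params, rng):
        state = LatticeState.random(np.full(8, 1 / 8), 11, rng)
        site = (5, 5)
        ref = site_cost(state, site, params)
        for _ in range(20):
            other = state.grid.copy()
            mask = np.ones_like(other, dtype=bool)
            mask[3:8, 3:8] = False
            other[mask] = rng.integers(0, 8, size=mask.sum())
            state2 = LatticeState(grid=other, rng=rng)
            assert site_cost(state2, site, params) == ref

    def test_cached_kernel_matches_reference(self, params, rng):
        grid = rng.integers(0, 8, (12, 12)).astype(np.int64)
        doses = _kernels.dose_field(grid)
        for x in range(12):
            for y in range(12):
                ref = _kernels.site_cost_kernel(
                    grid, x, y, params.Q, params.kappa, params.c0,
                    params.c, params.s, params.r, params.b
                )
                fast = _kernels._site_cost_cached(
                    grid, doses, x, y, params.Q, params.kappa, params.c0,
                    params.c, params.s, params.r, params.b
                )
                assert fast == ref


class TestGameStep:
    def test_identical_neighbors_leave_grid_unchanged(self, rng):
        p = ModelParams(rho=0.0)
        state = lattice_of(TR, 6, rng)
        before = state.grid.copy()
        game_step(state, p)
        assert (state.grid == before).all()

    def test_at_most_one_site_changes_without_mutation(self, rng):
        p = ModelParams(rho=0.0)
        state = LatticeState.random(np.full(8, 1 / 8), 10, rng)
        for _ in range(50):
            before = state.grid.copy()
            game_step(state, p)
            assert (state.grid != before).sum() <= 1

    def test_lazy_favored_against_subquorate_trusty(self, params):
        # embedded adjacent La-Tr pair in an all-La lattice: Tr pays c
        # with no benefit, so P(La wins) > 0.5 by sigma*c/dC_max
        state = lattice_of(LA, 10)
        state.grid[5, 5] = int(TR)
        c_tr = site_cost(state, (5, 5), params)
        c_la = site_cost(state, (5, 6), params)
        assert c_tr == pytest.approx(params.c0 + params.c)
        assert c_la == pytest.approx(params.c0)
        from cueqs.core import imitation_probability
        p_la_wins = imitation_probability(c_la, c_tr, params)
        assert p_la_wins == pytest.approx(
            0.5 * (1 + params.sigma * params.c / params.delta_C_max)
        )


class TestDiffusion:
    def test_zero_diffusion_is_identity(self, rng):
        state = LatticeState.random(np.full(8, 1 / 8), 8, rng)
        before = state.grid.copy()
        diffusion_steps(state, ModelParams(D=0.0))
        assert (state.grid == before).all()

    def test_swaps_preserve_genotype_counts(self, rng):
        state = LatticeState.random(np.full(8, 1 / 8), 8, rng)
        before = np.bincount(state.grid.ravel(), minlength=8)
        for _ in range(200):
            diffusion_steps(state, ModelParams(D=2.0))
        after = np.bincount(state.grid.ravel(), minlength=8)
        assert (before == after).all()

    def test_poisson_swap_count_mean(self, rng):
        p = ModelParams(D=0.5)
        state = LatticeState.random(np.full(8, 1 / 8), 8, rng)
        n_steps = 100_000
        total = 0
        for _ in range(n_steps):
            diffusion_steps(state, p)
            total += state.last_swap_count
        mean = total / n_steps
        se = np.sqrt(p.D / n_steps)
        assert abs(mean - p.D) < 3 * se


class TestRun:
    def test_frequencies_sum_to_one_and_closure(self):
        freqs = np.zeros(8)
        freqs[[0, 4, 5]] = 1 / 3
        p = ModelParams(rho=0.0, D=0.1)
        state = LatticeState.random(freqs, 30, 4)
        traj = run(state, p, 20, record_every=5)
        vals = traj.iloc[:, 1:].to_numpy()
        assert np.allclose(vals.sum(axis=1), 1.0, atol=1e-12)
        assert (vals[:, [1, 2, 3, 6, 7]] == 0).all()  # closure w/o mutation

    def test_seed_determinism_is_bitwise(self):
        freqs = np.full(8, 1 / 8)
        grids = []
        for _ in range(2):
            state = LatticeState.random(freqs, 20, 13)
            run(LatticeState(state.grid, state.rng), ModelParams(D=0.5, rho=1e-4), 10)
            grids.append(state.grid.copy())
        assert (grids[0] == grids[1]).all()

    def test_population_is_constant(self):
        state = LatticeState.random(np.full(8, 1 / 8), 20, 2)
        run(state, ModelParams(D=0.3), 10)
        assert np.bincount(state.grid.ravel(), minlength=8).sum() == 400


class TestSnapshots:
    def test_round_trip(self, tmp_path, rng):
        state = LatticeState.random(np.full(8, 1 / 8), 9, rng)
        path = tmp_path / "snap.txt"
        save_snapshot(state, path)
        loaded = load_snapshot(path)
        assert (loaded.grid == state.grid).all()
        first_token = path.read_text().split()[0]
        assert first_token in {Genotype(g).allele_string for g in range(8)}
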