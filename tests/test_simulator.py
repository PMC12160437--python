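"""Movement kernel sampling, step selection, and paired simulation."""

import numpy as np
import pytest
from scipy import special, stats

from dyadmove import MovementKernel, ScenarioConfig, simulate_crw_pair, simulate_pair
from dyadmove.landscapes import LandscapeGrid
from dyadmove.simulator import (
    draw_candidate_steps,
    enforce_barriers,
    reflect,
    select_step_habitat,
    select_step_social,
    wrap_angle,
)


class TestKernelSampling:
    def test_sample_moments_match_kernel(self, rng):
        kernel = MovementKernel()
        ends, lengths, turns = draw_candidate_steps(rng, kernel, (0.0, 0.0), 0.0, 100_000)
        assert lengths.mean() == pytest.approx(6 * 0.15, rel=0.02)
        # mean cosine of a von Mises(0, kappa) is the Bessel ratio I1/I0
        expected = special.i1e(4.0) / special.i0e(4.0)
        assert np.cos(turns).mean() == pytest.approx(expected, abs=0.01)

    def test_huge_kappa_degenerates_to_heading(self, rng):
        kernel = MovementKernel(kappa=1e6)
        _, _, turns = draw_candidate_steps(rng, kernel, (0.0, 0.0), 1.0, 1000)
        assert np.abs(turns).max() < 0.01

    def test_endpoints_polar_geometry(self, rng):
        ends, lengths, turns = draw_candidate_steps(rng, MovementKernel(), (2.0, 3.0), 0.7, 50)
        d = np.hypot(ends[:, 0] - 2.0, ends[:, 1] - 3.0)
        np.testing.assert_allclose(d, lengths, rtol=1e-10)


class TestReflect:
    @pytest.mark.parametrize(
        "coord,expected",
        [(-0.3, 0.3), (100.5, 99.5), (55.0, 55.0), (-100.2, 99.8), (250.0, 50.0)],
    )
    def test_mirrors(self, coord, expected):
        assert reflect(coord, 100.0) == pytest.approx(expected)

    def test_always_inside(self, rng):
        vals = reflect(rng.uniform(-1000, 1000, 10_000), 100.0)
        assert np.all((vals >= 0) & (vals <= 100))


class TestSelection:
    def test_argmax_habitat(self, rng):
        grid = LandscapeGrid(values=np.array([[0.1, 0.9], [0.1, 0.9]]), cell_size=1.0)
        cands = np.array([[0.5, 0.5], [1.5, 0.5]])
        picks = {
            select_step_habitat(cands, grid, 5.0, np.inf, rng, current_position=(0.5, 0.5))
            for _ in range(20)
        }
        assert picks == {1}

    def test_zero_bias_is_uniform(self, rng):
        grid = LandscapeGrid(values=np.array([[0.1, 0.9], [0.1, 0.9]]), cell_size=1.0)
        cands = np.array([[0.5, 0.5], [1.5, 0.5]])
        picks = [
            select_step_habitat(cands, grid, 5.0, 0.0, rng, current_position=(0.5, 0.5))
            for _ in range(4000)
        ]
        assert np.mean(picks) == pytest.approx(0.5, abs=0.03)

    def test_softmax_habitat_probability(self, rng):
        # closed-form softmax oracle: habitat 0.8 vs 0.2 at beta 5
        grid = LandscapeGrid(values=np.array([[0.8, 0.2], [0.8, 0.2]]), cell_size=1.0)
        cands = np.array([[0.5, 0.5], [1.5, 0.5]])
        picks = [
            select_step_habitat(cands, grid, 5.0, 5.0, rng, current_position=(0.5, 0.5))
            for _ in range(5000)
        ]
        expected = np.exp(4.0) / (np.exp(4.0) + np.exp(1.0))
        assert np.mean(np.array(picks) == 0) == pytest.approx(expected, abs=0.02)

    def test_social_softmax_probability(self, rng):
        # candidates at distances 1 and 3 from the partner, beta_soc = 1
        cands = np.array([[1.0, 0.0], [3.0, 0.0]])
        picks = [select_step_social(cands, (0.0, 0.0), 1.0, rng) for _ in range(5000)]
        expected = np.exp(-1.0) / (np.exp(-1.0) + np.exp(-3.0))
        assert np.mean(np.array(picks) == 0) == pytest.approx(expected, abs=0.02)

    def test_social_zero_bias_uniform(self, rng):
        cands = np.array([[1.0, 0.0], [30.0, 0.0]])
        picks = [select_step_social(cands, (0.0, 0.0), 0.0, rng) for _ in range(4000)]
        assert np.mean(picks) == pytest.approx(0.5, abs=0.03)


class TestBarrierFiltering:
    def test_no_barriers_passes_everything(self):
        grid = LandscapeGrid(values=np.full((4, 4), 0.5), barrier_mask=np.zeros((4, 4), bool))
        cands = np.array([[0.5, 0.5], [2.5, 3.5]])
        assert list(enforce_barriers(cands, grid)) == [0, 1]

    def test_all_blocked_returns_empty(self):
        mask = np.ones((4, 4), bool)
        grid = LandscapeGrid(values=np.zeros((4, 4)), barrier_mask=mask)
        cands = np.array([[0.5, 0.5], [2.5, 3.5]])
        assert len(enforce_barriers(cands, grid)) == 0


class TestSimulatePair:
    def test_fix_count_and_time_grid(self, pair_d):
        cfg = pair_d.config
        for traj in (pair_d.traj_a, pair_d.traj_b):
            assert traj.n_fixes == cfg.n_steps + 1
            assert np.array_equal(traj.t, np.arange(cfg.n_steps + 1))
            assert np.all((traj.x >= 0) & (traj.x <= cfg.area_size))
            assert np.all((traj.y >= 0) & (traj.y <= cfg.area_size))

    def test_bit_identical_reproducibility(self):
        cfg = ScenarioConfig(scenario="B", n_steps=120, seed=5)
        s1, s2 = simulate_pair(cfg), simulate_pair(cfg)
        assert np.array_equal(s1.traj_a.x, s2.traj_a.x)
        assert np.array_equal(s1.traj_b.y, s2.traj_b.y)
        assert np.array_equal(s1.landscape.values, s2.landscape.values)

    def test_scenario_c_never_enters_barriers(self):
        sim = simulate_pair(ScenarioConfig(scenario="C", n_steps=400, barrier_proportion=0.7, seed=8))
        for traj in (sim.traj_a, sim.traj_b):
            inside = sim.landscape.is_barrier_at(traj.x, traj.y)
            assert not np.any(inside)

    def test_attraction_shrinks_distance_vs_independent(self):
        # paired Monte-Carlo: scenario D vs independent CRWs, same kernel
        d_soc, d_ind = [], []
        for s in range(12):
            sim = simulate_pair(ScenarioConfig(scenario="D", n_steps=400, seed=3000 + s))
            ind = simulate_crw_pair(
                n_steps=400,
                seed=3000 + s,
                initial_positions=((47.5, 50.0), (52.5, 50.0)),
            )
            d_soc.append(np.hypot(sim.traj_a.x - sim.traj_b.x, sim.traj_a.y - sim.traj_b.y).mean())
            d_ind.append(np.hypot(ind.traj_a.x - ind.traj_b.x, ind.traj_a.y - ind.traj_b.y).mean())
        assert np.mean(d_soc) < np.mean(d_ind)

    def test_gradient_climbing_scenario_aa(self):
        sim = simulate_pair(ScenarioConfig(scenario="A.a", seed=7))
        traj, grid = sim.traj_a, sim.landscape
        q = traj.n_fixes // 4
        first = grid.value_at(traj.x[:q], traj.y[:q]).mean()
        last = grid.value_at(traj.x[-q:], traj.y[-q:]).mean()
        assert last > first

    def test_pure_crw_distributions(self):
        # with no habitat/social bias and no barriers the walk is a plain CRW
        sim = simulate_crw_pair(n_steps=10_000, seed=17)
        traj = sim.traj_a
        lengths = traj.step_lengths
        shape, _, scale = stats.gamma.fit(lengths, floc=0)
        assert shape == pytest.approx(6.0, rel=0.1)
        assert scale == pytest.approx(0.15, rel=0.1)
        ang = traj.turning_angles
        ks = stats.kstest(ang, stats.vonmises(4.0).cdf)
        assert ks.pvalue > 0.01


def test_wrap_angle_range(rng):
    a = wrap_angle(rng.uniform(-30, 30, 1000))
    assert np.all((a > -np.pi) & (a <= np.pi))
    assert wrap_angle(np.pi + 0.1) == pytest.approx(-np.pi + 0.1)
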