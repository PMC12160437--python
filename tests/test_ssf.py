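"""SSF machinery: distribution fitting, available steps, OD, conditional logit."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from dyadmove import (
    SSFConfig,
    attach_covariates,
    fit_clogit,
    fit_ssf,
    fit_step_distributions,
    generate_available_steps,
    make_gradient_landscape,
    occurrence_distribution,
)
from dyadmove.simulator import Trajectory
from dyadmove.ssf import (
    DegenerateFitError,
    InestimableCovariateError,
    InsufficientDataError,
    kappa_from_resultant_length,
)

from conftest import walk_trajectory


class TestDistributionFitting:
    def test_parameter_recovery(self, rng):
        traj = walk_trajectory(rng, 10_000)
        shape, scale, kappa = fit_step_distributions(traj)
        assert 5.5 <= shape <= 6.5
        assert 0.135 <= scale <= 0.165
        assert 3.6 <= kappa <= 4.4

    def test_kappa_inversion_bessel_oracle(self):
        # oracle: the Bessel ratio I1(4)/I0(4) evaluated numerically
        r = special.i1e(4.0) / special.i0e(4.0)
        assert kappa_from_resultant_length(r) == pytest.approx(4.0, abs=1e-6)

    def test_degenerate_angles(self):
        t = np.arange(40)
        traj = Trajectory("s", t, t.astype(float), np.zeros(40))  # straight line
        with pytest.raises(DegenerateFitError):
            fit_step_distributions(traj)

    def test_too_few_steps(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_step_distributions(walk_trajectory(rng, 10))


class TestAvailableSteps:
    def test_counts_and_geometry(self, rng):
        traj = walk_trajectory(rng, 500)
        strata = generate_available_steps(traj, (6.0, 0.15, 4.0), 20, rng)
        assert strata["stratum_id"].nunique() == 499  # first step dropped
        sizes = strata.groupby("stratum_id").size()
        assert (sizes == 21).all()
        assert (strata.groupby("stratum_id")["case"].sum() == 1).all()

    def test_available_anchored_at_observed_start(self, rng):
        traj = walk_trajectory(rng, 50)
        strata = generate_available_steps(traj, (6.0, 0.15, 4.0), 5, rng)
        avail = strata[strata.case == 0]
        sid = avail["stratum_id"].to_numpy()
        start_x = traj.x[1:-1][sid]
        start_y = traj.y[1:-1][sid]
        d = np.hypot(avail["x"] - start_x, avail["y"] - start_y)
        np.testing.assert_allclose(d, avail["step_length"], rtol=1e-10)

    def test_seeded_determinism(self, rng):
        traj = walk_trajectory(rng, 80)
        a = generate_available_steps(traj, (6.0, 0.15, 4.0), 10, np.random.default_rng(5))
        b = generate_available_steps(traj, (6.0, 0.15, 4.0), 10, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_too_short(self, rng):
        traj = Trajectory("a", np.arange(2), np.zeros(2), np.zeros(2))
        with pytest.raises(InsufficientDataError):
            generate_available_steps(traj, (6.0, 0.15, 4.0), 5, rng)


class TestOccurrenceDistribution:
    def test_normalisation(self, rng):
        traj = walk_trajectory(rng, 300)
        grid = make_gradient_landscape(100, 100, 1.0)
        od = occurrence_distribution(traj, grid)
        assert od.density.sum() * grid.cell_size**2 == pytest.approx(1.0, abs=1e-6)
        assert np.all(od.density >= 0)

    def test_mode_near_data_mass(self):
        t = np.arange(50)
        x = 30.0 + 0.3 * np.sin(t)
        y = 70.0 + 0.3 * np.cos(t)
        traj = Trajectory("c", t, x, y)
        grid = make_gradient_landscape(100, 100, 1.0)
        od = occurrence_distribution(traj, grid, bandwidth=2.0)
        r, c = np.unravel_index(np.argmax(od.density), od.density.shape)
        assert abs(c + 0.5 - 30.0) <= 1.5
        assert abs(r + 0.5 - 70.0) <= 1.5

    def test_two_clusters_dominate_midpoint(self):
        # direct KDE evaluation oracle: two tight clusters at opposite corners
        t = np.arange(100)
        x = np.where(t < 50, 10.0, 90.0) + 0.01 * t
        y = np.where(t < 50, 10.0, 90.0) - 0.01 * t
        traj = Trajectory("c", t, x, y)
        grid = make_gradient_landscape(100, 100, 1.0)
        od = occurrence_distribution(traj, grid, bandwidth=3.0)
        at_cluster = od.evaluate(10.0, 10.0)[0]
        at_mid = od.evaluate(50.0, 50.0)[0]
        assert at_cluster > 10 * at_mid

    def test_smooth_eval_matches_sklearn_kde(self, rng):
        # independent oracle: sklearn KernelDensity with the same bandwidth
        from sklearn.neighbors import KernelDensity

        traj = walk_trajectory(rng, 200)
        grid = make_gradient_landscape(100, 100, 1.0)
        od = occurrence_distribution(traj, grid, bandwidth=2.5)
        pts = np.column_stack([rng.uniform(20, 80, 30), rng.uniform(20, 80, 30)])
        kde = KernelDensity(bandwidth=2.5, kernel="gaussian")
        kde.fit(np.column_stack([traj.x, traj.y]))
        expected = np.exp(kde.score_samples(pts)) * od.norm
        got = od.evaluate(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-12 * expected.max())

    def test_zero_bandwidth_error(self):
        t = np.arange(10)
        traj = Trajectory("z", t, np.full(10, 5.0), np.full(10, 5.0))
        grid = make_gradient_landscape(20, 20, 1.0)
        with pytest.raises(ValueError):
            occurrence_distribution(traj, grid)


class TestCovariates:
    def _strata(self, rng, dist_sign="negated"):
        focal = walk_trajectory(rng, 100)
        partner = walk_trajectory(rng, 100, start=(55.0, 50.0), individual_id="p")
        grid = make_gradient_landscape(200, 200, 1.0, origin=(-50.0, -50.0))
        strata = generate_available_steps(focal, (6.0, 0.15, 4.0), 10, rng)
        od = occurrence_distribution(partner, grid, bandwidth=3.0)
        cfg = SSFConfig(covariate_set=("landscape", "dist", "od"), dist_sign=dist_sign)
        return attach_covariates(strata, grid=grid, other_traj=partner, od=od, config=cfg), focal, partner

    def test_dist_is_distance_at_target_time(self, rng):
        strata, focal, partner = self._strata(rng, dist_sign="raw")
        row = strata[strata.case == 1].iloc[7]
        t_end = int(row["t_end"])
        i = np.where(partner.t == t_end)[0][0]
        expected = np.hypot(row["x"] - partner.x[i], row["y"] - partner.y[i])
        assert row["dist"] == pytest.approx(expected)

    def test_negated_sign_default(self, rng):
        raw, _, _ = self._strata(rng, dist_sign="raw")
        rng2 = np.random.default_rng(12345)  # same stream as fixture start
        assert (raw["dist"] >= 0).all()
        neg, _, _ = self._strata(np.random.default_rng(999))
        assert (neg["dist"] <= 0).all()

    def test_landscape_from_grid(self, rng):
        strata, _, _ = self._strata(rng)
        assert strata["landscape"].between(0, 1).all()


class TestConditionalLogit:
    def test_grid_search_oracle(self):
        # brute-force conditional log-likelihood over a beta grid
        rng = np.random.default_rng(2024)
        n_strata, m = 5, 3
        x = rng.normal(size=(n_strata, m))
        true_beta = 1.5
        probs = np.exp(true_beta * x)
        probs /= probs.sum(axis=1, keepdims=True)
        case = np.zeros((n_strata, m), dtype=int)
        for i in range(n_strata):
            case[i, rng.choice(m, p=probs[i])] = 1
        df = pd.DataFrame(
            {
                "stratum_id": np.repeat(np.arange(n_strata), m),
                "case": case.ravel(),
                "z": x.ravel(),
            }
        )
        fit = fit_clogit(df, ["z"])

        def cll(beta):
            eta = beta * x
            return (eta[case == 1].sum() - special.logsumexp(eta, axis=1).sum())

        grid = np.linspace(-10, 10, 200_001)
        lls = np.array([cll(b) for b in grid[:: 1000]])
        coarse = grid[::1000][np.argmax(lls)]
        fine = np.linspace(coarse - 0.2, coarse + 0.2, 40_001)
        best = fine[np.argmax([cll(b) for b in fine])]
        assert abs(fit.coefficients["z"] - best) < 1e-3

    def test_matches_statsmodels_conditional_logit(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        n_strata, m = 60, 6
        x1 = rng.normal(size=n_strata * m)
        x2 = rng.normal(size=n_strata * m)
        groups = np.repeat(np.arange(n_strata), m)
        eta = 0.8 * x1 - 0.5 * x2
        case = np.zeros(n_strata * m, dtype=int)
        for g in range(n_strata):
            idx = np.where(groups == g)[0]
            p = np.exp(eta[idx])
            case[rng.choice(idx, p=p / p.sum())] = 1
        df = pd.DataFrame({"stratum_id": groups, "case": case, "a": x1, "b": x2})
        ours = fit_clogit(df, ["a", "b"])
        ref = ConditionalLogit(case, np.column_stack([x1, x2]), groups=groups).fit(disp=0)
        np.testing.assert_allclose(
            [ours.coefficients["a"], ours.coefficients["b"]], ref.params, rtol=5e-4
        )
        np.testing.assert_allclose(
            [ours.std_errors["a"], ours.std_errors["b"]], ref.bse, rtol=5e-3
        )

    def test_stratum_constant_shift_invariance(self, rng):
        traj = walk_trajectory(rng, 200)
        strata = generate_available_steps(traj, (6.0, 0.15, 4.0), 10, rng)
        strata["z"] = rng.normal(size=len(strata))
        base = fit_clogit(strata, ["z"])
        shifted = strata.copy()
        shifts = rng.normal(size=strata["stratum_id"].nunique())
        shifted["z"] = shifted["z"] + shifts[shifted["stratum_id"].to_numpy()]
        moved = fit_clogit(shifted, ["z"])
        assert moved.coefficients["z"] == pytest.approx(base.coefficients["z"], abs=1e-6)

    def test_scaling_equivariance(self, rng):
        traj = walk_trajectory(rng, 150)
        strata = generate_available_steps(traj, (6.0, 0.15, 4.0), 8, rng)
        strata["z"] = rng.normal(size=len(strata))
        base = fit_clogit(strata, ["z"])
        strata["z"] = 4.0 * strata["z"]
        scaled = fit_clogit(strata, ["z"])
        assert scaled.coefficients["z"] == pytest.approx(base.coefficients["z"] / 4.0, rel=1e-6)

    def test_inestimable_covariate_raises(self, rng):
        traj = walk_trajectory(rng, 60)
        strata = generate_available_steps(traj, (6.0, 0.15, 4.0), 5, rng)
        strata["flat"] = strata["stratum_id"].astype(float)  # constant within stratum
        with pytest.raises(InestimableCovariateError, match="flat"):
            fit_clogit(strata, ["flat"])

    def test_wald_coverage(self, rng):
        # 95% CI coverage for a known selection coefficient
        covered = 0
        n_rep = 120
        for _ in range(n_rep):
            n_strata, m = 200, 11
            x = rng.normal(size=(n_strata, m))
            p = np.exp(1.0 * x)
            p /= p.sum(axis=1, keepdims=True)
            case = np.zeros((n_strata, m), dtype=int)
            picks = (p.cumsum(axis=1) > rng.uniform(size=(n_strata, 1))).argmax(axis=1)
            case[np.arange(n_strata), picks] = 1
            df = pd.DataFrame(
                {
                    "stratum_id": np.repeat(np.arange(n_strata), m),
                    "case": case.ravel(),
                    "z": x.ravel(),
                }
            )
            fit = fit_clogit(df, ["z"])
            lo = fit.coefficients["z"] - 1.96 * fit.std_errors["z"]
            hi = fit.coefficients["z"] + 1.96 * fit.std_errors["z"]
            covered += lo <= 1.0 <= hi
        assert 0.91 <= covered / n_rep <= 0.985

    def test_standardized_fit_zscores_invariant(self, rng):
        traj = walk_trajectory(rng, 150)
        strata = generate_available_steps(traj, (6.0, 0.15, 4.0), 8, rng)
        strata["z"] = 3.0 + 2.5 * rng.normal(size=len(strata))
        raw = fit_clogit(strata, ["z"])
        std = fit_ssf(strata, ["z"], SSFConfig(covariate_set=("z",), standardize=True))
        assert std.z_values["z"] == pytest.approx(raw.z_values["z"], rel=1e-6)
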