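"""Dipole construction, the Θ statistic, ensemble averaging and decay fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from efield_orient import (
    DipoleTrajectory,
    ExponentialDecayModel,
    NotOrientedError,
    OrientationSeries,
    ZeroDipoleError,
    compute_dipole,
    degree_of_orientation,
    dipole_magnitude_debye,
    ensemble_mean,
    field_at_orientation_time,
    final_orientation,
    fit_decay,
    generate_theta_ensemble,
    make_protocol,
    orientation_time,
    plane_projection,
    theta_series,
)


class TestComputeDipole:
    def test_two_charge_hand_sum(self):
        mu = compute_dipole([[0.1, 0, 0], [-0.1, 0, 0]], [1, -1], [1, 1])
        np.testing.assert_allclose(mu, [0.2, 0, 0], atol=1e-15)

    def test_single_charge_at_com_is_zero(self):
        mu = compute_dipole([[3.7, -1.2, 9.9]], [1.0], [12.0])
        np.testing.assert_allclose(mu, np.zeros(3), atol=1e-12)

    def test_three_charge_term_by_term_oracle(self):
        coords = np.array([[0, 0.1, 0], [0, -0.1, 0], [0.1, 0, 0]], float)
        charges = np.array([0.5, 0.5, -1.0])
        masses = np.ones(3)
        com = coords.mean(axis=0)
        expected = np.zeros(3)
        for r, q in zip(coords, charges):  # independent term-by-term sum
            expected += q * (r - com)
        np.testing.assert_allclose(
            compute_dipole(coords, charges, masses), expected, atol=1e-15
        )
        np.testing.assert_allclose(expected, [-0.1, 0, 0], atol=1e-15)

    def test_debye_conversion(self):
        assert dipole_magnitude_debye([0.0, 0.0, 1.0]) == pytest.approx(48.0321)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_dipole([[0, 0, 0]], [1, 2], [1])
        with pytest.raises(ValueError):
            compute_dipole([[0, 0, 0]], [1], [0.0])


class TestDegreeOfOrientation:
    @pytest.mark.parametrize(
        "dipole,expected",
        [((2.0, 0, 0), 0.0), ((0, 3.0, 0), 1.0), ((-1.0, 0, 0), 2.0)],
    )
    def test_reference_geometries(self, dipole, expected):
        assert degree_of_orientation(dipole, (1, 0, 0)) == pytest.approx(expected)

    def test_zero_dipole_rejected(self):
        with pytest.raises(ZeroDipoleError):
            degree_of_orientation((0, 0, 0), (1, 0, 0))

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    def test_rotation_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(3)
        f = rng.standard_normal(3)
        if np.linalg.norm(d) < 1e-6 or np.linalg.norm(f) < 1e-6:
            return
        f = f / np.linalg.norm(f)
        R = Rotation.random(rng=rng).as_matrix()
        base = degree_of_orientation(d, f)
        assert degree_of_orientation(R @ (scale * d), R @ f) == pytest.approx(
            base, abs=1e-9
        )
        assert 0.0 <= base <= 2.0

    def test_random_orientation_expectation_is_one(self):
        # uniformly random dipoles average Theta = 1 (cos theta averages to 0)
        rng = np.random.default_rng(7)
        d = rng.standard_normal((100_000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        theta = 1.0 - d[:, 0]
        assert abs(theta.mean() - 1.0) < 3.0 * theta.std() / math.sqrt(len(theta))


class TestThetaSeries:
    def test_constant_parallel_dipole_gives_zero(self):
        traj = DipoleTrajectory(np.arange(5.0), np.tile([2.0, 0, 0], (5, 1)))
        s = theta_series(traj, (1, 0, 0))
        np.testing.assert_allclose(s.theta, 0.0, atol=1e-12)

    def test_rotating_dipole_closed_form(self):
        omega = 2.0 * math.pi
        t = np.linspace(0, 1, 200)
        mu = np.column_stack([np.cos(omega * t), np.sin(omega * t), np.zeros_like(t)])
        s = theta_series(DipoleTrajectory(t, mu), (1, 0, 0))
        np.testing.assert_allclose(s.theta, 1.0 - np.cos(omega * t), atol=1e-12)

    def test_production_start_geometry_is_perpendicular(self):
        # starting structures carry their dipole along z while the field is on x
        traj = DipoleTrajectory([0.0, 1.0], [[0, 0, 5.0], [0, 0, 5.0]])
        s = theta_series(traj, (1, 0, 0))
        assert s.theta[0] == pytest.approx(1.0)

    def test_zero_dipole_frames_flagged_not_dropped(self):
        traj = DipoleTrajectory([0.0, 1.0, 2.0], [[1, 0, 0], [0, 0, 0], [1, 0, 0]])
        s = theta_series(traj, (1, 0, 0))
        assert len(s) == 3
        assert s.zero_dipole.tolist() == [False, True, False]
        assert math.isnan(s.theta[1])


class TestEnsembleMean:
    def test_identical_series_unchanged(self):
        t = np.linspace(0, 1, 50)
        s = OrientationSeries(t, np.exp(-t))
        m = ensemble_mean([s] * 10)
        np.testing.assert_allclose(m.theta, s.theta)
        assert m.n_replicas == 10

    def test_opposite_extremes_average_to_one(self):
        t = np.linspace(0, 1, 20)
        m = ensemble_mean(
            [OrientationSeries(t, np.zeros(20)), OrientationSeries(t, np.full(20, 2.0))]
        )
        np.testing.assert_allclose(m.theta, 1.0)

    def test_grid_mismatch_rejected(self):
        t = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            ensemble_mean(
                [OrientationSeries(t, np.ones(20)), OrientationSeries(t + 1e-6, np.ones(20))]
            )

    def test_noisy_replicas_recover_trend(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 5, 200)
        k = 0.7
        sd = 0.05
        n = 10
        series = [
            OrientationSeries(t, np.clip(np.exp(-k * t) + rng.normal(0, sd, t.shape), 0, 2))
            for _ in range(n)
        ]
        m = ensemble_mean(series)
        se = sd / math.sqrt(n)
        # clipping at 0 biases upward only where the trend is ~0; stay on the bulk
        bulk = np.exp(-k * t) > 4 * sd
        assert np.all(np.abs(m.theta[bulk] - np.exp(-k * t[bulk])) < 4 * se)


class TestFinalOrientation:
    def test_constant_series(self):
        t = np.linspace(0, 10, 101)
        mean, sd = final_orientation(OrientationSeries(t, np.full(101, 0.2)), 2.0)
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.0)

    def test_linear_ramp_hand_mean(self):
        # theta falls 1 -> 0 over 10 ns; mean over the last 2 ns is 0.1
        t = np.linspace(0, 10, 1001)
        mean, _ = final_orientation(OrientationSeries(t, 1.0 - t / 10.0), 2.0)
        assert mean == pytest.approx(0.1, abs=1e-12)

    def test_window_longer_than_series_rejected(self):
        t = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            final_orientation(OrientationSeries(t, np.ones(20)), 2.0)

    def test_random_orientations_average_to_one(self):
        rng = np.random.default_rng(11)
        d = rng.standard_normal((20_000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        t = np.linspace(0, 10, 20_000)
        s = theta_series(DipoleTrajectory(t, d), (1, 0, 0))
        mean, sd = final_orientation(s, 2.0)
        assert mean == pytest.approx(1.0, abs=3 * sd / math.sqrt(4000))


class TestFitDecay:
    @pytest.mark.parametrize("k", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_noiseless_recovery(self, k):
        t = np.linspace(0, min(10.0, 10.0 / k), 400)
        fit = fit_decay(OrientationSeries(t, np.exp(-k * t)))
        assert fit.converged
        assert fit.k == pytest.approx(k, rel=1e-6)

    def test_constant_series_flagged_infinite_tau(self):
        t = np.linspace(0, 10, 100)
        fit = fit_decay(OrientationSeries(t, np.ones(100)))
        assert fit.converged
        assert fit.k == pytest.approx(0.0, abs=1e-9)
        assert math.isinf(fit.tau)
        assert not fit.oriented

    def test_all_zero_series_unbounded_flagged(self):
        t = np.linspace(0, 10, 100)
        fit = fit_decay(OrientationSeries(t, np.zeros(100)))
        assert not fit.converged
        assert math.isinf(fit.tau)

    def test_synthetic_ensemble_recovery(self):
        series = generate_theta_ensemble(
            k_true=1.0, oscillation_amplitude=0.2, noise_sd=0.05,
            n_replicas=10, dt=0.01, duration=10.0, seed=42,
        )
        fit = fit_decay(ensemble_mean(series))
        assert fit.converged
        assert fit.k == pytest.approx(1.0, rel=0.05)

    def test_parameter_recovery_grid_median_under_5pct(self):
        errs = []
        for i, k in enumerate([0.1, 0.3, 1.0, 3.0]):
            series = generate_theta_ensemble(
                k_true=k, oscillation_amplitude=0.2, noise_sd=0.05,
                n_replicas=10, dt=0.01, duration=10.0, seed=100 + i,
            )
            fit = fit_decay(ensemble_mean(series))
            errs.append(abs(fit.k - k) / k)
        assert np.median(errs) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(OrientationSeries([0, 1, 2], [1.0, 0.5, 0.2]))

    def test_model_results_api(self):
        t = np.linspace(0, 5, 100)
        model = ExponentialDecayModel(t, np.exp(-2.0 * t))
        res = model.fit()
        assert "tau" in res.summary()
        np.testing.assert_allclose(res.predict(t), np.exp(-2.0 * t), atol=1e-6)
        import pandas as pd

        df = pd.DataFrame({"time_ns": t, "theta": np.exp(-2.0 * t)})
        res2 = ExponentialDecayModel.from_dataframe(df).fit()
        assert res2.k == pytest.approx(res.k)


class TestOrientationTime:
    @pytest.mark.parametrize("k,tau", [(math.log(10), 1.0), (math.log(10) / 8.3, 8.3)])
    def test_inverse_relation(self, k, tau):
        t = np.linspace(0, 3 * tau, 200)
        fit = fit_decay(OrientationSeries(t, np.exp(-k * t)))
        assert orientation_time(fit) == pytest.approx(tau, rel=1e-6)

    def test_ninety_percent_identity(self):
        t = np.linspace(0, 4, 200)
        fit = fit_decay(OrientationSeries(t, np.exp(-1.7 * t)))
        assert math.exp(-fit.k * fit.tau) == pytest.approx(0.1, abs=1e-12)


class TestFieldAtOrientationTime:
    def test_plateau_branch(self):
        p = make_protocol(2.0, 1.0)
        assert field_at_orientation_time(p, 5.0) == 2.0

    def test_constant_field_any_tau(self):
        p = make_protocol(1.3, 0.0)
        assert field_at_orientation_time(p, 0.001) == 1.3

    def test_gaussian_branch(self):
        p = make_protocol(1.0, 6.0, 2.0)
        assert field_at_orientation_time(p, 4.0) == pytest.approx(math.exp(-0.5))

    def test_infinite_tau_is_not_a_number(self):
        with pytest.raises(NotOrientedError):
            field_at_orientation_time(make_protocol(1.0, 0.0), math.inf)


class TestPlaneProjection:
    def test_all_aligned(self):
        rng = np.random.default_rng(0)
        n = 100
        ang = np.radians(rng.uniform(0, 10, n))
        az = rng.uniform(0, 2 * math.pi, n)
        mu = np.column_stack(
            [np.cos(ang), np.sin(ang) * np.cos(az), np.sin(ang) * np.sin(az)]
        )
        pp = plane_projection(DipoleTrajectory(np.arange(n, dtype=float), mu), (1, 0, 0))
        assert pp.aligned_fraction == 1.0

    def test_uniform_random_matches_spherical_cap_oracle(self):
        # MC oracle: fraction of the unit sphere within a 15 deg cone about
        # the axis; closed form (1 - cos 15deg)/2 = 0.017037
        rng = np.random.default_rng(5)
        d = rng.standard_normal((100_000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        cap = float(np.mean(d[:, 0] >= math.cos(math.radians(15.0))))
        pp = plane_projection(
            DipoleTrajectory(np.arange(len(d), dtype=float), d), (1, 0, 0)
        )
        assert pp.aligned_fraction == pytest.approx(cap, abs=1e-12)
        assert pp.aligned_fraction == pytest.approx(
            (1.0 - math.cos(math.radians(15.0))) / 2.0, abs=0.002
        )

    def test_perpendicular_dipole_azimuth_defined(self):
        traj = DipoleTrajectory([0.0, 1.0], [[0, 2.0, 0], [0, 2.0, 0]])
        pp = plane_projection(traj, (1, 0, 0))
        np.testing.assert_allclose(pp.alignment_deg, 90.0)
        assert np.all(np.isfinite(pp.azimuth_deg))
        assert pp.azimuth_deg[0] == pp.azimuth_deg[1]

    def test_parallel_frames_flagged_and_counted_aligned(self):
        traj = DipoleTrajectory([0.0, 1.0], [[3.0, 0, 0], [0, 1.0, 0]])
        pp = plane_projection(traj, (1, 0, 0))
        assert pp.degenerate.tolist() == [True, False]
        assert math.isnan(pp.azimuth_deg[0])
        assert pp.aligned_fraction == pytest.approx(0.5)
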