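import numpy as np
import pytest

from burstcode.geometry import (
    SDMeanFit,
    burst_phase,
    circular_stats,
    fit_sd_vs_mean,
    independent_components,
    phase_sets,
    short_isi_replacement,
    spike_count_isi_correlation,
    steepest_gradient,
    transform_to_u,
    trial_to_trial_pca,
)


class TestSdMeanFit:
    def test_exact_line_through_origin(self):
        fit = fit_sd_vs_mean([10, 20, 30], [2, 4, 6], min_isi=8.0)
        assert fit.a == pytest.approx(0.2, abs=1e-12)
        assert fit.m == pytest.approx(0.0, abs=1e-9)

    def test_exact_line_with_offset(self):
        fit = fit_sd_vs_mean([12, 22, 32], [2, 4, 6], min_isi=10.0)
        assert fit.a == pytest.approx(0.2, abs=1e-12)
        assert fit.m == pytest.approx(2.0, abs=1e-9)

    def test_intercept_shrunk_when_too_large(self):
        with pytest.warns(UserWarning, match="shrunk"):
            fit = fit_sd_vs_mean([12, 22, 32], [2, 4, 6], min_isi=1.5)
        assert fit.m == pytest.approx(1.4)
        assert fit.shrunk

    def test_negative_slope_errors(self):
        with pytest.raises(ValueError):
            fit_sd_vs_mean([10, 20, 30], [6, 4, 2], min_isi=8.0)

    def test_planted_offsets_recovered(self, default_run):
        g = default_run.result.summary["ground_truth"]
        assert g["m1_error_ms"] < 1.0
        assert g["m2_error_ms"] < 1.0


class TestTransform:
    def _fits(self):
        return SDMeanFit(m=2.0, a=0.2, n_events=10), SDMeanFit(m=2.0, a=0.2, n_events=10)

    def test_whitening_contract(self, rng):
        # cov(u) = I to 1e-9 for any non-degenerate ISI cloud
        f1, f2 = self._fits()
        z = rng.multivariate_normal([0, 0], [[1.0, 0.6], [0.6, 2.0]], 500)
        isi1 = 2.0 + 10 ** (0.8 + 0.1 * z[:, 0])
        isi2 = 2.0 + 10 ** (0.8 + 0.1 * z[:, 1])
        coords = transform_to_u(isi1, isi2, f1, f2)
        cov = np.cov(coords.u1, coords.u2, ddof=1)
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-9)

    def test_uncorrelated_input_is_identity(self, rng):
        # when v* is exactly uncorrelated the whitening map is the identity
        f1, f2 = self._fits()
        a = rng.standard_normal(400)
        b = rng.standard_normal(400)
        a -= a.mean()
        b -= b.mean()
        b = b - a * np.dot(a, b) / np.dot(a, a)  # exact zero sample covariance
        isi1 = 2.0 + 10 ** (0.8 + 0.1 * a)
        isi2 = 2.0 + 10 ** (0.8 + 0.1 * b)
        coords = transform_to_u(isi1, isi2, f1, f2)
        v1s = (coords.v1 - coords.v1.mean()) / coords.v1.std(ddof=1)
        np.testing.assert_allclose(coords.u1, v1s - v1s.mean(), atol=1e-9)

    def test_round_trip(self, rng):
        f1, f2 = self._fits()
        isi1 = 2.0 + 10 ** rng.normal(0.8, 0.2, 200)
        isi2 = 2.0 + 10 ** rng.normal(0.8, 0.2, 200)
        coords = transform_to_u(isi1, isi2, f1, f2)
        np.testing.assert_allclose(2.0 + 10**coords.v1, coords.isi1, atol=1e-9)
        np.testing.assert_allclose(2.0 + 10**coords.v2, coords.isi2, atol=1e-9)

    def test_short_isis_excluded(self, rng):
        f1, f2 = self._fits()
        isi1 = np.concatenate([[1.5], 2.0 + 10 ** rng.normal(0.8, 0.2, 100)])
        isi2 = 2.0 + 10 ** rng.normal(0.8, 0.2, 101)
        coords = transform_to_u(isi1, isi2, f1, f2)
        assert coords.n == 100
        assert not coords.included[0]


class TestPhase:
    @pytest.mark.parametrize(
        "u1,u2,expected", [(1, 0, 0.0), (0, 1, 90.0), (-1, -1, 225.0)]
    )
    def test_tabulated_angles(self, u1, u2, expected):
        assert burst_phase(u1, u2)[0] == pytest.approx(expected)

    def test_origin_flagged(self):
        with pytest.warns(UserWarning):
            out = burst_phase(np.array([0.0]), np.array([0.0]))
        assert np.isnan(out[0])


class TestShortIsiReplacement:
    def test_no_excluded_is_identity(self, rng):
        f1 = SDMeanFit(m=2.0, a=0.2, n_events=10)
        isi1 = 3.0 + 10 ** rng.normal(0.5, 0.2, 100)
        isi2 = 3.0 + 10 ** rng.normal(0.5, 0.2, 100)
        a = transform_to_u(isi1, isi2, f1, f1)
        b = short_isi_replacement(isi1, isi2, f1, f1)
        np.testing.assert_allclose(a.u1, b.u1)

    def test_excluded_isi_replaced_with_min_included(self, rng):
        f1 = SDMeanFit(m=2.0, a=0.2, n_events=10)
        isi1 = np.concatenate([[1.0], 3.0 + 10 ** rng.normal(0.5, 0.2, 50)])
        isi2 = 3.0 + 10 ** rng.normal(0.5, 0.2, 51)
        out = short_isi_replacement(isi1, isi2, f1, f1)
        assert out.n == 51
        assert out.isi1[0] == pytest.approx(isi1[1:].min())

    def test_phase_analysis_robust_to_replacement(self, default_run):
        # deviation-by-phase waveforms with and without short-ISI replacement
        # stay nearly identical on the default simulation
        from burstcode import triggered as trg

        res = default_run.result
        tab3 = res.train.of_count(3)
        isi1 = tab3["isi1_ms"].to_numpy()
        isi2 = tab3["isi2_ms"].to_numpy()
        coords = res.coords
        repl = short_isi_replacement(isi1, isi2, coords.fit1, coords.fit2)
        trig = tab3["first_spike_ms"].to_numpy()
        seqs, ok = trg.extract_sequences(res.stimulus, trig, (-300, 25))
        # without replacement: included bursts only; with: every burst
        _, dev_a = trg.deviation_by_phase(
            seqs[coords.included[ok]], coords.phase_deg[ok[coords.included]], n_bins=12
        )
        _, dev_b = trg.deviation_by_phase(seqs, repl.phase_deg[ok], n_bins=12)
        cors = []
        for da, db in zip(dev_a, dev_b):
            if da is not None and db is not None:
                cors.append(np.corrcoef(da.values, db.values)[0, 1])
        assert np.mean(cors) > 0.95


class TestTrialToTrialPca:
    def test_recovers_planted_axes(self, rng):
        # residuals with sigma 0.1 along 30 deg and sigma 1 along 120 deg
        th = np.deg2rad(30)
        e_small = np.array([np.cos(th), np.sin(th)])
        e_large = np.array([-np.sin(th), np.cos(th)])
        n_ev, per = 100, 20
        u = []
        ids = []
        for j in range(n_ev):
            center = rng.standard_normal(2) * 2
            pts = (
                center
                + rng.normal(0, 0.1, (per, 1)) * e_small
                + rng.normal(0, 1.0, (per, 1)) * e_large
            )
            u.append(pts)
            ids.extend([j] * per)
        u = np.vstack(u)
        theta, variances, unstable = trial_to_trial_pca(u[:, 0], u[:, 1], np.asarray(ids))
        assert theta == pytest.approx(30.0, abs=3.0)
        assert not unstable

    def test_isotropic_flagged(self):
        # perfectly isotropic residuals by construction
        u1 = np.array([1.0, -1.0, 0.0, 0.0] * 3)
        u2 = np.array([0.0, 0.0, 1.0, -1.0] * 3)
        ids = np.repeat([0, 1, 2], 4)
        with pytest.warns(UserWarning):
            _, _, unstable = trial_to_trial_pca(u1, u2, ids)
        assert unstable

    def test_end_to_end_theta_recovery(self, default_run):
        assert default_run.result.summary["ground_truth"]["theta_error_deg"] < 15.0


class TestIndependentComponents:
    def test_theta_zero_is_identity(self, rng):
        u1, u2 = rng.standard_normal((2, 50))
        c = independent_components(u1, u2, 0.0)
        np.testing.assert_allclose(c.w1, u1)
        np.testing.assert_allclose(c.w2, u2)

    def test_theta_ninety_swaps(self, rng):
        u1, u2 = rng.standard_normal((2, 50))
        c = independent_components(u1, u2, 90.0)
        np.testing.assert_allclose(c.w1, u2, atol=1e-12)
        np.testing.assert_allclose(c.w2, -u1, atol=1e-12)

    def test_rotation_preserves_radius(self, rng):
        u1, u2 = rng.standard_normal((2, 200))
        c = independent_components(u1, u2, 37.3)
        np.testing.assert_allclose(c.w1**2 + c.w2**2, u1**2 + u2**2, atol=1e-9)

    def test_quadrant_sets_partition(self, rng):
        phases = rng.uniform(0, 360, 500)
        sets = phase_sets(phases, 28.6, 45.0)
        total = sum(m.sum() for m in sets.values())
        assert total == 500
        stacked = np.vstack(list(sets.values()))
        assert (stacked.sum(axis=0) == 1).all()


class TestSteepestGradient:
    def test_pure_u1_gradient(self):
        u1 = np.array([0.0, 1, 2, 3])
        u2 = np.array([0.0, 1, -1, 0.5])
        m = 5 + 2 * u1
        direction, _ = steepest_gradient(m, u1, u2)
        assert direction == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_gradient(self):
        u1 = np.array([0.0, 1, 2, 0.5])
        u2 = np.array([0.0, -1, 1, 2.0])
        m = 5 + u1 + u2
        direction, _ = steepest_gradient(m, u1, u2)
        assert direction == pytest.approx(45.0, abs=1e-9)

    def test_rank_deficient_errors(self):
        u1 = np.array([1.0, 1, 1, 1])
        with pytest.raises(ValueError):
            steepest_gradient(np.arange(4.0), u1, u1)

    def test_gradient_recovers_planted_angle(self, default_run):
        assert default_run.result.summary["ground_truth"]["gradient_error_deg"] < 20.0


class TestCountIsiCorrelation:
    def test_perfect_anticorrelation(self):
        assert spike_count_isi_correlation([2, 3, 4], [10, 8, 6]) == pytest.approx(-1.0)

    def test_constant_flagged(self):
        with pytest.warns(UserWarning):
            out = spike_count_isi_correlation([2, 3, 4], [5, 5, 5])
        assert np.isnan(out)

    def test_near_zero_on_orthogonal_mechanisms(self, default_run):
        # count and ISI are driven by orthogonal features in the simulator
        assert abs(default_run.result.summary["count_isi_correlation"]) < 0.2


class TestCircularStats:
    def test_wraparound_mean(self):
        mean, _ = circular_stats([10.0, 350.0], fold_deg=360)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_pair(self):
        mean, sd = circular_stats([30.0, 30.0])
        assert mean == pytest.approx(30.0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_pair_closed_form(self):
        # Rbar = sqrt(2)/2, SD = sqrt(-2 ln Rbar) = sqrt(ln 2) rad ~ 47.7 deg
        mean, sd = circular_stats([0.0, 90.0], fold_deg=360)
        assert mean == pytest.approx(45.0)
        assert sd == pytest.approx(np.degrees(np.sqrt(np.log(2))), abs=1e-9)

    def test_axial_fold(self):
        mean, sd = circular_stats([5.0, 175.0], fold_deg=180)
        assert mean == pytest.approx(0.0, abs=1e-9) or mean == pytest.approx(180.0, abs=1e-9)

    def test_zero_resultant_errors(self):
        with pytest.raises(ValueError):
            circular_stats([0.0, 90.0, 180.0, 270.0], fold_deg=360)
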