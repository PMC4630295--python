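import numpy as np
import pytest

from phasereg.block_simulator import simulate_voxel, suppress_timecourse
from phasereg.core_signal import BlockDesign, realized_fsnr, zscore
from phasereg.errors import ConfigurationError, DegenerateVarianceError
from phasereg.fixtures import VEIN_VOXEL
from phasereg.vein_phantom import ComplexVolumeSeries
from phasereg.vein_suppression import (apply_pr, apply_spr, chisq_loss,
                                       face_neighborhood, fit_pr_chisq, fit_spr,
                                       minimize_chisq_brute, suppress_volume)

SQRT3_M1 = np.sqrt(3.0) - 1.0


def corr_pair(rho, n=80, seed=0):
    """Z-scored pair with sample correlation exactly rho (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    u = zscore(rng.standard_normal(n))
    v = rng.standard_normal(n)
    v = zscore(v - (v @ u) / (u @ u) * u)
    return u, zscore(rho * u + np.sqrt(1 - rho**2) * v)


class TestFitPrChisq:
    def test_identical_series_exact_slope_is_one(self):
        Sm = zscore(np.sin(np.arange(30.0)))
        fit = fit_pr_chisq(Sm, Sm)
        assert fit.b1_star == pytest.approx(1.0, abs=1e-10)
        assert fit.r == 1 and fit.b0_star == 0.0

    def test_identical_series_printed_variant_root(self):
        Sm = zscore(np.sin(np.arange(30.0)))
        fit = fit_pr_chisq(Sm, Sm, coefficients="printed")
        assert fit.b1_star == pytest.approx(SQRT3_M1, abs=1e-10)

    def test_sign_antisymmetry(self, pr_pair):
        Sm, Sp = pr_pair
        plus = fit_pr_chisq(Sm, Sp)
        minus = fit_pr_chisq(Sm, -Sp)
        assert minus.r == -plus.r
        assert minus.b1_star == pytest.approx(-plus.b1_star, abs=1e-12)

    @pytest.mark.parametrize("coefficients", ["exact", "printed"])
    def test_root_satisfies_stored_quadratic(self, pr_pair, coefficients):
        Sm, Sp = pr_pair
        fit = fit_pr_chisq(Sm, Sp, coefficients=coefficients)
        resid = fit.A * fit.b1_star**2 + fit.B * fit.b1_star + fit.C
        assert abs(resid) < 1e-8
        # and it matches numpy's independent polynomial root finder
        roots = np.roots([fit.A, fit.B, fit.C])
        assert min(abs(roots - fit.b1_star)) < 1e-10

    def test_exact_root_minimizes_the_loss(self, pr_pair):
        """Closed form vs brute-force scan of the chi-squared loss."""
        Sm, Sp = pr_pair
        fit = fit_pr_chisq(Sm, Sp)
        brute = minimize_chisq_brute(Sm, Sp)
        assert fit.b1_star == pytest.approx(brute, abs=0.02)

    def test_exact_root_loss_not_above_neighbors(self, pr_pair):
        Sm, Sp = pr_pair
        b = fit_pr_chisq(Sm, Sp).b1_star
        f0 = chisq_loss(Sm, Sp, 0.0, b)
        for db in (-1e-4, 1e-4):
            assert f0 <= chisq_loss(Sm, Sp, 0.0, b + db) + 1e-12

    def test_overestimation_vs_ols_slope(self):
        """The chi-squared slope exceeds the OLS slope (= correlation) for
        positively correlated z-scored series: the over-suppression the OLS
        variant was introduced to avoid."""
        for rho in (0.3, 0.6, 0.9):
            Sm, Sp = corr_pair(rho, seed=int(rho * 10))
            fit = fit_pr_chisq(Sm, Sp)
            assert fit.b1_star > rho

    def test_zero_correlation_falls_back_flagged(self):
        Sm, Sp = corr_pair(0.0, seed=5)
        fit = fit_pr_chisq(Sm, Sp)
        assert fit.b1_star == 0.0 and fit.r == 0
        assert "zero-correlation-fallback" in fit.flags

    def test_unknown_coefficient_convention(self, pr_pair):
        with pytest.raises(ConfigurationError):
            fit_pr_chisq(*pr_pair, coefficients="menon")


class TestApply:
    def test_zero_slope_is_identity(self, pr_pair):
        Sm, Sp = pr_pair
        fit = fit_pr_chisq(Sm, Sp)
        fit.b1_star = 0.0
        np.testing.assert_array_equal(apply_pr(Sm, Sp, fit), Sm)

    def test_unit_slope_on_identical_series_gives_zero(self):
        Sm = zscore(np.cos(np.arange(25.0)))
        fit = fit_pr_chisq(Sm, Sm)
        np.testing.assert_allclose(apply_pr(Sm, Sm, fit), 0.0, atol=1e-9)

    def test_matches_hand_computed_residual(self, pr_pair):
        Sm, Sp = pr_pair
        fit = fit_pr_chisq(Sm, Sp)
        np.testing.assert_allclose(apply_pr(Sm, Sp, fit), Sm - fit.b1_star * Sp,
                                   atol=1e-12)

    def test_shape_mismatch_raises(self, pr_pair):
        Sm, Sp = pr_pair
        fit = fit_pr_chisq(Sm, Sp)
        with pytest.raises(ValueError):
            apply_pr(Sm[:-1], Sp, fit)
        with pytest.raises(ValueError):
            apply_spr(Sm[:-1], Sp, 0.5)

    def test_apply_spr_arithmetic(self, pr_pair):
        Sm, Sp = pr_pair
        np.testing.assert_allclose(apply_spr(Sm, Sp, 0.37), Sm - 0.37 * Sp,
                                   atol=1e-12)
        np.testing.assert_array_equal(apply_spr(Sm, Sp, 0.0), Sm)
        np.testing.assert_allclose(apply_spr(Sm, Sm, 1.0), 0.0, atol=1e-12)


class TestFitSpr:
    def test_single_voxel_neighborhood_is_self(self):
        Sm, Sp = corr_pair(0.5, seed=1)
        fit = fit_spr(Sm, {7: Sp}, self_index=7)
        assert fit.source_index == 7
        assert fit.correlation == pytest.approx(0.5, abs=1e-9)

    def test_most_correlated_neighbor_wins_by_absolute_value(self):
        Sm, Sp_self = corr_pair(0.2, seed=2)
        _, Sp_neigh = corr_pair(-0.9, n=len(Sm), seed=2)
        fit = fit_spr(Sm, {"i": Sp_self, "k": Sp_neigh}, self_index="i")
        assert fit.source_index == "k"
        assert fit.correlation == pytest.approx(-0.9, abs=1e-9)

    def test_orthogonal_sources_give_no_suppression(self):
        Sm, Sp = corr_pair(0.0, seed=3)
        fit = fit_spr(Sm, {0: Sp}, self_index=0)
        assert abs(fit.correlation) < 1e-9
        np.testing.assert_allclose(apply_spr(Sm, Sp, fit.correlation), Sm,
                                   atol=1e-8)

    def test_tie_prefers_self(self):
        Sm, Sp = corr_pair(0.4, seed=4)
        fit = fit_spr(Sm, {2: Sp.copy(), 1: Sp.copy()}, self_index=2)
        assert fit.source_index == 2

    def test_all_constant_neighborhood_raises(self):
        Sm, _ = corr_pair(0.1, seed=5)
        with pytest.raises(DegenerateVarianceError):
            fit_spr(Sm, {0: np.ones_like(Sm)})


class TestRegimeStatistics:
    design = BlockDesign()

    def _shifts(self, mag, ph, n=500):
        pr, spr, base = [], [], []
        for s in range(n):
            tc = simulate_voxel(mag, ph, self.design, seed=s)
            base.append(realized_fsnr(tc.magnitude, self.design))
            pr.append(suppress_timecourse(tc, "pr", self.design))
            spr.append(suppress_timecourse(tc, "spr", self.design))
        return np.array(pr), np.array(spr), np.array(base)

    def test_spr_unbiased_pr_oversuppresses_without_phase_signal(self):
        pr, spr, base = self._shifts(5.0, 0.0)
        assert -0.15 < np.mean(spr - base) < 0.15
        assert np.mean(pr - base) < -0.5

    def test_pr_artifact_exceeds_spr_in_vein_adjacent_regime(self):
        pr, spr, _ = self._shifts(0.0, 5.0)
        assert np.mean(np.abs(spr)) < 0.3
        assert np.mean(np.abs(pr)) > np.mean(np.abs(spr))


class TestFaceNeighborhood:
    def test_interior_seven(self):
        nb = face_neighborhood((2, 2, 2), (5, 5, 5), 7)
        assert len(nb) == 7 and (2, 2, 2) in nb

    def test_corner_truncated(self):
        nb = face_neighborhood((0, 0, 0), (5, 5, 5), 7)
        assert sorted(nb) == [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)]

    def test_size_one_is_self(self):
        assert face_neighborhood((3, 1, 0), (5, 5, 5), 1) == [(3, 1, 0)]

    def test_invalid_size(self):
        with pytest.raises(ConfigurationError):
            face_neighborhood((0, 0, 0), (5, 5, 5), 5)


class TestSuppressVolume:
    def test_seven_neighborhood_suppresses_vein_voxel(self, single_pre, design):
        pre = single_pre.series
        before = realized_fsnr(pre.magnitude[VEIN_VOXEL], design)
        out = suppress_volume(pre, pre, "spr", 7)
        after = realized_fsnr(out.suppressed[VEIN_VOXEL], design)
        assert before > 3 and after < 1.5

    def test_single_voxel_neighborhood_suppresses_poorly(self, single_pre, design):
        pre = single_pre.series
        out = suppress_volume(pre, pre, "spr", 1)
        after = realized_fsnr(out.suppressed[VEIN_VOXEL], design)
        assert after > 2

    def test_pure_noise_volume_passes_through(self, design):
        rng = np.random.default_rng(8)
        shape = (5, 5, 3, design.n_timepoints)
        mk = lambda: ComplexVolumeSeries(
            np.stack([zscore(v) for v in rng.standard_normal((75, shape[3]))]
                     ).reshape(shape),
            np.stack([zscore(v) for v in rng.standard_normal((75, shape[3]))]
                     ).reshape(shape), (2.25, 2.25, 2.5), 2.0)
        train, test = mk(), mk()
        out = suppress_volume(train, test, "spr", 7)
        deltas = []
        for idx in np.ndindex(5, 5, 3):
            deltas.append(realized_fsnr(out.suppressed[idx], design)
                          - realized_fsnr(test.magnitude[idx], design))
        assert np.mean(np.abs(deltas)) < 0.2

    def test_fits_come_from_training_run_only(self, single_pre, design):
        """Sentinel: replacing the test run must not change the fit report."""
        pre = single_pre.series
        rng = np.random.default_rng(9)
        sentinel = ComplexVolumeSeries(
            rng.standard_normal(pre.magnitude.shape),
            rng.standard_normal(pre.phase.shape),
            pre.voxel_size, pre.sample_interval)
        rep_a = suppress_volume(pre, pre, "spr", 7).report
        rep_b = suppress_volume(pre, sentinel, "spr", 7).report
        for col in ("source_dx", "source_dy", "source_dz", "coef"):
            np.testing.assert_array_equal(rep_a[col].values, rep_b[col].values)

    def test_degenerate_voxels_flagged_and_passed_through(self, design):
        rng = np.random.default_rng(10)
        shape = (3, 3, 2, design.n_timepoints)
        mag = rng.standard_normal(shape)
        phase = rng.standard_normal(shape)
        phase[1, 1, 0] = 0.0                     # constant-phase voxel
        mag[0, 0, 0] = 2.0                       # constant-magnitude voxel
        series = ComplexVolumeSeries(mag, phase, (2.25, 2.25, 2.5), 2.0)
        out = suppress_volume(series, series, "pr", 1)
        assert out.degenerate_mask[0, 0, 0]
        np.testing.assert_array_equal(out.suppressed[0, 0, 0], mag[0, 0, 0])
        flags = out.report.set_index(["x", "y", "z"]).loc[(0, 0, 0), "flag"]
        assert "degenerate" in flags

    def test_unknown_method_rejected(self, single_pre):
        with pytest.raises(ConfigurationError):
            suppress_volume(single_pre.series, single_pre.series, "glm", 7)
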