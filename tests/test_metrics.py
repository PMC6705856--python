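import numpy as np
import pytest

from disct2.geometry import Geometry
from disct2.metrics import disc_metrics, fit_two_gaussians, roi_mean_sd
from disct2.phantom import build_phantom
from disct2.regions import SubRegionPartition, partition_subregions
from disct2.segment import DiscROI
from disct2.t2map import T2Map, fit_t2_map

from _oracles import gmm_grid_search, gmm_loglik
from conftest import single_disc_spec


def _flat_map(values, valid=None):
    t2 = np.asarray(values, dtype=float).reshape(1, 1, -1)
    if valid is None:
        valid = np.isfinite(t2) & (t2 > 0)
    geom = Geometry(pixel_spacing=(1, 1), slice_thickness=4, slice_positions=(0.0,))
    nan = np.where(valid, t2, np.nan)
    return T2Map(t2=nan, s0=np.where(valid, 1.0, np.nan), valid=valid,
                 r2=np.where(valid, 1.0, np.nan), geometry=geom)


class TestRoiMeanSd:
    def test_constant_field(self):
        m = _flat_map([80.0] * 6)
        mean, sd, n = roi_mean_sd(m, np.ones((1, 1, 6), dtype=bool))
        assert (mean, sd, n) == (80.0, 0.0, 6)

    def test_two_values_hand_computed(self):
        # {40, 60}: mean 50; sample SD (n-1 denominator) = sqrt(200)
        m = _flat_map([40.0, 60.0])
        mean, sd, n = roi_mean_sd(m, np.ones((1, 1, 2), dtype=bool))
        assert mean == 50.0
        assert sd == pytest.approx(np.sqrt((10.0**2 + 10.0**2) / 1), abs=1e-12)
        assert n == 2

    def test_single_valid_voxel_sd_undefined(self):
        m = _flat_map([40.0, np.nan])
        mean, sd, n = roi_mean_sd(m, np.ones((1, 1, 2), dtype=bool))
        assert mean == 40.0 and np.isnan(sd) and n == 1

    def test_empty_set_error(self):
        m = _flat_map([40.0])
        with pytest.raises(ValueError, match="empty"):
            roi_mean_sd(m, np.zeros((1, 1, 1), dtype=bool))

    def test_grade1_exceeds_grade4(self):
        stats = {}
        for grade in (1, 4):
            series, truth = build_phantom(
                single_disc_spec(grade=grade, noise_sigma=2.0, seed=33))
            d = truth.discs[0]
            t2map = fit_t2_map(series, mask=d.mask)
            stats[grade] = roi_mean_sd(t2map, d.mask)
        assert stats[1][0] > stats[4][0]  # mean T2 declines with degeneration
        assert stats[1][1] > stats[4][1]  # so does the spread


class TestFitTwoGaussians:
    def test_well_separated_recovery_vs_grid_oracle(self, rng):
        x = np.concatenate([rng.normal(40, 10, 2500), rng.normal(110, 15, 2500)])
        fit = fit_two_gaussians(x)
        assert fit.converged
        assert abs(fit.delta_mu - 70.0) / 70.0 < 0.05
        best, oracle_ll = gmm_grid_search(
            x, np.arange(36, 45), np.arange(105, 116), [8, 10, 12],
            [12, 15, 18], [0.4, 0.5, 0.6])
        assert fit.loglik >= oracle_ll - 1e-6  # EM at least as good as the grid
        assert abs(fit.delta_mu - (best["mu2"] - best["mu1"])) <= 2.0

    def test_loglik_matches_direct_evaluation(self, rng):
        x = np.concatenate([rng.normal(50, 8, 500), rng.normal(90, 12, 500)])
        fit = fit_two_gaussians(x)
        direct = gmm_loglik(x, fit.mu1, fit.mu2, fit.sigma1, fit.sigma2, fit.pi1)
        assert fit.loglik == pytest.approx(direct, rel=1e-9)

    def test_single_population_small_delta(self, rng):
        # For a single-Gaussian sample the population Δμ is 0, but the
        # finite-sample unconstrained-EM optimum keeps a nonzero split that
        # soaks up skew/kurtosis (sklearn's EM lands in the same place, see
        # below), so the practical bound is a fraction of the SD rather than
        # Δμ ≈ 0.
        x = rng.normal(70, 12, 4000)
        fit = fit_two_gaussians(x, max_iter=3000, tol=1e-10)
        assert fit.delta_mu < 0.5 * x.std()

    def test_single_population_matches_sklearn(self, rng):
        from sklearn.mixture import GaussianMixture

        x = rng.normal(70, 12, 4000)
        fit = fit_two_gaussians(x, max_iter=3000, tol=1e-10)
        sk = GaussianMixture(2, max_iter=3000, tol=1e-8, random_state=0,
                             means_init=[[np.percentile(x, 25)], [np.percentile(x, 75)]],
                             weights_init=[0.5, 0.5],
                             precisions_init=[[[4 / x.var()]], [[4 / x.var()]]])
        sk.fit(x[:, None])
        sk_delta = float(abs(np.diff(np.sort(sk.means_.ravel()))[0]))
        assert fit.delta_mu == pytest.approx(sk_delta, abs=0.15 * x.std())

    def test_translation_equivariance(self, rng):
        x = np.concatenate([rng.normal(40, 10, 1000), rng.normal(110, 15, 1000)])
        f0 = fit_two_gaussians(x)
        f1 = fit_two_gaussians(x + 100.0)
        assert f1.mu1 == pytest.approx(f0.mu1 + 100.0, abs=1e-6)
        assert f1.mu2 == pytest.approx(f0.mu2 + 100.0, abs=1e-6)
        assert f1.delta_mu == pytest.approx(f0.delta_mu, abs=1e-6)

    def test_order_and_duplication_invariance(self, rng):
        x = np.concatenate([rng.normal(40, 10, 600), rng.normal(110, 15, 600)])
        f0 = fit_two_gaussians(x)
        f1 = fit_two_gaussians(x[::-1].copy())
        f2 = fit_two_gaussians(np.concatenate([x, x]))
        assert f1.delta_mu == pytest.approx(f0.delta_mu, abs=1e-9)
        assert f2.delta_mu == pytest.approx(f0.delta_mu, abs=1e-7)

    def test_loglik_monotone(self, rng):
        x = np.concatenate([rng.normal(45, 12, 800), rng.normal(95, 20, 800)])
        fit = fit_two_gaussians(x)
        assert np.all(np.diff(fit.loglik_path) >= -1e-7)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_two_gaussians(np.arange(9, dtype=float))

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            fit_two_gaussians(np.full(100, 50.0))

    def test_delta_mu_recovery_over_seeds(self):
        # median relative error over 50 simulated samples < 5%
        errs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(40, 10, 400), r.normal(110, 15, 400)])
            errs.append(abs(fit_two_gaussians(x).delta_mu - 70.0) / 70.0)
        assert np.median(errs) < 0.05


class TestDiscMetrics:
    def _analyze(self, spec):
        series, truth = build_phantom(spec)
        d = truth.discs[0]
        t2map = fit_t2_map(series, mask=d.mask)
        roi = DiscROI("s", d.level, d.mask, truth.geometry)
        part = partition_subregions(roi)
        return disc_metrics(t2map, roi, part), d

    def test_noise_free_two_delta_masses(self):
        # NP 110 / AF 45 exactly: the mixture recovers the two point masses
        from disct2.phantom import GradeParams

        params = {2: GradeParams(np_t2=110.0, af_t2=45.0, blend=0.0)}
        m, _ = self._analyze(single_disc_spec(grade_params=params, sharp=False))
        assert m.delta_mu == pytest.approx(65.0, abs=0.5)

    def test_whole_mean_is_weighted_band_mean(self, noisy_phantom):
        series, truth = noisy_phantom
        d = truth.discs[0]
        t2map = fit_t2_map(series, mask=d.mask)
        roi = DiscROI("s", d.level, d.mask, truth.geometry)
        part = partition_subregions(roi)
        m = disc_metrics(t2map, roi, part)
        ns = np.array(m.subregion_n)
        means = np.array(m.subregion_mean)
        assert m.mean_t2 == pytest.approx(float((ns * means).sum() / ns.sum()), rel=1e-12)
        assert m.n_valid == int(ns.sum())

    def test_gradient_monotone_across_bands(self):
        # linear AP T2 gradient: band means strictly increase 1 -> 5
        geom = Geometry(pixel_spacing=(1, 1), slice_thickness=4,
                        slice_positions=(0.0, 4.0, 8.0))
        t2 = np.tile(np.linspace(40, 140, 50)[None, None, :], (3, 10, 1))
        valid = np.ones_like(t2, dtype=bool)
        t2map = T2Map(t2=t2, s0=np.ones_like(t2), valid=valid,
                      r2=np.ones_like(t2), geometry=geom)
        mask = np.zeros_like(valid)
        mask[:, 2:8, 5:45] = True
        roi = DiscROI("s", "x", mask, geom)
        part = partition_subregions(roi, ap_axis=np.array([0.0, 1.0]))
        m = disc_metrics(t2map, roi, part)
        assert np.all(np.diff(m.subregion_mean) > 0)

    def test_hiz_linked_np_reduction_lowers_central_bands(self):
        m_hiz, _ = self._analyze(
            single_disc_spec(grade=3, hiz=True, seed=2, hiz_np_t2_drop=30.0))
        m_ref, _ = self._analyze(single_disc_spec(grade=3, hiz=False, seed=2))
        for band in (1, 2, 3):  # central/anterior bands hold NP tissue
            assert m_hiz.subregion_mean[band] < m_ref.subregion_mean[band]

    def test_empty_band_flagged_nan(self):
        geom = Geometry(pixel_spacing=(1, 1), slice_thickness=4,
                        slice_positions=(0.0, 4.0, 8.0))
        t2 = np.full((3, 10, 50), 80.0)
        valid = np.ones_like(t2, dtype=bool)
        valid[:, :, 0:10] = False  # first band entirely invalid
        t2m = np.where(valid, t2, np.nan)
        t2map = T2Map(t2=t2m, s0=np.where(valid, 1.0, np.nan), valid=valid,
                      r2=np.where(valid, 1.0, np.nan), geometry=geom)
        mask = np.zeros_like(valid)
        mask[:, 2:8, 0:50] = True
        roi = DiscROI("s", "x", mask, geom)
        part = partition_subregions(roi, ap_axis=np.array([0.0, 1.0]))
        m = disc_metrics(t2map, roi, part)
        assert m.subregion_n[0] == 0
        assert np.isnan(m.subregion_mean[0]) and np.isnan(m.subregion_sd[0])
        assert not np.isnan(m.subregion_mean[1])
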