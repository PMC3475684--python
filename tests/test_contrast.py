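"""Weibull contrast model: filters, gain control, scale selection, MLE."""

import numpy as np
import pytest
from scipy import integrate

from deadleaves import contrast
from deadleaves.contrast import (
    BETA_BANK,
    GAMMA_BANK,
    ContrastHistogram,
    DegenerateInputError,
    FilterBankSpec,
    NoiseThresholds,
)


class TestBuildFilter:
    @pytest.mark.parametrize("scale", [1.5, 4.0, 16.0, 64.0])
    def test_kernel_is_dc_free(self, scale):
        assert abs(contrast.build_filter(scale).sum()) < 1e-10

    def test_invalid_scale_raises(self):
        with pytest.raises(ValueError):
            contrast.build_filter(0.0)
        with pytest.raises(ValueError):
            contrast.filter_response(np.zeros((8, 8)), -1.0)

    @pytest.mark.parametrize("scale", [3.0, 20.0])
    def test_uniform_image_gives_zero_response(self, scale):
        resp = contrast.filter_response(np.full((64, 64), 0.7), scale)
        assert np.abs(resp).max() < 1e-10

    def test_step_edge_response_matches_quadrature(self):
        """Response to an ideal step edge vs dense numerical convolution.

        The separable image-domain filtering of a 1D step must agree with
        direct quadrature of the Gaussian second derivative against the
        step profile at the edge location.
        """
        scale = 4.0
        n = 129
        img = np.zeros((n, n))
        img[:, n // 2 :] = 1.0
        resp = contrast.filter_response(img, scale)

        def g2(x):
            return (
                (x * x - scale * scale)
                / scale**4
                * np.exp(-(x * x) / (2 * scale * scale))
                / (np.sqrt(2 * np.pi) * scale)
            )

        # continuous convolution of step(x - x0) with the second-derivative
        # kernel: integral of g2 over [x - x0, inf), rescaled to the
        # documented contrast normalization (2D kernel L1 norm = 2)
        x0 = n // 2 - 0.5  # step lies between pixel columns
        col = n // 2 + 6  # a little inside the bright side
        raw, _ = integrate.quad(lambda u: g2(u), -np.inf, col - x0)

        def g(x):
            return np.exp(-(x * x) / (2 * scale * scale)) / (
                np.sqrt(2 * np.pi) * scale
            )

        l1, _ = integrate.dblquad(
            lambda y, x: abs(g2(x) * g(y) + g(x) * g2(y)),
            -4 * scale,
            4 * scale,
            -4 * scale,
            4 * scale,
        )
        expected = raw * 2.0 / l1
        # 5% headroom: the implementation truncates kernel support at 3 sd
        assert resp[n // 2, col] == pytest.approx(expected, rel=0.05)

    def test_fft_and_separable_paths_agree(self):
        """The large-kernel FFT path must match direct separable filtering."""
        rng = np.random.default_rng(0)
        img = rng.random((96, 96))
        scale = 17.0  # radius 51 -> FFT path
        via_fft = contrast.filter_response(img, scale)
        kernel = contrast.build_filter(scale)
        from scipy import ndimage

        direct = ndimage.correlate(img, kernel, mode="reflect")
        assert np.allclose(via_fft, direct, atol=1e-10)


class TestNakaRushton:
    def test_fixed_points(self):
        assert contrast.naka_rushton(0.0, 0.3) == 0.0
        assert contrast.naka_rushton(0.3, 0.3) == pytest.approx(0.5)

    def test_monotone_and_saturating(self):
        r = np.linspace(0, 50, 1000)
        out = contrast.naka_rushton(r, 0.5)
        assert np.all(np.diff(out) > 0)
        assert out.max() < 1.0

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError):
            contrast.naka_rushton(-0.1, 0.5)
        with pytest.raises(ValueError):
            contrast.naka_rushton(0.1, 0.0)

    def test_gain_grid_spans_documented_range(self):
        gains = np.array(contrast.GAINS)
        assert gains[0] == pytest.approx(0.15)
        assert gains[-1] == pytest.approx(1.6)
        assert np.all(np.diff(gains) > 0)
        assert len(gains) == 5


class TestCalibration:
    def test_identical_images_give_zero_thresholds(self):
        imgs = [np.tile(np.linspace(0, 1, 64), (64, 1))] * 5
        thr = contrast.calibrate_noise_thresholds(imgs, BETA_BANK)
        assert np.allclose(thr.thresholds, 0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            contrast.calibrate_noise_thresholds([], BETA_BANK)

    def test_thresholds_deterministic(self, tiny_calibration_thresholds):
        from deadleaves import calibration

        thr_b, _ = tiny_calibration_thresholds
        again = contrast.calibrate_noise_thresholds(
            calibration.calibration_images(n=12, size=128), BETA_BANK
        )
        assert np.array_equal(thr_b.thresholds, again.thresholds)

    def test_contrast_doubling_is_nonlinear_through_gain_control(self):
        """Doubling image contrast must not double thresholds (saturation)."""
        rng = np.random.default_rng(3)
        base = [rng.random((64, 64)) * 0.5 for _ in range(6)]
        doubled = [2 * im for im in base]
        t1 = contrast.calibrate_noise_thresholds(base, BETA_BANK).thresholds
        t2 = contrast.calibrate_noise_thresholds(doubled, BETA_BANK).thresholds
        ratio = t2[t1 > 1e-12] / t1[t1 > 1e-12]
        assert np.all(ratio < 2.0)  # strictly sublinear growth
        assert not np.allclose(ratio, 1.0)


class TestScaleSelection:
    def _bank(self, n_scales, n_gains=1):
        return FilterBankSpec(tuple(4.0 * 2**k for k in range(n_scales)), (0.5,) * n_gains)

    def test_zero_thresholds_select_smallest_scale(self):
        rng = np.random.default_rng(0)
        resp = rng.random((3, 2, 4, 4)) + 0.01
        thr = NoiseThresholds(np.zeros((3, 2)), self._bank(3, 2))
        cmap = contrast.select_min_reliable_scale(resp, thr)
        assert np.all(cmap.selected_scale_index == 0)
        assert np.allclose(cmap.magnitude, resp[0].mean(axis=0))

    def test_fallback_to_largest_scale(self):
        resp = np.full((3, 1, 2, 2), 0.1)
        thr = NoiseThresholds(np.full((3, 1), 0.5), self._bank(3))
        cmap = contrast.select_min_reliable_scale(resp, thr)
        assert np.all(cmap.selected_scale_index == 2)
        assert np.allclose(cmap.magnitude, 0.1)

    def test_two_scale_hand_cases(self):
        thr = NoiseThresholds(np.array([[0.1], [0.3]]), self._bank(2))
        resp = np.zeros((2, 1, 1, 1))
        resp[:, 0, 0, 0] = [0.05, 0.4]
        assert contrast.select_min_reliable_scale(resp, thr).selected_scale_index[0, 0, 0] == 1
        resp[:, 0, 0, 0] = [0.2, 0.4]
        assert contrast.select_min_reliable_scale(resp, thr).selected_scale_index[0, 0, 0] == 0

    def test_matches_bruteforce_on_random_grid(self):
        """Vectorized selection vs an explicit per-pixel loop oracle."""
        rng = np.random.default_rng(42)
        resp = rng.random((4, 3, 4, 4))
        thr_values = rng.random((4, 3)) * 0.8
        thr = NoiseThresholds(thr_values, self._bank(4, 3))
        cmap = contrast.select_min_reliable_scale(resp, thr)
        for g in range(3):
            for y in range(4):
                for x in range(4):
                    sel = 3
                    for s in range(4):
                        if resp[s, g, y, x] > thr_values[s, g]:
                            sel = s
                            break
                    assert cmap.selected_scale_index[g, y, x] == sel
                    assert cmap.per_gain_magnitude[g, y, x] == resp[sel, g, y, x]

    def test_raising_thresholds_never_selects_smaller_scale(self):
        rng = np.random.default_rng(5)
        resp = rng.random((4, 2, 8, 8))
        low = NoiseThresholds(np.full((4, 2), 0.2), self._bank(4, 2))
        high = NoiseThresholds(np.full((4, 2), 0.6), self._bank(4, 2))
        sel_low = contrast.select_min_reliable_scale(resp, low).selected_scale_index
        sel_high = contrast.select_min_reliable_scale(resp, high).selected_scale_index
        assert np.all(sel_high >= sel_low)

    def test_magnitudes_nonnegative(self):
        rng = np.random.default_rng(6)
        resp = rng.random((5, 5, 6, 6))
        thr = NoiseThresholds(rng.random((5, 5)), FilterBankSpec())
        assert contrast.select_min_reliable_scale(resp, thr).magnitude.min() >= 0


class TestWeibullFit:
    def test_pdf_normalizes_to_one(self):
        for mu, beta, gam in [(0.0, 0.3, 1.2), (0.1, 1.5, 0.7), (0.0, 0.05, 3.0)]:
            total, _ = integrate.quad(
                lambda x: contrast.weibull_pdf(np.array([x]), mu, beta, gam)[0],
                mu,
                np.inf,
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_sampler_matches_cdf(self, rng):
        from scipy import stats

        draws = contrast.sample_weibull(50_000, 0.0, 0.4, 1.5, rng)
        ks = stats.kstest(draws, lambda x: contrast.weibull_cdf(x, 0.0, 0.4, 1.5))
        assert ks.statistic < 0.01

    def test_parameter_recovery_reference_point(self, rng):
        """beta = 0.3, gamma = 1.2 recovered within 2% from 1e5 draws."""
        draws = contrast.sample_weibull(100_000, 0.0, 0.3, 1.2, rng)
        fit = contrast.fit_weibull(draws, fix_mu=0.0)
        assert fit.beta == pytest.approx(0.3, rel=0.02)
        assert fit.gamma == pytest.approx(1.2, rel=0.02)
        assert fit.converged

    def test_histogram_fit_matches_grid_search(self, rng):
        """Optimizer must find the same optimum as an exhaustive lattice."""
        draws = contrast.sample_weibull(5_000, 0.0, 0.4, 1.3, rng)
        hist = contrast.contrast_histogram(draws, n_bins=64)
        fit = contrast.fit_weibull(hist, fix_mu=0.0)

        betas = np.linspace(0.1, 1.0, 200)
        gammas = np.linspace(0.5, 3.0, 200)
        counts = hist.counts.astype(float)
        best = (np.inf, None, None)
        for b in betas:
            cdf = contrast.weibull_cdf(hist.bin_edges[None, :], 0.0, b, 1.0)
            for g in gammas:
                cdf_g = contrast.weibull_cdf(hist.bin_edges, 0.0, b, g)
                p = np.diff(cdf_g)
                occ = counts > 0
                if np.any(p[occ] <= 0):
                    continue
                nll = -float(counts[occ] @ np.log(p[occ]))
                if nll < best[0]:
                    best = (nll, b, g)
        _, b_grid, g_grid = best
        assert fit.beta == pytest.approx(b_grid, abs=betas[1] - betas[0])
        assert fit.gamma == pytest.approx(g_grid, abs=gammas[1] - gammas[0])
        assert -fit.log_likelihood <= best[0] + 1e-6

    def test_fit_invariant_to_bin_permutation(self, rng):
        """The likelihood depends on bin contents, not their storage order."""
        draws = contrast.sample_weibull(20_000, 0.0, 0.3, 1.0, rng)
        x = np.round(draws, 3)
        values, counts = np.unique(x, return_counts=True)
        perm = rng.permutation(len(values))
        f1 = contrast.fit_weibull(values, weights=counts.astype(float), fix_mu=0.0)
        f2 = contrast.fit_weibull(values[perm], weights=counts[perm].astype(float), fix_mu=0.0)
        assert f1.beta == pytest.approx(f2.beta, rel=1e-6)
        assert f1.gamma == pytest.approx(f2.gamma, rel=1e-6)

    def test_recovery_sweep_median_error_below_5_percent(self):
        """Binned-likelihood recovery over the documented parameter box."""
        rels = []
        for k in range(50):
            r = np.random.default_rng(100 + k)
            b = 10 ** r.uniform(np.log10(0.05), 0.0)
            g = 10 ** r.uniform(np.log10(0.5), np.log10(3.5))
            draws = contrast.sample_weibull(50_000, 0.0, b, g, r)
            fit = contrast.fit_weibull(contrast.contrast_histogram(draws))
            rels.append(max(abs(fit.beta - b) / b, abs(fit.gamma - g) / g))
        assert np.median(rels) < 0.05

    def test_degenerate_histogram_rejected(self):
        hist = ContrastHistogram(
            counts=np.r_[np.zeros(255), 100].astype(np.int64),
            bin_edges=np.linspace(0, 1, 257),
        )
        with pytest.raises(DegenerateInputError):
            contrast.fit_weibull(hist)

    def test_normalization_constant_is_derived(self):
        from scipy.special import gamma as gamma_fn

        fit = contrast.WeibullParams(0.0, 0.5, 2.0, 0.0, 0.0, True)
        c = 1.0 / (fit.beta * gamma_fn(1 + 1 / fit.gamma))
        assert contrast.weibull_pdf(np.array([0.0]), 0.0, 0.5, 2.0)[0] == pytest.approx(c)


class TestComputeStats:
    def test_constant_image_raises_degenerate(self, tiny_calibration_thresholds):
        thr_b, thr_g = tiny_calibration_thresholds
        with pytest.raises(DegenerateInputError):
            contrast.compute_weibull_stats(np.full((128, 128), 0.5), thr_b, thr_g)

    def test_cluttered_scene_has_higher_gamma_than_few_edges_scene(
        self, tiny_calibration_thresholds, small_config
    ):
        """Cluttered many-edge scenes approach Gaussian contrast
        distributions (high gamma); scenes with few strong coherent edges
        approach power law (low gamma)."""
        from deadleaves import stimuli

        thr_b, thr_g = tiny_calibration_thresholds
        specs = stimuli.category_specs()
        cluttered_spec = specs[0]  # opaque flat small disks
        sparse_spec = specs[2]  # opaque flat large disks
        gammas = {}
        for name, spec in [("cluttered", cluttered_spec), ("sparse", sparse_spec)]:
            gs = []
            for idx in (1, 2, 3):
                im = stimuli.generate_image(spec, idx, 3, small_config)
                gs.append(contrast.compute_weibull_stats(im, thr_b, thr_g).gamma)
            gammas[name] = np.mean(gs)
        assert gammas["cluttered"] > gammas["sparse"]

    def test_stats_deterministic(self, tiny_calibration_thresholds):
        thr_b, thr_g = tiny_calibration_thresholds
        rng = np.random.default_rng(9)
        img = rng.random((128, 128))
        a = contrast.compute_weibull_stats(img, thr_b, thr_g)
        b = contrast.compute_weibull_stats(img, thr_b, thr_g)
        assert (a.beta, a.gamma) == (b.beta, b.gamma)
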