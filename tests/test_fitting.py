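import numpy as np
import pytest

from snsmil.camera import CameraOpticsConfig, psf_sigma_px
from snsmil.detection import select_roi, score_candidate
from snsmil.fitting import (GaussianModelSpec, Localization, initial_estimate,
                            fit_gaussian, width_filter, fit_quality_filter)

from conftest import gaussian_spot

CAMERA = CameraOpticsConfig()
SIGMA = psf_sigma_px(CAMERA)  # ~1.4645 px


def candidate_for(img, bg_level=10.0, peak=None):
    bg = np.full(img.shape, float(bg_level))
    if peak is None:
        peak = tuple(np.unravel_index(np.argmax(img), img.shape))
    cand = select_roi(img, bg, peak, SIGMA)
    score_candidate(cand, bg, CAMERA)
    return cand


class TestInitialEstimate:
    def test_centroid_of_noiseless_gaussian(self):
        img = gaussian_spot((24, 24), 12.3, 11.6, 100.0, SIGMA, offset=10.0)
        cand = candidate_for(img)
        p0 = initial_estimate(cand, img, SIGMA)
        assert abs(p0[0] - 12.3) < 0.05 and abs(p0[1] - 11.6) < 0.05
        assert p0[4] == pytest.approx(10.0)

    def test_single_pixel_roi_centroid_is_peak(self):
        img = np.full((16, 16), 10.0)
        img[8, 9] = 50.0
        cand = candidate_for(img, peak=(8, 9))
        p0 = initial_estimate(cand, img, SIGMA)
        assert (p0[0], p0[1]) == (9.0, 8.0)  # (x=col, y=row)

    def test_uniform_roi_centroid_is_geometric_center(self):
        # symmetric uniform excess over background: centroid = peak by symmetry
        img = np.full((16, 16), 15.0)
        bg = np.full((16, 16), 10.0)
        cand = select_roi(img, bg, (8, 8), SIGMA)
        p0 = initial_estimate(cand, img, SIGMA)
        assert (p0[0], p0[1]) == (8.0, 8.0)

    def test_zero_signal_returns_none(self):
        img = np.full((16, 16), 10.0)
        cand = candidate_for(img, peak=(8, 8))
        assert initial_estimate(cand, img, SIGMA) is None


class TestFitGaussian:
    @pytest.mark.parametrize("model", [1, 2, 3])
    def test_noiseless_recovery(self, model):
        truth = dict(x=10.30, y=12.70, amp=100.0, off=10.0)
        img = gaussian_spot((24, 24), truth["x"], truth["y"], truth["amp"],
                            SIGMA, truth["off"])
        cand = candidate_for(img)
        spec = GaussianModelSpec(model=model, theoretical_sigma_px=SIGMA)
        loc = fit_gaussian(cand, img, spec, CAMERA)
        assert loc.status == "accepted"
        assert loc.x_px == pytest.approx(truth["x"], abs=1e-4)
        assert loc.y_px == pytest.approx(truth["y"], abs=1e-4)
        assert loc.amplitude == pytest.approx(truth["amp"], abs=1e-3)
        assert loc.offset == pytest.approx(truth["off"], abs=1e-3)
        if model >= 2:
            assert loc.sigma_x_px == pytest.approx(SIGMA, abs=1e-4)

    def test_noiseless_beats_dense_grid_search(self):
        # independent oracle: SSE over a fine position grid is minimised at
        # the fitted position, not at any displaced grid point
        img = gaussian_spot((24, 24), 10.30, 12.70, 100.0, SIGMA, 10.0)
        cand = candidate_for(img)
        loc = fit_gaussian(cand, img, GaussianModelSpec(1, SIGMA), CAMERA)
        yy, xx = np.mgrid[9:16, 7:14]
        win = img[9:16, 7:14]

        def sse(x0, y0):
            model = 100.0 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                                   / (2 * SIGMA**2)) + 10.0
            return float(np.sum((model - win) ** 2))

        best = min(((sse(x, y), x, y)
                    for x in np.arange(10.0, 10.6, 0.01)
                    for y in np.arange(12.4, 13.0, 0.01)))
        assert abs(best[1] - loc.x_px) < 0.01 and abs(best[2] - loc.y_px) < 0.01

    def test_model2_is_circular_by_construction(self, rng):
        img = gaussian_spot((24, 24), 12.0, 12.0, 80.0, SIGMA, 10.0)
        img = rng.poisson(img).astype(float)
        cand = candidate_for(img, peak=(12, 12))
        loc = fit_gaussian(cand, img, GaussianModelSpec(2, SIGMA), CAMERA)
        assert loc.sigma_x_px == loc.sigma_y_px

    def test_monte_carlo_localization_error(self, rng):
        # 500-photon spots on 10 e-/px background, model 1: RMS error <~ 0.2 px
        spec = GaussianModelSpec(1, SIGMA)
        amp = 500.0 / (2 * np.pi * SIGMA**2)
        errs = []
        for _ in range(300):
            x0, y0 = rng.uniform(10.5, 11.5, 2)
            img = rng.poisson(gaussian_spot((22, 22), x0, y0, amp, SIGMA, 10.0)
                              ).astype(float)
            cand = candidate_for(img)
            loc = fit_gaussian(cand, img, spec, CAMERA)
            if loc.status == "accepted":
                errs.append((loc.x_px - x0) ** 2 + (loc.y_px - y0) ** 2)
        assert len(errs) > 280
        assert np.sqrt(np.mean(errs)) < 0.2

    def test_integer_translation_invariance(self):
        img_a = gaussian_spot((30, 30), 10.25, 11.40, 90.0, SIGMA, 5.0)
        img_b = gaussian_spot((30, 30), 16.25, 14.40, 90.0, SIGMA, 5.0)
        spec = GaussianModelSpec(3, SIGMA)
        loc_a = fit_gaussian(candidate_for(img_a, 5.0), img_a, spec, CAMERA)
        loc_b = fit_gaussian(candidate_for(img_b, 5.0), img_b, spec, CAMERA)
        assert loc_b.x_px - loc_a.x_px == pytest.approx(6.0, abs=1e-8)
        assert loc_b.y_px - loc_a.y_px == pytest.approx(3.0, abs=1e-8)

    def test_photons_consistent_with_parameters(self):
        loc = Localization(0, 5, 5, amplitude=30.0, sigma_x_px=1.2,
                           sigma_y_px=1.5, offset=3.0)
        assert loc.photons == pytest.approx(2 * np.pi * 30.0 * 1.2 * 1.5, rel=1e-6)

    def test_edge_peak_rejected(self):
        img = gaussian_spot((16, 16), 1.0, 1.0, 100.0, SIGMA, 10.0)
        cand = candidate_for(img, peak=(1, 1))
        loc = fit_gaussian(cand, img, GaussianModelSpec(1, SIGMA), CAMERA)
        assert loc.status == "rejected_edge"


class TestWidthFilter:
    def loc(self, sx, sy=None):
        return Localization(0, 5, 5, 10.0, sx, sy if sy is not None else sx, 0.0)

    def test_spike_width_rejected(self):
        spec = GaussianModelSpec(2, SIGMA, pwt=3.0)
        assert width_filter(self.loc(0.3), spec).status == "rejected_width"

    def test_inside_range_accepted(self):
        spec = GaussianModelSpec(2, SIGMA, pwt=3.0)
        assert width_filter(self.loc(2.9 * SIGMA), spec).status == "accepted"

    def test_model1_always_passes(self):
        spec = GaussianModelSpec(1, SIGMA)
        assert width_filter(self.loc(0.1), spec).status == "accepted"

    def test_elliptical_requires_both_sigmas_valid(self):
        spec = GaussianModelSpec(3, SIGMA, pwt=2.0)
        assert width_filter(self.loc(SIGMA, 2.5 * SIGMA), spec).status == "rejected_width"

    def test_widening_pwt_accepts_a_superset(self, rng):
        sigmas = rng.uniform(0.2, 5.0, 200)
        for pwt_lo, pwt_hi in [(1.5, 3.0)]:
            acc_lo = {i for i, s in enumerate(sigmas)
                      if width_filter(self.loc(s), GaussianModelSpec(2, SIGMA, pwt_lo)
                                      ).status == "accepted"}
            acc_hi = {i for i, s in enumerate(sigmas)
                      if width_filter(self.loc(s), GaussianModelSpec(2, SIGMA, pwt_hi)
                                      ).status == "accepted"}
            assert acc_lo <= acc_hi


class TestFitQualityFilter:
    def test_model_on_its_own_output_r_is_one(self):
        img = gaussian_spot((24, 24), 12.0, 12.0, 100.0, SIGMA, 10.0)
        cand = candidate_for(img)
        spec = GaussianModelSpec(1, SIGMA)
        loc = fit_gaussian(cand, img, spec, CAMERA)
        loc = fit_quality_filter(loc, cand, img, spec)
        assert loc.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert loc.status == "accepted"

    def test_pure_noise_rejected(self, rng):
        spec = GaussianModelSpec(1, SIGMA)
        rejected = 0
        n = 50
        for _ in range(n):
            img = rng.poisson(10.0, (24, 24)).astype(float)
            img[12, 12] += 30  # force a candidate
            cand = candidate_for(img, peak=(12, 12))
            loc = fit_gaussian(cand, img, spec, CAMERA)
            if loc.status != "accepted":
                rejected += 1
                continue
            loc = fit_quality_filter(loc, cand, img, spec, r_min=0.5)
            if loc.status == "rejected_fit_quality":
                rejected += 1
        assert rejected > 0.5 * n

    def test_pearson_matches_textbook_formula(self, rng):
        img = rng.poisson(gaussian_spot((24, 24), 12.2, 11.8, 60.0, SIGMA, 10.0)
                          ).astype(float)
        cand = candidate_for(img, peak=(12, 12))
        spec = GaussianModelSpec(1, SIGMA)
        loc = fit_gaussian(cand, img, spec, CAMERA)
        loc = fit_quality_filter(loc, cand, img, spec, r_min=0.0)
        half = int(np.ceil(2 * SIGMA))
        pr, pc = cand.peak
        win = img[pr - half:pr + half + 1, pc - half:pc + half + 1].ravel()
        yy, xx = np.mgrid[pr - half:pr + half + 1, pc - half:pc + half + 1]
        model = (loc.amplitude * np.exp(-((xx - loc.x_px) ** 2 / (2 * loc.sigma_x_px**2)
                                          + (yy - loc.y_px) ** 2 / (2 * loc.sigma_y_px**2)))
                 + loc.offset).ravel()
        mx, my = model.mean(), win.mean()
        r_oracle = (np.sum((model - mx) * (win - my))
                    / np.sqrt(np.sum((model - mx) ** 2) * np.sum((win - my) ** 2)))
        assert loc.pearson_r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_window_rejected(self):
        img = np.full((24, 24), 10.0)
        cand = candidate_for(img, peak=(12, 12))
        loc = Localization(0, 12.0, 12.0, 5.0, SIGMA, SIGMA, 10.0)
        loc = fit_quality_filter(loc, cand, img, GaussianModelSpec(1, SIGMA))
        assert loc.status == "rejected_fit_quality"


class TestModelRecoveryFloor:
    def test_in_focus_median_error_all_models(self, rng):
        # 500-photon in-focus spots, bg 10: median position error <= 0.15 px,
        # and the fixed-width model is not worse than the elliptical one
        amp = 500.0 / (2 * np.pi * SIGMA**2)
        errors = {1: [], 3: []}
        for _ in range(250):
            x0, y0 = rng.uniform(10.5, 11.5, 2)
            img = rng.poisson(gaussian_spot((22, 22), x0, y0, amp, SIGMA, 10.0)
                              ).astype(float)
            cand = candidate_for(img)
            for model in (1, 3):
                loc = fit_gaussian(cand, img, GaussianModelSpec(model, SIGMA), CAMERA)
                if loc.status == "accepted":
                    errors[model].append(np.hypot(loc.x_px - x0, loc.y_px - y0))
        for model in (1, 3):
            assert np.median(errors[model]) <= 0.15
        assert np.sqrt(np.mean(np.square(errors[1]))) <= np.sqrt(
            np.mean(np.square(errors[3]))) * 1.05
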