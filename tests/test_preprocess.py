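import itertools

import numpy as np
import pytest
from scipy import ndimage

import mcttrack as m
from mcttrack.phantom import _render_bead
from mcttrack.preprocess import estimate_translation, subtract_background_frame


def _seq(frames, pixel_size=16.0, interval=2.4):
    return m.ImageSequence([np.asarray(f) for f in frames], pixel_size, interval)


class TestFlatField:
    def test_frame_equal_flat_gives_ones(self):
        flat = np.full((16, 16), 2.0)
        seq = _seq([flat.copy(), flat.copy()])
        out = m.flat_field_correct(seq, flat, 0.0)
        for f in out:
            np.testing.assert_allclose(f, 1.0)

    def test_frame_equal_dark_gives_zeros(self):
        dark = np.full((16, 16), 0.5)
        flat = np.full((16, 16), 2.0)
        out = m.flat_field_correct(_seq([dark.copy()]), flat, dark)
        np.testing.assert_allclose(out[0], 0.0)

    def test_idempotent_with_unit_flat(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0.2, 0.8, (16, 16))
        out = m.flat_field_correct(_seq([frame]), np.ones((16, 16)), 0.0)
        np.testing.assert_allclose(out[0], frame, rtol=1e-6)

    def test_gradient_removed_bead_contrast_uniform(self):
        # a 2x illumination gradient with two identical beads at either end:
        # after correction their fractional contrasts agree within 1%
        h, w = 64, 192
        flat = np.tile(np.linspace(1.0, 2.0, w), (h, 1))
        frame = flat.copy()
        _render_bead(frame, 30.0, 32.0, radius_px=3.2, contrast=0.3)
        _render_bead(frame, 160.0, 32.0, radius_px=3.2, contrast=0.3)
        out = m.flat_field_correct(_seq([frame]), flat, 0.0)[0]

        def frac_contrast(img, x):
            patch = img[24:41, x - 8:x + 9]
            local_bg = np.median(img[24:41, x - 20:x - 12])
            return (local_bg - patch.min()) / local_bg

        c1, c2 = frac_contrast(out, 30), frac_contrast(out, 160)
        assert abs(c1 - c2) / c1 < 0.01

    def test_nonpositive_flat_minus_dark_names_pixel(self):
        flat = np.ones((8, 8))
        flat[3, 5] = 0.0
        with pytest.raises(ValueError, match=r"row=3, col=5"):
            m.flat_field_correct(_seq([np.ones((8, 8))]), flat, 0.0)


class TestBuildBackground:
    def test_static_reference_is_the_reference(self):
        ref = np.random.default_rng(0).uniform(size=(16, 16))
        model = m.build_background(mode="static_reference", reference=ref)
        np.testing.assert_array_equal(model.background, ref)

    def test_static_mode_requires_reference(self):
        with pytest.raises(ValueError, match="reference"):
            m.build_background(_seq([np.ones((4, 4))]), mode="static_reference")

    def test_temporal_median_needs_three_frames(self):
        with pytest.raises(ValueError, match=">= 3"):
            m.build_background(_seq([np.ones((4, 4))] * 2), mode="temporal_median")

    def test_temporal_median_suppresses_a_moving_bead(self):
        # 11 frames; the bead crosses so each pixel is dark in <= 2 frames
        rng = np.random.default_rng(1)
        true_bg = 0.75 + 0.05 * rng.standard_normal((48, 48))
        true_bg = ndimage.gaussian_filter(true_bg, 3)
        noise_sd = 0.005
        frames = []
        for k in range(11):
            f = true_bg.copy()
            _render_bead(f, 4.0 + 4.0 * k, 24.0, radius_px=3.2, contrast=0.3)
            frames.append(f + rng.normal(0, noise_sd, f.shape))
        model = m.build_background(_seq(frames), mode="temporal_median")
        assert np.abs(model.background - true_bg).max() < noise_sd * 5


class TestSubtract:
    def test_frame_equals_background_gives_zero_residual(self):
        bg = np.random.default_rng(2).uniform(size=(16, 16))
        model = m.build_background(mode="static_reference", reference=bg)
        out = m.subtract_background(_seq([bg.copy()]), model)
        np.testing.assert_allclose(out[0], 0.0, atol=1e-7)

    def test_beads_become_positive_peaks_at_truth(self, small_phantom):
        model = m.build_background(mode="static_reference",
                                   reference=small_phantom.background)
        res0 = subtract_background_frame(small_phantom.sequence[0], model)
        truth0 = small_phantom.truth.at_frame(0)
        for _, r in truth0.iterrows():
            y, x = int(round(r.y_px)), int(round(r.x_px))
            assert res0[y, x] > 0.05  # bead amplitude far above noise

    def test_bead_free_residual_is_noise_limited(self):
        p = m.sheep_preset(shape=(128, 128), n_frames=5, n_particles=0, seed=3)
        res = m.generate_phantom(p)
        model = m.build_background(mode="static_reference", reference=res.background)
        resid = m.subtract_background(res.sequence, model)
        for f in resid:
            assert np.abs(f).max() < 5 * p.noise_sd
            assert abs(float(f.mean())) < p.noise_sd

    def test_drifted_frame_blows_residual_energy(self):
        p = m.sheep_preset(shape=(128, 128), n_frames=2, n_particles=0, seed=4)
        res = m.generate_phantom(p)
        model = m.build_background(mode="static_reference", reference=res.background)
        shifted = np.roll(res.sequence[0], 10, axis=0)
        resid = subtract_background_frame(shifted, model)
        aligned = subtract_background_frame(res.sequence[0], model)
        assert resid.std() > 3 * aligned.std()
        assert resid.std() > 4 * p.noise_sd

    def test_shape_mismatch(self):
        model = m.build_background(mode="static_reference", reference=np.ones((8, 8)))
        with pytest.raises(ValueError):
            m.subtract_background(_seq([np.ones((4, 4))]), model)


def _exhaustive_integer_shift(frame, background, max_shift=6):
    """Brute-force oracle: the integer (dx, dy) minimizing the SSD between
    the circularly shifted background and the frame."""
    best, best_err = (0, 0), np.inf
    for dy, dx in itertools.product(range(-max_shift, max_shift + 1), repeat=2):
        err = np.sum((np.roll(background, (dy, dx), axis=(0, 1)) - frame) ** 2)
        if err < best_err:
            best_err, best = err, (dx, dy)
    return best


class TestAssessDrift:
    def test_integer_shifts_recovered_exactly(self):
        p = m.sheep_preset(shape=(64, 64), n_frames=1, n_particles=0,
                           noise_sd=0.0, seed=5)
        bg = m.generate_phantom(p).background.astype(np.float64)
        for dx, dy in [(0, 0), (3, -2), (-4, 5), (6, 6)]:
            frame = np.roll(bg, (dy, dx), axis=(0, 1))
            ex, ey = estimate_translation(frame, bg)
            assert (round(ex), round(ey)) == (dx, dy)
            assert abs(ex - dx) < 0.1 and abs(ey - dy) < 0.1
            assert _exhaustive_integer_shift(frame, bg) == (dx, dy)

    def test_undrifted_phantom_passes_with_tiny_estimates(self, small_phantom):
        model = m.build_background(mode="static_reference",
                                   reference=small_phantom.background)
        report = m.assess_drift(small_phantom.sequence, model, drift_threshold_px=5.0)
        assert report.passed
        assert report.max_drift_px < 0.5

    def test_imposed_drift_fails_threshold(self):
        p = m.sheep_preset(shape=(256, 256), n_frames=60, n_particles=5,
                           drift_px_per_frame=(0.15, 0.2), seed=6)
        res = m.generate_phantom(p)
        model = m.build_background(mode="static_reference", reference=res.background)
        report = m.assess_drift(res.sequence, model, drift_threshold_px=5.0)
        assert not report.passed
        assert report.max_drift_px > 10.0
        # an effectively infinite threshold always passes
        assert m.assess_drift(res.sequence, model, drift_threshold_px=1e9).passed

    def test_featureless_background_is_an_error(self):
        model = m.build_background(mode="static_reference", reference=np.ones((32, 32)))
        seq = _seq([np.ones((32, 32))] * 3)
        with pytest.raises(ValueError, match="featureless"):
            m.assess_drift(seq, model, 5.0)

    def test_needs_two_frames(self):
        model = m.build_background(mode="static_reference",
                                   reference=np.random.default_rng(0).uniform(size=(16, 16)))
        with pytest.raises(ValueError):
            m.assess_drift(_seq([model.background]), model, 5.0)
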