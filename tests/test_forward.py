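import numpy as np
import pytest

from fpmrecon import (ObjectField, SceneSpec, SystemGeometry, aberrated_pupil,
                      fft2c, forward_capture, ideal_pupil, ifft2c,
                      led_wavevectors, make_synthetic_scene, sample_random_coeffs,
                      simulate_dataset)
from fpmrecon.forward import _crop_slices, capture_field
from fpmrecon.geometry import frequency_grid
from fpmrecon.zernike import unit_disk_coordinates


class TestCentredFFT:
    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        lhs = np.sum(np.abs(x) ** 2)
        rhs = np.sum(np.abs(fft2c(x)) ** 2) / x.size
        assert abs(lhs - rhs) / lhs < 1e-10

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((32, 32)) * 1j + rng.standard_normal((32, 32))
        assert np.allclose(ifft2c(fft2c(x)), x, atol=1e-12)

    def test_dc_is_centred(self):
        x = np.ones((16, 16))
        X = fft2c(x)
        assert abs(X[8, 8]) == pytest.approx(256.0)
        X[8, 8] = 0
        assert np.allclose(X, 0, atol=1e-9)


class TestContainers:
    def test_object_field_round_trip(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        obj = ObjectField.from_complex(f)
        assert np.allclose(obj.complex, f)

    def test_object_field_validation(self):
        with pytest.raises(ValueError):
            ObjectField(np.ones((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            ObjectField(-np.ones((4, 4)), np.zeros((4, 4)))


class TestPupils:
    def test_ideal_pupil_binary_disk(self, grid_small):
        p = ideal_pupil(grid_small)
        assert np.array_equal(np.abs(p.values), p.support.astype(float))
        rho, _, _ = unit_disk_coordinates(grid_small)
        assert np.array_equal(p.support, rho <= 1.0)

    def test_aberrated_pupil_unit_modulus(self, grid_small):
        p = aberrated_pupil(grid_small, sample_random_coeffs(3))
        assert np.allclose(np.abs(p.values[p.support]), 1.0)
        assert np.all(p.values[~p.support] == 0)

    def test_zero_coeffs_give_ideal(self, grid_small):
        from fpmrecon import ZernikeCoefficients
        p = aberrated_pupil(grid_small, ZernikeCoefficients.zeros())
        assert np.allclose(p.values, ideal_pupil(grid_small).values)


class TestCapture:
    def test_crop_slices_centre(self):
        rs, cs = _crop_slices(512, 128, (0, 0))
        assert (rs.start, rs.stop) == (192, 320)
        assert (cs.start, cs.stop) == (192, 320)

    def test_crop_slices_off_grid(self):
        with pytest.raises(ValueError):
            _crop_slices(512, 128, (200, 0))

    def test_uniform_object_intensity_scale(self, geom_small, grid_small):
        """A uniform object of amplitude A yields frames of intensity A^2."""
        n = geom_small.hr_size
        obj = ObjectField(np.full((n, n), 0.7), np.zeros((n, n)))
        frame = forward_capture(obj, ideal_pupil(grid_small), (0, 0))
        assert np.allclose(frame, 0.49, atol=1e-12)

    def test_central_frame_is_lowpass_image(self, geom_small, grid_small):
        amp, ph = make_synthetic_scene("blobs", geom_small.hr_size, 5)
        obj = ObjectField(amp, ph)
        frame = forward_capture(obj, ideal_pupil(grid_small), (0, 0))
        # energy preserved up to the NA cutoff: the frame is a smooth,
        # positive image of the same mean brightness scale as |o|^2
        assert frame.min() >= 0
        assert frame.mean() == pytest.approx(np.mean(amp ** 2), rel=0.2)

    def test_shift_selects_subband(self, geom_small, grid_small):
        """Capture with shift s equals capture of the spectrum rolled by -s."""
        amp, ph = make_synthetic_scene("speckle", geom_small.hr_size, 6)
        spectrum = fft2c(ObjectField(amp, ph).complex)
        p = ideal_pupil(grid_small)
        shifted = capture_field(spectrum, p, (2, -1))
        rolled = capture_field(np.roll(spectrum, (-2, 1), axis=(0, 1)), p, (0, 0))
        assert np.allclose(shifted, rolled, atol=1e-12)


class TestScenes:
    def test_patterns_deterministic_and_bounded(self):
        for pat in ("blobs", "speckle", "strokes"):
            a1, p1 = make_synthetic_scene(pat, 128, 3)
            a2, p2 = make_synthetic_scene(pat, 128, 3)
            assert np.array_equal(a1, a2) and np.array_equal(p1, p2)
            assert a1.min() >= 0.1 - 1e-12 and a1.max() <= 1.0 + 1e-12
            assert p1.min() >= 0.0 and p1.max() <= 1.0 + 1e-12

    def test_amplitude_phase_streams_independent(self):
        a, p = make_synthetic_scene("blobs", 128, 3)
        assert abs(np.corrcoef(a.ravel(), p.ravel())[0, 1]) < 0.2

    def test_unknown_pattern(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            make_synthetic_scene("nope", 64, 0)

    def test_scene_spec_accepts_arrays(self):
        amp = np.linspace(0, 1, 64 * 64).reshape(64, 64)
        spec = SceneSpec(amplitude=amp, phase=amp, size=64, phase_scale_rad=2.0)
        obj = spec.resolve()
        assert np.allclose(obj.amplitude, amp)
        assert obj.phase.max() == pytest.approx(2.0)

    def test_scene_spec_rejects_wrong_size(self):
        with pytest.raises(ValueError):
            SceneSpec(amplitude=np.ones((32, 32)), phase="blobs", size=64).resolve()


class TestSimulateDataset:
    def test_shapes_and_provenance(self, geom_small, small_stack_aberrated):
        stack = small_stack_aberrated
        assert stack.frames.shape == (geom_small.n_leds, geom_small.lr_size,
                                      geom_small.lr_size)
        assert np.all(stack.frames >= 0)
        assert stack.truth_object is not None
        assert stack.truth_coeffs is not None and stack.seed == 11

    def test_aberration_changes_frames_not_energy_much(self, geom_small,
                                                       small_scene,
                                                       small_stack_plain):
        aberr = simulate_dataset(small_scene, geom_small,
                                 sample_random_coeffs(11, jmax=15, bound=0.1))
        plain = small_stack_plain
        assert not np.allclose(aberr.frames, plain.frames)
        # a phase-only pupil preserves each frame's total energy
        assert np.allclose(aberr.frames.sum(axis=(1, 2)),
                           plain.frames.sum(axis=(1, 2)), rtol=1e-10)

    def test_deterministic(self, geom_small, small_scene):
        c = sample_random_coeffs(4)
        s1 = simulate_dataset(small_scene, geom_small, c)
        s2 = simulate_dataset(small_scene, geom_small, c)
        assert np.array_equal(s1.frames, s2.frames)
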