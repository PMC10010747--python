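import numpy as np
import pytest

from fpmrecon import ReconConfig, ideal_pupil, run_reconstruction
from fpmrecon.forward import _crop_slices, Pupil
from fpmrecon.recon import (_clamp_transmission, _update_adaptive_pupil,
                            _update_adaptive_spectrum, _update_ap,
                            _update_epry_pupil, compute_tau_alpha,
                            convergence_error, denoise_threshold,
                            initialize_state, ratio_map, replace_amplitude)


class TestReconConfig:
    def test_defaults_and_validation(self):
        c = ReconConfig()
        assert c.algorithm == "aap" and c.updates_pupil and c.denoise_enabled
        assert not ReconConfig(algorithm="ap").denoise_enabled
        assert ReconConfig(algorithm="aa").denoise_enabled
        assert ReconConfig(algorithm="epry").updates_pupil
        assert not ReconConfig(algorithm="epry").denoise_enabled
        assert not ReconConfig(algorithm="ap").updates_pupil
        assert ReconConfig(algorithm="epry", denoise=True).denoise_enabled
        with pytest.raises(ValueError):
            ReconConfig(algorithm="grad")
        with pytest.raises(ValueError):
            ReconConfig(max_iterations=0)
        with pytest.raises(ValueError):
            ReconConfig(zeta1=-1)


class TestDenoiseThreshold:
    def test_arithmetic(self):
        rng = np.random.default_rng(0)
        im = rng.uniform(0.3, 0.7, (16, 16))
        im = im - im.mean() + 0.5                 # mean exactly 0.5
        it = np.full((16, 16), 0.3)
        out, thr = denoise_threshold(im, it)
        assert thr == pytest.approx(0.2)
        assert np.allclose(out, np.clip(im - 0.2, 0, None))

    def test_identity_when_consistent(self):
        im = np.random.default_rng(1).uniform(size=(8, 8))
        out, thr = denoise_threshold(im, im)
        assert thr == 0.0
        assert np.array_equal(out, im)

    def test_mean_matching_without_clamp(self):
        im = np.full((8, 8), 0.9)
        it = np.full((8, 8), 0.4)
        out, _ = denoise_threshold(im, it)
        assert out.mean() == pytest.approx(it.mean())


class TestReplaceAmplitude:
    def test_modulus_contract(self):
        rng = np.random.default_rng(2)
        psi = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        intensity = rng.uniform(0.1, 2.0, (16, 16))
        phi = replace_amplitude(psi, intensity)
        assert np.allclose(np.abs(phi) ** 2, intensity, rtol=1e-12)
        # phase preserved
        assert np.allclose(np.angle(phi), np.angle(psi))

    def test_self_consistent_fixed_point(self):
        rng = np.random.default_rng(3)
        psi = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        phi = replace_amplitude(psi, np.abs(psi) ** 2)
        assert np.allclose(phi, psi, rtol=1e-12)

    def test_zero_field_pixels(self):
        psi = np.zeros((4, 4), complex)
        phi = replace_amplitude(psi, np.full((4, 4), 4.0))
        assert np.allclose(phi, 2.0)


class TestAdaptiveFactor:
    def test_alpha_arithmetic(self, grid_small):
        p = ideal_pupil(grid_small)
        tau, alpha = compute_tau_alpha([0.0], p)
        assert tau == 0.0 and alpha == 2.0        # tau=0, max|P|=1 -> alpha=2

    def test_tau_is_mean(self, grid_small):
        p = ideal_pupil(grid_small)
        tau, alpha = compute_tau_alpha([0.1, 0.3], p)
        assert tau == pytest.approx(0.2)
        assert alpha == pytest.approx(1.8)

    def test_empty_thresholds_rejected(self, grid_small):
        with pytest.raises(ValueError):
            compute_tau_alpha([], ideal_pupil(grid_small))

    def test_ratio_map(self):
        m = np.array([[1.0, 2.0], [0.0, 4.0]])
        assert np.allclose(ratio_map(m), m / 4.0)
        with pytest.raises(ValueError):
            ratio_map(np.zeros((2, 2)))


class TestFixedPoints:
    """Delta = 0 leaves spectrum and pupil of every rule unchanged."""

    def setup_method(self):
        rng = np.random.default_rng(4)
        self.region = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        self.pupil = np.exp(1j * rng.standard_normal((8, 8)))
        self.zero = np.zeros((8, 8), complex)

    def test_ap(self):
        assert np.array_equal(
            _update_ap(self.region, self.pupil, self.zero), self.region)

    def test_adaptive_spectrum(self):
        out = _update_adaptive_spectrum(self.region, self.pupil, self.zero,
                                        alpha=2.0, zeta1=1.0)
        assert np.array_equal(out, self.region)

    def test_adaptive_pupil(self):
        out = _update_adaptive_pupil(self.pupil, self.region, self.zero,
                                     beta=2.0, zeta2=10.0)
        assert np.array_equal(out, self.pupil)

    def test_epry_pupil(self):
        out = _update_epry_pupil(self.pupil, self.region, self.zero)
        assert np.array_equal(out, self.pupil)

    def test_unit_pupil_ap_step_is_plain_correlation(self):
        delta = np.full((8, 8), 0.5 + 0.5j)
        out = _update_ap(self.region, self.pupil, delta)
        assert np.allclose(out - self.region, np.conj(self.pupil) * delta)


class TestClamp:
    def test_caps_modulus_keeps_phase(self):
        vals = np.array([0.5 * np.exp(0.3j), 2.0 * np.exp(-1.2j)])
        out = _clamp_transmission(vals)
        assert np.abs(out[0]) == pytest.approx(0.5)
        assert np.abs(out[1]) == pytest.approx(1.0)
        assert np.angle(out[1]) == pytest.approx(-1.2)


class TestSupportAndLocality:
    def test_pupil_zero_outside_support(self, small_stack_aberrated):
        for algo in ("epry", "aap"):
            res = run_reconstruction(small_stack_aberrated,
                                     ReconConfig(algorithm=algo, max_iterations=2))
            assert np.all(res.pupil.values[~res.pupil.support] == 0)

    def test_spectrum_update_is_local(self, small_stack_aberrated):
        stack = small_stack_aberrated
        config = ReconConfig(algorithm="aap", max_iterations=1)
        before = initialize_state(stack, config).spectrum.copy()
        res = run_reconstruction(stack, config)
        n_hr = before.shape[0]
        n_lr = stack.geometry.lr_size
        touched = np.zeros_like(before, dtype=bool)
        for s in stack.illumination.pixel_shifts:
            rs, cs = _crop_slices(n_hr, n_lr, tuple(s))
            touched[rs, cs] = True
        after = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(res.field)))
        # the field went through one inverse FFT, so allow round-off
        assert np.allclose(after[~touched], before[~touched], atol=1e-9)


class TestConvergenceError:
    def test_zero_on_perfect_agreement(self, small_stack_plain):
        from fpmrecon.forward import fft2c
        stack = small_stack_plain
        grid_n = stack.geometry.lr_size
        state = initialize_state(stack, ReconConfig(algorithm="ap"))
        state.spectrum = fft2c(stack.truth_object.complex)
        assert convergence_error(stack, state) < 1e-20

    def test_positive_on_disagreement(self, small_stack_plain):
        state = initialize_state(small_stack_plain, ReconConfig(algorithm="ap"))
        state.spectrum = state.spectrum * 0.5
        assert convergence_error(small_stack_plain, state) > 0

    def test_scale_invariance(self, geom_small, small_scene):
        """Scaling measurements and object together leaves the error fixed."""
        from dataclasses import replace as dc_replace
        from fpmrecon import simulate_dataset
        from fpmrecon.forward import LRStack
        stack = simulate_dataset(small_scene, geom_small, None)
        state = initialize_state(stack, ReconConfig(algorithm="ap"))
        e1 = convergence_error(stack, state)
        scaled = LRStack(frames=stack.frames * 4.0, geometry=stack.geometry,
                         illumination=stack.illumination)
        state.spectrum = state.spectrum * 2.0
        e2 = convergence_error(scaled, state)
        assert e2 == pytest.approx(e1, rel=1e-12)
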