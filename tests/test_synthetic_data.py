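"""Phantom generator: directions, tensor signals, mixtures, noise."""

import numpy as np
import pytest

from mapboot import synthetic_data as sd
from mapboot.scheme_io import AcquisitionScheme


class TestGenerateDirections:
    def test_unit_norm_and_determinism(self):
        a = sd.generate_directions(30, seed=7)
        b = sd.generate_directions(30, seed=7)
        np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(a, b)

    def test_single_direction(self):
        v = sd.generate_directions(1, seed=0)
        assert v.shape == (1, 3)

    def test_min_pairwise_angle_n60(self):
        v = sd.generate_directions(60, seed=2)
        dots = np.abs(v @ v.T)
        np.fill_diagonal(dots, 0.0)
        min_angle = np.degrees(np.arccos(np.clip(dots.max(), -1, 1)))
        assert min_angle > 10.0

    def test_zero_directions_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_directions(0)


class TestTensorSignal:
    def test_isotropic_attenuation_closed_form(self, sparcgold):
        D = 1e-3 * np.eye(3)
        sig = sd.tensor_signal(D, sparcgold, S0=100.0)
        b1000 = np.abs(sparcgold.bvals - 1000) < 1
        np.testing.assert_allclose(sig[b1000] / 100.0, np.exp(-1.0), rtol=1e-12)

    def test_b0_returns_s0(self, sparcgold):
        sig = sd.tensor_signal(np.diag([1.7e-3, 3e-4, 3e-4]), sparcgold, S0=42.0)
        assert np.all(sig[sparcgold.b0_mask] == 42.0)

    def test_non_pd_tensor_rejected(self, sparcgold):
        D = np.diag([1e-3, 1e-3, 0.0])
        with pytest.raises(ValueError, match="positive-definite"):
            sd.tensor_signal(D, sparcgold)

    def test_perpendicular_signal_larger_than_parallel(self):
        D = sd.fiber_tensor()  # principal axis along x
        scheme = AcquisitionScheme(
            [1000.0, 1000.0], [[1, 0, 0], [0, 0, 1]], 0.062, 0.062
        )
        sig = sd.tensor_signal(D, scheme)
        assert sig[1] > sig[0]  # perpendicular attenuates less


class TestBuildPhantom:
    def test_two_fiber_signal_is_exact_mixture(self, small_scheme):
        layout = np.array([[[2]]])
        stack, truth = sd.build_phantom(layout, small_scheme)
        comps = truth.tensors[(0, 0, 0)]
        expected = 0.5 * (
            sd.tensor_signal(comps[0], small_scheme)
            + sd.tensor_signal(comps[1], small_scheme)
        )
        np.testing.assert_allclose(truth.clean_signal[0, 0, 0], expected, rtol=1e-12)

    def test_crossing_angle_between_principal_axes(self, small_scheme):
        _, truth = sd.build_phantom(np.array([[[2]]]), small_scheme, crossing_angle=45.0)
        e1 = np.linalg.eigh(truth.tensors[(0, 0, 0)][0])[1][:, -1]
        e2 = np.linalg.eigh(truth.tensors[(0, 0, 0)][1])[1][:, -1]
        angle = np.degrees(np.arccos(np.abs(e1 @ e2)))
        assert angle == pytest.approx(45.0, abs=1e-8)

    def test_zero_crossing_angle_degenerates_to_single_fiber(self, small_scheme):
        _, t2 = sd.build_phantom(np.array([[[2]]]), small_scheme, crossing_angle=0.0)
        _, t1 = sd.build_phantom(np.array([[[1]]]), small_scheme)
        np.testing.assert_allclose(
            t2.clean_signal[0, 0, 0], t1.clean_signal[0, 0, 0], rtol=1e-12
        )

    def test_mixture_bounded_by_components(self, small_scheme):
        _, truth = sd.build_phantom(np.array([[[2]]]), small_scheme)
        comps = truth.tensors[(0, 0, 0)]
        s1 = sd.tensor_signal(comps[0], small_scheme)
        s2 = sd.tensor_signal(comps[1], small_scheme)
        mix = truth.clean_signal[0, 0, 0]
        assert np.all(mix >= np.minimum(s1, s2) - 1e-12)
        assert np.all(mix <= np.maximum(s1, s2) + 1e-12)

    def test_b0_equals_s0_exactly(self, small_scheme):
        layout = sd.default_layout((3, 3, 1))
        _, truth = sd.build_phantom(layout, small_scheme, S0=100.0)
        b0_vals = truth.clean_signal[..., small_scheme.b0_mask]
        np.testing.assert_array_equal(b0_vals, 100.0)

    def test_unknown_fiber_count_rejected(self, small_scheme):
        with pytest.raises(ValueError, match="unknown fiber count"):
            sd.build_phantom(np.array([[[3]]]), small_scheme)

    def test_seeded_determinism(self, small_scheme):
        layout = sd.default_layout((3, 3, 1))
        s1, _ = sd.build_phantom(layout, small_scheme, snr=10.0, seed=5)
        s2, _ = sd.build_phantom(layout, small_scheme, snr=10.0, seed=5)
        np.testing.assert_array_equal(s1.data, s2.data)


class TestAddNoise:
    def test_infinite_snr_returns_signal(self):
        sig = np.linspace(0, 100, 50)
        out = sd.add_noise(sig, np.inf, seed=0)
        np.testing.assert_array_equal(out, sig)

    def test_gaussian_sigma_matches_snr(self):
        sig = np.full(100_000, 50.0)
        out = sd.add_noise(sig, 10.0, model="gaussian", S0_reference=100.0, seed=3)
        assert np.std(out - sig) == pytest.approx(10.0, rel=0.01)

    def test_rician_floor_is_rayleigh_mean(self):
        sig = np.zeros(100_000)
        out = sd.add_noise(sig, 10.0, model="rician", S0_reference=100.0, seed=4)
        assert np.mean(out) == pytest.approx(10.0 * np.sqrt(np.pi / 2), rel=0.02)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            sd.add_noise(np.ones(3), 0.0)
        with pytest.raises(ValueError):
            sd.add_noise(np.ones(3), -5.0)

    def test_snr_recovery_on_phantom(self, small_scheme):
        layout = sd.default_layout((4, 4, 1))
        stack, truth = sd.build_phantom(layout, small_scheme, snr=10.0, seed=9)
        est = sd.estimate_snr(stack, small_scheme, truth.clean_signal)
        assert est == pytest.approx(10.0, rel=0.15)


class TestPresets:
    @pytest.mark.parametrize(
        "name,total,dwi,n_shells",
        [
            ("sparc20", 61, 60, 3),
            ("sparc30", 91, 90, 3),
            ("sparc60", 181, 180, 3),
            ("sparcgold", 406, 405, 5),
            ("hcp_mgh", 552, 512, 4),
        ],
    )
    def test_measurement_counts(self, name, total, dwi, n_shells):
        scheme = sd.preset_scheme(name, seed=1)
        assert len(scheme) == total
        assert scheme.n_dwi == dwi
        assert len(scheme.shells()) == n_shells

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            sd.preset_scheme("nope")


class TestSubsample:
    def test_keeps_b0_and_fraction_per_shell(self, sparcgold):
        sub, idx = sd.subsample_scheme(sparcgold, 0.5, seed=1)
        assert np.sum(sub.bvals == 0) == np.sum(sparcgold.bvals == 0)
        for b, n in sub.shells():
            assert n == round(0.5 * 81)

    def test_full_fraction_is_identity(self, sparc30):
        sub, idx = sd.subsample_scheme(sparc30, 1.0, seed=1)
        assert len(sub) == len(sparc30)
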