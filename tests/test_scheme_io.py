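"""Scheme and volume I/O: gradient tables, q-vectors, NIfTI round trips."""

import numpy as np
import pytest

import nibabel as nib

from mapboot import (
    AcquisitionScheme,
    VolumeStack,
    q_from_scheme,
    read_scheme,
    read_volumes,
    write_metric_map,
    write_scheme,
)
from mapboot.scheme_io import q_vectors, write_volume_stack
from mapboot import synthetic_data as sd


class TestReadScheme:
    def test_sparcgold_preset_has_406_measurements(self, sparcgold, tmp_path):
        write_scheme(sparcgold, tmp_path / "g.bval", tmp_path / "g.bvec")
        back = read_scheme(tmp_path / "g.bval", tmp_path / "g.bvec", 0.062, 0.062)
        assert len(back) == 406
        assert back.n_dwi == 405

    def test_round_trip_identity(self, sparc30, tmp_path):
        write_scheme(sparc30, tmp_path / "s.bval", tmp_path / "s.bvec")
        back = read_scheme(tmp_path / "s.bval", tmp_path / "s.bvec", 0.062, 0.062)
        np.testing.assert_allclose(back.bvals, sparc30.bvals, atol=1e-6)
        np.testing.assert_allclose(back.bvecs, sparc30.bvecs, atol=1e-8)
        assert back.t_d == pytest.approx(sparc30.t_d)

    def test_transposed_bvec_autodetected(self, tmp_path):
        bvals = np.array([0.0, 1000.0, 1000.0, 2000.0])
        vecs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        np.savetxt(tmp_path / "b.bval", bvals[None])
        np.savetxt(tmp_path / "t.bvec", vecs)  # T x 3 layout
        scheme = read_scheme(tmp_path / "b.bval", tmp_path / "t.bvec", 0.06, 0.06)
        np.testing.assert_allclose(scheme.bvecs, vecs)

    def test_all_zero_bvals_is_legal(self, tmp_path):
        np.savetxt(tmp_path / "z.bval", np.zeros((1, 5)))
        np.savetxt(tmp_path / "z.bvec", np.zeros((3, 5)))
        scheme = read_scheme(tmp_path / "z.bval", tmp_path / "z.bvec", 0.06, 0.06)
        assert scheme.n_dwi == 0

    def test_count_mismatch_raises(self, tmp_path):
        np.savetxt(tmp_path / "m.bval", np.zeros((1, 4)))
        np.savetxt(tmp_path / "m.bvec", np.zeros((3, 5)))
        with pytest.raises(ValueError, match="b-values"):
            read_scheme(tmp_path / "m.bval", tmp_path / "m.bvec", 0.06, 0.06)

    def test_non_numeric_token_raises(self, tmp_path):
        (tmp_path / "bad.bval").write_text("0 foo 1000\n")
        np.savetxt(tmp_path / "bad.bvec", np.zeros((3, 3)))
        with pytest.raises(ValueError, match="non-numeric"):
            read_scheme(tmp_path / "bad.bval", tmp_path / "bad.bvec", 0.06, 0.06)

    def test_non_unit_bvec_renormalized(self):
        scheme = AcquisitionScheme(
            [0.0, 1000.0], [[0, 0, 0], [0.5, 0, 0]], 0.062, 0.062
        )
        np.testing.assert_allclose(np.linalg.norm(scheme.bvecs[1]), 1.0)

    def test_default_t_d_is_stejskal_tanner(self):
        scheme = AcquisitionScheme([0.0], [[0, 0, 0]], 0.02, 0.05)
        assert scheme.t_d == pytest.approx(0.05 - 0.02 / 3)


class TestQFromScheme:
    def test_b_zero_gives_q_zero(self, sparcgold):
        qmag, _ = q_from_scheme(sparcgold)
        assert np.all(qmag[sparcgold.b0_mask] == 0)

    def test_worked_example_b1000(self):
        scheme = AcquisitionScheme(
            [1000.0], [[1, 0, 0]], 0.0075, 0.02, t_d=0.0175
        )
        qmag, _ = q_from_scheme(scheme)
        expected = np.sqrt(1000.0 / (4 * np.pi**2 * 0.0175))
        assert qmag[0] == pytest.approx(expected)
        assert qmag[0] == pytest.approx(38.05, abs=0.01)

    def test_b_q_consistency(self, sparcgold):
        qmag, _ = q_from_scheme(sparcgold)
        recon = 4 * np.pi**2 * qmag**2 * sparcgold.t_d
        np.testing.assert_allclose(recon, sparcgold.bvals, rtol=1e-8, atol=1e-8)

    def test_doubling_b_scales_q_by_sqrt2(self):
        s1 = AcquisitionScheme([1000.0], [[1, 0, 0]], 0.062, 0.062)
        s2 = AcquisitionScheme([2000.0], [[1, 0, 0]], 0.062, 0.062)
        q1, _ = q_from_scheme(s1)
        q2, _ = q_from_scheme(s2)
        assert q2[0] / q1[0] == pytest.approx(np.sqrt(2))

    def test_q_vectors_along_bvecs(self, sparc30):
        q = q_vectors(sparc30)
        dwi = sparc30.bvals > 0
        norms = np.linalg.norm(q[dwi], axis=1)
        np.testing.assert_allclose(q[dwi] / norms[:, None], sparc30.bvecs[dwi], atol=1e-12)


class TestShellGrouping:
    def test_jittered_bvals_group_into_one_shell(self):
        scheme = AcquisitionScheme(
            [0, 990, 1000, 1010, 2000],
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]],
            0.062,
            0.062,
        )
        shells = scheme.shells()
        assert len(shells) == 2
        assert shells[0][1] == 3


class TestVolumes:
    def _write_vol(self, tmp_path, data, name="dwi.nii.gz"):
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4))
        path = tmp_path / name
        nib.save(img, str(path))
        return path

    def test_read_without_mask_gives_all_true(self, tmp_path, rng):
        path = self._write_vol(tmp_path, rng.random((4, 4, 1, 10)))
        stack = read_volumes(path)
        assert stack.n_voxels == 16

    def test_3d_input_rejected(self, tmp_path, rng):
        path = self._write_vol(tmp_path, rng.random((4, 4, 2)))
        with pytest.raises(ValueError, match="4-D"):
            read_volumes(path)

    def test_mask_shape_mismatch_rejected(self, tmp_path, rng):
        vol = self._write_vol(tmp_path, rng.random((4, 4, 1, 3)))
        bad_mask = self._write_vol(tmp_path, np.ones((3, 3, 1)), "mask.nii.gz")
        with pytest.raises(ValueError, match="mask shape"):
            read_volumes(vol, bad_mask)

    def test_negative_intensities_rejected(self, tmp_path):
        data = -np.ones((2, 2, 1, 3))
        path = self._write_vol(tmp_path, data)
        with pytest.raises(ValueError, match="negative"):
            read_volumes(path)

    def test_metric_map_round_trip(self, tmp_path, rng):
        mask = np.ones((4, 4, 1), bool)
        values = rng.random(16).astype(np.float32) * 1e4
        out = tmp_path / "rtop.nii.gz"
        write_metric_map(values, mask, np.eye(4), out)
        back = np.asarray(nib.load(str(out)).dataobj)
        np.testing.assert_allclose(back[mask], values, rtol=1e-5)

    def test_out_of_mask_fill_and_nan_passthrough(self, tmp_path):
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 0, 0] = True
        out = tmp_path / "m.nii.gz"
        write_metric_map(np.array([np.nan]), mask, np.eye(4), out, fill=-1.0)
        back = np.asarray(nib.load(str(out)).dataobj)
        assert np.isnan(back[0, 0, 0])
        assert back[1, 1, 0] == -1.0

    def test_empty_mask_writes_all_fill(self, tmp_path):
        mask = np.zeros((2, 2, 1), bool)
        out = tmp_path / "e.nii.gz"
        write_metric_map(np.array([]), mask, np.eye(4), out, fill=0.0)
        assert np.all(np.asarray(nib.load(str(out)).dataobj) == 0)

    def test_volume_stack_round_trip(self, tmp_path, rng):
        stack = VolumeStack(rng.random((3, 3, 2, 5)))
        out = tmp_path / "v.nii.gz"
        write_volume_stack(stack, out)
        back = read_volumes(out)
        np.testing.assert_allclose(back.data, stack.data, rtol=1e-6)
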