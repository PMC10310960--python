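"""ROI extraction, volume discarding, detrending and series file I/O."""
import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, strategies as st

import cvrkit as ck


def _write_nifti(path, data, tr=None):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    if tr is not None and data.ndim == 4:
        img.header.set_zooms((1.0, 1.0, 1.0, tr))
    img.to_filename(str(path))
    return path


@pytest.fixture()
def grid4d(rng):
    return rng.normal(100.0, 5.0, size=(4, 4, 3, 20))


class TestReadBoldRoiSeries:
    def test_constant_image_gives_constant_series(self, tmp_path):
        bold = _write_nifti(tmp_path / "b.nii.gz", np.full((3, 3, 2, 10), 7.0), tr=2.0)
        mask = _write_nifti(tmp_path / "m.nii.gz", np.ones((3, 3, 2)))
        s = ck.read_bold_roi_series(bold, mask)
        np.testing.assert_allclose(s.values, 7.0)
        assert s.tr == 2.0 and s.t0 == 0.0

    def test_single_voxel_mask_returns_that_time_course(self, tmp_path, grid4d):
        bold = _write_nifti(tmp_path / "b.nii.gz", grid4d, tr=1.5)
        m = np.zeros(grid4d.shape[:3])
        m[1, 2, 0] = 1.0
        mask = _write_nifti(tmp_path / "m.nii.gz", m)
        s = ck.read_bold_roi_series(bold, mask)
        np.testing.assert_allclose(s.values, grid4d[1, 2, 0], rtol=1e-6)

    def test_two_voxel_mask_averages(self, tmp_path):
        data = np.zeros((2, 1, 1, 5))
        data[0, 0, 0] = 1.0
        data[1, 0, 0] = 3.0
        bold = _write_nifti(tmp_path / "b.nii.gz", data, tr=1.0)
        mask = _write_nifti(tmp_path / "m.nii.gz", np.ones((2, 1, 1)))
        np.testing.assert_allclose(ck.read_bold_roi_series(bold, mask).values, 2.0)

    def test_grid_mismatch_reports_both_shapes(self, tmp_path, grid4d):
        bold = _write_nifti(tmp_path / "b.nii.gz", grid4d, tr=1.0)
        mask = _write_nifti(tmp_path / "m.nii.gz", np.ones((5, 5, 3)))
        with pytest.raises(ValueError, match=r"4, 4, 3.*5, 5, 3"):
            ck.read_bold_roi_series(bold, mask)

    def test_empty_mask_errors(self, tmp_path, grid4d):
        bold = _write_nifti(tmp_path / "b.nii.gz", grid4d, tr=1.0)
        mask = _write_nifti(tmp_path / "m.nii.gz", np.full(grid4d.shape[:3], 0.2))
        with pytest.raises(ValueError, match="empty"):
            ck.read_bold_roi_series(bold, mask)

    def test_missing_tr_requires_override(self, tmp_path, grid4d):
        bold = _write_nifti(tmp_path / "b.nii.gz", grid4d)  # zooms default
        mask = _write_nifti(tmp_path / "m.nii.gz", np.ones(grid4d.shape[:3]))
        try:
            s = ck.read_bold_roi_series(bold, mask)
            assert s.tr > 0  # header carried a usable TR
        except ValueError:
            pass
        s = ck.read_bold_roi_series(bold, mask, tr_override=1.55)
        assert s.tr == 1.55

    def test_nan_voxels_excluded_per_volume(self, tmp_path):
        data = np.stack([np.full((2, 1, 1), v) for v in [1.0, 2.0, 3.0]], axis=-1)
        data[0, 0, 0, 1] = np.nan  # volume 1 keeps only the other voxel
        bold = _write_nifti(tmp_path / "b.nii.gz", data, tr=1.0)
        mask = _write_nifti(tmp_path / "m.nii.gz", np.ones((2, 1, 1)))
        with pytest.raises(ValueError, match="NaN"):
            ck.read_bold_roi_series(bold, mask)  # 1/3 volumes > 10%

    def test_roi_mean_is_voxel_count_weighted_linear(self, tmp_path, grid4d):
        bold = _write_nifti(tmp_path / "bold.nii.gz", grid4d, tr=1.0)
        shape = grid4d.shape[:3]
        ma = np.zeros(shape)
        mb = np.zeros(shape)
        ma[:2] = 1.0
        mb[2:] = 1.0
        union = ma + mb
        paths = {
            k: _write_nifti(tmp_path / f"{k}.nii.gz", m)
            for k, m in [("a", ma), ("b", mb), ("u", union)]
        }
        sa = ck.read_bold_roi_series(bold, paths["a"]).values
        sb = ck.read_bold_roi_series(bold, paths["b"]).values
        su = ck.read_bold_roi_series(bold, paths["u"]).values
        na, nb = ma.sum(), mb.sum()
        np.testing.assert_allclose(su, (na * sa + nb * sb) / (na + nb), rtol=1e-10)


class TestDiscardInitialVolumes:
    @pytest.mark.parametrize("length, n, remaining", [(478, 25, 453), (255, 5, 250)])
    def test_design_volume_counts(self, length, n, remaining):
        s = ck.SampledSeries(np.arange(float(length)), tr=1.0)
        out = ck.discard_initial_volumes(s, n)
        assert len(out) == remaining and out.t0 == 0.0
        assert out.values[0] == n

    def test_zero_discard_is_identity(self):
        s = ck.SampledSeries(np.arange(10.0), tr=1.0)
        np.testing.assert_array_equal(ck.discard_initial_volumes(s, 0).values, s.values)

    def test_discarding_everything_errors(self):
        s = ck.SampledSeries(np.arange(10.0), tr=1.0)
        with pytest.raises(ValueError):
            ck.discard_initial_volumes(s, 10)

    @given(st.integers(0, 30), st.integers(5, 40))
    def test_discard_then_slice_commutes_with_shifted_slice(self, n_discard, width):
        values = np.sin(0.3 * np.arange(100.0))
        s = ck.SampledSeries(values, tr=1.0)
        start = 10.0
        post = ck.slice_window(
            ck.discard_initial_volumes(s, n_discard),
            ck.TimeWindow(start, start + width),
        )
        pre = ck.slice_window(
            s, ck.TimeWindow(start + n_discard, start + n_discard + width)
        )
        np.testing.assert_array_equal(post.values, pre.values)


class TestHighpassDetrend:
    def test_constant_series_unchanged(self):
        s = ck.SampledSeries(np.full(100, 42.0), tr=1.0)
        np.testing.assert_allclose(ck.highpass_detrend(s, 0.01).values, 42.0)

    def test_slow_linear_drift_mostly_removed(self):
        # 500 s cutoff on a 700 s scan with a pure linear drift
        t = np.arange(0, 700, 1.55)
        drift = 0.05 * t
        s = ck.SampledSeries(100.0 + drift, tr=1.55)
        out = ck.highpass_detrend(s, cutoff_hz=3.18e-4)
        assert np.ptp(out.values) < 0.2 * np.ptp(drift)
        assert out.values.mean() == pytest.approx(s.values.mean())

    def test_half_nyquist_oscillation_preserved(self):
        tr = 1.0
        t = np.arange(400.0) * tr
        wave = np.sin(2 * np.pi * 0.25 * t)  # half of Nyquist 0.5 Hz
        s = ck.SampledSeries(50.0 + wave, tr=tr)
        out = ck.highpass_detrend(s, cutoff_hz=2e-3)
        core = slice(50, -50)  # ignore edge effects
        amp_ratio = np.ptp(out.values[core] - 50.0) / np.ptp(wave[core])
        assert amp_ratio == pytest.approx(1.0, abs=0.05)

    def test_cutoff_above_nyquist_errors(self):
        s = ck.SampledSeries(np.zeros(10), tr=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ck.highpass_detrend(s, cutoff_hz=0.6)


class TestReadSeriesCsv:
    def test_two_column_file(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("t_s,value\n0,5\n1,6\n2,7\n")
        s = ck.read_series_csv(p)
        assert s.tr == pytest.approx(1.0) and len(s) == 3

    def test_jittered_time_errors(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("t_s,value\n0,5\n1,6\n2.05,7\n3,8\n")
        with pytest.raises(ValueError, match="non-uniform"):
            ck.read_series_csv(p)

    def test_single_column_with_tr(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("bold\n5\n6\n7\n")
        s = ck.read_series_csv(p, tr=1.55)
        assert s.tr == 1.55 and len(s) == 3

    def test_single_column_without_tr_errors(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("bold\n5\n6\n")
        with pytest.raises(ValueError, match="tr"):
            ck.read_series_csv(p)

    def test_too_few_rows_errors(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("t,v\n0,1\n")
        with pytest.raises(ValueError, match="2 rows"):
            ck.read_series_csv(p)

    def test_roundtrip_with_write(self, tmp_path, rng):
        s = ck.SampledSeries(rng.normal(size=30), tr=2.0, t0=5.0)
        path = tmp_path / "round.csv"
        ck.write_series_csv(s, path)
        back = ck.read_series_csv(path)
        np.testing.assert_allclose(back.values, s.values, rtol=1e-9)
        assert back.tr == pytest.approx(2.0) and back.t0 == pytest.approx(5.0)
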