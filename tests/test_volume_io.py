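"""Volume/mask I/O, resampling and ROI-union tests."""

import numpy as np
import pytest

from pancrad.errors import CoRegistrationError, InputFormatError, MetadataError
from pancrad.volume import (CTVolume, LabelMask, ResampleSpec, read_mask,
                            read_volume, resample_pair, roi_union, write_mask,
                            write_volume)


class TestReadWrite:
    def test_nifti_roundtrip_is_bit_exact(self, tmp_path, rng):
        vox = rng.normal(0, 100, size=(4, 8, 8)).astype(np.float32)
        vol = CTVolume(voxels=vox, spacing=(0.7, 0.7, 2.5))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.array_equal(back.voxels, vox)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_mask_roundtrip_preserves_labels(self, tmp_path, rng):
        labels = rng.integers(0, 3, size=(3, 6, 6)).astype(np.uint8)
        mask = LabelMask(labels=labels, spacing=(1.0, 1.0, 5.0))
        path = tmp_path / "mask.nii.gz"
        write_mask(mask, path)
        back = read_mask(path)
        assert np.array_equal(back.labels, labels)

    def test_zero_byte_file_is_input_format_error(self, tmp_path):
        path = tmp_path / "empty.nii"
        path.touch()
        with pytest.raises(InputFormatError):
            read_volume(path)

    def test_missing_file_is_input_format_error(self, tmp_path):
        with pytest.raises(InputFormatError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_dicom_series_applies_rescale_slope_intercept(self, tmp_path, rng):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        stored = rng.integers(0, 2000, size=(2, 16, 16)).astype(np.uint16)
        slope, intercept = 1.0, -1024.0
        series_uid = generate_uid()
        study_uid = generate_uid()
        for i in range(2):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(str(tmp_path / f"s{i}.dcm"), {}, file_meta=meta,
                             preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.StudyInstanceUID = study_uid
            ds.Modality = "CT"
            ds.Rows, ds.Columns = 16, 16
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.RescaleSlope = slope
            ds.RescaleIntercept = intercept
            ds.PixelSpacing = [0.8, 0.8]
            ds.SliceThickness = 5.0
            ds.ImagePositionPatient = [0.0, 0.0, 5.0 * i]
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            ds.InstanceNumber = i + 1
            ds.PixelData = stored[i].tobytes()
            ds.save_as(tmp_path / f"s{i}.dcm", enforce_file_format=True)

        vol = read_volume(tmp_path)
        expected = slope * stored.astype(np.float64) + intercept
        assert vol.voxels.shape == (2, 16, 16)
        assert np.allclose(np.sort(vol.voxels.ravel()),
                           np.sort(expected.ravel()))

    def test_invalid_spacing_rejected(self):
        with pytest.raises(MetadataError):
            CTVolume(voxels=np.zeros((2, 2, 2)), spacing=(1.0, 0.0, 5.0))

    def test_nonfinite_voxels_rejected(self):
        vox = np.zeros((2, 2, 2))
        vox[0, 0, 0] = np.nan
        with pytest.raises(MetadataError):
            CTVolume(voxels=vox, spacing=(1, 1, 1))


class TestResample:
    def test_identity_resample_preserves_voxels(self, rng):
        vox = rng.normal(50, 20, size=(4, 10, 10))
        vol = CTVolume(voxels=vox, spacing=(1.0, 1.0, 5.0))
        mask = LabelMask(labels=np.zeros((4, 10, 10), dtype=np.uint8),
                         spacing=(1.0, 1.0, 5.0))
        out_vol, _ = resample_pair(vol, mask, ResampleSpec((1.0, 1.0, 5.0)))
        assert out_vol.voxels.shape == vox.shape
        assert np.allclose(out_vol.voxels, vox, atol=1e-6)

    def test_constant_volume_halves_inplane_shape(self):
        vox = np.full((4, 20, 20), 42.0)
        vol = CTVolume(voxels=vox, spacing=(0.5, 0.5, 5.0))
        mask = LabelMask(labels=np.ones((4, 20, 20), dtype=np.uint8),
                         spacing=(0.5, 0.5, 5.0))
        out_vol, out_mask = resample_pair(vol, mask)
        assert out_vol.voxels.shape == (4, 10, 10)
        assert np.allclose(out_vol.voxels, 42.0, atol=1e-6)
        assert out_mask.labels.shape == (4, 10, 10)

    def test_mask_label_set_preserved_by_nearest_neighbor(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 3, size=(3, 12, 12)).astype(np.uint8)
            vol = CTVolume(voxels=r.normal(size=(3, 12, 12)),
                           spacing=(0.6, 0.6, 3.0))
            mask = LabelMask(labels=labels, spacing=(0.6, 0.6, 3.0))
            _, up = resample_pair(vol, mask, ResampleSpec((0.3, 0.3, 1.5)))
            _, down = resample_pair(vol, mask, ResampleSpec((1.2, 1.2, 6.0)))
            assert set(np.unique(up.labels)) <= set(np.unique(labels))
            assert set(np.unique(down.labels)) <= set(np.unique(labels))

    def test_physical_extent_preserved_within_one_voxel(self, rng):
        vol = CTVolume(voxels=rng.normal(size=(6, 30, 30)),
                       spacing=(0.73, 0.73, 1.4))
        mask = LabelMask(labels=np.zeros((6, 30, 30), np.uint8),
                         spacing=(0.73, 0.73, 1.4))
        out, _ = resample_pair(vol, mask)
        for before, after, target in zip(vol.physical_extent(),
                                         out.physical_extent(), (1.0, 1.0, 5.0)):
            assert abs(before - after) <= target

    def test_disjoint_frames_raise_coregistration_error(self, rng):
        vol = CTVolume(voxels=rng.normal(size=(3, 8, 8)), spacing=(1, 1, 5))
        mask = LabelMask(labels=np.zeros((3, 8, 8), np.uint8),
                         spacing=(1, 1, 5), origin=(500.0, 500.0, 500.0))
        with pytest.raises(CoRegistrationError):
            resample_pair(vol, mask)


class TestRoiUnion:
    def test_pancreas_only_union_equals_pancreas(self):
        labels = np.zeros((2, 5, 5), np.uint8)
        labels[0, 1:4, 1:4] = 1
        mask = LabelMask(labels=labels, spacing=(1, 1, 5))
        union = roi_union(mask)
        assert np.array_equal(union.labels > 0, labels == 1)

    def test_disjoint_pancreas_tumor_counts_add(self, rng):
        labels = np.zeros((4, 10, 10), np.uint8)
        flat = rng.choice(400, size=130, replace=False)
        labels.ravel()[flat[:100]] = 1
        labels.ravel()[flat[100:]] = 2
        mask = LabelMask(labels=labels, spacing=(1, 1, 5))
        assert int(roi_union(mask).labels.sum()) == 130

    def test_all_background_is_flagged_empty(self):
        mask = LabelMask(labels=np.zeros((2, 4, 4), np.uint8), spacing=(1, 1, 5))
        union = roi_union(mask)
        assert union.is_empty
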