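"""I/O round trips, orientation canonicalization and scheme validation."""
import numpy as np
import nibabel as nib
import pytest

from renovol.errors import FormatError, MetadataError, SchemeViolationError
from renovol.imaging import (
    ClassScheme,
    CTVolume,
    LabelMap,
    load_labelmap,
    load_volume,
    save_labelmap,
    save_volume,
)


def test_nifti_round_trip_preserves_metadata_and_integer_voxels(tmp_path, rng):
    vox = rng.integers(-1000, 2000, size=(12, 10, 8)).astype(np.int16)
    vol = CTVolume(vox, spacing=(0.625, 0.625, 1.0), origin=(3.0, -2.0, 10.0))
    path = tmp_path / "vol.nii.gz"
    save_volume(vol, path)
    back = load_volume(path)
    assert back.spacing == pytest.approx((0.625, 0.625, 1.0))
    assert back.origin == pytest.approx((3.0, -2.0, 10.0))
    np.testing.assert_array_equal(back.voxels, vox)


def test_round_trip_of_random_integer_hu_grid_is_lossless(tmp_path, rng):
    vox = rng.integers(-1024, 3026, size=(16, 16, 16))
    vol = CTVolume(vox, spacing=(1.5, 1.5, 2.0))
    save_volume(vol, tmp_path / "v.nii")
    back = load_volume(tmp_path / "v.nii")
    assert np.abs(back.voxels - vox).max() == 0


def test_spacing_example_from_synthetic_three_slice_file(tmp_path):
    vol = CTVolume(np.zeros((3, 4, 4), dtype=np.int16) + 10, spacing=(1.5, 1.5, 2.0))
    save_volume(vol, tmp_path / "s.nii")
    assert load_volume(tmp_path / "s.nii").spacing == (1.5, 1.5, 2.0)


def test_slice_reversed_file_is_reordered_cranial_to_caudal(tmp_path, noiseless_phantom):
    """A file stored tail-first must load with lung slices before kidney slices."""
    vol, gt = noiseless_phantom
    # write with a +z (caudal-first) affine and the data z-reversed: the same
    # physical object, stored in the opposite slice order
    flipped = vol.voxels[::-1].copy()
    sx, sy, sz = vol.spacing
    nz = vol.shape[0]
    aff = np.array([[sx, 0, 0, 0], [0, sy, 0, 0], [0, 0, sz, -(nz - 1) * sz], [0, 0, 0, 1.0]])
    nib.save(nib.Nifti1Image(flipped.transpose(2, 1, 0).astype(np.int16), aff), tmp_path / "rev.nii")
    back = load_volume(tmp_path / "rev.nii")
    np.testing.assert_array_equal(back.voxels, vol.voxels)
    lung_slices = np.flatnonzero((back.voxels < -600).any(axis=(1, 2)))
    kidney_slices = np.flatnonzero(
        np.isin(gt.labels.labels, list(gt.labels.scheme.parenchyma_classes)).any(axis=(1, 2))
    )
    assert lung_slices.min() < kidney_slices.min()


def test_labelmap_scheme_validation(tmp_path, pre_scheme, post_scheme):
    lab = np.zeros((4, 4, 4), dtype=np.uint8)
    lab[1, 1, 1] = 1
    lab[2, 2, 2] = 2
    lm = LabelMap(lab, (1.0, 1.0, 1.0), pre_scheme)
    save_labelmap(lm, tmp_path / "lab.nii")
    assert set(np.unique(load_labelmap(tmp_path / "lab.nii", pre_scheme).labels)) == {0, 1, 2}

    lab[3, 3, 3] = 3  # undeclared under the pre-contrast scheme
    save_labelmap(LabelMap(lab, (1.0, 1.0, 1.0), post_scheme), tmp_path / "bad.nii")
    with pytest.raises(SchemeViolationError) as err:
        load_labelmap(tmp_path / "bad.nii", pre_scheme)
    assert 3 in err.value.offending


def test_phantom_post_contrast_labels_contain_all_four_classes(tmp_path, post_phantom, post_scheme):
    _, gt = post_phantom
    save_labelmap(gt.labels, tmp_path / "gt.nii.gz")
    back = load_labelmap(tmp_path / "gt.nii.gz", post_scheme)
    assert set(np.unique(back.labels)) == {0, 1, 2, 3}


def test_invalid_metadata_rejected():
    with pytest.raises(MetadataError):
        CTVolume(np.zeros((2, 2, 2)), spacing=(0.0, 1.0, 1.0))
    with pytest.raises(MetadataError):
        CTVolume(np.zeros((0, 2, 2)), spacing=(1.0, 1.0, 1.0))


def _make_dicom_slice(path, z, data, iop=(1, 0, 0, 0, 1, 0)):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = data.shape
    ds.PixelSpacing = [0.7, 0.5]  # (row=y, col=x)
    ds.ImageOrientationPatient = list(iop)
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = data.astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def test_dicom_series_sorted_by_position_not_filename(tmp_path):
    # slice at patient z=10 is more cranial (DICOM +z is toward the head);
    # name files so lexicographic order disagrees with spatial order
    a = np.full((4, 4), 1024 + 100, dtype=np.uint16)  # HU 100 after rescale
    b = np.full((4, 4), 1024 - 500, dtype=np.uint16)  # HU -500
    _make_dicom_slice(tmp_path / "s1.dcm", z=0.0, data=a)
    _make_dicom_slice(tmp_path / "s2.dcm", z=10.0, data=b)
    _make_dicom_slice(tmp_path / "s3.dcm", z=5.0, data=a)
    vol = load_volume(tmp_path, format="dicom_series")
    assert vol.shape == (3, 4, 4)
    assert vol.spacing == pytest.approx((0.5, 0.7, 5.0))
    # most cranial (z=10) first
    assert vol.voxels[0, 0, 0] == pytest.approx(-500.0)
    assert vol.voxels[1, 0, 0] == pytest.approx(100.0)


def test_mixed_orientation_dicom_series_rejected(tmp_path):
    a = np.zeros((4, 4), dtype=np.uint16)
    _make_dicom_slice(tmp_path / "a.dcm", z=0.0, data=a)
    _make_dicom_slice(tmp_path / "b.dcm", z=5.0, data=a, iop=(0, 1, 0, 1, 0, 0))
    with pytest.raises(FormatError):
        load_volume(tmp_path, format="dicom_series")


def test_class_scheme_invariants(pre_scheme, post_scheme):
    assert pre_scheme.parenchyma_classes == {1}
    assert post_scheme.parenchyma_classes == {1, 2}
    with pytest.raises(ValueError):
        ClassScheme("pre_contrast", {"a": 0, "b": 0}, frozenset({0}))
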