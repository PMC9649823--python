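"""Volumetric CT image and label-map I/O.

Conventions used throughout the package
---------------------------------------
* Voxel grids are stored as ``(z, y, x)`` arrays where ``z`` is the axial
  slice index increasing cranial (head) to caudal (tail), ``y`` is
  dorsoventral and ``x`` is left-right.
* ``spacing`` is the voxel edge length in mm, ordered ``(x, y, z)`` to match
  how CT spacing is usually reported; ``origin`` is the physical position of
  voxel ``(0, 0, 0)`` in mm, also ``(x, y, z)``.
* Physical position of voxel index ``(k, j, i)`` is
  ``origin + (i*sx, j*sy, k*sz)``.
* On load, axial slices are re-sorted so that index 0 is the most cranial
  slice, whatever the on-disk order; NIfTI orientation is resolved through
  the affine, DICOM through ``ImagePositionPatient`` projected on the slice
  normal (never ``InstanceNumber``).

Volumes are stored as NIfTI (``.nii``/``.nii.gz``); label maps as unsigned
8-bit NIfTI (at most four classes are ever used). DICOM series directories
are read-only inputs.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import FormatError, MetadataError, SchemeViolationError

__all__ = [
    "CTVolume",
    "LabelMap",
    "ClassScheme",
    "load_volume",
    "save_volume",
    "load_labelmap",
    "save_labelmap",
]

# Target orientation for loaded NIfTI data, in RAS axis codes: x toward the
# animal's right, y anterior, z *inferior* — so that increasing z runs
# cranial -> caudal, matching the axial-index convention above.
_TARGET_AXCODES = ("R", "A", "I")


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with anisotropic spacing.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensities in HU, axial axis first (cranial -> caudal).
    spacing : tuple of float
        Voxel edge lengths ``(x, y, z)`` in mm; all components > 0.
    origin : tuple of float
        Physical position (mm) of voxel ``(0, 0, 0)``, ordered ``(x, y, z)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.size == 0:
            raise MetadataError("voxel grid must be a non-empty 3D array")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or not all(np.isfinite(s) and s > 0 for s in sp):
            raise MetadataError(f"spacing must be three positive floats, got {self.spacing!r}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape ``(nz, ny, nx)``."""
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3 (x*y*z spacing)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_voxels(self, voxels, spacing=None, origin=None) -> "CTVolume":
        return CTVolume(voxels, spacing or self.spacing, origin or self.origin)


@dataclass(frozen=True)
class ClassScheme:
    """The label-value vocabulary of a contrast phase.

    Pre-contrast kidneys are labelled parenchyma vs. pelvis-and-fat; in
    post-contrast scans cortex and medulla can be distinguished, and renal
    parenchyma is the union of the two.
    """

    phase: str  # "pre_contrast" | "post_contrast"
    class_ids: Mapping[str, int]
    parenchyma_classes: frozenset[int]

    def __post_init__(self):
        ids = list(self.class_ids.values())
        if len(ids) != len(set(ids)):
            raise ValueError("class ids must be distinct")
        if not self.parenchyma_classes <= set(ids):
            raise ValueError("parenchyma classes must be declared class ids")
        object.__setattr__(self, "class_ids", dict(self.class_ids))
        object.__setattr__(self, "parenchyma_classes", frozenset(int(i) for i in self.parenchyma_classes))

    @property
    def values(self) -> frozenset[int]:
        return frozenset(self.class_ids.values())

    @staticmethod
    def pre_contrast() -> "ClassScheme":
        return ClassScheme(
            phase="pre_contrast",
            class_ids={"background": 0, "parenchyma": 1, "pelvis_fat": 2},
            parenchyma_classes=frozenset({1}),
        )

    @staticmethod
    def post_contrast() -> "ClassScheme":
        return ClassScheme(
            phase="post_contrast",
            class_ids={"background": 0, "cortex": 1, "medulla": 2, "pelvis_fat": 3},
            parenchyma_classes=frozenset({1, 2}),
        )

    @staticmethod
    def model_output() -> "ClassScheme":
        """Scheme of the 3-channel segmentation output.

        Channel 1 holds cortex (post-contrast) or the whole parenchyma
        (pre-contrast), channel 2 medulla; pelvis-fat is not a network class
        and decodes as background. Parenchyma is always classes {1, 2}.
        """
        return ClassScheme(
            phase="post_contrast",
            class_ids={"background": 0, "cortex_or_parenchyma": 1, "medulla": 2},
            parenchyma_classes=frozenset({1, 2}),
        )


@dataclass(frozen=True)
class LabelMap:
    """An integer class grid aligned to a :class:`CTVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    scheme: ClassScheme
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3 or lab.size == 0:
            raise MetadataError("label grid must be a non-empty 3D array")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise SchemeViolationError(np.unique(lab[lab != np.round(lab)])[:5])
            lab = lab.astype(np.uint8)
        present = set(np.unique(lab).tolist())
        undeclared = present - set(int(v) for v in self.scheme.values)
        if undeclared:
            raise SchemeViolationError(undeclared)
        object.__setattr__(self, "labels", lab.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def class_mask(self, ids) -> np.ndarray:
        ids = {ids} if np.isscalar(ids) else set(ids)
        return np.isin(self.labels, sorted(ids))

    def parenchyma_mask(self) -> np.ndarray:
        return self.class_mask(self.scheme.parenchyma_classes)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _canonical_nifti(img):
    """Reorient a nibabel image so its data axes run (R, A, I)."""
    ornt_in = nib.orientations.io_orientation(img.affine)
    if np.any(~np.isfinite(ornt_in)):
        raise MetadataError("affine does not define a full orientation")
    ornt_tgt = nib.orientations.axcodes2ornt(_TARGET_AXCODES)
    transform = nib.orientations.ornt_transform(ornt_in, ornt_tgt)
    return img.as_reoriented(transform)


def _spacing_origin(img):
    aff = img.affine
    spacing = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise MetadataError(f"non-positive or missing spacing in affine: {spacing}")
    # data axes are (R, A, I); our world axes are (R, A, I) as well, which is
    # RAS with the z axis negated.
    origin = (float(aff[0, 3]), float(aff[1, 3]), float(-aff[2, 3]))
    return tuple(float(s) for s in spacing), origin


def _our_affine(spacing, origin):
    sx, sy, sz = spacing
    ox, oy, oz = origin
    return np.array(
        [[sx, 0, 0, ox], [0, sy, 0, oy], [0, 0, -sz, -oz], [0, 0, 0, 1.0]]
    )


def _load_nifti_array(path):
    img = nib.load(os.fspath(path))
    img = _canonical_nifti(img)
    spacing, origin = _spacing_origin(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got shape {data.shape}")
    # file axes (R, A, I) -> our (z, y, x)
    return np.ascontiguousarray(data.transpose(2, 1, 0)), spacing, origin


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _load_dicom_series(path):
    import pydicom

    paths = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for p in paths:
        try:
            ds = pydicom.dcmread(os.fspath(p), force=True)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM slices with pixel data found in {path}")

    def _iop(ds):
        try:
            return np.asarray([float(v) for v in ds.ImageOrientationPatient])
        except Exception as exc:
            raise MetadataError("slice lacks ImageOrientationPatient") from exc

    iop0 = _iop(slices[0])
    for ds in slices[1:]:
        if not np.allclose(_iop(ds), iop0, atol=1e-4):
            raise FormatError("mixed-orientation DICOM series")
    try:
        ps = [float(v) for v in slices[0].PixelSpacing]
    except Exception as exc:
        raise MetadataError("missing PixelSpacing") from exc
    for ds in slices[1:]:
        if not np.allclose([float(v) for v in ds.PixelSpacing], ps, atol=1e-6):
            raise MetadataError("inconsistent in-plane spacing across series")

    row, col = iop0[:3], iop0[3:]
    normal = np.cross(row, col)

    def _ipp(ds):
        try:
            return np.asarray([float(v) for v in ds.ImagePositionPatient])
        except Exception as exc:
            raise MetadataError("slice lacks ImagePositionPatient") from exc

    # Sort cranial -> caudal. DICOM patient +z points toward the head, so the
    # most cranial slice has the largest z position; sort by the position
    # projected on the slice normal, oriented toward the head.
    head = normal if normal[2] >= 0 else -normal
    d = np.array([float(np.dot(_ipp(ds), head)) for ds in slices])
    order = np.argsort(-d)
    slices = [slices[i] for i in order]
    d = d[order]
    dz = np.abs(np.diff(d))
    if dz.size == 0:
        raise FormatError("DICOM series must contain at least two slices")
    z_spacing = float(np.median(dz))
    if z_spacing <= 0 or np.any(np.abs(dz - z_spacing) > 0.05 * z_spacing + 1e-3):
        raise MetadataError("inconsistent slice spacing along the series")

    def _hu(ds):
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept

    vox = np.stack([_hu(ds) for ds in slices], axis=0)  # (z, rows=y, cols=x)
    # PixelSpacing is (row spacing, column spacing) = (y, x)
    spacing = (float(ps[1]), float(ps[0]), z_spacing)
    # In-plane patient orientation is not re-gridded: rows/cols are taken as
    # the y/x axes directly and the origin is left at zero (slice ordering and
    # spacing are what the pipeline depends on).
    return vox, spacing, (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def load_volume(path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : path-like
        A ``.nii``/``.nii.gz`` file or a directory of DICOM slices.
    format : {"nifti", "dicom_series", None}
        Explicit format; inferred from the path by default.

    Returns
    -------
    CTVolume
        With axial slices sorted cranial -> caudal regardless of the on-disk
        order, and spacing read from the metadata.
    """
    path = Path(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "dicom_series":
        vox, spacing, origin = _load_dicom_series(path)
    elif format == "nifti":
        vox, spacing, origin = _load_nifti_array(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    return CTVolume(vox.astype(np.float32), spacing, origin)


def save_volume(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI, preserving spacing and origin.

    Integer-valued HU grids are stored as int16 so that a save/load round
    trip is lossless.
    """
    data = vol.voxels
    if np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.int16)
    elif np.all(data == np.round(data)) and np.all(np.abs(data) < 32000):
        out = data.astype(np.int16)
    else:
        out = data.astype(np.float32)
    img = nib.Nifti1Image(out.transpose(2, 1, 0), _our_affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def load_labelmap(path, scheme: ClassScheme) -> LabelMap:
    """Load an integer label map and validate it against a class scheme.

    Raises
    ------
    SchemeViolationError
        If the file contains label values the scheme does not declare; the
        error lists the offending values.
    """
    data, spacing, origin = _load_nifti_array(path)
    if not np.all(data == np.round(data)):
        raise SchemeViolationError(np.unique(data[data != np.round(data)])[:5])
    return LabelMap(data.astype(np.uint8), spacing, scheme, origin)


def save_labelmap(lab: LabelMap, path) -> None:
    """Write a label map as unsigned 8-bit NIfTI."""
    img = nib.Nifti1Image(
        lab.labels.astype(np.uint8).transpose(2, 1, 0),
        _our_affine(lab.spacing, lab.origin),
    )
    img.header.set_zooms(lab.spacing)
    nib.save(img, os.fspath(path))
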