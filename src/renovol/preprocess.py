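"""Preprocessing: non-zero crop, kidney localization, resampling, normalization.

Four steps prepare a raw CT volume for the segmentation network:

1. **Non-zero region crop** — the tightest axis-aligned box containing every
   voxel above a background HU threshold (default -900 HU: comfortably above
   noisy air, below aerated lung), so the surrounding air and table are discarded without
   losing a single foreground voxel.
2. **Kidney localization** — canine kidneys sit just caudal to the lung, so
   the lung's caudal margin is found by scanning axial slices cranial to
   caudal and calling a slice lung-containing when at least a fraction
   ``tau`` of its in-body voxels fall below an air threshold (default
   -400 HU). The returned box spans a configurable margin cranial of that
   landmark plus a caudal window, with the full in-plane body crop.
3. **Resampling** — trilinear (images) or nearest-neighbour (labels)
   interpolation to a fixed spacing, default (x=1.5, y=1.5, z=2.0) mm; the
   output grid size is ``round(extent / target)`` per axis (min 1) so the
   physical extent is preserved within one voxel.
4. **Intensity normalization** — HU values are clipped to [-1024, 3025],
   then to [-175, 250], then linearly rescaled to [0, 1] for the network.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyForegroundError, LocalizationError, ParameterError
from .imaging import CTVolume, LabelMap

__all__ = [
    "BoundingBox",
    "LungDetectionParams",
    "crop_nonzero",
    "localize_kidney_region",
    "crop_to_box",
    "resample",
    "normalize_intensity",
    "HU_CLIP_OUTER",
    "HU_CLIP_INNER",
    "TARGET_SPACING",
]

HU_CLIP_OUTER = (-1024.0, 3025.0)
HU_CLIP_INNER = (-175.0, 250.0)
TARGET_SPACING = (1.5, 1.5, 2.0)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open, 0-based per-axis (start, stop) voxel indices, array order (z, y, x)."""

    ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        rs = tuple((int(a), int(b)) for a, b in self.ranges)
        for a, b in rs:
            if a < 0 or b <= a:
                raise ParameterError(f"invalid bounding box ranges {rs}")
        object.__setattr__(self, "ranges", rs)

    @property
    def slices(self):
        return tuple(slice(a, b) for a, b in self.ranges)

    @property
    def shape(self):
        return tuple(b - a for a, b in self.ranges)

    def contains(self, other: "BoundingBox") -> bool:
        return all(a <= oa and ob <= b for (a, b), (oa, ob) in zip(self.ranges, other.ranges))

    def to_dict(self):
        return {"z": self.ranges[0], "y": self.ranges[1], "x": self.ranges[2]}


@dataclass(frozen=True)
class LungDetectionParams:
    """Parameters of the air-fraction lung rule.

    ``air_threshold_hu``: voxels below this are counted as air-like;
    ``lung_fraction_tau``: fraction of in-body voxels that must be air-like
    for a slice to count as lung-containing; ``cranial_margin_mm`` /
    ``caudal_window_mm``: box extension around the detected caudal margin.
    """

    air_threshold_hu: float = -400.0
    lung_fraction_tau: float = 0.05
    cranial_margin_mm: float = 10.0
    caudal_window_mm: float = 120.0
    body_threshold_hu: float = -900.0

    def __post_init__(self):
        if not (0 < self.lung_fraction_tau <= 1):
            raise ParameterError("tau must lie in (0, 1]")
        if self.cranial_margin_mm < 0 or self.caudal_window_mm < 0:
            raise ParameterError("margins must be >= 0")


def crop_nonzero(vol: CTVolume, background_hu: float = -900.0) -> tuple[CTVolume, BoundingBox]:
    """Crop to the tightest box containing every voxel above ``background_hu``.

    Returns the cropped volume (origin shifted accordingly) and the box in
    the input volume's own grid. Raises :class:`EmptyForegroundError` when
    nothing exceeds the threshold.
    """
    fg = vol.voxels > background_hu
    if not fg.any():
        raise EmptyForegroundError(f"no voxel above {background_hu} HU")
    ranges = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        prof = fg.any(axis=other)
        idx = np.flatnonzero(prof)
        ranges.append((int(idx[0]), int(idx[-1]) + 1))
    box = BoundingBox(tuple(ranges))
    return crop_to_box(vol, box), box


def crop_to_box(obj, box: BoundingBox):
    """Apply a bounding box to a CTVolume or LabelMap, shifting the origin."""
    sx, sy, sz = obj.spacing
    (z0, _), (y0, _), (x0, _) = box.ranges
    origin = (obj.origin[0] + x0 * sx, obj.origin[1] + y0 * sy, obj.origin[2] + z0 * sz)
    if isinstance(obj, LabelMap):
        return LabelMap(obj.labels[box.slices], obj.spacing, obj.scheme, origin)
    return CTVolume(obj.voxels[box.slices], obj.spacing, origin)


def localize_kidney_region(vol: CTVolume, params: LungDetectionParams | None = None) -> BoundingBox:
    """Locate the kidney-containing region from the lung's caudal margin.

    Scans axial slices cranial to caudal inside the body crop; the caudal
    margin is the last lung-containing slice. The returned box spans
    ``[margin - cranial_margin, margin + caudal_window]`` axially (clamped
    to the grid) and the full in-plane body crop.

    Raises
    ------
    LocalizationError
        If no slice qualifies as lung-containing; callers may fall back to
        the whole-volume box.
    """
    params = params or LungDetectionParams()
    _, body_box = crop_nonzero(vol, params.body_threshold_hu)
    body = vol.voxels[body_box.slices]
    in_body = body > params.body_threshold_hu
    airlike = (body < params.air_threshold_hu) & in_body

    n_body = in_body.sum(axis=(1, 2))
    n_air = airlike.sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_body > 0, n_air / np.maximum(n_body, 1), 0.0)
    lungy = np.flatnonzero(frac >= params.lung_fraction_tau)
    if lungy.size == 0:
        raise LocalizationError("no lung-containing axial slice found")

    sz = vol.spacing[2]
    (bz0, bz1), by, bx = body_box.ranges
    margin_idx = bz0 + int(lungy.max())
    z0 = max(0, margin_idx - int(round(params.cranial_margin_mm / sz)))
    z1 = min(vol.shape[0], margin_idx + int(round(params.caudal_window_mm / sz)) + 1)
    if z1 <= z0:
        z1 = min(vol.shape[0], z0 + 1)
    return BoundingBox(((z0, z1), by, bx))


def _resample_array(arr, in_spacing, target_spacing, order):
    sx, sy, sz = in_spacing
    tx, ty, tz = target_spacing
    nz, ny, nx = arr.shape
    out_shape = (
        max(1, int(round(nz * sz / tz))),
        max(1, int(round(ny * sy / ty))),
        max(1, int(round(nx * sx / tx))),
    )
    scale = (tz / sz, ty / sy, tx / sx)
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(out_shape, scale)], indexing="ij"
    )
    coords = [np.clip(c, 0, dim - 1) for c, dim in zip(coords, arr.shape)]
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest"), out_shape


def resample(obj, target_spacing=TARGET_SPACING):
    """Resample a CTVolume (trilinear) or LabelMap (nearest) to a fixed spacing.

    The output grid has ``round(n * spacing / target)`` voxels per axis (at
    least 1), preserving the physical extent within one output voxel.
    """
    ts = tuple(float(t) for t in target_spacing)
    if len(ts) != 3 or any(t <= 0 for t in ts):
        raise ParameterError(f"target spacing must be three positive values, got {target_spacing!r}")
    if isinstance(obj, LabelMap):
        out, _ = _resample_array(obj.labels, obj.spacing, ts, order=0)
        return LabelMap(out.astype(np.uint8), ts, obj.scheme, obj.origin)
    out, _ = _resample_array(obj.voxels.astype(np.float32), obj.spacing, ts, order=1)
    return CTVolume(out.astype(np.float32), ts, obj.origin)


def normalize_intensity(vol: CTVolume) -> CTVolume:
    """Clip HU to [-1024, 3025], then [-175, 250], then rescale to [0, 1].

    Idempotent: an input already lying in [0, 1] is recognized as normalized
    and returned unchanged, so applying the function twice equals applying
    it once.
    """
    v = vol.voxels.astype(np.float32)
    if v.min() >= 0.0 and v.max() <= 1.0:
        return vol
    v = np.clip(v, *HU_CLIP_OUTER)
    lo, hi = HU_CLIP_INNER
    v = np.clip(v, lo, hi)
    v = (v - lo) / (hi - lo)
    return CTVolume(v, vol.spacing, vol.origin)
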