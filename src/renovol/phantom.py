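"""Synthetic canine abdominal CT phantoms with analytic ground truth.

The phantom emulates the anatomy the pipeline relies on, not realistic dog
anatomy: a soft-tissue torso (elliptic cylinder) surrounded by air, aerated
lung filling the cranial fraction of the torso, and two bilateral kidneys
caudal to the lung's caudal margin. Each kidney is a set of nested,
concentric ellipsoids — cortex shell, medulla shell, and a pelvis-plus-fat
core — so every structure has an exact closed-form volume
(``4/3*pi*a*b*c`` differences) to serve as the volumetry oracle.

Voxel class membership is decided at the voxel centre in physical
coordinates (no partial-volume modelling), which keeps the analytic oracle
exact up to discretization. Image intensity is the tissue mean HU per class
plus seeded additive Gaussian noise.

A cohort generator produces tabular dog records (sex, neuter status, age,
body weight, body condition score) with kidney volumes drawn from a known
linear model, for exercising the reference-model fitting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PhantomSpecError
from .imaging import ClassScheme, CTVolume, LabelMap
from .preprocess import BoundingBox

__all__ = [
    "KidneySpec",
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_phantom",
    "voxelized_volume_error",
    "generate_cohort",
    "phantom_suite",
]

ELLIPSOID_VOLUME_CM3 = lambda a, b, c: 4.0 / 3.0 * math.pi * a * b * c / 1000.0

# Tissue HU defaults: standard CT soft-tissue/fat/lung ranges.
PRE_CONTRAST_HU = {"parenchyma": 35.0, "pelvis_fat": -90.0}
POST_CONTRAST_HU = {"cortex": 150.0, "medulla": 100.0, "pelvis_fat": -90.0}


@dataclass(frozen=True)
class KidneySpec:
    """One kidney as nested concentric ellipsoids.

    ``center`` and ``semi_axes`` are (x, y, z) in mm. The medulla boundary is
    the outer ellipsoid shrunk by ``cortex_thickness`` mm on every semi-axis;
    the pelvis-fat core has semi-axes ``core_fraction`` times the medulla's.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    cortex_thickness: float = 3.0
    core_fraction: float = 0.35

    def __post_init__(self):
        if any(s <= 0 for s in self.semi_axes):
            raise PhantomSpecError("kidney semi-axes must be positive")
        if not (0 < self.core_fraction < 1):
            raise PhantomSpecError("core_fraction must lie in (0, 1)")
        if self.cortex_thickness < 0 or self.cortex_thickness >= min(self.semi_axes):
            raise PhantomSpecError("cortex thickness must be >= 0 and thinner than every semi-axis")

    @property
    def medulla_axes(self):
        return tuple(s - self.cortex_thickness for s in self.semi_axes)

    @property
    def core_axes(self):
        return tuple(self.core_fraction * s for s in self.medulla_axes)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scan.

    ``shape`` is the voxel grid ``(nz, ny, nx)``; ``spacing`` is (x, y, z)
    mm. ``lung_fraction`` is the cranial fraction of the axial extent filled
    with lung-density tissue; kidney centres must lie caudal to it.
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.0)
    phase: str = "post_contrast"
    kidneys: tuple[KidneySpec, ...] = ()
    torso_hu: float = 55.0
    lung_hu: float = -800.0
    air_hu: float = -1000.0
    lung_fraction: float = 0.3
    tissue_hu: dict = field(default_factory=dict)  # overrides per class name
    noise_sigma: float = 10.0
    torso_inplane_fraction: tuple[float, float] = (0.42, 0.45)  # (y, x) of extent
    seed: int = 0

    def __post_init__(self):
        if self.phase not in ("pre_contrast", "post_contrast"):
            raise PhantomSpecError(f"unknown phase {self.phase!r}")
        if not (0 < self.lung_fraction < 1):
            raise PhantomSpecError("lung_fraction must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise sigma must be >= 0")
        if not self.kidneys:
            object.__setattr__(self, "kidneys", _default_kidneys(self))
        ext = self.extent_mm
        lung_end = self.lung_fraction * ext[2]
        for k in self.kidneys:
            cx, cy, cz = k.center
            ax, ay, az = k.semi_axes
            if cz <= lung_end:
                raise PhantomSpecError("kidney centers must lie caudal to the lung extent")
            for c, a, e in ((cx, ax, ext[0]), (cy, ay, ext[1]), (cz, az, ext[2])):
                if c - a < 0 or c + a > e:
                    raise PhantomSpecError("kidney ellipsoid falls outside the grid")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical grid extent (x, y, z) in mm."""
        nz, ny, nx = self.shape
        sx, sy, sz = self.spacing
        return (nx * sx, ny * sy, nz * sz)

    @property
    def hu_means(self) -> dict:
        base = dict(PRE_CONTRAST_HU if self.phase == "pre_contrast" else POST_CONTRAST_HU)
        base.update(self.tissue_hu)
        return base

    @property
    def scheme(self) -> ClassScheme:
        return (
            ClassScheme.pre_contrast()
            if self.phase == "pre_contrast"
            else ClassScheme.post_contrast()
        )


def _default_kidneys(spec: PhantomSpec):
    ex, ey, ez = spec.extent_mm
    cz = min(0.60 * ez, spec.lung_fraction * ez + 0.32 * ez)
    return (
        KidneySpec(center=(0.5 * ex - 0.21 * ex, 0.5 * ey, cz), semi_axes=(12.0, 10.0, 20.0)),
        KidneySpec(center=(0.5 * ex + 0.21 * ex, 0.5 * ey, cz + 6.0), semi_axes=(12.0, 10.0, 20.0)),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Exact labels and analytic volumes for a generated phantom."""

    labels: LabelMap
    analytic_volumes_cm3: dict  # per structure name, both kidneys summed
    lung_caudal_index: int
    kidney_bbox: BoundingBox
    lung_mask: np.ndarray


def _ellipsoid_membership(X, Y, Z, center, axes):
    cx, cy, cz = center
    ax, ay, az = axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Rasterize a phantom spec into an HU volume and its ground truth.

    Labels are assigned by exact ellipsoid membership tests at voxel centres
    in physical coordinates; the image is the per-class HU mean plus
    ``N(0, noise_sigma)`` noise from a generator seeded with ``spec.seed``,
    so identical specs give bit-identical outputs.
    """
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    ex, ey, ez = spec.extent_mm

    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx

    fy, fx = spec.torso_inplane_fraction
    torso = (((x - 0.5 * ex) / (fx * ex)) ** 2 + ((y - 0.5 * ey) / (fy * ey)) ** 2) <= 1.0
    torso = np.broadcast_to(torso, spec.shape).copy()

    lung_extent = spec.lung_fraction * ez
    lung_inplane = (((x - 0.5 * ex) / (0.7 * fx * ex)) ** 2 + ((y - 0.5 * ey) / (0.7 * fy * ey)) ** 2) <= 1.0
    lung = np.broadcast_to(lung_inplane, spec.shape) & (np.broadcast_to(z, spec.shape) < lung_extent) & torso

    labels = np.zeros(spec.shape, dtype=np.uint8)
    scheme = spec.scheme
    ids = scheme.class_ids
    analytic: dict[str, float] = {}

    for k in spec.kidneys:
        outer = _ellipsoid_membership(x, y, z, k.center, k.semi_axes)
        med = _ellipsoid_membership(x, y, z, k.center, k.medulla_axes)
        core = _ellipsoid_membership(x, y, z, k.center, k.core_axes)
        v_outer = ELLIPSOID_VOLUME_CM3(*k.semi_axes)
        v_med = ELLIPSOID_VOLUME_CM3(*k.medulla_axes)
        v_core = ELLIPSOID_VOLUME_CM3(*k.core_axes)
        if spec.phase == "post_contrast":
            labels[outer & ~med] = ids["cortex"]
            labels[med & ~core] = ids["medulla"]
            labels[core] = ids["pelvis_fat"]
            analytic["cortex"] = analytic.get("cortex", 0.0) + (v_outer - v_med)
            analytic["medulla"] = analytic.get("medulla", 0.0) + (v_med - v_core)
        else:
            labels[outer & ~core] = ids["parenchyma"]
            labels[core] = ids["pelvis_fat"]
        analytic["pelvis_fat"] = analytic.get("pelvis_fat", 0.0) + v_core
        analytic["parenchyma"] = analytic.get("parenchyma", 0.0) + (v_outer - v_core)
        analytic["total_kidney"] = analytic.get("total_kidney", 0.0) + v_outer

    hu = np.full(spec.shape, spec.air_hu, dtype=np.float32)
    hu[torso] = spec.torso_hu
    hu[lung] = spec.lung_hu
    for name, mean in spec.hu_means.items():
        hu[labels == ids[name]] = mean
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)

    fg = np.argwhere(labels > 0)
    if fg.size == 0:
        raise PhantomSpecError("phantom has no kidney voxels")
    lo, hi = fg.min(axis=0), fg.max(axis=0) + 1
    bbox = BoundingBox(tuple((int(a), int(b)) for a, b in zip(lo, hi)))
    lung_slices = np.flatnonzero(lung.any(axis=(1, 2)))
    if lung_slices.size == 0:
        raise PhantomSpecError("phantom lung region is empty")

    vol = CTVolume(hu.astype(np.float32), spec.spacing)
    gt = GroundTruth(
        labels=LabelMap(labels, spec.spacing, scheme),
        analytic_volumes_cm3=analytic,
        lung_caudal_index=int(lung_slices.max()),
        kidney_bbox=bbox,
        lung_mask=lung,
    )
    return vol, gt


def voxelized_volume_error(gt: GroundTruth, spacing=None) -> dict:
    """Fractional discretization error of voxel-count vs analytic volumes.

    Returns ``{structure: |voxel - analytic| / analytic}`` for every
    structure with a positive analytic volume; structures with zero voxels
    and zero analytic volume are omitted (the error is undefined).
    """
    spacing = spacing or gt.labels.spacing
    vox_mm3 = float(np.prod(spacing))
    ids = gt.labels.scheme.class_ids
    out = {}
    for name, analytic in gt.analytic_volumes_cm3.items():
        if analytic <= 0:
            continue
        if name == "parenchyma":
            count = int(gt.labels.parenchyma_mask().sum())
        elif name == "total_kidney":
            count = int((gt.labels.labels > 0).sum())
        elif name in ids:
            count = int((gt.labels.labels == ids[name]).sum())
        else:
            continue
        if count == 0:
            continue
        voxel_cm3 = count * vox_mm3 / 1000.0
        out[name] = abs(voxel_cm3 - analytic) / analytic
    return out


def phantom_suite(n: int, base_seed: int = 0, phase: str = "post_contrast",
                  noise_sigma: float = 10.0, shape=(64, 96, 96),
                  spacing=(1.5, 1.5, 2.0)) -> list[PhantomSpec]:
    """The standard test suite: ``n`` phantoms with per-seed kidney geometry.

    Kidney semi-axes vary uniformly in [9, 14] mm (x, y) and [16, 24] mm (z)
    and centres jitter by a few mm, so kidney volumes genuinely differ
    across the suite (needed for correlation-style agreement statistics).
    """
    specs = []
    for i in range(n):
        seed = base_seed + i
        rng = np.random.default_rng(seed + 20_000_000)
        base = PhantomSpec(shape=shape, spacing=spacing, phase=phase,
                           noise_sigma=noise_sigma, seed=seed)
        ex, ey, ez = base.extent_mm
        kidneys = []
        for k in base.kidneys:
            axes = (float(rng.uniform(9, 14)), float(rng.uniform(9, 14)), float(rng.uniform(16, 24)))
            jitter = rng.uniform(-4, 4, size=3)
            center = (float(k.center[0] + jitter[0]), float(k.center[1] + jitter[1]),
                      float(min(max(k.center[2] + jitter[2], base.lung_fraction * ez + axes[2] + 1), ez - axes[2] - 1)))
            kidneys.append(KidneySpec(center=center, semi_axes=axes))
        specs.append(replace(base, kidneys=tuple(kidneys)))
    return specs


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Synthetic normal-dog cohort for reference-model fitting.

    Body weight is log-normal (parameters chosen to match a small-breed
    hospital population: mean ~6.8 kg, SD ~5.4 kg); body condition score is
    a 1-9 integer distribution peaked at 5; age is a clipped normal. Kidney
    volume is generated from a known linear model plus Gaussian residual
    noise, so OLS refits have a ground truth to recover.
    """

    n: int = 159
    slopes: dict = field(default_factory=lambda: {"BW": 3.701})
    intercept: float = 11.962
    residual_sigma: float = 11.8
    bw_log_mu: float = 1.668
    bw_log_sigma: float = 0.70
    bcs_probs: tuple = (0.01, 0.02, 0.05, 0.15, 0.30, 0.25, 0.12, 0.07, 0.03)
    age_mean: float = 9.31
    age_sd: float = 4.07
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise PhantomSpecError("cohort size must be at least 3")
        if self.residual_sigma < 0:
            raise PhantomSpecError("residual sigma must be >= 0")
        if abs(sum(self.bcs_probs) - 1.0) > 1e-9 or len(self.bcs_probs) != 9:
            raise PhantomSpecError("bcs_probs must be 9 probabilities summing to 1")
        unknown = set(self.slopes) - {"BW", "BCS", "age", "BW_BCS"}
        if unknown:
            raise PhantomSpecError(f"unknown covariates in slopes: {sorted(unknown)}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with columns id, sex, neutered, age, BW, BCS, true_volume.

    ``true_volume = intercept + sum(slope_i * covariate_i) + N(0, sigma)``.
    Non-positive body weights (impossible under the log-normal but possible
    under user-supplied parameters) are redrawn by rejection.
    """
    rng = np.random.default_rng(spec.seed)
    bw = np.exp(rng.normal(spec.bw_log_mu, spec.bw_log_sigma, size=spec.n))
    for _ in range(100):
        bad = ~(bw > 0)
        if not bad.any():
            break
        bw[bad] = np.exp(rng.normal(spec.bw_log_mu, spec.bw_log_sigma, size=int(bad.sum())))
    bw = np.round(bw, 3)  # volumes derive from the recorded (rounded) covariates
    bcs = rng.choice(np.arange(1, 10), size=spec.n, p=spec.bcs_probs)
    age = np.round(np.clip(rng.normal(spec.age_mean, spec.age_sd, size=spec.n), 0.3, None), 2)
    sex = rng.choice(["male", "female"], size=spec.n, p=[0.503, 0.497])
    neutered = rng.random(spec.n) < 0.836  # hospital populations are mostly neutered

    covs = {"BW": bw, "BCS": bcs.astype(float), "age": age, "BW_BCS": bw / bcs}
    vol = np.full(spec.n, spec.intercept, dtype=float)
    for name, slope in spec.slopes.items():
        vol = vol + slope * covs[name]
    if spec.residual_sigma > 0:
        vol = vol + rng.normal(0.0, spec.residual_sigma, size=spec.n)

    return pd.DataFrame(
        {
            "id": [f"dog{i:04d}" for i in range(spec.n)],
            "sex": sex,
            "neutered": neutered,
            "age": age,
            "BW": bw,
            "BCS": bcs,
            "true_volume": vol,
        }
    )
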