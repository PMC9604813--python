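"""Digitally reconstructed radiographs (DRRs) from attenuation volumes.

A DRR pixel is the line integral of attenuation along the ray from the
X-ray source through that pixel,

    I(p) = integral of A along L(p, s) ds,

discretised by fixed-step ray marching with trilinear interpolation of
the volume and zero contribution outside it.  The module also provides
the imaging protocol used to build training data: for every patient,
20 views drawn from four C-arm-reachable categories —

* AP: one strict anterior-posterior shot plus two tilted by +-15 deg in
  the sagittal plane;
* lateral: two strict lateral shots (one per side) plus two with
  +-20 deg deviation in the coronal plane;
* oblique: shots separated from the AP by +-20 and +-35 deg;
* miscellaneous: nine shots deviating in two planes at once —

each with a focal length drawn from {850, 900, 1000} pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .geometry import (
    Extrinsics,
    Intrinsics,
    ProjectionMatrix,
    compose_projection,
)
from .volume import AttenuationVolume

__all__ = [
    "ViewCategory",
    "ViewSpec",
    "Ray",
    "DRRImage",
    "FOCAL_LENGTH_CHOICES",
    "pixel_ray",
    "render_drr",
    "sample_view_protocol",
    "select_input_views",
    "make_view_projection",
    "normalize_image",
]

FOCAL_LENGTH_CHOICES = (850.0, 900.0, 1000.0)


class ViewCategory(str, Enum):
    AP = "AP"
    LATERAL = "lateral"
    OBLIQUE = "oblique"
    MISC = "misc"


@dataclass(frozen=True)
class ViewSpec:
    """One imaging pose: orbital rotation from AP, cranio-caudal tilt.

    ``orbital_deg`` rotates the source around the patient's long axis
    (0 = AP, +-90 = lateral); ``tilt_deg`` tilts the beam cranio-caudally,
    which for an AP view is a deviation within the sagittal plane and for
    a lateral view a deviation within the coronal plane.
    """

    category: ViewCategory
    orbital_deg: float
    tilt_deg: float
    focal_length: float


@dataclass(frozen=True)
class Ray:
    source: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "source", np.asarray(self.source, float).reshape(3))
        object.__setattr__(self, "direction", d)

    def point_at(self, s: float) -> np.ndarray:
        return self.source + s * self.direction


@dataclass(frozen=True)
class DRRImage:
    """Rendered radiograph: pixels[v, u] plus its calibration."""

    pixels: np.ndarray
    view_category: ViewCategory
    projection: ProjectionMatrix
    focal_length: float


def _rot_axis(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def view_direction(orbital_deg: float, tilt_deg: float) -> np.ndarray:
    """Unit vector from the source toward the patient center."""
    d0 = np.array([0.0, 1.0, 0.0])  # AP: source anterior, beam posterior
    Rz = _rot_axis(np.array([0.0, 0.0, 1.0]), orbital_deg)
    d = Rz @ d0
    horiz = Rz @ np.array([1.0, 0.0, 0.0])
    return _rot_axis(horiz, tilt_deg) @ d


def make_view_projection(
    view: ViewSpec,
    target_center,
    image_size: tuple[int, int] = (224, 224),
    source_distance: float | None = None,
    fit_radius: float | None = None,
) -> ProjectionMatrix:
    """Place the source for a view spec and compose its projection matrix.

    By default the target center sits at a depth of 0.7x the focal
    length; if ``fit_radius`` (mm, bounding sphere of the anatomy) is
    given the distance is increased as needed so the sphere fits inside
    the frame with a 5% margin.
    """
    f = view.focal_length
    w, h = image_size
    if source_distance is None:
        source_distance = 0.7 * f
        if fit_radius is not None:
            source_distance = max(source_distance,
                                  f * fit_radius / (0.95 * min(w, h) / 2.0))
    d = view_direction(view.orbital_deg, view.tilt_deg)
    center = np.asarray(target_center, float)
    source = center - source_distance * d
    up = np.array([0.0, 0.0, 1.0])
    x_cam = np.cross(up, d)
    x_cam = x_cam / np.linalg.norm(x_cam)
    y_cam = np.cross(d, x_cam)
    R = np.stack([x_cam, y_cam, d])
    K = Intrinsics(f, (w / 2.0, h / 2.0), (w, h))
    return compose_projection(K, Extrinsics(R, source))


def pixel_ray(P: ProjectionMatrix, p) -> Ray:
    """Ray from the X-ray source through pixel ``p = (u, v)``."""
    if not P.has_provenance:
        raise ValueError("projection matrix has no calibration provenance")
    u, v = p
    K = P.intrinsics.K
    R = P.extrinsics.rotation
    d_cam = np.linalg.solve(K, np.array([u, v, 1.0]))
    d = R.T @ d_cam
    return Ray(P.extrinsics.camera_center, d / np.linalg.norm(d))


def _slab_clip(source, dirs, lo, hi):
    """Per-ray AABB entry/exit parameters (tmin, tmax), tmin >= 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t1 = (lo - source) * inv
        t2 = (hi - source) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=-1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=-1)
    return np.maximum(tmin, 0.0), tmax


def render_drr(
    vol: AttenuationVolume,
    P: ProjectionMatrix,
    size: tuple[int, int] | None = None,
    step: float = 0.5,
    category: ViewCategory = ViewCategory.MISC,
) -> DRRImage:
    """Ray-march the attenuation line integral for every pixel.

    ``step`` is the marching step in mm; samples use trilinear
    interpolation inside the volume and contribute zero outside.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not P.has_provenance:
        raise ValueError("projection matrix has no calibration provenance")
    if size is None:
        size = P.intrinsics.image_size
    w, h = size
    source = P.extrinsics.camera_center
    K = P.intrinsics.K
    R = P.extrinsics.rotation

    uu, vv = np.meshgrid(np.arange(w), np.arange(h))
    pix_h = np.stack([uu.ravel(), vv.ravel(), np.ones(w * h)], axis=0)
    d_cam = np.linalg.solve(K, pix_h)
    dirs = (R.T @ d_cam).T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    lo, hi = vol.world_extent()
    tmin, tmax = _slab_clip(source, dirs, lo, hi)
    hit = tmax > tmin
    image = np.zeros(w * h, dtype=np.float64)
    if not np.any(hit):
        import warnings

        warnings.warn("volume entirely outside the camera frustum; blank DRR")
        return DRRImage(image.reshape(h, w).astype(np.float32),
                        category, P, P.intrinsics.focal_length)

    n_steps = int(np.ceil((tmax[hit] - tmin[hit]).max() / step))
    origin = np.asarray(vol.origin)
    spacing = np.asarray(vol.spacing)
    acc = np.zeros(hit.sum(), dtype=np.float64)
    src_idx = (source - origin) / spacing
    dir_idx = dirs[hit] / spacing  # ray directions in index units
    t0 = tmin[hit]
    t1 = tmax[hit]
    chunk = max(1, int(4e6 // max(hit.sum(), 1)))
    for s0 in range(0, n_steps, chunk):
        ks = np.arange(s0, min(s0 + chunk, n_steps))
        ts = t0[:, None] + (ks[None, :] + 0.5) * step
        inside = ts < t1[:, None]
        pts = src_idx[None, None, :] + ts[:, :, None] * dir_idx[:, None, :]
        vals = ndimage.map_coordinates(
            vol.values, pts.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
        ).reshape(ts.shape)
        acc += (vals * inside).sum(axis=1)
    image[hit] = acc * step
    return DRRImage(image.reshape(h, w).astype(np.float32),
                    category, P, P.intrinsics.focal_length)


def normalize_image(pixels: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to zeros."""
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi - lo < 1e-12:
        return np.zeros_like(pixels, dtype=np.float32)
    return ((pixels - lo) / (hi - lo)).astype(np.float32)


def sample_view_protocol(rng_seed: int) -> list[ViewSpec]:
    """The per-patient 20-view protocol (3 AP, 4 lateral, 4 oblique, 9 misc).

    Fixed poses are deterministic; the nine miscellaneous poses draw
    both angles from +-[10, 35] deg (excluding pure single-plane poses)
    and every view draws its focal length from {850, 900, 1000}.
    """
    rng = np.random.default_rng(rng_seed)

    def f() -> float:
        return float(rng.choice(FOCAL_LENGTH_CHOICES))

    views: list[ViewSpec] = []
    for tilt in (0.0, 15.0, -15.0):
        views.append(ViewSpec(ViewCategory.AP, 0.0, tilt, f()))
    for orb, tilt in ((90.0, 0.0), (-90.0, 0.0), (90.0, 20.0), (-90.0, -20.0)):
        views.append(ViewSpec(ViewCategory.LATERAL, orb, tilt, f()))
    for orb in (20.0, -20.0, 35.0, -35.0):
        views.append(ViewSpec(ViewCategory.OBLIQUE, orb, 0.0, f()))
    for _ in range(9):
        orb = rng.uniform(10.0, 35.0) * rng.choice([-1.0, 1.0])
        tilt = rng.uniform(10.0, 35.0) * rng.choice([-1.0, 1.0])
        views.append(ViewSpec(ViewCategory.MISC, orb, tilt, f()))
    return views


def select_input_views(samples, n_views: int, rng_seed: int) -> list:
    """Select the network's input views from a per-patient pool.

    For 4 views: one random sample per category (AP, lateral, oblique,
    misc).  For 8 views: the same four plus four drawn randomly from the
    remaining pool regardless of category.
    """
    if n_views not in (4, 8):
        raise ValueError("n_views must be 4 or 8")
    rng = np.random.default_rng(rng_seed)
    by_cat: dict[ViewCategory, list] = {c: [] for c in ViewCategory}
    for s in samples:
        cat = getattr(s, "view_category", None) or getattr(s, "category")
        by_cat[ViewCategory(cat)].append(s)
    if any(len(v) == 0 for v in by_cat.values()):
        missing = [c.value for c, v in by_cat.items() if not v]
        raise ValueError(f"pool is missing view categories: {missing}")
    chosen = [by_cat[c][rng.integers(len(by_cat[c]))] for c in ViewCategory]
    if n_views == 8:
        taken = {id(c) for c in chosen}
        rest = [s for s in samples if id(s) not in taken]
        extra = rng.choice(len(rest), size=4, replace=False)
        chosen += [rest[i] for i in sorted(extra)]
    return chosen
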