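"""Build network training pairs from volumes, labels and the view protocol.

The pipeline mirrors the clinical setting: render full-size radiographs
for the 20-view protocol, find the 2D bounding box and projected mask of
each lumbar level, crop each radiograph down to one vertebra (updating
the projection matrix for the crop and the resize), and pair the crops
with a ground-truth occupancy grid derived from the 3D labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from .drr import (
    DRRImage,
    ViewCategory,
    make_view_projection,
    normalize_image,
    render_drr,
    sample_view_protocol,
    select_input_views,
)
from .geometry import (
    CropOffset,
    GridSpec,
    ProjectionMatrix,
    adjust_for_crop,
    project_points,
    scale_pixels,
)
from .grids import OccupancyGrid
from .phantoms import DeformationSpec, PhantomConfig, elastic_deform, make_phantom
from .volume import AttenuationVolume

__all__ = [
    "CaseRecord",
    "LocalizedSample",
    "ReconSample",
    "filter_cases",
    "project_bbox",
    "crop_localize",
    "warp_mask_to_crop",
    "make_segmented_variants",
    "make_ground_truth_grid",
    "grid_for_level",
    "split_dataset",
    "build_manifest",
    "build_phantom_dataset",
    "DatasetConfig",
]

VIEWS_PER_PATIENT = 20
LEVELS_PER_PATIENT = 5


@dataclass(frozen=True)
class CaseRecord:
    """Inclusion/exclusion metadata for one CT case."""

    case_id: str
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    present_levels: tuple[int, ...]
    synostosis: bool = False


@dataclass
class LocalizedSample:
    """One cropped, resized, normalized vertebra view and its geometry."""

    image: np.ndarray  # (S, S) float32 in [0, 1]
    p_hat: ProjectionMatrix
    level: int
    variant: str = "unsegmented"  # unsegmented | seg_grayscale | seg_binary
    view_category: ViewCategory = ViewCategory.MISC
    grid: GridSpec | None = None
    gt: OccupancyGrid | None = None


@dataclass
class ReconSample:
    """A multi-view reconstruction sample: n input views + ground truth."""

    case_id: str
    level: int
    images: list[np.ndarray]
    p_hats: list[ProjectionMatrix]
    grid: GridSpec
    gt: OccupancyGrid
    variant: str = "unsegmented"
    view_categories: list[ViewCategory] = field(default_factory=list)


def filter_cases(records: list[CaseRecord]) -> list[CaseRecord]:
    """Apply the inclusion/exclusion criteria.

    Keep cases with sub-millimetre voxels on all axes, more than 128
    voxels on every axis, all five lumbar levels present and no
    synostosis.
    """
    kept = []
    for r in records:
        if any(s >= 1.0 for s in r.spacing):
            continue
        if any(n <= 128 for n in r.shape):
            continue
        if set(range(1, 6)) - set(r.present_levels):
            continue
        if r.synostosis:
            continue
        kept.append(r)
    return kept


def project_bbox(
    vol: AttenuationVolume,
    level: int,
    P: ProjectionMatrix,
    image_size: tuple[int, int],
) -> tuple[tuple[int, int, int, int], np.ndarray]:
    """2D bounding box and mask of one vertebral level under a projection.

    The mask is rasterized from the projected centers of the level's
    voxels, then morphologically closed to bridge sub-pixel gaps left by
    magnification.  Returns ``((x, y, w, h), mask)`` with the box clipped
    to the image.
    """
    if vol.labels is None or level not in vol.present_levels():
        raise ValueError(f"level {level} absent from volume labels")
    w, h = image_size
    idx = np.argwhere(vol.labels == level)
    pts = np.asarray(vol.origin) + idx * np.asarray(vol.spacing)
    pix, depth = project_points(P, pts)
    pix = pix[depth > 0]
    ui = np.rint(pix[:, 0]).astype(int)
    vi = np.rint(pix[:, 1]).astype(int)
    ok = (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
    mask = np.zeros((h, w), dtype=bool)
    mask[vi[ok], ui[ok]] = True
    if mask.any():
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)), iterations=2)
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError(f"level {level} projects entirely outside the image")
    vs, us = np.nonzero(mask)
    x0, y0 = int(us.min()), int(vs.min())
    return (x0, y0, int(us.max() - x0 + 1), int(vs.max() - y0 + 1)), mask


def _square_window(bbox, margin: float = 0.10) -> tuple[int, int, int]:
    """Expand a bbox to a square crop window (x0, y0, side)."""
    x, y, w, h = bbox
    if w <= 0 or h <= 0:
        raise ValueError("degenerate bounding box")
    side = int(np.ceil(max(w, h) * (1.0 + margin)))
    cx, cy = x + w / 2.0, y + h / 2.0
    return int(round(cx - side / 2.0)), int(round(cy - side / 2.0)), side


def _extract_window(image: np.ndarray, x0: int, y0: int, side: int) -> np.ndarray:
    """Crop a square window, zero-padding where it leaves the image."""
    h, w = image.shape
    out = np.zeros((side, side), dtype=image.dtype)
    xs0, ys0 = max(x0, 0), max(y0, 0)
    xs1, ys1 = min(x0 + side, w), min(y0 + side, h)
    if xs1 > xs0 and ys1 > ys0:
        out[ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = image[ys0:ys1, xs0:xs1]
    return out


def crop_localize(
    drr: DRRImage, bbox, out_size: int = 224, margin: float = 0.10
) -> tuple[LocalizedSample, tuple[int, int, int]]:
    """Crop a full-size DRR to one vertebra and update its calibration.

    The bounding box is expanded to a square with a margin (so crops
    keep parts of neighbouring vertebrae and soft tissue), resized to
    ``out_size`` and min-max normalized; the projection matrix is
    composed with the crop shift Q and the exact resize affine.
    Also returns the crop window for aligning segmentation masks.
    """
    x0, y0, side = _square_window(bbox, margin)
    crop = _extract_window(drr.pixels, x0, y0, side)
    image = sk_resize(crop.astype(np.float64), (out_size, out_size), order=1,
                      anti_aliasing=side > out_size, preserve_range=True)
    image = normalize_image(image)
    s = out_size / side
    p_hat = adjust_for_crop(drr.projection, CropOffset(x0, y0))
    p_hat = scale_pixels(p_hat, s, s, offset=((s - 1) / 2.0, (s - 1) / 2.0))
    sample = LocalizedSample(image=image, p_hat=p_hat, level=0,
                             view_category=drr.view_category)
    return sample, (x0, y0, side)


def warp_mask_to_crop(mask: np.ndarray, window: tuple[int, int, int],
                      out_size: int) -> np.ndarray:
    """Apply the same crop+resize to a full-size 2D mask (nearest)."""
    x0, y0, side = window
    crop = _extract_window(mask.astype(np.float32), x0, y0, side)
    out = sk_resize(crop, (out_size, out_size), order=0, anti_aliasing=False,
                    preserve_range=True)
    return out > 0.5


def make_segmented_variants(
    sample: LocalizedSample, mask2d: np.ndarray
) -> tuple[LocalizedSample, LocalizedSample]:
    """Masked-grayscale and thresholded-binary versions of a localized view."""
    if mask2d.shape != sample.image.shape:
        raise ValueError("mask shape does not match sample image")
    gray = (sample.image * mask2d).astype(np.float32)
    binary = (gray > 0).astype(np.float32)
    seg_gray = replace(sample, image=gray, variant="seg_grayscale")
    seg_bin = replace(sample, image=binary, variant="seg_binary")
    return seg_gray, seg_bin


def grid_for_level(
    vol: AttenuationVolume, level: int, resolution: int, expand: float = 1.5
) -> GridSpec:
    """Cubic grid centered on a level's 3D bounding box.

    Side length is ``expand`` times the largest bounding-box extent, so
    adjacent anatomy remains in context.
    """
    if vol.labels is None or level not in vol.present_levels():
        raise ValueError(f"level {level} absent from volume labels")
    idx = np.argwhere(vol.labels == level)
    pts = np.asarray(vol.origin) + idx * np.asarray(vol.spacing)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    side = float((hi - lo).max()) * expand
    return GridSpec.around_center((lo + hi) / 2.0, side, resolution)


def make_ground_truth_grid(
    vol: AttenuationVolume, level: int, grid: GridSpec
) -> OccupancyGrid:
    """Sample the label volume at grid voxel centers (nearest neighbour)."""
    if vol.labels is None:
        raise ValueError("volume has no labels")
    pts = grid.voxel_centers()
    idx = np.rint((pts - np.asarray(vol.origin)) / np.asarray(vol.spacing)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
    occ = np.zeros(len(pts), dtype=bool)
    ii = idx[inside]
    occ[inside] = vol.labels[ii[:, 0], ii[:, 1], ii[:, 2]] == level
    if level in vol.present_levels():
        lab_idx = np.argwhere(vol.labels == level)
        lab_pts = np.asarray(vol.origin) + lab_idx * np.asarray(vol.spacing)
        lo = np.asarray(grid.origin) - grid.spacing / 2.0
        hi = lo + grid.side_length
        if np.any(lab_pts < lo) or np.any(lab_pts >= hi):
            warnings.warn(f"grid does not fully enclose level {level}")
    r = grid.resolution
    return OccupancyGrid(occ.reshape(r, r, r), grid, binary=True)


def split_dataset(
    case_ids, fractions=(0.7, 0.2, 0.1), rng_seed: int = 0
) -> tuple[list, list, list]:
    """Patient-level shuffled split into train/validation/test lists.

    Test takes ``round(f_test * N)``, validation ``round(f_val * N)`` and
    training the remainder; partitions are disjoint and exhaustive.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    ids = list(case_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 cases to split")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    test = [ids[i] for i in order[:n_test]]
    val = [ids[i] for i in order[n_test:n_test + n_val]]
    train = [ids[i] for i in order[n_test + n_val:]]
    return train, val, test


def build_manifest(cases: list[CaseRecord], n_views: int = VIEWS_PER_PATIENT,
                   n_levels: int = LEVELS_PER_PATIENT) -> dict:
    """Enumerate the dataset: 20 full-size DRRs and 100 localized crops
    per patient (one crop per view and level)."""
    images = []
    localized = []
    for c in cases:
        for v in range(n_views):
            img_id = f"{c.case_id}_v{v:02d}"
            images.append({"id": img_id, "case_id": c.case_id, "view": v})
            for lev in range(1, n_levels + 1):
                localized.append({
                    "id": f"{img_id}_L{lev}",
                    "image_id": img_id,
                    "case_id": c.case_id,
                    "level": lev,
                })
    return {
        "n_cases": len(cases),
        "images": images,
        "localized": localized,
    }


# --------------------------------------------------------------- phantom path


@dataclass(frozen=True)
class DatasetConfig:
    """End-to-end configuration for the synthetic phantom pipeline.

    Defaults are the full-scale study conditions (224^2 crops, 128^3
    grids, sub-millimetre phantoms); the desk preset scales sizes down
    for CPU runs.
    """

    n_phantoms: int = 10
    phantom: PhantomConfig = PhantomConfig()
    full_size: tuple[int, int] = (224, 224)
    crop_size: int = 224
    grid_resolution: int = 128
    n_views: int = 4
    variant: str = "unsegmented"
    augment: bool = False
    render_step: float = 0.5
    rng_seed: int = 0

    @classmethod
    def desk(cls, n_phantoms: int = 44, rng_seed: int = 0, **kw) -> "DatasetConfig":
        """CPU-friendly scale: 2 mm phantoms, 128^2 DRRs, 64^2 crops, 32^3 grids."""
        phantom = PhantomConfig(shape=(64, 64, 96), spacing=2.0)
        defaults = dict(
            n_phantoms=n_phantoms,
            phantom=phantom,
            full_size=(128, 128),
            crop_size=64,
            grid_resolution=32,
            render_step=2.0,
            rng_seed=rng_seed,
        )
        defaults.update(kw)
        return cls(**defaults)


def _phantom_samples(
    vol: AttenuationVolume,
    case_id: str,
    cfg: DatasetConfig,
    rng: np.random.Generator,
) -> list[ReconSample]:
    """Render the selected views of one volume and cut per-level samples."""
    views = sample_view_protocol(int(rng.integers(2**31)))
    chosen = select_input_views(views, cfg.n_views, int(rng.integers(2**31)))
    fit_radius = float(np.linalg.norm(
        np.asarray(vol.shape) * np.asarray(vol.spacing)) / 2.0)
    drrs = []
    for view in chosen:
        P = make_view_projection(view, vol.center, cfg.full_size,
                                 fit_radius=fit_radius)
        drrs.append(render_drr(vol, P, cfg.full_size, step=cfg.render_step,
                               category=view.category))
    samples = []
    for level in vol.present_levels():
        grid = grid_for_level(vol, level, cfg.grid_resolution)
        gt = make_ground_truth_grid(vol, level, grid)
        images, p_hats = [], []
        for drr in drrs:
            bbox, mask = project_bbox(vol, level, drr.projection, cfg.full_size)
            loc, window = crop_localize(drr, bbox, out_size=cfg.crop_size)
            if cfg.variant != "unsegmented":
                m = warp_mask_to_crop(mask, window, cfg.crop_size)
                gray, binary = make_segmented_variants(loc, m)
                loc = gray if cfg.variant == "seg_grayscale" else binary
            images.append(loc.image)
            p_hats.append(loc.p_hat)
        samples.append(ReconSample(case_id, level, images, p_hats, grid, gt,
                                   cfg.variant,
                                   [d.view_category for d in drrs]))
    return samples


def build_phantom_dataset(cfg: DatasetConfig) -> list[ReconSample]:
    """Generate phantoms and turn them into reconstruction samples.

    With ``augment=True`` (the binary-segmented recipe) each phantom
    additionally contributes one elastically deformed copy, doubling the
    sample count.
    """
    if cfg.augment and cfg.variant != "seg_binary":
        raise ValueError("elastic augmentation is reserved for the seg_binary variant")
    rng = np.random.default_rng(cfg.rng_seed)
    out: list[ReconSample] = []
    for i in range(cfg.n_phantoms):
        pcfg = replace(cfg.phantom, rng_seed=int(rng.integers(2**31)))
        vol = make_phantom(pcfg)
        out.extend(_phantom_samples(vol, f"phantom{i:04d}", cfg, rng))
        if cfg.augment:
            spec = DeformationSpec(rng_seed=int(rng.integers(2**31)))
            warped = elastic_deform(vol, spec)
            out.extend(_phantom_samples(warped, f"phantom{i:04d}_aug", cfg, rng))
    return out
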