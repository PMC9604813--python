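"""Disk layout for simulated datasets.

A simulated dataset directory contains::

    phantoms/case0000_image.nii.gz        attenuation volume
    phantoms/case0000_label.nii.gz        per-vertebra labels
    drrs/case0000_v00.png                 full-size DRR (16-bit PNG)
    drrs/case0000_v00.json                projection sidecar (P, K, R, t)
    localized/case0000_v00_L3.png         cropped vertebra view
    localized/case0000_v00_L3.json        adjusted P-hat + grid spec
    gt/case0000_L3.nii.gz                 ground-truth occupancy grid
    manifest.json                         COCO-style images/annotations
    split.json                            patient-level train/val/test
    config.yaml                           resolved generation config

Images are stored as 16-bit grayscale PNG (lossless); volumes and grids
as NIfTI; all geometry as JSON sidecars.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .dataset import (
    DatasetConfig,
    ReconSample,
    crop_localize,
    grid_for_level,
    make_ground_truth_grid,
    make_segmented_variants,
    project_bbox,
    split_dataset,
    warp_mask_to_crop,
)
from .drr import make_view_projection, render_drr, sample_view_protocol, select_input_views
from .geometry import GridSpec, ProjectionMatrix
from .grids import OccupancyGrid
from .phantoms import make_phantom

__all__ = ["export_dataset", "load_samples", "write_png16", "read_png16", "mask_to_rle"]


def write_png16(path: Path, image: np.ndarray) -> None:
    """Save a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(image, 0.0, 1.0)
    iio.imwrite(path, (arr * 65535.0 + 0.5).astype(np.uint16))


def read_png16(path: Path) -> np.ndarray:
    return iio.imread(path).astype(np.float32) / 65535.0


def mask_to_rle(mask: np.ndarray) -> dict:
    """Column-major uncompressed run-length encoding (COCO style)."""
    flat = np.asarray(mask, bool).T.ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]]))
    counts = runs.tolist()
    if flat[0]:  # counts must start with a background run
        counts = [0] + counts
    return {"size": list(mask.shape), "counts": counts}


def export_dataset(cfg: DatasetConfig, out_dir: str | Path) -> dict:
    """Generate phantoms and write the full annotated dataset to disk."""
    out = Path(out_dir)
    for sub in ("phantoms", "drrs", "localized", "gt"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.rng_seed)
    manifest: dict = {"images": [], "annotations": [], "localized": [],
                      "categories": [{"id": lev, "name": f"L{lev}"}
                                     for lev in range(1, 6)]}
    case_ids = []
    ann_id = 0
    for i in range(cfg.n_phantoms):
        case = f"case{i:04d}"
        case_ids.append(case)
        vol = make_phantom(replace(cfg.phantom, rng_seed=int(rng.integers(2**31))))
        vol.save(out / "phantoms" / f"{case}_image.nii.gz",
                 out / "phantoms" / f"{case}_label.nii.gz")
        views = sample_view_protocol(int(rng.integers(2**31)))
        chosen = select_input_views(views, cfg.n_views, int(rng.integers(2**31)))
        fit_radius = float(np.linalg.norm(
            np.asarray(vol.shape) * np.asarray(vol.spacing)) / 2.0)
        grids = {lev: grid_for_level(vol, lev, cfg.grid_resolution)
                 for lev in vol.present_levels()}
        for lev, grid in grids.items():
            gt = make_ground_truth_grid(vol, lev, grid)
            gt.save(out / "gt" / f"{case}_L{lev}.nii.gz")
        for v, view in enumerate(chosen):
            P = make_view_projection(view, vol.center, cfg.full_size,
                                     fit_radius=fit_radius)
            drr = render_drr(vol, P, cfg.full_size, step=cfg.render_step,
                             category=view.category)
            img_id = f"{case}_v{v:02d}"
            write_png16(out / "drrs" / f"{img_id}.png", drr.pixels
                        / max(float(drr.pixels.max()), 1e-12))
            sidecar = json.loads(P.to_json())
            sidecar["category"] = view.category.value
            sidecar["focal_length"] = view.focal_length
            (out / "drrs" / f"{img_id}.json").write_text(json.dumps(sidecar))
            manifest["images"].append({
                "id": img_id, "case_id": case,
                "width": cfg.full_size[0], "height": cfg.full_size[1],
                "file_name": f"drrs/{img_id}.png",
                "view_category": view.category.value,
            })
            for lev, grid in grids.items():
                bbox, mask = project_bbox(vol, lev, P, cfg.full_size)
                loc, window = crop_localize(drr, bbox, out_size=cfg.crop_size)
                if cfg.variant != "unsegmented":
                    m = warp_mask_to_crop(mask, window, cfg.crop_size)
                    gray, binary = make_segmented_variants(loc, m)
                    loc = gray if cfg.variant == "seg_grayscale" else binary
                loc_id = f"{img_id}_L{lev}"
                write_png16(out / "localized" / f"{loc_id}.png", loc.image)
                loc_sidecar = json.loads(loc.p_hat.to_json())
                loc_sidecar.update({
                    "level": lev, "grid": grid.to_dict(),
                    "gt": f"gt/{case}_L{lev}.nii.gz",
                    "category": view.category.value,
                    "variant": cfg.variant,
                })
                (out / "localized" / f"{loc_id}.json").write_text(
                    json.dumps(loc_sidecar))
                ann_id += 1
                manifest["annotations"].append({
                    "id": ann_id, "image_id": img_id, "category_id": lev,
                    "bbox": list(bbox), "segmentation": mask_to_rle(mask),
                    "area": int(np.count_nonzero(mask)),
                })
                manifest["localized"].append({
                    "id": loc_id, "image_id": img_id, "case_id": case,
                    "level": lev, "file_name": f"localized/{loc_id}.png",
                })
    splits = split_dataset(case_ids, rng_seed=cfg.rng_seed)
    split_d = dict(zip(("train", "val", "test"), splits))
    (out / "split.json").write_text(json.dumps(split_d, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest))
    (out / "config.yaml").write_text(yaml.safe_dump(_cfg_dict(cfg)))
    return manifest


def _cfg_dict(cfg: DatasetConfig) -> dict:
    d = asdict(cfg)
    d["full_size"] = list(cfg.full_size)
    d["phantom"]["shape"] = list(cfg.phantom.shape)
    for k in ("body_radius_range", "body_height_range", "canal_radius_range",
              "process_length_range"):
        d["phantom"][k] = list(d["phantom"][k])
    return d


def load_samples(data_dir: str | Path, split: str = "train") -> list[ReconSample]:
    """Load reconstruction samples of one split from an exported dataset."""
    root = Path(data_dir)
    split_d = json.loads((root / "split.json").read_text())
    if split not in split_d:
        raise ValueError(f"unknown split {split!r}")
    wanted = set(split_d[split])
    manifest = json.loads((root / "manifest.json").read_text())
    by_case_level: dict[tuple, list] = {}
    for entry in manifest["localized"]:
        if entry["case_id"] in wanted:
            by_case_level.setdefault((entry["case_id"], entry["level"]),
                                     []).append(entry)
    samples = []
    from .drr import ViewCategory

    for (case, lev), entries in sorted(by_case_level.items()):
        images, p_hats, cats = [], [], []
        grid = gt = None
        for e in entries:
            sidecar = json.loads((root / "localized" / f"{e['id']}.json").read_text())
            images.append(read_png16(root / e["file_name"]))
            p_hats.append(ProjectionMatrix.from_json(json.dumps(sidecar)))
            cats.append(ViewCategory(sidecar["category"]))
            grid = GridSpec.from_dict(sidecar["grid"])
            gt = OccupancyGrid.load(root / sidecar["gt"])
        samples.append(ReconSample(case, lev, images, p_hats, grid, gt,
                                   view_categories=cats))
    return samples
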