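"""Dataset construction: filtering, crops, occupancy targets, splits."""

import numpy as np
import pytest

from spinerecon.dataset import (
    CaseRecord,
    DatasetConfig,
    LocalizedSample,
    build_manifest,
    build_phantom_dataset,
    crop_localize,
    filter_cases,
    grid_for_level,
    make_ground_truth_grid,
    make_segmented_variants,
    project_bbox,
    split_dataset,
    warp_mask_to_crop,
)
from spinerecon.drr import DRRImage, ViewCategory, make_view_projection, render_drr, sample_view_protocol
from spinerecon.geometry import GridSpec, project_point
from spinerecon.volume import AttenuationVolume


def _ok_record(i=0, **kw):
    d = dict(case_id=f"c{i}", spacing=(0.8, 0.8, 0.8), shape=(512, 512, 300),
             present_levels=(1, 2, 3, 4, 5), synostosis=False)
    d.update(kw)
    return CaseRecord(**d)


class TestFilterCases:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(spacing=(0.8, 0.8, 1.2)),
            dict(shape=(512, 512, 100)),
            dict(present_levels=(1, 2, 3, 4)),
            dict(synostosis=True),
        ],
    )
    def test_excludes_violations(self, kw):
        assert filter_cases([_ok_record(**kw)]) == []

    def test_keeps_compliant_case(self):
        r = _ok_record()
        assert filter_cases([r]) == [r]


class TestSplitDataset:
    def test_sizes_for_ten_cases(self):
        tr, va, te = split_dataset([f"p{i}" for i in range(10)], rng_seed=1)
        assert (len(tr), len(va), len(te)) == (7, 2, 1)

    def test_disjoint_and_exhaustive(self):
        ids = [f"p{i}" for i in range(23)]
        tr, va, te = split_dataset(ids, rng_seed=5)
        assert set(tr) | set(va) | set(te) == set(ids)
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            split_dataset(["a", "b"])


class TestBuildManifest:
    def test_counts_per_patient(self):
        m = build_manifest([_ok_record(0)])
        assert len(m["images"]) == 20
        assert len(m["localized"]) == 100

    def test_full_cohort_counts(self):
        cases = [_ok_record(i) for i in range(871)]
        m = build_manifest(cases)
        assert len(m["images"]) == 17_420
        assert len(m["localized"]) == 87_100


def _single_voxel_volume():
    vals = np.zeros((41, 41, 41), np.float32)
    lab = np.zeros_like(vals, dtype=np.int16)
    vals[20, 20, 20] = 0.05
    lab[20, 20, 20] = 1
    origin = (-20.0, -20.0, -20.0)
    return AttenuationVolume(vals, (1, 1, 1), origin, labels=lab)


class TestProjectBbox:
    def test_single_voxel_projects_to_single_pixel(self):
        vol = _single_voxel_volume()
        from spinerecon.drr import ViewSpec

        P = make_view_projection(ViewSpec(ViewCategory.AP, 0, 0, 900.0),
                                 (0, 0, 0), (65, 65))
        bbox, mask = project_bbox(vol, 1, P, (65, 65))
        assert bbox == (32, 32, 1, 1)
        assert mask.sum() == 1 and mask[32, 32]

    def test_cube_bbox_matches_corner_projection(self):
        vals = np.zeros((41, 41, 41), np.float32)
        lab = np.zeros_like(vals, dtype=np.int16)
        lab[15:26, 15:26, 15:26] = 2
        vals[lab > 0] = 0.05
        vol = AttenuationVolume(vals, (1, 1, 1), (-20, -20, -20), labels=lab)
        from spinerecon.drr import ViewSpec

        P = make_view_projection(ViewSpec(ViewCategory.AP, 0, 0, 1000.0),
                                 (0, 0, 0), (129, 129))
        bbox, _ = project_bbox(vol, 2, P, (129, 129))
        corners = np.array([(x, y, z) for x in (-5, 5) for y in (-5, 5)
                            for z in (-5, 5)], float)
        pix = np.array([project_point(P, c)[0] for c in corners])
        x0, y0 = pix.min(axis=0)
        x1, y1 = pix.max(axis=0)
        assert abs(bbox[0] - x0) <= 1 and abs(bbox[1] - y0) <= 1
        assert abs(bbox[0] + bbox[2] - 1 - x1) <= 1
        assert abs(bbox[1] + bbox[3] - 1 - y1) <= 1

    def test_absent_level_raises(self):
        vol = _single_voxel_volume()
        from spinerecon.drr import ViewSpec

        P = make_view_projection(ViewSpec(ViewCategory.AP, 0, 0, 900.0),
                                 (0, 0, 0), (65, 65))
        with pytest.raises(ValueError):
            project_bbox(vol, 3, P, (65, 65))


class TestCropLocalize:
    def _render(self, desk_phantom, seed=0):
        from spinerecon.drr import select_input_views

        views = sample_view_protocol(seed)
        view = select_input_views(views, 4, seed)[0]
        r = float(np.linalg.norm(np.asarray(desk_phantom.shape)
                                 * np.asarray(desk_phantom.spacing)) / 2)
        P = make_view_projection(view, desk_phantom.center, (128, 128), fit_radius=r)
        return render_drr(desk_phantom, P, (128, 128), step=2.0,
                          category=view.category)

    def test_landmark_reprojection_within_half_pixel(self, desk_phantom):
        """A world point visible in the crop lands on the same feature after
        crop + resize, under the updated projection matrix."""
        drr = self._render(desk_phantom)
        for level in (1, 3, 5):
            bbox, _ = project_bbox(desk_phantom, level, drr.projection, (128, 128))
            loc, window = crop_localize(drr, bbox, out_size=64)
            idx = np.argwhere(desk_phantom.labels == level)
            X = np.asarray(desk_phantom.origin) + idx.mean(axis=0) * np.asarray(
                desk_phantom.spacing)
            pix_full, _ = project_point(drr.projection, X)
            pix_crop, _ = project_point(loc.p_hat, X)
            x0, y0, side = window
            s = 64 / side
            expected = ((pix_full - np.array([x0, y0])) + 0.5) * s - 0.5
            assert np.allclose(pix_crop, expected, atol=0.5)

    def test_full_image_bbox_keeps_projection_up_to_resize(self, desk_phantom):
        drr = self._render(desk_phantom)
        loc, window = crop_localize(drr, (0, 0, 128, 128), out_size=64, margin=0.0)
        assert window == (0, 0, 128)
        X = desk_phantom.center + np.array([10.0, 5.0, -8.0])
        a, _ = project_point(drr.projection, X)
        b, _ = project_point(loc.p_hat, X)
        assert np.allclose(b, (a + 0.5) * 0.5 - 0.5, atol=1e-9)

    def test_output_normalized(self, desk_phantom):
        drr = self._render(desk_phantom)
        bbox, _ = project_bbox(desk_phantom, 2, drr.projection, (128, 128))
        loc, _ = crop_localize(drr, bbox, out_size=64)
        assert loc.image.shape == (64, 64)
        assert loc.image.min() == 0.0 and loc.image.max() == pytest.approx(1.0)

    def test_degenerate_bbox_raises(self, desk_phantom):
        drr = self._render(desk_phantom)
        with pytest.raises(ValueError):
            crop_localize(drr, (10, 10, 0, 5))


class TestSegmentedVariants:
    def _sample(self, image):
        from spinerecon.geometry import Extrinsics, Intrinsics, compose_projection

        P = compose_projection(Intrinsics(900.0, (1, 1), (4, 4)),
                               Extrinsics(np.eye(3), np.zeros(3)))
        return LocalizedSample(image=image.astype(np.float32), p_hat=P, level=1)

    def test_full_mask_preserves_image(self, rng):
        img = rng.random((4, 4)).astype(np.float32)
        gray, _ = make_segmented_variants(self._sample(img), np.ones((4, 4), bool))
        assert np.array_equal(gray.image, img)

    def test_empty_mask_blanks_both(self, rng):
        img = rng.random((4, 4)).astype(np.float32)
        gray, binary = make_segmented_variants(self._sample(img),
                                               np.zeros((4, 4), bool))
        assert not gray.image.any() and not binary.image.any()

    def test_binary_is_elementwise_threshold(self):
        img = np.array([[0.0, 0.4], [0.0, 0.9]], np.float32)
        mask = np.array([[1, 1], [0, 1]], bool)
        gray, binary = make_segmented_variants(self._sample(img), mask)
        assert np.array_equal(gray.image, img * mask)
        assert np.array_equal(binary.image, (img * mask > 0).astype(np.float32))
        assert set(np.unique(binary.image)) <= {0.0, 1.0}

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            make_segmented_variants(self._sample(rng.random((4, 4))),
                                    np.ones((5, 5), bool))


class TestGroundTruthGrid:
    def test_cube_occupancy_fraction(self):
        vals = np.zeros((40, 40, 40), np.float32)
        lab = np.zeros_like(vals, np.int16)
        lab[10:30, 10:30, 10:30] = 1  # 20 mm cube at 1 mm spacing
        vol = AttenuationVolume(vals + 0.01, (1, 1, 1), (0, 0, 0), labels=lab)
        grid = GridSpec.around_center((19.5, 19.5, 19.5), 40.0, 40)
        occ = make_ground_truth_grid(vol, 1, grid)
        expect = 20.0**3 / 40.0**3
        shell = 6 * 20.0**2 * grid.spacing / 40.0**3  # one-voxel surface band
        assert abs(occ.occupancy_fraction() - expect) <= shell

    def test_absent_level_gives_empty_grid(self, desk_phantom):
        grid = GridSpec.around_center(desk_phantom.center, 60.0, 16)
        occ = make_ground_truth_grid(desk_phantom, 9, grid)
        assert not occ.values.any()

    def test_regeneration_is_bit_identical(self, desk_phantom):
        grid = grid_for_level(desk_phantom, 2, 32)
        a = make_ground_truth_grid(desk_phantom, 2, grid)
        b = make_ground_truth_grid(desk_phantom, 2, grid)
        assert np.array_equal(a.values, b.values)

    def test_warns_when_grid_too_small(self, desk_phantom):
        grid = grid_for_level(desk_phantom, 2, 16, expand=0.5)
        with pytest.warns(UserWarning):
            make_ground_truth_grid(desk_phantom, 2, grid)

    def test_grid_for_level_contains_vertebra(self, desk_phantom):
        grid = grid_for_level(desk_phantom, 3, 32)
        occ = make_ground_truth_grid(desk_phantom, 3, grid)
        assert occ.values.any()
        idx = np.argwhere(desk_phantom.labels == 3)
        pts = np.asarray(desk_phantom.origin) + idx * np.asarray(desk_phantom.spacing)
        lo = np.asarray(grid.origin) - grid.spacing / 2
        assert np.all(pts >= lo) and np.all(pts < lo + grid.side_length)


class TestPhantomPipeline:
    def test_samples_have_consistent_geometry(self, desk_samples):
        assert len(desk_samples) == 10  # 2 phantoms x 5 levels
        s = desk_samples[0]
        assert len(s.images) == len(s.p_hats) == 4
        cats = sorted(c.value for c in s.view_categories)
        assert cats == sorted(c.value for c in ViewCategory)
        assert s.gt.values.shape == (32, 32, 32)
        assert 0.005 < s.gt.occupancy_fraction() < 0.5

    def test_augmentation_doubles_samples(self):
        cfg = DatasetConfig.desk(n_phantoms=1, rng_seed=2, variant="seg_binary",
                                 augment=True)
        assert len(build_phantom_dataset(cfg)) == 10
        bad = DatasetConfig.desk(n_phantoms=1, variant="unsegmented", augment=True)
        with pytest.raises(ValueError):
            build_phantom_dataset(bad)

    def test_binary_variant_images_are_binary(self):
        cfg = DatasetConfig.desk(n_phantoms=1, rng_seed=2, variant="seg_binary")
        for s in build_phantom_dataset(cfg):
            for img in s.images:
                assert set(np.unique(img)) <= {0.0, 1.0}

    def test_mask_warp_follows_crop(self, desk_phantom):
        mask = np.zeros((128, 128), bool)
        mask[40:60, 30:50] = True
        out = warp_mask_to_crop(mask, (30, 40, 20), 64)
        assert out.shape == (64, 64)
        assert out.all()
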