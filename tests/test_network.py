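"""Reconstruction network: shapes, back-projection, fusion, gradients."""

import numpy as np
import pytest

from spinerecon import autodiff as ad
from spinerecon.autodiff import Tensor
from spinerecon.drr import ViewCategory, ViewSpec, make_view_projection, pixel_ray
from spinerecon.geometry import GridSpec, ProjectionMatrix
from spinerecon.network import (
    ModelConfig,
    ReconstructionNet,
    backproject,
    fuse_average,
)

TINY = ModelConfig(encoder_channels=(8, 16), refiner_channels=(4, 8),
                   n_feature_channels=8, grid_resolution=16, input_size=32)


@pytest.fixture(scope="module")
def desk_net():
    return ReconstructionNet(ModelConfig.desk(rng_seed=0))


@pytest.fixture(scope="module")
def tiny_net():
    return ReconstructionNet(TINY)


def _ortho_p(scale=1.0):
    """Orthographic-style rank-3 matrix mapping (x, y, z) -> (x, y)."""
    P = np.array([[scale, 0, 0, 0], [0, scale, 0, 0], [0, 0, 0, 1.0]])
    return ProjectionMatrix(P)


class TestEncoder:
    def test_desk_input_maps_to_half_resolution_32_channels(self, desk_net, rng):
        fmap = desk_net.encode(rng.random((64, 64)).astype(np.float32))
        assert fmap.shape == (32, 32, 32)

    def test_zero_input_finite(self, desk_net):
        fmap = desk_net.encode(np.zeros((64, 64), np.float32))
        assert np.all(np.isfinite(fmap.data))

    def test_wrong_size_rejected(self, desk_net, rng):
        with pytest.raises(ValueError):
            desk_net.encode(rng.random((48, 48)))

    def test_unnormalized_input_rejected(self, desk_net, rng):
        with pytest.raises(ValueError):
            desk_net.encode(rng.random((64, 64)) * 300.0)


class TestBackproject:
    def test_constant_feature_map_fills_frustum(self):
        fmap = Tensor(np.full((3, 8, 8), 2.5, np.float32), requires_grad=False)
        grid = GridSpec(16, (0.0, 0.0, 0.0), 0.25)  # x, y in [0, 3.75]
        out = backproject(fmap, _ortho_p(), grid)
        assert out.shape == (3, 16, 16, 16)
        # voxels whose (x, y) lie strictly inside the map read the constant
        inner = out.data[:, 4:12, 4:12, :]
        assert np.allclose(inner, 2.5, atol=1e-6)

    def test_integer_pixel_reads_exact_feature(self, rng):
        fmap_np = rng.random((2, 8, 8)).astype(np.float32)
        fmap = Tensor(fmap_np, requires_grad=False)
        grid = GridSpec(16, (0.0, 0.0, 0.0), 1.0)
        out = backproject(fmap, _ortho_p(), grid)
        # voxel (3, 5, k) projects to pixel (u=3, v=5) exactly
        for k in (0, 7):
            assert np.allclose(out.data[:, 3, 5, k], fmap_np[:, 5, 3])

    def test_behind_camera_and_outside_are_zero(self, rng):
        fmap = Tensor(rng.random((2, 8, 8)).astype(np.float32), requires_grad=False)
        # perspective camera at origin looking along +z
        P = ProjectionMatrix(np.hstack([np.eye(3), np.zeros((3, 1))]))
        behind = GridSpec(16, (-2.0, -2.0, -20.0), 0.25)  # z < 0
        out = backproject(fmap, P, behind)
        assert not out.data.any()

    def test_mass_concentrates_along_pixel_ray(self):
        """A one-hot feature pixel back-projects onto (a tube around) its ray."""
        view = ViewSpec(ViewCategory.AP, 0.0, 0.0, 900.0)
        P = make_view_projection(view, (0.0, 0.0, 0.0), (32, 32))
        # voxel pitch (0.5 mm) projects to ~0.7 px: the map is oversampled
        grid = GridSpec(32, (-8.0, -8.0, -8.0), 0.5)
        fmap_np = np.zeros((1, 32, 32), np.float32)
        fmap_np[0, 18, 14] = 1.0
        out = backproject(Tensor(fmap_np, requires_grad=False), P, grid)
        ray = pixel_ray(P, (14, 18))
        hot = np.argwhere(out.data[0] > 0.5 * out.data.max())
        assert len(hot) > 0
        pts = np.asarray(grid.origin) + hot * grid.spacing
        rel = pts - ray.source
        along = rel @ ray.direction
        perp = np.linalg.norm(rel - along[:, None] * ray.direction, axis=1)
        assert np.all(perp <= 2.0 * grid.spacing)


class TestFusion:
    def test_identical_grids_average_to_themselves(self, rng):
        g = Tensor(rng.random((2, 4, 4, 4)).astype(np.float32))
        out = fuse_average([g, g, g])
        assert np.allclose(out.data, g.data, atol=1e-7)

    def test_constants_average(self):
        a = Tensor(np.zeros((1, 2, 2, 2), np.float32))
        b = Tensor(np.ones((1, 2, 2, 2), np.float32))
        assert np.allclose(fuse_average([a, b]).data, 0.5)

    def test_permutation_invariance_bitwise(self, rng):
        gs = [Tensor(rng.random((2, 4, 4, 4)).astype(np.float32)) for _ in range(4)]
        assert np.array_equal(fuse_average(gs).data, fuse_average(gs[::-1]).data)

    def test_shape_mismatch_rejected(self, rng):
        a = Tensor(rng.random((1, 4, 4, 4)).astype(np.float32))
        b = Tensor(rng.random((1, 2, 2, 2)).astype(np.float32))
        with pytest.raises(ValueError):
            fuse_average([a, b])
        with pytest.raises(ValueError):
            fuse_average([])


class TestReconstruct:
    def _views(self, net, rng, n=4):
        size = net.cfg.input_size
        grid = GridSpec(net.cfg.grid_resolution, (-24.0, -24.0, -24.0),
                        48.0 / net.cfg.grid_resolution)
        images, p_hats = [], []
        for orb in np.linspace(0, 135, n):
            view = ViewSpec(ViewCategory.MISC, float(orb), 5.0, 900.0)
            P = make_view_projection(view, (0.0, 0.0, 0.0), (size, size),
                                     fit_radius=42.0)
            images.append(rng.random((size, size)).astype(np.float32))
            p_hats.append(P)
        return images, p_hats, grid

    def test_output_shapes_and_range(self, tiny_net, rng):
        images, p_hats, grid = self._views(tiny_net, rng)
        probs, binary = tiny_net.reconstruct(images, p_hats, grid)
        r = tiny_net.cfg.grid_resolution
        assert probs.values.shape == (r, r, r)
        assert probs.values.min() > 0 and probs.values.max() < 1
        assert binary.binary and binary.values.dtype == bool

    def test_view_order_permutation_bit_identical(self, tiny_net, rng):
        images, p_hats, grid = self._views(tiny_net, rng)
        a, _ = tiny_net.reconstruct(images, p_hats, grid)
        order = [2, 0, 3, 1]
        b, _ = tiny_net.reconstruct([images[i] for i in order],
                                    [p_hats[i] for i in order], grid)
        assert np.array_equal(a.values, b.values)

    def test_duplicated_view_equals_single_view(self, tiny_net, rng):
        images, p_hats, grid = self._views(tiny_net, rng)
        a, _ = tiny_net.reconstruct([images[0]] * 4, [p_hats[0]] * 4, grid)
        b, _ = tiny_net.reconstruct([images[0]], [p_hats[0]], grid)
        assert np.allclose(a.values, b.values, atol=1e-6)

    def test_mismatched_lengths_rejected(self, tiny_net, rng):
        images, p_hats, grid = self._views(tiny_net, rng)
        with pytest.raises(ValueError):
            tiny_net.reconstruct(images[:3], p_hats, grid)

    def test_deterministic_for_fixed_weights(self, tiny_net, rng):
        images, p_hats, grid = self._views(tiny_net, rng)
        a, _ = tiny_net.reconstruct(images, p_hats, grid)
        b, _ = tiny_net.reconstruct(images, p_hats, grid)
        assert np.array_equal(a.values, b.values)


class TestGradientFlow:
    def test_loss_reaches_first_encoder_layer_through_backprojection(self, rng):
        net = ReconstructionNet(TINY)
        images = [rng.random((32, 32)).astype(np.float32) for _ in range(2)]
        p_hats = []
        for orb in (0.0, 90.0):
            view = ViewSpec(ViewCategory.AP, orb, 0.0, 900.0)
            p_hats.append(make_view_projection(view, (0.0, 0.0, 0.0), (32, 32),
                                               fit_radius=20.0))
        grid = GridSpec(16, (-12.0, -12.0, -12.0), 1.5)
        target = (rng.random((16, 16, 16)) > 0.9).astype(np.float32)
        logits = net.forward(images, p_hats, grid)
        loss = ad.bce_with_logits(logits, target)
        loss.backward()
        first_w = net.encoder.down[0].w1
        assert first_w.grad is not None
        assert np.all(np.isfinite(first_w.grad))
        assert np.any(first_w.grad != 0)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_net, rng, tmp_path):
        path = tmp_path / "net.npz"
        tiny_net.save(path)
        loaded = ReconstructionNet.load(path)
        assert loaded.cfg == tiny_net.cfg
        for a, b in zip(tiny_net.parameters(), loaded.parameters()):
            assert np.array_equal(a.data, b.data)


class TestModelConfig:
    def test_grid_resolution_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(grid_resolution=24)
        with pytest.raises(ValueError):
            ModelConfig(grid_resolution=8)

    def test_default_matches_paperlike_dimensions(self):
        cfg = ModelConfig()
        assert cfg.input_size == 224 and cfg.feature_size == 112
        assert cfg.grid_resolution == 128
        assert cfg.n_feature_channels == 32


class TestMaskedFusion:
    def test_masked_mean_counts_only_seeing_views(self, rng):
        from spinerecon import autodiff as ad

        a = Tensor(np.full((1, 2, 2, 2), 2.0, np.float32))
        b = Tensor(np.full((1, 2, 2, 2), 4.0, np.float32))
        ma = np.ones((2, 2, 2), bool)
        mb = np.zeros((2, 2, 2), bool)
        mb[0] = True  # second view sees only half the grid
        out = fuse_average([a, b], masks=[ma, mb])
        assert np.allclose(out.data[0, 0], 3.0)  # both views
        assert np.allclose(out.data[0, 1], 2.0)  # only the first view

    def test_backproject_mask_marks_frustum(self, rng):
        fmap = Tensor(rng.random((2, 8, 8)).astype(np.float32),
                      requires_grad=False)
        grid = GridSpec(16, (0.0, 0.0, 0.0), 1.0)
        out, mask = backproject(fmap, _ortho_p(), grid, return_mask=True)
        assert mask.shape == (16, 16, 16)
        assert mask[3, 5, 0] and not mask[12, 3, 0]  # u=12 beyond the 8-wide map
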