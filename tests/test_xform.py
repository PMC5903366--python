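"""Reflection, chain resampling, affine registration, reflection warp."""

import numpy as np
import pytest

import atlasforge as af
from atlasforge.xform import Reflection, TransformChain, apply_chain


def _translation(t):
    m = np.eye(4)
    m[:3, 3] = t
    return af.AffineTransform(m)


def _scaling(s, center=(0.0, 0.0, 0.0)):
    m = np.eye(4)
    m[:3, :3] = np.eye(3) * s
    m[:3, 3] = np.asarray(center) - s * np.asarray(center)
    return af.AffineTransform(m)


class TestReflectMidsagittal:
    def test_single_voxel_maps_across_plane(self):
        grid = af.VoxelGrid.create((21, 9, 9), (1, 1, 1), centered=True)
        data = np.zeros(grid.shape, np.uint8)
        data[17, 4, 4] = 1  # world x = +7
        vol = af.LabeledVolume(grid, data, "binary")
        out = af.reflect_midsagittal(vol)
        pos = grid.index_to_world(np.argwhere(out.data))
        assert np.allclose(pos, [[-7.0, 0.0, 0.0]])

    def test_involution_bit_exact_for_binary(self):
        grid = af.VoxelGrid.create((16, 8, 8), (0.7, 0.7, 0.7), centered=True)
        rng = np.random.default_rng(4)
        vol = af.LabeledVolume(
            grid, (rng.random(grid.shape) < 0.3).astype(np.uint8), "binary"
        )
        twice = af.reflect_midsagittal(af.reflect_midsagittal(vol))
        assert np.array_equal(twice.data, vol.data)
        assert af.reflect_midsagittal(vol).foreground_count == vol.foreground_count

    def test_voxel_on_plane_is_fixed_point(self):
        grid = af.VoxelGrid.create((21, 5, 5), (1, 1, 1), centered=True)
        data = np.zeros(grid.shape, np.uint8)
        data[10, 2, 2] = 1  # world x = 0 exactly
        out = af.reflect_midsagittal(af.LabeledVolume(grid, data, "binary"))
        assert np.array_equal(out.data, data)

    def test_oblique_grid_rejected(self):
        aff = np.eye(4)
        aff[0, 1] = 0.3  # shear: not axis-aligned
        grid = af.VoxelGrid((8, 8, 8), aff)
        vol = af.LabeledVolume(grid, np.zeros(grid.shape, np.uint8), "binary")
        with pytest.raises(af.GeometryError):
            af.reflect_midsagittal(vol)

    def test_nonzero_plane_offset(self):
        grid = af.VoxelGrid.create((21, 9, 9), (1, 1, 1), centered=True)
        data = np.zeros(grid.shape, np.uint8)
        data[14, 4, 4] = 1  # world x = +4
        out = af.reflect_midsagittal(af.LabeledVolume(grid, data, "binary"), plane_x=2.0)
        pos = grid.index_to_world(np.argwhere(out.data))
        assert np.allclose(pos, [[0.0, 0.0, 0.0]])  # 2*2 - 4


class TestTransformChain:
    def test_reflection_only_first(self):
        with pytest.raises(af.ValidationError):
            TransformChain([_translation((1, 0, 0)), Reflection()])

    def test_forward_then_inverse_is_identity(self):
        grid = af.VoxelGrid.create((10, 10, 10), (1, 1, 1), centered=True)
        rng = np.random.default_rng(7)
        fld = af.DisplacementField(
            grid,
            np.stack(
                [ndi_smooth(rng.standard_normal(grid.shape), 2.0) for _ in range(3)],
                axis=-1,
            ),
        )
        chain = TransformChain([Reflection(), _translation((0.5, -1.0, 2.0)), fld])
        pts = rng.uniform(-3, 3, (50, 3))
        back = chain.inverse_map_points(chain.map_points(pts))
        assert np.allclose(back, pts, atol=0.02)  # fixed-point inversion tolerance


def ndi_smooth(x, sigma):
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(x, sigma)


class TestApplyChain:
    def test_identity_chain_reproduces_interior(self):
        grid = af.VoxelGrid.create((16, 16, 16), (1, 1, 1))
        rng = np.random.default_rng(2)
        vol = af.LabeledVolume(grid, rng.random(grid.shape), "intensity")
        out = apply_chain(vol, TransformChain([af.AffineTransform.identity()]), grid)
        interior = (slice(2, -2),) * 3
        assert np.allclose(out.data[interior], vol.data[interior], atol=1e-6)

    def test_constant_probability_reproduced(self):
        grid = af.VoxelGrid.create((16, 16, 16), (1, 1, 1))
        vol = af.LabeledVolume(grid, np.full(grid.shape, 0.4), "probability")
        chain = TransformChain([_translation((0.3, -0.2, 0.15))])
        out = apply_chain(vol, chain, grid)
        interior = (slice(2, -2),) * 3
        assert np.allclose(out.data[interior], 0.4, atol=1e-6)

    def test_step_edge_overshoots_then_clips(self):
        grid = af.VoxelGrid.create((16, 16, 16), (1, 1, 1))
        step = np.zeros(grid.shape)
        step[:8] = 1.0
        vol = af.LabeledVolume(grid, step, "probability")
        chain = TransformChain([_translation((0.5, 0, 0))])
        raw = apply_chain(vol, chain, grid, clip=False)
        assert raw.data.min() < 0.0 and raw.data.max() > 1.0  # cubic ringing
        clipped = apply_chain(vol, chain, grid)
        assert clipped.data.min() == 0.0 and clipped.data.max() == 1.0
        assert clipped.kind == "probability"

    def test_nearest_preserves_index_value_set(self):
        grid = af.VoxelGrid.create((12, 12, 12), (1, 1, 1))
        rng = np.random.default_rng(3)
        vol = af.LabeledVolume(
            grid, rng.integers(0, 4, grid.shape).astype(np.int32), "index"
        )
        chain = TransformChain([_translation((0.4, 0.4, 0.4))], interpolation="nearest")
        out = apply_chain(vol, chain, grid)
        assert set(np.unique(out.data)) <= set(np.unique(vol.data))

    def test_index_with_smooth_interpolation_rejected(self):
        grid = af.VoxelGrid.create((8, 8, 8), (1, 1, 1))
        vol = af.LabeledVolume(grid, np.zeros(grid.shape, np.int32), "index")
        with pytest.raises(af.ValidationError):
            apply_chain(vol, TransformChain([af.AffineTransform.identity()]), grid)

    def test_binary_promoted_to_probability(self):
        grid = af.VoxelGrid.create((12, 12, 12), (1, 1, 1))
        data = np.zeros(grid.shape, np.uint8)
        data[4:8] = 1
        vol = af.LabeledVolume(grid, data, "binary")
        out = apply_chain(vol, TransformChain([_translation((0.5, 0, 0))]), grid)
        assert out.kind == "probability"

    def test_constant_displacement_field_acts_as_translation(self):
        grid = af.VoxelGrid.create((16, 16, 16), (1, 1, 1), centered=True)
        data = np.zeros(grid.shape)
        data[8, 8, 8] = 1.0
        vol = af.LabeledVolume(grid, data, "intensity")
        fld = af.DisplacementField(grid, np.broadcast_to([2.0, 0, 0], grid.shape + (3,)).copy())
        out_field = apply_chain(vol, TransformChain([fld], "linear"), grid)
        out_affine = apply_chain(
            vol, TransformChain([_translation((2.0, 0, 0))], "linear"), grid
        )
        assert np.allclose(out_field.data, out_affine.data, atol=1e-6)

    def test_probability_mass_conserved_under_rigid_chain(self):
        # smooth phantom label well inside the FOV; rotation+translation
        # resampling should conserve probability mass to < 1%
        grid = af.VoxelGrid.create((48, 48, 48), (1, 1, 1), centered=True)
        spec = af.PhantomSpec(
            grid=grid,
            regions=[af.PhantomRegion("Pu", (-8, 0, 0), (5, 4, 3))],
            seed=9,
        )
        prob = af.make_ground_truth(spec)[0].labels["Pu"]
        ang = np.deg2rad(5.0)
        rot = np.eye(4)
        rot[:3, :3] = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        rot[:3, 3] = (1.1, -0.7, 0.4)
        chain = TransformChain([af.AffineTransform(rot)])
        out = apply_chain(prob, chain, prob.grid)
        assert af.prob_volume(out) == pytest.approx(af.prob_volume(prob), rel=0.01)


@pytest.fixture(scope="module")
def blob():
    spec = af.PhantomSpec(
        grid=af.VoxelGrid.create((32, 32, 32), (1.4, 1.4, 1.4), centered=True),
        regions=[af.PhantomRegion("Pu", (-8, 0, 0), (6, 5, 4))],
        seed=3,
    )
    return af.make_ground_truth(spec)[2]


class TestRegisterAffine:

    def test_self_registration_is_identity(self, blob):
        t = af.register_affine(blob, blob)
        assert np.abs(t.matrix[:3, 3]).max() < 1e-3
        assert np.abs(t.matrix[:3, :3] - np.eye(3)).max() < 1e-3

    def test_translation_recovery(self, blob):
        # moving = fixed translated by +2.1 mm: forward map ~ (-2.1, 0, 0)
        chain = TransformChain([_translation((2.1, 0, 0))], "linear")
        moving = apply_chain(blob, chain, blob.grid)
        t = af.register_affine(moving, blob)
        err = np.abs(t.matrix[:3, 3] - np.array([-2.1, 0, 0]))
        assert err.max() < 0.25 * 1.4  # 0.25 voxel

    def test_scale_recovery(self, blob):
        # moving = fixed scaled 1.05 about the image centre: recovered ~ 1/1.05
        chain = TransformChain([_scaling(1.05)], "linear")
        moving = apply_chain(blob, chain, blob.grid)
        t = af.register_affine(moving, blob)
        recovered = np.linalg.det(t.matrix[:3, :3]) ** (1 / 3)
        assert recovered == pytest.approx(1 / 1.05, rel=0.01)

    def test_deterministic(self, blob):
        chain = TransformChain([_translation((1.0, -0.5, 0.7))], "linear")
        moving = apply_chain(blob, chain, blob.grid)
        t1 = af.register_affine(moving, blob)
        t2 = af.register_affine(moving, blob)
        assert np.array_equal(t1.matrix, t2.matrix)


@pytest.fixture(scope="module")
def left_label():
    spec = af.PhantomSpec(
        grid=af.VoxelGrid.create((48, 48, 48), (1, 1, 1), centered=True),
        regions=[af.PhantomRegion("Pu", (-8, 0, 0), (5, 4, 3))],
        seed=5,
    )
    return af.make_ground_truth(spec)[0].labels["Pu"]


class TestReflectionWarp:

    def test_identity_warp_preserves_volume(self, left_label):
        out = af.reflection_warp(left_label)
        assert af.prob_volume(out) == pytest.approx(
            af.prob_volume(left_label), rel=0.005
        )
        # mass landed in the right hemisphere
        x = out.grid.voxel_centers()[:, 0].reshape(out.grid.shape)
        assert out.data[x < 0].sum() < 0.01 * out.data.sum()

    def test_scaling_warp_follows_jacobian(self, left_label):
        out = af.reflection_warp(left_label, _scaling(1.1))
        assert af.prob_volume(out) == pytest.approx(
            1.1**3 * af.prob_volume(left_label), rel=0.02
        )

    def test_empty_left_gives_empty_right(self, unit_grid):
        empty = af.LabeledVolume(unit_grid, np.zeros(unit_grid.shape), "probability")
        out = af.reflection_warp(empty)
        assert out.foreground_count == 0

    def test_bilateral_union(self, left_label):
        right = af.reflection_warp(left_label)
        both = af.bilateral_label(left_label, right)
        assert af.prob_volume(both) == pytest.approx(
            af.prob_volume(left_label) + af.prob_volume(right), rel=0.01
        )


def test_syn_preset_matches_published_parameters():
    preset = af.load_syn_preset()
    assert preset["syn_gradient_step"] == 0.25
    assert preset["syn_gaussian_regularization_sigma_voxels"] == 3.0
    assert preset["multiscale_downsampling_factors"] == [4, 2, 1]
    assert preset["template_refinement_iterations"] == 4
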