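"""Trilinear sampling, scalar embedding, and streamline warping."""

import numpy as np
import pytest
from scipy import ndimage

from grouptract.core import ImageGrid, ScalarVolume, Tractogram
from grouptract.synth import default_grid, make_displacement, make_scalar_volume
from grouptract.transform import (
    AffineTransform,
    DisplacementField,
    OutOfBoundsError,
    embed_scalars,
    sample_trilinear,
    warp_streamlines,
)

from conftest import random_tractogram


@pytest.fixture
def linear_vol(grid):
    # f(i,j,k) = 2i + 3j - k : trilinear interpolation is exact on affine fields
    return make_scalar_volume(grid, "linear", (2.0, 3.0, -1.0, 0.0))


class TestSampleTrilinear:
    def test_voxel_centers_return_stored_values(self, grid, rng):
        vol = ScalarVolume(values=rng.random(grid.dims), grid=grid)
        ijk = np.array([[0, 0, 0], [3, 7, 2], [19, 19, 19]])
        got = sample_trilinear(vol, grid.voxel_to_world(ijk))
        want = vol.values[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_midpoint_is_arithmetic_mean(self, grid, rng):
        vol = ScalarVolume(values=rng.random(grid.dims), grid=grid)
        mid = grid.voxel_to_world([[4.5, 7.0, 2.0]])
        want = (vol.values[4, 7, 2] + vol.values[5, 7, 2]) / 2
        np.testing.assert_allclose(sample_trilinear(vol, mid), [want], atol=1e-12)

    def test_fractional_index_closed_form(self, linear_vol, grid):
        pt = grid.voxel_to_world([[1.25, 2.5, 0.75]])
        np.testing.assert_allclose(
            sample_trilinear(linear_vol, pt), [2 * 1.25 + 3 * 2.5 - 0.75], atol=1e-12
        )

    def test_matches_map_coordinates_oracle(self, grid, rng):
        vol = ScalarVolume(values=rng.random(grid.dims), grid=grid)
        ijk = rng.uniform(0, 19, size=(200, 3))
        got = sample_trilinear(vol, grid.voxel_to_world(ijk))
        want = ndimage.map_coordinates(vol.values, ijk.T, order=1, mode="nearest")
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_strict_mode_raises_out_of_bounds(self, linear_vol, grid):
        far = grid.voxel_to_world([[25.0, 5.0, 5.0]])
        with pytest.raises(OutOfBoundsError):
            sample_trilinear(linear_vol, far, mode="strict")

    def test_lenient_mode_fills(self, linear_vol, grid):
        far = grid.voxel_to_world([[25.0, 5.0, 5.0]])
        got = sample_trilinear(linear_vol, far, mode="lenient", fill_value=-1.0)
        assert got[0] == -1.0

    def test_edge_points_clamp_to_border(self, grid, rng):
        vol = ScalarVolume(values=rng.random(grid.dims), grid=grid)
        edge = grid.voxel_to_world([[-0.4, 5.0, 5.0]])
        got = sample_trilinear(vol, edge)
        np.testing.assert_allclose(got, [vol.values[0, 5, 5]], atol=1e-12)


class TestEmbedScalars:
    def test_constant_volume_embeds_constant(self, grid, rng):
        vol = make_scalar_volume(grid, "constant", (0, 0, 0, 0.37))
        tract = random_tractogram(grid, rng)
        out = embed_scalars(tract, {"FA": vol})
        for s in out.streamlines:
            np.testing.assert_allclose(s.scalars["FA"], 0.37, atol=1e-12)

    def test_linear_volume_matches_closed_form(self, grid, rng, linear_vol):
        tract = random_tractogram(grid, rng)
        out = embed_scalars(tract, {"f": linear_vol})
        for s in out.streamlines:
            ijk = grid.world_to_voxel(s.points)
            want = 2 * ijk[:, 0] + 3 * ijk[:, 1] - ijk[:, 2]
            np.testing.assert_allclose(s.scalars["f"], want, atol=1e-9)

    def test_idempotent_per_name(self, grid, rng, linear_vol):
        tract = random_tractogram(grid, rng)
        once = embed_scalars(tract, {"f": linear_vol})
        twice = embed_scalars(once, {"f": linear_vol})
        for a, b in zip(once.streamlines, twice.streamlines):
            np.testing.assert_array_equal(a.scalars["f"], b.scalars["f"])

    def test_embedded_values_survive_warping(self, grid, rng, linear_vol):
        # diffusion metrics belong to the native space: embedding then warping
        # must leave the scalar sequences untouched
        tract = random_tractogram(grid, rng)
        embedded = embed_scalars(tract, {"FA": linear_vol})
        aff = AffineTransform(np.diag([1.2, 0.8, 1.0, 1.0]))
        disp = make_displacement(grid, max_amplitude=1.5, seed=7)
        warped = warp_streamlines(embedded, aff, disp, template_grid=grid)
        for a, b in zip(embedded.streamlines, warped.streamlines):
            np.testing.assert_array_equal(a.scalars["FA"], b.scalars["FA"])


class TestWarpStreamlines:
    def test_identity_affine_zero_displacement(self, grid, rng):
        tract = random_tractogram(grid, rng)
        disp = make_displacement(grid, max_amplitude=0.0)
        out = warp_streamlines(tract, AffineTransform.identity(), disp,
                               template_grid=grid)
        for a, b in zip(tract.streamlines, out.streamlines):
            np.testing.assert_allclose(a.points, b.points, atol=1e-12)
        assert out.space_tag == "template"

    def test_constant_displacement_translates(self, grid, rng):
        tract = random_tractogram(grid, rng)
        d = np.array([1.5, -2.0, 0.5])
        vec = np.tile(d, grid.dims + (1,))
        disp = DisplacementField(vectors=vec, grid=grid)
        out = warp_streamlines(tract, AffineTransform.identity(), disp,
                               template_grid=grid)
        for a, b in zip(tract.streamlines, out.streamlines):
            np.testing.assert_allclose(b.points, a.points + d, atol=1e-9)

    def test_pure_affine_matches_matrix_oracle(self, grid, rng):
        mat = np.eye(4)
        mat[:3, :3] = rng.normal(0, 1, (3, 3)) + 2 * np.eye(3)
        mat[:3, 3] = rng.normal(0, 5, 3)
        aff = AffineTransform(mat)
        tract = random_tractogram(grid, rng)
        out = warp_streamlines(tract, aff, template_grid=grid)
        for a, b in zip(tract.streamlines, out.streamlines):
            hom = np.c_[a.points, np.ones(len(a.points))]
            np.testing.assert_allclose(b.points, (mat @ hom.T).T[:, :3], atol=1e-9)

    def test_affine_round_trip(self, grid, rng):
        mat = np.eye(4)
        mat[:3, :3] = np.diag([1.3, 0.7, 1.1]) + rng.normal(0, 0.05, (3, 3))
        aff = AffineTransform(mat)
        tract = random_tractogram(grid, rng)
        fwd = warp_streamlines(tract, aff, template_grid=grid)
        fwd_native = Tractogram(fwd.streamlines, grid, "native")
        back = warp_streamlines(fwd_native, aff.inverse(), template_grid=grid)
        for a, b in zip(tract.streamlines, back.streamlines):
            np.testing.assert_allclose(a.points, b.points, atol=1e-6)

    def test_counts_invariant(self, grid, rng):
        tract = random_tractogram(grid, rng, n_streamlines=7, n_points=11)
        disp = make_displacement(grid, max_amplitude=2.0, seed=3)
        out = warp_streamlines(tract, AffineTransform.identity(), disp,
                               template_grid=grid)
        assert len(out) == 7
        assert all(len(s) == 11 for s in out.streamlines)

    def test_strict_mode_rejects_outside_field(self, grid, rng):
        tract = random_tractogram(grid, rng, lo=30.0, hi=40.0)  # beyond the grid
        disp = make_displacement(grid, max_amplitude=1.0, seed=1)
        with pytest.raises(OutOfBoundsError):
            warp_streamlines(tract, AffineTransform.identity(), disp,
                             template_grid=grid, strict=True)

    def test_affine_text_round_trip(self, tmp_path, rng):
        mat = np.eye(4)
        mat[:3, :] = rng.normal(0, 1, (3, 4))
        mat[:3, :3] += 2 * np.eye(3)
        AffineTransform(mat).to_text(tmp_path / "aff.txt")
        loaded = AffineTransform.from_text(tmp_path / "aff.txt")
        np.testing.assert_allclose(loaded.matrix, mat, atol=1e-12)
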