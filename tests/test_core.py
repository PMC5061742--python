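"""Domain types, streamline/volume I/O, and tractogram merging."""

import numpy as np
import pytest

from grouptract.core import (
    FormatError,
    ImageGrid,
    LabelVolume,
    ScalarVolume,
    SpaceError,
    Streamline,
    Tractogram,
    merge_tractograms,
    read_label_lut,
    read_tractogram,
    read_volume,
    write_label_lut,
    write_tractogram,
    write_volume,
)

from conftest import random_tractogram


class TestDomainTypes:
    def test_grid_rejects_singular_affine(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            ImageGrid(dims=(4, 4, 4), affine=aff)

    def test_grid_rejects_bad_dims(self):
        with pytest.raises(ValueError):
            ImageGrid(dims=(0, 4, 4), affine=np.eye(4))

    def test_streamline_rejects_nonfinite_points(self):
        pts = np.array([[0.0, 0.0, np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            Streamline(points=pts)

    def test_streamline_rejects_mismatched_scalars(self):
        with pytest.raises(ValueError, match="FA"):
            Streamline(points=np.zeros((3, 3)), scalars={"FA": np.zeros(2)})

    def test_label_volume_requires_lut_entries(self, grid):
        labels = np.zeros(grid.dims, dtype=np.int32)
        labels[0, 0, 0] = 7
        with pytest.raises(ValueError, match="7"):
            LabelVolume(labels=labels, grid=grid, lut={1: "A"})

    def test_voxel_world_round_trip(self, grid, rng):
        ijk = rng.uniform(0, 19, size=(10, 3))
        back = grid.world_to_voxel(grid.voxel_to_world(ijk))
        np.testing.assert_allclose(back, ijk, atol=1e-10)


class TestStreamlineIO:
    @pytest.mark.parametrize("ext", ["tck", "trk"])
    def test_round_trip_preserves_points(self, ext, grid, rng, tmp_path):
        tract = random_tractogram(grid, rng, n_streamlines=4, scalars=("FA",))
        path = tmp_path / f"t.{ext}"
        write_tractogram(tract, path)
        loaded = read_tractogram(path)
        assert len(loaded) == len(tract)
        for a, b in zip(tract.streamlines, loaded.streamlines):
            np.testing.assert_allclose(a.points, b.points, atol=1e-4)

    def test_trk_round_trip_preserves_scalars(self, grid, rng, tmp_path):
        tract = random_tractogram(grid, rng, scalars=("FA", "AD"))
        path = tmp_path / "t.trk"
        write_tractogram(tract, path)
        loaded = read_tractogram(path)
        for a, b in zip(tract.streamlines, loaded.streamlines):
            for name in ("FA", "AD"):
                np.testing.assert_allclose(a.scalars[name], b.scalars[name],
                                           atol=1e-5)

    def test_minimal_tck_bytes_read_back(self, tmp_path):
        # handwritten minimal TCK: one 2-point streamline at known coords,
        # written independently of the package's writer
        coords = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], dtype="<f4")
        prefix = b"mrtrix tracks\ndatatype: Float32LE\ncount: 1\nfile: . "
        for n_digits in (1, 2, 3):
            body_offset = len(prefix) + n_digits + len(b"\nEND\n")
            if len(str(body_offset)) == n_digits:
                break
        header = prefix + str(body_offset).encode() + b"\nEND\n"
        assert len(header) == body_offset
        body = coords.tobytes()
        body += np.full(3, np.nan, dtype="<f4").tobytes()  # streamline delimiter
        body += np.full(3, np.inf, dtype="<f4").tobytes()  # EOF marker
        path = tmp_path / "minimal.tck"
        path.write_bytes(header + body)
        tract = read_tractogram(path)
        assert len(tract) == 1
        np.testing.assert_allclose(tract.streamlines[0].points, coords, atol=1e-6)

    def test_empty_tractogram_round_trip(self, grid, tmp_path):
        empty = Tractogram(streamlines=[], grid=grid, space_tag="native")
        path = tmp_path / "empty.tck"
        write_tractogram(empty, path)
        assert len(read_tractogram(path)) == 0

    def test_malformed_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.tck"
        path.write_bytes(b"this is not a tck file")
        with pytest.raises(FormatError):
            read_tractogram(path)

    def test_unknown_extension_rejected(self, tmp_path, grid):
        with pytest.raises(FormatError):
            read_tractogram(tmp_path / "t.vtk")


class TestVolumeIO:
    def test_scalar_round_trip_bit_exact(self, rng, tmp_path):
        grid = ImageGrid(dims=(8, 8, 8), affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        vol = ScalarVolume(values=rng.random((8, 8, 8)), grid=grid)
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        loaded = read_volume(path)
        np.testing.assert_array_equal(loaded.values, vol.values)
        np.testing.assert_allclose(loaded.grid.affine, grid.affine, atol=1e-6)

    def test_anisotropic_spacing_recovered(self, tmp_path):
        # clinical DWI-style anisotropic voxels: 0.9375 x 0.9375 x 3 mm
        affine = np.diag([0.9375, 0.9375, 3.0, 1.0])
        grid = ImageGrid(dims=(16, 16, 8), affine=affine)
        vol = ScalarVolume(values=np.zeros((16, 16, 8)), grid=grid)
        path = tmp_path / "aniso.nii.gz"
        write_volume(vol, path)
        loaded = read_volume(path)
        np.testing.assert_allclose(loaded.grid.voxel_sizes, [0.9375, 0.9375, 3.0],
                                   atol=1e-6)

    def test_label_volume_with_lut(self, label_volume, tmp_path):
        vol_path = tmp_path / "labels.nii.gz"
        lut_path = tmp_path / "labels.tsv"
        write_volume(label_volume, vol_path)
        write_label_lut(label_volume.lut, lut_path)
        loaded = read_volume(vol_path, lut_path=lut_path)
        assert isinstance(loaded, LabelVolume)
        assert loaded.lut == {1: "A", 2: "B"}
        np.testing.assert_array_equal(loaded.labels, label_volume.labels)

    def test_4d_volume_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4))
        path = tmp_path / "vec.nii.gz"
        nib.save(img, str(path))
        with pytest.raises(FormatError, match="4D"):
            read_volume(path)

    def test_lut_round_trip(self, tmp_path):
        lut = {1: "ctx-lh-precentral", 5: "Brain-Stem"}
        path = tmp_path / "lut.tsv"
        write_label_lut(lut, path)
        assert read_label_lut(path) == lut


class TestMerge:
    def test_counts_and_provenance(self, grid, rng):
        a = random_tractogram(grid, rng, n_streamlines=3)
        b = random_tractogram(grid, rng, n_streamlines=2)
        for t in (a, b):
            t.space_tag = "template"
        merged = merge_tractograms([a, b])
        assert len(merged) == 5
        np.testing.assert_array_equal(merged.provenance, [0, 0, 0, 1, 1])

    def test_single_input_identity(self, grid, rng):
        a = random_tractogram(grid, rng, n_streamlines=4)
        merged = merge_tractograms([a])
        assert len(merged) == 4
        for s, m in zip(a.streamlines, merged.streamlines):
            np.testing.assert_array_equal(s.points, m.points)

    def test_scalars_preserved_bit_exact(self, grid, rng):
        cohort = [random_tractogram(grid, rng, scalars=("FA",)) for _ in range(4)]
        merged = merge_tractograms(cohort)
        # concatenation oracle: flatten the inputs in order
        expected = [s for t in cohort for s in t.streamlines]
        assert len(merged) == len(expected)
        for got, want in zip(merged.streamlines, expected):
            np.testing.assert_array_equal(got.scalars["FA"], want.scalars["FA"])

    def test_associative_in_content(self, grid, rng):
        a, b, c = (random_tractogram(grid, rng, n_streamlines=k) for k in (2, 3, 1))
        left = merge_tractograms([merge_tractograms([a, b]), c])
        right = merge_tractograms([a, merge_tractograms([b, c])])
        assert len(left) == len(right) == 6
        for x, y in zip(left.streamlines, right.streamlines):
            np.testing.assert_array_equal(x.points, y.points)

    def test_mismatched_grids_rejected(self, grid, rng):
        other = ImageGrid(dims=(10, 10, 10), affine=np.diag([2.0, 2, 2, 1]))
        a = random_tractogram(grid, rng)
        b = random_tractogram(other, rng, lo=2.0, hi=9.0)
        with pytest.raises(SpaceError):
            merge_tractograms([a, b])
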