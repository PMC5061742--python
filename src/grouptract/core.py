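"""Domain types and file I/O for group tractography evaluation.

All streamline coordinates are world millimetres in RAS orientation.  Voxel
indices are 0-based and the grid affine maps a voxel index to the *center* of
that voxel in world mm.  TRK's corner-origin voxel-mm convention is converted
to this convention at the I/O boundary by nibabel, so nothing downstream ever
sees a space-dependent coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import nibabel as nib
from nibabel import streamlines as nib_streamlines


class SpaceError(ValueError):
    """Raised when objects defined on different grids/spaces are combined."""


class FormatError(ValueError):
    """Raised for malformed streamline or volume files."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel lattice with a voxel-center-to-world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got shape {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Spacing per axis in mm (norms of the affine's direction columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (N,3) world-mm points to continuous 0-based voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_as(self, other: "ImageGrid", atol: float = 1e-5) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class Streamline:
    """One fiber trajectory: an ordered polyline plus per-point scalars."""

    points: np.ndarray
    scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError(f"points must be (n>=1, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite streamline coordinates")
        self.points = pts
        cleaned = {}
        for name, vals in self.scalars.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (len(pts),):
                raise ValueError(
                    f"scalar {name!r} has length {vals.shape}, "
                    f"expected ({len(pts)},)"
                )
            cleaned[name] = vals
        self.scalars = cleaned

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Tractogram:
    """A set of streamlines on a reference grid, tagged native or template.

    ``provenance`` records, per streamline, the index of the subject it came
    from; it is populated by :func:`merge_tractograms` so that streamlines in
    a merged group model can be attributed (e.g. colored per subject).
    """

    streamlines: list[Streamline]
    grid: ImageGrid
    space_tag: str = "native"
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.space_tag not in ("native", "template"):
            raise ValueError(f"space_tag must be native|template, got {self.space_tag!r}")
        if self.provenance is not None:
            prov = np.asarray(self.provenance, dtype=int)
            if prov.shape != (len(self.streamlines),):
                raise ValueError("provenance length must match streamline count")
            self.provenance = prov

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def scalar_names(self) -> list[str]:
        names: list[str] = []
        for s in self.streamlines:
            for k in s.scalars:
                if k not in names:
                    names.append(k)
        return names


@dataclass
class ScalarVolume:
    """A real-valued 3D map (e.g. FA/AD/RD) on an ImageGrid."""

    values: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.dims:
            raise ValueError(f"values shape {vals.shape} != grid dims {self.grid.dims}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite volume values")
        self.values = vals


@dataclass
class LabelVolume:
    """Integer segmentation labels plus an id<->name lookup table."""

    labels: np.ndarray
    grid: ImageGrid
    lut: dict[int, str]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValueError("labels must be integer-valued")
            lab = lab.astype(np.int32)
        if lab.shape != self.grid.dims:
            raise ValueError(f"labels shape {lab.shape} != grid dims {self.grid.dims}")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab
        self.lut = {int(k): str(v) for k, v in self.lut.items()}
        names = list(self.lut.values())
        if len(set(n.lower() for n in names)) != len(names):
            raise ValueError("LUT names must be unique (case-insensitive)")
        present = set(np.unique(lab)) - {0}
        missing = sorted(int(i) for i in present if int(i) not in self.lut)
        if missing:
            raise ValueError(f"labels present without LUT entry: {missing}")

    def id_for_name(self, name: str) -> int:
        low = name.lower()
        for i, n in self.lut.items():
            if n.lower() == low:
                return i
        raise KeyError(name)


@dataclass
class BinaryMask:
    """Boolean voxel mask on an ImageGrid."""

    values: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=bool)
        if vals.shape != self.grid.dims:
            raise ValueError(f"mask shape {vals.shape} != grid dims {self.grid.dims}")
        self.values = vals

    @property
    def n_true(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# Streamline file I/O (TCK / TRK)
# ---------------------------------------------------------------------------

def _grid_from_header(header: Mapping, fmt: str) -> ImageGrid:
    if fmt == "trk":
        dims = tuple(int(d) for d in header["dimensions"])
        affine = np.array(header["voxel_to_rasmm"], dtype=float)
    else:  # tck headers carry no grid; fall back to identity unit grid
        dims = (1, 1, 1)
        affine = np.eye(4)
    return ImageGrid(dims=dims, affine=affine)


def read_tractogram(
    path: str | Path,
    format: str | None = None,
    grid: ImageGrid | None = None,
    space_tag: str = "native",
) -> Tractogram:
    """Load a TCK or TRK file into a world-mm :class:`Tractogram`.

    nibabel converts TRK's corner-origin voxel-mm coordinates to RAS world mm
    on load (``to_world()``), so both formats arrive in the one internal
    convention.  TCK files carry no reference grid; pass ``grid`` explicitly
    or a unit identity grid is attached.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("tck", "trk"):
        raise FormatError(f"unsupported streamline format {format!r} (want tck|trk)")
    try:
        tfile = nib_streamlines.load(str(path))
    except Exception as exc:  # nibabel raises HeaderError/DataError subclasses
        raise FormatError(f"cannot read {path.name}: {exc}") from exc
    sl_tractogram = tfile.tractogram.to_world()  # apply affine_to_rasmm

    scalar_names = list(sl_tractogram.data_per_point.keys())
    streamlines: list[Streamline] = []
    for idx, pts in enumerate(sl_tractogram.streamlines):
        scalars = {
            name: np.asarray(sl_tractogram.data_per_point[name][idx]).reshape(-1)
            for name in scalar_names
        }
        streamlines.append(Streamline(points=np.asarray(pts, float), scalars=scalars))

    if grid is None:
        grid = _grid_from_header(tfile.header, format)
    return Tractogram(streamlines=streamlines, grid=grid, space_tag=space_tag)


def write_tractogram(tract: Tractogram, path: str | Path) -> None:
    """Write a Tractogram to TCK or TRK (chosen by file extension)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("tck", "trk"):
        raise FormatError(f"unsupported streamline format {fmt!r} (want tck|trk)")

    names = tract.scalar_names
    data_per_point = {}
    for name in names:
        per_point = []
        for s in tract.streamlines:
            vals = s.scalars.get(name)
            if vals is None:
                vals = np.full(len(s), np.nan)
            per_point.append(np.asarray(vals, float).reshape(-1, 1))
        data_per_point[name] = per_point

    sl_tractogram = nib_streamlines.Tractogram(
        streamlines=[s.points for s in tract.streamlines],
        data_per_point=data_per_point or None,
        affine_to_rasmm=np.eye(4),  # points already world mm
    )
    if fmt == "trk":
        header = {
            "voxel_to_rasmm": np.asarray(tract.grid.affine, float),
            "voxel_sizes": tract.grid.voxel_sizes,
            "dimensions": tract.grid.dims,
        }
        nib_streamlines.save(sl_tractogram, str(path), header=header)
    else:
        nib_streamlines.save(sl_tractogram, str(path))


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI-1)
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, lut_path: str | Path | None = None):
    """Read a 3D NIfTI as a ScalarVolume, or as a LabelVolume when a LUT
    TSV (two columns: id, name) is supplied.

    The affine is the file's best transform (nibabel prefers sform over
    qform, the NIfTI-recommended order).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{Path(path).name}: expected a 3D volume, got {data.ndim}D shape {data.shape}"
        )
    grid = ImageGrid(dims=data.shape, affine=np.asarray(img.affine, float))
    if lut_path is None:
        return ScalarVolume(values=data.astype(float), grid=grid)
    lut = read_label_lut(lut_path)
    return LabelVolume(labels=np.asarray(np.round(data), dtype=np.int32), grid=grid, lut=lut)


def write_volume(vol, path: str | Path) -> None:
    if isinstance(vol, ScalarVolume):
        data = vol.values.astype(np.float64)
    elif isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int32)
    elif isinstance(vol, BinaryMask):
        data = vol.values.astype(np.uint8)
    else:
        raise TypeError(f"cannot write {type(vol).__name__} as a volume")
    img = nib.Nifti1Image(data, np.asarray(vol.grid.affine, float))
    nib.save(img, str(path))


def read_label_lut(path: str | Path) -> dict[int, str]:
    """Two-column TSV (id<TAB>name); '#' lines are comments."""
    lut: dict[int, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"LUT line {lineno}: expected 'id<TAB>name', got {raw!r}")
        lut[int(parts[0])] = parts[1]
    return lut


def write_label_lut(lut: Mapping[int, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{int(i)}\t{name}\n" for i, name in sorted(lut.items()))
    )


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_tractograms(tractograms: Sequence[Tractogram]) -> Tractogram:
    """Concatenate per-subject template-space tractograms into one group model.

    Streamline order is input order then within-subject order; per-point
    scalars are carried through untouched; ``provenance[i]`` is the index of
    the input tractogram streamline ``i`` came from.
    """
    tractograms = list(tractograms)
    if not tractograms:
        raise ValueError("need at least one tractogram to merge")
    ref = tractograms[0]
    for t in tractograms[1:]:
        if not t.grid.same_as(ref.grid):
            raise SpaceError("tractograms live on different grids")
        if t.space_tag != ref.space_tag:
            raise SpaceError(
                f"space_tag mismatch: {t.space_tag!r} vs {ref.space_tag!r}"
            )
    merged: list[Streamline] = []
    provenance: list[int] = []
    for subj_idx, t in enumerate(tractograms):
        for s in t.streamlines:
            merged.append(Streamline(points=s.points.copy(),
                                     scalars={k: v.copy() for k, v in s.scalars.items()}))
            provenance.append(subj_idx)
    return Tractogram(
        streamlines=merged,
        grid=ref.grid,
        space_tag=ref.space_tag,
        provenance=np.asarray(provenance, dtype=int),
    )
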