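"""Warping streamlines between spaces and embedding scalars along them.

Diffusion scalars (FA/AD/RD) are always sampled in the native DWI space,
*before* any deformation, so tract metrics are never interpolated through a
registration warp.  The deformable composition is y = A·x followed by
y + D(y), i.e. the displacement field is defined in target-space world
coordinates and sampled at the affinely transformed point; a flag allows
source-space fields for registrations that export them that way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import nibabel as nib

from .core import (
    BinaryMask,
    FormatError,
    ImageGrid,
    ScalarVolume,
    SpaceError,
    Streamline,
    Tractogram,
)

logger = logging.getLogger(__name__)


class OutOfBoundsError(ValueError):
    """A sample point fell outside the volume by more than half a voxel."""


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous world-mm transform (last row 0,0,0,1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {mat.shape}")
        if not np.allclose(mat[3], [0, 0, 0, 1]):
            raise ValueError("last affine row must be (0,0,0,1)")
        if abs(np.linalg.det(mat[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(np.asarray(self.matrix)))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_text(cls, path: str | Path) -> "AffineTransform":
        """Read a whitespace-separated 4x4 (or 3x4) text matrix."""
        rows = [
            [float(x) for x in line.split()]
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        mat = np.asarray(rows, dtype=float)
        if mat.shape == (3, 4):
            mat = np.vstack([mat, [0, 0, 0, 1]])
        if mat.shape != (4, 4):
            raise FormatError(f"expected 4x4 text matrix, got shape {mat.shape}")
        return cls(mat)

    def to_text(self, path: str | Path) -> None:
        np.savetxt(path, np.asarray(self.matrix), fmt="%.17g")


@dataclass
class DisplacementField:
    """Per-voxel world-mm displacement vectors on an ImageGrid."""

    vectors: np.ndarray  # shape grid.dims + (3,)
    grid: ImageGrid

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=float)
        if vec.shape != self.grid.dims + (3,):
            raise ValueError(
                f"vectors shape {vec.shape} != grid dims + (3,) = {self.grid.dims + (3,)}"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError("non-finite displacement components")
        self.vectors = vec

    @classmethod
    def read(cls, path: str | Path) -> "DisplacementField":
        """Read a 4D NIfTI with the vector dimension last (squeezing a
        5D ANTs-style (x,y,z,1,3) layout if present)."""
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim == 5 and data.shape[3] == 1:
            data = data[:, :, :, 0, :]
        if data.ndim != 4 or data.shape[-1] != 3:
            raise FormatError(
                f"displacement field must be (x,y,z,3), got shape {data.shape}"
            )
        grid = ImageGrid(dims=data.shape[:3], affine=np.asarray(img.affine, float))
        return cls(vectors=data, grid=grid)

    def write(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.vectors.astype(np.float64),
                              np.asarray(self.grid.affine, float))
        nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Trilinear sampling
# ---------------------------------------------------------------------------

def _trilinear(values: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``values`` at continuous voxel coords
    ``vox`` (N,3), with indices clamped to the border (edge extension)."""
    dims = np.asarray(values.shape)
    lo = np.floor(vox).astype(int)
    frac = vox - lo
    out = np.zeros(len(vox), dtype=float)
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = np.clip(lo + off, 0, dims - 1)
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
        out += w * values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def sample_trilinear(
    vol: ScalarVolume,
    points: np.ndarray,
    mode: str = "strict",
    fill_value: float = 0.0,
) -> np.ndarray:
    """Sample a scalar volume at world-mm points with trilinear weighting.

    A point is in-bounds when its continuous voxel coordinate lies in
    [-0.5, dim-0.5) per axis (i.e. within half a voxel of a stored center).
    Edge points use clamped border values.  ``mode="strict"`` raises
    :class:`OutOfBoundsError` for out-of-bounds points; ``mode="lenient"``
    substitutes ``fill_value``.

    Returns a 1-D array of samples (scalar input point -> length-1 array).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be strict|lenient, got {mode!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vox = vol.grid.world_to_voxel(pts)
    dims = np.asarray(vol.grid.dims)
    oob = np.any((vox < -0.5) | (vox >= dims - 0.5), axis=1)
    if oob.any() and mode == "strict":
        bad = int(np.flatnonzero(oob)[0])
        raise OutOfBoundsError(
            f"point {pts[bad]} maps to voxel {vox[bad]} outside grid {tuple(dims)}"
        )
    out = _trilinear(vol.values, vox)
    if oob.any():
        out[oob] = fill_value
    return out


def embed_scalars(
    tract: Tractogram,
    vols: dict[str, ScalarVolume],
    mode: str = "strict",
    fill_value: float = 0.0,
) -> Tractogram:
    """Attach per-point scalar sequences sampled from named native-space maps.

    Must be called before warping (the scalars belong to the native DWI
    space); re-embedding a name overwrites it with identical values.
    """
    new_streamlines = []
    for s_idx, s in enumerate(tract.streamlines):
        scalars = dict(s.scalars)
        for name, vol in vols.items():
            try:
                scalars[name] = sample_trilinear(vol, s.points, mode=mode,
                                                 fill_value=fill_value)
            except OutOfBoundsError as exc:
                raise OutOfBoundsError(
                    f"streamline {s_idx}, volume {name!r}: {exc}"
                ) from exc
        new_streamlines.append(Streamline(points=s.points.copy(), scalars=scalars))
    return Tractogram(
        streamlines=new_streamlines,
        grid=tract.grid,
        space_tag=tract.space_tag,
        provenance=None if tract.provenance is None else tract.provenance.copy(),
    )


def warp_streamlines(
    tract: Tractogram,
    aff: AffineTransform,
    disp: DisplacementField | None = None,
    template_grid: ImageGrid | None = None,
    strict: bool = False,
    field_space: str = "target",
) -> Tractogram:
    """Deform native-space streamlines into the template space.

    Each point x maps to y = A·x; when a displacement field is given, the
    field is sampled trilinearly at y (``field_space="target"``, the default)
    or at x (``field_space="source"``) and added to y.  Points that land
    outside the field are clamped to its border (a warning totals them) or
    raise when ``strict``.  Scalars and provenance are carried unchanged.
    """
    if field_space not in ("target", "source"):
        raise ValueError(f"field_space must be target|source, got {field_space!r}")
    if template_grid is None:
        template_grid = disp.grid if disp is not None else tract.grid

    disp_vols = None
    if disp is not None:
        disp_vols = [ScalarVolume(values=disp.vectors[..., c], grid=disp.grid)
                     for c in range(3)]

    n_clamped = 0
    new_streamlines = []
    for s in tract.streamlines:
        y = aff.apply(s.points)
        if disp_vols is not None:
            at = s.points if field_space == "source" else y
            vox = disp.grid.world_to_voxel(at)
            dims = np.asarray(disp.grid.dims)
            oob = np.any((vox < -0.5) | (vox >= dims - 0.5), axis=1)
            if oob.any():
                if strict:
                    raise OutOfBoundsError(
                        f"{int(oob.sum())} warped points fall outside the "
                        f"displacement field grid {tuple(dims)}"
                    )
                n_clamped += int(oob.sum())
            offsets = np.stack(
                [sample_trilinear(v, at, mode="lenient") for v in disp_vols], axis=1
            )
            # lenient fill is only hit beyond the border; emulate clamping by
            # re-sampling with clipped voxel coordinates instead
            if oob.any():
                vox_cl = np.clip(vox, 0, dims - 1)
                for c, v in enumerate(disp_vols):
                    offsets[oob, c] = _trilinear(v.values, vox_cl[oob])
            y = y + offsets
        new_streamlines.append(
            Streamline(points=y, scalars={k: v.copy() for k, v in s.scalars.items()})
        )
    if n_clamped:
        logger.warning("warp_streamlines: clamped %d points to the displacement "
                       "field border", n_clamped)
    return Tractogram(
        streamlines=new_streamlines,
        grid=template_grid,
        space_tag="template",
        provenance=None if tract.provenance is None else tract.provenance.copy(),
    )
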