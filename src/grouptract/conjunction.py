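"""Rasterizing tractograms and stacking binary masks into the conjunction
percentage-overlap image.

Each subject's tract is converted to a binary voxel mask; the masks are then
summed voxel-wise over the cohort.  The resulting overlap fraction
s = k/N (k subjects covering a voxel out of N) lies in [0, 1] and is the
substrate for both the level-set visualizations and the normalized overlap
score.  Counts are stored as integers together with N, never as floats, so
that downstream super-level-set binning can be done in exact integer
arithmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import nibabel as nib

from .core import BinaryMask, ImageGrid, SpaceError, Tractogram
from .filtering import subdivide_points

logger = logging.getLogger(__name__)


@dataclass
class ConjunctionImage:
    """Voxel-wise subject coverage counts k with cohort size N."""

    counts: np.ndarray
    n_subjects: int
    grid: ImageGrid

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            raise TypeError("counts must be an integer array")
        if counts.shape != self.grid.dims:
            raise ValueError(f"counts shape {counts.shape} != grid dims {self.grid.dims}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if counts.min() < 0 or counts.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")
        self.counts = counts
        self.n_subjects = int(self.n_subjects)

    @property
    def overlap_fraction(self) -> np.ndarray:
        """s = k/N as floats, for export and display."""
        return self.counts.astype(float) / self.n_subjects

    def write(self, counts_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Serialize as an integer counts NIfTI plus a JSON sidecar {n_subjects}."""
        counts_path = Path(counts_path)
        img = nib.Nifti1Image(self.counts.astype(np.int32),
                              np.asarray(self.grid.affine, float))
        nib.save(img, str(counts_path))
        if sidecar_path is None:
            base = counts_path.name.removesuffix(".gz").removesuffix(".nii")
            sidecar_path = counts_path.parent / (base + ".json")
        Path(sidecar_path).write_text(json.dumps({"n_subjects": self.n_subjects}) + "\n")

    @classmethod
    def read(cls, counts_path: str | Path, sidecar_path: str | Path | None = None) -> "ConjunctionImage":
        counts_path = Path(counts_path)
        if sidecar_path is None:
            base = counts_path.name.removesuffix(".gz").removesuffix(".nii")
            sidecar_path = counts_path.parent / (base + ".json")
        img = nib.load(str(counts_path))
        counts = np.asanyarray(img.dataobj).astype(np.int64)
        meta = json.loads(Path(sidecar_path).read_text())
        grid = ImageGrid(dims=counts.shape, affine=np.asarray(img.affine, float))
        return cls(counts=counts, n_subjects=int(meta["n_subjects"]), grid=grid)


def rasterize(tract: Tractogram, grid: ImageGrid) -> BinaryMask:
    """Convert a tractogram to a binary spatial image on ``grid``.

    A voxel is marked when any streamline point — after subdividing segments
    at a step of half the minimum voxel size — falls inside it.  Points
    outside the grid are ignored (their total is logged).  An empty
    tractogram yields an all-false mask.
    """
    values = np.zeros(grid.dims, dtype=bool)
    step = float(grid.voxel_sizes.min()) / 2.0
    dims = np.asarray(grid.dims)
    n_outside = 0
    for s in tract.streamlines:
        pts = subdivide_points(s.points, step)
        vox = np.round(grid.world_to_voxel(pts)).astype(int)
        inside = np.all((vox >= 0) & (vox < dims), axis=1)
        n_outside += int((~inside).sum())
        vox = vox[inside]
        values[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    if n_outside:
        logger.info("rasterize: %d subdivided points fell outside the grid", n_outside)
    return BinaryMask(values=values, grid=grid)


def build_conjunction(masks: list[BinaryMask]) -> ConjunctionImage:
    """Stack binary per-subject masks into the conjunction overlap image."""
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0].grid
    for m in masks[1:]:
        if not m.grid.same_as(ref):
            raise SpaceError("conjunction masks live on different grids")
    counts = np.zeros(ref.dims, dtype=np.int64)
    for m in masks:
        counts += m.values
    return ConjunctionImage(counts=counts, n_subjects=len(masks), grid=ref)


def threshold_levels(conj: ConjunctionImage, step: float = 0.10) -> list[BinaryMask]:
    """Super-level-set masks at thresholds j*step for j = 1..floor(1/step).

    Each mask is {voxels : s >= j*step}; comparison is done in integer
    arithmetic (k*m >= j*N for step = 1/m when 1/step is integral), and the
    masks are nested by construction.  The default 10% step gives the ten
    concentric levels used for overlap visualization.
    """
    if not (0 < step <= 1):
        raise ValueError(f"step must lie in (0, 1], got {step}")
    n_levels = int(np.floor(1.0 / step + 1e-12))
    masks = []
    k = conj.counts
    N = conj.n_subjects
    inv = 1.0 / step
    exact = abs(inv - round(inv)) < 1e-12
    for j in range(1, n_levels + 1):
        if exact:
            vals = k * int(round(inv)) >= j * N  # s >= j*step exactly
        else:
            vals = k >= (j * step) * N - 1e-12
        masks.append(BinaryMask(values=vals, grid=conj.grid))
    return masks
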