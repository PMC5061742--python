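"""Inclusion/exclusion filtering of streamlines against binary ROI masks.

A streamline is kept iff it intersects every inclusion mask and no exclusion
mask.  Intersection is tested on the streamline's points after subdividing
each segment at a step no larger than half the smallest voxel size, so a
long segment cannot jump a thin mask.  The unfiltered condition is simply
``include=[], exclude=[]``, which keeps everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, SpaceError, Streamline, Tractogram


def subdivide_points(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline so consecutive samples are at most ``step`` apart.

    Original vertices are always retained; each segment of length L gains
    ceil(L/step) - 1 evenly spaced interior points.  A single-point polyline
    is returned unchanged.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return points
    if step <= 0:
        raise ValueError("step must be positive")
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        seg_len = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(seg_len / step)))
        ts = np.linspace(0.0, 1.0, n + 1)[1:]
        out.append(a + ts[:, None] * (b - a))
    return np.vstack(out)


def _mask_step(mask: BinaryMask) -> float:
    return float(mask.grid.voxel_sizes.min()) / 2.0


def _points_in_mask(points: np.ndarray, mask: BinaryMask) -> bool:
    """True iff any point falls in a True voxel (out-of-grid points ignored)."""
    vox = np.round(mask.grid.world_to_voxel(points)).astype(int)
    dims = np.asarray(mask.grid.dims)
    inside = np.all((vox >= 0) & (vox < dims), axis=1)
    if not inside.any():
        return False
    vox = vox[inside]
    return bool(mask.values[vox[:, 0], vox[:, 1], vox[:, 2]].any())


def streamline_intersects(
    s: Streamline,
    mask: BinaryMask,
    mode: str = "any_point",
) -> bool:
    """Does a streamline touch the mask?

    ``any_point`` tests every point including segment-subdivision points at a
    step of half the minimum voxel size; ``endpoints`` tests only the first
    and last stored points.
    """
    if mode == "endpoints":
        pts = s.points[[0, -1]] if len(s) > 1 else s.points
        return _points_in_mask(pts, mask)
    if mode == "any_point":
        return _points_in_mask(subdivide_points(s.points, _mask_step(mask)), mask)
    raise ValueError(f"mode must be any_point|endpoints, got {mode!r}")


@dataclass
class FilterResult:
    tractogram: Tractogram
    kept: int
    discarded: int
    kept_indices: np.ndarray


def filter_tractogram(
    tract: Tractogram,
    include: list[BinaryMask] | None = None,
    exclude: list[BinaryMask] | None = None,
    mode: str = "any_point",
    include_logic: str = "all",
) -> FilterResult:
    """Keep streamlines traversing the inclusion ROIs and avoiding the
    exclusion ROIs.

    ``include_logic="all"`` (default) requires every inclusion mask to be
    hit (waypoint semantics); ``"any"`` requires at least one.  Empty lists
    impose no constraint, so ``include=[], exclude=[]`` reproduces the
    unfiltered condition exactly.  Streamline order is preserved and
    provenance subset accordingly.
    """
    include = list(include or [])
    exclude = list(exclude or [])
    if include_logic not in ("all", "any"):
        raise ValueError(f"include_logic must be all|any, got {include_logic!r}")
    for m in include + exclude:
        if not m.grid.same_as(tract.grid):
            raise SpaceError("filter mask grid does not match tractogram grid")

    kept_idx: list[int] = []
    for i, s in enumerate(tract.streamlines):
        hits = [streamline_intersects(s, m, mode=mode) for m in include]
        if include:
            ok = all(hits) if include_logic == "all" else any(hits)
            if not ok:
                continue
        if any(streamline_intersects(s, m, mode=mode) for m in exclude):
            continue
        kept_idx.append(i)

    kept_streamlines = [tract.streamlines[i] for i in kept_idx]
    prov = None
    if tract.provenance is not None:
        prov = tract.provenance[kept_idx]
    out = Tractogram(
        streamlines=kept_streamlines,
        grid=tract.grid,
        space_tag=tract.space_tag,
        provenance=prov,
    )
    return FilterResult(
        tractogram=out,
        kept=len(kept_idx),
        discarded=len(tract) - len(kept_idx),
        kept_indices=np.asarray(kept_idx, dtype=int),
    )
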