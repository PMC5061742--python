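"""Synthetic cohorts for exercising every pipeline stage without MRI data.

The generator emulates the statistical structure of a group tractography
study: each subject contributes a tube-like bundle of streamlines around a
shared analytic centerline (a curved arc, imitating the curvature of
structures like the forniceal crura), with three orthogonal knobs —

* ``radial_dispersion``: per-streamline Gaussian spread around the
  centerline (how tight each subject's bundle is);
* ``subject_jitter``: a per-subject rigid offset (inter-subject anatomical
  variability / registration error);
* ``false_positive_rate``: the fraction of streamlines rerouted to a decoy
  curve (spurious delineations).

Tight, low-false-positive settings emulate a conservative deterministic
tracker; loose, high-false-positive settings emulate a dispersed
probabilistic one.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageGrid, LabelVolume, ScalarVolume, Streamline, Tractogram
from .transform import DisplacementField


def arc_centerline(
    start: np.ndarray | tuple = (10.0, 10.0, 15.0),
    end: np.ndarray | tuple = (30.0, 30.0, 15.0),
    bow: float = 8.0,
    n_points: int = 40,
) -> np.ndarray:
    """A planar arc from ``start`` to ``end`` bowing ``bow`` mm out of the
    chord at mid-arc (quadratic Bezier), sampled at ``n_points``."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    chord = end - start
    # perpendicular in the plane z = const, falling back to +z for vertical chords
    perp = np.array([-chord[1], chord[0], 0.0])
    norm = np.linalg.norm(perp)
    perp = np.array([0.0, 0.0, 1.0]) if norm < 1e-9 else perp / norm
    control = (start + end) / 2 + 2.0 * bow * perp  # Bezier midpoint offset = bow/2*2
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return (1 - t) ** 2 * start + 2 * t * (1 - t) * control + t**2 * end


@dataclass(frozen=True)
class BundleSpec:
    """Statistical description of one synthetic cohort."""

    centerline: np.ndarray = field(default_factory=arc_centerline)
    n_streamlines: int = 20
    radial_dispersion: float = 0.5  # mm std around the centerline
    subject_jitter: float = 0.5  # mm std of the per-subject rigid offset
    false_positive_rate: float = 0.0
    n_subjects: int = 10
    decoy_offset: tuple[float, float, float] = (0.0, 0.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, float)
        if cl.ndim != 2 or cl.shape[1] != 3 or len(cl) < 2:
            raise ValueError("centerline must be an (M>=2, 3) polyline")
        object.__setattr__(self, "centerline", cl)
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError("false_positive_rate must lie in [0, 1]")
        if self.radial_dispersion < 0 or self.subject_jitter < 0:
            raise ValueError("dispersions must be >= 0")
        if self.n_streamlines < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")

    def with_(self, **kwargs) -> "BundleSpec":
        return replace(self, **kwargs)


def make_cohort(spec: BundleSpec, grid: ImageGrid) -> list[Tractogram]:
    """Generate one native/template-agnostic tractogram per subject.

    Each streamline is the centerline (or the decoy curve, with probability
    ``false_positive_rate``) translated by a per-streamline Gaussian radial
    offset plus the subject's rigid jitter.  Bit-reproducible for a fixed
    spec (the seed is part of the spec).
    """
    if min(grid.dims) < 1:
        raise ValueError("degenerate grid")
    rng = np.random.default_rng(spec.seed)
    decoy = spec.centerline + np.asarray(spec.decoy_offset, float)
    cohort = []
    for _ in range(spec.n_subjects):
        jitter = rng.normal(0.0, spec.subject_jitter, size=3) if spec.subject_jitter > 0 else np.zeros(3)
        streamlines = []
        for _ in range(spec.n_streamlines):
            is_fp = rng.random() < spec.false_positive_rate
            base = decoy if is_fp else spec.centerline
            offset = (
                rng.normal(0.0, spec.radial_dispersion, size=3)
                if spec.radial_dispersion > 0
                else np.zeros(3)
            )
            streamlines.append(Streamline(points=base + offset + jitter))
        cohort.append(Tractogram(streamlines=streamlines, grid=grid, space_tag="template"))
    return cohort


def default_grid(dims: tuple[int, int, int] = (40, 40, 30), spacing: float = 1.0) -> ImageGrid:
    """An axis-aligned RAS grid with isotropic spacing and origin at 0."""
    affine = np.diag([spacing, spacing, spacing, 1.0])
    return ImageGrid(dims=dims, affine=affine)


def make_label_volume(
    regions: dict[str, dict],
    grid: ImageGrid,
) -> LabelVolume:
    """Paint named box/sphere regions into a label volume.

    Each region is ``{"shape": "box", "lo": (i,j,k), "hi": (i,j,k)}``
    (inclusive voxel bounds) or ``{"shape": "sphere", "center": (i,j,k),
    "radius": r}`` (voxel units).  Labels are assigned 1..K in insertion
    order; overlapping regions resolve last-wins with a warning.
    """
    labels = np.zeros(grid.dims, dtype=np.int32)
    lut: dict[int, str] = {}
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij")
    for label_id, (name, region) in enumerate(regions.items(), start=1):
        shape = region.get("shape", "box")
        if shape == "box":
            lo = np.asarray(region["lo"], int)
            hi = np.asarray(region["hi"], int)
            sel = (
                (ii >= lo[0]) & (ii <= hi[0])
                & (jj >= lo[1]) & (jj <= hi[1])
                & (kk >= lo[2]) & (kk <= hi[2])
            )
        elif shape == "sphere":
            c = np.asarray(region["center"], float)
            r = float(region["radius"])
            sel = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2 <= r**2
        else:
            raise ValueError(f"unknown region shape {shape!r}")
        if (labels[sel] != 0).any():
            warnings.warn(f"region {name!r} overlaps an earlier region; last wins",
                          stacklevel=2)
        labels[sel] = label_id
        lut[label_id] = name
    return LabelVolume(labels=labels, grid=grid, lut=lut)


def make_scalar_volume(
    grid: ImageGrid,
    kind: str = "linear",
    coefficients: tuple[float, float, float, float] = (0.01, 0.02, -0.005, 0.4),
) -> ScalarVolume:
    """A scalar map with a known closed form: ``linear`` gives
    a*i + b*j + c*k + d over voxel indices; ``constant`` gives d."""
    ii, jj, kk = np.meshgrid(*(np.arange(d, dtype=float) for d in grid.dims),
                             indexing="ij")
    a, b, c, d = coefficients
    if kind == "linear":
        values = a * ii + b * jj + c * kk + d
    elif kind == "constant":
        values = np.full(grid.dims, d)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return ScalarVolume(values=values, grid=grid)


def make_displacement(
    grid: ImageGrid,
    max_amplitude: float,
    smoothness_voxels: float = 4.0,
    seed: int = 0,
) -> DisplacementField:
    """A smooth band-limited random displacement field.

    White noise per component is Gaussian-smoothed (sigma in voxels) and
    rescaled so the maximum displacement magnitude equals ``max_amplitude``
    mm; amplitude 0 yields the zero field.
    """
    if max_amplitude < 0:
        raise ValueError("max_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    vec = np.zeros(grid.dims + (3,))
    if max_amplitude > 0:
        for c in range(3):
            noise = rng.standard_normal(grid.dims)
            vec[..., c] = ndimage.gaussian_filter(noise, sigma=smoothness_voxels)
        mags = np.linalg.norm(vec, axis=-1)
        peak = mags.max()
        if peak > 0:
            vec *= max_amplitude / peak
    return DisplacementField(vectors=vec, grid=grid)


def make_ratings(
    tightness: dict[str, float],
    anatomies: list[str],
    n_raters: int = 5,
    noise: float = 0.1,
    conditions: tuple[str, ...] = ("filtered", "unfiltered"),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic rater table whose scores increase monotonically with the
    per-algorithm bundle tightness, plus bounded uniform noise.

    ``tightness`` maps algorithm name -> value in [0, 1]; the noiseless score
    is 10 * tightness, and each rater adds U(-noise*10, +noise*10), clipped
    to [0, 10].
    """
    rng = np.random.default_rng(seed)
    records = []
    for anatomy in anatomies:
        for algorithm, t in tightness.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"tightness for {algorithm!r} must lie in [0,1]")
            for condition in conditions:
                for rater in range(n_raters):
                    score = 10.0 * t + rng.uniform(-10.0 * noise, 10.0 * noise)
                    records.append(
                        {
                            "anatomy": anatomy,
                            "algorithm": algorithm,
                            "condition": condition,
                            "rater": f"R{rater}",
                            "score": float(np.clip(score, 0.0, 10.0)),
                        }
                    )
    return pd.DataFrame.from_records(records)
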