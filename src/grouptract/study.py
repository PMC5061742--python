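"""Synthetic benchmark studies of the group pipeline.

These drive the whole stack — cohort generation, ROI filtering, conjunction,
NOS, and the rating regression — on synthetic algorithm archetypes whose
ground-truth quality is known, so the pipeline's behavior can be measured
without MRI data.  An "algorithm" here is a point on a tightness scale
t in [0, 1]: high t emulates a conservative tracker (small dispersion and
jitter, few false positives), low t a dispersed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conjunction import rasterize
from .core import BinaryMask, ImageGrid
from .filtering import filter_tractogram
from .nos import DegenerateSupportError, EmptyConjunctionError, nos_from_masks
from .stats import RegressionResult, regress_by_condition
from .synth import (
    BundleSpec,
    arc_centerline,
    default_grid,
    make_cohort,
    make_label_volume,
    make_ratings,
)

# algorithm archetypes: name -> tightness
DEFAULT_ALGORITHMS: dict[str, float] = {
    "tight_det": 0.9,
    "mid_det": 0.65,
    "mid_prob": 0.4,
    "loose_prob": 0.15,
}

# six anatomies as differently curved arcs on the shared grid
DEFAULT_ANATOMIES: dict[str, dict] = {
    "arc_a": {"start": (8, 8, 15), "end": (32, 30, 15), "bow": 8.0},
    "arc_b": {"start": (8, 30, 15), "end": (32, 8, 15), "bow": 6.0},
    "arc_c": {"start": (8, 20, 10), "end": (32, 20, 20), "bow": 5.0},
    "arc_d": {"start": (10, 10, 18), "end": (30, 30, 10), "bow": 7.0},
    "arc_e": {"start": (8, 15, 12), "end": (32, 25, 18), "bow": 4.0},
    "arc_f": {"start": (12, 8, 14), "end": (28, 32, 16), "bow": 9.0},
}


def spec_for_tightness(
    tightness: float,
    centerline: np.ndarray,
    n_subjects: int = 6,
    n_streamlines: int = 15,
    seed: int = 0,
) -> BundleSpec:
    """Map a tightness t in [0, 1] to cohort noise parameters: dispersion
    and jitter shrink linearly with t, the false-positive rate with t/2."""
    loose = 1.0 - tightness
    return BundleSpec(
        centerline=centerline,
        n_streamlines=n_streamlines,
        radial_dispersion=0.3 + 2.2 * loose,
        subject_jitter=0.3 + 2.2 * loose,
        false_positive_rate=0.5 * loose,
        n_subjects=n_subjects,
        seed=seed,
    )


def _roi_masks(grid: ImageGrid, centerline: np.ndarray) -> tuple[BinaryMask, BinaryMask]:
    """Seed-region inclusion mask around the bundle start, exclusion mask
    over the decoy band (10 mm above the bundle plane)."""
    start = np.round(centerline[0]).astype(int)
    labels = make_label_volume(
        {
            "seed": {
                "shape": "box",
                "lo": tuple(np.maximum(start - 3, 0)),
                "hi": tuple(np.minimum(start + 3, np.asarray(grid.dims) - 1)),
            },
            "decoy_band": {
                "shape": "box",
                "lo": (0, 0, min(grid.dims[2] - 6, int(start[2]) + 8)),
                "hi": (grid.dims[0] - 1, grid.dims[1] - 1, grid.dims[2] - 1),
            },
        },
        grid,
    )
    include = BinaryMask(values=labels.labels == 1, grid=grid)
    exclude = BinaryMask(values=labels.labels == 2, grid=grid)
    return include, exclude


def cohort_nos(
    spec: BundleSpec,
    grid: ImageGrid,
    filtered: bool = True,
) -> float:
    """NOS of one synthetic cohort after the (optionally filtered) pipeline.

    An algorithm that produces no (surviving) streamlines in any subject has
    no reproducible support at all and scores 0, the natural floor of the
    metric for absent results.
    """
    cohort = make_cohort(spec, grid)
    if filtered:
        include, exclude = _roi_masks(grid, spec.centerline)
        cohort = [
            filter_tractogram(t, include=[include], exclude=[exclude]).tractogram
            for t in cohort
        ]
    masks = [rasterize(t, grid) for t in cohort]
    try:
        return nos_from_masks(masks).score
    except (EmptyConjunctionError, DegenerateSupportError):
        return 0.0


@dataclass
class ContrastStudyResult:
    win_fraction: float
    mean_nos_tight: float
    mean_nos_loose: float
    n_runs: int


def algorithm_contrast_study(
    seed: int = 0,
    n_runs: int = 20,
    tight: float = 0.9,
    loose: float = 0.15,
) -> ContrastStudyResult:
    """How often does the pipeline rank a tight algorithm above a loose one?

    Runs ``n_runs`` independent seeded cohort pairs (same anatomy, different
    noise realizations) through the filtered pipeline and reports the
    fraction with NOS(tight) > NOS(loose).
    """
    grid = default_grid((40, 40, 30))
    centerline = arc_centerline(**DEFAULT_ANATOMIES["arc_a"])
    wins = 0
    tight_scores, loose_scores = [], []
    for run in range(n_runs):
        run_seed = seed * n_runs + run
        s_tight = cohort_nos(
            spec_for_tightness(tight, centerline, seed=2 * run_seed), grid)
        s_loose = cohort_nos(
            spec_for_tightness(loose, centerline, seed=2 * run_seed + 1), grid)
        tight_scores.append(s_tight)
        loose_scores.append(s_loose)
        wins += s_tight > s_loose
    return ContrastStudyResult(
        win_fraction=wins / n_runs,
        mean_nos_tight=float(np.mean(tight_scores)),
        mean_nos_loose=float(np.mean(loose_scores)),
        n_runs=n_runs,
    )


def rating_regression_study(
    seed: int = 0,
    algorithms: dict[str, float] | None = None,
    anatomies: dict[str, dict] | None = None,
    rating_noise: float = 0.08,
) -> tuple[dict[str, RegressionResult], pd.DataFrame]:
    """Regress synthetic expert ratings against pipeline NOS.

    For every (anatomy, algorithm) cell a cohort is generated at the
    algorithm's tightness, scored by the filtered and unfiltered pipeline,
    and paired with ratings drawn as a monotone function of tightness plus
    bounded noise.  Returns the per-condition regression results and the
    NOS table (anatomy, algorithm, condition, nos).
    """
    algorithms = algorithms or DEFAULT_ALGORITHMS
    anatomies = anatomies or DEFAULT_ANATOMIES
    grid = default_grid((40, 40, 30))

    records = []
    for a_idx, (anatomy, arc) in enumerate(anatomies.items()):
        centerline = arc_centerline(**arc)
        for g_idx, (algorithm, tightness) in enumerate(algorithms.items()):
            cell_seed = seed * 1009 + a_idx * 101 + g_idx
            spec = spec_for_tightness(tightness, centerline, seed=cell_seed)
            for condition, filtered in (("filtered", True), ("unfiltered", False)):
                records.append(
                    {
                        "anatomy": anatomy,
                        "algorithm": algorithm,
                        "condition": condition,
                        "nos": cohort_nos(spec, grid, filtered=filtered),
                    }
                )
    nos_table = pd.DataFrame.from_records(records)
    ratings = make_ratings(
        algorithms, list(anatomies), n_raters=5, noise=rating_noise, seed=seed
    )
    results = regress_by_condition(ratings, nos_table, pooling="mean")
    return results, nos_table
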