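"""Rater-score normalization and the rating-vs-NOS regression.

Human raters score each (anatomy, algorithm, condition) cell; scores are
normalized per anatomy so anatomies of different intrinsic difficulty become
comparable, then the per-cell mean normalized rating is regressed against
the corresponding NOS by ordinary least squares with a two-sided test of
zero slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

REQUIRED_COLUMNS = ("anatomy", "algorithm", "condition", "rater", "score")
CONDITIONS = ("filtered", "unfiltered")


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_points": self.n_points,
        }


def load_rater_table(path: str | Path) -> pd.DataFrame:
    """Read a rater CSV/TSV with columns anatomy,algorithm,condition,rater,score."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    return validate_rater_table(table)


def validate_rater_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rater table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("rater table is empty")
    if not np.all(np.isfinite(table["score"].to_numpy(dtype=float))):
        raise ValueError("rater scores must be finite")
    bad = set(table["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    dup = table.duplicated(subset=["anatomy", "algorithm", "condition", "rater"])
    if dup.any():
        raise ValueError(
            f"duplicate (anatomy, algorithm, condition, rater) rows at indices "
            f"{list(table.index[dup])}"
        )
    return table


def normalize_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale scores to [0, 1] within each (anatomy, condition) stratum.

    A constant stratum (all raters gave the same score to every cell) carries
    no ordering information; it maps to 0.5 and a warning is emitted.
    """
    table = validate_rater_table(table.copy())

    def _scale(group: pd.Series) -> pd.Series:
        lo, hi = group.min(), group.max()
        if hi == lo:
            warnings.warn(
                f"constant rating stratum (all scores == {lo}); mapped to 0.5",
                stacklevel=2,
            )
            return pd.Series(0.5, index=group.index)
        return (group - lo) / (hi - lo)

    table["score"] = (
        table.groupby(["anatomy", "condition"], group_keys=False)["score"]
        .apply(_scale)
        .astype(float)
    )
    return table


def mean_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Mean rating across raters per (anatomy, algorithm, condition)."""
    return (
        table.groupby(["anatomy", "algorithm", "condition"], as_index=False)["score"]
        .mean()
    )


def regress_ratings_vs_nos(
    ratings: np.ndarray | pd.Series,
    nos_scores: np.ndarray | pd.Series,
) -> RegressionResult:
    """OLS of mean normalized rating on NOS, two-sided p for slope = 0."""
    y = np.asarray(ratings, dtype=float)
    x = np.asarray(nos_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ratings and NOS scores must be matched 1-D arrays")
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 matched pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("NOS predictor has zero variance")
    res = sp_stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_points=len(x),
    )


def regress_by_condition(
    rater_table: pd.DataFrame,
    nos_table: pd.DataFrame,
    pooling: str = "mean",
) -> dict[str, RegressionResult]:
    """Run the rating-vs-NOS regression separately per condition.

    ``nos_table`` has columns anatomy, algorithm, condition, nos.  With
    ``pooling="mean"`` (default) ratings are averaged across raters before
    pairing; ``pooling="per_rater"`` pairs every rater's normalized score
    with the cell's NOS.
    """
    if pooling not in ("mean", "per_rater"):
        raise ValueError(f"pooling must be mean|per_rater, got {pooling!r}")
    normalized = normalize_ratings(rater_table)
    pooled = mean_ratings(normalized) if pooling == "mean" else normalized
    merged = pooled.merge(nos_table, on=["anatomy", "algorithm", "condition"])
    out = {}
    for condition, group in merged.groupby("condition"):
        out[str(condition)] = regress_ratings_vs_nos(
            group["score"].to_numpy(), group["nos"].to_numpy()
        )
    return out
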