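"""The normalized overlap score (NOS).

NOS summarizes a group conjunction image — the voxel-wise overlap fraction
s = k/N over N subjects — as a single number in [0, 1] measuring how much of
the tract's spatial support persists at increasingly strict agreement
levels.  With n bins (default 10) and v_i the number of voxels whose overlap
exceeds i/n,

    NOS = (1/n) * sum_{i=0}^{n-1} ln(v_i) / ln(v_0),

where v_0 is the support size |{s > 0}|.  Perfect inter-subject overlap
gives every ratio 1 and a score of 1; a cohort whose masks barely co-locate
keeps only the i = 0 term and scores 1/n.  Empty high-agreement bins
(v_i = 0) contribute 0 rather than -inf, keeping the score in [0, 1]: an
agreement level no voxel reaches adds no evidence of reproducibility.

Bin membership is computed in exact integer arithmetic (k*n > i*N) so that
cohort sizes that are not multiples of n (e.g. N = 42 with n = 10) never
suffer float-threshold artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conjunction import ConjunctionImage, build_conjunction
from .core import BinaryMask


class EmptyConjunctionError(ValueError):
    """The conjunction image has no covered voxels (v_0 = 0)."""


class DegenerateSupportError(ValueError):
    """The support is a single voxel, so ln(v_0) = 0 and NOS is undefined."""


@dataclass(frozen=True)
class NOSResult:
    """The score plus its per-bin voxel counts, for auditability."""

    score: float
    bin_counts: tuple[int, ...]
    n_bins: int
    n_subjects: int

    def as_dict(self) -> dict:
        return {
            "score": self.score,
            "bin_counts": list(self.bin_counts),
            "n": self.n_bins,
            "n_subjects": self.n_subjects,
        }


def nos(conj: ConjunctionImage, n: int = 10, bin_rule: str = "gt") -> NOSResult:
    """Compute the normalized overlap score of a conjunction image.

    Parameters
    ----------
    conj:
        Integer-count conjunction image (k out of N subjects per voxel).
    n:
        Number of super-level-set bins; 10 matches the standard 10% steps.
    bin_rule:
        ``"gt"`` (default): v_i = |{voxels : s > i/n}|, the strict rule under
        which the i = 0 bin reduces to the support |{s > 0}|.
        ``"ge"``: v_i = |{voxels : s >= i/n}| for i >= 1 (i = 0 stays the
        support so the leading term is always 1).

    Raises
    ------
    EmptyConjunctionError
        if no voxel is covered (v_0 = 0).
    DegenerateSupportError
        if the support is one voxel (ln v_0 = 0).
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if bin_rule not in ("gt", "ge"):
        raise ValueError(f"bin_rule must be gt|ge, got {bin_rule!r}")

    k = conj.counts
    N = conj.n_subjects
    # histogram of coverage counts: hist[c] = #voxels with k == c
    hist = np.bincount(k.ravel(), minlength=N + 1).astype(np.int64)

    bin_counts = []
    for i in range(n):
        # s > i/n  <=>  k*n > i*N  (exact integers); s >= i/n <=> k*n >= i*N
        if bin_rule == "gt" or i == 0:
            thresh_counts = [c for c in range(1, N + 1) if c * n > i * N]
        else:
            thresh_counts = [c for c in range(1, N + 1) if c * n >= i * N]
        bin_counts.append(int(hist[thresh_counts].sum()) if thresh_counts else 0)

    v0 = bin_counts[0]
    if v0 == 0:
        raise EmptyConjunctionError("conjunction image has no covered voxels")
    if v0 == 1:
        raise DegenerateSupportError(
            "support is a single voxel; ln(v_0) = 0 makes NOS undefined"
        )

    log_v0 = math.log(v0)
    score = sum(math.log(v) / log_v0 for v in bin_counts if v > 0) / n
    return NOSResult(
        score=score,
        bin_counts=tuple(bin_counts),
        n_bins=n,
        n_subjects=N,
    )


def nos_from_masks(masks: list[BinaryMask], n: int = 10, bin_rule: str = "gt") -> NOSResult:
    """Convenience: stack per-subject binary masks and score the result."""
    return nos(build_conjunction(masks), n=n, bin_rule=bin_rule)
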