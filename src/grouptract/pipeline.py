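"""The group pipeline: embed -> filter -> warp -> merge -> conjoin -> score.

Runs the whole per-anatomy flow for a cohort of subjects, in both the
filtered and unfiltered conditions, and writes a run directory containing
the merged tractogram, conjunction counts image, level masks, NOS JSON, a
slice-montage report and a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conjunction import ConjunctionImage, build_conjunction, rasterize, threshold_levels
from .core import (
    ImageGrid,
    LabelVolume,
    ScalarVolume,
    Tractogram,
    merge_tractograms,
    read_tractogram,
    read_volume,
    write_tractogram,
    write_volume,
)
from .filtering import filter_tractogram
from .nos import nos
from .query import evaluate_query_string
from .transform import AffineTransform, DisplacementField, warp_streamlines
from .transform import embed_scalars as embed_scalars_op

logger = logging.getLogger(__name__)


@dataclass
class SubjectInputs:
    """Per-subject file paths (tractogram, transforms, maps, segmentation)."""

    tractogram: str
    affine: str | None = None
    displacement: str | None = None
    scalar_volumes: dict[str, str] = field(default_factory=dict)
    labels: str | None = None
    labels_lut: str | None = None


@dataclass
class AnatomyConfig:
    """ROI queries and filter semantics for one anatomy."""

    include_queries: list[str] = field(default_factory=list)
    exclude_queries: list[str] = field(default_factory=list)
    include_logic: str = "all"
    intersect_mode: str = "any_point"


@dataclass
class RunConfig:
    subjects: list[SubjectInputs]
    template_grid: str
    anatomies: dict[str, AnatomyConfig]
    nos_bins: int = 10
    conditions: tuple[str, ...] = ("filtered", "unfiltered")
    output_dir: str = "grouptract_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len(set(self.anatomies)) != len(self.anatomies):
            raise ValueError("anatomy names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        subjects = [SubjectInputs(**s) for s in raw.pop("subjects")]
        anatomies = {
            name: AnatomyConfig(**(spec or {}))
            for name, spec in raw.pop("anatomies").items()
        }
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(subjects=subjects, anatomies=anatomies, **raw)

    def validate_paths(self) -> None:
        missing = []
        for s in self.subjects:
            for p in [s.tractogram, s.affine, s.displacement, s.labels,
                      s.labels_lut, *s.scalar_volumes.values()]:
                if p is not None and not Path(p).exists():
                    missing.append(p)
        if not Path(self.template_grid).exists():
            missing.append(self.template_grid)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _load_template_grid(path: str) -> ImageGrid:
    vol = read_volume(path)
    return vol.grid


def process_subject(
    subject: SubjectInputs,
    anatomy: AnatomyConfig,
    template_grid: ImageGrid,
    condition: str,
) -> tuple[Tractogram, dict]:
    """Embed scalars, filter (unless unfiltered), and warp one subject."""
    tract = read_tractogram(subject.tractogram, space_tag="native")
    if tract.grid.dims == (1, 1, 1):
        # TCK carries no reference grid; adopt the subject's native grid
        native_grid = template_grid
        if subject.labels is not None:
            native_grid = read_volume(subject.labels, lut_path=subject.labels_lut).grid
        tract = Tractogram(tract.streamlines, native_grid, "native")
    counts = {"input": len(tract)}

    if subject.scalar_volumes:
        vols = {name: read_volume(p) for name, p in subject.scalar_volumes.items()}
        tract = embed_scalars_op(tract, vols, mode="lenient")

    if condition == "filtered" and (anatomy.include_queries or anatomy.exclude_queries):
        if subject.labels is None:
            raise ValueError("filtered condition requires a subject label volume")
        labels = read_volume(subject.labels, lut_path=subject.labels_lut)
        assert isinstance(labels, LabelVolume)
        include = [evaluate_query_string(q, labels) for q in anatomy.include_queries]
        exclude = [evaluate_query_string(q, labels) for q in anatomy.exclude_queries]
        result = filter_tractogram(
            tract, include, exclude,
            mode=anatomy.intersect_mode, include_logic=anatomy.include_logic,
        )
        tract = result.tractogram
        counts["kept"] = result.kept
        counts["discarded"] = result.discarded
    else:
        counts["kept"] = len(tract)
        counts["discarded"] = 0

    aff = AffineTransform.from_text(subject.affine) if subject.affine else AffineTransform.identity()
    disp = DisplacementField.read(subject.displacement) if subject.displacement else None
    tract = warp_streamlines(tract, aff, disp, template_grid=template_grid)
    return tract, counts


def run_anatomy(
    config: RunConfig,
    anatomy_name: str,
    condition: str,
    out_dir: Path,
) -> dict:
    """Run one (anatomy, condition) cell end to end and write its outputs."""
    anatomy = config.anatomies[anatomy_name]
    template_grid = _load_template_grid(config.template_grid)

    warped: list[Tractogram] = []
    per_subject = []
    for subject in config.subjects:
        tract, counts = process_subject(subject, anatomy, template_grid, condition)
        warped.append(tract)
        per_subject.append(counts)
        logger.info("%s/%s: subject %s: %s", anatomy_name, condition,
                    subject.tractogram, counts)

    merged = merge_tractograms(warped)
    masks = [rasterize(t, template_grid) for t in warped]
    conj = build_conjunction(masks)
    result = nos(conj, n=config.nos_bins)
    levels = threshold_levels(conj)

    out_dir.mkdir(parents=True, exist_ok=True)
    write_tractogram(merged, out_dir / "merged.trk")
    conj.write(out_dir / "conjunction_counts.nii.gz")
    s_vol = ScalarVolume(values=conj.overlap_fraction, grid=conj.grid)
    write_volume(s_vol, out_dir / "conjunction_fraction.nii.gz")
    for j, mask in enumerate(levels, start=1):
        write_volume(mask, out_dir / f"level_{j:02d}.nii.gz")
    (out_dir / "nos.json").write_text(json.dumps(result.as_dict(), indent=2) + "\n")

    from .report import montage_report  # deferred: matplotlib import cost
    montage_report(conj, out_dir / "report.png",
                   title=f"{anatomy_name} ({condition}) — NOS {result.score:.3f}")

    return {
        "anatomy": anatomy_name,
        "condition": condition,
        "n_subjects": len(config.subjects),
        "merged_streamlines": len(merged),
        "per_subject_counts": per_subject,
        "nos": result.as_dict(),
        "outputs": str(out_dir),
    }


def run_group(config: RunConfig) -> dict:
    """Run every anatomy and condition; a failure in one anatomy is recorded
    and the rest continue.  Returns the manifest (also written to disk);
    raises RuntimeError if every anatomy fails."""
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    root = Path(config.output_dir)
    root.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"version": __version__, "seed": config.seed, "anatomies": {}}
    n_failed = 0
    for anatomy_name in config.anatomies:
        manifest["anatomies"][anatomy_name] = {}
        for condition in config.conditions:
            cell_dir = root / anatomy_name / condition
            try:
                summary = run_anatomy(config, anatomy_name, condition, cell_dir)
            except Exception as exc:
                logger.error("anatomy %s (%s) failed: %s", anatomy_name, condition, exc)
                summary = {
                    "anatomy": anatomy_name,
                    "condition": condition,
                    "error": f"{type(exc).__name__}: {exc}",
                    "traceback": traceback.format_exc(),
                }
                n_failed += 1
            manifest["anatomies"][anatomy_name][condition] = summary

    (root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    n_cells = len(config.anatomies) * len(config.conditions)
    if n_cells and n_failed == n_cells:
        raise RuntimeError("all anatomies failed; see manifest.json")
    return manifest
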