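"""2D slice-montage reports of conjunction overlap images.

Axial/coronal/sagittal maximum-intensity projections of the overlap
fraction, rendered with a perceptually uniform color map so that equal
steps in overlap read as equal steps in brightness (no rainbow artifacts
biasing visual judgment)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .conjunction import ConjunctionImage

_VIEWS = (("sagittal", 0), ("coronal", 1), ("axial", 2))


def montage_report(
    conj: ConjunctionImage,
    out_path: str | Path,
    title: str = "",
    cmap: str = "viridis",
) -> Path:
    """Write a 3-panel MIP montage PNG; returns the output path."""
    s = conj.overlap_fraction
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 4))
    for ax, (view, axis) in zip(axes, _VIEWS):
        mip = s.max(axis=axis)
        im = ax.imshow(mip.T, origin="lower", cmap=cmap, vmin=0.0, vmax=1.0)
        ax.set_title(view)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, fraction=0.03, pad=0.02,
                 label="overlap fraction s = k/N")
    if title:
        fig.suptitle(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
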