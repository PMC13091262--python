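"""Rendering datasets as annotated MSA raster images.

Reproduces the benchmark's visual protocol: sequences wrapped into rows
of 60 alignment columns, residue numbers every 10 columns, and each
ground-truth region drawn as a colored bar with its name above in the
same color. Output is standardized to an exact pixel size (default
1006 x 867) by post-render resampling, since native figure output
varies with backend and DPI.

A region spanning a wrap boundary is split across row panels — the
visual situation that invites annotators to read the fragments as
separate regions.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle
from PIL import Image

from .io import write_ground_truth  # re-exported: sidecar lives with the image
from .synthetic import GAP, Dataset, RegionAnnotation

PathLike = Union[str, Path]

DEFAULT_PALETTE = ("red", "green", "blue", "orange", "purple")

# Clustal-like residue group coloring for the alignment letters.
_RESIDUE_COLORS = {
    **{aa: "#1f77b4" for aa in "AILMFWV"},   # hydrophobic
    **{aa: "#d62728" for aa in "KR"},        # positive
    **{aa: "#9467bd" for aa in "ED"},        # negative
    **{aa: "#2ca02c" for aa in "NQST"},      # polar
    "C": "#e377c2",
    "G": "#8c564b",
    "P": "#bcbd22",
    **{aa: "#17becf" for aa in "HY"},
    GAP: "#999999",
}


@dataclass(frozen=True)
class RenderStyle:
    """Visual parameters of the rendered benchmark image."""

    wrap_length: int = 60
    tick_interval: int = 10
    palette: tuple[str, ...] = DEFAULT_PALETTE
    canvas_size: tuple[int, int] = (1006, 867)
    image_format: str = "PNG"

    def __post_init__(self) -> None:
        if self.wrap_length < 1 or self.tick_interval < 1:
            raise ValueError("wrap_length and tick_interval must be >= 1")
        if not self.palette:
            raise ValueError("palette must be non-empty")
        if min(self.canvas_size) < 1:
            raise ValueError("canvas dimensions must be positive")

    def to_dict(self) -> dict:
        return {
            "wrap_length": self.wrap_length,
            "tick_interval": self.tick_interval,
            "palette": list(self.palette),
            "canvas_size": list(self.canvas_size),
            "image_format": self.image_format,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RenderStyle":
        d = dict(d)
        for key in ("palette", "canvas_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def assign_colors(
    regions: Sequence[RegionAnnotation],
    palette: Sequence[str],
    rng: np.random.Generator,
) -> list[RegionAnnotation]:
    """Give each region an independent uniform color draw (collisions allowed)."""
    if not palette:
        raise ValueError("palette must be non-empty")
    idx = rng.integers(0, len(palette), size=len(regions))
    return [r.with_color(palette[int(i)]) for r, i in zip(regions, idx)]


def _panel_regions(
    regions: Sequence[RegionAnnotation], c0: int, c1: int
) -> list[tuple[RegionAnnotation, int, int, bool]]:
    """Clip regions to the column window [c0+1, c1]; flag the piece holding the start."""
    out = []
    for r in regions:
        lo, hi = max(r.start, c0 + 1), min(r.end, c1)
        if lo <= hi:
            out.append((r, lo, hi, r.start >= c0 + 1))
    return out


def render_msa_image(
    dataset: Dataset,
    style: RenderStyle = RenderStyle(),
    out_path: Optional[PathLike] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Render one dataset to a raster image; returns the render record.

    Regions must carry colors, or an ``rng`` must be supplied so colors
    can be drawn here. The output file is resampled to exactly
    ``style.canvas_size`` pixels.
    """
    regions = list(dataset.regions)
    for r in regions:
        if r.start < 1 or r.end > dataset.msa.n_columns:
            raise ValueError(f"region {r.sbre!r} outside alignment columns")
    if any(r.color is None for r in regions):
        if rng is None:
            raise ValueError("regions lack colors and no rng was provided")
        regions = assign_colors(regions, style.palette, rng)

    msa = dataset.msa
    wrap = style.wrap_length
    n_panels = max(1, -(-msa.n_columns // wrap))
    n_seq = msa.n_sequences

    rows_per_panel = n_seq + 3.6  # bar lane + tick lane + sequence rows
    fig_h = 0.24 * rows_per_panel * n_panels
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(10.5, fig_h), squeeze=False, dpi=100
    )
    fig.subplots_adjust(left=0.07, right=0.99, top=0.995, bottom=0.005, hspace=0.12)

    label_y, bar_y, tick_y = 0.45, 1.35, 2.45
    seq_y0 = 3.4

    for p in range(n_panels):
        ax = axes[p][0]
        c0, c1 = p * wrap, min((p + 1) * wrap, msa.n_columns)
        width = c1 - c0
        ax.set_xlim(0, wrap)
        ax.set_ylim(seq_y0 + n_seq - 0.4, -0.4)
        ax.axis("off")

        # residue-number ticks
        first_tick = (c0 // style.tick_interval + 1) * style.tick_interval
        for c in range(first_tick, c1 + 1, style.tick_interval):
            ax.text(c - c0 - 0.5, tick_y, str(c), ha="center", va="center",
                    fontsize=6.5, color="#444444")

        # sequence letters
        for row, (seq_id, seq) in enumerate(zip(msa.ids, msa.sequences)):
            y = seq_y0 + row
            ax.text(-1.0, y, seq_id, ha="right", va="center", fontsize=6.0,
                    color="#222222", family="monospace")
            for j in range(width):
                ch = seq[c0 + j]
                ax.text(j + 0.5, y, ch, ha="center", va="center", fontsize=6.5,
                        family="monospace", color=_RESIDUE_COLORS.get(ch, "black"))

        # region bars and names
        for region, lo, hi, has_start in _panel_regions(regions, c0, c1):
            x0, x1 = lo - 1 - c0, hi - c0
            ax.add_patch(Rectangle((x0, bar_y - 0.3), x1 - x0, 0.6,
                                   facecolor=region.color, edgecolor="none"))
            if has_start:
                ax.text(x0, label_y, region.sbre, ha="left", va="center",
                        fontsize=7.5, color=region.color)

    buf = _io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    buf.seek(0)
    image = Image.open(buf).convert("RGB")
    if image.size != tuple(style.canvas_size):
        image = image.resize(tuple(style.canvas_size), Image.LANCZOS)
    if out_path is not None:
        image.save(str(out_path), format=style.image_format)

    return {
        "dataset_id": dataset.dataset_id,
        "image_path": str(out_path) if out_path is not None else None,
        "colors": {r.sbre: r.color for r in regions},
        "style": style.to_dict(),
    }
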