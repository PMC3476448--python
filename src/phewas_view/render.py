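"""Rasterize layouts to image files with matplotlib.

Rendering consumes a :class:`~phewas_view.layout.PlotLayout` or
:class:`~phewas_view.sunplot.SunLayout` verbatim — geometry is never
recomputed here.  Output is PNG by default at 300 dpi (72 dpi in low-res
mode); other raster formats depend on the matplotlib backend and an unknown
format raises an error listing the supported ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import to_rgb
from PIL import Image

from .layout import PlotConfig, PlotLayout
from .model import LayoutError, PheWASError
from .sunplot import SunLayout

__all__ = ["RenderResult", "render"]

_MARKERS = {"circle": "o", "triangle_up": "^", "triangle_down": "v"}


@dataclass(frozen=True)
class RenderResult:
    """Where and how a plot was written."""

    output_path: Path
    format: str
    dpi: int
    width: int
    height: int


def _check_format(fmt: str) -> str:
    fmt = fmt.lower().lstrip(".")
    supported = plt.figure().canvas.get_supported_filetypes()
    plt.close()
    if fmt not in supported:
        raise PheWASError(
            f"unsupported image format {fmt!r}; this installation supports: "
            + ", ".join(sorted(supported))
        )
    return fmt


def _finish(fig, output_path: Path, fmt: str, dpi: int) -> RenderResult:
    fig.savefig(output_path, format=fmt, dpi=dpi)
    plt.close(fig)
    if fmt == "png":
        with Image.open(output_path) as img:
            width, height = img.size
    else:
        width = int(fig.get_figwidth() * dpi)
        height = int(fig.get_figheight() * dpi)
    return RenderResult(
        output_path=Path(output_path),
        format=fmt,
        dpi=dpi,
        width=width,
        height=height,
    )


def _group_points(layout: PlotLayout) -> Dict[tuple, List]:
    """Bucket points by (color, glyph) so each bucket is one scatter call."""
    buckets: Dict[tuple, List] = {}
    for p in layout.points:
        buckets.setdefault((p.color, p.glyph), []).append(p)
    return buckets


def _render_standard(
    layout: PlotLayout, config: PlotConfig, output_path: Path, fmt: str
) -> RenderResult:
    if not layout.points:
        raise LayoutError("refusing to render an empty layout")
    vertical = layout.orientation == "vertical"
    n_phen = len(layout.phenotype_axis)

    n_panels = 1
    ratios = [4.0]
    if layout.effect_track is not None:
        n_panels += 1
        ratios.append(1.0)
    if layout.sample_size_track is not None:
        n_panels += 1
        ratios.append(1.0)
    if layout.heatmap is not None:
        n_panels += 1
        ratios.append(2.0)

    long_axis = max(4.0, 0.35 * n_phen + 2.0)
    cross_axis = 3.0 + 1.5 * (n_panels - 1) + (2.0 if vertical else 0.0)
    figsize = (cross_axis, long_axis) if vertical else (long_axis, cross_axis)
    gridspec_kw = (
        {"width_ratios": ratios} if vertical else {"height_ratios": ratios}
    )
    fig, axes = plt.subplots(
        nrows=1 if vertical else n_panels,
        ncols=n_panels if vertical else 1,
        figsize=figsize,
        sharey=vertical,
        sharex=not vertical,
        gridspec_kw=gridspec_kw,
        squeeze=False,
    )
    axes = axes.ravel()
    main = axes[0]

    for (color, glyph), pts in _group_points(layout).items():
        xs = [p.position for p in pts]
        ys = [p.value for p in pts]
        if vertical:
            xs, ys = ys, xs
        main.scatter(
            xs, ys, c=color, marker=_MARKERS[glyph], s=28, zorder=3,
            edgecolors="none",
        )

    positions = [pos for _, pos in layout.phenotype_axis]
    labels = [label for label, _ in layout.phenotype_axis]
    if vertical:
        main.set_yticks(positions)
        main.set_yticklabels(labels, fontsize=8)
        main.set_xlabel(r"$-\log_{10}$(p-value)")
        main.invert_yaxis()
        if layout.redline is not None:
            main.axvline(layout.redline, color="red", zorder=2)
        if layout.show_grid_lines:
            main.grid(axis="x", color="0.85", zorder=0)
    else:
        main.set_xticks(positions)
        main.set_xticklabels(labels, fontsize=8, rotation=90)
        main.set_ylabel(r"$-\log_{10}$(p-value)")
        if layout.redline is not None:
            main.axhline(layout.redline, color="red", zorder=2)
        if layout.show_grid_lines:
            main.grid(axis="y", color="0.85", zorder=0)

    for pos, text in layout.annotations:
        if vertical:
            xmax = max(p.value for p in layout.points)
            main.text(xmax * 1.02, pos, text, fontsize=7, va="center")
        else:
            ymax = max(p.value for p in layout.points)
            main.text(pos, ymax * 1.02, text, fontsize=7, rotation=90,
                      ha="center")

    panel = 1
    for track, label in (
        (layout.effect_track, "effect size"),
        (layout.sample_size_track, "sample size"),
    ):
        if track is None:
            continue
        ax = axes[panel]
        panel += 1
        xs = [pos for pos, _ in track]
        ys = [val for _, val in track]
        if vertical:
            ax.scatter(ys, xs, c="black", marker="o", s=12)
            ax.set_xlabel(label, fontsize=8)
            if label == "effect size":
                ax.axvline(0.0, color="0.6", linewidth=0.8)
        else:
            ax.scatter(xs, ys, c="black", marker="o", s=12)
            ax.set_ylabel(label, fontsize=8)
            if label == "effect size":
                ax.axhline(0.0, color="0.6", linewidth=0.8)

    if layout.heatmap is not None:
        ax = axes[panel]
        grid = np.ones((n_phen, n_phen, 3))
        for r, c, color in layout.heatmap:
            grid[r, c, :] = to_rgb(color)
        # origin/extent chosen so heatmap rows line up with axis positions
        ax.imshow(
            grid,
            origin="lower",
            extent=(-0.5, n_phen - 0.5, -0.5, n_phen - 0.5),
            interpolation="nearest",
        )
        if vertical:
            ax.set_xticks([])
        else:
            ax.set_yticks([])

    if layout.title:
        fig.suptitle(layout.title)
    fig.tight_layout()
    return _finish(fig, output_path, fmt, config.dpi)


def _render_sun(
    layout: SunLayout, config: PlotConfig, output_path: Path, fmt: str
) -> RenderResult:
    if not layout.rays:
        raise LayoutError("refusing to render an empty sun layout")
    fig, ax = plt.subplots(figsize=(8, 8))
    for ray in layout.rays:
        # clockwise from 12 o'clock -> standard math angle
        theta = math.radians(90.0 - ray.angle)
        x = ray.length * math.cos(theta)
        y = ray.length * math.sin(theta)
        ax.plot([0, x], [0, y], color=ray.color, linewidth=1.4, zorder=2)
        ha = "left" if x >= 0 else "right"
        ax.text(x * 1.05, y * 1.05, ray.label, fontsize=7, ha=ha,
                va="center", zorder=3)
    ax.text(0, -0.06, layout.center_label, fontsize=11, ha="center",
            va="top", weight="bold", zorder=4)
    ax.text(0, 1.12, layout.scale_annotation, fontsize=9, ha="center")
    ax.set_xlim(-1.45, 1.45)
    ax.set_ylim(-1.45, 1.45)
    ax.set_aspect("equal")
    ax.axis("off")
    if config.title:
        fig.suptitle(config.title)
    return _finish(fig, output_path, fmt, config.dpi)


def render(
    layout: Union[PlotLayout, SunLayout],
    config: PlotConfig,
    output_path: Union[str, Path],
) -> RenderResult:
    """Write a layout to an image file and report its geometry.

    Raises
    ------
    PheWASError
        If the requested image format is not supported by the backend.
    LayoutError
        If the layout contains nothing to draw (no file is written).
    """
    output_path = Path(output_path)
    fmt = _check_format(config.image_format)
    if isinstance(layout, SunLayout):
        return _render_sun(layout, config, output_path, fmt)
    return _render_standard(layout, config, output_path, fmt)
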