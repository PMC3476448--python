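"""Renderer-independent geometry for standard and vertical plots.

The layout engine turns a filtered, classified dataset into a
:class:`PlotLayout`: phenotype axis positions, one point per record at
(position, -log10 p) with a color role and glyph, optional best-hit
annotations, an optional red significance rule, optional effect-size and
sample-size tracks, and an optional correlation-heatmap panel.  Renderers
consume the layout verbatim; it also serializes to a plain-dict structure
used as the deterministic test surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .filters import SignificanceClass, best_per_phenotype, neg_log10
from .model import (
    ConfigurationError,
    CorrelationMatrix,
    DEFAULT_GROUP_STYLES,
    EmptyResultError,
    GroupStyleMap,
    LayoutError,
    PheWASDataset,
)

__all__ = [
    "PlotConfig",
    "PlotPoint",
    "PlotLayout",
    "assign_axis_positions",
    "build_standard_layout",
    "build_vertical_layout",
    "build_group_glyph_layout",
    "build_tracks",
    "build_heatmap_panel",
    "heatmap_color",
    "best_annotation_text",
]

# Color roles attached to significance classes.  The single-series default
# (no -p / -x classification) is blue; grey is reserved for below-threshold
# background points; novel associations are purple.
_CLASS_COLORS = {
    SignificanceClass.HIGHLIGHT: "blue",
    SignificanceClass.BACKGROUND: "grey",
    SignificanceClass.EXPECTED: "blue",
    SignificanceClass.NOVEL: "purple",
}

_HEATMAP_YELLOW = (255, 255, 0)  # |r| = 1
_HEATMAP_BLUE = (0, 0, 255)  # |r| = 0


@dataclass(frozen=True)
class PlotConfig:
    """Presentation options for a standard or vertical plot."""

    title: str = ""
    orientation: str = "horizontal"  # or "vertical"
    show_grid_lines: bool = True
    show_best_annotations: bool = False
    show_effect_track: bool = False
    show_sample_size_track: bool = False
    show_heatmap: bool = False
    redline_p: Optional[float] = None
    group_styles: GroupStyleMap = DEFAULT_GROUP_STYLES
    dpi: int = 300
    image_format: str = "png"

    def __post_init__(self) -> None:
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.dpi not in (300, 72):
            raise ValueError(f"dpi must be 300 or 72, got {self.dpi}")
        if self.redline_p is not None and not (0.0 < self.redline_p <= 1.0):
            raise ValueError("redline_p must be in (0, 1]")


@dataclass(frozen=True)
class PlotPoint:
    """One plotted association: axis position, height, color and glyph."""

    position: int
    value: float  # -log10(p), finite and >= 0
    color: str
    glyph: str  # circle | triangle_up | triangle_down
    phenotype: str
    snp_id: str
    group: Optional[str] = None


@dataclass(frozen=True)
class PlotLayout:
    """Complete renderer-independent description of one plot."""

    orientation: str
    title: str
    phenotype_axis: Tuple[Tuple[str, int], ...]  # (display label, position)
    points: Tuple[PlotPoint, ...]
    annotations: Tuple[Tuple[int, str], ...] = ()
    redline: Optional[float] = None
    effect_track: Optional[Tuple[Tuple[int, float], ...]] = None
    sample_size_track: Optional[Tuple[Tuple[int, int], ...]] = None
    heatmap: Optional[Tuple[Tuple[int, int, str], ...]] = None
    show_grid_lines: bool = True

    def to_dict(self) -> dict:
        """Plain-dict serialization (stable key order, JSON-ready)."""
        return {
            "kind": "standard",
            "orientation": self.orientation,
            "title": self.title,
            "phenotype_axis": [
                {"label": label, "position": pos}
                for label, pos in self.phenotype_axis
            ],
            "points": [
                {
                    "position": p.position,
                    "value": p.value,
                    "color": p.color,
                    "glyph": p.glyph,
                    "phenotype": p.phenotype,
                    "snp": p.snp_id,
                    "group": p.group,
                }
                for p in self.points
            ],
            "annotations": [
                {"position": pos, "text": text}
                for pos, text in self.annotations
            ],
            "redline": self.redline,
            "effect_track": (
                None
                if self.effect_track is None
                else [list(pair) for pair in self.effect_track]
            ),
            "sample_size_track": (
                None
                if self.sample_size_track is None
                else [list(pair) for pair in self.sample_size_track]
            ),
            "heatmap": (
                None
                if self.heatmap is None
                else [
                    {"row": r, "col": c, "color": color}
                    for r, c, color in self.heatmap
                ]
            ),
            "show_grid_lines": self.show_grid_lines,
        }


def assign_axis_positions(
    dataset: PheWASDataset,
) -> List[Tuple[str, int]]:
    """Phenotypes at consecutive integer positions in first-appearance order.

    Plots never sort: the axis follows the input file, so a file pre-sorted
    by p-value yields an axis in that sorted order.
    """
    if len(dataset) == 0:
        raise LayoutError("cannot lay out an empty dataset")
    return [(phen, i) for i, phen in enumerate(dataset.phenotypes)]


def _axis_labels(
    dataset: PheWASDataset, axis: Sequence[Tuple[str, int]]
) -> List[Tuple[str, int]]:
    """Display labels for the axis: long description when present."""
    if not dataset.has_long_description:
        return list(axis)
    long_by_phen: Dict[str, str] = {}
    for rec in dataset:
        if rec.phenotype not in long_by_phen and rec.phenotype_long:
            long_by_phen[rec.phenotype] = rec.phenotype_long
    return [(long_by_phen.get(phen, phen), pos) for phen, pos in axis]


def best_annotation_text(
    snp_id: str, gene: Optional[str], effect: Optional[float]
) -> str:
    """Best-hit annotation: "<snp> <gene> <sign>", missing fields omitted."""
    parts = [snp_id]
    if gene:
        parts.append(gene)
    if effect is not None:
        parts.append("+" if effect >= 0 else "-")
    return " ".join(parts)


def _build_layout(
    dataset: PheWASDataset,
    config: PlotConfig,
    classes: Optional[Sequence[SignificanceClass]],
    orientation: str,
    group_glyphs: bool = False,
) -> PlotLayout:
    if len(dataset) == 0:
        raise EmptyResultError(
            "no records left to plot; relax the filters (-c/-L/-s/-r/-m)"
        )
    if classes is not None and len(classes) != len(dataset):
        raise ValueError("classes must align one-to-one with records")

    axis = assign_axis_positions(dataset)
    position = {phen: pos for phen, pos in axis}

    points = []
    for i, rec in enumerate(dataset):
        if group_glyphs:
            if rec.group is None:
                raise ConfigurationError(
                    f"record {rec.snp_id}/{rec.phenotype} has no group label"
                )
            color = config.group_styles.color(rec.group)
            glyph = (
                "triangle_up"
                if (rec.effect is None or rec.effect >= 0)
                else "triangle_down"
            )
        else:
            cls = classes[i] if classes is not None else None
            color = _CLASS_COLORS.get(cls, "blue")
            glyph = "circle"
        points.append(
            PlotPoint(
                position=position[rec.phenotype],
                value=neg_log10(rec.p_value),
                color=color,
                glyph=glyph,
                phenotype=rec.phenotype,
                snp_id=rec.snp_id,
                group=rec.group,
            )
        )

    annotations: List[Tuple[int, str]] = []
    if config.show_best_annotations:
        if not (dataset.has_gene or dataset.has_effect):
            import logging

            logging.getLogger("phewas_view").warning(
                "best-hit annotations degrade to SNP id only: no Gene or ES "
                "column in the input"
            )
        for phen, rec in best_per_phenotype(dataset).items():
            annotations.append(
                (
                    position[phen],
                    best_annotation_text(rec.snp_id, rec.gene, rec.effect),
                )
            )

    effect_track = sample_size_track = None
    if config.show_effect_track or config.show_sample_size_track:
        effect_track, sample_size_track = build_tracks(dataset, config)

    redline = (
        neg_log10(config.redline_p) if config.redline_p is not None else None
    )

    return PlotLayout(
        orientation=orientation,
        title=config.title,
        phenotype_axis=tuple(_axis_labels(dataset, axis)),
        points=tuple(points),
        annotations=tuple(annotations),
        redline=redline,
        effect_track=effect_track,
        sample_size_track=sample_size_track,
        heatmap=None,
        show_grid_lines=config.show_grid_lines,
    )


def build_standard_layout(
    dataset: PheWASDataset,
    config: PlotConfig,
    classes: Optional[Sequence[SignificanceClass]] = None,
) -> PlotLayout:
    """Horizontal layout: phenotypes on x, -log10(p) on y, one point per
    record; color roles from the per-record significance classes."""
    return _build_layout(dataset, config, classes, "horizontal")


def build_vertical_layout(
    dataset: PheWASDataset,
    config: PlotConfig,
    classes: Optional[Sequence[SignificanceClass]] = None,
) -> PlotLayout:
    """Vertical layout: phenotypes listed down the y axis with readable
    horizontal labels, -log10(p) on x.

    This is a true re-layout, not a raster rotation: the point set is the
    exact transpose of the horizontal layout, and best-hit annotations
    (SNP id, gene symbol, effect-direction sign) attach to phenotype rows.
    """
    return _build_layout(dataset, config, classes, "vertical")


def build_group_glyph_layout(
    dataset: PheWASDataset, config: PlotConfig
) -> PlotLayout:
    """Group-comparison layout: per-record triangles, up for effect >= 0 and
    down for negative effect, colored by the group style map."""
    if not dataset.has_group:
        raise ConfigurationError(
            "group-comparison plot requires a Groups column"
        )
    if not dataset.has_effect:
        raise ConfigurationError("group-comparison plot requires an ES column")
    return _build_layout(
        dataset, config, None, config.orientation, group_glyphs=True
    )


def build_tracks(
    dataset: PheWASDataset, config: PlotConfig
) -> Tuple[
    Optional[Tuple[Tuple[int, float], ...]],
    Optional[Tuple[Tuple[int, int], ...]],
]:
    """Per-point effect-size and sample-size track values, aligned to the
    phenotype axis positions of the main panel."""
    position = {phen: pos for phen, pos in assign_axis_positions(dataset)}
    effect_track = sample_size_track = None
    if config.show_effect_track:
        if not dataset.has_effect:
            raise ConfigurationError(
                "effect-direction track requested (-b) but the input has no "
                "ES column"
            )
        effect_track = tuple(
            (position[r.phenotype], r.effect)
            for r in dataset
            if r.effect is not None
        )
    if config.show_sample_size_track:
        if not dataset.has_sample_size:
            raise ConfigurationError(
                "sample-size track requested (-A) but the input has no "
                "sample-size column"
            )
        sample_size_track = tuple(
            (position[r.phenotype], r.sample_size)
            for r in dataset
            if r.sample_size is not None
        )
    return effect_track, sample_size_track


def heatmap_color(r: float) -> str:
    """Hex cell color for a correlation r: linear RGB ramp on |r| from blue
    (0, 0, 255) at |r| = 0 to yellow (255, 255, 0) at |r| = 1."""
    a = abs(r)
    if a > 1.0 + 1e-9:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    a = min(a, 1.0)
    rgb = tuple(
        round(lo + a * (hi - lo))
        for lo, hi in zip(_HEATMAP_BLUE, _HEATMAP_YELLOW)
    )
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def build_heatmap_panel(
    matrix: CorrelationMatrix, axis: Sequence[Tuple[str, int]]
) -> Tuple[Tuple[int, int, str], ...]:
    """Correlation-heatmap grid aligned to the phenotype axis.

    Cell (i, j) is colored by |r| between the phenotypes at axis positions
    i and j, so r and -r produce identical cells.
    """
    for phen, _ in axis:
        if phen not in matrix.labels:
            raise LayoutError(
                f"phenotype {phen!r} missing from the correlation matrix"
            )
    cells = []
    for phen_i, pos_i in axis:
        for phen_j, pos_j in axis:
            cells.append(
                (pos_i, pos_j, heatmap_color(matrix.abs_value(phen_i, phen_j)))
            )
    return tuple(cells)
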