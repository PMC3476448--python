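"""Radial "sun plot" geometry for one SNP, gene, or phenotype.

All qualifying results radiate from a central label.  Ray length is linear
in -log10(p), normalized so the most significant result has the maximal
radius; that ray sits at 12 o'clock and the rest sweep clockwise in
decreasing significance at uniform angular spacing.  The minimal p-value is
annotated to give the radial scale.  Rays are red when strictly more
significant than the highlight threshold, grey otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .filters import neg_log10
from .model import (
    AssociationRecord,
    ConfigurationError,
    EmptyResultError,
    PheWASDataset,
)

__all__ = ["SunLayout", "SunRay", "select_sun_records", "build_sun_layout"]

_MODES = ("snp", "gene", "phenotype")


@dataclass(frozen=True)
class SunRay:
    """One radial line: angle clockwise from 12 o'clock, normalized length,
    red/grey color role, and its tip label."""

    angle: float  # degrees in [0, 360)
    length: float  # in (0, 1], 1 = most significant
    color: str  # "red" | "grey"
    label: str
    p_value: float


@dataclass(frozen=True)
class SunLayout:
    """Complete renderer-independent description of one sun plot."""

    center_label: str
    rays: Tuple[SunRay, ...]
    scale_annotation: str  # most significant p-value, for radial scale

    def to_dict(self) -> dict:
        return {
            "kind": "sun",
            "center_label": self.center_label,
            "rays": [
                {
                    "angle": r.angle,
                    "length": r.length,
                    "color": r.color,
                    "label": r.label,
                    "p": r.p_value,
                }
                for r in self.rays
            ],
            "scale_annotation": self.scale_annotation,
        }


def select_sun_records(
    dataset: PheWASDataset,
    mode: str,
    key: str,
    max_p: float = 1.0,
) -> List[AssociationRecord]:
    """Records for one SNP / gene / phenotype with p <= max_p, sorted by
    ascending p-value (ties by input-file order)."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if not key:
        raise ValueError("key must be non-empty")
    if not (0.0 < max_p <= 1.0):
        raise ValueError(f"max_p must be in (0, 1], got {max_p}")
    if mode == "gene" and not dataset.has_gene:
        raise ConfigurationError(
            "gene-centred sun plot requires a Gene column in the input"
        )

    if mode == "snp":
        matched = [r for r in dataset if r.snp_id == key]
    elif mode == "gene":
        matched = [r for r in dataset if r.gene == key]
    else:
        matched = [r for r in dataset if r.phenotype == key]
    if not matched:
        raise EmptyResultError(f"{mode} {key!r} not found in the input file")

    survivors = [r for r in matched if r.p_value <= max_p]
    if not survivors:
        raise EmptyResultError(
            f"no results for {mode} {key!r} pass p <= {max_p}; "
            f"loosen the -m threshold"
        )
    return sorted(survivors, key=lambda r: (r.p_value, r.row_index))


def build_sun_layout(
    records: List[AssociationRecord],
    highlight_p: Optional[float] = None,
    show_gene: bool = False,
    show_group: bool = False,
    show_effect_sign: bool = False,
    center_label: Optional[str] = None,
    label_field: str = "phenotype",
) -> SunLayout:
    """Lay out significance-sorted records as rays around a center label.

    n records give n rays at uniform 360/n degree spacing, the most
    significant at angle 0 (12 o'clock), the rest clockwise; ray length is
    (-log10 p) / (-log10 p_min) so the top ray has length 1.  A ray is red
    iff p < highlight_p; with no threshold every ray is grey.  Labels carry
    the phenotype (or, for a phenotype-centred plot, the SNP id), the group
    when ``show_group``, and a +/- effect sign when ``show_effect_sign``.
    """
    if not records:
        raise EmptyResultError("sun plot requires at least one record")
    if highlight_p is not None and not (0.0 < highlight_p <= 1.0):
        raise ValueError(f"highlight_p must be in (0, 1], got {highlight_p}")

    top = records[0]
    if any(r.p_value < top.p_value for r in records[1:]):
        raise ValueError("records must be sorted ascending by p-value")

    max_height = neg_log10(top.p_value)
    n = len(records)
    step = 360.0 / n

    if center_label is None:
        center_label = top.snp_id
        if show_gene and top.gene:
            center_label = f"{top.snp_id} ({top.gene})"

    rays = []
    for i, rec in enumerate(records):
        label = rec.snp_id if label_field == "snp" else rec.phenotype
        if show_group and rec.group:
            label = f"{label} [{rec.group}]"
        if show_effect_sign and rec.effect is not None:
            label = f"{label} {'+' if rec.effect >= 0 else '-'}"
        length = (
            neg_log10(rec.p_value) / max_height if max_height > 0 else 1.0
        )
        color = (
            "red"
            if highlight_p is not None and rec.p_value < highlight_p
            else "grey"
        )
        rays.append(
            SunRay(
                angle=i * step,
                length=length,
                color=color,
                label=label,
                p_value=rec.p_value,
            )
        )

    return SunLayout(
        center_label=center_label,
        rays=tuple(rays),
        scale_annotation=f"p = {top.p_value:.3g}",
    )
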