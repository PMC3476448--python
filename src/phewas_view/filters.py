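"""Filters and per-record transformations, independent of plotting.

Threshold semantics: "more significant than" thresholds (the highlight
threshold ``-p``, the expected/novel gate, the sun-plot red threshold) are
strict (p < t); the retention filter ``-m`` is non-strict (p <= t survives).
All filters preserve relative record order and are idempotent.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .model import (
    AssociationRecord,
    ConfigurationError,
    ExpectedPairSet,
    PheWASDataset,
)

__all__ = [
    "SignificanceClass",
    "FilterConfig",
    "neg_log10",
    "filter_by_class",
    "filter_by_phenotype_list",
    "filter_by_snp",
    "filter_by_groups",
    "filter_by_max_p",
    "classify_significance",
    "classify_expected",
    "classify_dataset",
    "best_per_phenotype",
    "apply_filters",
]

logger = logging.getLogger("phewas_view")


class SignificanceClass(enum.Enum):
    """Display category of one record under the active configuration."""

    HIGHLIGHT = "highlight"
    BACKGROUND = "background"
    EXPECTED = "expected"
    NOVEL = "novel"
    FILTERED_OUT = "filtered_out"


@dataclass(frozen=True)
class FilterConfig:
    """User-selected filters and thresholds for a standard plot.

    ``phenotype_class`` and ``phenotype_list`` are mutually exclusive at the
    CLI; all thresholds live in (0, 1].  ``redline_p`` is purely an
    annotation and never filters or recolors points.
    """

    phenotype_class: Optional[str] = None
    phenotype_list: Optional[Sequence[str]] = None
    snp_id: Optional[str] = None
    groups: Optional[Sequence[str]] = None
    max_p: Optional[float] = None
    highlight_p: Optional[float] = None
    redline_p: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("max_p", "highlight_p", "redline_p"):
            value = getattr(self, name)
            if value is not None and not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.phenotype_class is not None and self.phenotype_list:
            raise ValueError(
                "phenotype_class and phenotype_list are mutually exclusive"
            )


def neg_log10(p: float) -> float:
    """-log10(p), the plotted significance magnitude.

    Strictly decreasing in p; defined on (0, 1] so the result is finite and
    non-negative.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -math.log10(p)


def filter_by_class(dataset: PheWASDataset, class_name: str) -> PheWASDataset:
    """Keep records whose phenotype_class equals ``class_name`` exactly."""
    if not dataset.has_class:
        raise ConfigurationError(
            "phenotype-class filtering requested but the input file has no "
            "phenotype_class column"
        )
    survivors = [r for r in dataset if r.phenotype_class == class_name]
    if not survivors:
        logger.warning("phenotype class %r matched no records", class_name)
    return dataset.subset(survivors)


def filter_by_phenotype_list(
    dataset: PheWASDataset, names: Sequence[str]
) -> PheWASDataset:
    """Keep records whose phenotype appears in ``names`` (dataset order)."""
    if not names:
        raise ValueError("phenotype list must be non-empty")
    wanted = set(names)
    present = {r.phenotype for r in dataset}
    for missing in [n for n in names if n not in present]:
        logger.warning("phenotype %r not found in input; ignored", missing)
    return dataset.subset(r for r in dataset if r.phenotype in wanted)


def filter_by_snp(dataset: PheWASDataset, snp_id: str) -> PheWASDataset:
    """Keep records for a single SNP identifier."""
    survivors = [r for r in dataset if r.snp_id == snp_id]
    if not survivors:
        logger.warning("SNP %r matched no records", snp_id)
    return dataset.subset(survivors)


def filter_by_groups(
    dataset: PheWASDataset, groups: Sequence[str]
) -> PheWASDataset:
    """Keep records whose group label is in ``groups``."""
    if not dataset.has_group:
        raise ConfigurationError(
            "group filtering requested but the input file has no Groups "
            "column"
        )
    if not groups:
        raise ConfigurationError("group filter requires at least one label")
    wanted = set(groups)
    return dataset.subset(r for r in dataset if r.group in wanted)


def filter_by_max_p(dataset: PheWASDataset, max_p: float) -> PheWASDataset:
    """Keep records with p <= max_p (values less significant are dropped)."""
    if not (0.0 < max_p <= 1.0):
        raise ValueError(f"max_p must be in (0, 1], got {max_p}")
    survivors = [r for r in dataset if r.p_value <= max_p]
    if not survivors:
        logger.warning("max-p filter %g removed every record", max_p)
    return dataset.subset(survivors)


def classify_significance(
    record: AssociationRecord, highlight_p: float
) -> SignificanceClass:
    """Highlight iff the record is strictly more significant than the
    threshold (p < highlight_p); boundary values are background."""
    if not (0.0 < highlight_p <= 1.0):
        raise ValueError(f"highlight_p must be in (0, 1], got {highlight_p}")
    if record.p_value < highlight_p:
        return SignificanceClass.HIGHLIGHT
    return SignificanceClass.BACKGROUND


def classify_expected(
    record: AssociationRecord,
    pairs: ExpectedPairSet,
    highlight_p: Optional[float] = None,
) -> SignificanceClass:
    """Split qualifying records into expected (known pair) vs novel.

    With a threshold, only records strictly below it are split; the rest
    are background.  Without one, the split applies to every record.
    """
    if highlight_p is not None and record.p_value >= highlight_p:
        return SignificanceClass.BACKGROUND
    if (record.snp_id, record.phenotype) in pairs:
        return SignificanceClass.EXPECTED
    return SignificanceClass.NOVEL


def classify_dataset(
    dataset: PheWASDataset,
    highlight_p: Optional[float] = None,
    expected_pairs: Optional[ExpectedPairSet] = None,
) -> List[SignificanceClass]:
    """Per-record classes for a whole dataset, aligned with its records.

    Expected/novel classification takes precedence when a pair set is
    supplied; otherwise the highlight threshold splits blue vs grey; with
    neither, every record is HIGHLIGHT (single-series default coloring).
    """
    classes = []
    for rec in dataset:
        if expected_pairs is not None:
            classes.append(classify_expected(rec, expected_pairs, highlight_p))
        elif highlight_p is not None:
            classes.append(classify_significance(rec, highlight_p))
        else:
            classes.append(SignificanceClass.HIGHLIGHT)
    return classes


def best_per_phenotype(
    dataset: PheWASDataset,
) -> Dict[str, AssociationRecord]:
    """The most significant record for each phenotype, in display order.

    Ties on p-value are broken by the smallest row index (first occurrence
    in the input file), keeping the result deterministic and order-faithful.
    """
    if len(dataset) == 0:
        raise ValueError("best_per_phenotype requires a non-empty dataset")
    best: Dict[str, AssociationRecord] = {}
    for rec in dataset:
        incumbent = best.get(rec.phenotype)
        if incumbent is None or (rec.p_value, rec.row_index) < (
            incumbent.p_value,
            incumbent.row_index,
        ):
            best[rec.phenotype] = rec
    # re-key in display (first-appearance) order
    return {phen: best[phen] for phen in dataset.phenotypes}


def apply_filters(
    dataset: PheWASDataset, config: FilterConfig
) -> PheWASDataset:
    """Apply the configured filters in the documented order:
    class/list, then SNP, then groups, then max-p.

    The filters commute, so the order only affects which warning fires
    first on an empty intermediate result.
    """
    out = dataset
    if config.phenotype_class is not None:
        out = filter_by_class(out, config.phenotype_class)
    if config.phenotype_list:
        out = filter_by_phenotype_list(out, config.phenotype_list)
    if config.snp_id is not None:
        out = filter_by_snp(out, config.snp_id)
    if config.groups:
        out = filter_by_groups(out, config.groups)
    if config.max_p is not None:
        out = filter_by_max_p(out, config.max_p)
    return out
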