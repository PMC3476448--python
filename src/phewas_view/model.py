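"""Domain types for PheWAS result visualization.

A PheWAS (phenome-wide association study) tests one or more SNPs against a
broad spectrum of phenotypes — the transpose of a GWAS.  The unit of data is
one test of association: a SNP, a phenotype, a p-value, and optional
annotations (gene symbol, signed effect size, population/ancestry group,
sample size, a longer phenotype description, and a phenotype class used for
filtering).  These types are the in-memory contract shared by the parsers,
the filter layer, and the layout engines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "AssociationRecord",
    "PheWASDataset",
    "CorrelationMatrix",
    "GroupStyleMap",
    "ExpectedPairSet",
    "DEFAULT_GROUP_STYLES",
    "PheWASError",
    "FormatError",
    "ConfigurationError",
    "LayoutError",
    "EmptyResultError",
    "MIN_P",
]

#: Smallest representable p-value; zero / underflowed p-values are clamped
#: here so that -log10(p) stays finite.
MIN_P = 1e-300


class PheWASError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PheWASError):
    """An input file violates its dialect (missing column, bad value...)."""


class ConfigurationError(PheWASError):
    """A requested operation needs a column or option that is absent."""


class LayoutError(PheWASError):
    """Layout construction failed (typically: nothing left to plot)."""


class EmptyResultError(LayoutError):
    """Filters removed every record; advise the user to relax them."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-phenotype(-group) test of association.

    ``p_value`` is always in ``(0, 1]`` after parsing (zero is clamped to
    :data:`MIN_P`).  ``row_index`` is the 0-based position of the record in
    its source file and is unique within a dataset; plots preserve file
    order, so it doubles as the deterministic tie-break everywhere.
    """

    snp_id: str
    phenotype: str
    p_value: float
    row_index: int
    phenotype_long: Optional[str] = None
    phenotype_class: Optional[str] = None
    gene: Optional[str] = None
    effect: Optional[float] = None
    group: Optional[str] = None
    sample_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if not self.phenotype:
            raise ValueError("phenotype must be non-empty")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"p_value must be in (0, 1], got {self.p_value!r}"
            )
        if self.sample_size is not None and self.sample_size < 0:
            raise ValueError("sample_size must be non-negative")


@dataclass(frozen=True)
class PheWASDataset:
    """Ordered collection of association records with column-presence flags.

    Phenotype display order on every plot equals the first-appearance order
    of phenotypes in ``records`` (i.e. in the input file); the parser never
    sorts.  Presence flags are true iff the corresponding column existed in
    the source and is populated on at least one record.
    """

    records: Tuple[AssociationRecord, ...]
    has_class: bool = False
    has_gene: bool = False
    has_effect: bool = False
    has_group: bool = False
    has_sample_size: bool = False
    has_long_description: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen = set()
        for rec in self.records:
            if rec.row_index in seen:
                raise ValueError(f"duplicate row_index {rec.row_index}")
            seen.add(rec.row_index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    @property
    def phenotypes(self) -> Tuple[str, ...]:
        """Distinct phenotypes in first-appearance order."""
        out = []
        seen = set()
        for rec in self.records:
            if rec.phenotype not in seen:
                seen.add(rec.phenotype)
                out.append(rec.phenotype)
        return tuple(out)

    def subset(self, records: Iterable[AssociationRecord]) -> "PheWASDataset":
        """A new dataset with the given records and this dataset's flags."""
        return replace(self, records=tuple(records))

    @classmethod
    def from_records(
        cls, records: Sequence[AssociationRecord]
    ) -> "PheWASDataset":
        """Build a dataset inferring presence flags from populated fields."""
        recs = tuple(records)
        return cls(
            records=recs,
            has_class=any(r.phenotype_class is not None for r in recs),
            has_gene=any(r.gene is not None for r in recs),
            has_effect=any(r.effect is not None for r in recs),
            has_group=any(r.group is not None for r in recs),
            has_sample_size=any(r.sample_size is not None for r in recs),
            has_long_description=any(
                r.phenotype_long is not None for r in recs
            ),
        )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Labeled square matrix of pairwise phenotype correlations.

    Stores the signed correlation coefficient r; heatmap rendering uses
    ``abs_value`` so that r and -r display identically.
    """

    labels: Tuple[str, ...]
    values: Tuple[Tuple[float, ...], ...]

    #: Tolerance for the symmetry and unit-diagonal invariants.
    TOLERANCE = 1e-6

    def __post_init__(self) -> None:
        n = len(self.labels)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(
            self, "values", tuple(tuple(row) for row in self.values)
        )
        if len(self.values) != n or any(len(row) != n for row in self.values):
            raise ValueError(
                f"values must be a {n}x{n} square matrix matching labels"
            )
        for i in range(n):
            if abs(self.values[i][i] - 1.0) > self.TOLERANCE:
                raise ValueError(
                    f"diagonal entry [{i}][{i}] = {self.values[i][i]} != 1"
                )
            for j in range(n):
                v = self.values[i][j]
                if not (-1.0 - self.TOLERANCE <= v <= 1.0 + self.TOLERANCE):
                    raise ValueError(f"entry [{i}][{j}] = {v} outside [-1, 1]")
                if abs(v - self.values[j][i]) > self.TOLERANCE:
                    raise ValueError(
                        f"matrix asymmetric at [{i}][{j}]: "
                        f"{v} vs {self.values[j][i]}"
                    )

    def abs_value(self, row_label: str, col_label: str) -> float:
        """|r| between two labeled phenotypes."""
        i = self.labels.index(row_label)
        j = self.labels.index(col_label)
        return abs(self.values[i][j])


@dataclass(frozen=True)
class GroupStyleMap:
    """Mapping from population/ancestry label to (color name, description)."""

    entries: Mapping[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    def color(self, label: str) -> str:
        try:
            return self.entries[label][0]
        except KeyError:
            raise ConfigurationError(
                f"group label {label!r} has no color in the group map; "
                f"supply an alternate map file with -l"
            ) from None

    def description(self, label: str) -> str:
        return self.entries[label][1]

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def labels(self) -> Tuple[str, ...]:
        return tuple(self.entries)


#: Built-in population / genetic-ancestry abbreviations and display colors.
DEFAULT_GROUP_STYLES = GroupStyleMap(
    {
        "EA": ("red", "European American"),
        "AA": ("blue", "African American"),
        "H": ("green", "Hawaiian"),
        "API": ("purple", "Asian Pacific Islander"),
        "AI": ("orange", "American Indian"),
    }
)


@dataclass(frozen=True)
class ExpectedPairSet:
    """Set of (snp_id, phenotype) pairs the study considers expected hits.

    Associations in this set are drawn in blue; qualifying associations
    outside it are "novel" and drawn in purple.
    """

    pairs: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)
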