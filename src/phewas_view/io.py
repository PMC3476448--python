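"""Readers and writers for the five tab-delimited dialects.

All files are UTF-8 tab-delimited text; LF and CRLF line endings are both
accepted.  The main results file has a header row with required columns for
the SNP identifier, the phenotype description and the association p-value,
plus the optional annotation columns ``phenotype_class``, ``Gene``, ``ES``
(signed effect), ``Groups``, sample size and a long phenotype description.
Column-name matching is case-insensitive with surrounding whitespace
stripped.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from matplotlib.colors import is_color_like

from .model import (
    MIN_P,
    AssociationRecord,
    CorrelationMatrix,
    DEFAULT_GROUP_STYLES,
    ExpectedPairSet,
    FormatError,
    GroupStyleMap,
    PheWASDataset,
)

__all__ = [
    "parse_phewas_file",
    "write_phewas_file",
    "parse_group_map",
    "parse_correlation_matrix",
    "parse_expected_pairs",
    "parse_phenotype_list",
]

logger = logging.getLogger("phewas_view")

PathLike = Union[str, Path]

# Recognized header names, lower-cased.  The optional annotation columns use
# the canonical input-file names; the required columns and the sample-size
# column accept a small alias set.
_SNP_ALIASES = {"snp", "snp_id", "snpid", "rsid"}
_PHENOTYPE_ALIASES = {"phenotype", "phenotype_short"}
_PVALUE_ALIASES = {"p-value", "pvalue", "p_value", "p"}
_CLASS_ALIASES = {"phenotype_class"}
_GENE_ALIASES = {"gene"}
_EFFECT_ALIASES = {"es"}
_GROUP_ALIASES = {"groups", "group"}
_SAMPLE_SIZE_ALIASES = {"n", "sample_size", "samp_size"}
_LONG_ALIASES = {"phenotype_long"}


def _find_column(columns: Sequence[str], aliases: set) -> Optional[str]:
    for col in columns:
        if col.strip().lower() in aliases:
            return col
    return None


def _read_tsv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    try:
        # keep_default_na=False: identifiers like "NULL" or "NA" are data,
        # not missing values; only the empty cell means absent.
        frame = pd.read_csv(
            path, sep="\t", dtype=str, encoding="utf-8",
            skip_blank_lines=True, keep_default_na=False, na_values=[""],
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty input file: {path}") from None
    if frame.empty and len(frame.columns) == 0:
        raise FormatError(f"empty input file: {path}")
    return frame


def parse_phewas_file(path: PathLike) -> PheWASDataset:
    """Read a PheWAS results file into a :class:`PheWASDataset`.

    One record is produced per data row, in file order.  p-values may be in
    decimal or scientific notation; a p-value of zero (or one that
    underflows) is clamped to ``1e-300`` with a logged warning so that
    ``-log10`` stays finite, while negative p-values or p > 1 are rejected
    as row errors.

    Raises
    ------
    FormatError
        If a required column (SNP, phenotype, p-value) is missing, a
        p-value is unparseable or out of range (the message carries the
        1-based line number), or the file is empty.
    """
    frame = _read_tsv(path)
    cols = list(frame.columns)

    snp_col = _find_column(cols, _SNP_ALIASES)
    phen_col = _find_column(cols, _PHENOTYPE_ALIASES)
    p_col = _find_column(cols, _PVALUE_ALIASES)
    for needed, col in (
        ("SNP", snp_col),
        ("Phenotype", phen_col),
        ("p-value", p_col),
    ):
        if col is None:
            raise FormatError(
                f"{path}: required column {needed!r} not found in header "
                f"{cols}"
            )

    class_col = _find_column(cols, _CLASS_ALIASES)
    gene_col = _find_column(cols, _GENE_ALIASES)
    effect_col = _find_column(cols, _EFFECT_ALIASES)
    group_col = _find_column(cols, _GROUP_ALIASES)
    n_col = _find_column(cols, _SAMPLE_SIZE_ALIASES)
    long_col = _find_column(cols, _LONG_ALIASES)

    def _cell(row, col: Optional[str]) -> Optional[str]:
        if col is None:
            return None
        value = row[col]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        value = str(value).strip()
        return value or None

    records: List[AssociationRecord] = []
    for idx, (_, row) in enumerate(frame.iterrows()):
        line_no = idx + 2  # 1-based, after the header line
        snp = _cell(row, snp_col)
        phen = _cell(row, phen_col)
        p_raw = _cell(row, p_col)
        if not snp or not phen or p_raw is None:
            raise FormatError(
                f"{path}:{line_no}: missing SNP, phenotype or p-value"
            )
        try:
            p = float(p_raw)
        except ValueError:
            raise FormatError(
                f"{path}:{line_no}: unparseable p-value {p_raw!r}"
            ) from None
        if p < 0.0 or p > 1.0:
            raise FormatError(
                f"{path}:{line_no}: p-value {p} outside [0, 1]"
            )
        if p < MIN_P:
            logger.warning(
                "%s:%d: p-value %s clamped to %g", path, line_no, p_raw, MIN_P
            )
            p = MIN_P

        effect_raw = _cell(row, effect_col)
        n_raw = _cell(row, n_col)
        try:
            effect = float(effect_raw) if effect_raw is not None else None
        except ValueError:
            raise FormatError(
                f"{path}:{line_no}: unparseable effect size {effect_raw!r}"
            ) from None
        try:
            n = int(float(n_raw)) if n_raw is not None else None
        except ValueError:
            raise FormatError(
                f"{path}:{line_no}: unparseable sample size {n_raw!r}"
            ) from None

        records.append(
            AssociationRecord(
                snp_id=snp,
                phenotype=phen,
                p_value=p,
                row_index=idx,
                phenotype_long=_cell(row, long_col),
                phenotype_class=_cell(row, class_col),
                gene=_cell(row, gene_col),
                effect=effect,
                group=_cell(row, group_col),
                sample_size=n,
            )
        )
    if not records:
        raise FormatError(f"{path}: no data rows")

    return PheWASDataset(
        records=tuple(records),
        has_class=class_col is not None
        and any(r.phenotype_class is not None for r in records),
        has_gene=gene_col is not None
        and any(r.gene is not None for r in records),
        has_effect=effect_col is not None
        and any(r.effect is not None for r in records),
        has_group=group_col is not None
        and any(r.group is not None for r in records),
        has_sample_size=n_col is not None
        and any(r.sample_size is not None for r in records),
        has_long_description=long_col is not None
        and any(r.phenotype_long is not None for r in records),
    )


def write_phewas_file(dataset: PheWASDataset, path: PathLike) -> None:
    """Write a dataset as a results file that re-parses to an equal dataset.

    Optional columns are emitted only when the corresponding presence flag
    is set, so a dataset parsed from a minimal 3-column file round-trips to
    a 3-column file.
    """
    columns: Dict[str, List[Optional[str]]] = {"SNP": [], "Phenotype": []}
    if dataset.has_long_description:
        columns["Phenotype_long"] = []
    columns["p-value"] = []
    if dataset.has_class:
        columns["phenotype_class"] = []
    if dataset.has_gene:
        columns["Gene"] = []
    if dataset.has_effect:
        columns["ES"] = []
    if dataset.has_group:
        columns["Groups"] = []
    if dataset.has_sample_size:
        columns["N"] = []

    for rec in dataset:
        columns["SNP"].append(rec.snp_id)
        columns["Phenotype"].append(rec.phenotype)
        if dataset.has_long_description:
            columns["Phenotype_long"].append(rec.phenotype_long)
        columns["p-value"].append(repr(rec.p_value))
        if dataset.has_class:
            columns["phenotype_class"].append(rec.phenotype_class)
        if dataset.has_gene:
            columns["Gene"].append(rec.gene)
        if dataset.has_effect:
            columns["ES"].append(
                repr(rec.effect) if rec.effect is not None else None
            )
        if dataset.has_group:
            columns["Groups"].append(rec.group)
        if dataset.has_sample_size:
            columns["N"].append(
                str(rec.sample_size) if rec.sample_size is not None else None
            )

    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, encoding="utf-8")


def parse_group_map(path: Optional[PathLike] = None) -> GroupStyleMap:
    """Read a group/ancestry map file: label TAB color [TAB description].

    With no file, the built-in map is returned (EA red, AA blue, H green,
    API purple, AI orange).  Duplicate labels and color names the renderer
    cannot resolve are format errors.
    """
    if path is None:
        return DEFAULT_GROUP_STYLES
    path = Path(path)
    if not path.exists():
        raise FormatError(f"group map file not found: {path}")
    entries: Dict[str, tuple] = {}
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}:{line_no}: expected 'label<TAB>color"
                    f"[<TAB>description]'"
                )
            label, color = fields[0], fields[1]
            description = fields[2] if len(fields) > 2 else label
            if label in entries:
                raise FormatError(
                    f"{path}:{line_no}: duplicate group label {label!r}"
                )
            if not is_color_like(color):
                raise FormatError(
                    f"{path}:{line_no}: unknown color name {color!r}"
                )
            entries[label] = (color, description)
    if not entries:
        raise FormatError(f"{path}: empty group map file")
    return GroupStyleMap(entries)


def parse_correlation_matrix(path: PathLike) -> CorrelationMatrix:
    """Read a tab-delimited square matrix of pairwise phenotype correlations.

    Phenotype labels appear on both the row and column headers.  The matrix
    must be square, symmetric within 1e-6, have a unit diagonal and entries
    in [-1, 1]; violations are format errors.
    """
    frame = _read_tsv(path)
    labels = [str(c).strip() for c in frame.columns[1:]]
    row_labels = [str(v).strip() for v in frame.iloc[:, 0]]
    if len(row_labels) != len(labels):
        raise FormatError(
            f"{path}: non-square matrix ({len(row_labels)} rows x "
            f"{len(labels)} columns)"
        )
    if row_labels != labels:
        raise FormatError(
            f"{path}: row labels {row_labels} do not match column labels "
            f"{labels}"
        )
    try:
        values = frame.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from None
    try:
        return CorrelationMatrix(
            labels=tuple(labels),
            values=tuple(tuple(row) for row in values),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def parse_expected_pairs(path: PathLike) -> ExpectedPairSet:
    """Read an expected SNP/phenotype pair file: SNP TAB phenotype per row.

    Duplicate rows collapse to one pair; an empty file yields an empty set
    (every plotted result is then treated as novel).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"expected-pair file not found: {path}")
    pairs = set()
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}:{line_no}: expected 'SNP<TAB>phenotype'"
                )
            pairs.add((fields[0], fields[1]))
    return ExpectedPairSet(pairs=frozenset(pairs))


def parse_phenotype_list(path: PathLike) -> List[str]:
    """Read a phenotype list file: one phenotype name per line.

    Blank lines are ignored; repeated names are kept once at their first
    position.  An entirely empty file is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"phenotype list file not found: {path}")
    names: List[str] = []
    seen = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            name = line.strip()
            if name and name not in seen:
                seen.add(name)
                names.append(name)
    if not names:
        raise FormatError(f"{path}: empty phenotype list")
    return names
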