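"""Synthetic PheWAS inputs for demos and tests.

Real PheWAS result files are study-specific and not redistributable, so the
package generates its own: a results table of SNP x phenotype (x group)
association tests whose null p-values are uniform on (0, 1) and whose
"signal" subset is drawn log-uniform across several orders of magnitude (so
-log10 axes and sun plots are exercised realistically), plus the companion
group-map, correlation-matrix, expected-pair and phenotype-list files.

Everything is deterministic under the spec's seed, and every generated
artifact round-trips through its parser in :mod:`phewas_view.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import (
    AssociationRecord,
    CorrelationMatrix,
    ExpectedPairSet,
    PheWASDataset,
)

__all__ = [
    "FixtureSpec",
    "generate_dataset",
    "generate_correlation_matrix",
    "generate_expected_pairs",
    "paper_like_spec",
    "write_demo_directory",
]

#: Default population/ancestry labels, matching the built-in style map.
DEFAULT_GROUPS = ("EA", "AA", "H", "API", "AI")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic PheWAS results table.

    ``fraction_signal`` of all records get a "signal" p-value drawn
    log-uniform from ``signal_p_range``; the rest are null, uniform(0, 1).
    Effects are Normal(0, ``effect_scale``); sample sizes are uniform
    integers in ``sample_size_range``.  ``correlation_block_structure``
    lists (block size, within-block r) pairs covering the phenotypes in
    order; remaining phenotypes are uncorrelated.
    """

    n_snps: int = 10
    n_phenotypes: int = 25
    phenotype_classes: Tuple[str, ...] = (
        "Allergy",
        "Cardiovascular",
        "Metabolic",
    )
    groups: Tuple[str, ...] = ("AA", "EA")
    fraction_signal: float = 0.05
    signal_p_range: Tuple[float, float] = (1e-8, 1e-3)
    effect_scale: float = 0.3
    sample_size_range: Tuple[int, int] = (500, 3000)
    correlation_block_structure: Tuple[Tuple[int, float], ...] = (
        (5, 0.8),
        (5, 0.4),
    )
    snp_ids: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_phenotypes < 1:
            raise ValueError("n_snps and n_phenotypes must be positive")
        if not (0.0 <= self.fraction_signal <= 1.0):
            raise ValueError("fraction_signal must be in [0, 1]")
        lo, hi = self.signal_p_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("signal_p_range must satisfy 0 < lo <= hi <= 1")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be positive")
        n_lo, n_hi = self.sample_size_range
        if not (0 <= n_lo <= n_hi):
            raise ValueError("sample_size_range must be a valid interval")
        if self.snp_ids is not None and len(self.snp_ids) != self.n_snps:
            raise ValueError("snp_ids length must equal n_snps")


def _snp_ids(spec: FixtureSpec) -> Tuple[str, ...]:
    if spec.snp_ids is not None:
        return spec.snp_ids
    return tuple(f"rs{100000 + 7 * i}" for i in range(spec.n_snps))


def _phenotype_names(spec: FixtureSpec) -> Tuple[str, ...]:
    return tuple(f"Phen{i + 1}" for i in range(spec.n_phenotypes))


def _class_assignment(spec: FixtureSpec) -> Dict[str, str]:
    """Phenotype -> class, contiguous blocks of roughly equal size."""
    phens = _phenotype_names(spec)
    k = len(spec.phenotype_classes)
    if k == 0:
        return {}
    block = -(-len(phens) // k)  # ceil
    return {
        phen: spec.phenotype_classes[min(i // block, k - 1)]
        for i, phen in enumerate(phens)
    }


def generate_dataset(spec: FixtureSpec) -> PheWASDataset:
    """Generate ``n_snps * n_phenotypes * max(1, |groups|)`` records.

    Deterministic under ``spec.seed``: the same spec always produces an
    identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    snps = _snp_ids(spec)
    phens = _phenotype_names(spec)
    groups: Sequence[Optional[str]] = spec.groups or (None,)
    classes = _class_assignment(spec)
    has_groups = bool(spec.groups)

    n_records = len(snps) * len(phens) * len(groups)
    if n_records == 0:
        raise ValueError("degenerate spec: zero records requested")

    p_values = rng.uniform(0.0, 1.0, size=n_records)
    is_signal = rng.random(n_records) < spec.fraction_signal
    lo, hi = spec.signal_p_range
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    n_signal = int(is_signal.sum())
    if n_signal:
        p_values[is_signal] = 10.0 ** rng.uniform(
            log_lo, log_hi, size=n_signal
        )
    effects = rng.normal(0.0, spec.effect_scale, size=n_records)
    n_lo, n_hi = spec.sample_size_range
    sizes = rng.integers(n_lo, n_hi + 1, size=n_records)

    records: List[AssociationRecord] = []
    idx = 0
    for snp_i, snp in enumerate(snps):
        gene = f"GENE{snp_i + 1}"
        for phen in phens:
            for group in groups:
                records.append(
                    AssociationRecord(
                        snp_id=snp,
                        phenotype=phen,
                        p_value=float(p_values[idx]),
                        row_index=idx,
                        phenotype_long=f"{phen} long description",
                        phenotype_class=classes.get(phen),
                        gene=gene,
                        effect=float(effects[idx]),
                        group=group,
                        sample_size=int(sizes[idx]),
                    )
                )
                idx += 1

    return PheWASDataset(
        records=tuple(records),
        has_class=bool(classes),
        has_gene=True,
        has_effect=True,
        has_group=has_groups,
        has_sample_size=True,
        has_long_description=True,
    )


def generate_correlation_matrix(spec: FixtureSpec) -> CorrelationMatrix:
    """Block-structured phenotype correlation matrix.

    Within each block the off-diagonal equals the requested r (a constant-r
    block with r in [0, 1) is positive semidefinite by construction, being
    the correlation of a one-factor model); between blocks the correlation
    is 0; the diagonal is 1.  The result always validates as a
    :class:`CorrelationMatrix` and is verified PSD.
    """
    n = spec.n_phenotypes
    values = np.eye(n)
    start = 0
    for size, r in spec.correlation_block_structure:
        if not (-1.0 < r < 1.0):
            raise ValueError(f"block correlation {r} outside (-1, 1)")
        stop = min(start + size, n)
        for i in range(start, stop):
            for j in range(start, stop):
                if i != j:
                    values[i, j] = r
        start = stop
        if start >= n:
            break
    eigvals = np.linalg.eigvalsh(values)
    if eigvals.min() < -1e-9:
        raise ValueError(
            f"block structure is not positive semidefinite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    return CorrelationMatrix(
        labels=_phenotype_names(spec),
        values=tuple(tuple(float(v) for v in row) for row in values),
    )


def generate_expected_pairs(
    dataset: PheWASDataset, k: int, seed: int
) -> ExpectedPairSet:
    """Sample ``k`` distinct (SNP, phenotype) pairs, preferring small
    p-values, without replacement; deterministic under ``seed``."""
    best: Dict[Tuple[str, str], float] = {}
    for rec in dataset:
        key = (rec.snp_id, rec.phenotype)
        if key not in best or rec.p_value < best[key]:
            best[key] = rec.p_value
    ordered = sorted(best, key=lambda key: (best[key], key))
    if k > len(ordered):
        raise ValueError(
            f"k = {k} exceeds the {len(ordered)} distinct SNP/phenotype pairs"
        )
    if k == 0:
        return ExpectedPairSet(pairs=frozenset())
    # candidate pool: pairs with small p, widened to at least k entries
    pool = [key for key in ordered if best[key] < 0.05]
    if len(pool) < k:
        pool = ordered[: max(k, len(pool))]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=k, replace=False)
    return ExpectedPairSet(pairs=frozenset(pool[i] for i in chosen))


def paper_like_spec(seed: int = 0) -> FixtureSpec:
    """A small preset shaped like the published example figures: ~25
    phenotypes in classes including "Allergy", a SNP named rs673548, and
    AA/EA ancestry groups."""
    return FixtureSpec(
        n_snps=8,
        n_phenotypes=25,
        phenotype_classes=("Allergy", "Cardiovascular", "Metabolic"),
        groups=("AA", "EA"),
        fraction_signal=0.08,
        snp_ids=(
            "rs673548",
            "rs100007",
            "rs100014",
            "rs100021",
            "rs100028",
            "rs100035",
            "rs100042",
            "rs100049",
        ),
        seed=seed,
    )


def write_demo_directory(
    directory: Union[str, Path], spec: Optional[FixtureSpec] = None
) -> Dict[str, Path]:
    """Emit a complete demo input set (all five file dialects).

    Returns a mapping of dialect name to written path:
    ``results``, ``group_map``, ``correlations``, ``expected_pairs``,
    ``phenotype_list``.
    """
    from .io import write_phewas_file

    if spec is None:
        spec = paper_like_spec()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    dataset = generate_dataset(spec)
    paths = {"results": directory / "phewas_results.txt"}
    write_phewas_file(dataset, paths["results"])

    paths["group_map"] = directory / "group_map.txt"
    from .model import DEFAULT_GROUP_STYLES

    with open(paths["group_map"], "w", encoding="utf-8") as handle:
        for label in spec.groups:
            color = DEFAULT_GROUP_STYLES.color(label)
            desc = DEFAULT_GROUP_STYLES.description(label)
            handle.write(f"{label}\t{color}\t{desc}\n")

    matrix = generate_correlation_matrix(spec)
    paths["correlations"] = directory / "correlations.txt"
    with open(paths["correlations"], "w", encoding="utf-8") as handle:
        handle.write("Phenotype\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            handle.write(
                label + "\t" + "\t".join(repr(v) for v in row) + "\n"
            )

    pairs = generate_expected_pairs(dataset, k=5, seed=spec.seed)
    paths["expected_pairs"] = directory / "expected_pairs.txt"
    with open(paths["expected_pairs"], "w", encoding="utf-8") as handle:
        for snp, phen in sorted(pairs.pairs):
            handle.write(f"{snp}\t{phen}\n")

    paths["phenotype_list"] = directory / "phenotype_list.txt"
    with open(paths["phenotype_list"], "w", encoding="utf-8") as handle:
        for phen in dataset.phenotypes[:5]:
            handle.write(phen + "\n")

    return paths
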