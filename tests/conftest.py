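"""Shared fixtures and hypothesis strategies for the test suite."""

import string

import pytest
from hypothesis import strategies as st

from phewas_view import (
    AssociationRecord,
    FixtureSpec,
    PheWASDataset,
    generate_dataset,
    paper_like_spec,
    write_demo_directory,
)

_IDENT = string.ascii_letters + string.digits + "_."


def identifiers(min_size=1, max_size=12):
    return st.text(alphabet=_IDENT, min_size=min_size, max_size=max_size)


@st.composite
def p_values(draw):
    """p in (0, 1] whose repr round-trips exactly through text."""
    return draw(
        st.floats(
            min_value=1e-300, max_value=1.0, allow_nan=False,
            allow_infinity=False,
        )
    )


@st.composite
def datasets(draw, min_records=1, max_records=30):
    """Arbitrary small datasets with contiguous row indices and a random
    subset of the optional columns populated."""
    n = draw(st.integers(min_records, max_records))
    snps = draw(st.lists(identifiers(), min_size=1, max_size=5, unique=True))
    phens = draw(st.lists(identifiers(), min_size=1, max_size=6, unique=True))
    with_class = draw(st.booleans())
    with_gene = draw(st.booleans())
    with_effect = draw(st.booleans())
    with_group = draw(st.booleans())
    with_n = draw(st.booleans())
    with_long = draw(st.booleans())
    records = []
    for i in range(n):
        records.append(
            AssociationRecord(
                snp_id=draw(st.sampled_from(snps)),
                phenotype=draw(st.sampled_from(phens)),
                p_value=draw(p_values()),
                row_index=i,
                phenotype_class=(
                    draw(st.sampled_from(["ClassA", "ClassB"]))
                    if with_class else None
                ),
                gene=draw(identifiers()) if with_gene else None,
                effect=(
                    draw(st.floats(-5, 5, allow_nan=False))
                    if with_effect else None
                ),
                group=(
                    draw(st.sampled_from(["AA", "EA", "H"]))
                    if with_group else None
                ),
                sample_size=(
                    draw(st.integers(0, 10**6)) if with_n else None
                ),
                phenotype_long=(
                    draw(identifiers()) if with_long else None
                ),
            )
        )
    return PheWASDataset.from_records(records)


@pytest.fixture(scope="session")
def demo_spec():
    return paper_like_spec(seed=11)


@pytest.fixture(scope="session")
def demo_dataset(demo_spec):
    return generate_dataset(demo_spec)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory, demo_spec):
    """A complete demo input directory (all five file dialects)."""
    directory = tmp_path_factory.mktemp("demo")
    paths = write_demo_directory(directory, demo_spec)
    return paths
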