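import pytest

from unsense.fixtures import FixtureSpec, generate
from unsense.genetic_code import (
    CodonTable,
    enumerate_substitution_space,
    summarize_space,
)


@pytest.fixture(scope="session")
def standard_table():
    return CodonTable.standard()


@pytest.fixture(scope="session")
def space_records(standard_table):
    return enumerate_substitution_space(standard_table)


@pytest.fixture(scope="session")
def space_summary(standard_table, space_records):
    return summarize_space(space_records, standard_table)


@pytest.fixture(scope="session")
def bundle():
    """Medium deterministic bundle shared across classifier/io tests."""
    spec = FixtureSpec(
        seed=7,
        n_transcripts=4,
        n_variants=200,
        exon_length=(80, 200),
    )
    return generate(spec)


@pytest.fixture
def bundle_dir(bundle, tmp_path):
    out = tmp_path / "bundle"
    bundle.write(out)
    return out
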