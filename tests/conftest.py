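import collections

import pytest

import fedvar


@pytest.fixture
def federation():
    fed = fedvar.Federation(seed=7)
    fed.register_platform("gcp_like")
    fed.register_platform("aws_like")
    return fed


@pytest.fixture
def fixture_vcf(tmp_path):
    """The four-variant rsID fixture VCF (six samples, hand-set genotypes)."""
    path = tmp_path / "fixture.vcf"
    fedvar.write_fixture_vcf(path)
    return str(path)


@pytest.fixture
def ingested_fixture(federation, fixture_vcf):
    """Fixture VCF loaded as a partitioned table on the first platform."""
    platform = federation.platform("gcp_like")
    handle = fedvar.ingest_vcf(fixture_vcf, platform, "fixture_variants")
    return federation, platform, handle


def row_multiset(rows):
    """Order-insensitive, hashable view of a list of row dicts."""
    return collections.Counter(
        tuple(sorted((k, repr(v)) for k, v in row.items())) for row in rows
    )


@pytest.fixture
def multiset():
    return row_multiset
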