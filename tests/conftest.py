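import pytest

from polyguide import (
    BuildConfig,
    FixtureSpec,
    build_database,
    load_cfd_tables,
    load_rs2_model,
    make_toy_genome,
)


@pytest.fixture(scope="session")
def cfd_tables():
    return load_cfd_tables()


@pytest.fixture(scope="session")
def rs2_model():
    return load_rs2_model()


@pytest.fixture(scope="session")
def toy_fixture():
    """Mid-size two-isoform toy genome shared across read-only tests."""
    return make_toy_genome(
        FixtureSpec(
            n_genes=6,
            contig_length=42_000,
            isoforms_per_gene=2,
            n_planted_guides=2,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def toy_db(toy_fixture):
    return build_database(toy_fixture.genome, toy_fixture.genes, BuildConfig())
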