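import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from homoref.pipeline import RunConfig, run
from homoref.synthetic_fixtures import FixtureConfig, generate_fixture

DEFAULT_SEED = 20260921


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic collection: 3 genomes x 4 families, one
    duplicated (paralog) lineage, decoys, annotations and truth table."""
    return generate_fixture(FixtureConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def fixture_dir(default_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    paths = default_fixture.write(outdir)
    return paths


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig(
        query_path=str(fixture_dir["query"]),
        collection_path=str(fixture_dir["fasta"]),
        links_path=str(fixture_dir["links"]),
        pubs_path=str(fixture_dir["pubs"]),
        genomes_path=str(fixture_dir["genomes"]),
        output_dir=str(outdir),
        log_level="WARNING",
    )
    return run(config)
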