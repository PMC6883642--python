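import pytest

from metorigin.fixtures import SynthSpec, synth_kegg, worked_example_fixture
from metorigin.kegg_db import build_database, parse_flat_file


def db_from_files(files, provenance=None):
    """Parse a kind->text flat-file mapping into a database."""
    return build_database(
        ko_records=parse_flat_file(files["ko"], "ko"),
        reaction_records=parse_flat_file(files["reaction"], "reaction"),
        compound_records=parse_flat_file(files["compound"], "compound"),
        pathway_records=parse_flat_file(files["pathway"], "pathway"),
        provenance=provenance,
    )


@pytest.fixture(scope="session")
def worked_files():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_db(worked_files):
    return db_from_files(worked_files)


@pytest.fixture(scope="session")
def synth_bundle():
    """A planted-enrichment synthetic universe: (files, truth, db)."""
    spec = SynthSpec(seed=1, planted_enrichment=(2, 5))
    files, truth = synth_kegg(spec)
    return files, truth, db_from_files(files)
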