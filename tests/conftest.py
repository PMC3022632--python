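import datetime

import pytest

from credence import fixtures
from credence import io as data_io
from credence.model import EvidenceItem, Gene, GeneList, GeneListEntry, Provenance

TODAY = datetime.date(2010, 12, 30)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One generated synthetic-data directory shared by the session."""
    d = tmp_path_factory.mktemp("synth")
    fixtures.generate(fixtures.FixtureSpec(seed=1), d)
    return d


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    return fixtures.manifest(fixture_dir)


@pytest.fixture(scope="session")
def term_graph(fixture_dir):
    return data_io.read_annotations(
        fixture_dir / "annotations.tsv", data_io.read_obo(fixture_dir / "ontology.obo")
    )


@pytest.fixture(scope="session")
def ortholog_table(fixture_dir):
    return data_io.read_orthologs(fixture_dir / "orthologs.tsv")


@pytest.fixture(scope="session")
def interaction_table(fixture_dir):
    return data_io.read_interactions(fixture_dir / "interactions.tsv")


@pytest.fixture(scope="session")
def coords_table(fixture_dir):
    return data_io.read_coordinates(fixture_dir / "coords.tsv")


def make_gene_list(name, species, ids, score=0.05, kind="default", source="src"):
    lst = GeneList(name, species, Provenance(source, TODAY, "import"))
    for gid in ids:
        lst.add_entry(
            GeneListEntry(
                Gene(gid, species), [EvidenceItem(source, score, kind, TODAY)]
            )
        )
    return lst
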