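import pytest

from taxomem.labeled_index import LabeledIndex
from taxomem.seqdb import SequenceDatabase, SequenceRecord
from taxomem.taxonomy import TaxonomyTree

# Two level-1 subtrees of a 4-level hierarchy: enough structure for LCA,
# level-ancestor and LTU behavior to be non-trivial.
EXAMPLE_EDGES = [
    ("1", "R"),
    ("1.1", "1"),
    ("1.1.1", "1.1"),
    ("1.1.1.1", "1.1.1"),
    ("1.1.1.2", "1.1.1"),
    ("2", "R"),
    ("2.1", "2"),
    ("2.1.1", "2.1"),
    ("2.1.1.1", "2.1.1"),
]


@pytest.fixture(scope="session")
def example_tree() -> TaxonomyTree:
    return TaxonomyTree.from_edges(EXAMPLE_EDGES)


@pytest.fixture(scope="session")
def example_db(example_tree) -> SequenceDatabase:
    records = [
        SequenceRecord("S1", "MKVLA", example_tree.id_of("1.1.1.1")),
        SequenceRecord("S2", "KVLAG", example_tree.id_of("1.1.1.2")),
        SequenceRecord("S3", "GGWWP", example_tree.id_of("2.1.1.1")),
    ]
    return SequenceDatabase(records, "AA", example_tree)


@pytest.fixture(scope="session")
def example_index(example_db) -> LabeledIndex:
    return LabeledIndex.build(example_db)
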