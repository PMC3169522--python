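import dendropy
import pytest

from clustevo.core import GeneLocus, GenomeRecord
from clustevo.io import read_newick


@pytest.fixture
def four_taxon_tree() -> dendropy.Tree:
    """Balanced rooted tree ((A,B),(C,D)) with unit branch lengths."""
    return read_newick("((A:1,B:1)X:1,(C:1,D:1)Y:1)R;")


@pytest.fixture
def six_taxon_tree() -> dendropy.Tree:
    return read_newick("(((A:1,B:1)AB:1,C:2)ABC:1,((D:1,E:1)DE:1,F:2)DEF:1)R;")


def make_genome(genome_id, tags_with_index, clade=("Bacteria",), families=None):
    families = families or {}
    loci = tuple(
        GeneLocus(genome_id, tag, idx, "+", family_id=families.get(tag))
        for tag, idx in sorted(tags_with_index, key=lambda t: t[1])
    )
    return GenomeRecord(genome_id, genome_id, tuple(clade), loci)
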