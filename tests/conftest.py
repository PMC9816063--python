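import pytest

from ace.trees import Tree


@pytest.fixture
def balanced_tree() -> Tree:
    """Four genomes, two clades, unit-ish branch lengths."""
    return Tree.from_newick("((A:1,B:1)NAB:1,(C:1,D:1)NCD:1)ROOT;")


@pytest.fixture
def ladder_tree() -> Tree:
    return Tree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
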