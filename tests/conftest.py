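import pytest

from ltrkit.io_formats import parse_dotbracket, parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def hairpin():
    # 6-nt stem, 4-nt loop hairpin
    return parse_dotbracket("((((((....))))))")
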