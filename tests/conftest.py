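import io

import pytest
from hypothesis import settings

from diego.ontology import parse_obo, propagate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


DIAMOND_OBO = """format-version: 1.2
ontology: synthetic

[Term]
id: T:0000001
name: root
namespace: synthetic

[Term]
id: T:0000002
name: left
is_a: T:0000001

[Term]
id: T:0000003
name: right
relationship: part_of T:0000001

[Term]
id: T:0000004
name: bottom
is_a: T:0000002
is_a: T:0000003
"""


@pytest.fixture
def diamond_graph():
    """Diamond DAG: T4 -> {T2, T3} -> T1."""
    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture
def diamond_annot(diamond_graph):
    direct = {
        "g1": {"T:0000004"},
        "g2": {"T:0000002"},
        "g3": {"T:0000001"},
    }
    return propagate(diamond_graph, direct)
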