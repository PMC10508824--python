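import io

import pytest

from gsnamer.fixtures import ToyOntologySpec, make_toy_ontology
from gsnamer.ontology import attach_annotations, parse_obo

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: T:0
name: grandparent
namespace: biological_process

[Term]
id: T:1
name: left parent
namespace: biological_process
is_a: T:0

[Term]
id: T:2
name: right parent
namespace: biological_process
is_a: T:0

[Term]
id: T:3
name: grandchild
namespace: biological_process
is_a: T:1
is_a: T:2
"""


@pytest.fixture
def diamond_ontology():
    """Diamond DAG: T:3 reaches T:0 by two paths; direct gene on each node."""
    ont = parse_obo(io.StringIO(DIAMOND_OBO))
    attach_annotations(
        ont, {"T:0": {"a"}, "T:1": {"b"}, "T:2": {"b", "d"}, "T:3": {"c"}}
    )
    return ont


@pytest.fixture(scope="session")
def toy():
    """Default 12-term seeded toy ontology (in-memory only)."""
    return make_toy_ontology(ToyOntologySpec()).ontology
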