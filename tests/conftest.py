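import numpy as np
import pytest

from raredx.ontology import GroupMap, information_content, load_ontology

# A small hand-written DAG used by the ontology and similarity tests.
#
#            root
#           /    \
#          A      B
#         / \    / \
#        C   D  E   F
#        |    \ |
#        G      H     (H has two parents: D and E)
TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: T:ROOT
name: root

[Term]
id: T:A
name: a
is_a: T:ROOT

[Term]
id: T:B
name: b
is_a: T:ROOT

[Term]
id: T:C
name: c
is_a: T:A

[Term]
id: T:D
name: d
is_a: T:A
alt_id: T:D_OLD

[Term]
id: T:E
name: e
is_a: T:B

[Term]
id: T:F
name: f
is_a: T:B

[Term]
id: T:G
name: g
is_a: T:C

[Term]
id: T:H
name: h
is_a: T:D
is_a: T:E

[Term]
id: T:OBS
name: obsolete term
is_obsolete: true
is_a: T:ROOT
"""

# corpus of 8 annotated entities: propagation makes the root universal
TOY_CORPUS = {
    "d1": {"T:G"},
    "d2": {"T:C"},
    "d3": {"T:D"},
    "d4": {"T:H"},
    "d5": {"T:E"},
    "d6": {"T:F"},
    "d7": {"T:A"},
    "d8": {"T:B"},
}


@pytest.fixture(scope="session")
def toy_index():
    index = load_ontology(TOY_OBO)
    information_content(index, TOY_CORPUS)
    return index


@pytest.fixture(scope="session")
def toy_group_map():
    return GroupMap(
        subcategory_of={
            "T:C": "sub_left1",
            "T:G": "sub_left1",
            "T:D": "sub_left2",
            "T:E": "sub_right1",
            "T:F": "sub_right2",
        },
        higher_group_of={
            "sub_left1": "left",
            "sub_left2": "left",
            "sub_right1": "right",
            "sub_right2": "right",
        },
    )


@pytest.fixture(scope="session")
def small_ontology():
    """Seeded synthetic ontology shared by the heavier tests."""
    from raredx.synthetic import make_ontology

    return make_ontology(n_terms=300, seed=0, n_genes=120)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
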