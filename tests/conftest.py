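"""Shared fixtures: a hand-built concept DAG and seeded synthetic corpora."""
from __future__ import annotations

import pytest

from vaxnorm.encoder import build_index, char_ngram_backend
from vaxnorm.fixtures import NoiseConfig, make_mentions, make_ontology
from vaxnorm.ontology import Concept, ConceptGraph


@pytest.fixture(scope="session")
def toy_dag() -> ConceptGraph:
    """8 concepts, 3 levels, one multi-parent node.

    ::

        A
        ├── B ── D ── F
        │         └── G
        └── C ── E (parents B and C)
        H (isolated second root)
    """
    return ConceptGraph(
        [
            Concept("A", "alpha"),
            Concept("B", "beta", parent_ids=("A",)),
            Concept("C", "gamma", parent_ids=("A",)),
            Concept("D", "delta", parent_ids=("B",)),
            Concept("E", "epsilon", parent_ids=("B", "C")),
            Concept("F", "zeta", parent_ids=("D",)),
            Concept("G", "eta", parent_ids=("D",)),
            Concept("H", "theta"),
        ]
    )


@pytest.fixture(scope="session")
def fixture_graph() -> ConceptGraph:
    """Seeded 100-concept synthetic ontology (80 vaccine + 20 distractor)."""
    return make_ontology(n_vaccine=80, n_distractor=20, seed=1)


@pytest.fixture(scope="session")
def fixture_corpus(fixture_graph):
    """200 noisy mentions with gold mappings under the default noise config."""
    return make_mentions(fixture_graph, 200, NoiseConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_backend(fixture_graph):
    names = [name for _, name in fixture_graph.iter_names()]
    return char_ngram_backend(names, (3, 3))


@pytest.fixture(scope="session")
def fixture_index(fixture_graph, fixture_backend):
    return build_index(fixture_graph, fixture_backend)
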