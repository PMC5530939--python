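from __future__ import annotations

import numpy as np
import pytest

from diseasetax import (
    AssociationTable,
    CitationTable,
    DistanceMatrix,
    Hierarchy,
)


@pytest.fixture
def simple_table() -> AssociationTable:
    return AssociationTable({
        ("d1", "g1"), ("d1", "g2"),
        ("d2", "g2"), ("d2", "g3"),
        ("d3", "g4"),
    })


@pytest.fixture
def two_chain_pair() -> tuple[Hierarchy, Hierarchy]:
    """Reference chain r→a→b against inferred chain r→b→a."""
    ref = Hierarchy(["r", "a", "b"], [("r", "a"), ("a", "b")])
    inf = Hierarchy(["r", "a", "b"], [("r", "b"), ("b", "a")])
    return ref, inf


@pytest.fixture
def fig2_case() -> tuple[DistanceMatrix, CitationTable]:
    """Six preterm-infant-style diseases whose dendrogram merges
    {5,6}, {1,2}, {1,2,3}, {4,5,6}, then everything; disease 3 is the
    best-studied term and 6 outcites 5."""
    labels = ["1", "2", "3", "4", "5", "6"]
    d = np.full((6, 6), 0.9)
    np.fill_diagonal(d, 0.0)

    def set_(a, b, v):
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v

    set_("5", "6", 0.1)
    set_("1", "2", 0.2)
    set_("1", "3", 0.3)
    set_("2", "3", 0.3)
    set_("4", "5", 0.4)
    set_("4", "6", 0.4)
    citations = CitationTable(
        {"1": 30, "2": 20, "3": 100, "4": 40, "5": 10, "6": 50}
    )
    return DistanceMatrix(labels, d), citations
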