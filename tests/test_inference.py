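"""Complete linkage, Parent Promotion, and the MWST baseline."""

import numpy as np
import pytest

import oracles
from diseasetax import (
    AssociationTable,
    CitationTable,
    DistanceMatrix,
    DomainError,
    ParseError,
    complete_linkage,
    infer,
    make_separable_fixture,
    mwst_infer,
    parent_promotion,
    read_citations,
)
from diseasetax.evaluation import edge_correctness


def _dm(labels, values):
    return DistanceMatrix(labels, np.asarray(values, dtype=float))


class TestCompleteLinkage:
    def test_two_diseases(self):
        d = _dm(["a", "b"], [[0, 0.4], [0.4, 0]])
        dend = complete_linkage(d)
        assert dend.merges == [(0, 1, 0.4)]

    def test_three_point_example(self):
        d = _dm(
            ["p1", "p2", "p3"],
            [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
        )
        dend = complete_linkage(d)
        assert dend.merges[0][:2] == (0, 1)
        assert [h for _, _, h in dend.merges] == [0.1, 0.9]

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            labels = [f"d{i}" for i in range(n)]
            dend = complete_linkage(
                _dm(labels, oracles.random_distance_matrix(rng, n))
            )
            heights = [h for _, _, h in dend.merges]
            assert heights == sorted(heights)

    def test_matches_naive_agglomeration(self):
        """Merge heights and cluster compositions agree with a from-scratch
        O(n^3) complete-linkage oracle."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            labels = [f"d{i}" for i in range(n)]
            values = oracles.random_distance_matrix(rng, n)
            dend = complete_linkage(_dm(labels, values))
            exp_heights, exp_pairs = oracles.naive_complete_linkage(
                labels, values
            )
            got_heights = [h for _, _, h in dend.merges]
            assert np.allclose(got_heights, exp_heights)
            # reconstruct member sets from integer cluster ids
            members = {i: frozenset([lab]) for i, lab in enumerate(labels)}
            for k, (a, b, _) in enumerate(dend.merges):
                got = {members[a], members[b]}
                assert got == set(exp_pairs[k])
                members[n + k] = members[a] | members[b]

    def test_matches_scipy_on_tie_free_matrix(self):
        """Cross-check against scipy's complete linkage where no ties can
        make tie-break conventions differ."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(23)
        n = 12
        vals = rng.permutation(n * (n - 1) // 2) + 1.0  # all distinct
        values = squareform(vals)
        labels = [f"d{i}" for i in range(n)]
        dend = complete_linkage(_dm(labels, values))
        expected = linkage(vals, method="complete")
        assert np.allclose(
            [h for _, _, h in dend.merges], expected[:, 2]
        )

    def test_single_disease_rejected(self):
        with pytest.raises(DomainError):
            complete_linkage(_dm(["a"], [[0.0]]))


class TestParentPromotion:
    def test_worked_six_disease_ordering(self, fig2_case):
        """6 outcites 5 and becomes its parent; 3 outcites everyone and
        ends up as root with 5 still beneath 6."""
        d, citations = fig2_case
        tree = parent_promotion(complete_linkage(d), citations)
        assert tree.roots == {"3"}
        assert ("6", "5") in tree.edges
        assert ("3", "6") in tree.edges
        assert ("3", "5") not in tree.edges

    def test_two_leaves(self):
        d = _dm(["a", "b"], [[0, 0.5], [0.5, 0]])
        tree = parent_promotion(
            complete_linkage(d), CitationTable({"a": 9, "b": 4})
        )
        assert tree.edges == {("a", "b")} and tree.roots == {"a"}

    def test_equal_citations_tie_rule(self):
        rng = np.random.default_rng(2)
        labels = [f"d{i}" for i in range(6)]
        d = _dm(labels, oracles.random_distance_matrix(rng, 6))
        tree = parent_promotion(
            complete_linkage(d), CitationTable({x: 7 for x in labels})
        )
        assert len(tree.edges) == 5 and len(tree.roots) == 1
        for p, c in tree.edges:
            assert p < c  # ties promote the lexicographically smaller id

    def test_missing_citation_named(self):
        d = _dm(["a", "b"], [[0, 0.5], [0.5, 0]])
        with pytest.raises(DomainError, match="'b'"):
            parent_promotion(complete_linkage(d), CitationTable({"a": 1}))

    def test_structural_invariants_random(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            labels = [f"d{i}" for i in range(n)]
            d = _dm(labels, oracles.random_distance_matrix(rng, n))
            citations = CitationTable(
                {x: int(rng.integers(0, 1000)) for x in labels}
            )
            tree = parent_promotion(complete_linkage(d), citations)
            assert len(tree.roots) == 1
            assert len(tree.edges) == n - 1
            for p, c in tree.edges:
                assert citations[p] >= citations[c]


class TestMwst:
    def test_three_disease_enumeration(self):
        # similarities 0.9 / 0.8 / 0.1 -> distances 0.1 / 0.2 / 0.9
        d = _dm(
            ["A", "B", "C"],
            [[0, 0.1, 0.9], [0.1, 0, 0.2], [0.9, 0.2, 0]],
        )
        tree = mwst_infer(d, CitationTable({"A": 1, "B": 2, "C": 30}))
        assert tree.edges == {("C", "B"), ("B", "A")}
        assert tree.roots == {"C"}

    def test_two_diseases(self):
        d = _dm(["a", "b"], [[0, 0.3], [0.3, 0]])
        tree = mwst_infer(d, CitationTable({"a": 1, "b": 5}))
        assert tree.edges == {("b", "a")}

    def test_weight_matches_brute_force(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            labels = [f"d{i}" for i in range(n)]
            values = oracles.random_distance_matrix(rng, n)
            citations = CitationTable(
                {x: int(rng.integers(100)) for x in labels}
            )
            tree = mwst_infer(_dm(labels, values), citations)
            idx = {lab: i for i, lab in enumerate(labels)}
            weight = sum(values[idx[p], idx[c]] for p, c in tree.edges)
            assert weight == pytest.approx(
                oracles.min_spanning_weight(values), abs=1e-12
            )

    def test_label_order_invariance(self):
        """With distinct distances and citations, shuffling the label
        order must not change the inferred edges."""
        rng = np.random.default_rng(53)
        n = 8
        labels = [f"d{i}" for i in range(n)]
        vals = (rng.permutation(n * (n - 1) // 2) + 1.0) / 100.0
        from scipy.spatial.distance import squareform

        values = squareform(vals)
        citations = CitationTable({x: 10 + i for i, x in enumerate(labels)})
        base = mwst_infer(_dm(labels, values), citations)
        perm = list(rng.permutation(n))
        shuffled = mwst_infer(
            _dm([labels[i] for i in perm], values[np.ix_(perm, perm)]),
            citations,
        )
        assert shuffled == base


class TestInferPipeline:
    def test_two_disease_table(self):
        table = AssociationTable({("a", "g1"), ("b", "g1"), ("b", "g2")})
        citations = CitationTable({"a": 4, "b": 2})
        tree = infer("parent_promotion", table, ["a", "b"], citations)
        assert tree.edges == {("a", "b")}

    @pytest.mark.parametrize("method", ["pp", "mwst"])
    def test_deterministic_across_calls(self, method):
        h, table, citations = make_separable_fixture(15, seed=9)
        diseases = sorted(h.nodes)
        t1 = infer(method, table, diseases, citations)
        t2 = infer(method, table, diseases, citations)
        assert t1 == t2

    def test_separable_fixture_recovered(self):
        h, table, citations = make_separable_fixture(20, seed=4)
        tree = infer("pp", table, sorted(h.nodes), citations)
        assert edge_correctness(h, tree) == 1.0

    def test_unknown_method(self):
        table = AssociationTable({("a", "g"), ("b", "g")})
        with pytest.raises(DomainError):
            infer("clixo", table, ["a", "b"], CitationTable({"a": 1, "b": 1}))


class TestCitationIO:
    def test_round_trip(self, tmp_path):
        from diseasetax.inference import write_citations

        c = CitationTable({"a": 3, "b": 0})
        p = tmp_path / "c.tsv"
        write_citations(c, p, ["meta"])
        assert read_citations(p).counts == c.counts

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("a\t-1\n")
        with pytest.raises(ParseError):
            read_citations(p)
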