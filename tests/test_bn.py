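"""DAG enumeration, d-separation, Markov classes, notation."""

import itertools
import random

import networkx as nx
import pytest

from rabn import (
    VariableSystem,
    canonical_text,
    d_separated,
    enumerate_dags,
    general_classes,
    independencies,
    markov_equivalent,
    parse_structure,
    skeleton,
    specific_classes,
    v_structures,
)
from rabn.bn import (
    Dag,
    bn_notation,
    cpdag,
    elementary_independencies,
    factorization,
    factorization_text,
    minimal_independencies,
    moral_graph,
)
from rabn.core import IndependenceStatement
from tests.conftest import dag_from_factorization, parse_statements


class TestDag:
    def test_rejects_cycles_and_self_edges(self, sys3):
        with pytest.raises(ValueError):
            Dag(sys3, [("A", "B"), ("B", "C"), ("C", "A")])
        with pytest.raises(ValueError):
            Dag(sys3, [("A", "A")])

    def test_edge_text_round_trip(self, sys4):
        dag = Dag(sys4, [("C", "A"), ("D", "A"), ("C", "B"), ("D", "B"), ("C", "D")])
        assert Dag.from_edge_text(dag.edge_text(), sys4) == dag
        iso = Dag(sys4, [("B", "D"), ("C", "D")])
        assert "A" in iso.edge_text()
        assert Dag.from_edge_text(iso.edge_text(), sys4) == iso


class TestEnumeration:
    @pytest.mark.parametrize("n, count", [(1, 1), (2, 3), (3, 25), (4, 543)])
    def test_labeled_dag_counts(self, n, count):
        system = VariableSystem(tuple("ABCD"[:n]))
        assert len(enumerate_dags(system)) == count

    def test_enumeration_refuses_large_systems(self):
        with pytest.raises(ValueError, match="limited"):
            enumerate_dags(VariableSystem(tuple("ABCDEF")))

    def test_deterministic_order(self, sys3):
        assert enumerate_dags(sys3) == enumerate_dags(sys3)


class TestSkeletonAndVStructures:
    def test_collider(self, sys3):
        dag = Dag(sys3, [("A", "B"), ("C", "B")])
        assert skeleton(dag) == frozenset({frozenset("AB"), frozenset("BC")})
        (vs,) = v_structures(dag)
        assert (vs.parent1, vs.child, vs.parent2) == ("A", "B", "C")

    def test_chain_has_none(self, sys3):
        assert v_structures(Dag(sys3, [("A", "B"), ("B", "C")])) == frozenset()

    def test_married_parents_are_not_a_v_structure(self, sys4):
        dag = Dag(sys4, [("B", "D"), ("C", "D"), ("B", "C")])
        assert v_structures(dag) == frozenset()


class TestMarkovEquivalence:
    def test_mirrored_chain(self, sys3):
        assert markov_equivalent(
            Dag(sys3, [("A", "B"), ("B", "C")]), Dag(sys3, [("C", "B"), ("B", "A")])
        )

    def test_collider_differs_from_chain(self, sys3):
        assert not markov_equivalent(
            Dag(sys3, [("A", "B"), ("C", "B")]), Dag(sys3, [("A", "B"), ("B", "C")])
        )

    def test_equivalence_iff_same_independencies_n3(self, sys3):
        dags = enumerate_dags(sys3)
        elem = {d: elementary_independencies(d) for d in dags}
        for d1, d2 in itertools.combinations(dags, 2):
            assert markov_equivalent(d1, d2) == (elem[d1] == elem[d2])

    def test_equivalence_iff_same_independencies_n4_sampled(self, sys4):
        rng = random.Random(3)
        dags = rng.sample(list(enumerate_dags(sys4)), 60)
        for d1, d2 in itertools.combinations(dags, 2):
            assert markov_equivalent(d1, d2) == (
                elementary_independencies(d1) == elementary_independencies(d2)
            )


def _random_dag(system, rng):
    edges = []
    names = list(system.names)
    rng.shuffle(names)
    for i, j in itertools.combinations(range(len(names)), 2):
        if rng.random() < 0.5:
            edges.append((names[i], names[j]))
    return Dag(system, edges)


def _brute_force_d_separated(dag, x, y, given):
    """Independent oracle: enumerate every undirected path and test activity."""
    adj = {v: set() for v in dag.system.names}
    for a, b in dag.edges:
        adj[a].add(b)
        adj[b].add(a)

    def descendants_or_self(v):
        return {v} | set(dag.descendants(v))

    def active(path):
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            collider = (prev, node) in dag.edges and (nxt, node) in dag.edges
            if collider:
                if not (descendants_or_self(node) & set(given)):
                    return False
            elif node in given:
                return False
        return True

    def paths(node, target, seen):
        if node == target:
            yield [node]
            return
        for w in adj[node]:
            if w not in seen:
                for rest in paths(w, target, seen | {w}):
                    yield [node] + rest

    return not any(active(p) for p in paths(x, y, {x}))


class TestDSeparation:
    def test_published_verdicts(self, sys4, sys3):
        bn2 = Dag(sys4, [("C", "A"), ("D", "A"), ("C", "B"), ("D", "B"), ("C", "D")])
        assert d_separated(bn2, "A", "B", {"C", "D"})
        assert not d_separated(bn2, "A", "B", {"C"})
        collider = Dag(sys3, [("A", "B"), ("C", "B")])
        assert not d_separated(collider, "A", "C", {"B"})
        assert d_separated(collider, "A", "C")

    def test_descendant_of_collider_opens_path(self, sys4):
        dag = Dag(sys4, [("A", "B"), ("C", "B"), ("B", "D")])
        assert not d_separated(dag, "A", "C", {"D"})

    def test_invalid_queries(self, sys3):
        dag = Dag(sys3, [("A", "B")])
        with pytest.raises(ValueError):
            d_separated(dag, "A", "A")
        with pytest.raises(ValueError):
            d_separated(dag, "A", "B", {"A"})
        with pytest.raises(ValueError):
            d_separated(dag, "A", "X")

    def test_agrees_with_path_oracle_and_networkx(self, sys4):
        rng = random.Random(11)
        for _ in range(60):
            dag = _random_dag(sys4, rng)
            x, y = rng.sample(list(sys4.names), 2)
            rest = [v for v in sys4.names if v not in (x, y)]
            given = frozenset(rng.sample(rest, rng.randint(0, 2)))
            got = d_separated(dag, x, y, given)
            assert got == _brute_force_d_separated(dag, x, y, given)
            g = nx.DiGraph(list(dag.edges))
            g.add_nodes_from(sys4.names)
            assert got == nx.is_d_separator(g, {x}, {y}, set(given))


class TestIndependencies:
    def test_complete_dag_has_none(self, sys4):
        dag = dag_from_factorization("p(B|A)p(A)p(C|AB)p(D|ABC)", sys4)
        assert independencies(dag) == frozenset()
        assert minimal_independencies(dag) == frozenset()

    def test_empty_dag_is_full_mutual_independence(self, sys4):
        dag = Dag(sys4, [])
        assert minimal_independencies(dag) == parse_statements(
            "(A ⊥ B, C, D), (B ⊥ C, D), (C ⊥ D)"
        )

    def test_isolated_plus_collider(self, sys4):
        dag = Dag(sys4, [("B", "D"), ("C", "D")])
        assert minimal_independencies(dag) == parse_statements(
            "(B ⊥ C), (A ⊥ B, C, D)"
        )

    def test_minimal_list_closure_equals_elementary_set(self, sys4):
        # every statement in the display list must be true, and its
        # elementary decompositions must lie inside the full elementary set
        rng = random.Random(5)
        for _ in range(25):
            dag = _random_dag(sys4, rng)
            elem = elementary_independencies(dag)
            for stmt in minimal_independencies(dag):
                for x in stmt.left:
                    for y in stmt.right:
                        assert (
                            IndependenceStatement({x}, {y}, stmt.given) in elem
                        )


class TestClasses:
    def test_specific_class_counts(self, sys3, sys4):
        spec4 = specific_classes(sys4)
        assert len(spec4) == 185
        assert sum(c.size for c in spec4) == 543
        assert len(specific_classes(sys3)) == 11

    def test_general_class_counts(self, sys3, sys4):
        assert len(general_classes(specific_classes(sys4))) == 20
        assert len(general_classes(specific_classes(sys3))) == 5

    def test_representative_is_lexicographically_least_member(self, sys4):
        for cls in specific_classes(sys4)[:40]:
            keys = sorted(tuple(sorted(d.edges)) for d in cls.members)
            assert tuple(sorted(cls.representative.edges)) == keys[0]


class TestCpdag:
    def test_chain_class_fully_undirected(self, sys3):
        cls = next(
            c
            for c in specific_classes(sys3)
            if Dag(sys3, [("A", "B"), ("B", "C")]) in c.members
        )
        p = cpdag(cls)
        assert p.directed == frozenset()
        assert p.undirected == frozenset({frozenset("AB"), frozenset("BC")})

    def test_collider_class_fully_directed(self, sys3):
        cls = next(
            c
            for c in specific_classes(sys3)
            if Dag(sys3, [("A", "B"), ("C", "B")]) in c.members
        )
        p = cpdag(cls)
        assert p.directed == frozenset({("A", "B"), ("C", "B")})

    def test_star_class_excludes_new_collider(self, sys4):
        # B-D-C undirected, but the B→D←C orientation is a different class
        star = Dag(sys4, [("D", "B"), ("D", "C")])
        cls = next(c for c in specific_classes(sys4) if star in c.members)
        assert len(cls.members) == 3
        assert Dag(sys4, [("B", "D"), ("C", "D")]) not in cls.members
        assert cpdag(cls).undirected == frozenset(
            {frozenset("BD"), frozenset("CD")}
        )


class TestFactorizationAndNotation:
    def test_factorization_terms(self, sys4):
        dag = Dag(sys4, [("C", "A"), ("D", "A"), ("C", "B"), ("D", "B"), ("C", "D")])
        assert factorization_text(dag) == "p(A|CD)p(B|CD)p(C)p(D|C)"
        assert [t.child for t in factorization(dag)] == list("ABCD")

    def test_factorization_of_empty_dag(self, sys4):
        assert factorization_text(Dag(sys4, [])) == "p(A)p(B)p(C)p(D)"

    def test_moral_graph_marries_parents(self, sys3, sys4):
        assert moral_graph(Dag(sys3, [("A", "B"), ("C", "B")])) == frozenset(
            {frozenset("AB"), frozenset("BC"), frozenset("AC")}
        )
        assert moral_graph(Dag(sys3, [("A", "B"), ("B", "C")])) == frozenset(
            {frozenset("AB"), frozenset("BC")}
        )
        assert moral_graph(Dag(sys4, [("B", "D"), ("C", "D")])) == frozenset(
            {frozenset("BD"), frozenset("CD"), frozenset("BC")}
        )

    @pytest.mark.parametrize(
        "notation, factor_text",
        [
            ("BCD_B:C_:A", "p(D|BC)p(B)p(C)p(A)"),
            ("ABCD_AC:BC_", "p(A|C)p(C)p(B|C)p(D|ABC)"),
            ("ACD_C:D_:BCD_C:D_", "p(A|CD)p(C)p(D)p(B|CD)"),
            ("AD:BD:CD", "p(A|D)p(D)p(B|D)p(C|D)"),
        ],
    )
    def test_notation_examples(self, sys4, notation, factor_text):
        dag = dag_from_factorization(factor_text, sys4)
        assert bn_notation(dag) == parse_structure(notation, sys4)

    def test_notation_is_class_invariant(self, sys4):
        rng = random.Random(13)
        for cls in rng.sample(list(specific_classes(sys4)), 30):
            texts = {canonical_text(bn_notation(d)) for d in cls.members}
            assert len(texts) == 1
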