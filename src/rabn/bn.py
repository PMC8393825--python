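"""Bayesian-network graphs: enumeration, d-separation, equivalence, notation.

A BN topology is a labeled DAG; its independence semantics are given by
d-separation.  Two DAGs with the same skeleton and the same V-structures
(two non-adjacent parents converging on a child) are Markov equivalent and
describe the same set of independencies — a "specific graph" in RA-style
terminology is such a Markov equivalence class, and a "general graph" is a
specific graph with the variable labels removed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .core import (
    ExtendedNotation,
    IndependenceStatement,
    SubscriptedRelation,
    VariableSystem,
    enumerate_independence_statements,
)

_MAX_ENUM_N = 5  # 3^C(n,2) orientation patterns; 3^10 = 59049 at n=5


@dataclass(frozen=True)
class Dag:
    """A labeled directed acyclic graph over a variable system."""

    system: VariableSystem
    edges: frozenset  # frozenset[(parent, child)]

    def __init__(self, system: VariableSystem, edges: Iterable):
        edges = frozenset((str(a), str(b)) for a, b in edges)
        known = system.variables()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"unknown variable in edge {a}->{b}")
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "edges", edges)
        if self._has_cycle():
            raise ValueError("directed cycle in edge set")

    def _has_cycle(self) -> bool:
        children = self.children_map()
        state = {}  # 0 = visiting, 1 = done

        def visit(v):
            state[v] = 0
            for w in children[v]:
                s = state.get(w)
                if s == 0:
                    return True
                if s is None and visit(w):
                    return True
            state[v] = 1
            return False

        return any(state.get(v) is None and visit(v) for v in self.system.names)

    def parents(self, v: str) -> frozenset:
        return frozenset(a for a, b in self.edges if b == v)

    def children(self, v: str) -> frozenset:
        return frozenset(b for a, b in self.edges if a == v)

    def parents_map(self) -> dict:
        out = {v: set() for v in self.system.names}
        for a, b in self.edges:
            out[b].add(a)
        return out

    def children_map(self) -> dict:
        out = {v: set() for v in self.system.names}
        for a, b in self.edges:
            out[a].add(b)
        return out

    def descendants(self, v: str) -> frozenset:
        children = self.children_map()
        seen, stack = set(), [v]
        while stack:
            for w in children[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(seen)

    def topological_order(self) -> tuple:
        parents = {v: set(p) for v, p in self.parents_map().items()}
        order, ready = [], sorted(v for v, p in parents.items() if not p)
        while ready:
            v = ready.pop(0)
            order.append(v)
            for w in self.system.names:
                if v in parents[w]:
                    parents[w].discard(v)
                    if not parents[w]:
                        ready.append(w)
                        ready.sort()
        return tuple(order)

    def edge_text(self) -> str:
        """Semicolon edge format, isolated nodes as bare tokens: "C>A;D>A;B"."""
        touched = {v for e in self.edges for v in e}
        parts = sorted(f"{a}>{b}" for a, b in self.edges)
        parts += [v for v in self.system.names if v not in touched]
        return ";".join(parts)

    @classmethod
    def from_edge_text(cls, text: str, system: VariableSystem) -> "Dag":
        edges = []
        for token in text.replace(" ", "").split(";"):
            if not token:
                continue
            if ">" in token:
                a, b = token.split(">")
                edges.append((a, b))
            elif token not in system.variables():
                raise ValueError(f"unknown isolated node {token!r}")
        return cls(system, edges)

    def __str__(self) -> str:
        return self.edge_text()


@dataclass(frozen=True)
class VStructure:
    """Two non-adjacent parents converging on a child (parent1 < parent2)."""

    parent1: str
    child: str
    parent2: str

    def __init__(self, parent1: str, child: str, parent2: str):
        if parent2 < parent1:
            parent1, parent2 = parent2, parent1
        object.__setattr__(self, "parent1", parent1)
        object.__setattr__(self, "child", child)
        object.__setattr__(self, "parent2", parent2)


@dataclass(frozen=True)
class Pdag:
    """A partially directed graph standing for a Markov equivalence class."""

    system: VariableSystem
    directed: frozenset  # frozenset[(a, b)]
    undirected: frozenset  # frozenset[frozenset{a, b}]

    def __post_init__(self):
        pairs = [frozenset(e) for e in self.directed]
        if len(set(pairs) | set(self.undirected)) != len(pairs) + len(
            self.undirected
        ):
            raise ValueError("a pair may appear in only one edge set")


@dataclass(frozen=True)
class FactorTerm:
    """One term p(child | parents) of a BN factorization."""

    child: str
    parents: frozenset

    def __str__(self) -> str:
        if self.parents:
            return f"p({self.child}|{''.join(sorted(self.parents))})"
        return f"p({self.child})"


@dataclass(frozen=True)
class GraphClass:
    """An equivalence class of model structures.

    ``kind`` is "bn" or "ra" for specific (labeled) classes and gains a
    "-general" suffix for unlabeled classes, whose members are themselves
    specific GraphClass objects.
    """

    kind: str
    system: VariableSystem
    representative: object
    members: tuple
    label: str = ""

    @property
    def size(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        rep = self.representative
        if isinstance(rep, GraphClass):
            return str(rep)
        if isinstance(rep, Dag):
            from .core import canonical_text

            return canonical_text(bn_notation(rep))
        return str(rep)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def enumerate_dags(system: VariableSystem) -> tuple:
    """Every labeled DAG over the system, in a deterministic order.

    Each unordered variable pair independently carries no edge or an edge in
    either direction; orientation patterns containing a directed cycle are
    discarded.  Exhaustive enumeration is refused for n > 5 (3^C(n,2)
    candidate patterns).
    """
    n = system.n
    if n > _MAX_ENUM_N:
        raise ValueError(
            f"exhaustive DAG enumeration is limited to n <= {_MAX_ENUM_N} "
            f"(3^{n * (n - 1) // 2} orientation patterns at n = {n})"
        )
    pairs = list(itertools.combinations(system.names, 2))
    out = []
    for choices in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), c in zip(pairs, choices):
            if c == 1:
                edges.append((a, b))
            elif c == 2:
                edges.append((b, a))
        try:
            out.append(Dag(system, edges))
        except ValueError:
            continue
    return tuple(out)


def skeleton(dag: Dag) -> frozenset:
    """Undirected edge set: orientation dropped."""
    return frozenset(frozenset(e) for e in dag.edges)


def v_structures(dag: Dag) -> frozenset:
    """All converging non-adjacent parent pairs."""
    skel = skeleton(dag)
    out = set()
    for child in dag.system.names:
        for p, q in itertools.combinations(sorted(dag.parents(child)), 2):
            if frozenset((p, q)) not in skel:
                out.add(VStructure(p, child, q))
    return frozenset(out)


def markov_equivalent(d1: Dag, d2: Dag) -> bool:
    """Same skeleton and same V-structures — identical independencies."""
    if d1.system.names != d2.system.names:
        raise ValueError("DAGs must share one variable system")
    return skeleton(d1) == skeleton(d2) and v_structures(d1) == v_structures(d2)


# ---------------------------------------------------------------------------
# d-separation
# ---------------------------------------------------------------------------


def d_separated(dag: Dag, x: str, y: str, given: Iterable = ()) -> bool:
    """Standard d-separation verdict by active-trail reachability.

    A trail is active given Z when every head-to-head (collider) node on it
    is in Z or has a descendant in Z, and no other node on it is in Z.
    Returns True when no active trail joins x and y.
    """
    given = frozenset(given)
    known = dag.system.variables()
    if x not in known or y not in known or not given <= known:
        raise ValueError("unknown variables in d-separation query")
    if x == y or x in given or y in given:
        raise ValueError("query variables must be distinct and not conditioned on")

    parents, children = dag.parents_map(), dag.children_map()
    # ancestors of the conditioning set (for collider activation)
    anc = set(given)
    stack = list(given)
    while stack:
        for p in parents[stack.pop()]:
            if p not in anc:
                anc.add(p)
                stack.append(p)

    # reachability over (node, direction): direction "up" = arrived via an
    # edge out of the node (from a child), "down" = via an edge into it
    start = [(x, "up")]
    seen = set(start)
    while start:
        v, direction = start.pop()
        if v == y and v not in given:
            return False
        moves = []
        if direction == "up" and v not in given:
            moves += [(p, "up") for p in parents[v]]
            moves += [(c, "down") for c in children[v]]
        elif direction == "down":
            if v not in given:
                moves += [(c, "down") for c in children[v]]
            if v in anc:  # collider (or its ancestor-of-evidence) opens upward
                moves += [(p, "up") for p in parents[v]]
        for move in moves:
            if move not in seen:
                seen.add(move)
                start.append(move)
    return True


def statement_holds(dag: Dag, stmt: IndependenceStatement) -> bool:
    """Evaluate a (possibly compound) statement as a conjunction of pairs.

    Valid because d-separation satisfies composition: (X ⊥ Y ∪ W | S) holds
    exactly when (X ⊥ Y | S) and (X ⊥ W | S) do.
    """
    return all(
        d_separated(dag, x, y, stmt.given) for x in stmt.left for y in stmt.right
    )


def elementary_independencies(dag: Dag) -> frozenset:
    """All true pairwise statements (X ⊥ Y | S) over every conditioning set.

    This is the semantic fingerprint of a BN: two DAGs are Markov equivalent
    exactly when their elementary sets agree.
    """
    names = dag.system.names
    out = set()
    for x, y in itertools.combinations(names, 2):
        rest = [v for v in names if v not in (x, y)]
        for k in range(len(rest) + 1):
            for s in itertools.combinations(rest, k):
                if d_separated(dag, x, y, s):
                    out.add(IndependenceStatement({x}, {y}, s))
    return frozenset(out)


def independencies(dag: Dag) -> frozenset:
    """All tabulated-form statements satisfied by d-separation."""
    return frozenset(
        s for s in set(enumerate_independence_statements(dag.system))
        if statement_holds(dag, s)
    )


# ---------------------------------------------------------------------------
# minimal display list
# ---------------------------------------------------------------------------


def _components(dag: Dag) -> list:
    adj = {v: set() for v in dag.system.names}
    for a, b in dag.edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for v in sorted(dag.system.names):
        if v in seen:
            continue
        comp, stack = {v}, [v]
        while stack:
            for w in adj[stack.pop()]:
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def _depths(dag: Dag, comp: frozenset) -> dict:
    depth = {}
    for v in dag.topological_order():
        if v in comp:
            ps = dag.parents(v)
            depth[v] = 1 + max((depth[p] for p in ps), default=-1)
    return depth


def minimal_independencies(dag: Dag) -> frozenset:
    """A compact list of statements that fully characterizes the DAG.

    Built in two layers.  Disconnected skeleton components yield block
    statements (component ⊥ union of later components).  Inside a component
    the candidates are the local-Markov statements
    (X ⊥ nondescendants(X) ∖ pa(X) | pa(X)); a greedy cover of all separable
    pairs retains the fewest of them, trimming each retained statement to the
    pairs it newly covers.  Ties prefer statements covering the most new
    pairs, then statements all of whose pairs are new, then smaller
    conditioning sets, then deeper nodes, then alphabetical order.  The full
    elementary set is recovered from the result by the semi-graphoid rules;
    equivalence tests always use ``elementary_independencies``.
    """
    out = []
    comps = _components(dag)
    for i, comp in enumerate(comps[:-1]):
        later = frozenset().union(*comps[i + 1:])
        out.append(IndependenceStatement(comp, later))

    for comp in comps:
        if len(comp) < 2:
            continue
        # separable pairs within the component
        pairs = set()
        rest_of = {}
        for x, y in itertools.combinations(sorted(comp), 2):
            rest = [v for v in comp if v not in (x, y)]
            for k in range(len(rest) + 1):
                if any(
                    d_separated(dag, x, y, s)
                    for s in itertools.combinations(rest, k)
                ):
                    pairs.add(frozenset((x, y)))
                    break
            rest_of[frozenset((x, y))] = rest
        if not pairs:
            continue
        depth = _depths(dag, comp)
        candidates = []
        for x in sorted(comp):
            nd = comp - dag.descendants(x) - {x} - dag.parents(x)
            if nd:
                candidates.append((x, nd, dag.parents(x)))
        uncovered = set(pairs)
        while uncovered:
            best = None
            for x, nd, pa in candidates:
                covered = {frozenset((x, y)) for y in nd}
                new = covered & uncovered
                if not new:
                    continue
                key = (
                    -len(new),
                    0 if covered <= uncovered else 1,
                    len(pa),
                    -depth[x],
                    x,
                )
                if best is None or key < best[0]:
                    best = (key, x, new, pa)
            if best is None:  # cannot happen: local Markov covers all pairs
                raise AssertionError("uncovered separable pair")
            _, x, new, pa = best
            right = frozenset(y for p in new for y in p if y != x)
            out.append(IndependenceStatement({x}, right, pa))
            uncovered -= new
    return frozenset(out)


# ---------------------------------------------------------------------------
# classes
# ---------------------------------------------------------------------------


def _edge_key(dag: Dag) -> tuple:
    return tuple(sorted(dag.edges))


def specific_classes(system: VariableSystem) -> tuple:
    """Markov equivalence classes of all labeled DAGs, deterministically ordered.

    The representative of each class is the member with the
    lexicographically smallest sorted edge list.
    """
    groups = {}
    for dag in enumerate_dags(system):
        key = (skeleton(dag), v_structures(dag))
        groups.setdefault(key, []).append(dag)
    classes = []
    for members in groups.values():
        members.sort(key=_edge_key)
        classes.append(
            GraphClass("bn", system, members[0], tuple(members))
        )
    classes.sort(key=lambda c: (len(c.representative.edges), _edge_key(c.representative)))
    return tuple(classes)


def _statement_tuple(stmt: IndependenceStatement) -> tuple:
    return (
        tuple(sorted(stmt.left)),
        tuple(sorted(stmt.right)),
        tuple(sorted(stmt.given)),
    )


def permuted_statements(statements: Iterable, mapping: dict) -> frozenset:
    return frozenset(
        IndependenceStatement(
            (mapping[v] for v in s.left),
            (mapping[v] for v in s.right),
            (mapping[v] for v in s.given),
        )
        for s in statements
    )


def independence_signature(statements: Iterable, names: Sequence,
                           fixed: Iterable = ()) -> tuple:
    """Canonical form of a statement set under variable permutation.

    Two labeled independence sets have the same signature exactly when some
    bijection of the variables (fixing ``fixed``) maps one onto the other.
    """
    statements = frozenset(statements)
    names = sorted(names)
    fixed = set(fixed)
    free = [v for v in names if v not in fixed]
    best = None
    for perm in itertools.permutations(free):
        mapping = dict(zip(free, perm))
        mapping.update({v: v for v in fixed})
        key = tuple(
            sorted(_statement_tuple(s) for s in permuted_statements(statements, mapping))
        )
        if best is None or key < best:
            best = key
    return best


def general_classes(specific: Iterable, fixed: Iterable = ()) -> tuple:
    """Group specific classes whose independence structures are unlabeled-equal."""
    groups = {}
    order = []
    for cls in specific:
        elem = class_elementary(cls)
        sig = independence_signature(elem, cls.system.names, fixed)
        if sig not in groups:
            groups[sig] = []
            order.append(sig)
        groups[sig].append(cls)
    out = []
    for sig in order:
        members = groups[sig]
        out.append(
            GraphClass(
                members[0].kind + "-general",
                members[0].system,
                members[0],
                tuple(members),
            )
        )
    return tuple(out)


def class_elementary(cls: GraphClass) -> frozenset:
    """Elementary independence set of a specific class (BN or RA)."""
    if cls.kind.startswith("bn"):
        return elementary_independencies(cls.representative)
    from .ra import ra_elementary_independencies

    return ra_elementary_independencies(cls.representative)


@dataclass(frozen=True)
class ClassLattice:
    """Markov classes with a single-edge-deletion hierarchy, searchable like
    an RA lattice (nodes are GraphClass objects)."""

    system: VariableSystem
    structures: tuple
    hierarchy: tuple


def class_lattice(system: VariableSystem) -> ClassLattice:
    """All Markov equivalence classes, linked parent→child by edge deletion.

    A class is a child of another when deleting one edge from some member
    of the parent yields a member of the child.
    """
    classes = specific_classes(system)
    by_dag = {}
    for cls in classes:
        for dag in cls.members:
            by_dag[dag] = cls
    edges = []
    seen = set()
    for cls in classes:
        for dag in cls.members:
            for edge in dag.edges:
                child = by_dag[Dag(system, dag.edges - {edge})]
                key = (id(cls), id(child))
                if child is not cls and key not in seen:
                    seen.add(key)
                    edges.append((cls, child))
    return ClassLattice(system, classes, tuple(edges))


def cpdag(cls: GraphClass) -> Pdag:
    """Class representation: an edge keeps its direction only when every
    member of the Markov class orients it identically."""
    skel = skeleton(cls.representative)
    directed, undirected = set(), set()
    for pair in skel:
        orientations = {
            (a, b) for d in cls.members for a, b in d.edges if frozenset((a, b)) == pair
        }
        if len(orientations) == 1:
            directed.add(next(iter(orientations)))
        else:
            undirected.add(pair)
    return Pdag(cls.system, frozenset(directed), frozenset(undirected))


# ---------------------------------------------------------------------------
# factorization and notation
# ---------------------------------------------------------------------------


def factorization(dag: Dag) -> tuple:
    """One p(node | parents) term per node, alphabetical by node."""
    return tuple(
        FactorTerm(v, dag.parents(v)) for v in sorted(dag.system.names)
    )


def factorization_text(dag: Dag) -> str:
    return "".join(str(t) for t in factorization(dag))


def moral_graph(dag: Dag) -> frozenset:
    """Skeleton plus an edge between every pair of parents sharing a child."""
    out = set(skeleton(dag))
    for child in dag.system.names:
        for p, q in itertools.combinations(dag.parents(child), 2):
            out.add(frozenset((p, q)))
    return frozenset(out)


def _minimal_separators_within(dag: Dag, x: str, y: str, pool: frozenset) -> list:
    """Inclusion-minimal S ⊆ pool with x d-separated from y given S."""
    pool = sorted(pool)
    found = []
    for k in range(len(pool) + 1):
        for s in itertools.combinations(pool, k):
            s = frozenset(s)
            if any(m <= s for m in found):
                continue
            if d_separated(dag, x, y, s):
                found.append(s)
    return found


def bn_notation(dag: Dag) -> ExtendedNotation:
    """Extended RA notation for a BN.

    Relations are the maximal cliques of the moral graph (isolated variables
    as singletons).  Independencies whose variables all lie inside one clique
    — those encoded by V-structures, which the colon structure cannot express
    — are attached to every clique containing them as a subscripted
    substructure: the relation set of the graph on the involved variables
    with the separable pairs removed.  Graphs without V-structures get plain
    RA notation.
    """
    g = nx.Graph()
    g.add_nodes_from(dag.system.names)
    g.add_edges_from(tuple(e) for e in moral_graph(dag))
    skel = skeleton(dag)
    parts = []
    for clique in nx.find_cliques(g):
        clique = frozenset(clique)
        separable, involved = set(), set()
        for x, y in itertools.combinations(sorted(clique), 2):
            if frozenset((x, y)) in skel:
                continue
            seps = _minimal_separators_within(dag, x, y, clique - {x, y})
            if seps:
                separable.add(frozenset((x, y)))
                involved.update((x, y))
                involved.update(*seps)
        if not separable:
            parts.append(SubscriptedRelation(clique))
            continue
        sub = nx.Graph()
        sub.add_nodes_from(sorted(involved))
        for u, v in itertools.combinations(sorted(involved), 2):
            if frozenset((u, v)) not in separable:
                sub.add_edge(u, v)
        sub_rels = frozenset(frozenset(c) for c in nx.find_cliques(sub))
        parts.append(SubscriptedRelation(clique, sub_rels))
    return ExtendedNotation(dag.system, parts)
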