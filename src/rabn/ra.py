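"""RA structures: loops, the neutral lattice, and directed (predictive) lattices.

The neutral lattice is generated from the saturated structure (one relation
holding all variables) by repeated relation deletion: deleting a maximal
relation surfaces the relations embedded in it.  Structures whose relation
hypergraph is acyclic ("loopless", decided by Graham reduction) have
closed-form maximum-entropy solutions; structures with loops require
iterative proportional fitting.

Directed systems single out a dependent variable (DV, conventionally "Z");
the conventional directed lattice keeps one relation holding all the
explanatory variables (the "IV relation") next to an antichain of
Z-containing predictive relations, and the augmented lattice adds the
"primed" variants obtained by removing the IV relation when doing so changes
the prediction of Z.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

from .core import (
    IndependenceStatement,
    RAStructure,
    VariableSystem,
    _cooccurrence_statements,
    _separated_in_graph,
    enumerate_independence_statements,
    maximal_relations,
    relabel_min,
)
from .bn import Dag, GraphClass, minimal_independencies as _dag_minimal, v_structures


@dataclass(frozen=True)
class DirectedSpec:
    """A directed-system designation: explanatory variables and one DV."""

    ivs: frozenset
    dv: str

    def __init__(self, ivs: Iterable, dv: str):
        ivs = frozenset(ivs)
        if dv in ivs:
            raise ValueError("the DV cannot also be an IV")
        if not ivs:
            raise ValueError("at least one IV required")
        object.__setattr__(self, "ivs", ivs)
        object.__setattr__(self, "dv", dv)

    def validate(self, system: VariableSystem):
        if self.ivs | {self.dv} != system.variables():
            raise ValueError("IVs plus DV must exhaust the system")


@dataclass(frozen=True)
class RALattice:
    """A lattice of RA structures with deletion hierarchy and class groupings.

    ``hierarchy`` holds (parent, child) structure pairs; ``levels`` maps each
    structure to its longest-chain distance from the top.  ``classes`` are
    the specific (labeled) classes — one per distinct canonical structure —
    and ``general`` groups them under variable relabeling.
    """

    system: VariableSystem
    structures: tuple
    hierarchy: tuple
    classes: tuple
    general: tuple
    levels: dict = field(compare=False, default_factory=dict)

    @property
    def top(self) -> RAStructure:
        return self.structures[0]

    @property
    def specific_count(self) -> int:
        return len(self.structures)

    @property
    def general_count(self) -> int:
        return len(self.general)


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------


def has_loop(structure: RAStructure) -> bool:
    """True when the relation hypergraph is cyclic (Graham reduction fails).

    Graham reduction repeatedly (a) removes any variable that occurs in
    exactly one relation and (b) removes any relation contained in another;
    the hypergraph is acyclic exactly when this empties it.  Acyclicity is
    what gives a structure a closed-form (factorized) maximum-entropy
    solution, so this predicate marks exactly the structures needing IPF.
    """
    rels = [set(r) for r in structure.relations]
    changed = True
    while changed and rels:
        changed = False
        counts = {}
        for r in rels:
            for v in r:
                counts[v] = counts.get(v, 0) + 1
        for r in rels:
            lonely = {v for v in r if counts[v] == 1}
            if lonely:
                r -= lonely
                changed = True
        rels = [r for r in rels if r]
        keep = []
        for i, r in enumerate(rels):
            if any(i != j and r <= s for j, s in enumerate(rels)):
                changed = True
            else:
                keep.append(r)
        rels = keep
    return bool(rels)


# ---------------------------------------------------------------------------
# lattice generation
# ---------------------------------------------------------------------------


def children(structure: RAStructure) -> tuple:
    """Structures one relation-deletion below.

    Deleting a (non-singleton) maximal relation removes it from the down
    closure of the structure; the embedded relations it was covering surface
    as the new maximal elements.  Singleton relations are never deleted, so
    every variable stays covered and the bottom of the lattice is the full
    independence structure.
    """
    closure = structure.down_closure()
    out = []
    seen = set()
    for rel in structure.relations:
        if len(rel) < 2:
            continue
        child = RAStructure(structure.system, maximal_relations(closure - {rel}))
        if child.relations not in seen:
            seen.add(child.relations)
            out.append(child)
    return tuple(sorted(out, key=lambda s: str(s)))


def _group_general(system: VariableSystem, structures, fixed=()) -> tuple:
    groups, order = {}, []
    for s in structures:
        sig = relabel_min(s.relations, system.names, "ra", fixed)
        key = tuple(sorted(tuple(sorted(r)) for r in sig))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    out = []
    for key in order:
        members = tuple(
            GraphClass("ra", system, s, (s,)) for s in groups[key]
        )
        out.append(GraphClass("ra-general", system, members[0], members))
    return out


def _assemble(system, structures, hierarchy, fixed=()) -> RALattice:
    with_parent = {c for _, c in hierarchy}
    levels = {s: 0 for s in structures if s not in with_parent}
    changed = True
    while changed:  # longest-path levels by relaxation from the roots
        changed = False
        for p, c in hierarchy:
            if p in levels and levels.get(c, -1) < levels[p] + 1:
                levels[c] = levels[p] + 1
                changed = True
    structures = tuple(
        sorted(structures, key=lambda s: (levels.get(s, 0), str(s)))
    )
    classes = tuple(GraphClass("ra", system, s, (s,)) for s in structures)
    general = tuple(_group_general(system, structures, fixed))
    return RALattice(system, structures, tuple(hierarchy), classes, general, levels)


def ra_lattice(system: VariableSystem) -> RALattice:
    """The neutral lattice: transitive deletion closure of the saturated structure."""
    top = RAStructure(system, [system.variables()])
    seen = {top}
    frontier = [top]
    hierarchy = []
    while frontier:
        nxt = []
        for s in frontier:
            for c in children(s):
                hierarchy.append((s, c))
                if c not in seen:
                    seen.add(c)
                    nxt.append(c)
        frontier = nxt
    return _assemble(system, sorted(seen, key=str), hierarchy)


# ---------------------------------------------------------------------------
# independence semantics
# ---------------------------------------------------------------------------


def _adjacency(structure: RAStructure) -> dict:
    adj = {v: set() for v in structure.system.names}
    for r in structure.relations:
        for a, b in itertools.combinations(sorted(r), 2):
            adj[a].add(b)
            adj[b].add(a)
    return adj


def ra_elementary_independencies(structure: RAStructure) -> frozenset:
    """All pairwise (X ⊥ Y | S): S separates X and Y in the co-occurrence graph.

    Variables are adjacent when they share a relation.  This is the labeled
    independence fingerprint used for RA-BN equivalence tests.
    """
    return _cooccurrence_statements(structure.relations)


def _ra_statement_holds(adj: dict, stmt: IndependenceStatement) -> bool:
    return all(
        _separated_in_graph(adj, x, y, set(stmt.given))
        for x in stmt.left
        for y in stmt.right
    )


def ra_independencies(structure: RAStructure) -> frozenset:
    """All tabulated-form statements satisfied by co-occurrence separation."""
    adj = _adjacency(structure)
    return frozenset(
        s
        for s in set(enumerate_independence_statements(structure.system))
        if _ra_statement_holds(adj, s)
    )


def _perfect_dag(structure: RAStructure) -> Dag:
    """A DAG with the same independencies as a loopless structure.

    Loopless structures are decomposable: their co-occurrence graph is
    chordal, its maximal cliques are the relations, and some orientation of
    the graph is acyclic with no V-structures.  Among those orientations the
    one with the lexicographically greatest factorization term list is
    returned — this hangs alphabetically early variables off later hubs,
    which is how the published class representatives are drawn.
    """
    if has_loop(structure):
        raise ValueError("no equivalent DAG: structure has a loop")
    adj = _adjacency(structure)
    edges = [
        (a, b)
        for a, b in itertools.combinations(sorted(adj), 2)
        if b in adj[a]
    ]
    best = None
    for orient in itertools.product((0, 1), repeat=len(edges)):
        directed = [
            (b, a) if o else (a, b) for (a, b), o in zip(edges, orient)
        ]
        try:
            dag = Dag(structure.system, directed)
        except ValueError:
            continue
        if v_structures(dag):
            continue
        key = sorted(
            (v, tuple(sorted(dag.parents(v)))) for v in structure.system.names
        )
        if best is None or key > best[0]:
            best = (key, dag)
    return best[1]


def ra_minimal_independencies(structure: RAStructure) -> frozenset:
    """Compact display list for an RA structure.

    Loopless structures delegate to the DAG display algorithm via an
    independence-equivalent DAG, so equivalent RA and BN structures print
    the same lists.  For structures with loops (no DAG counterpart) the
    same greedy runs on Markov-blanket candidates
    (X ⊥ component ∖ closure(X) | boundary(X)).
    """
    if not has_loop(structure):
        return _dag_minimal(_perfect_dag(structure))
    adj = _adjacency(structure)
    variables = sorted(adj)
    # connected components
    seen, comps = set(), []
    for v in variables:
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
    out = []
    for i, comp in enumerate(comps[:-1]):
        later = frozenset().union(*comps[i + 1:])
        out.append(IndependenceStatement(comp, later))
    for comp in comps:
        if len(comp) < 2:
            continue
        pairs = set()
        for x, y in itertools.combinations(sorted(comp), 2):
            if y in adj[x]:
                continue
            rest = [v for v in comp if v not in (x, y)]
            if any(
                _separated_in_graph(adj, x, y, set(s))
                for k in range(len(rest) + 1)
                for s in itertools.combinations(rest, k)
            ):
                pairs.add(frozenset((x, y)))
        uncovered = set(pairs)
        candidates = []
        for x in sorted(comp):
            boundary = adj[x] & comp
            far = comp - boundary - {x}
            far = frozenset(
                y for y in far if _separated_in_graph(adj, x, y, boundary)
            )
            if far:
                candidates.append((x, far, frozenset(boundary)))
        while uncovered:
            best = None
            for x, far, bd in candidates:
                covered = {frozenset((x, y)) for y in far}
                new = covered & uncovered
                if not new:
                    continue
                key = (
                    -len(new),
                    0 if covered <= uncovered else 1,
                    len(bd),
                    x,
                )
                if best is None or key < best[0]:
                    best = (key, x, new, bd)
            if best is None:
                break
            _, x, new, bd = best
            right = frozenset(y for p in new for y in p if y != x)
            out.append(IndependenceStatement({x}, right, bd))
            uncovered -= new
    return frozenset(out)


# ---------------------------------------------------------------------------
# directed lattices
# ---------------------------------------------------------------------------


def _z_antichains(ivs: frozenset, dv: str):
    """All non-empty antichains of DV-containing relations."""
    z_sets = [
        frozenset({dv}) | frozenset(c)
        for k in range(len(ivs) + 1)
        for c in itertools.combinations(sorted(ivs), k)
    ]
    for k in range(1, len(z_sets) + 1):
        for combo in itertools.combinations(z_sets, k):
            if any(a < b or b < a for a, b in itertools.combinations(combo, 2)):
                continue
            yield frozenset(combo)


def _directed_children(structure: RAStructure, dv: str) -> tuple:
    """Deletion restricted to non-singleton DV-containing relations."""
    out, seen = [], set()
    closure = structure.down_closure()
    for rel in structure.relations:
        if dv not in rel or len(rel) < 2:
            continue
        remaining = maximal_relations(closure - {rel})
        child = RAStructure(structure.system, remaining)
        if child.relations not in seen:
            seen.add(child.relations)
            out.append(child)
    return tuple(out)


def conventional_directed_lattice(
    system: VariableSystem, spec: DirectedSpec
) -> RALattice:
    """Directed lattice with the IV relation always present.

    Every structure is {IV relation} ∪ T for a non-empty antichain T of
    DV-containing relations (T = {DV} alone gives the independence model
    IVs:Z; T = {all variables} absorbs the IV relation and gives the
    saturated top).  General classes permute the IVs only — the DV is
    distinguished.
    """
    spec.validate(system)
    structures = set()
    for t in _z_antichains(spec.ivs, spec.dv):
        rels = maximal_relations(t | {spec.ivs})
        structures.add(RAStructure(system, rels))
    hierarchy = [
        (s, c)
        for s in sorted(structures, key=str)
        for c in _directed_children(s, spec.dv)
        if c in structures
    ]
    return _assemble(system, sorted(structures, key=str), hierarchy, fixed={spec.dv})


def primed_variant(structure: RAStructure, spec: DirectedSpec):
    """Remove the IV relation; cover orphaned IVs with singletons.

    Returns None when the structure has no explicit IV relation.
    """
    if spec.ivs not in structure.relations:
        return None
    rels = set(structure.relations) - {spec.ivs}
    covered = frozenset().union(*rels) if rels else frozenset()
    rels |= {frozenset({v}) for v in spec.ivs - covered}
    return RAStructure(structure.system, maximal_relations(rels))


def augmented_directed_lattice(
    system: VariableSystem, spec: DirectedSpec
) -> RALattice:
    """Conventional lattice plus the retained primed (IV-relation-free) variants.

    A primed variant is kept only when it holds at least two DV-containing
    relations: with a single predictive relation the maximum-entropy
    prediction of the DV is unchanged by dropping the IV relation, so the
    variant is redundant.  The full-independence structure joins as the
    natural reference for the primed sub-lattice.  General classes here use
    full unlabeled isomorphism (the naive-Bayes-type additions group with
    conventional classes of the same shape), which reproduces the published
    class count.
    """
    spec.validate(system)
    conv = conventional_directed_lattice(system, spec)
    structures = list(conv.structures)
    have = set(structures)
    hierarchy = list(conv.hierarchy)
    for s in conv.structures:
        primed = primed_variant(s, spec)
        if primed is None or primed in have:
            continue
        z_rels = [r for r in primed.relations if spec.dv in r]
        if len(z_rels) >= 2:
            structures.append(primed)
            have.add(primed)
            hierarchy.append((s, primed))
    bottom = RAStructure(system, [frozenset({v}) for v in system.names])
    if bottom not in have:
        structures.append(bottom)
        have.add(bottom)
        conv_bottom = RAStructure(
            system, maximal_relations({spec.ivs, frozenset({spec.dv})})
        )
        hierarchy.append((conv_bottom, bottom))
    # deletion edges among the primed additions: delete a predictive relation,
    # keep only DV-containing maximal elements, re-cover IVs with singletons
    for s in structures:
        if spec.ivs in s.relations:
            continue
        closure = s.down_closure()
        for rel in s.relations:
            if spec.dv not in rel or len(rel) < 2:
                continue
            z_max = {
                r for r in maximal_relations(closure - {rel}) if spec.dv in r
            }
            covered = frozenset().union(*z_max) if z_max else frozenset()
            z_max |= {frozenset({v}) for v in system.variables() - covered}
            child = RAStructure(system, maximal_relations(z_max))
            if child in have and (s, child) not in hierarchy:
                hierarchy.append((s, child))
    return _assemble(system, structures, hierarchy, fixed=())
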