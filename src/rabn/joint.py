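"""The joint RA-BN neutral lattice, organized by Rho (variable-adjacency) graphs.

A Rho graph is an unlabeled undirected graph recording only which variables
are directly connected by some relation (RA) or edge (BN).  Every RA and
every BN class maps to exactly one Rho graph, which makes the Rho lattice
the scaffold for merging the two families: under each Rho graph sit the RA
classes with loops, the BN classes with V-structures, and the equivalent
RA-BN pairs (loopless, V-structure-free, identical independencies).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Union

from .core import RAStructure, ExtendedNotation, VariableSystem
from .bn import (
    Dag,
    GraphClass,
    class_elementary,
    elementary_independencies,
    general_classes,
    independence_signature,
    specific_classes,
)
from .ra import has_loop, ra_elementary_independencies, ra_lattice


@dataclass(frozen=True)
class RhoGraph:
    """An unlabeled undirected graph, stored in canonical (permutation-least) form.

    Nodes are 0..n-1; ``edges`` is the canonical sorted tuple of (i, j) pairs.
    """

    n: int
    edges: tuple

    @classmethod
    def from_edges(cls, n: int, edges: Iterable) -> "RhoGraph":
        edges = {frozenset(e) for e in edges}
        best = None
        for perm in itertools.permutations(range(n)):
            mapping = {}
            relabeled = sorted(
                tuple(sorted(perm[i] for i in e)) for e in edges
            )
            if best is None or relabeled < best:
                best = relabeled
        return cls(n, tuple(best if best is not None else ()))

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def __str__(self) -> str:
        return f"rho(n={self.n}, edges={list(self.edges)})"


def rho_of(model: Union[RAStructure, ExtendedNotation, Dag, GraphClass]) -> RhoGraph:
    """The Rho graph of a model: co-occurrence graph (RA) or skeleton (BN)."""
    if isinstance(model, GraphClass):
        model = model.representative
        if isinstance(model, GraphClass):  # general class of specific classes
            model = model.representative
    if isinstance(model, ExtendedNotation):
        model = model.plain
    if isinstance(model, RAStructure):
        index = {v: i for i, v in enumerate(model.system.names)}
        edges = {
            frozenset((index[a], index[b]))
            for r in model.relations
            for a, b in itertools.combinations(r, 2)
        }
        return RhoGraph.from_edges(model.system.n, edges)
    if isinstance(model, Dag):
        index = {v: i for i, v in enumerate(model.system.names)}
        edges = {frozenset((index[a], index[b])) for a, b in model.edges}
        return RhoGraph.from_edges(model.system.n, edges)
    raise TypeError(f"cannot take the Rho graph of {type(model).__name__}")


def rho_lattice(system: VariableSystem):
    """All Rho graphs on n unlabeled nodes, with single-edge-deletion hierarchy.

    Returns (graphs, hierarchy): graphs ordered by descending edge count,
    hierarchy as (parent, child) pairs.
    """
    n = system.n
    pairs = list(itertools.combinations(range(n), 2))
    seen = {}
    for mask in itertools.product((0, 1), repeat=len(pairs)):
        edges = [p for p, m in zip(pairs, mask) if m]
        rho = RhoGraph.from_edges(n, edges)
        seen[rho] = rho
    graphs = sorted(seen, key=lambda r: (-r.edge_count, r.edges))
    hierarchy = []
    for rho in graphs:
        for drop in rho.edges:
            child = RhoGraph.from_edges(n, set(rho.edges) - {drop})
            if (rho, child) not in hierarchy:
                hierarchy.append((rho, child))
    return tuple(graphs), tuple(hierarchy)


def _ra_class_elementary(cls: GraphClass) -> frozenset:
    return ra_elementary_independencies(cls.representative)


def equivalent_ra_bn(ra_class: GraphClass, bn_class: GraphClass) -> bool:
    """True when some labeling makes the elementary independence sets equal.

    Equivalence is statistical, not merely set-theoretic: an RA structure
    with a loop has no factorized solution, so it is never equivalent to a
    BN even when its separation independencies happen to coincide (the
    saturated structure and its loop-bearing decompositions all have the
    empty set).  Looplessness is therefore required on the RA side.
    """
    ra_rep = ra_class.representative
    if isinstance(ra_rep, GraphClass):
        ra_rep = ra_rep.representative
        ra_elem = _ra_class_elementary(ra_class.representative)
    else:
        ra_elem = _ra_class_elementary(ra_class)
    if has_loop(ra_rep):
        return False
    bn_rep = bn_class
    while isinstance(bn_rep, GraphClass):
        bn_rep = bn_rep.representative
    bn_elem = elementary_independencies(bn_rep)
    if not ra_rep.system.same_profile(bn_rep.system):
        return False
    names = ra_rep.system.names
    return independence_signature(ra_elem, names) == independence_signature(
        bn_elem, names
    )


@dataclass(frozen=True)
class _SearchSpace:
    structures: tuple
    hierarchy: tuple


@dataclass(frozen=True)
class JointLattice:
    """The merged RA-BN neutral lattice.

    ``entries`` maps each Rho graph to a dict with keys ``ra_only``,
    ``bn_only`` (tuples of general GraphClass) and ``equivalent`` (tuple of
    (RA general, BN general) pairs); ``specific_*`` fields carry the
    labeled-level partition.
    """

    system: VariableSystem
    rho_graphs: tuple
    entries: dict = field(compare=False)
    ra_general: tuple = ()
    bn_general: tuple = ()
    specific_ra_only: tuple = ()
    specific_bn_only: tuple = ()
    specific_equivalent: tuple = ()

    @property
    def general_counts(self) -> dict:
        ra = sum(len(e["ra_only"]) for e in self.entries.values())
        bn = sum(len(e["bn_only"]) for e in self.entries.values())
        eq = sum(len(e["equivalent"]) for e in self.entries.values())
        return {"ra_only": ra, "bn_only": bn, "equivalent": eq, "total": ra + bn + eq}

    def search_space(self):
        """Both families as one searchable lattice.

        Nodes are all RA structures plus the BN classes without an RA
        equivalent, so every distinct model appears once (an equivalent
        pair is represented by its RA side).  Hierarchy edges are each
        family's own deletion hierarchy; BN edges touching a paired class
        are rerouted to its RA partner, which keeps the V-structure
        classes reachable from a common start.
        """
        from .bn import class_lattice
        from .ra import ra_lattice

        ra = ra_lattice(self.system)
        bn = class_lattice(self.system)
        to_ra = {b: r.representative for r, b in self.specific_equivalent}
        nodes = tuple(ra.structures) + tuple(
            c for c in bn.structures if c not in to_ra
        )
        bn_edges = []
        for p, c in bn.hierarchy:
            p, c = to_ra.get(p, p), to_ra.get(c, c)
            if (p, c) not in bn_edges:
                bn_edges.append((p, c))
        hierarchy = tuple(ra.hierarchy) + tuple(
            e for e in bn_edges if e not in set(ra.hierarchy)
        )
        return _SearchSpace(nodes, hierarchy)

    @property
    def specific_counts(self) -> dict:
        ra, bn = len(self.specific_ra_only), len(self.specific_bn_only)
        eq = len(self.specific_equivalent)
        return {"ra_only": ra, "bn_only": bn, "equivalent": eq, "total": ra + bn + eq}


def build_joint(system: VariableSystem) -> JointLattice:
    """Merge the RA and BN neutral lattices over the Rho scaffold.

    Specific (labeled) level: a loopless RA structure pairs with the BN
    class having the identical labeled elementary independence set (the
    identity labeling, per the definition of specific-graph equivalence);
    every other structure or class stands alone.  General level: RA and BN
    general classes pair under unlabeled independence equivalence.
    """
    ra = ra_lattice(system)
    bn_specific = specific_classes(system)
    bn_gen = general_classes(bn_specific)

    # --- specific level: pair by labeled elementary sets
    bn_by_elem = {}
    for cls in bn_specific:
        bn_by_elem[class_elementary(cls)] = cls
    eq_pairs, ra_only = [], []
    paired_bn = set()
    for cls in ra.classes:
        struct = cls.representative
        elem = ra_elementary_independencies(struct)
        partner = bn_by_elem.get(elem) if not has_loop(struct) else None
        if partner is not None:
            eq_pairs.append((cls, partner))
            paired_bn.add(id(partner))
        else:
            ra_only.append(cls)
    bn_only = tuple(c for c in bn_specific if id(c) not in paired_bn)

    # --- general level
    ra_gen = ra.general
    names = system.names
    bn_sigs = {
        g: independence_signature(class_elementary(g.representative), names)
        for g in bn_gen
    }
    entries = {}
    graphs, _ = rho_lattice(system)
    for rho in graphs:
        entries[rho] = {"ra_only": [], "bn_only": [], "equivalent": []}
    bn_unpaired = dict(bn_sigs)
    for g in ra_gen:
        struct = g.representative.representative
        rho = rho_of(struct)
        if has_loop(struct):
            entries[rho]["ra_only"].append(g)
            continue
        sig = independence_signature(
            ra_elementary_independencies(struct), names
        )
        partner = next(
            (h for h, s in bn_unpaired.items() if s == sig), None
        )
        if partner is not None:
            del bn_unpaired[partner]
            entries[rho]["equivalent"].append((g, partner))
        else:
            entries[rho]["ra_only"].append(g)
    for h in bn_unpaired:
        entries[rho_of(h)]["bn_only"].append(h)
    for rho in entries:
        entries[rho] = {k: tuple(v) for k, v in entries[rho].items()}

    return JointLattice(
        system,
        graphs,
        entries,
        ra_general=ra_gen,
        bn_general=bn_gen,
        specific_ra_only=tuple(ra_only),
        specific_bn_only=bn_only,
        specific_equivalent=tuple(eq_pairs),
    )
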