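"""Core structure types and the RA / extended-BN notation.

An RA model structure over a set of discrete variables is an antichain of
variable subsets ("relations") covering every variable, written with ':'
between relations, e.g. ``AD:BD:CD``.  The extended notation adds optional
subscripts ``_..._`` to a relation that record independence constraints
internal to it, e.g. ``BCD_B:C_:A`` (the triad BCD with B and C marginally
independent inside it) — these arise from Bayesian-network V-structures and
have no plain-RA counterpart.

Grammar (whitespace ignored)::

    structure    := part (':' part)*
    part         := VARS ['_' substructure '_']
    substructure := VARS (':' VARS)*
    VARS         := one or more variable tokens

Variable tokens are single characters when every system name is a single
character; systems with longer names use ',' between tokens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

Relation = frozenset  # frozenset[str]; a non-empty subset of the system's variables

_MAX_BRUTE_FORCE_N = 8


@dataclass(frozen=True)
class VariableSystem:
    """An ordered collection of named discrete variables with cardinalities.

    Parameters
    ----------
    names:
        Distinct, non-empty variable identifiers; their order fixes the axis
        order of every contingency table and distribution over the system.
    cardinalities:
        Number of states per variable (default 2 for every variable).
    """

    names: tuple
    cardinalities: tuple = ()

    def __init__(self, names: Sequence, cardinalities: Sequence | None = None):
        names = tuple(names)
        if len(names) == 0:
            raise ValueError("a variable system needs at least one variable")
        if len(set(names)) != len(names):
            raise ValueError(f"variable names must be unique: {names}")
        if any(not isinstance(n, str) or not n for n in names):
            raise ValueError("variable names must be non-empty strings")
        if cardinalities is None:
            cards = tuple(2 for _ in names)
        else:
            cards = tuple(int(c) for c in cardinalities)
            if len(cards) != len(names):
                raise ValueError("one cardinality per variable required")
        if any(c < 2 for c in cards):
            raise ValueError("every cardinality must be at least 2")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "cardinalities", cards)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def cardinality(self, name: str) -> int:
        return self.cardinalities[self.index(name)]

    @property
    def shape(self) -> tuple:
        return self.cardinalities

    def variables(self) -> frozenset:
        return frozenset(self.names)

    def sort(self, names: Iterable) -> tuple:
        """Sort variable names into system order."""
        order = {v: i for i, v in enumerate(self.names)}
        return tuple(sorted(names, key=order.__getitem__))

    def same_profile(self, other: "VariableSystem") -> bool:
        """True when the two systems have equal size and cardinality multiset."""
        return self.n == other.n and sorted(self.cardinalities) == sorted(
            other.cardinalities
        )


def _side_key(side: frozenset) -> tuple:
    return (len(side), tuple(sorted(side)))


@dataclass(frozen=True)
class IndependenceStatement:
    """A conditional-independence triple (left ⊥ right | given).

    The two sides are interchangeable — (A ⊥ B | C) and (B ⊥ A | C) assert
    the same thing — so they are canonicalized at construction and equality
    is symmetric.  ``given`` may be empty (marginal independence).
    """

    left: frozenset
    right: frozenset
    given: frozenset = field(default_factory=frozenset)

    def __init__(self, left: Iterable, right: Iterable, given: Iterable = ()):
        left, right, given = frozenset(left), frozenset(right), frozenset(given)
        if not left or not right:
            raise ValueError("both sides of an independence statement are non-empty")
        if left & right or left & given or right & given:
            raise ValueError("left, right and given must be pairwise disjoint")
        if _side_key(right) < _side_key(left):
            left, right = right, left
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        object.__setattr__(self, "given", given)

    @property
    def variables(self) -> frozenset:
        return self.left | self.right | self.given

    def is_elementary(self) -> bool:
        return len(self.left) == 1 and len(self.right) == 1

    def elementary(self) -> frozenset:
        """Decompose into the pairwise statements it implies (same conditioning)."""
        return frozenset(
            IndependenceStatement({x}, {y}, self.given)
            for x in self.left
            for y in self.right
        )

    def __str__(self) -> str:
        def fmt(side):
            return ", ".join(sorted(side))

        # paper style: put a singleton side first when the other is larger
        a, b = self.left, self.right
        if len(b) == 1 and len(a) > 1:
            a, b = b, a
        text = f"({fmt(a)} ⟂ {fmt(b)}"
        if self.given:
            text += f" | {fmt(self.given)}"
        return text + ")"


@dataclass(frozen=True)
class RAStructure:
    """An RA model structure: an antichain of relations covering the system."""

    system: VariableSystem
    relations: frozenset  # frozenset[Relation]

    def __init__(self, system: VariableSystem, relations: Iterable):
        rels = frozenset(frozenset(r) for r in relations)
        if not rels or any(not r for r in rels):
            raise ValueError("relations must be non-empty")
        allvars = system.variables()
        for r in rels:
            if not r <= allvars:
                raise ValueError(f"unknown variables in relation {sorted(r)}")
        if maximal_relations(rels) != rels:
            raise ValueError("relations must form an antichain (no containments)")
        if frozenset().union(*rels) != allvars:
            raise ValueError("relations must cover every variable")
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "relations", rels)

    @property
    def sorted_relations(self) -> tuple:
        return _sort_relations(self.system, self.relations)

    def __str__(self) -> str:
        return canonical_text(self)

    def down_closure(self) -> frozenset:
        """All non-empty subsets embedded in some relation."""
        out = set()
        for r in self.relations:
            for k in range(1, len(r) + 1):
                out.update(frozenset(c) for c in itertools.combinations(r, k))
        return frozenset(out)


@dataclass(frozen=True)
class SubscriptedRelation:
    """A relation with an optional internal independence substructure.

    ``subscript`` is an antichain of subsets of ``members`` (the mini
    RA-structure printed between underscores); ``None`` means a plain
    relation.  The independence statements it encodes are derived from
    separation in the substructure's co-occurrence graph.
    """

    members: frozenset
    subscript: frozenset | None = None

    def __init__(self, members: Iterable, subscript=None):
        members = frozenset(members)
        if not members:
            raise ValueError("empty relation")
        if subscript is not None:
            subscript = frozenset(frozenset(s) for s in subscript)
            for s in subscript:
                if not s <= members:
                    raise ValueError(
                        "subscript variables must lie inside the host relation"
                    )
            if maximal_relations(subscript) != subscript:
                raise ValueError("subscript parts must form an antichain")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "subscript", subscript)

    @property
    def is_plain(self) -> bool:
        return self.subscript is None

    @property
    def internal(self) -> frozenset:
        """Elementary independence statements encoded by the subscript."""
        if self.subscript is None:
            return frozenset()
        return _cooccurrence_statements(self.subscript)


@dataclass(frozen=True)
class ExtendedNotation:
    """A parsed structure string: a set of (possibly subscripted) relations."""

    system: VariableSystem
    parts: frozenset  # frozenset[SubscriptedRelation]

    def __init__(self, system: VariableSystem, parts: Iterable):
        parts = frozenset(parts)
        if not parts:
            raise ValueError("a structure needs at least one relation")
        # the plain projection must be a valid RA structure
        plain = RAStructure(system, (p.members for p in parts))
        if len(plain.relations) != len(parts):
            raise ValueError("duplicate relations after canonicalization")
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "parts", parts)

    @property
    def plain(self) -> RAStructure:
        """The RA structure obtained by ignoring all subscripts."""
        return RAStructure(self.system, (p.members for p in self.parts))

    @property
    def is_plain(self) -> bool:
        return all(p.is_plain for p in self.parts)

    @property
    def internal_statements(self) -> frozenset:
        out = frozenset()
        for p in self.parts:
            out |= p.internal
        return out

    def __str__(self) -> str:
        return canonical_text(self)


StructureLike = Union[RAStructure, ExtendedNotation]


def _cooccurrence_statements(relations: frozenset) -> frozenset:
    """Elementary statements from separation in a relation set's co-occurrence graph.

    Variables are adjacent when they share a relation; (X ⊥ Y | S) holds when S
    separates X and Y.  Only the variables of `relations` take part.
    """
    variables = sorted(frozenset().union(*relations))
    adj = {v: set() for v in variables}
    for r in relations:
        for a, b in itertools.combinations(sorted(r), 2):
            adj[a].add(b)
            adj[b].add(a)
    out = set()
    for x, y in itertools.combinations(variables, 2):
        if y in adj[x]:
            continue
        rest = [v for v in variables if v not in (x, y)]
        for k in range(len(rest) + 1):
            for s in itertools.combinations(rest, k):
                if _separated_in_graph(adj, x, y, set(s)):
                    out.add(IndependenceStatement({x}, {y}, s))
    return frozenset(out)


def _separated_in_graph(adj: dict, x: str, y: str, blocked: set) -> bool:
    """Undirected separation: no path from x to y avoiding `blocked`."""
    if x in blocked or y in blocked:
        raise ValueError("endpoints cannot be in the separating set")
    seen = {x}
    stack = [x]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w == y:
                return False
            if w not in blocked and w not in seen:
                seen.add(w)
                stack.append(w)
    return True


# ---------------------------------------------------------------------------
# notation parsing and printing
# ---------------------------------------------------------------------------


def _tokenize_vars(text: str, system: VariableSystem) -> frozenset:
    text = text.strip()
    if not text:
        raise ValueError("empty relation in structure string")
    multi = any(len(n) > 1 for n in system.names)
    if multi or "," in text:
        tokens = [t.strip() for t in text.split(",") if t.strip()]
    else:
        tokens = list(text)
    known = system.variables()
    for t in tokens:
        if t not in known:
            raise ValueError(f"unknown variable token {t!r}")
    return frozenset(tokens)


def parse_structure(text: str, system: VariableSystem) -> ExtendedNotation:
    """Parse a structure string in RA / extended-BN notation.

    Plain-RA inputs yield parts with no subscript; duplicated relations are
    merged silently; embedded (non-maximal) relations are absorbed into the
    relations that contain them.

    Examples
    --------
    ``"AD:BD:CD"`` — three dyadic relations sharing D.
    ``"BCD_B:C_:A"`` — triad BCD carrying internal (B ⊥ C), plus isolated A.
    """
    text = "".join(text.split())
    if text.count("_") % 2:
        raise ValueError("unbalanced '_' in structure string")
    # split on ':' at depth 0 (outside _..._ spans)
    parts_text, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "_":
            depth = 1 - depth
        elif ch == ":" and depth == 0:
            parts_text.append(text[start:i])
            start = i + 1
    parts_text.append(text[start:])

    parts = []
    for pt in parts_text:
        if "_" in pt:
            head, sub, tail = pt.split("_")
            if tail:
                raise ValueError(f"trailing text after subscript in {pt!r}")
            members = _tokenize_vars(head, system)
            sub_rels = frozenset(
                _tokenize_vars(s, system) for s in sub.split(":") if s
            )
            if not sub_rels:
                raise ValueError(f"empty subscript in {pt!r}")
            sub_rels = maximal_relations(sub_rels)
            parts.append(SubscriptedRelation(members, sub_rels))
        else:
            parts.append(SubscriptedRelation(_tokenize_vars(pt, system)))

    # absorb embedded relations; merge duplicates (plain parts absorbed into
    # subscripted ones with the same members)
    keep = {}
    maximal = maximal_relations(frozenset(p.members for p in parts))
    for p in parts:
        if p.members not in maximal:
            if not p.is_plain:
                raise ValueError(
                    f"subscripted relation {''.join(sorted(p.members))} is embedded "
                    "in a larger relation"
                )
            continue
        prev = keep.get(p.members)
        if prev is None or prev.is_plain:
            keep[p.members] = p
        elif not p.is_plain and p != prev:
            raise ValueError("conflicting subscripts on a repeated relation")
    return ExtendedNotation(system, keep.values())


def _sort_relations(system: VariableSystem, relations: Iterable) -> tuple:
    """Canonical relation order: size descending, then alphabetical."""
    return tuple(
        sorted(relations, key=lambda r: (-len(r), "".join(system.sort(r))))
    )


def _vars_text(system: VariableSystem, members: frozenset) -> str:
    names = system.sort(members)
    sep = "," if any(len(n) > 1 for n in system.names) else ""
    return sep.join(names)


def canonical_text(structure: StructureLike) -> str:
    """Render a structure in canonical form.

    Variables appear in system (alphabetical) order inside each relation;
    relations are sorted by descending size then alphabetically; subscript
    parts are sorted the same way.  ``parse_structure`` of the result equals
    the input.
    """
    if isinstance(structure, RAStructure):
        system = structure.system
        parts = [SubscriptedRelation(r) for r in structure.relations]
    else:
        system = structure.system
        parts = list(structure.parts)
    parts.sort(
        key=lambda p: (-len(p.members), "".join(system.sort(p.members)))
    )
    pieces = []
    for p in parts:
        text = _vars_text(system, p.members)
        if not p.is_plain:
            sub = ":".join(
                _vars_text(system, r)
                for r in _sort_relations(system, p.subscript)
            )
            text += f"_{sub}_"
        pieces.append(text)
    return ":".join(pieces)


# ---------------------------------------------------------------------------
# antichain algebra and isomorphism
# ---------------------------------------------------------------------------


def maximal_relations(relations: Iterable) -> frozenset:
    """Keep only relations not strictly contained in another (idempotent)."""
    rels = [frozenset(r) for r in relations]
    if not rels:
        raise ValueError("empty relation set")
    return frozenset(
        r for r in rels if not any(r < s for s in rels)
    )


def _relabel_relations(relations: frozenset, mapping: dict) -> frozenset:
    return frozenset(frozenset(mapping[v] for v in r) for r in relations)


def _iso_signature(obj) -> tuple:
    """(kind, variables, canonical content) for isomorphism testing."""
    from .bn import Dag  # local import to avoid a cycle

    if isinstance(obj, ExtendedNotation):
        vars_ = sorted(obj.system.names)
        content = frozenset(
            (p.members, p.subscript if p.subscript is not None else frozenset())
            for p in obj.parts
        )
        return "ra+", vars_, content
    if isinstance(obj, RAStructure):
        return "ra", sorted(obj.system.names), obj.relations
    if isinstance(obj, Dag):
        return "dag", sorted(obj.system.names), obj.edges
    raise TypeError(f"cannot test isomorphism on {type(obj).__name__}")


def _apply_mapping(kind: str, content, mapping: dict):
    if kind == "ra":
        return _relabel_relations(content, mapping)
    if kind == "ra+":
        return frozenset(
            (
                frozenset(mapping[v] for v in members),
                _relabel_relations(sub, mapping) if sub else frozenset(),
            )
            for members, sub in content
        )
    return frozenset((mapping[a], mapping[b]) for a, b in content)


def unlabeled_isomorphic(a, b, fixed: Iterable = ()) -> bool:
    """True when some variable bijection maps structure/graph `a` onto `b`.

    Both arguments must be of the same kind (RA structures with each other,
    DAGs with each other).  Decided by exhaustive permutation, so only
    practical for small systems (n <= 8).  Variables listed in ``fixed`` must
    map to themselves (used for directed systems, where the DV is
    distinguished).
    """
    kind_a, vars_a, content_a = _iso_signature(a)
    kind_b, vars_b, content_b = _iso_signature(b)
    base = {"ra": "ra", "ra+": "ra", "dag": "dag"}
    if base[kind_a] != base[kind_b]:
        raise TypeError(f"cannot compare {kind_a} with {kind_b}")
    if kind_a != kind_b:  # ra vs ra+: compare plain projections
        if kind_a == "ra+":
            return unlabeled_isomorphic(a.plain, b, fixed)
        return unlabeled_isomorphic(a, b.plain, fixed)
    if len(vars_a) != len(vars_b):
        return False
    if len(vars_a) > _MAX_BRUTE_FORCE_N:
        raise ValueError(
            f"brute-force isomorphism limited to n <= {_MAX_BRUTE_FORCE_N}"
        )
    fixed = set(fixed)
    free_a = [v for v in vars_a if v not in fixed]
    free_b = [v for v in vars_b if v not in fixed]
    if sorted(fixed & set(vars_a)) != sorted(fixed & set(vars_b)):
        return False
    for perm in itertools.permutations(free_b):
        mapping = dict(zip(free_a, perm))
        mapping.update({v: v for v in fixed})
        if _apply_mapping(kind_a, content_a, mapping) == content_b:
            return True
    return False


def relabel_min(content: frozenset, variables: Sequence, kind: str = "ra",
                fixed: Iterable = ()) -> frozenset:
    """Canonical form of relation/edge content under variable permutation.

    Returns the lexicographically least relabeling; two objects are
    unlabeled-isomorphic exactly when their canonical forms agree.
    """
    variables = sorted(variables)
    fixed = set(fixed)
    free = [v for v in variables if v not in fixed]
    best = None
    for perm in itertools.permutations(free):
        mapping = dict(zip(free, perm))
        mapping.update({v: v for v in fixed})
        candidate = _apply_mapping(kind, content, mapping)
        key = sorted(
            (tuple(sorted(x)) if isinstance(x, frozenset) else x)
            if kind != "ra+"
            else (tuple(sorted(x[0])), tuple(sorted(tuple(sorted(r)) for r in x[1])))
            for x in candidate
        )
        if best is None or key < best[0]:
            best = (key, candidate)
    return best[1]


# ---------------------------------------------------------------------------
# independence-statement enumeration
# ---------------------------------------------------------------------------


def enumerate_independence_statements(system: VariableSystem) -> tuple:
    """All independence statements of the standard tabulated forms.

    The listing generalizes the four-variable table of statements used to
    characterize BN independence structures: a single left variable against
    right-hand sets of every size (symmetric pairs listed once), then
    conditional pair statements.  Conditioning sets smaller than the full
    remainder are listed once per unordered pair; pairs conditioned on all
    remaining variables are listed in both orders, matching the published
    table (whose four-variable count is 46 = 6 + 12 + 4 + 12 + 12).
    """
    names = list(system.names)
    n = len(names)
    if n < 2:
        raise ValueError("need at least two variables")
    out = []
    # marginal columns, by right-hand-side size
    for size in range(1, n):
        for x in names:
            rest = [v for v in names if v != x]
            for right in itertools.combinations(rest, size):
                if size == 1 and right[0] < x:
                    continue  # symmetric duplicate
                out.append(IndependenceStatement({x}, right))
    # conditional pair columns, by conditioning-set size
    for s_size in range(1, n - 1):
        ordered = s_size == n - 2  # the full-remainder column is printed both ways
        for x in names:
            rest = [v for v in names if v != x]
            for y in rest:
                if not ordered and y < x:
                    continue
                others = [v for v in rest if v != y]
                for given in itertools.combinations(others, s_size):
                    stmt = IndependenceStatement({x}, {y}, given)
                    out.append(stmt)
    return tuple(out)
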