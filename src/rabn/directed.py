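"""The BN directed (prediction) lattice and its RA equivalents.

When a single dependent variable (DV) is to be predicted, most of the BN
neutral lattice is redundant: many Markov classes induce the very same
conditional p(DV | IVs) once fitted to data.  The directed lattice keeps
one representative — the one with the fewest degrees of freedom — per group
of predictively equivalent classes.  Nodes that are parents inside a
V-structure are not eligible DVs (predicting a V-structure parent is a
genuinely different problem, demonstrated in
``v_structure_parent_dv_demo``).  Every retained BN prediction has an
equivalent structure in the augmented RA directed lattice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

from .core import RAStructure, VariableSystem
from .bn import Dag, GraphClass, FactorTerm, specific_classes, v_structures, bn_notation
from .ra import DirectedSpec, RALattice, augmented_directed_lattice
from .fitting import (
    ContingencyTable,
    degrees_of_freedom,
    fit_bn,
    fit_maxent,
    predict_dv,
)
from .io import random_distribution


@dataclass(frozen=True)
class PredictiveModel:
    """A model read as a predictor of one DV.

    ``predictive_terms`` are the parts of the model that the conditional
    p(DV | IVs) depends on: the DV-containing factor terms for a BN, the
    DV-containing relations for an RA structure.
    """

    base: Union[Dag, RAStructure, GraphClass]
    dv: str

    @property
    def system(self) -> VariableSystem:
        base = self.base
        if isinstance(base, GraphClass):
            base = base.representative
        return base.system

    @property
    def predictive_terms(self) -> frozenset:
        base = self.base
        if isinstance(base, GraphClass):
            base = base.representative
        if isinstance(base, Dag):
            return frozenset(
                FactorTerm(v, base.parents(v))
                for v in base.system.names
                if v == self.dv or self.dv in base.parents(v)
            )
        return frozenset(r for r in base.relations if self.dv in r)

    def fitted_conditional(self, table: ContingencyTable) -> np.ndarray:
        """p(dv | all other variables) from the model's own fitting method."""
        base = self.base
        if isinstance(base, GraphClass):
            base = base.representative
        if isinstance(base, Dag):
            dist = fit_bn(base, table)
        else:
            dist, _ = fit_maxent(base, table)
        return predict_dv(dist, self.dv)


def eligible_dvs(dag: Dag) -> frozenset:
    """All nodes except parents inside a V-structure."""
    banned = set()
    for vs in v_structures(dag):
        banned.update((vs.parent1, vs.parent2))
    return dag.system.variables() - banned


def dv_free_of_v_structure(dag: Dag, dv: str) -> bool:
    """True when no V-structure-encoded independence statement involves ``dv``.

    Stricter than ``eligible_dvs``: it also rejects DVs that appear in a
    subscripted statement only as a conditioning variable (e.g. the DV in
    ``ABCZ_AZ:CZ_``, where (A ⊥ C | Z) is internal to the relation).  Such
    models predict the DV through a subscripted — BN-unique — term, so like
    the V-structure-parent case they have no RA-equivalent prediction and
    stay outside the directed lattice.
    """
    if dv not in eligible_dvs(dag):
        return False
    for stmt in bn_notation(dag).internal_statements:
        if dv in stmt.variables:
            return False
    return True


def _audit_tables(system: VariableSystem, seed: int, k: int):
    out = []
    for i in range(k):
        dist = random_distribution(system, seed + i)
        out.append(
            ContingencyTable(system, dist.probabilities * 1000.0)
        )
    return out


def predictively_equivalent(
    m1: PredictiveModel,
    m2: PredictiveModel,
    tables: Iterable = None,
    seed: int = 7,
    n_tables: int = 3,
    tol: float = 1e-8,
) -> bool:
    """True when the two models fit identical conditionals p(dv | IVs).

    Equal canonical predictive-term sets are sufficient and decided first;
    otherwise the fitted conditionals are compared numerically on seeded
    random tables (strictly positive, so the conditional is defined
    everywhere).  Identical predictions agree exactly as functions of the
    data, so random generic tables separate the inequivalent pairs.
    """
    if m1.dv != m2.dv:
        raise ValueError("predictive comparison needs a common DV")
    if m1.system.names != m2.system.names:
        raise ValueError("predictive comparison needs a common system")
    if type(m1.base) is type(m2.base) and m1.predictive_terms == m2.predictive_terms:
        return True
    if tables is None:
        tables = _audit_tables(m1.system, seed, n_tables)
    for table in tables:
        c1 = m1.fitted_conditional(table)
        c2 = m2.fitted_conditional(table)
        if not np.allclose(c1, c2, atol=tol, rtol=0, equal_nan=True):
            return False
    return True


@dataclass(frozen=True)
class BnDirectedLattice:
    """The reduced BN lattice of unique DV predictions.

    ``retained`` holds the least-df representative classes; ``partitions``
    maps each retained class to the tuple of all predictively equivalent
    classes it stands for; ``general`` groups retained classes by their
    neutral general graph.
    """

    system: VariableSystem
    dv: str
    retained: tuple
    partitions: dict = field(compare=False)
    general: tuple = ()

    @property
    def specific_count(self) -> int:
        return len(self.retained)

    @property
    def general_count(self) -> int:
        return len(self.general)


def bn_directed_lattice(
    system: VariableSystem, dv: str, seed: int = 7, n_tables: int = 3
) -> BnDirectedLattice:
    """Partition eligible BN classes by prediction of ``dv``; keep least df.

    Classes whose V-structures entangle ``dv`` (see
    ``dv_free_of_v_structure``) are excluded.  Partitioning
    is by the fitted conditional p(dv | IVs) on seeded random tables (exact
    agreement of predictively equivalent models, generic separation
    otherwise); the member with minimal degrees of freedom represents each
    partition, ties broken by canonical edge order.
    """
    classes = specific_classes(system)
    eligible = [
        c for c in classes if dv_free_of_v_structure(c.representative, dv)
    ]
    tables = _audit_tables(system, seed, n_tables)
    signatures = []
    for cls in eligible:
        conds = [
            predict_dv(fit_bn(cls.representative, t), dv) for t in tables
        ]
        signatures.append(np.concatenate([c.ravel() for c in conds]))
    # union-find over numerically identical signatures
    parent = list(range(len(eligible)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(eligible)), 2):
        if np.allclose(signatures[i], signatures[j], atol=1e-9, rtol=0):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    groups = {}
    for i in range(len(eligible)):
        groups.setdefault(find(i), []).append(eligible[i])
    retained, partitions = [], {}
    for members in groups.values():
        members.sort(
            key=lambda c: (
                degrees_of_freedom(c.representative),
                tuple(sorted(c.representative.edges)),
            )
        )
        retained.append(members[0])
        partitions[members[0]] = tuple(members)
    retained.sort(key=lambda c: tuple(sorted(c.representative.edges)))

    from .bn import general_classes

    general = general_classes(retained)
    return BnDirectedLattice(system, dv, tuple(retained), partitions, general)


def ra_equivalent_of(
    bn_model: Union[PredictiveModel, GraphClass],
    lattice: RALattice = None,
    dv: str = None,
    seed: int = 7,
    n_tables: int = 3,
) -> RAStructure:
    """The augmented-directed-lattice RA structure predicting the DV identically.

    The match is decided numerically (fitted p(dv | IVs) within 1e-8 on
    seeded random tables, each model fitted by its own method: closed-form
    BN factorization vs IPF maximum entropy); among multiple matches the
    least-df structure is returned.  No match raises ValueError — every
    retained BN prediction has one in the augmented lattice.
    """
    if isinstance(bn_model, GraphClass):
        if dv is None:
            raise ValueError("dv required when passing a GraphClass")
        bn_model = PredictiveModel(bn_model, dv)
    system = bn_model.system
    if lattice is None:
        spec = DirectedSpec(system.variables() - {bn_model.dv}, bn_model.dv)
        lattice = augmented_directed_lattice(system, spec)
    tables = _audit_tables(system, seed, n_tables)
    targets = [bn_model.fitted_conditional(t) for t in tables]
    matches = []
    for struct in lattice.structures:
        ra = PredictiveModel(struct, bn_model.dv)
        if all(
            np.allclose(ra.fitted_conditional(t), want, atol=1e-8, rtol=0)
            for t, want in zip(tables, targets)
        ):
            matches.append(struct)
    if not matches:
        raise ValueError(
            f"no RA equivalent in the augmented lattice for {bn_model.base}"
        )
    # ties (e.g. ABC:Z vs A:B:C:Z, both predicting the DV margin) resolve to
    # the conventional (IV-relation-bearing, hierarchically nested) structure
    ivs = system.variables() - {bn_model.dv}
    matches.sort(
        key=lambda s: (
            0 if (ivs in s.relations or s.relations == frozenset({system.variables()}))
            else 1,
            degrees_of_freedom(s),
            str(s),
        )
    )
    return matches[0]


def v_structure_parent_dv_demo(seed: int = 0) -> dict:
    """Demonstrate that a V-structure-parent DV predicts differently.

    For the three-variable structures with edges A→Z←B (Z the collider
    child, notation ABZ_A:B_) versus A→B←Z (Z a V-structure parent,
    notation ABZ_A:Z_), the two models fitted to the same joint p(ABZ)
    yield different conditionals p(Z|AB) vs q(Z|AB) — which is why
    V-structure-parent DVs are excluded from the directed lattice.  Returns
    both conditionals and their maximum absolute difference, computed on a
    synthetic random table (the published illustration's numeric table is
    not reproduced here).
    """
    system = VariableSystem(("A", "B", "Z"))
    dist = random_distribution(system, seed)
    table = ContingencyTable(system, dist.probabilities * 1000.0)
    child = Dag(system, [("A", "Z"), ("B", "Z")])
    parent = Dag(system, [("A", "B"), ("Z", "B")])
    p = predict_dv(fit_bn(child, table), "Z")
    q = predict_dv(fit_bn(parent, table), "Z")
    return {
        "p_z_given_ab": p,
        "q_z_given_ab": q,
        "max_abs_difference": float(np.nanmax(np.abs(p - q))),
    }
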