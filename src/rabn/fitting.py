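"""Fitting structures to contingency data and searching lattices.

BN models fit in closed form (product of empirical node-given-parents
conditionals).  RA models fit by iterative proportional fitting (IPF) to
the maximum-entropy distribution matching every relation's margin; for
loopless structures the IPF fixed point equals a closed-form product over
a running-intersection ordering of the relations, which serves as an
internal cross-check.  Information quantities are in bits (log base 2), as
is customary in the RA literature; likelihood-ratio statistics convert via
ln 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
from scipy import stats

from .core import ExtendedNotation, RAStructure, VariableSystem
from .bn import Dag, GraphClass

LN2 = math.log(2.0)


@dataclass(frozen=True, eq=False)
class ContingencyTable:
    """Dense non-negative counts over the full state space of a system."""

    system: VariableSystem
    counts: np.ndarray = field(compare=False)

    def __init__(self, system: VariableSystem, counts):
        counts = np.asarray(counts, dtype=float)
        if counts.shape != system.shape:
            raise ValueError(
                f"counts shape {counts.shape} does not match system {system.shape}"
            )
        if counts.min() < 0:
            raise ValueError("negative counts")
        if counts.sum() <= 0:
            raise ValueError("empty table")
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def distribution(self) -> "JointDistribution":
        return JointDistribution(self.system, self.counts / self.counts.sum())


@dataclass(frozen=True, eq=False)
class JointDistribution:
    """A dense probability table over the full state space."""

    system: VariableSystem
    probabilities: np.ndarray = field(compare=False)

    def __init__(self, system: VariableSystem, probabilities):
        p = np.asarray(probabilities, dtype=float)
        if p.shape != system.shape:
            raise ValueError("probability shape does not match system")
        if p.min() < -1e-12:
            raise ValueError("negative probabilities")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "probabilities", np.clip(p, 0.0, None))


def _axes(system: VariableSystem, variables: Iterable) -> tuple:
    return tuple(system.index(v) for v in variables)


def margin(array: np.ndarray, system: VariableSystem, variables: Iterable,
           keepdims: bool = False) -> np.ndarray:
    """Marginalize onto ``variables`` (summing out everything else)."""
    keep = set(_axes(system, variables))
    axes = tuple(i for i in range(array.ndim) if i not in keep)
    return array.sum(axis=axes, keepdims=keepdims)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_bn(dag: Dag, table: ContingencyTable) -> JointDistribution:
    """Closed-form BN fit: the product of empirical p(node | parents).

    Parent configurations with zero observed mass get a uniform conditional
    (the factor is then irrelevant to the joint, but stays a proper
    distribution).
    """
    if dag.system.names != table.system.names:
        raise ValueError("DAG and table must share a variable system")
    system = table.system
    p = table.counts / table.counts.sum()
    out = np.ones_like(p)
    for v in system.names:
        fam = set(dag.parents(v)) | {v}
        m_fam = margin(p, system, fam, keepdims=True)
        m_pa = m_fam.sum(axis=system.index(v), keepdims=True)
        card = system.cardinality(v)
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(m_pa > 0, m_fam / np.where(m_pa > 0, m_pa, 1.0), 1.0 / card)
        out = out * cond
    return JointDistribution(system, out / out.sum())


def _relation_list(structure: RAStructure) -> list:
    return sorted(structure.relations, key=lambda r: (-len(r), tuple(sorted(r))))


def fit_maxent(
    structure: Union[RAStructure, ExtendedNotation],
    table: ContingencyTable,
    tol: float = 1e-9,
    max_sweeps: int = 10_000,
) -> tuple:
    """Maximum-entropy fit matching every relation margin, by IPF.

    Uniform initialization, cyclic margin sweeps; convergence when the
    largest absolute deviation of any fitted margin from its target falls
    below ``tol``.  Returns (distribution, sweeps used).  Loopless
    structures converge in very few sweeps; structures with loops may take
    many.  Raises RuntimeError with the residual when the cap is exceeded.
    """
    if isinstance(structure, ExtendedNotation):
        if not structure.is_plain:
            raise ValueError("subscripted (BN-only) notation cannot be fitted as RA")
        structure = structure.plain
    if structure.system.names != table.system.names:
        raise ValueError("structure and table must share a variable system")
    system = table.system
    rels = _relation_list(structure)
    targets = [
        margin(table.counts / table.counts.sum(), system, r, keepdims=True)
        for r in rels
    ]
    q = np.full(system.shape, 1.0 / np.prod(system.shape))
    sweeps = 0
    residual = np.inf
    while sweeps < max_sweeps:
        sweeps += 1
        for r, m in zip(rels, targets):
            qm = margin(q, system, r, keepdims=True)
            ratio = np.divide(m, qm, out=np.zeros_like(m), where=qm > 0)
            q = q * ratio
        residual = max(
            float(np.abs(margin(q, system, r, keepdims=True) - m).max())
            for r, m in zip(rels, targets)
        )
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"IPF did not converge in {max_sweeps} sweeps (residual {residual:.3e})"
        )
    return JointDistribution(system, q / q.sum()), sweeps


def _running_intersection_order(relations: list):
    """An ordering R1..Rk with Ri ∩ (R1∪..∪R(i-1)) inside a single earlier Rj."""
    for perm in itertools.permutations(relations):
        ok = True
        for i in range(1, len(perm)):
            sep = perm[i] & frozenset().union(*perm[:i])
            if sep and not any(sep <= perm[j] for j in range(i)):
                ok = False
                break
        if ok:
            return list(perm)
    return None


def closed_form_fit(structure: RAStructure, table: ContingencyTable) -> JointDistribution:
    """Direct factorized max-entropy solution for a loopless structure.

    Uses a running-intersection ordering of the relations:
    p = Π p(R_i | R_i ∩ previous) built from empirical margins.  Exists
    exactly when the structure is loopless; it equals the IPF fixed point.
    """
    from .ra import has_loop

    if has_loop(structure):
        raise ValueError("closed form requires a loopless structure")
    system = table.system
    rels = _running_intersection_order(_relation_list(structure))
    if rels is None:  # cannot happen for loopless structures
        raise ValueError("no running-intersection ordering found")
    p = table.counts / table.counts.sum()
    out = np.ones(system.shape)
    seen = frozenset()
    for r in rels:
        sep = r & seen
        num = margin(p, system, r, keepdims=True)
        if sep:
            den = margin(p, system, sep, keepdims=True)
        else:
            den = np.ones_like(num) * 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            out = out * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        seen |= r
    total = out.sum()
    return JointDistribution(system, out / total)


def fit_model(model, table: ContingencyTable, **kwargs):
    """Dispatch: BN models fit in closed form, RA models by IPF.

    Returns (distribution, ipf_sweeps) with sweeps = 0 for BN fits.
    """
    if isinstance(model, GraphClass):
        model = model.representative
        if isinstance(model, GraphClass):
            model = model.representative
    if isinstance(model, Dag):
        return fit_bn(model, table), 0
    if isinstance(model, (RAStructure, ExtendedNotation)):
        return fit_maxent(model, table, **kwargs)
    raise TypeError(f"cannot fit a {type(model).__name__}")


# ---------------------------------------------------------------------------
# information quantities
# ---------------------------------------------------------------------------


def entropy(dist: JointDistribution) -> float:
    """Shannon entropy in bits."""
    p = dist.probabilities
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def transmission(p: JointDistribution, q: JointDistribution) -> float:
    """Directed divergence T(p:q) = Σ p log2(p/q) in bits.

    Non-negative; zero exactly when p = q on p's support; infinite when q
    vanishes somewhere p does not.
    """
    if p.system.names != q.system.names:
        raise ValueError("distributions must share a variable system")
    pp, qq = p.probabilities.ravel(), q.probabilities.ravel()
    mask = pp > 0
    if np.any(qq[mask] == 0):
        return float("inf")
    return float((pp[mask] * np.log2(pp[mask] / qq[mask])).sum())


def loglik(table: ContingencyTable, dist: JointDistribution) -> float:
    """Log-likelihood (natural log) of the counts under the distribution."""
    c, q = table.counts.ravel(), dist.probabilities.ravel()
    mask = c > 0
    if np.any(q[mask] == 0):
        return float("-inf")
    return float((c[mask] * np.log(q[mask])).sum())


def degrees_of_freedom(model) -> int:
    """Independent parameters of a structure.

    RA: one u-term per non-empty subset in the down-closure of the
    relations, each worth Π(card − 1).  BN: per node, (card − 1) × Π parent
    cards.  The two formulas agree on every equivalent RA/BN pair, which is
    what makes least-df selection comparable across methods.
    """
    if isinstance(model, GraphClass):
        model = model.representative
        if isinstance(model, GraphClass):
            model = model.representative
    if isinstance(model, ExtendedNotation):
        model = model.plain
    if isinstance(model, RAStructure):
        system = model.system
        return int(
            sum(
                int(np.prod([system.cardinality(v) - 1 for v in subset]))
                for subset in model.down_closure()
            )
        )
    if isinstance(model, Dag):
        system = model.system
        total = 0
        for v in system.names:
            total += (system.cardinality(v) - 1) * int(
                np.prod([system.cardinality(p) for p in model.parents(v)])
            )
        return int(total)
    raise TypeError(f"no degrees of freedom for {type(model).__name__}")


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its information-theoretic report card.

    ``transmission_bits`` is T(data : fitted); the likelihood-ratio
    statistic against the saturated model satisfies
    lr_stat = 2 n ln2 · transmission_bits.
    """

    model: object
    fitted: JointDistribution = field(compare=False)
    df: int = 0
    entropy_bits: float = 0.0
    transmission_bits: float = 0.0
    lr_stat: float = 0.0
    ddf: int = 0
    p_value: float = 1.0
    aic: float = 0.0
    bic: float = 0.0
    ipf_iterations: int = 0


def evaluate(model, table: ContingencyTable, **kwargs) -> FitResult:
    """Fit a model and compute its statistics against the data (saturated model)."""
    dist, sweeps = fit_model(model, table, **kwargs)
    data = table.distribution()
    t = transmission(data, dist)
    n = table.n
    df = degrees_of_freedom(model)
    df_sat = int(np.prod(table.system.shape)) - 1
    ddf = df_sat - df
    lr = 2.0 * n * LN2 * t
    p_value = float(stats.chi2.sf(lr, ddf)) if ddf > 0 else 1.0
    ll = loglik(table, dist)
    return FitResult(
        model=model,
        fitted=dist,
        df=df,
        entropy_bits=entropy(dist),
        transmission_bits=t,
        lr_stat=lr,
        ddf=ddf,
        p_value=p_value,
        aic=-2.0 * ll + 2.0 * df,
        bic=-2.0 * ll + df * math.log(n),
        ipf_iterations=sweeps,
    )


def information_criteria(fit: FitResult, table: ContingencyTable) -> tuple:
    """(AIC, BIC) of a fitted model on the table."""
    ll = loglik(table, fit.fitted)
    n = table.n
    return (-2.0 * ll + 2.0 * fit.df, -2.0 * ll + fit.df * math.log(n))


def lr_test(model_fit: FitResult, reference_fit: FitResult,
            table: ContingencyTable) -> tuple:
    """Likelihood-ratio (chi-square) test between two nested fitted models.

    The reference is the more complex model.  Returns (statistic, ddf,
    p-value); nestedness is the caller's responsibility.
    """
    ddf = abs(model_fit.df - reference_fit.df)
    if ddf == 0:
        raise ValueError("models have equal degrees of freedom (ddf = 0)")
    stat = 2.0 * (loglik(table, reference_fit.fitted) - loglik(table, model_fit.fitted))
    stat = max(stat, 0.0)
    return stat, ddf, float(stats.chi2.sf(stat, ddf))


def predict_dv(dist: JointDistribution, dv: str) -> np.ndarray:
    """Conditional table p(dv | all other variables).

    Returned with the system's full axis layout; IV configurations with zero
    mass are NaN (undefined).
    """
    axis = dist.system.index(dv)
    denom = dist.probabilities.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(denom > 0, dist.probabilities / np.where(denom > 0, denom, 1.0), np.nan)
    return cond


# ---------------------------------------------------------------------------
# lattice search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchResult:
    """A logged lattice search: the accepted chain and the selected model."""

    path: tuple  # FitResult per accepted step, in order
    selected: object
    selected_fit: FitResult
    criterion: str
    direction: str


def _lattice_nodes_edges(lattice):
    nodes = getattr(lattice, "structures", None) or getattr(lattice, "nodes", None)
    edges = getattr(lattice, "hierarchy", None)
    if nodes is None or edges is None:
        raise TypeError("lattice must expose structures/nodes and hierarchy")
    return tuple(nodes), tuple(edges)


def search(
    lattice,
    table: ContingencyTable,
    direction: str = "up",
    criterion: str = "bic",
    width: int = 1,
    alpha: float = 0.05,
    start=None,
) -> SearchResult:
    """Greedy/beam traversal of a lattice along its hierarchy edges.

    ``direction="up"`` starts at the bottom (most independent) structure and
    moves toward the top, ``"down"`` the reverse.  With ``criterion`` "bic"
    or "aic" the search moves while the best neighbor improves the score and
    selects the best model visited; with "chi2" an upward move must improve
    fit significantly (p < alpha in the likelihood-ratio test against the
    current model) and a downward move must lose fit non-significantly
    (p > alpha), the last accepted model being selected.  ``width`` is the
    beam size (1 = greedy).  The full accepted path is logged.
    """
    if criterion not in ("bic", "aic", "chi2"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    nodes, edges = _lattice_nodes_edges(lattice)
    if not nodes:
        raise ValueError("empty lattice")
    up_map = {}  # child -> parents
    down_map = {}  # parent -> children
    for p, c in edges:
        up_map.setdefault(c, []).append(p)
        down_map.setdefault(p, []).append(c)
    neighbors = up_map if direction == "up" else down_map
    if start is None:
        if direction == "up":
            bottoms = [v for v in nodes if not down_map.get(v)]
            start = bottoms[-1] if bottoms else nodes[-1]
        else:
            tops = [v for v in nodes if not up_map.get(v)]
            start = tops[0] if tops else nodes[0]

    cache = {}

    def fit_of(node):
        if node not in cache:
            cache[node] = evaluate(node, table)
        return cache[node]

    def score(fr: FitResult) -> float:
        return fr.bic if criterion == "bic" else fr.aic

    path = [fit_of(start)]
    frontier = [start]
    visited = {start}
    best_node, best_fit = start, fit_of(start)

    while True:
        candidates = []
        for node in frontier:
            for nb in neighbors.get(node, []):
                if nb not in visited:
                    candidates.append((node, nb))
        if not candidates:
            break
        if criterion in ("bic", "aic"):
            scored = sorted(
                ((score(fit_of(nb)), nb) for _, nb in candidates),
                key=lambda t: (t[0], str(t[1])),
            )
            best_cand_score, best_cand = scored[0]
            if best_cand_score >= score(best_fit):
                break
            frontier = [nb for _, nb in scored[:width]]
            visited.update(frontier)
            best_node, best_fit = best_cand, fit_of(best_cand)
            path.append(best_fit)
        else:  # chi2 significance walk
            accepted = []
            for cur, nb in candidates:
                cur_fit, nb_fit = fit_of(cur), fit_of(nb)
                if cur_fit.df == nb_fit.df:
                    continue
                if direction == "up":
                    stat, ddf, p = lr_test(cur_fit, nb_fit, table)
                    if p < alpha:
                        accepted.append((p, nb))
                else:
                    stat, ddf, p = lr_test(nb_fit, cur_fit, table)
                    if p > alpha:
                        accepted.append((-p, nb))
            if not accepted:
                break
            accepted.sort(key=lambda t: (t[0], str(t[1])))
            frontier = [nb for _, nb in accepted[:width]]
            visited.update(frontier)
            best_node, best_fit = frontier[0], fit_of(frontier[0])
            path.append(best_fit)

    return SearchResult(tuple(path), best_node, best_fit, criterion, direction)
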