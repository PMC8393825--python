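"""Readers/writers and the synthetic-data generator.

Two CSV dialects are supported.  *Case* format has one row per observation
and one column per variable.  *Contingency* format has one row per observed
state with a final ``count`` column.  Values may be arbitrary strings;
states are indexed by sorted order unless the values are already
non-negative integers, which are used directly as state indices.

The synthetic generator draws a generating distribution from a stated
model: for an RA structure, the maximum-entropy (IPF) projection of a
symmetric-Dirichlet random joint onto the structure (the margins of a
single joint are always mutually consistent); for a DAG, random Dirichlet
conditional tables multiplied along the factorization.  The Dirichlet
concentration alpha controls effect strength (small alpha = strong,
spiky dependencies; default 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .core import ExtendedNotation, RAStructure, VariableSystem
from .bn import Dag
from .fitting import ContingencyTable, JointDistribution, fit_maxent


@dataclass(frozen=True)
class CaseTable:
    """One row per observation; states as integer indices."""

    header: tuple
    rows: tuple

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class SyntheticSpec:
    """A stated world to sample from.

    ``model`` is the generating structure (RA or DAG); ``alpha`` the
    Dirichlet concentration behind the generating distribution (smaller =
    stronger effects); ``n`` the sample size; ``seed`` drives all
    randomness.
    """

    model: Union[RAStructure, ExtendedNotation, Dag]
    n: int = 1000
    seed: int = 0
    alpha: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("sample size must be at least 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class SyntheticSample:
    """A drawn sample plus the exact generating distribution."""

    spec: SyntheticSpec
    distribution: JointDistribution
    contingency: ContingencyTable

    @property
    def cases(self) -> CaseTable:
        """Expanded case rows (grouped by state, deterministic order)."""
        system = self.contingency.system
        rows = []
        counts = np.round(self.contingency.counts).astype(int)
        for idx in np.ndindex(*system.shape):
            rows.extend([idx] * counts[idx])
        return CaseTable(system.names, tuple(rows))


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def _state_maps(frame: pd.DataFrame, columns, system: VariableSystem | None):
    maps, cards = [], []
    for i, col in enumerate(columns):
        values = frame[col]
        uniques = sorted(values.astype(str).unique())
        if all(v.isdigit() for v in uniques):
            card = max(int(v) for v in uniques) + 1
            mapping = {v: int(v) for v in uniques}
        else:
            card = len(uniques)
            mapping = {v: k for k, v in enumerate(uniques)}
        card = max(card, 2)
        if system is not None:
            preset = system.cardinalities[i]
            if card > preset:
                raise ValueError(
                    f"column {col!r} has states beyond cardinality {preset}"
                )
            card = preset
        maps.append(mapping)
        cards.append(card)
    return maps, cards


def read_table(
    path,
    format: str = "case",
    system: VariableSystem | None = None,
) -> ContingencyTable:
    """Read a CSV in case or contingency format into a dense table."""
    if format not in ("case", "contingency"):
        raise ValueError("format must be 'case' or 'contingency'")
    frame = pd.read_csv(path, dtype=str)
    if format == "contingency":
        if "count" not in frame.columns:
            raise ValueError("contingency format requires a 'count' column")
        counts = frame["count"].astype(float)
        if (counts < 0).any():
            raise ValueError("negative count")
        frame = frame.drop(columns=["count"])
    else:
        counts = pd.Series(np.ones(len(frame)))
    columns = list(frame.columns)
    if frame.isna().any().any():
        raise ValueError("malformed row (missing value)")
    if system is not None and tuple(columns) != system.names:
        raise ValueError(
            f"CSV columns {columns} do not match system {list(system.names)}"
        )
    maps, cards = _state_maps(frame, columns, system)
    if system is None:
        system = VariableSystem(tuple(columns), tuple(cards))
    array = np.zeros(system.shape)
    for row, c in zip(frame.itertuples(index=False), counts):
        idx = tuple(maps[i][str(v)] for i, v in enumerate(row))
        array[idx] += float(c)
    return ContingencyTable(system, array)


def write_table(table: ContingencyTable, path, format: str = "contingency"):
    """Write a table to CSV; round-trips counts exactly."""
    system = table.system
    records = []
    for idx in np.ndindex(*system.shape):
        c = table.counts[idx]
        if c == 0:
            continue
        rec = dict(zip(system.names, idx))
        if format == "contingency":
            rec["count"] = c
            records.append(rec)
        else:
            records.extend([dict(zip(system.names, idx))] * int(round(c)))
    pd.DataFrame.from_records(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


def random_distribution(system: VariableSystem, seed: int,
                        alpha: float = 1.0) -> JointDistribution:
    """A strictly positive random joint from a symmetric Dirichlet."""
    rng = np.random.default_rng(seed)
    size = int(np.prod(system.shape))
    p = rng.dirichlet(np.full(size, alpha))
    p = np.clip(p, 1e-300, None)
    return JointDistribution(system, (p / p.sum()).reshape(system.shape))


def generating_distribution(spec: SyntheticSpec) -> JointDistribution:
    """The exact distribution a SyntheticSpec samples from."""
    model = spec.model
    if isinstance(model, ExtendedNotation):
        model = model.plain
    if isinstance(model, RAStructure):
        base = random_distribution(model.system, spec.seed, spec.alpha)
        table = ContingencyTable(model.system, base.probabilities)
        dist, _ = fit_maxent(model, table)
        return dist
    if isinstance(model, Dag):
        system = model.system
        rng = np.random.default_rng(spec.seed)
        out = np.ones(system.shape)
        for v in system.names:
            parents = sorted(model.parents(v), key=system.index)
            card = system.cardinality(v)
            n_cfg = int(np.prod([system.cardinality(p) for p in parents])) or 1
            cond = rng.dirichlet(np.full(card, spec.alpha), size=n_cfg)
            cond = cond.reshape(
                [system.cardinality(p) for p in parents] + [card]
            )
            # move axes into ascending system-axis order
            var_axes = [system.index(p) for p in parents] + [system.index(v)]
            axes = sorted(var_axes)
            cond = np.transpose(cond, np.argsort(var_axes))
            full_shape = [1] * system.n
            for a, s in zip(axes, cond.shape):
                full_shape[a] = s
            out = out * cond.reshape(full_shape)
        return JointDistribution(system, out / out.sum())
    raise TypeError(f"cannot generate from {type(model).__name__}")


def sample_from_model(spec: SyntheticSpec) -> SyntheticSample:
    """Seeded multinomial sample from the spec's generating distribution."""
    dist = generating_distribution(spec)
    system = dist.system
    rng = np.random.default_rng(spec.seed + 1)
    counts = rng.multinomial(spec.n, dist.probabilities.ravel())
    return SyntheticSample(
        spec,
        dist,
        ContingencyTable(system, counts.reshape(system.shape).astype(float)),
    )
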