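"""Network assembly, serialization, ORF collapsing and reference scoring.

Per-target models are flattened to a directed edge list in which the
coefficient sign encodes activation (positive) versus repression
(negative).  Edges can be exported as TSV or GraphML, collapsed from
probe level to ORF level, and scored against curated reference edge
sets with a 1/0/NA consistency rule: an edge is 1 (true) when the pair
is present in a reference, 0 (false) when both endpoints are covered by
the reference but the pair is absent, and NA when the reference does
not cover the endpoints.  Accuracy is the number of edges flagged 1 in
any reference divided by the number flagged 0 or 1 in any reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .selection import TargetModel

log = logging.getLogger(__name__)

NETWORK_COLUMNS = ["regulator", "target", "coefficient", "delay", "adj.R.squared"]


@dataclass(frozen=True)
class Edge:
    """A directed, signed, delay-annotated regulator -> target edge."""

    regulator_id: str
    target_id: str
    coefficient: float
    delay_minutes: float
    adj_r2: float

    def __post_init__(self) -> None:
        if self.regulator_id == self.target_id:
            raise ValueError(f"self-loop edge on {self.regulator_id!r}")
        if self.delay_minutes < 0:
            raise ValueError("delay_minutes must be >= 0")


def build_network(models: Sequence[TargetModel]) -> list[Edge]:
    """Flatten per-target models into a directed edge list."""
    seen_targets: set[str] = set()
    edges: list[Edge] = []
    for m in models:
        if m.target_id in seen_targets:
            raise ValueError(f"duplicate target in model list: {m.target_id!r}")
        seen_targets.add(m.target_id)
        for term in m.regulators:
            edges.append(
                Edge(term.regulator_id, m.target_id, term.coefficient,
                     term.delay_minutes, m.adj_r2)
            )
    return edges


def edges_to_frame(edges: Sequence[Edge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.regulator_id, e.target_id, e.coefficient, e.delay_minutes, e.adj_r2)
            for e in edges
        ],
        columns=NETWORK_COLUMNS,
    )


def export_network(edges: Sequence[Edge], path: str | Path, format: str = "tsv") -> None:
    """Write the edge list as TSV or GraphML.

    The TSV columns are regulator, target, coefficient, delay (minutes)
    and adjusted R^2; reading the file back reproduces the edge list.
    GraphML nodes are the gene ids and edges carry the three numeric
    attributes.
    """
    if format == "tsv":
        edges_to_frame(edges).to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "graphml":
        g = nx.DiGraph()
        for e in edges:
            g.add_edge(
                e.regulator_id, e.target_id,
                coefficient=float(e.coefficient),
                delay=float(e.delay_minutes),
                adj_r2=float(e.adj_r2),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network_tsv(path: str | Path) -> list[Edge]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"network file {path} lacks columns {missing}")
    return [
        Edge(str(reg), str(tgt), float(coef), float(delay), float(r2))
        for reg, tgt, coef, delay, r2 in df[NETWORK_COLUMNS].itertuples(
            index=False, name=None
        )
    ]


def _orf_from_probe_id(gid: str) -> str:
    # probe ids of the form NAME_ORF_probe(_at) carry the ORF as the
    # second underscore-separated token
    parts = gid.split("_")
    if len(parts) >= 3:
        return parts[1]
    return gid


def collapse_to_orf(
    edges: Sequence[Edge], mapping: Mapping[str, str] | None = None
) -> list[Edge]:
    """Collapse probe-level edges to ORF level.

    With an explicit probe->ORF ``mapping``, unmapped ids pass through
    unchanged with a warning.  Without a mapping, composite probe ids of
    the form ``NAME_ORF_probe`` are parsed for their ORF.  Duplicate
    ORF-level edges keep the occurrence with the highest adjusted R^2;
    edges that collapse onto a self-loop are dropped.
    """

    def to_orf(gid: str) -> str:
        if mapping is not None:
            if gid in mapping:
                return mapping[gid]
            warnings.warn(f"id {gid!r} missing from probe->ORF mapping; kept as is")
            return gid
        return _orf_from_probe_id(gid)

    best: dict[tuple[str, str], Edge] = {}
    order: list[tuple[str, str]] = []
    n_loops = 0
    for e in edges:
        reg, tgt = to_orf(e.regulator_id), to_orf(e.target_id)
        if reg == tgt:
            n_loops += 1
            continue
        mapped = Edge(reg, tgt, e.coefficient, e.delay_minutes, e.adj_r2)
        key = (reg, tgt)
        if key not in best:
            best[key] = mapped
            order.append(key)
        elif mapped.adj_r2 > best[key].adj_r2:
            best[key] = mapped
    if n_loops:
        log.info("dropped %d edges that collapsed onto ORF self-loops", n_loops)
    return [best[k] for k in order]


@dataclass(frozen=True)
class ReferenceSet:
    """A known-interaction reference: directed or undirected pairs.

    ``universe`` is the set of gene ids the reference covers; a pair
    with both endpoints in the universe but absent from ``pairs`` is
    scored 0, a pair with an endpoint outside the universe is NA.
    Undirected pairs are stored canonically (lexicographic order).
    """

    name: str
    pairs: frozenset[tuple[str, str]]
    directed: bool
    universe: frozenset[str]

    @classmethod
    def from_pairs(
        cls,
        name: str,
        pairs: Iterable[tuple[str, str]],
        directed: bool = True,
        universe: Iterable[str] | None = None,
    ) -> "ReferenceSet":
        canon = frozenset(
            (a, b) if directed else (min(a, b), max(a, b)) for a, b in pairs
        )
        if universe is None:
            universe = {g for p in canon for g in p}
        return cls(name, canon, directed, frozenset(universe))

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        name: str | None = None,
        directed: bool = True,
        universe: Iterable[str] | None = None,
    ) -> "ReferenceSet":
        """Read a two- or three-column TSV (regulator, target[, score])."""
        pairs: list[tuple[str, str]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"reference line with <2 columns in {path}: {line!r}")
            pairs.append((fields[0], fields[1]))
        return cls.from_pairs(name or Path(path).stem, pairs, directed, universe)

    def score(self, regulator_id: str, target_id: str) -> int | None:
        """1 = pair present, 0 = covered but absent, None = not covered."""
        if self.directed:
            key = (regulator_id, target_id)
        else:
            key = (min(regulator_id, target_id), max(regulator_id, target_id))
        if key in self.pairs:
            return 1
        if regulator_id in self.universe and target_id in self.universe:
            return 0
        return None


@dataclass
class EvaluationTable:
    """Per-edge 1/0/NA consistency flags against each reference."""

    edges: list[Edge]
    ref_names: list[str]
    flags: list[dict[str, int | None]]  # aligned with edges

    @property
    def accuracy(self) -> float | None:
        """True edges over scorable edges; None when nothing is scorable.

        An edge is true if any reference flags it 1, scorable if any
        reference flags it 0 or 1; edges NA everywhere are excluded.
        """
        scorable = sum(
            1 for f in self.flags if any(v is not None for v in f.values())
        )
        if scorable == 0:
            return None
        true = sum(1 for f in self.flags if any(v == 1 for v in f.values()))
        return true / scorable

    def to_frame(self) -> pd.DataFrame:
        df = edges_to_frame(self.edges)
        for name in self.ref_names:
            df[name] = [
                f[name] if f[name] is not None else pd.NA for f in self.flags
            ]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(
            path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
        )


def evaluate_against_references(
    edges: Sequence[Edge], refs: Sequence[ReferenceSet]
) -> EvaluationTable:
    """Score every edge against every reference with the 1/0/NA rule."""
    if not refs:
        raise ValueError("need at least one reference set")
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise ValueError(f"reference names must be unique, got {names}")
    flags = [
        {r.name: r.score(e.regulator_id, e.target_id) for r in refs} for e in edges
    ]
    return EvaluationTable(list(edges), names, flags)
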