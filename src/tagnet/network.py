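"""Post-inference graph analytics on fitted regulatory models.

Pseudo variables (per-group average z-score profiles), strong-edge
extraction (|standardized weight| strictly above a threshold), sign
summaries, and exhaustive simple-cycle enumeration.  Cycles are reported
canonically, rotated to start at the lexicographically smallest node and
sorted deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import AnalysisDataset
from .factor import GroupAssignment

EDGE_COLUMNS = ["source", "target", "standardized_weight", "p_value"]


@dataclass
class RegulatoryGraph:
    """Directed graph of standardized regulatory effects."""

    graph: nx.DiGraph
    provenance: str = "fitted"   # fitted | fixture

    @classmethod
    def from_edges(cls, df: pd.DataFrame, provenance: str = "fitted"
                   ) -> "RegulatoryGraph":
        g = nx.DiGraph()
        seen = set()
        for _, row in df.iterrows():
            key = (row["source"], row["target"])
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            w = float(row["standardized_weight"])
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on edge {key}")
            p = row.get("p_value", np.nan)
            try:
                p = float(p)
            except (TypeError, ValueError):
                p = np.nan
            g.add_edge(*key, weight=w, p_value=p)
        return cls(graph=g, provenance=provenance)

    @classmethod
    def from_fitted(cls, fitted) -> "RegulatoryGraph":
        df = fitted.standardized_weights().rename(
            columns={"standardized_weight": "standardized_weight"})
        return cls.from_edges(df[["source", "target", "standardized_weight",
                                  "p_value"]])

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, t, d["weight"], d.get("p_value", np.nan))
                for s, t, d in self.graph.edges(data=True)]
        df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return df.sort_values(["source", "target"]).reset_index(drop=True)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class PseudoVariableSet:
    """Per-group average expression profiles (the group-level variables)."""

    profiles: pd.DataFrame                  # index Group<k>, columns samples
    members: dict[str, list[str]] = field(default_factory=dict)


def pseudo_variables(dataset: AnalysisDataset, groups: GroupAssignment
                     ) -> PseudoVariableSet:
    """Average the member profiles of every group into one pseudo variable.

    Oil productivity contributes to its group's average like any other
    member but remains available as its own row for within-group
    modeling.
    """
    data = dataset.data
    missing = [v for v in groups.factor.index if v not in data.index]
    if missing:
        raise KeyError(f"group member {missing[0]!r} absent from dataset")
    profiles, members = [], {}
    for k in sorted(groups.factor.unique()):
        roster = groups.members(int(k))
        if not roster:
            raise ValueError(f"group {k} is empty")
        name = f"Group{int(k)}"
        profiles.append(data.loc[roster].mean(axis=0).rename(name))
        members[name] = roster
    return PseudoVariableSet(profiles=pd.DataFrame(profiles), members=members)


def strong_edges(g: RegulatoryGraph, threshold: float = 0.3
                 ) -> RegulatoryGraph:
    """Subgraph of edges with |standardized weight| strictly > threshold.

    Strict inequality: an edge printed at exactly the threshold is
    excluded.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = nx.DiGraph()
    for s, t, d in g.graph.edges(data=True):
        if abs(d["weight"]) > threshold:
            out.add_edge(s, t, **d)
    return RegulatoryGraph(graph=out, provenance=g.provenance)


def sign_counts(g: RegulatoryGraph) -> tuple[int, int, int]:
    """(total, positive, negative) edge counts; exact zeros are flagged
    separately via :func:`zero_weight_edges`."""
    weights = [d["weight"] for *_, d in g.graph.edges(data=True)]
    pos = sum(1 for w in weights if w > 0)
    neg = sum(1 for w in weights if w < 0)
    return len(weights), pos, neg


def zero_weight_edges(g: RegulatoryGraph) -> list[tuple[str, str]]:
    return [(s, t) for s, t, d in g.graph.edges(data=True)
            if d["weight"] == 0]


def _canonical_cycle(cycle: list[str]) -> tuple[str, ...]:
    i = min(range(len(cycle)), key=lambda j: cycle[j])
    return tuple(cycle[i:] + cycle[:i])


def enumerate_cycles(g: RegulatoryGraph) -> list[tuple[str, ...]]:
    """All simple directed cycles, canonicalized and deterministically
    ordered (by length, then lexicographically)."""
    cycles = [_canonical_cycle(c) for c in nx.simple_cycles(g.graph)]
    return sorted(set(cycles), key=lambda c: (len(c), c))


def _to_dot(g: RegulatoryGraph) -> str:
    lines = ["digraph regulatory {"]
    for node in sorted(g.graph.nodes):
        lines.append(f'    "{node}";')
    for s, t, d in sorted(g.graph.edges(data=True)):
        lines.append(f'    "{s}" -> "{t}" [weight={d["weight"]!r}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(g: RegulatoryGraph, path: str | Path, fmt: str = "tsv"
                 ) -> Path:
    """Write the graph as a TSV edge list, GraphML or DOT file.

    The TSV uses the canonical column order (source, target,
    standardized_weight, p_value) sorted by source then target, so a
    TSV -> graph -> TSV round trip is byte identical.
    """
    path = Path(path)
    if fmt == "tsv":
        g.to_frame().to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(g.graph, path)
    elif fmt == "dot":
        path.write_text(_to_dot(g))
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_graph_tsv(path: str | Path, provenance: str = "fixture"
                   ) -> RegulatoryGraph:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"edge table lacks column {missing[0]!r}")
    return RegulatoryGraph.from_edges(df, provenance=provenance)
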