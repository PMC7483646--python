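"""Shortest communication paths between mutation sites and functional classes.

Path length is counted as the number of intermediate nodes between source
and target (a direct contact has length 0); the search is minimum-hop.
Ties between equally short paths are broken by higher mean edge persistence,
then lexicographically on the node labels, so results are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .ensemble_io import FunctionalAnnotation, ResidueID
from .psn import PSNGraph

logger = logging.getLogger(__name__)


class PathTableError(ValueError):
    """Mismatched rosters between path tables."""


@dataclass
class PathResult:
    source: ResidueID
    target: ResidueID
    nodes: tuple[ResidueID, ...]
    average_weight: float
    target_class: str | None = None

    def __post_init__(self) -> None:
        if self.nodes[0] != self.source or self.nodes[-1] != self.target:
            raise ValueError("node sequence does not join source and target")

    @property
    def length(self) -> int:
        """Number of intermediate nodes (direct contact -> 0)."""
        return len(self.nodes) - 2

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def label(self) -> str:
        return "-".join(n.label for n in self.nodes)

    def sort_key(self):
        # fewer hops first, then higher persistence, then lexicographic labels
        return (self.n_edges, -self.average_weight, tuple(n.label for n in self.nodes))


def _mean_weight(graph: PSNGraph, nodes) -> float:
    ws = [graph[a][b]["persistence"] for a, b in zip(nodes, nodes[1:])]
    return float(sum(ws) / len(ws))


def shortest_paths(
    graph: PSNGraph, source: ResidueID, targets: set[ResidueID] | list[ResidueID]
) -> list[PathResult]:
    """Minimum-hop path from ``source`` to each reachable target.

    Unreachable targets (and a source absent from the graph) yield no entry;
    absence is a result, not an error.  Among equally short paths the one
    with the highest average persistence (then lexicographically smallest
    label sequence) is returned.
    """
    if source not in graph:
        logger.info("source %s is not a node of the network; no paths", source)
        return []
    results = []
    for target in sorted(set(targets)):
        if target == source or target not in graph:
            continue
        try:
            candidates = [
                PathResult(source, target, tuple(p), _mean_weight(graph, p))
                for p in nx.all_shortest_paths(graph, source, target)
            ]
        except nx.NetworkXNoPath:
            continue
        results.append(min(candidates, key=PathResult.sort_key))
    return results


def class_paths(
    graph: PSNGraph,
    sources: list[ResidueID],
    annotation: FunctionalAnnotation,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Best path from each source to each functional residue class.

    For every (source, class) cell the single best path over all member
    targets is kept (shortest; ties as in :func:`shortest_paths`).  Classes
    are matched to graph nodes by sequence position.  Cells with no path are
    recorded explicitly with a null path.
    """
    classes = classes or annotation.class_names()
    unknown = [c for c in classes if c not in annotation.sets]
    if unknown:
        raise KeyError(f"unknown annotation class(es): {unknown}")
    by_position = {}
    for node in graph.nodes:
        by_position.setdefault(node.position, []).append(node)
    rows = []
    for source in sources:
        for cls in classes:
            targets = [n for p in annotation[cls] for n in by_position.get(p, []) if n != source]
            found = shortest_paths(graph, source, targets)
            best = min(found, key=PathResult.sort_key) if found else None
            if best is not None:
                best.target_class = cls
            rows.append(
                {
                    "source": source,
                    "class": cls,
                    "path": best,
                    "length": best.length if best else None,
                    "average_weight": best.average_weight if best else None,
                }
            )
    return pd.DataFrame(rows, columns=["source", "class", "path", "length", "average_weight"])


def conserved_paths(
    table_a: pd.DataFrame, table_b: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """(source, class) cells with a path present in both ensembles' tables.

    ``strict=True`` additionally requires identical node sequences; the
    default only requires existence of a path in both (the looser reading).
    """
    key = ["source", "class"]
    ka = set(map(tuple, table_a[key].itertuples(index=False)))
    kb = set(map(tuple, table_b[key].itertuples(index=False)))
    if ka != kb:
        raise PathTableError("path tables were built over different sources/classes")
    merged = table_a.merge(table_b, on=key, suffixes=("_a", "_b"))
    keep = merged[merged.path_a.notna() & merged.path_b.notna()].copy()
    if strict:
        keep = keep[
            [pa.label == pb.label for pa, pb in zip(keep.path_a, keep.path_b)]
        ]
    return keep.reset_index(drop=True)


def communication_summary(conserved: pd.DataFrame, min_classes: int = 2) -> pd.DataFrame:
    """Distinct communicating classes per source; >= ``min_classes`` flags a
    long-range communicator."""
    counts = (
        conserved.groupby("source")["class"].nunique().rename("n_classes").reset_index()
    )
    counts["long_range"] = counts.n_classes >= min_classes
    return counts.sort_values("source", key=lambda s: s.map(lambda r: (r.chain, r.position))).reset_index(
        drop=True
    )


def path_table(table: pd.DataFrame, conserved_keys: set | None = None) -> pd.DataFrame:
    """Flat TSV-ready view: source, class, target, path, length, average_weight."""
    rows = []
    for _, rec in table.iterrows():
        p: PathResult | None = rec["path"]
        key = (rec["source"], rec["class"])
        rows.append(
            {
                "source": rec["source"].label,
                "class": rec["class"],
                "target": p.target.label if p else "",
                "path": p.label if p else "",
                "length": p.length if p else "",
                "average_weight": round(p.average_weight, 3) if p else "",
                "conserved": (key in conserved_keys) if conserved_keys is not None else "",
            }
        )
    return pd.DataFrame(rows)
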