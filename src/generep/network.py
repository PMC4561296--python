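"""Assembly and export of tripartite enrichment networks.

Significant over-representation results become edges of a typed graph linking
pathway / transcription-factor nodes to the condition sets (e.g. glucose-
regulated gene lists) they are enriched in, and condition sets to phenotype
sets.  Exports (SIF, JSON, TSV) are deterministically ordered so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .differential import DifferentialResult
from .enrichment import RepresentativityMatrix, format_percent
from .geneset import GeneSet, Universe

__all__ = [
    "EnrichmentNetwork",
    "build_network",
    "nested_overlap_summary",
    "export_network",
    "load_network_json",
]

NETWORK_SCHEMA_VERSION = 1

# catalog roles -> node types in the tripartite graph
_ROLE_TO_NODE_TYPE = {
    "pathway_targets": "pathway",
    "tf_targets": "tf",
    "phenotype": "phenotype",
    "condition": "condition",
    "annotation": "pathway",
}
NODE_TYPES = ("pathway", "tf", "condition", "phenotype")


@dataclass
class EnrichmentNetwork:
    """Typed enrichment graph with statistic-bearing edges.

    Nodes carry ``node_type`` in {pathway, tf, condition, phenotype} and a
    gene-count ``size``; edges carry the overlap statistics of the matrix cell
    they came from plus a tail ``direction`` (over/under).  At most one edge
    exists per (source, target, direction).
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    universe: str = ""
    confidence: float = 0.95
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, node_id: str, node_type: str, size: int) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        if node_id in self.graph:
            existing = self.graph.nodes[node_id]["node_type"]
            if existing != node_type:
                raise ValueError(
                    f"conflicting node types for {node_id!r}: {existing} vs {node_type}"
                )
            return
        self.graph.add_node(node_id, node_type=node_type, size=size)

    def add_edge(self, source: str, target: str, direction: str, **attrs) -> None:
        if source == target:
            raise ValueError(f"self-edge on {source!r} not allowed")
        for node in (source, target):
            if node not in self.graph:
                raise ValueError(f"edge endpoint {node!r} is not a node")
        if self.graph.has_edge(source, target, key=direction):
            raise ValueError(f"duplicate edge ({source}, {target}, {direction})")
        self.graph.add_edge(source, target, key=direction, direction=direction, **attrs)

    def significant_edges(self) -> list[tuple[str, str, dict]]:
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d.get("significant")
        ]

    def edge_records(self) -> list[dict]:
        """Edges as plain dicts in lexicographic (source, target, direction) order."""
        records = []
        for u, v, key, d in self.graph.edges(keys=True, data=True):
            rec = {"source": u, "target": v, **d}
            records.append(rec)
        records.sort(key=lambda r: (r["source"], r["target"], r["direction"]))
        return records

    def node_records(self) -> list[dict]:
        records = [
            {"id": n, "node_type": d["node_type"], "size": d["size"]}
            for n, d in self.graph.nodes(data=True)
        ]
        records.sort(key=lambda r: r["id"])
        return records

    def __eq__(self, other) -> bool:  # ordering-insensitive structural equality
        if not isinstance(other, EnrichmentNetwork):
            return NotImplemented
        return (
            self.node_records() == other.node_records()
            and self.edge_records() == other.edge_records()
            and self.universe == other.universe
            and self.confidence == other.confidence
        )


def build_network(
    matrices: list[RepresentativityMatrix],
    diffs: list[DifferentialResult] | None = None,
    confidence: float = 0.95,
    keep_nonsignificant: bool = False,
) -> EnrichmentNetwork:
    """Turn representativity matrices into one typed enrichment network.

    Nodes are created for every row and column entity of every matrix; a cell
    becomes an edge if significant (or unconditionally with
    ``keep_nonsignificant``, in which case edge count equals cell count).
    Differential classifications, when supplied, are attached to the matching
    source node's edges as ``differential`` attributes.
    """
    universes = {m.universe for m in matrices}
    if len(universes) > 1 and not all(m.metadata.get("tag") for m in matrices):
        raise ValueError(
            f"matrices span universes {sorted(universes)}; tag them explicitly via metadata['tag']"
        )
    net = EnrichmentNetwork(
        universe=universes.pop() if len(universes) == 1 else "mixed",
        confidence=confidence,
        metadata={"keep_nonsignificant": keep_nonsignificant, "n_matrices": len(matrices)},
    )
    diff_by_name = {d.catalog_set_name: d for d in diffs} if diffs else {}
    for m in matrices:
        row_type = _ROLE_TO_NODE_TYPE.get(m.row_role, "pathway")
        col_type = _ROLE_TO_NODE_TYPE.get(m.col_role, "condition")
        for r in m.rows:
            for c in m.cols:
                cell = m.cells[(r, c)]
                net.add_node(r, row_type, cell.K)
                net.add_node(c, col_type, cell.n_query)
                if not (cell.significant or keep_nonsignificant):
                    continue
                attrs = dict(
                    k=cell.k,
                    representativity=cell.representativity,
                    z=cell.z,
                    p=cell.p_z,
                    significant=cell.significant,
                )
                diff = diff_by_name.get(r)
                if diff is not None:
                    attrs["differential"] = diff.classification
                net.add_edge(r, c, direction=cell.tail if cell.tail != "two_sided" else "over", **attrs)
    return net


def nested_overlap_summary(sets: list[GeneSet], universe: Universe) -> pd.DataFrame:
    """Summarise a nested-overlap figure: background, query, then crossings.

    The first set is the background, the second the focal query (reported as
    a percentage of the background); every later set is a crossing of the
    query and is reported as |set ∩ query| and its percentage of the query.
    Percentages use the shared rendering contract (integer at >= 10%, one
    decimal below), so a chain like (detected 20839, regulated 129,
    liver-overlap 22, disease-overlap 7) prints 0.6%, 17%, 5.4%.
    """
    if not sets:
        raise ValueError("need at least one set")
    rows = []
    restricted = [gs.genes & universe.genes for gs in sets]
    for i, gs in enumerate(sets):
        if i == 0:
            rows.append({"set": gs.name, "size": len(restricted[0]), "k": None, "percent_of_parent": None})
            continue
        parent = restricted[min(i - 1, 1)]
        if len(parent) == 0:
            raise ZeroDivisionError(f"empty parent set before {gs.name!r}")
        k = len(restricted[i] & parent)
        rows.append(
            {
                "set": gs.name,
                "size": len(restricted[i]),
                "k": k,
                "percent_of_parent": format_percent(k / len(parent)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_network(net: EnrichmentNetwork, path: str | Path, format: str = "json") -> None:
    """Write the network as SIF, JSON or long-format TSV (deterministic order)."""
    path = Path(path)
    if format == "sif":
        _export_sif(net, path)
    elif format == "json":
        _export_json(net, path)
    elif format == "tsv":
        _export_tsv(net, path)
    else:
        raise ValueError(f"unknown export format {format!r}; use sif, json or tsv")


def _relation(net: EnrichmentNetwork, source: str, target: str, direction: str) -> str:
    st = net.graph.nodes[source]["node_type"]
    tt = net.graph.nodes[target]["node_type"]
    return f"{st}-{tt}-{direction}"


def _export_sif(net: EnrichmentNetwork, path: Path) -> None:
    lines = ["# generep enrichment network (source\trelation\ttarget)"]
    for rec in net.edge_records():
        lines.append(
            "\t".join([rec["source"], _relation(net, rec["source"], rec["target"], rec["direction"]), rec["target"]])
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _export_json(net: EnrichmentNetwork, path: Path) -> None:
    payload = {
        "schema_version": NETWORK_SCHEMA_VERSION,
        "universe": net.universe,
        "confidence": net.confidence,
        "metadata": net.metadata,
        "nodes": net.node_records(),
        "edges": net.edge_records(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _export_tsv(net: EnrichmentNetwork, path: Path) -> None:
    records = net.edge_records()
    cols = ["source", "target", "direction", "k", "representativity", "z", "p", "significant", "differential"]
    df = pd.DataFrame(records).reindex(columns=cols) if records else pd.DataFrame(columns=cols)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_network_json(path: str | Path) -> EnrichmentNetwork:
    """Read back a JSON export; round-trips to an equal network."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema_version") != NETWORK_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {payload.get('schema_version')}")
    net = EnrichmentNetwork(
        universe=payload["universe"],
        confidence=payload["confidence"],
        metadata=payload.get("metadata", {}),
    )
    for node in payload["nodes"]:
        net.add_node(node["id"], node["node_type"], node["size"])
    for edge in payload["edges"]:
        attrs = {k: v for k, v in edge.items() if k not in ("source", "target", "direction")}
        net.add_edge(edge["source"], edge["target"], edge["direction"], **attrs)
    return net
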