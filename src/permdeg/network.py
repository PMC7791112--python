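"""Assembly and export of the fold-change-annotated DEG interaction network.

Nodes are DEGs (optionally restricted to members of chosen enriched gene
sets) carrying their log2 fold change, direction and set memberships; edges
come from user-supplied interaction lists (protein-protein, activation,
inhibition) and are filtered to pairs whose endpoints are both retained.
Undirected protein-protein edges are canonicalized by lexicographic endpoint
order so duplicates collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrichment import GeneSetCollection
from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

EDGE_TYPES = ("ppi", "activation", "inhibition")
EVIDENCE = ("direct", "indirect")
#: SIF relation tokens, one per edge type
_SIF_TOKEN = {"ppi": "pp", "activation": "activates", "inhibition": "inhibits"}
_SIF_INVERSE = {v: k for k, v in _SIF_TOKEN.items()}


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    edge_type: str = "ppi"
    evidence: str = "direct"

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ParameterError(f"unknown edge type {self.edge_type!r}")
        if self.evidence not in EVIDENCE:
            raise ParameterError(f"unknown evidence class {self.evidence!r}")


@dataclass
class InteractionNetwork:
    """Nodes with attributes plus typed edges; invariants enforced on
    construction by :func:`build_network`."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for gene, attrs in self.nodes.items():
            G.add_node(gene, **attrs)
        for e in self.edges:
            G.add_edge(e.source, e.target, edge_type=e.edge_type, evidence=e.evidence)
        return G

    def sorted_edges(self) -> list[Edge]:
        return sorted(
            self.edges, key=lambda e: (e.source, e.target, e.edge_type)
        )


def _coerce_edge(item) -> Edge:
    if isinstance(item, Edge):
        return item
    parts = tuple(item)
    if not 2 <= len(parts) <= 4:
        raise ParameterError(f"edge {item!r} needs 2-4 fields")
    return Edge(*parts)


def build_network(
    deg_table: pd.DataFrame,
    selected_sets: GeneSetCollection | Mapping[str, Iterable[str]] | None = None,
    interactions: Sequence = (),
) -> InteractionNetwork:
    """Nodes = DEGs (intersected with the union of ``selected_sets`` when
    given); edges filtered to retained endpoints; unknown-ID edges and
    self-loops dropped with a logged count."""
    degs = deg_table[deg_table["is_deg"]]
    membership: dict[str, list[str]] = {g: [] for g in degs.index}
    if selected_sets:
        chosen: set[str] = set()
        for set_id in selected_sets:
            for gene in selected_sets[set_id]:
                if gene in membership:
                    membership[gene].append(set_id)
                    chosen.add(gene)
        kept = [g for g in degs.index if g in chosen]
    else:
        kept = list(degs.index)
    nodes = {
        g: {
            "log2_fc": float(degs.at[g, "log2_fc"]),
            "direction": str(degs.at[g, "direction"]),
            "member_sets": sorted(membership[g]),
        }
        for g in kept
    }
    edges: list[Edge] = []
    seen: set[tuple] = set()
    n_dropped = 0
    for item in interactions:
        e = _coerce_edge(item)
        if e.source not in nodes or e.target not in nodes or e.source == e.target:
            n_dropped += 1
            continue
        if e.edge_type == "ppi" and e.source > e.target:
            e = Edge(e.target, e.source, e.edge_type, e.evidence)
        key = (e.source, e.target, e.edge_type)
        if key in seen:
            continue
        seen.add(key)
        edges.append(e)
    if n_dropped:
        logger.info("dropped %d edges with unretained endpoints", n_dropped)
    return InteractionNetwork(nodes=nodes, edges=edges)


# --- export / import -------------------------------------------------------

FORMATS = ("sif", "tsv", "xml")


def _node_frame(network: InteractionNetwork) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g,
            "log2_fc": a["log2_fc"],
            "direction": a["direction"],
            "member_sets": ";".join(a["member_sets"]),
        }
        for g, a in sorted(network.nodes.items())
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "log2_fc", "direction", "member_sets"]
    )


def export_network(
    network: InteractionNetwork, prefix: str | Path, format: str = "sif"
) -> list[Path]:
    """Write the network under ``prefix`` in one of ``sif`` (plus a node
    attribute table), ``tsv`` (edge + node tables) or ``xml`` (GraphML).
    Round-trip safe via :func:`import_network`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "sif":
        sif = prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            for e in network.sorted_edges():
                fh.write(f"{e.source}\t{_SIF_TOKEN[e.edge_type]}\t{e.target}\n")
        nodes = prefix.with_suffix(".nodes.tsv")
        _node_frame(network).to_csv(nodes, sep="\t", index=False)
        # evidence is not expressible in SIF; keep it in a sidecar table
        ev = prefix.with_suffix(".edges.tsv")
        _edge_frame(network).to_csv(ev, sep="\t", index=False)
        return [sif, nodes, ev]
    if format == "tsv":
        edges = prefix.with_suffix(".edges.tsv")
        _edge_frame(network).to_csv(edges, sep="\t", index=False)
        nodes = prefix.with_suffix(".nodes.tsv")
        _node_frame(network).to_csv(nodes, sep="\t", index=False)
        return [edges, nodes]
    if format == "xml":
        path = prefix.with_suffix(".graphml")
        G = network.to_networkx()
        # GraphML has no list type; serialize memberships as ';'-joined text
        for _, attrs in G.nodes(data=True):
            attrs["member_sets"] = ";".join(attrs["member_sets"])
        nx.write_graphml(G, path)
        return [path]
    raise ParameterError(f"unknown network format {format!r}; use one of {FORMATS}")


def _edge_frame(network: InteractionNetwork) -> pd.DataFrame:
    rows = [
        {
            "source": e.source,
            "target": e.target,
            "edge_type": e.edge_type,
            "evidence": e.evidence,
        }
        for e in network.sorted_edges()
    ]
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "evidence"])


def _network_from_frames(
    nodes: pd.DataFrame, edges: pd.DataFrame
) -> InteractionNetwork:
    node_dict = {
        str(r.gene_id): {
            "log2_fc": float(r.log2_fc),
            "direction": str(r.direction),
            "member_sets": [s for s in str(r.member_sets).split(";") if s]
            if not pd.isna(r.member_sets)
            else [],
        }
        for r in nodes.itertuples()
    }
    edge_list = [
        Edge(str(r.source), str(r.target), str(r.edge_type), str(r.evidence))
        for r in edges.itertuples()
    ]
    for e in edge_list:
        if e.source not in node_dict or e.target not in node_dict:
            raise FormatError(f"edge endpoint {e.source}-{e.target} missing a node")
    return InteractionNetwork(nodes=node_dict, edges=edge_list)


def import_network(prefix: str | Path, format: str = "sif") -> InteractionNetwork:
    """Inverse of :func:`export_network`."""
    prefix = Path(prefix)
    if format in ("sif", "tsv"):
        nodes = pd.read_csv(
            prefix.with_suffix(".nodes.tsv"), sep="\t", keep_default_na=False
        )
        edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t")
        return _network_from_frames(nodes, edges)
    if format == "xml":
        G = nx.read_graphml(prefix.with_suffix(".graphml"))
        node_dict = {
            str(n): {
                "log2_fc": float(a["log2_fc"]),
                "direction": str(a["direction"]),
                "member_sets": [s for s in str(a.get("member_sets", "")).split(";") if s],
            }
            for n, a in G.nodes(data=True)
        }
        edge_list = []
        for u, v, a in G.edges(data=True):
            e = Edge(str(u), str(v), str(a["edge_type"]), str(a["evidence"]))
            if e.edge_type == "ppi" and e.source > e.target:
                e = Edge(e.target, e.source, e.edge_type, e.evidence)
            edge_list.append(e)
        return InteractionNetwork(nodes=node_dict, edges=edge_list)
    raise ParameterError(f"unknown network format {format!r}; use one of {FORMATS}")
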