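"""Serialization of built maps to standard network formats.

Supported formats: GraphML (one self-contained file, lossless for all
node/edge attributes), CX (the JSON network-interchange aspect list), and
SIF (topology plus two tab-separated attribute tables).  A JSON "style
hints" side-car describes the visual mapping conventions — node fill by
phenotype, node size by gene-set size, edge width by similarity — without
prescribing renderer-specific syntax.

All output is deterministic: nodes and edges are emitted in sorted order,
so byte-identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx

from .model import EMEdge, EMNetwork, EMNode

__all__ = [
    "network_to_graph",
    "export_network",
    "import_graphml",
    "style_hints",
    "node_table",
    "edge_table",
    "INTERACTION_TYPE",
]

# single fixed relationship tag so downstream tools can filter edges
INTERACTION_TYPE = "geneset_overlap"

FORMATS = ("graphml", "cx", "sif")


def _node_attrs(node: EMNode) -> dict:
    attrs: dict = {
        "label": node.display_label,
        "size": node.size,
        "genes": ",".join(sorted(node.genes)),
        "datasets": ",".join(str(i) for i in sorted(node.dataset_membership)),
    }
    for i in sorted(node.dataset_membership):
        attrs[f"pvalue_ds{i}"] = node.pvalue[i]
        if node.qvalue[i] is not None:
            attrs[f"qvalue_ds{i}"] = node.qvalue[i]
        if node.nes[i] is not None:
            attrs[f"nes_ds{i}"] = node.nes[i]
        attrs[f"phenotype_ds{i}"] = node.phenotype[i]
        attrs[f"neutral_ds{i}"] = bool(node.neutral[i])
        attrs[f"size_ds{i}"] = node.per_dataset_size[i]
    return attrs


def _edge_attrs(edge: EMEdge) -> dict:
    return {
        "interaction": edge.interaction_type,
        "similarity": edge.similarity,
        "overlap_size": edge.overlap_size,
        "overlap_genes": ",".join(sorted(edge.overlap_genes)),
    }


def network_to_graph(network: EMNetwork) -> nx.Graph:
    """The map as a networkx graph with flattened attribute dicts."""
    g = nx.Graph()
    g.graph["metric"] = network.parameters.metric
    g.graph["pvalue_cutoff"] = network.parameters.pvalue_cutoff
    g.graph["qvalue_cutoff"] = network.parameters.qvalue_cutoff
    g.graph["similarity_cutoff"] = network.parameters.similarity_cutoff
    for name in network.node_names:
        g.add_node(name, **_node_attrs(network.nodes[name]))
    for e in sorted(network.edges, key=lambda e: (e.set_a, e.set_b)):
        g.add_edge(e.set_a, e.set_b, **_edge_attrs(e))
    return g


def export_network(network: EMNetwork, path, fmt: str = "graphml") -> list[str]:
    """Write the map in the requested format; returns the files written.

    ``graphml`` and ``cx`` each produce one file.  ``sif`` produces the
    topology file plus ``<stem>.nodes.tsv`` and ``<stem>.edges.tsv``
    attribute tables (isolated nodes appear as single-column SIF lines).
    """
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown export format {fmt!r}; choose from {FORMATS}")
    path = Path(path)
    if fmt == "graphml":
        _write_graphml(network, path)
        return [str(path)]
    if fmt == "cx":
        path.write_text(json.dumps(_to_cx(network), indent=1, sort_keys=True) + "\n")
        return [str(path)]
    return _write_sif(network, path)


def _write_graphml(network: EMNetwork, path: Path) -> None:
    g = network_to_graph(network)
    # generate_graphml yields text lines in a fixed order, so identical
    # networks always serialize byte-identically
    lines = list(nx.generate_graphml(g, named_key_ids=True))
    path.write_text("\n".join(lines) + "\n")


def import_graphml(path) -> nx.Graph:
    """Read back a GraphML export as a networkx graph."""
    return nx.read_graphml(str(path))


def _to_cx(network: EMNetwork) -> list[dict]:
    node_ids = {name: i for i, name in enumerate(network.node_names)}
    nodes = [{"@id": node_ids[n], "n": n} for n in network.node_names]
    node_attributes = []
    for name in network.node_names:
        for key, value in _node_attrs(network.nodes[name]).items():
            node_attributes.append({"po": node_ids[name], "n": key, "v": value})
    edges = []
    edge_attributes = []
    for i, e in enumerate(sorted(network.edges, key=lambda e: (e.set_a, e.set_b))):
        edges.append(
            {"@id": i, "s": node_ids[e.set_a], "t": node_ids[e.set_b],
             "i": e.interaction_type}
        )
        for key, value in _edge_attrs(e).items():
            edge_attributes.append({"po": i, "n": key, "v": value})
    return [
        {"numberVerification": [{"longNumber": 2**48}]},
        {"metaData": [
            {"name": "nodes", "elementCount": len(nodes)},
            {"name": "edges", "elementCount": len(edges)},
        ]},
        {"nodes": nodes},
        {"edges": edges},
        {"nodeAttributes": node_attributes},
        {"edgeAttributes": edge_attributes},
        {"status": [{"error": "", "success": True}]},
    ]


def node_table(network: EMNetwork):
    """One row per node with all flattened attributes (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for name in network.node_names:
        row = {"name": name}
        row.update(_node_attrs(network.nodes[name]))
        rows.append(row)
    return pd.DataFrame(rows)


def edge_table(network: EMNetwork):
    """One row per edge with all flattened attributes (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for e in sorted(network.edges, key=lambda e: (e.set_a, e.set_b)):
        row = {"source": e.set_a, "target": e.set_b}
        row.update(_edge_attrs(e))
        rows.append(row)
    return pd.DataFrame(rows)


def _write_sif(network: EMNetwork, path: Path) -> list[str]:
    connected = set()
    lines = []
    for e in sorted(network.edges, key=lambda e: (e.set_a, e.set_b)):
        lines.append(f"{e.set_a}\t{e.interaction_type}\t{e.set_b}")
        connected.update((e.set_a, e.set_b))
    for name in network.node_names:
        if name not in connected:
            lines.append(name)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    nodes_path = path.with_suffix(".nodes.tsv")
    edges_path = path.with_suffix(".edges.tsv")
    node_table(network).to_csv(nodes_path, sep="\t", index=False)
    edge_table(network).to_csv(edges_path, sep="\t", index=False)
    return [str(path), str(nodes_path), str(edges_path)]


def style_hints(network: EMNetwork) -> dict:
    """Declarative visual-mapping hints as a JSON-serializable document.

    Node fill encodes phenotype: the first phenotype maps to red, the
    second to blue, with intensity interpolated by NES magnitude when NES
    is present; unsigned (neutral) nodes map to a neutral color.  Node
    size encodes gene-set size, edge width encodes similarity with the
    cutoff at minimum width.  Colors are named, not RGB values.
    """
    nes_values = [
        abs(v)
        for node in network.nodes.values()
        for v in node.nes.values()
        if v is not None
    ]
    sizes = [node.size for node in network.nodes.values()]
    sims = [e.similarity for e in network.edges]
    phen = network.phenotypes.get(1, ("UP", "DOWN"))
    return {
        "node_fill": {
            "attribute": "phenotype/NES",
            "phenotype1": {"label": phen[0], "color": "red"},
            "phenotype2": {"label": phen[1], "color": "blue"},
            "neutral": {"color": "lightgray"},
            "interpolate_by": "abs(NES)" if nes_values else None,
            "nes_max": max(nes_values) if nes_values else None,
        },
        "node_size": {
            "attribute": "size",
            "min": min(sizes) if sizes else 0,
            "max": max(sizes) if sizes else 0,
        },
        "edge_width": {
            "attribute": "similarity",
            "min": network.parameters.similarity_cutoff,
            "max": max(sims) if sims else 1.0,
        },
        "node_label": {"attribute": "label"},
        "interaction_type": INTERACTION_TYPE,
    }
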