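"""The microbes–signal–pathway communication network around AI-2.

Species that carry only the LuxS synthase produce the signal (green edges to
the AI-2 node), species with only receptors sense it (blue edges), and
species with both produce and sense (purple edges).  Receptor pathway classes
(MCP, HK, GCD, SP, STK, ACGC, HP, LsrB) are materialised as their own typed
nodes so per-class reach can be read off the graph; a collapsed mode
reproduces the simpler species–signal topology.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .summary import RolePartition

SIGNAL_NODE = "AI-2"

EDGE_COLORS = {"produce": "green", "sense": "blue", "produce_and_sense": "purple"}

PATHWAY_CLASSES = ("MCP", "HK", "GCD", "SP", "STK", "ACGC", "HP", "LsrB")


def build_network(
    partition: RolePartition,
    receptor_classes: Mapping[str, set[str]] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    collapse_classes: bool = False,
) -> nx.Graph:
    """Build the typed AI-2 communication graph.

    ``receptor_classes`` maps receptor-bearing genome ids to their pathway
    classes (``LsrB`` for the periplasmic receptor); ``taxonomy`` maps genome
    ids to a phylum label.  Synthase-only species get a green produce edge to
    the signal node, receptor-only species blue sense edges, and both-species
    a purple produce-and-sense edge; with classes materialised, receptor
    species additionally link to their pathway-class nodes in blue.
    """
    receptor_classes = dict(receptor_classes or {})
    taxonomy = dict(taxonomy or {})
    receptor_species = partition.receptor_only | partition.both
    stray = sorted(set(receptor_classes) - partition.positives)
    if stray:
        raise ValueError(f"receptor classes given for genomes outside the partition: {stray}")

    g = nx.Graph()
    g.add_node(SIGNAL_NODE, node_type="signal")

    def add_species(genome_id: str) -> None:
        g.add_node(
            genome_id, node_type="species", phylum=taxonomy.get(genome_id, "unknown")
        )

    for genome_id in sorted(partition.synthase_only):
        add_species(genome_id)
        g.add_edge(genome_id, SIGNAL_NODE, edge_type="produce", color="green")
    for genome_id in sorted(partition.receptor_only):
        add_species(genome_id)
        g.add_edge(genome_id, SIGNAL_NODE, edge_type="sense", color="blue")
    for genome_id in sorted(partition.both):
        add_species(genome_id)
        g.add_edge(genome_id, SIGNAL_NODE, edge_type="produce_and_sense", color="purple")

    if not collapse_classes:
        classes_present = sorted(
            {c for gid in receptor_species for c in receptor_classes.get(gid, set())}
        )
        for cls in classes_present:
            if cls not in PATHWAY_CLASSES:
                raise ValueError(f"unknown pathway class {cls!r}")
            g.add_node(cls, node_type="pathway_class")
            g.add_edge(SIGNAL_NODE, cls, edge_type="sense", color="blue")
        for genome_id in sorted(receptor_species):
            for cls in sorted(receptor_classes.get(genome_id, set())):
                g.add_edge(genome_id, cls, edge_type="sense", color="blue")
    return g


def network_stats(g: nx.Graph) -> dict:
    """Node/edge counts by type plus the per-phylum species-role breakdown."""
    node_counts: dict[str, int] = {}
    for _, data in g.nodes(data=True):
        node_counts[data["node_type"]] = node_counts.get(data["node_type"], 0) + 1
    edge_counts: dict[str, int] = {}
    for _, _, data in g.edges(data=True):
        edge_counts[data["edge_type"]] = edge_counts.get(data["edge_type"], 0) + 1

    roles = {"produce_only": 0, "sense_only": 0, "produce_and_sense": 0}
    per_phylum: dict[str, dict[str, int]] = {}
    for node, data in g.nodes(data=True):
        if data["node_type"] != "species":
            continue
        signal_edge = g.get_edge_data(node, SIGNAL_NODE)
        if signal_edge is None:
            continue
        role = {
            "produce": "produce_only",
            "sense": "sense_only",
            "produce_and_sense": "produce_and_sense",
        }[signal_edge["edge_type"]]
        roles[role] += 1
        phylum = data.get("phylum", "unknown")
        per_phylum.setdefault(
            phylum, {"produce_only": 0, "sense_only": 0, "produce_and_sense": 0}
        )[role] += 1

    return {
        "nodes_by_type": node_counts,
        "edges_by_type": edge_counts,
        "species_roles": roles,
        "per_phylum": per_phylum,
    }


def export_graph(g: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write the network as GraphML, SIF, or an edge-list CSV.

    ``fmt`` (graphml / sif / csv) defaults to the file extension.  GraphML
    round-trips exactly through :func:`read_graphml_network`; SIF has one
    line per edge with the edge type as the relation.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{data['edge_type']}\t{v}\n")
    elif fmt == "csv":
        rows = [
            {"source": u, "target": v, "edge_type": d["edge_type"], "color": d["color"]}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown graph export format {fmt!r}")


def read_graphml_network(path: str | Path) -> nx.Graph:
    """Re-import a GraphML export (inverse of :func:`export_graph`)."""
    return nx.read_graphml(path)


def receptor_class_table(component_table: pd.DataFrame, cahr_calls) -> dict[str, set[str]]:
    """Per-genome pathway-class sets for network construction.

    Passing CahR domains contribute their functional class; genomes with an
    LsrB or LuxP periplasmic receptor contribute the ``LsrB`` class.
    """
    classes: dict[str, set[str]] = {}
    for call in cahr_calls:
        if call.passed:
            classes.setdefault(call.genome_id, set()).add(call.functional_class)
    for genome_id, row in component_table.iterrows():
        if bool(row.get("has_lsrB", False)) or bool(row.get("has_luxP", False)):
            classes.setdefault(genome_id, set()).add("LsrB")
    return classes
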