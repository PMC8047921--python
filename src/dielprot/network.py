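"""Method consensus and protein–protein-interaction projection.

The three detectors (Monte-Carlo day/night contrast, JTK, BGLS) each yield
a set of flagged proteins; their overlap is summarized as the seven regions
of a three-set Venn partition.  Modulated and group-exclusive proteins are
then projected onto a binary PPI network built by concatenating edge-list
datasets, and the induced subgraph is summarized (nodes, edges, connected
components, fraction of proteins in the largest linked component, label
composition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "MethodSets",
    "ProjectionSummary",
    "venn_counts",
    "load_ppi",
    "project_and_summarize",
]

logger = logging.getLogger(__name__)


@dataclass
class MethodSets:
    jtk_set: set
    bgls_set: set
    mc_set: set


def venn_counts(set_a, set_b, set_c) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a three-set Venn diagram.

    Keys: "a", "b", "c" (exclusive to one set), "ab", "ac", "bc"
    (exactly two), "abc" (all three).  The counts partition the union.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "a": len(a - b - c),
        "b": len(b - a - c),
        "c": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }


def load_ppi(paths, comment: str = "#") -> nx.Graph:
    """Union of two-column TSV edge lists into one undirected graph.

    Symbols are upper-cased; duplicate edges collapse with provenance from
    every contributing file kept in the ``sources`` edge attribute;
    self-loops are dropped (logged).  Malformed rows raise with file and
    line number.
    """
    g = nx.Graph()
    for path in paths:
        tag = str(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(comment):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
                u, v = parts[0].strip().upper(), parts[1].strip().upper()
                if lineno == 1 and (u, v) == ("GENE_A", "GENE_B"):
                    continue  # optional header
                if u == v:
                    logger.info("%s:%d: dropped self-loop %s", path, lineno, u)
                    continue
                if g.has_edge(u, v):
                    g.edges[u, v]["sources"].add(tag)
                else:
                    g.add_edge(u, v, sources={tag})
    return g


@dataclass
class ProjectionSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    fraction_in_largest_component: float
    label_fractions: dict = field(default_factory=dict)
    largest_component_label_fractions: dict = field(default_factory=dict)
    components: list = field(default_factory=list)


def project_and_summarize(graph: nx.Graph, labeled_proteins: dict) -> ProjectionSummary:
    """Induce the subgraph on the labeled proteins present in ``graph`` and
    summarize its component structure and label composition.

    ``labeled_proteins`` maps protein/gene symbol to a label (e.g. "day",
    "night").  Labeled proteins absent from the graph are ignored; an empty
    projection yields a zero summary.
    """
    labels = {str(k).upper(): v for k, v in labeled_proteins.items()}
    nodes = [n for n in labels if graph.has_node(n)]
    sub = graph.subgraph(nodes)
    comps = sorted((sorted(c) for c in nx.connected_components(sub)),
                   key=lambda c: (-len(c), c))
    n_nodes = sub.number_of_nodes()
    largest = comps[0] if comps else []
    frac_largest = len(largest) / n_nodes if n_nodes else 0.0

    def _fractions(node_list):
        if not node_list:
            return {}
        counts: dict = {}
        for n in node_list:
            counts[labels[n]] = counts.get(labels[n], 0) + 1
        return {lab: cnt / len(node_list) for lab, cnt in sorted(counts.items())}

    return ProjectionSummary(
        n_nodes=n_nodes,
        n_edges=sub.number_of_edges(),
        n_components=len(comps),
        fraction_in_largest_component=frac_largest,
        label_fractions=_fractions(list(sub.nodes)),
        largest_component_label_fractions=_fractions(largest),
        components=comps,
    )
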