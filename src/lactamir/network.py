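"""Bipartite miRNA-target network with degree-based hub ranking.

Nodes are the differentially expressed miRNAs plus their target genes; an
edge joins gene i to miRNA j when the pair appears in the supplied target
table, weighted by the miRNA's |log2 fold change| (its differential
expression magnitude).  Hubs — the regulatory focal points — are the
highest-degree nodes of each partition.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .diffexpr import STATUS_DOWN, STATUS_UP

__all__ = ["build_network", "rank_hubs", "read_targets_tsv", "write_edge_list_tsv"]


def read_targets_tsv(path) -> list[tuple[str, str]]:
    """Read a two-column (mirna_id, gene_id) TSV, header optional."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            if i == 0 and parts[0].lower() in ("mirna_id", "mirna"):
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


def build_network(de_results: pd.DataFrame, targets) -> nx.Graph:
    """Bipartite graph over up/down miRNAs and their target genes.

    ``targets`` is an iterable of (mirna_id, gene_id) pairs; pairs whose
    miRNA is not differentially expressed are ignored, duplicate pairs are
    collapsed (count in ``graph.graph["duplicate_pairs"]``).  DE miRNAs with
    no targets are retained as isolated nodes.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("empty target table")
    de = de_results[de_results["status"].isin((STATUS_UP, STATUS_DOWN))]
    weight = de["log2fc"].abs().to_dict()

    g = nx.Graph()
    g.add_nodes_from(de.index, bipartite="mirna", kind="mirna")
    seen = set()
    duplicates = 0
    for mirna, gene in targets:
        if mirna not in weight:
            continue
        if (mirna, gene) in seen:
            duplicates += 1
            continue
        seen.add((mirna, gene))
        g.add_node(gene, bipartite="gene", kind="gene")
        g.add_edge(gene, mirna, weight=float(weight[mirna]))
    g.graph["duplicate_pairs"] = duplicates
    return g


def rank_hubs(net: nx.Graph, k: int = 10) -> dict[str, list[tuple[str, int]]]:
    """Top-k nodes of each partition by degree.

    Returns ``{"mirna": [(id, degree), ...], "gene": [...]}`` in descending
    degree order, ties broken lexicographically by node id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list] = {}
    for kind in ("mirna", "gene"):
        nodes = [v for v, d in net.nodes(data=True) if d.get("kind") == kind]
        ranked = sorted(nodes, key=lambda v: (-net.degree(v), v))
        out[kind] = [(v, net.degree(v)) for v in ranked[:k]]
    return out


def write_edge_list_tsv(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmirna\tweight\n")
        for u, v, data in sorted(net.edges(data=True)):
            gene, mirna = (u, v) if net.nodes[u]["kind"] == "gene" else (v, u)
            fh.write(f"{gene}\t{mirna}\t{data['weight']:.6g}\n")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, str(path))
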