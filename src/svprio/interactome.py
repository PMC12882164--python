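"""Patient-specific interactome analysis.

Candidate-SV genes are projected onto a confidence-filtered protein–protein
interaction network (HIPPIE-style scores in [0,1], kept at >= 0.63 by
default; STRING-style combined scores in 0–1000, normalized and kept at
>= 0.700). The patient subnetwork is the full induced subgraph over the
candidate genes plus their first neighbors. A convergence node is a gene
adjacent to candidate genes originating from at least two distinct SVs in
the same patient — the pattern by which, e.g., two disrupted gene-family
members and a third SV's gene can converge on one intermediary kinase.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .model import ConvergenceNode


def load_ppi(
    path: str | Path, min_confidence: float, source_tag: str
) -> nx.Graph:
    """Load a TSV edge list (gene_a, gene_b, confidence) as a PPI network.

    Integer scores in 0–1000 (STRING style) are auto-detected and divided by
    1000. Duplicate edges keep the maximum confidence (applied before
    thresholding); self-loops are dropped. The threshold is inclusive: an
    edge at exactly ``min_confidence`` survives, matching a filter stated as
    "confidence below X removed".
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)[:3]
    conf = pd.to_numeric(df[cols[2]], errors="raise").astype(float)
    if (conf > 1.0).any():  # STRING-style integer combined scores
        conf = conf / 1000.0
    bad = conf[(conf < 0.0) | (conf > 1.0)]
    if not bad.empty:
        line = int(bad.index[0]) + 2
        raise ValueError(f"{path}: line {line}: confidence {bad.iloc[0]} not in [0,1]")

    g = nx.Graph(source=source_tag, min_confidence=min_confidence)
    for a, b, c in zip(df[cols[0]].astype(str), df[cols[1]].astype(str), conf):
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    drop = [(a, b) for a, b, d in g.edges(data=True) if d["confidence"] < min_confidence]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


class PatientInteractome:
    """Candidate genes, their first neighbors, and the induced subgraph.

    Candidate genes absent from the network are retained as isolated,
    flagged nodes. Neighbor–neighbor edges are kept (full induced subgraph)
    unless ``star_only`` is set.
    """

    def __init__(
        self,
        network: nx.Graph,
        candidate_genes: Mapping[str, set[str]],
        star_only: bool = False,
    ) -> None:
        if not candidate_genes:
            raise ValueError("candidate gene set is empty")
        self.candidate_genes = {g: set(svs) for g, svs in candidate_genes.items()}
        self.missing_candidates = sorted(
            g for g in candidate_genes if g not in network
        )
        self.neighbor_nodes: set[str] = set()
        for g in candidate_genes:
            if g in network:
                self.neighbor_nodes.update(network.neighbors(g))
        self.neighbor_nodes -= set(candidate_genes)

        nodes = set(candidate_genes) | self.neighbor_nodes
        sub = network.subgraph(nodes & set(network.nodes)).copy()
        if star_only:
            keep = [
                (a, b) for a, b in sub.edges
                if a in self.candidate_genes or b in self.candidate_genes
            ]
            sub = sub.edge_subgraph(keep).copy()
        sub.add_nodes_from(candidate_genes)  # isolated candidates stay
        self.graph: nx.Graph = sub

    def node_role(self, node: str) -> str:
        return "candidate" if node in self.candidate_genes else "neighbor"


def patient_network(
    network: nx.Graph,
    candidate_genes_by_sv: Mapping[str, Sequence[str]],
    star_only: bool = False,
) -> PatientInteractome:
    """Build the first-neighbor subnetwork around a patient's candidate genes.

    ``candidate_genes_by_sv`` maps sv_id -> genes that SV overlaps.
    """
    gene_to_svs: dict[str, set[str]] = {}
    for sv_id, genes in candidate_genes_by_sv.items():
        for g in genes:
            gene_to_svs.setdefault(g, set()).add(sv_id)
    return PatientInteractome(network, gene_to_svs, star_only=star_only)


def convergence_nodes(pi: PatientInteractome) -> list[ConvergenceNode]:
    """Nodes adjacent to candidate genes from >= 2 distinct SVs.

    A candidate node's own SV origins count once it has at least one
    adjacent candidate gene, so a direct candidate–candidate edge across SVs
    is reported as a zero-intermediary convergence. Ranking: distinct SV
    count desc, number of linked candidates desc, then lexicographic.
    """
    out = []
    for node in pi.graph.nodes:
        adjacent_cands = sorted(
            n for n in pi.graph.neighbors(node) if n in pi.candidate_genes
        )
        if not adjacent_cands:
            continue
        linked = list(adjacent_cands)
        svs: set[str] = set()
        for c in adjacent_cands:
            svs |= pi.candidate_genes[c]
        is_cand = node in pi.candidate_genes
        if is_cand:
            linked = sorted(set(linked) | {node})
            svs |= pi.candidate_genes[node]
        if len(svs) >= 2:
            out.append(
                ConvergenceNode(
                    gene=node,
                    linked_candidates=linked,
                    distinct_sv_count=len(svs),
                    is_candidate_itself=is_cand,
                )
            )
    out.sort(key=lambda c: (-c.distinct_sv_count, -len(c.linked_candidates), c.gene))
    return out


def convergence_scan_oracle(pi: PatientInteractome) -> list[ConvergenceNode]:
    """Independent brute-force re-derivation of convergence_nodes.

    Scans every node's full adjacency list against the candidate map without
    reusing any of the ranking code; used as an equivalence oracle.
    """
    results = {}
    for node in list(pi.graph.nodes):
        sv_origins = set()
        linked = set()
        for other in pi.graph.nodes:
            if other != node and pi.graph.has_edge(node, other):
                if other in pi.candidate_genes:
                    linked.add(other)
                    for sv in pi.candidate_genes[other]:
                        sv_origins.add(sv)
        if node in pi.candidate_genes and linked:
            linked.add(node)
            sv_origins |= pi.candidate_genes[node]
        if len(sv_origins) >= 2:
            results[node] = ConvergenceNode(
                node, sorted(linked), len(sv_origins), node in pi.candidate_genes
            )
    order = sorted(
        results,
        key=lambda n: (
            -results[n].distinct_sv_count,
            -len(results[n].linked_candidates),
            n,
        ),
    )
    return [results[n] for n in order]


def export_network(
    pi: PatientInteractome,
    convergences: Sequence[ConvergenceNode],
    out_dir: str | Path,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write node/edge tables plus SIF and GraphML; byte-deterministic."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conv = {c.gene for c in convergences}

    nodes_path = out_dir / f"{prefix}_nodes.tsv"
    with open(nodes_path, "w") as fh:
        fh.write("node\trole\tsv_origins\n")
        for node in sorted(pi.graph.nodes):
            role = "convergence" if node in conv else pi.node_role(node)
            svs = ",".join(sorted(pi.candidate_genes.get(node, ())))
            fh.write(f"{node}\t{role}\t{svs}\n")

    edges_path = out_dir / f"{prefix}_edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tconfidence\n")
        for a, b in sorted(tuple(sorted(e)) for e in pi.graph.edges):
            fh.write(f"{a}\t{b}\t{pi.graph[a][b]['confidence']:.3f}\n")

    sif_path = out_dir / f"{prefix}.sif"
    with open(sif_path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in pi.graph.edges):
            fh.write(f"{a}\tpp\t{b}\n")
        for node in sorted(nx.isolates(pi.graph)):
            fh.write(f"{node}\n")

    graphml_path = out_dir / f"{prefix}.graphml"
    g = nx.Graph()
    for node in sorted(pi.graph.nodes):
        role = "convergence" if node in conv else pi.node_role(node)
        g.add_node(node, role=role)
    for a, b in sorted(tuple(sorted(e)) for e in pi.graph.edges):
        g.add_edge(a, b, confidence=float(pi.graph[a][b]["confidence"]))
    nx.write_graphml(g, graphml_path)
    return {
        "nodes": nodes_path, "edges": edges_path,
        "sif": sif_path, "graphml": graphml_path,
    }
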