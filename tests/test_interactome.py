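"""PPI filtering, first-neighbor subnetworks, convergence detection."""

import networkx as nx
import numpy as np
import pytest

from svprio.interactome import (
    convergence_nodes,
    convergence_scan_oracle,
    export_network,
    load_ppi,
    patient_network,
)


def _ppi_file(tmp_path, rows, name="ppi.tsv", header="gene_a\tgene_b\tconfidence"):
    path = tmp_path / name
    path.write_text(header + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")
    return path


def test_confidence_threshold_inclusive(tmp_path):
    path = _ppi_file(tmp_path, [("A", "B", 0.62), ("A", "C", 0.63), ("C", "D", 0.80)])
    g = load_ppi(path, 0.63, "HIPPIE_LIKE")
    assert not g.has_edge("A", "B")   # below threshold: dropped
    assert g.has_edge("A", "C")       # exactly at threshold: kept
    assert g.has_edge("C", "D")


def test_string_integer_scores_autodetected(tmp_path):
    path = _ppi_file(
        tmp_path, [("A", "B", 700), ("B", "C", 699), ("C", "D", 995)],
        header="protein_a\tprotein_b\tcombined_score",
    )
    g = load_ppi(path, 0.700, "STRING_LIKE")
    assert g.has_edge("A", "B") and g.has_edge("C", "D")
    assert not g.has_edge("B", "C")
    assert g["C"]["D"]["confidence"] == pytest.approx(0.995)


def test_duplicate_edges_keep_max_confidence(tmp_path):
    path = _ppi_file(
        tmp_path, [("A", "B", 0.70), ("B", "A", 0.90), ("A", "A", 0.99)]
    )
    g = load_ppi(path, 0.63, "HIPPIE_LIKE")
    assert g["A"]["B"]["confidence"] == pytest.approx(0.90)
    assert not g.has_edge("A", "A")  # self-loop dropped
    assert g.number_of_edges() == 1


def test_bad_confidence_fatal_with_line_number(tmp_path):
    path = _ppi_file(tmp_path, [("A", "B", 0.7), ("B", "C", -0.2)])
    with pytest.raises(ValueError, match="line 3"):
        load_ppi(path, 0.63, "HIPPIE_LIKE")


def test_raising_threshold_monotone(tmp_path):
    rng = np.random.default_rng(3)
    rows = [
        (f"G{rng.integers(0, 30)}", f"G{rng.integers(0, 30)}",
         round(float(rng.uniform(0, 1)), 3))
        for _ in range(200)
    ]
    path = _ppi_file(tmp_path, rows)
    prev_nodes, prev_edges = None, None
    for thr in (0.2, 0.5, 0.7, 0.9):
        g = load_ppi(path, thr, "HIPPIE_LIKE")
        nodes, edges = set(g.nodes), set(map(frozenset, g.edges))
        if prev_nodes is not None:
            assert nodes <= prev_nodes and edges <= prev_edges
        prev_nodes, prev_edges = nodes, edges


def _graph(edges):
    g = nx.Graph(source="T")
    for a, b in edges:
        g.add_edge(a, b, confidence=0.9)
    return g


def test_first_neighbor_subnetwork_excludes_distance_two():
    g = _graph([("A", "C"), ("C", "B"), ("B", "D"), ("D", "E")])
    pi = patient_network(g, {"sv1": ["A"], "sv2": ["B"]})
    assert set(pi.graph.nodes) == {"A", "B", "C", "D"}  # E is two hops away
    assert pi.neighbor_nodes == {"C", "D"}


def test_missing_candidate_retained_as_isolated_node():
    g = _graph([("X", "Y")])
    pi = patient_network(g, {"sv1": ["A"], "sv2": ["X"]})
    assert "A" in pi.graph.nodes
    assert pi.graph.degree("A") == 0
    assert pi.missing_candidates == ["A"]


def test_neighbor_neighbor_edges_kept_unless_star_only():
    g = _graph([("A", "C"), ("A", "D"), ("C", "D")])
    full = patient_network(g, {"sv1": ["A"]})
    assert full.graph.has_edge("C", "D")
    star = patient_network(g, {"sv1": ["A"]}, star_only=True)
    assert not star.graph.has_edge("C", "D")


def test_bridge_kinase_pattern_detected():
    # two gene-family members from distinct SVs converge on a third SV's
    # gene via an intermediary kinase
    g = _graph([("NBPF10", "NEK4"), ("NBPF14", "NEK4"), ("NEK4", "RGPD6")])
    pi = patient_network(
        g, {"sv_del1": ["NBPF10"], "sv_del2": ["NBPF14"], "sv_ins": ["RGPD6"]}
    )
    conv = convergence_nodes(pi)
    assert conv[0].gene == "NEK4"
    assert conv[0].distinct_sv_count == 3
    assert conv[0].linked_candidates == ["NBPF10", "NBPF14", "RGPD6"]
    assert not conv[0].is_candidate_itself


def test_corepressor_bridge_between_two_svs():
    g = _graph([("LDOC1", "SUDS3"), ("SUDS3", "USP17L2")])
    pi = patient_network(g, {"sv_inv": ["LDOC1"], "sv_del": ["USP17L2"]})
    conv = convergence_nodes(pi)
    assert [c.gene for c in conv] == ["SUDS3"]


def test_same_sv_pair_not_reported():
    g = _graph([("A", "M"), ("M", "B")])
    pi = patient_network(g, {"sv1": ["A", "B"]})
    assert convergence_nodes(pi) == []


def test_direct_cross_sv_edge_is_zero_intermediary_convergence():
    g = _graph([("A", "B")])
    pi = patient_network(g, {"sv1": ["A"], "sv2": ["B"]})
    conv = convergence_nodes(pi)
    assert {c.gene for c in conv} == {"A", "B"}
    assert all(c.is_candidate_itself and c.distinct_sv_count == 2 for c in conv)


def test_convergence_equals_bruteforce_on_random_graphs():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(5, 25))
        g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(0, 10_000)))
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        nx.set_edge_attributes(g, 0.9, "confidence")
        n_svs = int(rng.integers(1, 4))
        genes = list(g.nodes)
        by_sv = {}
        for s in range(n_svs):
            k = int(rng.integers(1, 3))
            by_sv[f"sv{s}"] = [genes[i] for i in rng.choice(len(genes), k, replace=False)]
        pi = patient_network(g, by_sv)
        fast = convergence_nodes(pi)
        slow = convergence_scan_oracle(pi)
        assert [(c.gene, c.distinct_sv_count, c.linked_candidates) for c in fast] == [
            (c.gene, c.distinct_sv_count, c.linked_candidates) for c in slow
        ]


def test_networks_do_not_leak_across_sources(tmp_path):
    """An edge present in one source and absent in the other never leaks:
    convergence can differ between the two networks."""
    hippie = _ppi_file(tmp_path, [("A", "M", 0.9), ("M", "B", 0.9)], name="h.tsv")
    string = _ppi_file(
        tmp_path, [("A", "M", 900)], name="s.tsv",
        header="protein_a\tprotein_b\tcombined_score",
    )
    gh = load_ppi(hippie, 0.63, "HIPPIE_LIKE")
    gs = load_ppi(string, 0.700, "STRING_LIKE")
    by_sv = {"sv1": ["A"], "sv2": ["B"]}
    assert [c.gene for c in convergence_nodes(patient_network(gh, by_sv))] == ["M"]
    assert convergence_nodes(patient_network(gs, by_sv)) == []


def test_export_round_trip_graphml_and_empty_network(tmp_path):
    g = _graph([("A", "C"), ("C", "B")])
    pi = patient_network(g, {"sv1": ["A"], "sv2": ["B"]})
    conv = convergence_nodes(pi)
    files = export_network(pi, conv, tmp_path, prefix="t")
    back = nx.read_graphml(files["graphml"])
    assert set(back.nodes) == set(pi.graph.nodes)
    assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in pi.graph.edges}
    assert back.nodes["C"]["role"] == "convergence"
    sif = files["sif"].read_text()
    assert "A\tpp\tC" in sif

    empty = patient_network(_graph([("X", "Y")]), {"sv1": ["Z"]})
    files = export_network(empty, [], tmp_path, prefix="empty")
    assert files["edges"].read_text().strip() == "node_a\tnode_b\tconfidence"
    assert "Z" in files["nodes"].read_text()
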