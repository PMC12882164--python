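"""Detect convergence nodes in a patient-specific interactome.

Builds a toy confidence-filtered PPI network in which two gene-family
members disrupted by distinct SVs and a third SV's gene all meet at one
intermediary kinase — the bridge pattern the convergence analysis exists
to find.
"""

import networkx as nx

from svprio.interactome import convergence_nodes, patient_network

g = nx.Graph()
for a, b, conf in [
    ("NBPF10", "NEK4", 0.90),   # SV 1: deletion hitting NBPF10
    ("NBPF14", "NEK4", 0.88),   # SV 2: deletion hitting NBPF14
    ("NEK4", "RGPD6", 0.85),    # SV 3: insertion hitting RGPD6
    ("RGPD6", "RANGAP1", 0.75), # an ordinary first neighbor
]:
    g.add_edge(a, b, confidence=conf)

pi = patient_network(
    g, {"sv_del_1q21.1": ["NBPF10"], "sv_del_1q21.2": ["NBPF14"],
        "sv_ins_2q13": ["RGPD6"]},
)
print(f"patient subnetwork: {sorted(pi.graph.nodes)}")
for c in convergence_nodes(pi):
    print(f"convergence node {c.gene}: adjacent to candidate genes "
          f"{c.linked_candidates} from {c.distinct_sv_count} distinct SVs")

print("\nNEK4 bridges all three SVs' genes: a single intermediary through"
      "\nwhich independent structural variants may converge on one pathway."
      "\nRANGAP1, adjacent to only one SV's gene, is a plain neighbor.")
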