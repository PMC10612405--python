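"""Build a residue contact graph from a synthetic structure.

Generates one 50-residue chain with a compact 12-residue motif, thresholds
Cα–Cα distances at 10 Å, and compares contact density inside and outside
the motif segment — the structural signal the classifier later exploits.
"""

from structfunc import build_contact_map, contact_density
from structfunc.synth import gen_chain

chain, span = gen_chain(length=50, has_motif=True, seed=3, motif_length=12)
graph = build_contact_map(chain, threshold_angstrom=10.0)

motif = graph.subgraph(list(range(span[0], span[1])))
rest = graph.subgraph([i for i in range(len(chain)) if not span[0] <= i < span[1]])

print(f"chain {chain.protein_id}: {len(chain)} residues, {len(graph.edges)} contacts")
print(f"overall contact density : {contact_density(graph):.3f}")
print(f"motif segment {span} density : {contact_density(motif):.3f}")
print(f"background density      : {contact_density(rest):.3f}")
print("-> the compact motif is an order denser than the extended background,")
print("   which is what the attention-pooling layers can pick up.")
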