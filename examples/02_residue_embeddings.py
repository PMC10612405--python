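"""Residue features: biased random walks + skip-gram + one-hot fusion.

Shows the node2vec transition law on a toy path graph (return parameter
p=0.8 makes revisiting the previous residue 1/0.8 = 1.25x as attractive as
an unbiased walk), then embeds a full synthetic protein into the N×50
feature matrix the classifier consumes.
"""

from structfunc import build_contact_map
from structfunc.structure import ContactGraph
from structfunc.synth import gen_chain
from structfunc.walks import WalkConfig, embed_protein, step_weights

cfg = WalkConfig()          # p=0.8, q=1.2, walk_length=30
path = ContactGraph("path", 3, {(0, 1), (1, 2)})
w = step_weights(prev=0, curr=1, graph=path, cfg=cfg)
print(f"walk at node 1 (came from 0): unnormalised weights {w}")
print(f"  return weight 1/p = {1/cfg.p:.2f}, onward weight 1/q = {1/cfg.q:.3f}")

chain, _ = gen_chain(length=40, has_motif=True, seed=11, motif_length=12)
graph = build_contact_map(chain)
features = embed_protein(chain, graph, cfg)
print(f"\n{chain.protein_id}: feature matrix {features.matrix.shape}")
print(f"  columns 0-29 walk embedding, 30-49 one-hot amino acid")
onehot_sums = features.matrix[:, 30:].sum(axis=1)
print(f"  every one-hot block sums to 1: {set(onehot_sums.tolist())}")
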