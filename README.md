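# structfunc

Protein function prediction from predicted 3D structures.

`structfunc` is a research library for structural bioinformaticians who
want to predict Gene Ontology (GO) annotations for proteins that have a
(possibly model-predicted, e.g. AlphaFold2) 3D structure but no
protein–protein-interaction context. It implements the full pipeline:

1. **Contact graphs** — residues become nodes; an edge joins residues i, j
   whenever their Cα–Cα distance is strictly below 10 Å (an all-atom
   `any_any` variant is available).
2. **Residue features** — node2vec-style biased random walks on the
   contact graph (return parameter *p* = 0.8, in–out parameter *q* = 1.2,
   walk length 30) are fed to a skip-gram model; the 30-d walk embedding is
   concatenated with the 20-d one-hot amino-acid encoding into 1×50 node
   features. The transition weight from node *v* to neighbour *x* after
   arriving from *t* is α_pq(t,x)·w_vx with α = 1/p, 1, 1/q for
   shortest-path distance d(t,x) = 0, 1, 2, normalised over the
   neighbours of *v*.
3. **Structural readout** — two stacked graph convolutions
   h^{l+1} = σ(D̃^{-1/2} Ã D̃^{-1/2} h^l Θ) (Ã = A + I), each followed by
   two-head self-attention top-rank pooling (keep the ⌈kN⌉ highest-scoring
   nodes, k = 0.75, gate their features by tanh of the score, induce the
   subgraph) and a mean‖max readout; the per-layer readouts are summed.
4. **Fusion and classification** — the structural vector is concatenated
   with a 1×1024 per-protein sequence embedding (a pluggable provider:
   precomputed language-model output, or a deterministic mock) and an MLP
   with per-label sigmoid outputs is trained with binary cross-entropy
   (Adam, 8:1:1 train/valid/test split, model selection on validation
   Fmax).
5. **Hierarchy-aware evaluation** — predictions are made DAG-consistent
   (each term takes the max over its descendants), then scored with the
   CAFA protein-centric Fmax, micro-AUC and micro-AUPR. Annotations are
   filtered to experimental evidence codes (IDA, IPI, EXP, IGI, IMP, IEP,
   IC, TAS), completed under the true path rule, and rare terms dropped.

A seeded synthetic-data generator (`structfunc.synth`) produces
self-avoiding Cα chains with a compact, contact-dense motif segment, a toy
GO branch, annotations in which the motif determines a subtree of labels,
and mock sequence embeddings — so the whole pipeline runs, trains and
validates with no downloads.

## Worked example

```bash
python examples/01_contact_map.py
```

```
chain SYN000003: 50 residues, 219 contacts
overall contact density : 0.179
motif segment (31, 43) density : 0.864
background density      : 0.172
```

The planted motif (residues 31–43) is ~5× denser in contacts than the
extended background — that local density is the structural signal the
attention-pooling layers exploit.

```bash
python examples/04_train_and_evaluate.py
```

```
held-out Fmax 0.667 (threshold 0.81)
held-out micro-AUC 0.741, AUPR 0.706
naive frequency baseline Fmax 0.560
```

On a 60-protein synthetic dataset the trained model clearly beats the
naive baseline that scores every term by its training frequency: it has
recovered the planted motif → label association. `examples/02_*` and
`03_*` walk through the residue-embedding and ontology stages.

The same pipeline is scriptable from the shell:

```bash
structfunc synth -o data -n 60 --seed 5
structfunc contact -c pipeline.yaml
structfunc embed   -c pipeline.yaml
structfunc train   -c pipeline.yaml
structfunc predict -c pipeline.yaml
structfunc evaluate -c pipeline.yaml
```

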