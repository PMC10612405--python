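"""Residue-level graph embeddings via biased second-order random walks.

The walk follows the node2vec transition rule: having stepped t → v, the
unnormalised weight for continuing to a neighbour x of v is

    α_pq(t, x) · w_vx,   α = 1/p if d(t,x)=0,  1 if d(t,x)=1,  1/q if d(t,x)=2,

with d the shortest-path distance, edge weight w = 1 everywhere, and
weights normalised over the neighbours of v at sampling time.  Low p keeps
the walk local (frequent returns), low q pushes it outward.  The walk
corpus is fed to a skip-gram model with negative sampling, trained here in
plain numpy so the whole step is dependency-free and deterministic under a
single seed.

The final per-residue feature is the walk embedding (default 30-d)
concatenated with the 20-d one-hot amino-acid encoding, giving 1×50 node
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import AMINO_ACIDS, ContactGraph, ResidueChain

log = logging.getLogger(__name__)


@dataclass
class WalkConfig:
    """Hyperparameters of the biased walk + skip-gram stage.

    Defaults p=0.8, q=1.2 and walk_length=30 are the published settings for
    residue graphs (chains under 1500 residues).  The skip-gram trainer
    works on the deduplicated (center, context) pair set with corpus-count
    weights; ``epochs`` counts passes over that small set.  The light
    default keeps embeddings in the regime where their norm structure
    (which transfers across proteins) dominates the protein-specific
    subspace orientation (which does not); raise epochs/learning_rate when
    within-graph community geometry is what matters.
    """

    p: float = 0.8
    q: float = 1.2
    walk_length: int = 30
    walks_per_node: int = 10
    embed_dim: int = 30
    window: int = 5
    epochs: int = 5
    negatives: int = 5
    learning_rate: float = 0.025
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")


def step_weights(prev: int | None, curr: int, graph: ContactGraph,
                 cfg: WalkConfig) -> dict[int, float]:
    """Unnormalised transition weights from ``curr`` given previous node.

    Non-neighbours of ``curr`` implicitly get weight 0.  On the first step
    (``prev is None``) every neighbour gets equal weight.  Normalisation by
    Z = Σ weights happens in the sampler.
    """
    nbrs = graph.neighbors(curr)
    if not nbrs:
        return {}
    if prev is None:
        return {x: 1.0 for x in nbrs}
    weights = {}
    for x in nbrs:
        if x == prev:                       # d(prev, x) = 0
            weights[x] = 1.0 / cfg.p
        elif graph.has_edge(prev, x):       # d(prev, x) = 1
            weights[x] = 1.0
        else:                               # d(prev, x) = 2
            weights[x] = 1.0 / cfg.q
    return weights


def sample_next(prev: int | None, curr: int, graph: ContactGraph,
                cfg: WalkConfig, rng: np.random.Generator) -> int | None:
    """One biased step; None when ``curr`` has no neighbours."""
    w = step_weights(prev, curr, graph, cfg)
    if not w:
        return None
    nodes = list(w)
    probs = np.fromiter(w.values(), dtype=float)
    probs /= probs.sum()
    # manual inverse-CDF draw: cheaper than rng.choice for tiny supports
    r = rng.random()
    acc = 0.0
    for node, pr in zip(nodes, probs):
        acc += pr
        if r < acc:
            return node
    return nodes[-1]


def simulate_walks(graph: ContactGraph, cfg: WalkConfig) -> list[list[int]]:
    """walks_per_node biased walks from every node, reproducible from cfg.seed.

    A walk that reaches a neighbour-less node terminates early.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(cfg.seed)
    walks: list[list[int]] = []
    for _ in range(cfg.walks_per_node):
        for start in range(graph.n_nodes):
            walk = [start]
            prev: int | None = None
            while len(walk) < cfg.walk_length:
                nxt = sample_next(prev, walk[-1], graph, cfg, rng)
                if nxt is None:
                    break
                prev = walk[-1]
                walk.append(nxt)
            walks.append(walk)
    return walks


def _sgns_pairs(walks: list[list[int]], window: int, n_nodes: int,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Distinct (center, context) pairs and their corpus counts.

    On residue graphs the vocabulary is tiny (one node per residue), so the
    skip-gram corpus contains each pair many times; training on weighted
    distinct pairs optimises the same objective at a fraction of the cost.
    """
    counts: dict[int, float] = {}
    for walk in walks:
        n = len(walk)
        for i, c in enumerate(walk):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    key = c * n_nodes + walk[j]
                    counts[key] = counts.get(key, 0.0) + 1.0
    keys = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
    order = np.argsort(keys)
    keys = keys[order]
    weights = np.fromiter(counts.values(), dtype=float, count=len(counts))[order]
    pairs = np.stack([keys // n_nodes, keys % n_nodes], axis=1)
    return pairs, weights


def train_node_embeddings(walks: list[list[int]], cfg: WalkConfig,
                          n_nodes: int | None = None) -> dict[int, np.ndarray]:
    """Skip-gram with negative sampling over the walk corpus.

    Minibatch SGD on the standard SGNS objective
    log σ(u_c·v_o) + Σ_k E[log σ(−u_c·v_neg)] with a unigram^0.75 negative
    table and a linearly decaying learning rate.  Single-threaded and fully
    seeded, so results are bit-reproducible.

    Nodes that never appear in a walk get a zero vector (with a warning).
    """
    if not walks:
        raise ValueError("no walks")
    if n_nodes is None:
        n_nodes = max(max(w) for w in walks) + 1
    rng = np.random.default_rng(cfg.seed + 1)
    dim = cfg.embed_dim

    counts = np.zeros(n_nodes)
    for walk in walks:
        np.add.at(counts, walk, 1.0)
    seen = counts > 0
    noise = counts ** 0.75
    noise_p = noise / noise.sum()

    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))

    pairs, pair_w = _sgns_pairs(walks, cfg.window, n_nodes)
    mean_w = pair_w.mean()
    n_pairs = len(pairs)
    total_steps = max(1, cfg.epochs * ((n_pairs + cfg.batch_size - 1) // cfg.batch_size))
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            c, o = pairs[sel, 0], pairs[sel, 1]
            # pair weight scales the gradient (relative to the mean weight,
            # keeping the effective learning rate comparable)
            w = (pair_w[sel] / mean_w)[:, None]
            neg = rng.choice(n_nodes, size=(len(sel), cfg.negatives), p=noise_p)
            lr = cfg.learning_rate * max(1e-4, 1.0 - step / total_steps)
            step += 1

            vc = w_in[c]                                   # (B, d)
            vo = w_out[o]                                  # (B, d)
            vn = w_out[neg]                                # (B, k, d)
            pos_dot = np.clip(np.sum(vc * vo, axis=1), -30, 30)
            neg_dot = np.clip(np.einsum("bd,bkd->bk", vc, vn), -30, 30)
            g_pos = (1.0 / (1.0 + np.exp(-pos_dot)) - 1.0)[:, None] * w   # σ − 1
            g_neg = (1.0 / (1.0 + np.exp(-neg_dot))) * w                  # σ

            grad_c = g_pos * vo + np.einsum("bk,bkd->bd", g_neg, vn)
            np.add.at(w_in, c, -lr * grad_c)
            np.add.at(w_out, o, -lr * (g_pos * vc))
            np.add.at(w_out.reshape(-1, dim), neg.ravel(),
                      (-lr * g_neg[..., None] * vc[:, None, :]).reshape(-1, dim))

    if not seen.all():
        log.warning("%d nodes never visited by any walk; zero embeddings",
                    int((~seen).sum()))
        w_in[~seen] = 0.0
    return {v: w_in[v].copy() for v in range(n_nodes)}


def one_hot(amino_acid: str) -> np.ndarray:
    """20-d indicator; all zeros for the unknown residue 'X'."""
    vec = np.zeros(len(AMINO_ACIDS))
    idx = AMINO_ACIDS.find(amino_acid)
    if idx >= 0:
        vec[idx] = 1.0
    return vec


@dataclass
class ResidueFeatureMatrix:
    """N×(embed_dim+20) node features: walk embedding ‖ one-hot amino acid."""

    protein_id: str
    matrix: np.ndarray
    embed_dim: int = 30

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def featurize_residues(chain: ResidueChain,
                       embeddings: dict[int, np.ndarray],
                       embed_dim: int = 30) -> ResidueFeatureMatrix:
    """Row i = walk embedding of residue i ‖ one-hot(aa_i); width embed_dim+20.

    Residues missing from ``embeddings`` get a zero embedding block.
    """
    rows = []
    for i, res in enumerate(chain.residues):
        emb = embeddings.get(i)
        if emb is None:
            emb = np.zeros(embed_dim)
        emb = np.asarray(emb, dtype=float)
        if emb.shape != (embed_dim,):
            raise ValueError(
                f"{chain.protein_id}: embedding for residue {i} has shape "
                f"{emb.shape}, expected ({embed_dim},)"
            )
        rows.append(np.concatenate([emb, one_hot(res.amino_acid)]))
    return ResidueFeatureMatrix(chain.protein_id, np.stack(rows), embed_dim)


def embed_protein(chain: ResidueChain, graph: ContactGraph,
                  cfg: WalkConfig) -> ResidueFeatureMatrix:
    """Walks → skip-gram → one-hot fusion, in one call."""
    walks = simulate_walks(graph, cfg)
    emb = train_node_embeddings(walks, cfg, n_nodes=graph.n_nodes)
    return featurize_residues(chain, emb, cfg.embed_dim)


def write_embeddings(embeddings: dict[int, np.ndarray], path) -> None:
    """Tabular persistence: node_index then the embedding floats per line."""
    with open(path, "w") as fh:
        for v in sorted(embeddings):
            vals = "\t".join(repr(float(x)) for x in embeddings[v])
            fh.write(f"{v}\t{vals}\n")


def read_embeddings(path) -> dict[int, np.ndarray]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            out[int(parts[0])] = np.array([float(x) for x in parts[1:]])
    return out
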