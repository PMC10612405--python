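"""Graph classifier: stacked GCN layers with self-attention top-rank pooling.

Architecture, per protein:

1. A symmetric-normalised graph convolution
   ``h' = σ(D̃^{-1/2} Ã D̃^{-1/2} h Θ)`` (Ã = A + I) over the contact graph.
2. A self-attention pooling layer: each attention head is a one-output
   graph convolution producing a per-node importance score; the head mean
   ranks nodes, the top ⌈kN⌉ are retained, their features gated by
   tanh(score), and the induced subgraph passed on.
3. A readout per pooling layer — column mean ‖ column max (a ``sum ‖ max``
   switch is available) — and the readouts of both layers summed into one
   structural feature vector.
4. The structural vector is concatenated with the 1×1024 sequence
   embedding and fed to a dropout-regularised MLP with one sigmoid output
   per GO term.

Training minimises the sum of per-label binary cross-entropies with Adam;
model selection is on validation Fmax.  All computation is numpy via the
in-package autodiff engine; runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, bce_with_logits, concat
from .structure import ContactGraph

__all__ = [
    "ModelConfig", "AttentionScores", "GraphBatch", "ProteinSample",
    "normalized_adjacency", "graph_conv", "attention_score",
    "top_rank_pool", "top_rank_indices", "readout",
    "FunctionPredictor", "train",
]


@dataclass
class ModelConfig:
    """Network and optimisation hyperparameters.

    The published settings are kept as defaults where they exist:
    two convolution layers, pooling ratio 0.75, two attention heads,
    dropout 0.3, learning rate 1e-4.  Hidden sizes, MLP width, batch size
    and epoch count are implementation choices.
    """

    conv_layers: int = 2
    hidden_dim: int = 128
    mlp_hidden: int = 512
    pooling_ratio: float = 0.75
    attention_heads: int = 2
    dropout: float = 0.3
    modality_dropout: float = 0.0
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    epochs: int = 100
    batch_size: int = 32
    readout_mode: str = "mean_max"        # or "sum_max"
    conv_type: str = "graphconv"          # other variants not implemented
    eval_every: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pooling_ratio <= 1.0):
            raise ValueError("pooling_ratio must be in (0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.conv_type != "graphconv":
            raise NotImplementedError(
                f"conv_type {self.conv_type!r}: only 'graphconv' is implemented"
            )
        if self.readout_mode not in ("mean_max", "sum_max"):
            raise ValueError("readout_mode must be 'mean_max' or 'sum_max'")


@dataclass
class AttentionScores:
    """Per-node importance scores: one row per head, plus the head mean."""

    per_head: np.ndarray          # (heads, N)
    mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.per_head = np.atleast_2d(np.asarray(self.per_head, dtype=float))
        self.mean = self.per_head.mean(axis=0)


@dataclass
class ProteinSample:
    """One protein ready for the classifier."""

    protein_id: str
    graph: ContactGraph
    residue_features: np.ndarray      # N × 50
    sequence_embedding: np.ndarray    # 1024
    labels: np.ndarray | None = None  # |LabelSpace| binary


@dataclass
class GraphBatch:
    """Several contact graphs stacked for one forward pass."""

    graphs: list[ContactGraph]
    features: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.graphs) != len(self.features):
            raise ValueError("graphs and features must align")
        for g, x in zip(self.graphs, self.features):
            if g.n_nodes != x.shape[0]:
                raise ValueError(f"{g.protein_id}: feature rows != n_nodes")

    @property
    def membership(self) -> np.ndarray:
        """Graph index of every stacked node."""
        return np.concatenate([
            np.full(g.n_nodes, i, dtype=int) for i, g in enumerate(self.graphs)
        ])

    def block_adjacency(self):
        """Block-diagonal sparse adjacency over all member graphs."""
        from scipy.sparse import block_diag, csr_matrix

        return block_diag([csr_matrix(g.adjacency()) for g in self.graphs])


def normalized_adjacency(graph: ContactGraph) -> np.ndarray:
    """D̃^{-1/2} (A + I) D̃^{-1/2} with D̃ the degree matrix of A + I."""
    a_tilde = graph.adjacency() + np.eye(graph.n_nodes)
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def graph_conv(features, graph: ContactGraph, weights, activation=None):
    """One GCN layer: ``activation(norm_adj @ features @ weights)``.

    Accepts numpy arrays or autodiff Tensors for features/weights; the
    activation is a callable (e.g. ``lambda t: t.relu()``) or None for
    identity.
    """
    norm = normalized_adjacency(graph)
    if isinstance(features, Tensor) or isinstance(weights, Tensor):
        feats = features if isinstance(features, Tensor) else Tensor(features)
        w = weights if isinstance(weights, Tensor) else Tensor(weights)
        if feats.shape[0] != graph.n_nodes:
            raise ValueError("feature rows must equal n_nodes")
        out = Tensor(norm).matmul(feats).matmul(w)
        return activation(out) if activation else out
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if features.shape[0] != graph.n_nodes:
        raise ValueError("feature rows must equal n_nodes")
    if features.shape[1] != weights.shape[0]:
        raise ValueError("feature/weight dimension mismatch")
    out = norm @ features @ weights
    return activation(out) if activation else out


def attention_score(features: np.ndarray, graph: ContactGraph,
                    head_weights: list[np.ndarray]) -> AttentionScores:
    """Importance scores: each head is a width-1 graph convolution."""
    if not head_weights:
        raise ValueError("need at least one attention head")
    per_head = np.stack([
        np.asarray(graph_conv(features, graph, w)).ravel() for w in head_weights
    ])
    return AttentionScores(per_head)


def top_rank_indices(scores: np.ndarray, k: float) -> np.ndarray:
    """Indices of the ⌈kN⌉ highest-scoring nodes (ties → lower index first).

    Returned sorted ascending, so retained nodes keep chain order.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    n = len(scores)
    if n == 0:
        raise ValueError("empty score vector")
    m = max(1, int(np.ceil(k * n)))
    order = np.argsort(-scores, kind="stable")   # stable: lower index wins ties
    return np.sort(order[:m])


def top_rank_pool(features: np.ndarray, graph: ContactGraph,
                  scores: AttentionScores, k: float,
                  ) -> tuple[np.ndarray, ContactGraph]:
    """Retain the top-⌈kN⌉ nodes, gate features by tanh(score), induce subgraph."""
    idx = top_rank_indices(scores.mean, k)
    gate = np.tanh(scores.mean[idx])[:, None]
    sub_features = np.asarray(features, dtype=float)[idx] * gate
    return sub_features, graph.subgraph([int(i) for i in idx])


def readout(features, mode: str = "mean_max"):
    """Permutation-invariant graph vector: column mean (or sum) ‖ column max."""
    if isinstance(features, Tensor):
        if features.shape[0] < 1:
            raise ValueError("readout of an empty graph")
        first = features.mean(axis=0) if mode == "mean_max" else features.sum(axis=0)
        return concat([first, features.max(axis=0)], axis=0)
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 1:
        raise ValueError("readout needs a nonempty N×d matrix")
    # math.fsum: exactly-rounded column sums, so the result is invariant
    # to node order bit-for-bit, not just to 1 ulp
    import math

    col_sums = np.array([math.fsum(col) for col in features.T])
    first = col_sums / features.shape[0] if mode == "mean_max" else col_sums
    return np.concatenate([first, features.max(axis=0)])


class FunctionPredictor:
    """The full structure+sequence GO classifier."""

    SEQ_DIM = 1024

    def __init__(self, n_features: int, n_labels: int, cfg: ModelConfig):
        self.cfg = cfg
        self.n_features = n_features
        self.n_labels = n_labels
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_dim

        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-s, s, size=(fan_in, fan_out)),
                          requires_grad=True)

        self.params: dict[str, Tensor] = {}
        dims = [n_features] + [h] * cfg.conv_layers
        for layer in range(cfg.conv_layers):
            self.params[f"conv{layer}_w"] = glorot(dims[layer], dims[layer + 1])
            self.params[f"conv{layer}_b"] = Tensor(np.zeros(dims[layer + 1]),
                                                   requires_grad=True)
            for head in range(cfg.attention_heads):
                self.params[f"attn{layer}_h{head}"] = glorot(dims[layer + 1], 1)
        fused = 2 * h + self.SEQ_DIM
        self.params["mlp_w1"] = glorot(fused, cfg.mlp_hidden)
        self.params["mlp_b1"] = Tensor(np.zeros(cfg.mlp_hidden), requires_grad=True)
        self.params["mlp_w2"] = glorot(cfg.mlp_hidden, n_labels)
        self.params["mlp_b2"] = Tensor(np.zeros(n_labels), requires_grad=True)
        self._norm_cache: dict[str, np.ndarray] = {}
        self.ablate_structure = False
        # residue-feature column standardisation (fit on the training set);
        # without it the walk-embedding block is ~1e-2 scale and the
        # structural branch is invisible next to the unit-scale sequence block
        self.feat_mean = np.zeros(n_features)
        self.feat_std = np.ones(n_features)

    def fit_feature_scaler(self, feature_matrices: list[np.ndarray]) -> None:
        stacked = np.concatenate(feature_matrices, axis=0)
        self.feat_mean = stacked.mean(axis=0)
        self.feat_std = np.maximum(stacked.std(axis=0), 1e-8)

    # -- forward ---------------------------------------------------------

    def _cached_norm(self, graph: ContactGraph) -> np.ndarray:
        key = f"{graph.protein_id}:{graph.n_nodes}:{len(graph.edges)}"
        if key not in self._norm_cache:
            self._norm_cache[key] = normalized_adjacency(graph)
        return self._norm_cache[key]

    def structural_branch(self, graph: ContactGraph, x: np.ndarray) -> Tensor:
        """Conv → attention pool → readout, twice; readouts summed."""
        cfg = self.cfg
        h = Tensor((x - self.feat_mean) / self.feat_std)
        g = graph
        norm = Tensor(self._cached_norm(g))
        total: Tensor | None = None
        for layer in range(cfg.conv_layers):
            w, b = self.params[f"conv{layer}_w"], self.params[f"conv{layer}_b"]
            h = (norm.matmul(h).matmul(w) + b).relu()
            heads = [
                norm.matmul(h).matmul(self.params[f"attn{layer}_h{head}"])
                for head in range(cfg.attention_heads)
            ]
            score = concat(heads, axis=1).mean(axis=1, keepdims=True)   # (N, 1)
            idx = top_rank_indices(score.data.ravel(), cfg.pooling_ratio)
            h = h.rows(idx) * score.rows(idx).tanh()
            g = g.subgraph([int(i) for i in idx])
            norm = Tensor(normalized_adjacency(g))
            s = readout(h, cfg.readout_mode)
            total = s if total is None else total + s
        return total

    def forward(self, batch: GraphBatch, sequence_embeddings: np.ndarray,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Logits for a batch: (n_proteins, n_labels)."""
        cfg = self.cfg
        seq = np.asarray(sequence_embeddings, dtype=float)
        if seq.shape != (len(batch.graphs), self.SEQ_DIM):
            raise ValueError("sequence embedding block has the wrong shape")
        fused_rows = []
        for i, (g, x) in enumerate(zip(batch.graphs, batch.features)):
            if self.ablate_structure:
                struct = Tensor(np.zeros(2 * cfg.hidden_dim))
            else:
                struct = self.structural_branch(g, x)
            fused_rows.append(concat([struct, Tensor(seq[i])], axis=0).reshape(1, -1))
        fused = concat(fused_rows, axis=0)
        if training and cfg.modality_dropout > 0:
            if rng is None:
                raise ValueError("training forward needs an rng for dropout")
            # independently silence whole input blocks (structure | sequence)
            # per protein, so the classifier cannot lean on one channel only
            p = cfg.modality_dropout
            d_struct = 2 * cfg.hidden_dim
            keep = (rng.random((len(batch.graphs), 2)) >= p) / (1.0 - p)
            mask = np.concatenate([
                np.repeat(keep[:, :1], d_struct, axis=1),
                np.repeat(keep[:, 1:], self.SEQ_DIM, axis=1),
            ], axis=1)
            fused = fused * Tensor(mask)
        hidden = (fused.matmul(self.params["mlp_w1"]) + self.params["mlp_b1"]).relu()
        if training and cfg.dropout > 0:
            if rng is None:
                raise ValueError("training forward needs an rng for dropout")
            mask = (rng.random(hidden.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            hidden = hidden * Tensor(mask)
        return hidden.matmul(self.params["mlp_w2"]) + self.params["mlp_b2"]

    def predict(self, samples: list[ProteinSample]) -> np.ndarray:
        """Per-label probabilities, (n_proteins, n_labels) in (0, 1)."""
        batch = GraphBatch([s.graph for s in samples],
                           [s.residue_features for s in samples])
        seq = np.stack([s.sequence_embedding for s in samples])
        return self.forward(batch, seq).sigmoid().data

    # -- persistence -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.params.items()}
        out["_feat_mean"] = self.feat_mean.copy()
        out["_feat_std"] = self.feat_std.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=float).copy()
        self.feat_mean = np.asarray(state["_feat_mean"], dtype=float).copy()
        self.feat_std = np.asarray(state["_feat_std"], dtype=float).copy()


class Adam:
    """Adaptive-moment SGD with decoupled (AdamW-style) weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and not k.endswith("_b"):
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(train_set: list[ProteinSample], valid_set: list[ProteinSample],
          cfg: ModelConfig, ablate_structure: bool = False,
          label_space=None, dag=None) -> tuple[FunctionPredictor, dict]:
    """Fit the classifier; select the epoch with the best validation Fmax.

    When ``label_space`` and ``dag`` are given, validation scores are made
    hierarchy-consistent before computing Fmax, matching the evaluation
    protocol.  Returns (model, history); history has per-epoch training
    loss and the validation Fmax trace.  Fully reproducible from cfg.seed.
    """
    from .evaluation import ScoreMatrix, fmax as fmax_metric, hierarchical_postprocess

    if not train_set:
        raise ValueError("empty training set")
    n_labels = len(train_set[0].labels)
    if n_labels == 0:
        raise ValueError("empty label space")
    model = FunctionPredictor(train_set[0].residue_features.shape[1],
                              n_labels, cfg)
    model.ablate_structure = ablate_structure
    model.fit_feature_scaler([s.residue_features for s in train_set])
    opt = Adam(model.params, cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 7)

    y_valid = np.stack([s.labels for s in valid_set]) if valid_set else None
    history: dict = {"loss": [], "val_fmax": [], "val_epoch": []}
    best = {"fmax": -1.0, "state": model.state_dict(), "epoch": 0}

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for s0 in range(0, len(order), cfg.batch_size):
            idx = order[s0:s0 + cfg.batch_size]
            samples = [train_set[i] for i in idx]
            batch = GraphBatch([s.graph for s in samples],
                               [s.residue_features for s in samples])
            seq = np.stack([s.sequence_embedding for s in samples])
            y = np.stack([s.labels for s in samples]).astype(float)
            logits = model.forward(batch, seq, training=True, rng=rng)
            loss = bce_with_logits(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        last = epoch == cfg.epochs - 1
        if valid_set and (epoch % cfg.eval_every == 0 or last):
            scores = model.predict(valid_set)
            if label_space is not None and dag is not None:
                scores = hierarchical_postprocess(
                    ScoreMatrix([s.protein_id for s in valid_set],
                                label_space, scores), dag).scores
            vf, _ = fmax_metric(scores, y_valid)
            history["val_fmax"].append(vf)
            history["val_epoch"].append(epoch)
            if vf > best["fmax"]:
                best = {"fmax": vf, "state": model.state_dict(), "epoch": epoch}
    if valid_set:
        model.load_state_dict(best["state"])
        history["best_epoch"] = best["epoch"]
        history["best_val_fmax"] = best["fmax"]
    return model, history
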