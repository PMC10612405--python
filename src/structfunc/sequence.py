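"""Per-protein 1×1024 sequence embeddings (pluggable providers).

The classifier consumes one 1024-dimensional vector per protein — the
shape produced by ELMo-style protein language models (per-residue 1024-d
states averaged over the chain).  Running such a model is out of scope
here; instead the contract is served by providers:

* ``precomputed`` — a tabular file of id + 1024 floats, as exported by any
  external embedder;
* ``mock`` — a deterministic pseudo-random vector derived from the
  sequence, optionally carrying a planted signal so synthetic datasets
  have a learnable sequence channel.

Swapping providers changes values, never shapes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EMBED_DIM = 1024


@dataclass
class ProteinEmbedding:
    protein_id: str
    vector: np.ndarray
    provider: str = "precomputed"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (EMBED_DIM,):
            raise ValueError(
                f"{self.protein_id}: embedding must have length {EMBED_DIM}, "
                f"got {self.vector.shape}"
            )
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"{self.protein_id}: non-finite embedding entries")


def load_precomputed(path: str | Path) -> dict[str, ProteinEmbedding]:
    """Read `id<TAB>1024 floats` rows; every row is width-checked."""
    out: dict[str, ProteinEmbedding] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            pid, vals = parts[0], parts[1:]
            if len(vals) != EMBED_DIM:
                raise ValueError(
                    f"embedding for {pid!r} has width {len(vals)}, expected {EMBED_DIM}"
                )
            out[pid] = ProteinEmbedding(pid, np.array([float(x) for x in vals]))
    return out


def write_embeddings(embeddings: dict[str, ProteinEmbedding], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(embeddings):
            vals = "\t".join(repr(float(x)) for x in embeddings[pid].vector)
            fh.write(f"{pid}\t{vals}\n")


def mock_embedding(sequence: str, seed: int = 0,
                   signal: tuple[bool, np.ndarray, float] | None = None,
                   protein_id: str = "") -> ProteinEmbedding:
    """Deterministic stand-in for a language-model embedding.

    The base vector is standard-normal noise seeded by a stable hash of
    (sequence, seed).  When ``signal=(motif_flag, direction, strength)`` is
    given and the flag is set, ``strength * direction`` is added — planting
    a linear signal synthetic classifiers can pick up.
    """
    if not sequence:
        raise ValueError("empty sequence")
    digest = hashlib.sha256(f"{sequence}|{seed}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    vec = rng.standard_normal(EMBED_DIM)
    if signal is not None:
        motif_flag, direction, strength = signal
        if motif_flag:
            direction = np.asarray(direction, dtype=float)
            vec = vec + strength * direction
    return ProteinEmbedding(protein_id or sequence[:8], vec, provider="mock")


def residue_to_protein_pool(residue_matrix: np.ndarray, method: str = "mean") -> np.ndarray:
    """Reduce an N×1024 per-residue matrix to one 1024-vector (column mean)."""
    residue_matrix = np.asarray(residue_matrix, dtype=float)
    if residue_matrix.ndim != 2 or residue_matrix.shape[0] < 1:
        raise ValueError("need an N×D matrix with N >= 1")
    if method != "mean":
        raise ValueError(f"unsupported pooling method {method!r}; use 'mean'")
    return residue_matrix.mean(axis=0)


def read_fasta(path: str | Path) -> dict[str, str]:
    """id → sequence, via Biopython."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sequences:
            fh.write(f">{pid}\n{sequences[pid]}\n")
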