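"""Seeded synthetic data: structures, sequences, a toy ontology, annotations.

The generator plants a structure→function signal so the whole pipeline is
exercisable (and learnable) without downloading real structures:

* chains are self-avoiding 3D random walks with the canonical ~3.8 Å
  consecutive-Cα spacing; in "motif" proteins a contiguous segment is
  grown under attraction to its own centroid, producing a locally dense
  contact neighbourhood the pooling layers can detect;
* a toy GO-like branch contains one deep chain of terms (the motif
  subtree) and a background subtree of leaves;
* motif proteins are annotated with the motif-subtree leaf, every protein
  gets one random background leaf, bits are flipped with a configurable
  noise rate, and the table is closed under the true path rule;
* mock sequence embeddings optionally carry the motif flag as a linear
  signal of configurable strength, so the structure and sequence channels
  can be ablated separately.

Everything is deterministic from ``SynthConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .ontology import AnnotationTable, GoDag, write_annotations_tsv, write_obo
from .sequence import EMBED_DIM, ProteinEmbedding, mock_embedding, write_fasta
from .sequence import write_embeddings as write_seq_embeddings
from .structure import AMINO_ACIDS, ContactGraph, Residue, ResidueChain, write_pdb

_STEP_MIN, _STEP_MAX = 3.7, 3.9      # consecutive Cα spacing (Å)
_HARD_CORE = 3.4                     # min non-consecutive residue distance (Å)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark."""

    n_proteins: int = 300
    chain_length_range: tuple[int, int] = (30, 60)
    motif_length: int = 12
    motif_prevalence: float = 0.5
    n_terms: int = 12
    dag_depth: int = 4
    label_noise: float = 0.0
    seq_signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.chain_length_range
        if not (2 <= lo <= hi < 1500):
            raise ValueError("chain lengths must satisfy 2 <= min <= max < 1500")
        if not (0 < self.motif_prevalence < 1):
            raise ValueError("motif_prevalence must be in (0, 1)")
        if not (0 <= self.label_noise < 1):
            raise ValueError("label_noise must be in [0, 1)")
        if self.n_terms < self.dag_depth + 2:
            raise ValueError("need n_terms >= dag_depth + 2")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def gen_chain(length: int, has_motif: bool, seed: int,
              motif_length: int = 12,
              ) -> tuple[ResidueChain, tuple[int, int] | None]:
    """Self-avoiding Cα walk; returns (chain, motif span [start, end))."""
    if has_motif and length < motif_length:
        raise ValueError("chain shorter than the motif")
    rng = np.random.default_rng(seed)
    span = None
    if has_motif:
        start = int(rng.integers(0, length - motif_length + 1))
        span = (start, start + motif_length)

    for _attempt in range(50):
        coords = [np.zeros(3)]
        direction = _unit(rng.standard_normal(3))
        ok = True
        for i in range(1, length):
            in_motif = span is not None and span[0] < i < span[1]
            placed = False
            for _try in range(200):
                if in_motif:
                    centroid = np.mean(coords[span[0]:i], axis=0)
                    pull = centroid - coords[-1]
                    norm = np.linalg.norm(pull)
                    pull = pull / norm if norm > 1e-9 else rng.standard_normal(3)
                    cand_dir = _unit(rng.standard_normal(3) + 1.2 * pull)
                else:
                    # persistent direction keeps the background extended
                    cand_dir = _unit(0.55 * direction + rng.standard_normal(3) * 0.6)
                step = rng.uniform(_STEP_MIN, _STEP_MAX)
                cand = coords[-1] + step * cand_dir
                prev = np.stack(coords[:-1]) if len(coords) > 1 else None
                if prev is None or np.linalg.norm(prev - cand, axis=1).min() >= _HARD_CORE:
                    coords.append(cand)
                    direction = cand_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            seq_rng = np.random.default_rng(seed + 1)
            aas = seq_rng.choice(list(AMINO_ACIDS), size=length)
            residues = [Residue(a, c) for a, c in zip(aas, coords)]
            return ResidueChain(f"SYN{seed:06d}", residues), span
    raise RuntimeError(f"self-avoiding chain generation failed (seed={seed})")


def gen_ontology(n_terms: int, depth: int, seed: int = 0) -> GoDag:
    """Toy GO branch: root, a depth-long chain (the motif subtree), and a
    background parent with leaves filling up to ``n_terms`` terms.

    The unique deepest term is the motif leaf; :func:`motif_subtree`
    recovers the planted subtree from the DAG alone.
    """
    if n_terms < 2:
        raise ValueError("need at least root + one child")
    if n_terms == 2:
        root, child = "GO:8000000", "GO:8000001"
        return GoDag("BPO", {root: set(), child: {root}}, root)
    if n_terms < depth + 2:
        raise ValueError("need n_terms >= depth + 2")
    ids = [f"GO:8{i:06d}" for i in range(n_terms)]
    root = ids[0]
    parents: dict[str, set[str]] = {root: set()}
    # motif chain: ids[1] .. ids[depth]
    for d in range(1, depth + 1):
        parents[ids[d]] = {ids[d - 1] if d > 1 else root}
    # background parent + leaves
    b0 = ids[depth + 1]
    parents[b0] = {root}
    for t in ids[depth + 2:]:
        parents[t] = {b0}
    return GoDag("BPO", parents, root)


def motif_subtree(dag: GoDag) -> list[str]:
    """The planted motif chain: the unique deepest leaf and its ancestors
    (root excluded), ordered root-most first."""
    def depth_of(t: str) -> int:
        return 0 if not dag.parents[t] else 1 + max(depth_of(p) for p in dag.parents[t])

    leaf = max(sorted(dag.terms), key=depth_of)
    chain = [leaf] + sorted(dag.ancestors(leaf) - {dag.root},
                            key=depth_of, reverse=True)
    return list(reversed(chain))


def background_leaves(dag: GoDag) -> list[str]:
    motif = set(motif_subtree(dag))
    return sorted(
        t for t in dag.terms
        if t != dag.root and t not in motif and not dag.children_of(t)
    )


def gen_annotations(proteins: list[tuple[str, bool]], dag: GoDag,
                    noise: float, seed: int = 0) -> AnnotationTable:
    """Annotations with the planted signal, noise flips, then true-path closure.

    Motif-flagged proteins get the motif-subtree leaf; every protein gets
    one uniformly random background leaf.  Each (protein, non-root term)
    bit is then flipped independently with probability ``noise``.
    All rows carry the experimental code IDA (flips included); rows added
    by propagation carry TPR.
    """
    from .ontology import propagate_true_path

    rng = np.random.default_rng(seed)
    terms = sorted(dag.terms - {dag.root})
    tidx = {t: i for i, t in enumerate(terms)}
    motif_leaf = motif_subtree(dag)[-1]
    bg = background_leaves(dag)

    bits = np.zeros((len(proteins), len(terms)), dtype=bool)
    for i, (_pid, flag) in enumerate(proteins):
        if flag:
            bits[i, tidx[motif_leaf]] = True
        if bg:
            bits[i, tidx[bg[int(rng.integers(0, len(bg)))]]] = True
    if noise > 0:
        bits ^= rng.random(bits.shape) < noise

    rows = [
        (pid, terms[j], "IDA")
        for i, (pid, _flag) in enumerate(proteins)
        for j in np.flatnonzero(bits[i])
    ]
    return propagate_true_path(AnnotationTable(rows), dag)


@dataclass
class SynthBundle:
    """Paths and in-memory handles of one generated dataset."""

    root: Path
    config: SynthConfig
    protein_ids: list[str]
    motif_flags: dict[str, bool]
    motif_spans: dict[str, tuple[int, int] | None]
    chains: dict[str, ResidueChain]
    dag: GoDag
    annotations: AnnotationTable
    embeddings: dict[str, ProteinEmbedding]

    @property
    def structures_dir(self) -> Path:
        return self.root / "structures"

    @property
    def fasta_path(self) -> Path:
        return self.root / "sequences.fasta"

    @property
    def obo_path(self) -> Path:
        return self.root / "ontology.obo"

    @property
    def annotations_path(self) -> Path:
        return self.root / "annotations.tsv"

    @property
    def embeddings_path(self) -> Path:
        return self.root / "seq_embeddings.tsv"


def gen_dataset(cfg: SynthConfig, outdir: str | Path) -> SynthBundle:
    """Generate and write a complete bundle (PDB, FASTA, OBO, TSV).

    Regenerating with the same config produces byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)

    n_motif = int(round(cfg.n_proteins * cfg.motif_prevalence))
    flags = np.array([True] * n_motif + [False] * (cfg.n_proteins - n_motif))
    rng.shuffle(flags)
    lengths = rng.integers(cfg.chain_length_range[0],
                           cfg.chain_length_range[1] + 1, size=cfg.n_proteins)

    chains: dict[str, ResidueChain] = {}
    spans: dict[str, tuple[int, int] | None] = {}
    motif_flags: dict[str, bool] = {}
    protein_ids: list[str] = []
    for i in range(cfg.n_proteins):
        chain_seed = (cfg.seed * 100_000 + i) % (2 ** 31)
        chain, span = gen_chain(int(lengths[i]), bool(flags[i]), chain_seed,
                                cfg.motif_length)
        pid = f"P{i:05d}"
        chain.protein_id = pid
        protein_ids.append(pid)
        chains[pid] = chain
        spans[pid] = span
        motif_flags[pid] = bool(flags[i])
        write_pdb(chain, outdir / "structures" / f"{pid}.pdb")

    write_fasta({pid: chains[pid].sequence for pid in protein_ids},
                outdir / "sequences.fasta")

    dag = gen_ontology(cfg.n_terms, cfg.dag_depth, cfg.seed)
    write_obo(dag, outdir / "ontology.obo")

    table = gen_annotations([(pid, motif_flags[pid]) for pid in protein_ids],
                            dag, cfg.label_noise, cfg.seed + 1)
    write_annotations_tsv(table, outdir / "annotations.tsv")

    dir_rng = np.random.default_rng(cfg.seed + 2)
    direction = _unit(dir_rng.standard_normal(EMBED_DIM))
    embeddings = {
        pid: mock_embedding(
            chains[pid].sequence, seed=cfg.seed,
            signal=(motif_flags[pid], direction, cfg.seq_signal_strength),
            protein_id=pid)
        for pid in protein_ids
    }
    write_seq_embeddings(embeddings, outdir / "seq_embeddings.tsv")

    meta = {
        "config": {**asdict(cfg), "chain_length_range": list(cfg.chain_length_range)},
        "protein_ids": protein_ids,
        "motif_flags": {p: motif_flags[p] for p in protein_ids},
        "motif_spans": {p: list(spans[p]) if spans[p] else None for p in protein_ids},
        "motif_subtree": motif_subtree(dag),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    return SynthBundle(outdir, cfg, protein_ids, motif_flags, spans, chains,
                       dag, table, embeddings)
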