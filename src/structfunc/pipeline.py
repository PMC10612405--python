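"""Pipeline orchestration: stages, dataset splits, and run manifests.

Stages (each resumable — up-to-date outputs are skipped):

  contact   structures → per-protein contact-graph edge lists
  embed     contact graphs → N×50 residue feature matrices
  train     features + sequence embeddings + labels → model checkpoint
  predict   checkpoint → CAFA-style predictions TSV
  evaluate  predictions vs held-out truth → EvalReport JSON

Proteins are split 8:1:1 (train/valid/test) by a seeded shuffle with
largest-remainder rounding; every stage writes into one output directory
together with a JSON manifest (config hash, seed, input hashes) that makes
the run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, ontology, sequence, structure, walks
from .model import ModelConfig, ProteinSample, train as train_model
from .walks import WalkConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    structures_dir: str = "structures"
    fasta: str = "sequences.fasta"
    obo: str = "ontology.obo"
    annotations: str = "annotations.tsv"
    seq_embeddings: str = "seq_embeddings.tsv"
    output_dir: str = "output"
    walk: WalkConfig = field(default_factory=WalkConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    min_count: int = 5
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "walk" in raw:
            raw["walk"] = WalkConfig(**raw["walk"])
        if "model" in raw:
            raw["model"] = ModelConfig(**raw["model"])
        if "split_ratios" in raw:
            raw["split_ratios"] = tuple(raw["split_ratios"])
        cfg = cls(**raw)
        if seed is not None:
            cfg = cfg.with_seed(seed)
        return cfg

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed,
                       walk=replace(self.walk, seed=seed),
                       model=replace(self.model, seed=seed))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def desk_scale_config(data_dir: str | Path, output_dir: str | Path,
                      seed: int = 0) -> PipelineConfig:
    """Pipeline settings sized for the synthetic desk-scale benchmark.

    Optimisation settings are scaled to a few hundred proteins of 30-60
    residues: a narrower network (hidden 64, MLP 256), a larger learning
    rate (1e-3) and nonzero weight decay, versus the published
    full-proteome settings, which target ~20k proteins and many more
    gradient steps.
    """
    data_dir = Path(data_dir)
    cfg = PipelineConfig(
        structures_dir=str(data_dir / "structures"),
        fasta=str(data_dir / "sequences.fasta"),
        obo=str(data_dir / "ontology.obo"),
        annotations=str(data_dir / "annotations.tsv"),
        seq_embeddings=str(data_dir / "seq_embeddings.tsv"),
        output_dir=str(output_dir),
        walk=WalkConfig(),
        model=ModelConfig(hidden_dim=64, mlp_hidden=256, learning_rate=1e-3,
                          weight_decay=1e-2, modality_dropout=0.4,
                          epochs=150, batch_size=32, eval_every=5),
        min_count=5,
        seed=seed,
    )
    return cfg.with_seed(seed)


def split_dataset(proteins: list[str], ratios: tuple[float, float, float],
                  seed: int) -> tuple[list[str], list[str], list[str]]:
    """Seeded shuffle, then a contiguous largest-remainder cut.

    Train receives any leftover protein; every split must be nonempty.
    """
    n = len(proteins)
    rng = np.random.default_rng(seed)
    order = [proteins[i] for i in rng.permutation(n)]
    raw = [r * n for r in ratios]
    sizes = [int(x) for x in raw]
    rema = [x - int(x) for x in raw]
    for i in sorted(range(3), key=lambda i: -rema[i]):
        if sum(sizes) == n:
            break
        sizes[i] += 1
    sizes[0] += n - sum(sizes)
    splits = (order[:sizes[0]],
              order[sizes[0]:sizes[0] + sizes[1]],
              order[sizes[0] + sizes[1]:])
    if any(len(s) == 0 for s in splits):
        raise ValueError(f"a split is empty for n={n}, ratios={ratios}")
    return splits


def _up_to_date(out: Path, *inputs: Path) -> bool:
    return out.exists() and all(out.stat().st_mtime >= p.stat().st_mtime
                                for p in inputs if p.exists())


def _structure_files(cfg: PipelineConfig) -> list[Path]:
    d = Path(cfg.structures_dir)
    if not d.is_dir():
        raise FileNotFoundError(
            f"structures directory {d} missing — run the synth stage or point "
            f"structures_dir at your PDB/mmCIF files")
    files = sorted(list(d.glob("*.pdb")) + list(d.glob("*.cif")))
    if not files:
        raise FileNotFoundError(f"no .pdb/.cif files under {d}")
    return files


def stage_contact(cfg: PipelineConfig) -> int:
    """Build and persist contact graphs; returns number of proteins."""
    outdir = Path(cfg.output_dir) / "contacts"
    outdir.mkdir(parents=True, exist_ok=True)
    n = 0
    for path in _structure_files(cfg):
        out = outdir / f"{path.stem}.edges.tsv"
        if _up_to_date(out, path):
            n += 1
            continue
        chain = structure.read_structure(path)
        graph = structure.build_contact_map(chain)
        structure.write_edge_list(graph, out)
        log.info("contact %s: %d nodes, %d edges", path.stem,
                 graph.n_nodes, len(graph.edges))
        n += 1
    return n


def stage_embed(cfg: PipelineConfig) -> int:
    """Biased walks + skip-gram + one-hot fusion per protein."""
    contacts = Path(cfg.output_dir) / "contacts"
    if not contacts.is_dir():
        raise FileNotFoundError("contact stage outputs missing — run 'contact' first")
    outdir = Path(cfg.output_dir) / "features"
    outdir.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, path in enumerate(_structure_files(cfg)):
        edge_file = contacts / f"{path.stem}.edges.tsv"
        if not edge_file.exists():
            raise FileNotFoundError(f"missing contact map {edge_file} — rerun 'contact'")
        out = outdir / f"{path.stem}.features.tsv"
        if _up_to_date(out, path, edge_file):
            n += 1
            continue
        chain = structure.read_structure(path)
        graph = structure.read_edge_list(edge_file)
        wcfg = replace(cfg.walk, seed=cfg.walk.seed + i)
        feats = walks.embed_protein(chain, graph, wcfg)
        np.savetxt(out, feats.matrix, delimiter="\t")
        n += 1
    return n


def load_labelled_dataset(cfg: PipelineConfig):
    """Assemble ProteinSamples from stage outputs + annotations.

    Returns (samples sorted by protein id, LabelSpace, GoDag).
    """
    dags = ontology.parse_obo(cfg.obo)
    if len(dags) != 1:
        raise ValueError(
            f"expected a single-branch ontology, found {sorted(dags)}; "
            "run one branch at a time")
    dag = next(iter(dags.values()))
    table = ontology.read_annotations_tsv(cfg.annotations)
    table = ontology.filter_evidence(table)
    table = ontology.resolve_terms(table, dag)
    table = ontology.propagate_true_path(table, dag)
    space = ontology.filter_labels(table, dag, cfg.min_count)
    if len(space) == 0:
        raise ValueError("label space is empty; lower min_count")

    seq_emb = sequence.load_precomputed(cfg.seq_embeddings)
    contacts = Path(cfg.output_dir) / "contacts"
    features = Path(cfg.output_dir) / "features"
    samples = []
    pids = []
    for path in _structure_files(cfg):
        pid = path.stem
        feat_file = features / f"{pid}.features.tsv"
        edge_file = contacts / f"{pid}.edges.tsv"
        if not feat_file.exists() or not edge_file.exists():
            raise FileNotFoundError(
                f"missing stage outputs for {pid} — run 'contact' and 'embed'")
        if pid not in seq_emb:
            raise KeyError(f"no sequence embedding for {pid}")
        pids.append(pid)
        samples.append((pid, edge_file, feat_file))
    y = ontology.label_matrix(table, space, pids)
    out = []
    for i, (pid, edge_file, feat_file) in enumerate(samples):
        graph = structure.read_edge_list(edge_file)
        mat = np.loadtxt(feat_file, delimiter="\t", ndmin=2)
        out.append(ProteinSample(pid, graph, mat, seq_emb[pid].vector, y[i]))
    return out, space, dag


def _write_manifest(cfg: PipelineConfig, stage: str, extra: dict) -> None:
    outdir = Path(cfg.output_dir)
    inputs = {}
    for name in ("fasta", "obo", "annotations", "seq_embeddings"):
        p = Path(getattr(cfg, name))
        if p.exists():
            inputs[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "input_hashes": inputs,
        **extra,
    }
    (outdir / f"manifest.{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))


def stage_train(cfg: PipelineConfig, ablate_structure: bool = False):
    """Split, fit, checkpoint; returns (model, history, splits)."""
    samples, space, dag = load_labelled_dataset(cfg)
    by_id = {s.protein_id: s for s in samples}
    tr, va, te = split_dataset(sorted(by_id), cfg.split_ratios, cfg.seed)
    model, history = train_model([by_id[p] for p in tr], [by_id[p] for p in va],
                                 cfg.model, ablate_structure=ablate_structure,
                                 label_space=space, dag=dag)
    outdir = Path(cfg.output_dir)
    np.savez(outdir / "model.npz", **model.state_dict())
    (outdir / "model.json").write_text(json.dumps({
        "model": asdict(cfg.model), "n_features": model.n_features,
        "n_labels": model.n_labels, "space": space.terms,
        "branch": space.branch, "ablate_structure": ablate_structure,
        "splits": {"train": tr, "valid": va, "test": te},
    }, indent=2))
    with open(outdir / "history.tsv", "w") as fh:
        fh.write("epoch\tloss\n")
        for e, l in enumerate(history["loss"]):
            fh.write(f"{e}\t{l:.6f}\n")
    _write_manifest(cfg, "train", {"best_val_fmax": history.get("best_val_fmax")})
    return model, history, (tr, va, te)


def _load_model(cfg: PipelineConfig):
    from .model import FunctionPredictor

    outdir = Path(cfg.output_dir)
    meta_path = outdir / "model.json"
    if not meta_path.exists():
        raise FileNotFoundError("no trained model found — run 'train' first")
    meta = json.loads(meta_path.read_text())
    model = FunctionPredictor(meta["n_features"], meta["n_labels"],
                              ModelConfig(**meta["model"]))
    model.ablate_structure = meta.get("ablate_structure", False)
    state = np.load(outdir / "model.npz")
    model.load_state_dict({k: state[k] for k in state.files})
    space = ontology.LabelSpace(meta["branch"], meta["space"])
    return model, space, meta


def stage_predict(cfg: PipelineConfig, subset: str = "test") -> evaluation.ScoreMatrix:
    """Score the requested split and write CAFA-style TSV."""
    model, space, meta = _load_model(cfg)
    samples, _space, dag = load_labelled_dataset(cfg)
    by_id = {s.protein_id: s for s in samples}
    pids = sorted(meta["splits"][subset]) if subset != "all" else sorted(by_id)
    chosen = [by_id[p] for p in pids]
    scores = model.predict(chosen)
    matrix = evaluation.ScoreMatrix(pids, space, scores)
    evaluation.write_predictions_tsv(matrix, Path(cfg.output_dir) / "predictions.tsv")
    _write_manifest(cfg, "predict", {"subset": subset, "n_proteins": len(pids)})
    return matrix


def stage_evaluate(cfg: PipelineConfig, subset: str = "test") -> evaluation.EvalReport:
    """Evaluate written predictions against the held-out truth."""
    model, space, meta = _load_model(cfg)
    samples, _space, dag = load_labelled_dataset(cfg)
    by_id = {s.protein_id: s for s in samples}
    pred_path = Path(cfg.output_dir) / "predictions.tsv"
    if not pred_path.exists():
        raise FileNotFoundError("no predictions found — run 'predict' first")
    matrix = evaluation.read_predictions_tsv(pred_path, space)
    truth = np.stack([by_id[p].labels for p in matrix.proteins])
    report = evaluation.evaluate(matrix, truth, dag)
    report.to_json(Path(cfg.output_dir) / "report.json")
    _write_manifest(cfg, "evaluate", {"subset": subset, "fmax": report.fmax})
    return report


def run_all(cfg: PipelineConfig, ablate_structure: bool = False) -> evaluation.EvalReport:
    """contact → embed → train → predict → evaluate."""
    stage_contact(cfg)
    stage_embed(cfg)
    stage_train(cfg, ablate_structure=ablate_structure)
    stage_predict(cfg)
    return stage_evaluate(cfg)
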