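"""Full pipeline on a small synthetic dataset (~1 minute).

Generates 60 proteins with a planted structure→function signal, runs
contact-map construction, residue embedding, training (8:1:1 split,
selection on validation Fmax) and hierarchy-consistent evaluation, then
prints the held-out metrics next to the naive term-frequency baseline.
"""

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from structfunc.evaluation import fmax, naive_frequency_baseline
from structfunc.ontology import label_matrix, read_annotations_tsv
from structfunc.pipeline import (desk_scale_config, load_labelled_dataset,
                                 run_all, split_dataset)
from structfunc.synth import SynthConfig, gen_dataset

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    gen_dataset(SynthConfig(n_proteins=60, label_noise=0.0, seed=5),
                root / "data")
    cfg = desk_scale_config(root / "data", root / "out", seed=5)
    cfg = replace(cfg, min_count=3, model=replace(cfg.model, epochs=60))

    report = run_all(cfg)
    print(f"held-out Fmax {report.fmax:.3f} (threshold {report.fmax_threshold:.2f})")
    print(f"held-out micro-AUC {report.auc:.3f}, AUPR {report.aupr:.3f}")

    samples, space, dag = load_labelled_dataset(cfg)
    by = {s.protein_id: s for s in samples}
    tr, va, te = split_dataset(sorted(by), cfg.split_ratios, cfg.seed)
    y_tr = np.stack([by[p].labels for p in tr])
    y_te = np.stack([by[p].labels for p in te])
    naive_f, _ = fmax(naive_frequency_baseline(y_tr, len(te)), y_te)
    print(f"naive frequency baseline Fmax {naive_f:.3f}")
    print("-> the trained model beats annotating every protein with the")
    print("   most frequent terms, because it recovers the planted motif labels.")
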