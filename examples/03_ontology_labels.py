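"""From raw annotations to a training label matrix.

Builds a toy GO-like branch, annotates proteins (with evidence codes),
keeps only experimentally supported rows, completes them under the true
path rule, filters rare terms and prints the resulting label matrix.
"""

from structfunc.ontology import (AnnotationTable, filter_evidence,
                                 filter_labels, label_matrix,
                                 propagate_true_path)
from structfunc.synth import gen_ontology, motif_subtree

dag = gen_ontology(n_terms=8, depth=3, seed=0)
print(f"branch {dag.branch}: {len(dag.terms)} terms, root {dag.root}")
print(f"planted motif subtree: {motif_subtree(dag)}")

leaf = motif_subtree(dag)[-1]
table = AnnotationTable([
    ("P1", leaf, "IDA"),          # experimental -> kept
    ("P2", leaf, "IEA"),          # electronic   -> dropped
    ("P2", dag.root, "EXP"),
    ("P3", leaf, "TAS"),
])
kept = filter_evidence(table)
print(f"\nevidence filter kept {len(kept)}/{len(table)} rows")

closed = propagate_true_path(kept, dag)
print(f"true-path closure: {len(kept)} -> {len(closed)} rows")
space = filter_labels(closed, dag, min_count=2)
proteins = ["P1", "P2", "P3"]
y = label_matrix(closed, space, proteins)
print(f"label space (>=2 proteins, root excluded): {space.terms}")
for pid, row in zip(proteins, y):
    print(f"  {pid}: {row.tolist()}")
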