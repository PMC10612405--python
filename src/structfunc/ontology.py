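"""Gene Ontology handling: DAGs, annotations, and label spaces.

Functional labels live in one of three GO branches (BPO, CCO, MFO), each a
rooted DAG of is_a relations.  The true path rule makes label sets
upward-closed: annotating a term implies all of its ancestors.  The
pipeline keeps only experimentally supported annotations (GAF evidence
codes IDA, IPI, EXP, IGI, IMP, IEP, IC, TAS), completes them under the
true path rule, and drops rare terms to control label sparsity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)

#: experimental / curated evidence codes trusted by default ("TA" is
#: accepted as an alias of TAS)
DEFAULT_EVIDENCE = frozenset(
    {"IDA", "IPI", "EXP", "IGI", "IMP", "IEP", "IC", "TAS"}
)

_NAMESPACE_TO_BRANCH = {
    "biological_process": "BPO",
    "cellular_component": "CCO",
    "molecular_function": "MFO",
}


@dataclass
class GoDag:
    """One GO branch: term ids, is_a parent sets, and the branch root."""

    branch: str
    parents: dict[str, set[str]]          # term -> direct is_a parents
    root: str

    def __post_init__(self) -> None:
        self.terms: set[str] = set(self.parents)
        self.terms.add(self.root)
        self.parents.setdefault(self.root, set())
        for t, ps in self.parents.items():
            missing = ps - self.terms
            if missing:
                raise ValueError(f"{t}: parents {missing} not in DAG")
        self._check_acyclic()
        self._children: dict[str, set[str]] | None = None

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            stack.append(t)
            for p in self.parents[t]:
                if state.get(p) == 1:
                    cycle = stack[stack.index(p):] + [p]
                    raise ValueError(f"cycle in ontology: {' -> '.join(cycle)}")
                if p not in state:
                    visit(p, stack)
            stack.pop()
            state[t] = 2

        for term in self.parents:
            if term not in state:
                visit(term, [])

    def children_of(self, term: str) -> set[str]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.terms}
            for t, ps in self.parents.items():
                for p in ps:
                    ch[p].add(t)
            self._children = ch
        return self._children[term]

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors of ``term`` up to and including the root."""
        out: set[str] = set()
        frontier = list(self.parents[term])
        while frontier:
            t = frontier.pop()
            if t not in out:
                out.add(t)
                frontier.extend(self.parents[t])
        return out

    def descendants(self, term: str) -> set[str]:
        out: set[str] = set()
        frontier = list(self.children_of(term))
        while frontier:
            t = frontier.pop()
            if t not in out:
                out.add(t)
                frontier.extend(self.children_of(t))
        return out


@dataclass
class AnnotationTable:
    """(protein_id, term_id, evidence_code) rows."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def proteins(self) -> list[str]:
        return sorted({p for p, _, _ in self.rows})

    def pairs(self) -> set[tuple[str, str]]:
        return {(p, t) for p, t, _ in self.rows}

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class LabelSpace:
    """Deterministically ordered (lexicographic) GO-term columns."""

    branch: str
    terms: list[str]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in label space")
        self.terms = sorted(self.terms)
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


def parse_obo(path: str | Path) -> dict[str, GoDag]:
    """Parse an OBO 1.2 file into per-branch DAGs (is_a edges only).

    Obsolete terms are excluded.  Returns a dict keyed by branch code
    (BPO/CCO/MFO) for every namespace present in the file.
    """
    import obonet

    graph = obonet.read_obo(str(path))   # MultiDiGraph, child -> parent, obsolete removed
    by_branch: dict[str, dict[str, set[str]]] = {}
    namespaces: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "unknown")
        namespaces[term] = ns
        by_branch.setdefault(ns, {}).setdefault(term, set())
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        ns = namespaces[child]
        if namespaces.get(parent) != ns:
            continue
        by_branch[ns][child].add(parent)

    out: dict[str, GoDag] = {}
    for ns, parents in by_branch.items():
        roots = [t for t, ps in parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"namespace {ns}: expected one root, found {roots}")
        branch = _NAMESPACE_TO_BRANCH.get(ns, ns)
        out[branch] = GoDag(branch, parents, roots[0])
    return out


def write_obo(dag: GoDag, path: str | Path, namespace: str | None = None) -> None:
    """Serialise a DAG back to minimal OBO 1.2 (fixture round-trips)."""
    ns = namespace or {v: k for k, v in _NAMESPACE_TO_BRANCH.items()}.get(
        dag.branch, "biological_process")
    lines = ["format-version: 1.2", "ontology: go", ""]
    for term in sorted(dag.terms):
        lines += [f"[Term]", f"id: {term}", f"name: {term}", f"namespace: {ns}"]
        for parent in sorted(dag.parents[term]):
            lines.append(f"is_a: {parent} ! {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_annotations_tsv(path: str | Path) -> AnnotationTable:
    """3-column TSV: protein_id, term_id, evidence_code (# comments skipped)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p, t, c = line.rstrip("\n").split("\t")[:3]
            rows.append((p, t, c))
    return AnnotationTable(rows)


def write_annotations_tsv(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p, t, c in table.rows:
            fh.write(f"{p}\t{t}\t{c}\n")


def read_gaf(path: str | Path) -> AnnotationTable:
    """GAF 2.x reader: DB object id (col 2), GO id (col 5), evidence (col 7)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                continue
            rows.append((cols[1], cols[4], cols[6]))
    return AnnotationTable(rows)


def filter_evidence(table: AnnotationTable,
                    allowed: frozenset[str] | set[str] = DEFAULT_EVIDENCE,
                    ) -> AnnotationTable:
    """Keep rows whose evidence code is trusted; "TA" aliases to TAS."""
    allowed = set(allowed)
    if "TAS" in allowed:
        allowed.add("TA")
    return AnnotationTable([r for r in table.rows if r[2] in allowed])


def resolve_terms(table: AnnotationTable, dag: GoDag) -> AnnotationTable:
    """Drop rows whose term is not in the DAG (with a warning)."""
    kept, dropped = [], 0
    for row in table.rows:
        if row[1] in dag.terms:
            kept.append(row)
        else:
            dropped += 1
    if dropped:
        log.warning("dropped %d annotations with unresolvable terms", dropped)
    return AnnotationTable(kept)


def propagate_true_path(table: AnnotationTable, dag: GoDag) -> AnnotationTable:
    """Upward closure: every annotated term implies all its ancestors.

    Added rows carry evidence code "TPR" (true-path rule); the operation is
    idempotent and leaves original rows untouched.
    """
    present = table.pairs()
    extra = []
    for prot, term in sorted(present):
        for anc in dag.ancestors(term):
            if (prot, anc) not in present:
                present.add((prot, anc))
                extra.append((prot, anc, "TPR"))
    return AnnotationTable(table.rows + extra)


def filter_labels(table: AnnotationTable, dag: GoDag, min_count: int = 25) -> LabelSpace:
    """Terms annotating >= min_count distinct proteins; the root is excluded.

    Counting happens on the (already propagated) table, so parents always
    count at least as high as their children.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, set[str]] = {}
    for prot, term in table.pairs():
        counts.setdefault(term, set()).add(prot)
    kept = [
        t for t, prots in counts.items()
        if len(prots) >= min_count and t != dag.root and t in dag.terms
    ]
    return LabelSpace(dag.branch, kept)


def label_matrix(table: AnnotationTable, space: LabelSpace,
                 proteins: list[str]):
    """proteins × terms binary matrix from a propagated table."""
    import numpy as np

    mat = np.zeros((len(proteins), len(space)), dtype=np.int8)
    pos = {p: i for i, p in enumerate(proteins)}
    for prot, term in table.pairs():
        if prot in pos and term in space.index:
            mat[pos[prot], space.index[term]] = 1
    return mat
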