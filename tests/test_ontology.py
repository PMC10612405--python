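import numpy as np
import pytest

from structfunc.ontology import (DEFAULT_EVIDENCE, AnnotationTable, GoDag,
                                 LabelSpace, filter_evidence, filter_labels,
                                 label_matrix, parse_obo, propagate_true_path,
                                 read_gaf, resolve_terms, write_obo)


def chain_dag():
    return GoDag("BPO", {"GO:root": set(), "GO:mid": {"GO:root"},
                         "GO:leaf": {"GO:mid"}}, "GO:root")


def random_dag(rng, n_terms: int) -> GoDag:
    """Random rooted DAG: term i picks 1-2 parents among earlier terms."""
    ids = [f"GO:{i:07d}" for i in range(n_terms)]
    parents = {ids[0]: set()}
    for i in range(1, n_terms):
        k = 1 if i == 1 else int(rng.integers(1, 3))
        choices = rng.choice(i, size=min(k, i), replace=False)
        parents[ids[i]] = {ids[int(c)] for c in choices}
    return GoDag("BPO", parents, ids[0])


class TestParseObo:
    def test_minimal_two_terms(self, tmp_path):
        (tmp_path / "t.obo").write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: root\n"
            "namespace: biological_process\n\n[Term]\nid: GO:0000002\n"
            "name: child\nnamespace: biological_process\n"
            "is_a: GO:0000001 ! root\n")
        dags = parse_obo(tmp_path / "t.obo")
        dag = dags["BPO"]
        assert dag.terms == {"GO:0000001", "GO:0000002"}
        assert dag.parents["GO:0000002"] == {"GO:0000001"}
        assert dag.root == "GO:0000001"

    def test_obsolete_terms_excluded(self, tmp_path):
        (tmp_path / "t.obo").write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: root\n"
            "namespace: biological_process\n\n[Term]\nid: GO:0000002\n"
            "name: dead\nnamespace: biological_process\nis_obsolete: true\n"
            "\n[Term]\nid: GO:0000003\nname: child\n"
            "namespace: biological_process\nis_a: GO:0000001 ! root\n")
        dag = parse_obo(tmp_path / "t.obo")["BPO"]
        assert "GO:0000002" not in dag.terms

    def test_cycle_raises(self):
        with pytest.raises(ValueError, match="cycle"):
            GoDag("BPO", {"GO:r": set(), "GO:a": {"GO:b", "GO:r"},
                          "GO:b": {"GO:a"}}, "GO:r")

    def test_writer_parser_round_trip_random_dags(self, tmp_path, rng):
        for trial in range(5):
            dag = random_dag(rng, 50)
            write_obo(dag, tmp_path / f"d{trial}.obo")
            back = parse_obo(tmp_path / f"d{trial}.obo")["BPO"]
            assert back.terms == dag.terms
            assert back.parents == dag.parents
            assert back.root == dag.root


class TestFilterEvidence:
    def test_default_filter_keeps_experimental_only(self):
        t = AnnotationTable([("P1", "GO:1", "IDA"), ("P1", "GO:2", "IEA")])
        assert filter_evidence(t).rows == [("P1", "GO:1", "IDA")]

    def test_ta_alias_for_tas(self):
        t = AnnotationTable([("P1", "GO:1", "TA"), ("P2", "GO:1", "TAS")])
        assert len(filter_evidence(t)) == 2

    def test_empty_table(self):
        assert filter_evidence(AnnotationTable([])).rows == []

    def test_matches_per_row_membership_loop(self, rng):
        codes = ["IDA", "IEA", "ISS", "EXP", "TAS", "ND", "IMP"]
        rows = [(f"P{i}", "GO:1", codes[int(rng.integers(len(codes)))])
                for i in range(100)]
        got = filter_evidence(AnnotationTable(rows)).rows
        expected = [r for r in rows if r[2] in DEFAULT_EVIDENCE]
        assert got == expected


class TestPropagation:
    def test_leaf_chain_completion(self):
        t = AnnotationTable([("P1", "GO:leaf", "IDA")])
        out = propagate_true_path(t, chain_dag())
        assert out.pairs() == {("P1", "GO:leaf"), ("P1", "GO:mid"),
                               ("P1", "GO:root")}

    def test_idempotent(self):
        t = propagate_true_path(AnnotationTable([("P1", "GO:leaf", "IDA")]),
                                chain_dag())
        again = propagate_true_path(t, chain_dag())
        assert again.pairs() == t.pairs()
        assert len(again) == len(t)

    def test_matches_dfs_closure_oracle(self, rng):
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(5, 50)))
            terms = sorted(dag.terms)
            rows = [(f"P{int(rng.integers(5))}",
                     terms[int(rng.integers(len(terms)))], "EXP")
                    for _ in range(15)]
            out = propagate_true_path(AnnotationTable(rows), dag).pairs()

            # independent DFS transitive-closure oracle
            def ancestors_dfs(t):
                seen, stack = set(), list(dag.parents[t])
                while stack:
                    x = stack.pop()
                    if x not in seen:
                        seen.add(x)
                        stack.extend(dag.parents[x])
                return seen

            expected = set()
            for p, t, _ in rows:
                expected.add((p, t))
                expected |= {(p, a) for a in ancestors_dfs(t)}
            assert out == expected


class TestFilterLabels:
    def _table(self):
        rows = [(f"P{i}", "GO:A", "IDA") for i in range(3)]
        rows += [("P0", "GO:B", "IDA")]
        return AnnotationTable(rows)

    def _dag(self):
        return GoDag("BPO", {"GO:root": set(), "GO:A": {"GO:root"},
                             "GO:B": {"GO:root"}}, "GO:root")

    def test_threshold(self):
        space = filter_labels(self._table(), self._dag(), min_count=2)
        assert space.terms == ["GO:A"]

    def test_min_count_one_keeps_all_nonroot(self):
        space = filter_labels(self._table(), self._dag(), min_count=1)
        assert space.terms == ["GO:A", "GO:B"]

    def test_root_always_excluded(self):
        t = propagate_true_path(self._table(), self._dag())
        space = filter_labels(t, self._dag(), min_count=1)
        assert "GO:root" not in space.terms

    def test_monotone_in_min_count(self, rng):
        dag = random_dag(rng, 20)
        terms = sorted(dag.terms)
        rows = [(f"P{int(rng.integers(10))}",
                 terms[int(rng.integers(len(terms)))], "IDA") for _ in range(60)]
        t = propagate_true_path(AnnotationTable(rows), dag)
        prev = None
        for mc in (1, 2, 4, 8):
            kept = set(filter_labels(t, dag, mc).terms)
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_matches_count_threshold_oracle(self, rng):
        dag = random_dag(rng, 30)
        terms = sorted(dag.terms)
        rows = [(f"P{int(rng.integers(12))}",
                 terms[int(rng.integers(len(terms)))], "IDA") for _ in range(80)]
        t = propagate_true_path(AnnotationTable(rows), dag)
        space = filter_labels(t, dag, 3)
        counts = {}
        for p, term in t.pairs():
            counts.setdefault(term, set()).add(p)
        expected = sorted(term for term, ps in counts.items()
                          if len(ps) >= 3 and term != dag.root)
        assert space.terms == expected


class TestLabelMatrix:
    def test_unannotated_protein_zero_row(self):
        dag = chain_dag()
        t = propagate_true_path(AnnotationTable([("P1", "GO:leaf", "IDA")]), dag)
        space = filter_labels(t, dag, 1)
        m = label_matrix(t, space, ["P1", "P2"])
        assert m[1].sum() == 0
        assert m[0].sum() == len(space)

    def test_column_sums_meet_min_count(self, rng):
        dag = random_dag(rng, 25)
        terms = sorted(dag.terms)
        rows = [(f"P{int(rng.integers(10))}",
                 terms[int(rng.integers(len(terms)))], "IDA") for _ in range(50)]
        t = propagate_true_path(AnnotationTable(rows), dag)
        space = filter_labels(t, dag, 2)
        m = label_matrix(t, space, sorted({p for p, _, _ in rows}))
        assert np.all(m.sum(axis=0) >= 2)

    def test_hierarchical_consistency_child_le_parent(self, rng):
        dag = random_dag(rng, 25)
        terms = sorted(dag.terms)
        rows = [(f"P{int(rng.integers(10))}",
                 terms[int(rng.integers(len(terms)))], "IDA") for _ in range(50)]
        t = propagate_true_path(AnnotationTable(rows), dag)
        space = filter_labels(t, dag, 1)
        m = label_matrix(t, space, sorted({p for p, _, _ in rows}))
        for child, parents in dag.parents.items():
            for parent in parents:
                if child in space.index and parent in space.index:
                    assert np.all(m[:, space.index[child]]
                                  <= m[:, space.index[parent]])


def test_resolve_drops_unknown_terms(caplog):
    dag = chain_dag()
    t = AnnotationTable([("P1", "GO:leaf", "IDA"), ("P1", "GO:nope", "IDA")])
    with caplog.at_level("WARNING"):
        out = resolve_terms(t, dag)
    assert len(out) == 1


def test_gaf_reader(tmp_path):
    gaf = ("!gaf-version: 2.2\n"
           "UniProtKB\tP12345\tGENE\t\tGO:0000001\tPMID:1\tIDA\t\tP\t\t\t"
           "protein\ttaxon:9606\t20200101\tUniProt\n")
    (tmp_path / "a.gaf").write_text(gaf)
    t = read_gaf(tmp_path / "a.gaf")
    assert t.rows == [("P12345", "GO:0000001", "IDA")]


def test_label_space_ordering_deterministic():
    s = LabelSpace("BPO", ["GO:b", "GO:a", "GO:c"])
    assert s.terms == ["GO:a", "GO:b", "GO:c"]
    assert s.index["GO:b"] == 1
    with pytest.raises(ValueError):
        LabelSpace("BPO", ["GO:a", "GO:a"])
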