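import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthoclock.go import (
    AnnotationSet,
    OntologyError,
    by_fdr,
    enrichment_scan,
    hypergeom_test,
    level_distribution,
    parse_obo,
    term_level,
)
from orthoclock.synthetic import make_go_fixture
from oracles import bfs_levels, by_adjust, hypergeom_tail

MINI_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: child a
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: child b
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: grandchild with two parents
namespace: biological_process
is_a: GO:0000002 ! child a
is_a: GO:0000003 ! child b

[Term]
id: GO:0000005
name: gone
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture()
def mini_dag(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(MINI_OBO)
    return parse_obo(path)


@pytest.fixture(scope="module")
def fixture_dag(tmp_path_factory):
    fix = make_go_fixture(n_terms=50, max_depth=5, n_genes=200, seed=12)
    d = tmp_path_factory.mktemp("go")
    fix.write(d / "f.obo", d / "f.tsv")
    dag = parse_obo(d / "f.obo")
    ann = AnnotationSet.read_tsv(d / "f.tsv", dag)
    return fix, dag, ann


class TestParseObo:
    def test_small_fixture(self, mini_dag):
        assert len(mini_dag.terms) == 4  # obsolete term dropped
        assert mini_dag.terms["GO:0000004"]["parents"] == (
            "GO:0000002", "GO:0000003"
        )
        assert mini_dag.roots == {"biological_process": "GO:0000001"}

    def test_alt_id_maps_to_primary(self, mini_dag):
        assert mini_dag.canonical("GO:0000099") == "GO:0000003"
        assert "GO:0000099" in mini_dag

    def test_cycle_detected(self, tmp_path):
        bad = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nnamespace: x\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nnamespace: x\nis_a: GO:1\n"
        )
        path = tmp_path / "bad.obo"
        path.write_text(bad)
        with pytest.raises(OntologyError):
            parse_obo(path)

    def test_roundtrips_generator_truth(self, fixture_dag):
        fix, dag, _ = fixture_dag
        assert set(dag.terms) == set(fix.term_parents)
        for tid, parents in fix.term_parents.items():
            assert dag.terms[tid]["parents"] == tuple(sorted(parents))
        assert dag.alt_ids == fix.alt_ids


class TestTermLevel:
    def test_root_is_level_one(self, mini_dag):
        assert term_level(mini_dag, "GO:0000001") == 1

    def test_direct_child_is_level_two(self, mini_dag):
        assert term_level(mini_dag, "GO:0000002") == 2

    def test_diamond_uses_shortest_path(self, tmp_path):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: r\nnamespace: x\n\n"
            "[Term]\nid: GO:2\nname: a\nnamespace: x\nis_a: GO:1\n\n"
            "[Term]\nid: GO:3\nname: b\nnamespace: x\nis_a: GO:2\n\n"
            "[Term]\nid: GO:4\nname: c\nnamespace: x\nis_a: GO:3\n\n"
            "[Term]\nid: GO:5\nname: diamond\nnamespace: x\n"
            "is_a: GO:2\nis_a: GO:4\n"
        )
        path = tmp_path / "d.obo"
        path.write_text(obo)
        dag = parse_obo(path)
        assert term_level(dag, "GO:5") == 3  # via GO:2, not via GO:4

    def test_unknown_term(self, mini_dag):
        with pytest.raises(OntologyError):
            term_level(mini_dag, "GO:9999999")

    def test_matches_bfs_oracle(self, fixture_dag):
        fix, dag, _ = fixture_dag
        oracle = bfs_levels(fix.term_parents, list(dag.roots.values()))
        for tid in dag.terms:
            assert term_level(dag, tid) == oracle[tid]

    def test_non_roots_are_at_least_level_two(self, fixture_dag):
        _, dag, _ = fixture_dag
        roots = set(dag.roots.values())
        for tid in dag.terms:
            if tid not in roots:
                assert term_level(dag, tid) >= 2


class TestAnnotationSet:
    def test_stats_match_generator_truth(self, fixture_dag):
        fix, dag, ann = fixture_dag
        stats = ann.stats()
        per_gene = [len(ts) for ts in fix.annotations.values()]
        assert stats["genes_annotated"] == len(fix.annotations)
        assert stats["total_mappings"] == sum(per_gene)
        assert stats["unique_terms"] == len(set().union(*fix.annotations.values()))
        assert stats["min_per_gene"] == min(per_gene)
        assert stats["max_per_gene"] == max(per_gene)

    def test_unknown_term_rejected(self, mini_dag):
        with pytest.raises(OntologyError):
            AnnotationSet.from_pairs([("g", "GO:7777777")], mini_dag)


class TestLevelDistribution:
    def test_direct_annotation_counts_fully(self, mini_dag):
        ann = AnnotationSet.from_pairs(
            [("g1", "GO:0000002"), ("g2", "GO:0000002")], mini_dag
        )
        rows = level_distribution(mini_dag, ann, 2)
        top = {r["term"]: r["pct"] for r in rows}
        assert top["GO:0000002"] == 100.0

    def test_child_annotation_propagates_to_parent(self, mini_dag):
        ann = AnnotationSet.from_pairs([("g1", "GO:0000004")], mini_dag)
        rows = level_distribution(mini_dag, ann, 2)
        terms = {r["term"] for r in rows}
        assert terms == {"GO:0000002", "GO:0000003"}

    def test_matches_bruteforce_ancestor_sets(self, fixture_dag):
        fix, dag, ann = fixture_dag
        rows = level_distribution(dag, ann, 3)
        # brute force: walk every gene's ancestor set explicitly
        counts = {}
        for gene, terms in fix.annotations.items():
            anc = set()
            stack = list(terms)
            while stack:
                t = stack.pop()
                if t in anc:
                    continue
                anc.add(t)
                stack.extend(fix.term_parents[t])
            for t in anc:
                if fix.term_levels[t] == 3:
                    counts[t] = counts.get(t, 0) + 1
        assert {r["term"]: r["genes"] for r in rows} == counts


class TestHypergeomTest:
    def test_exact_enumeration_example(self):
        p = hypergeom_test(4, 4, 5, 10, "enriched")
        assert math.isclose(p, 5.0 / 210.0, rel_tol=1e-12)

    def test_zero_diminished_closed_form(self):
        p = hypergeom_test(0, 4, 5, 10, "diminished")
        assert math.isclose(p, math.comb(5, 4) / math.comb(10, 4), rel_tol=1e-12)

    def test_complementarity(self):
        for k in range(1, 5):
            up = hypergeom_test(k, 6, 7, 15, "enriched")
            down = hypergeom_test(k - 1, 6, 7, 15, "diminished")
            assert math.isclose(up + down, 1.0, rel_tol=1e-12)

    def test_matches_combinatorial_oracle(self, rng):
        for _ in range(30):
            N = int(rng.integers(5, 25))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, n - (N - K)), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            for direction in ("enriched", "diminished"):
                assert math.isclose(
                    hypergeom_test(k, n, K, N, direction),
                    hypergeom_tail(k, n, K, N, direction),
                    rel_tol=1e-9,
                )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(OntologyError):
            hypergeom_test(5, 4, 5, 10, "enriched")


class TestByFdr:
    def test_hand_example(self):
        adj = by_fdr([0.01, 0.04])
        assert np.allclose(adj, [0.03, 0.06])

    def test_single_p_unchanged(self):
        assert by_fdr([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_definition_and_is_monotone(self, ps):
        adj = by_fdr(ps)
        assert np.allclose(adj, by_adjust(ps), atol=1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestEnrichmentScan:
    def test_self_comparison_is_null(self, fixture_dag):
        _, dag, ann = fixture_dag
        records = enrichment_scan(dag, ann, ann, fdr_level=0.05)
        assert not any(r.significant for r in records)

    def test_planted_term_detected(self):
        fix = make_go_fixture(n_terms=60, max_depth=5, n_genes=500,
                              planted_terms=[("enriched", 10.0)],
                              seed=31, study_size=200)
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            fix.write(os.path.join(d, "f.obo"), os.path.join(d, "f.tsv"))
            dag = parse_obo(os.path.join(d, "f.obo"))
            ann = AnnotationSet.read_tsv(os.path.join(d, "f.tsv"), dag)
        study = AnnotationSet({g: ann.direct[g] for g in fix.study_genes})
        records = enrichment_scan(dag, study, ann, fdr_level=0.05)
        planted = next(iter(fix.planted))
        rec = next(r for r in records
                   if r.term == planted and r.direction == "enriched")
        assert rec.significant
        assert rec.q >= rec.p

    def test_empty_background_rejected(self, mini_dag):
        with pytest.raises(OntologyError):
            enrichment_scan(mini_dag, AnnotationSet({}), AnnotationSet({}))

    def test_propagation_monotonicity(self, fixture_dag):
        fix, dag, ann = fixture_dag
        prop = ann.propagated(dag)
        counts = {}
        for terms in prop.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        for tid, parents in fix.term_parents.items():
            for p in parents:
                assert counts.get(p, 0) >= counts.get(tid, 0)
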