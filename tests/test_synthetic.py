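import math

import numpy as np
import pytest
from scipy.stats import chisquare

from orthoclock import phylo
from orthoclock.orf import Contig, select_orf
from orthoclock.synthetic import (
    SimScenario,
    SimulationError,
    evolve_alignment,
    inject_gaps,
    make_contigs,
    make_go_fixture,
    make_proteomes,
    revcomp,
    sample_tree,
    tree_height,
)


class TestSampleTree:
    def test_two_taxa_cherry_is_ultrametric(self):
        tree = sample_tree(2, 1.0, seed=1)
        tips = [lf.edge.length for lf in tree.leaf_node_iter()]
        assert len(tips) == 2 and math.isclose(tips[0], tips[1], rel_tol=1e-12)
        assert all(t > 0 for t in tips)

    def test_determinism(self):
        a = sample_tree(11, 1.0, seed=1).as_string(schema="newick")
        b = sample_tree(11, 1.0, seed=1).as_string(schema="newick")
        assert a == b

    def test_all_root_to_leaf_paths_equal_height(self):
        tree = sample_tree(11, 1.0, seed=3)
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert len(depths) == 11
        assert max(depths) - min(depths) < 1e-12
        assert math.isclose(max(depths), tree_height(tree), rel_tol=1e-12)

    def test_unique_labels_and_validation(self):
        tree = sample_tree(6, 2.0, seed=5)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert len(set(labels)) == 6
        with pytest.raises(SimulationError):
            sample_tree(1, 1.0, seed=0)


class TestEvolveAlignment:
    def test_zero_branches_copy_root(self, wag):
        tree = phylo.parse_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        rows = evolve_alignment(tree, wag, 50, seed=2)
        assert rows["A"] == rows["B"] == rows["C"]

    def test_unknown_focal_taxon_rejected(self, wag):
        tree = phylo.parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        with pytest.raises(SimulationError):
            evolve_alignment(tree, wag, 10, rate_multiplier=2.0,
                             focal_taxon="Z", seed=1)

    def test_unit_multiplier_identical_to_plain_run(self, wag, small_tree5):
        a = evolve_alignment(small_tree5, wag, 100, seed=9)
        b = evolve_alignment(small_tree5, wag, 100, rate_multiplier=1.0,
                             focal_taxon="sp2", seed=9)
        assert a == b

    def test_long_branch_reaches_stationarity(self, wag):
        """After a very long branch the focal row's composition matches the
        model's equilibrium frequencies (chi-squared goodness of fit)."""
        tree = phylo.parse_newick("((A:0.05,B:50.0):0.05,C:0.05);")
        rows = evolve_alignment(tree, wag, 10_000, seed=4)
        counts = np.array([rows["B"].count(a) for a in phylo.AA_ORDER])
        expected = wag.frequencies * 10_000
        stat, p = chisquare(counts, expected)
        assert p > 1e-3


class TestMakeContigs:
    def test_direct_reverse_translation_of_mk(self):
        contigs, truth = make_contigs([("p", "MK")], seed=0, utr_range=(0, 0))
        (cid, seq), = contigs
        assert len(seq) == 9
        fwd = seq if truth[cid].strand == "+" else revcomp(seq)
        assert fwd.startswith("ATG")
        assert fwd[3:6] in ("AAA", "AAG")  # a lysine codon
        assert select_orf(Contig(cid, seq)) is None  # below the 10 nt cutoff

    def test_truncated_contigs_have_no_upstream_start(self):
        proteins = [("p", "MAAAKLWERTYHGMDNNQRSTVVLKWE" + "GHEDKLA" * 4)]
        contigs, truth = make_contigs(proteins, seed=1, truncated_start_frac=1.0)
        (cid, seq), = contigs
        t = truth[cid]
        assert t.has_start is False
        got = select_orf(Contig(cid, seq))
        assert got.protein == t.protein and got.has_start is False

    def test_roundtrip_and_decoys(self):
        rng = np.random.default_rng(77)
        proteins = [
            (f"p{i}", "M" + "".join(rng.choice(list("ARNDCQEGHILKFPSTWYV"),
                                                size=60)))
            for i in range(15)
        ]
        contigs, truth = make_contigs(proteins, seed=8,
                                      truncated_start_frac=0.2,
                                      short_decoy_frac=0.2)
        n_decoys = sum(t.is_decoy for t in truth.values())
        assert n_decoys == 3
        for cid, seq in contigs:
            t = truth[cid]
            got = select_orf(Contig(cid, seq))
            if t.is_decoy:
                assert got is None and len(seq) < 10
            else:
                assert got.protein == t.protein
                assert (got.nt_start, got.nt_end) == (t.nt_start, t.nt_end)

    def test_deterministic(self):
        proteins = [("p", "MKLWERTYHGADNNQRST")]
        a, _ = make_contigs(proteins, seed=3)
        b, _ = make_contigs(proteins, seed=3)
        assert a == b


class TestMakeProteomes:
    def test_clean_scenario_one_gene_per_species(self):
        sc = SimScenario(n_taxa=4, n_families=6, sites_per_family=60, seed=5)
        proteomes, truth = make_proteomes(sc)
        for sp in sc.species:
            assert len(proteomes[sp]) == 6
        assert len(truth.complete_families) == 6
        assert not truth.paralogs

    def test_total_deletion_leaves_no_complete_family(self):
        sc = SimScenario(n_taxa=3, n_families=5, sites_per_family=50,
                         seed=6, missing_rate=1.0)
        proteomes, truth = make_proteomes(sc)
        assert truth.complete_families == []
        assert len(proteomes[sc.reference_taxon]) == 5  # reference retained

    def test_pair_conservation(self):
        sc = SimScenario(n_taxa=5, n_families=20, sites_per_family=50,
                         seed=7, missing_rate=0.2)
        _, truth = make_proteomes(sc)
        expected = 20 * (5 - 1) - len(truth.deletions)
        assert len(truth.ortholog_pairs) == expected

    def test_rate_classes_follow_multiplier(self):
        sc = SimScenario(n_taxa=4, n_families=10, sites_per_family=50,
                         seed=8, rate_multiplier=4.0, shifted_fraction=0.3)
        _, truth = make_proteomes(sc)
        classes = list(truth.family_rate_class.values())
        assert classes.count("accelerated") == 3
        assert classes.count("clock-like") == 7

    def test_byte_identical_determinism(self):
        sc = SimScenario(n_taxa=4, n_families=5, sites_per_family=40, seed=9)
        a, ta = make_proteomes(sc)
        b, tb = make_proteomes(sc)
        assert a == b
        assert phylo.to_newick(ta.tree) == phylo.to_newick(tb.tree)


class TestInjectGaps:
    def test_gap_fraction(self):
        rows = {"a": "A" * 100, "b": "C" * 100}
        gapped = inject_gaps(rows, 0.3, seed=4)
        cols_hit = sum(
            1 for c in range(100) if any(gapped[t][c] == "-" for t in rows)
        )
        assert cols_hit == 30


class TestMakeGoFixture:
    def test_dag_structure_and_determinism(self):
        fix = make_go_fixture(n_terms=40, max_depth=4, n_genes=100, seed=3)
        assert len({fix.namespaces[r] for r in list(fix.term_parents)[:3]}) == 3
        # every term reaches a root: truth levels are defined for all
        assert set(fix.term_levels) == set(fix.term_parents)
        assert max(fix.term_levels.values()) == 4
        again = make_go_fixture(n_terms=40, max_depth=4, n_genes=100, seed=3)
        assert again.obo_text == fix.obo_text
        assert again.annotations == fix.annotations

    def test_planting_selects_mid_frequency_terms(self):
        fix = make_go_fixture(n_terms=60, max_depth=5, n_genes=300,
                              planted_terms=[("enriched", 10.0),
                                             ("diminished", 10.0)],
                              seed=4, study_size=100)
        assert len(fix.planted) == 2
        directions = {d for d, _ in fix.planted.values()}
        assert directions == {"enriched", "diminished"}
        for term in fix.planted:
            assert fix.term_levels[term] >= 3

    def test_shallow_depth_rejected(self):
        with pytest.raises(SimulationError):
            make_go_fixture(n_terms=30, max_depth=2, n_genes=50, seed=1)
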