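import math

import numpy as np
import pytest

from orthoclock import phylo, synthetic
from orthoclock.phylo import (
    BUILTIN_MODELS,
    PhyloError,
    PhyloModelFit,
    discrete_gamma_rates,
    load_model,
    log_likelihood,
    neighbor_joining,
    optimize_branch_lengths,
    parse_newick,
    protein_distance,
    select_model,
    split_set,
)
from oracles import exhaustive_loglik


class TestSubstitutionModels:
    @pytest.mark.parametrize("name", BUILTIN_MODELS)
    def test_detailed_balance_and_unit_rate(self, name):
        m = load_model(name)
        flux = m.frequencies[:, None] * m.rate_matrix
        assert np.allclose(flux, flux.T, atol=1e-12)
        assert math.isclose(-np.dot(m.frequencies, np.diag(m.rate_matrix)), 1.0,
                            rel_tol=1e-9)

    def test_transition_matrix_rows_are_distributions(self, wag):
        for t in (0.0, 0.01, 0.5, 5.0):
            p = wag.transition_matrix(t)
            assert np.all(p >= 0) and np.allclose(p.sum(axis=1), 1.0)

    @pytest.mark.parametrize("alpha,p_inv", [(0.3, None), (1.5, 0.2), (None, 0.4)])
    def test_rate_mixture_has_unit_mean(self, wag, alpha, p_inv):
        rates, weights = wag.with_rates(alpha=alpha, p_inv=p_inv).rate_mixture()
        assert math.isclose(float(np.dot(rates, weights)), 1.0, abs_tol=1e-9)

    def test_discrete_gamma_mean_one(self):
        for alpha in (0.1, 0.5, 1.0, 7.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert math.isclose(rates.mean(), 1.0, abs_tol=1e-12)
            assert np.all(np.diff(rates) > 0)


class TestProteinDistance:
    def test_identical_rows(self):
        assert protein_distance("MKGA", "MKGA") == 0.0

    def test_poisson_correction(self):
        # p = 0.1 over 10 sites
        a, b = "AAAAAAAAAA", "AAAAAAAAAC"
        assert math.isclose(protein_distance(a, b), -math.log(0.9), rel_tol=1e-12)

    def test_clamp_at_saturation(self):
        a, b = "AAAA", "CCCC"
        assert math.isclose(protein_distance(a, b), -math.log(0.05), rel_tol=1e-12)

    def test_ambiguous_sites_excluded(self):
        assert protein_distance("MXKA", "MCKA") == 0.0
        with pytest.raises(PhyloError):
            protein_distance("XX", "XX")


class TestNeighborJoining:
    def test_additive_four_taxon_metric(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                     dtype=float)
        tree = neighbor_joining(labels, d)
        assert split_set(tree) in ({frozenset({frozenset({"A", "B"})})},
                                   {frozenset({frozenset({"C", "D"})})},
                                   frozenset({frozenset({"A", "B"})}),
                                   frozenset({frozenset({"C", "D"})}))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert math.isclose(pdm.distance(taxa[a], taxa[b]), d[i, j],
                                        abs_tol=1e-9)

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        dab, dac, dbc = 0.4, 0.6, 0.8
        d = np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]])
        tree = neighbor_joining(labels, d)
        tip = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert math.isclose(tip["A"], (dab + dac - dbc) / 2, abs_tol=1e-9)
        assert math.isclose(tip["B"], (dab + dbc - dac) / 2, abs_tol=1e-9)
        assert math.isclose(tip["C"], (dac + dbc - dab) / 2, abs_tol=1e-9)

    def test_rejects_asymmetric_input(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(PhyloError):
            neighbor_joining(["A", "B", "C"], d)

    def test_recovers_simulated_topology(self, wag, small_tree5):
        rows = synthetic.evolve_alignment(small_tree5, wag, 1500, seed=31)
        labels, d = phylo.distance_matrix(rows)
        tree = neighbor_joining(labels, d)
        assert split_set(tree) == split_set(small_tree5)


class TestLogLikelihood:
    def test_zero_branch_two_taxa_is_log_pi(self, wag):
        tree = parse_newick("(A:0.0,B:0.0);")
        lnl = log_likelihood({"A": "M", "B": "M"}, tree, wag)
        m_idx = phylo.AA_ORDER.index("M")
        assert math.isclose(lnl, math.log(wag.frequencies[m_idx]), rel_tol=1e-9)

    def test_matches_exhaustive_summation(self, wag):
        tree = parse_newick("((A:0.12,B:0.23):0.08,(C:0.3,D:0.05):0.17);")
        rows = {"A": "MKX", "B": "MLA", "C": "QKA", "D": "MKA"}
        assert math.isclose(
            log_likelihood(rows, tree, wag),
            exhaustive_loglik(tree, rows, wag),
            rel_tol=1e-10,
        )

    def test_pulley_principle(self, wag):
        rows = {"A": "MKGW", "B": "MLGW", "C": "QKAW", "D": "MKAF"}
        t1 = parse_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05);")
        t2 = parse_newick("((A:0.1,B:0.2):0.02,(C:0.3,D:0.1):0.18);")
        assert math.isclose(log_likelihood(rows, t1, wag),
                            log_likelihood(rows, t2, wag), abs_tol=1e-8)

    def test_invariant_to_row_order(self, wag):
        tree = parse_newick("((A:0.1,B:0.2):0.15,C:0.3);")
        rows = {"A": "MKGW", "B": "MLGW", "C": "QKAW"}
        rev = dict(reversed(list(rows.items())))
        assert log_likelihood(rows, tree, wag) == log_likelihood(rev, tree, wag)

    def test_gap_rejected(self, wag):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(PhyloError):
            log_likelihood({"A": "M-", "B": "MK"}, tree, wag)

    def test_mixture_likelihood_changes_with_alpha(self, wag):
        tree = parse_newick("((A:0.1,B:0.2):0.15,C:0.3);")
        rows = {"A": "MKGWMKGW", "B": "MLGWMLGW", "C": "QKAWQKAW"}
        plain = log_likelihood(rows, tree, wag)
        gamma = log_likelihood(rows, tree, wag.with_rates(alpha=0.3))
        assert plain != gamma


class TestBranchOptimization:
    def test_never_decreases_likelihood(self, wag, small_tree5):
        rows = synthetic.evolve_alignment(small_tree5, wag, 300, seed=7)
        start = log_likelihood(rows, small_tree5, wag)
        fit = optimize_branch_lengths(rows, small_tree5, wag)
        assert fit.lnL >= start - 1e-9

    def test_duplicate_rows_drive_path_to_zero(self, wag):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.3);")
        rows = synthetic.evolve_alignment(tree, wag, 400, seed=3)
        rows["B"] = rows["A"]
        fit = optimize_branch_lengths(rows, tree, wag)
        path = sum(
            lf.edge.length for lf in fit.tree.leaf_node_iter()
            if lf.taxon.label in ("A", "B")
        )
        assert path < 1e-3

    def test_free_param_count(self, wag):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.3);")
        rows = {"A": "MKGW", "B": "MLGW", "C": "QKAW"}
        fit = optimize_branch_lengths(rows, tree, wag)
        assert fit.n_free_params == 4  # 4 edges, no model parameters


class TestModelSelection:
    def test_aic_formula(self, wag):
        fit = PhyloModelFit(tree=None, model=wag, lnL=-100.0, n_free_params=2)
        assert fit.aic == 204.0

    def test_higher_likelihood_wins_at_equal_k(self, wag, small_tree5):
        rows = synthetic.evolve_alignment(small_tree5, wag, 600, seed=17)
        fits = select_model(
            rows, small_tree5,
            candidates=[("WAG", False, False, False),
                        ("Dayhoff", False, False, False)],
        )
        assert fits[0].aic <= fits[1].aic
        assert fits[0].model.name == "WAG"

    def test_gamma_model_recovered(self, wag, small_tree5):
        # simulate rate heterogeneity by category blocks (alpha = 0.5)
        rates = discrete_gamma_rates(0.5, 4)
        rows = {lf.taxon.label: "" for lf in small_tree5.leaf_node_iter()}
        for ci, r in enumerate(rates):
            scaled = small_tree5.clone(depth=1)
            for e in scaled.preorder_edge_iter():
                if e.length:
                    e.length *= r
            part = synthetic.evolve_alignment(scaled, wag, 250, seed=40 + ci)
            for k in rows:
                rows[k] += part[k]
        fits = select_model(
            rows, small_tree5,
            candidates=[("WAG", False, True, False),
                        ("WAG", False, False, False)],
        )
        assert fits[0].model.alpha is not None
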