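import numpy as np
import pytest
from scipy.linalg import expm

from _oracles import (
    enumerate_column_likelihood,
    random_column,
    random_model,
    random_tree,
)
from paleoref import asr, phylo, simulate
from paleoref.phylo import (
    PhyloTree,
    PruningEngine,
    SubstitutionModel,
    build_rate_matrix,
    column_log_likelihood,
    encode_columns,
    estimate_model_params,
    gamma_category_rates,
    optimize_branch_lengths,
    site_patterns,
    transition_matrix,
)


class TestRateMatrix:
    def test_jc69(self):
        rm = build_rate_matrix(SubstitutionModel.jc69())
        off = rm.Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 3)
        assert np.allclose(np.diag(rm.Q), -1)

    def test_hky_kappa1_equals_jc(self):
        rm1 = build_rate_matrix(SubstitutionModel.hky85(kappa=1.0))
        rm2 = build_rate_matrix(SubstitutionModel.jc69())
        assert np.allclose(rm1.Q, rm2.Q)

    def test_detailed_balance_random_gtr(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = random_model(rng, gamma=False)
            rm = build_rate_matrix(m)
            flux = m.base_freqs[:, None] * rm.Q
            assert np.abs(flux - flux.T).max() < 1e-12
            assert np.abs(rm.Q.sum(axis=1)).max() < 1e-12
            assert abs(-np.dot(m.base_freqs, np.diag(rm.Q)) - 1.0) < 1e-12

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError):
            SubstitutionModel("GTR", np.ones(6), np.array([0.5, 0.5, 0.0, 0.0]))


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        rm = build_rate_matrix(SubstitutionModel.jc69())
        assert np.allclose(transition_matrix(rm, 0.0), np.eye(4), atol=1e-12)

    def test_jc69_closed_form(self):
        rm = build_rate_matrix(SubstitutionModel.jc69())
        for t in (0.01, 0.3, 1.0, 5.0):
            P = transition_matrix(rm, t)
            p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
            assert np.abs(np.diag(P) - p_same).max() < 1e-12

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(3)
        rm = build_rate_matrix(random_model(rng, gamma=False))
        P = transition_matrix
        assert np.abs(P(rm, 0.1) @ P(rm, 0.2) - P(rm, 0.3)).max() < 1e-10

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        rm = build_rate_matrix(random_model(rng, gamma=False))
        for t in (0.0, 0.05, 2.0, 19.0):
            P = transition_matrix(rm, t)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
            assert P.min() >= 0 and P.max() <= 1

    def test_matches_expm(self):
        rng = np.random.default_rng(5)
        rm = build_rate_matrix(random_model(rng, gamma=False))
        assert np.abs(transition_matrix(rm, 0.7) - expm(rm.Q * 0.7)).max() < 1e-10

    def test_negative_t_error(self):
        rm = build_rate_matrix(SubstitutionModel.jc69())
        with pytest.raises(ValueError):
            transition_matrix(rm, -0.1)


class TestGammaRates:
    def test_single_category(self):
        assert list(gamma_category_rates(0.5, 1)) == [1.0]

    @pytest.mark.parametrize("alpha", [0.05, 0.3, 1.0, 7.5])
    def test_mean_one(self, alpha):
        rates = gamma_category_rates(alpha, 4)
        assert abs(rates.mean() - 1.0) < 1e-10
        assert np.all(rates > 0)
        assert np.all(np.diff(rates) >= 0)

    def test_large_alpha_concentrates(self):
        rates = gamma_category_rates(10_000, 4)
        assert np.abs(rates - 1).max() < 0.05


class TestColumnLikelihood:
    def test_single_leaf(self):
        tree = PhyloTree.from_newick("(A:0.0)R;")
        # degenerate: root with one child at distance 0
        m = SubstitutionModel.gtr([1, 1, 1, 1, 1, 1], [0.4, 0.3, 0.2, 0.1])
        ll = column_log_likelihood(tree, m, {"A": "A"})
        assert ll == pytest.approx(np.log(0.4), abs=1e-10)

    def test_two_leaf_brute_force(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1)R;")
        m = SubstitutionModel.jc69()
        rm = build_rate_matrix(m)
        P = transition_matrix(rm, 0.1)
        expected = np.log(sum(0.25 * P[x, 0] ** 2 for x in range(4)))
        assert column_log_likelihood(tree, m, {"A": "A", "B": "A"}) == pytest.approx(
            expected, abs=1e-12
        )

    def test_all_missing_is_zero(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2,C:0.3)R;")
        ll = column_log_likelihood(tree, SubstitutionModel.jc69(), {"A": "N", "B": "-"})
        assert abs(ll) < 1e-12

    def test_unknown_species_error(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2)R;")
        with pytest.raises(ValueError):
            column_log_likelihood(tree, SubstitutionModel.jc69(), {"Z": "A"})

    def test_pruning_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(2, 6)))
            model = random_model(rng, gamma=bool(rng.integers(0, 2)))
            col = random_column(rng, tree.leaf_labels)
            ll = column_log_likelihood(tree, model, col)
            oracle = np.log(enumerate_column_likelihood(tree, model, col))
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_pulley_principle(self):
        # reversible models: shifting length between the root's two child
        # branches leaves the likelihood unchanged
        rng = np.random.default_rng(12)
        model = random_model(rng, gamma=True)
        col = {"A": "A", "B": "C", "C": "G", "D": "T"}
        lls = []
        for delta in (0.0, 0.05, 0.12):
            tree = PhyloTree.from_newick(
                f"((A:0.1,B:0.2)U:{0.15 - delta},(C:0.1,D:0.3)V:{0.15 + delta})R;"
            )
            lls.append(column_log_likelihood(tree, model, col))
        assert np.abs(np.diff(lls)).max() < 1e-10

    def test_order_invariance_and_multiplicativity(self):
        rng = np.random.default_rng(13)
        tree = random_tree(rng, 4)
        model = random_model(rng, gamma=True)
        cols = [random_column(rng, tree.leaf_labels) for _ in range(6)]
        mat = encode_columns(cols, tree.leaf_labels)
        engine = PruningEngine(tree, model, tree.leaf_labels)
        lls = engine.site_log_likelihoods(mat)
        perm = np.array([3, 1, 5, 0, 2, 4])
        lls_perm = engine.site_log_likelihoods(mat[perm])
        assert np.allclose(lls[perm], lls_perm, atol=1e-12)
        total = engine.log_likelihood(mat, np.ones(6))
        assert total == pytest.approx(lls.sum(), abs=1e-10)


class TestBranchLengthOptimization:
    def test_zero_variation_hits_lower_bound(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.1)N1:0.1,C:0.1)R;")
        mat = encode_columns(
            [{"A": "G", "B": "G", "C": "G"}] * 50, tree.leaf_labels
        )
        patterns, weights = site_patterns(mat)
        est = optimize_branch_lengths(tree, SubstitutionModel.jc69(), patterns, weights)
        for length in est.branch_lengths().values():
            assert length < 1e-4

    def test_deterministic(self):
        rng = np.random.default_rng(21)
        tree = random_tree(rng, 4)
        model = random_model(rng, gamma=False)
        cols = [random_column(rng, tree.leaf_labels) for _ in range(30)]
        mat = encode_columns(cols, tree.leaf_labels)
        patterns, weights = site_patterns(mat)
        est1 = optimize_branch_lengths(tree, model, patterns, weights)
        est2 = optimize_branch_lengths(tree, model, patterns, weights)
        assert est1.branch_lengths() == est2.branch_lengths()

    def test_recovery_improves_with_data(self):
        tree = PhyloTree.from_newick("((A:0.05,B:0.05)N1:0.02,C:0.1,D:0.1)R;")
        model = SubstitutionModel.jc69()
        errors = []
        for n in (10_000, 100_000):
            sim = simulate.evolve_clade(tree, model, n, seed=5)
            mat = asr.block_code_matrix(sim.truth_maf[0], tree.leaf_labels)
            patterns, weights = site_patterns(mat)
            start = tree.copy()
            for node in start.postorder():
                if node.parent is not None:
                    node.length = 0.05
            est = optimize_branch_lengths(start, model, patterns, weights)
            truth = tree.branch_lengths()
            est_l = est.branch_lengths()
            errors.append(sum(abs(est_l[k] - truth[k]) for k in truth))
        assert errors[1] < errors[0]

    def test_empty_alignment_error(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1)R;")
        with pytest.raises(ValueError):
            optimize_branch_lengths(
                tree, SubstitutionModel.jc69(), np.empty((0, 2), dtype=np.uint8),
                np.empty(0),
            )


class TestModelEstimation:
    def test_jc_data_gives_uniform_freqs(self):
        tree = PhyloTree.from_newick("((A:0.05,B:0.05)N1:0.02,C:0.1,D:0.1)R;")
        sim = simulate.evolve_clade(tree, SubstitutionModel.jc69(), 50_000, seed=2)
        mat = asr.block_code_matrix(sim.truth_maf[0], tree.leaf_labels)
        patterns, weights = site_patterns(mat)
        est = estimate_model_params(tree, patterns, weights, "GTR", gamma=False)
        assert np.abs(est.base_freqs - 0.25).max() < 0.01

    def test_hky_nested_in_gtr(self):
        tree = PhyloTree.from_newick("((A:0.05,B:0.05)N1:0.02,C:0.1,D:0.1)R;")
        gen = SubstitutionModel.gtr([0.5, 3, 1.5, 0.8, 2, 1], [0.3, 0.2, 0.2, 0.3])
        sim = simulate.evolve_clade(tree, gen, 20_000, seed=3)
        mat = asr.block_code_matrix(sim.truth_maf[0], tree.leaf_labels)
        patterns, weights = site_patterns(mat)
        hky = estimate_model_params(tree, patterns, weights, "HKY85", gamma=False)
        gtr = estimate_model_params(tree, patterns, weights, "GTR", gamma=False)
        assert hky.family == "HKY85"
        eng_h = PruningEngine(tree, hky, tree.leaf_labels)
        eng_g = PruningEngine(tree, gtr, tree.leaf_labels)
        ll_h = eng_h.log_likelihood(patterns, weights)
        ll_g = eng_g.log_likelihood(patterns, weights)
        assert ll_h <= ll_g + 1e-6


class TestTree:
    def test_newick_roundtrip_preserves_labels(self):
        nw = "((A:0.1,B:0.2)N1:0.05,(C:0.3,D:0.4)N2:0.05)R;"
        tree = PhyloTree.from_newick(nw)
        assert tree.to_newick() == nw
        assert tree.internal_labels == ["N1", "N2", "R"]

    def test_auto_labels_unlabelled_internals(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        assert len(tree.internal_labels) == 2
        assert len(set(tree.internal_labels)) == 2

    def test_prune_leaf_collapses_unary(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.2)N1:0.05,C:0.3)R;")
        pruned = tree.prune_leaf("A")
        assert sorted(pruned.leaf_labels) == ["B", "C"]
        # B's branch absorbs N1's
        assert pruned.node("B").length == pytest.approx(0.25)
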