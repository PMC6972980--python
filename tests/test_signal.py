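"""Signal indices: closed forms, oracles, invariances, calibration.

Frozen cross-implementation values were computed with independent reference
implementations (ape's Moran.I on the row-normalized weight matrix,
phytools' phylosig for Blomberg's K and Pagel's lambda) on the 8-tip oracle
tree in conftest.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phylossd as ps
from conftest import ORACLE_NEWICK, morans_i_bruteforce, random_trees

# values frozen from ape 5.8-1 / phytools 2.5-2 on (ORACLE_NEWICK, ORACLE_TRAITS)
APE_MORAN_ROWNORM = 0.081354244206
PHYTOOLS_BLOMBERG_K = 1.321372462572
PHYTOOLS_LAMBDA = 1.201566913169
PHYTOOLS_LAMBDA_LOGLIK = -11.875471758130


def _weights(tree):
    return ps.weights_from_distances(ps.cophenetic_matrix(tree))


class TestWeights:
    def test_reciprocal(self):
        W = _weights(ps.parse_newick("(A:2,B:3);"))
        assert W.w[0, 1] == pytest.approx(0.2)

    def test_star_tree_uniform(self):
        W = _weights(ps.parse_newick("(A:1,B:1,C:1,D:1);"))
        off = W.w[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.5)

    def test_zero_distance_default_error_and_epsilon_policy(self):
        tree = ps.parse_newick("((A:0,B:0):1,C:1);")
        D = ps.cophenetic_matrix(tree)
        with pytest.raises(ps.ValidationError, match="zero patristic"):
            ps.weights_from_distances(D)
        W = ps.weights_from_distances(D, zero_policy="epsilon")
        assert np.isfinite(W.w).all() and W.w.max() > 0


class TestMoransI:
    def test_two_tips_closed_form_minus_one(self):
        W = _weights(ps.parse_newick("(A:1,B:4);"))
        assert ps.morans_i([0.0, 7.3], W) == pytest.approx(-1.0)

    def test_constant_traits_rejected(self):
        W = _weights(ps.parse_newick("(A:1,B:1,C:1);"))
        with pytest.raises(ps.ValidationError, match="zero trait variance"):
            ps.morans_i([2.0, 2.0, 2.0], W)

    def test_matches_double_loop_oracle_on_random_instances(self):
        """100 random (tree, trait) pairs against the brute-force summation."""
        rng = np.random.default_rng(42)
        for tree in random_trees(100, max_tips=25, seed=13):
            W = _weights(tree)
            y = rng.standard_normal(tree.n_tips)
            assert ps.morans_i(y, W) == pytest.approx(
                morans_i_bruteforce(y, W.w), abs=1e-12
            )

    def test_matches_ape_on_rownormalized_weights(self, oracle_tree, oracle_traits):
        W = _weights(oracle_tree)
        wn = W.w / W.w.sum(axis=1, keepdims=True)
        assert ps.morans_i(oracle_traits, wn) == pytest.approx(
            APE_MORAN_ROWNORM, abs=1e-9
        )

    def test_null_expectation_diagnostic(self):
        assert ps.morans_i_expectation(8) == pytest.approx(-1 / 7)

    @given(
        a=st.floats(-50, 50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b, oracle_tree, oracle_traits):
        W = _weights(oracle_tree)
        base = ps.morans_i(oracle_traits, W)
        assert ps.morans_i(a * oracle_traits + b, W) == pytest.approx(base, abs=1e-10)

    def test_relabeling_invariance(self, oracle_tree, oracle_traits):
        W = _weights(oracle_tree)
        base = ps.morans_i(oracle_traits, W)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(oracle_traits))
        assert ps.morans_i(oracle_traits[perm], W.w[np.ix_(perm, perm)]) == pytest.approx(
            base, abs=1e-12
        )

    def test_branch_length_scaling_invariance(self, oracle_traits):
        tree = ps.parse_newick(ORACLE_NEWICK)
        base = ps.morans_i(oracle_traits, _weights(tree))
        scaled_tree = tree.copy()
        for edge in scaled_tree.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 3.0
        scaled = ps.morans_i(oracle_traits, _weights(scaled_tree))
        assert scaled == pytest.approx(base, abs=1e-10)


class TestPermutationTest:
    def test_reproducible_given_seed(self, oracle_tree, oracle_traits):
        W = _weights(oracle_tree)
        r1 = ps.morans_i_test(oracle_traits, W, n_perm=299, seed=17)
        r2 = ps.morans_i_test(oracle_traits, W, n_perm=299, seed=17)
        assert (r1.value, r1.p_value) == (r2.value, r2.p_value)

    def test_p_never_below_add_one_floor(self, oracle_tree, oracle_traits):
        W = _weights(oracle_tree)
        res = ps.morans_i_test(oracle_traits, W, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_generic_engine_agrees_with_vectorized_path(self, oracle_tree, oracle_traits):
        W = _weights(oracle_tree)
        fast = ps.morans_i_test(oracle_traits, W, n_perm=199, seed=5)
        slow = ps.permutation_test(
            oracle_traits, lambda y: ps.morans_i(y, W),
            index_name="moran_i", n_perm=199, seed=5,
        )
        assert fast.value == pytest.approx(slow.value)
        assert fast.p_value == pytest.approx(slow.p_value)

    def test_invalid_alternative_rejected(self, oracle_tree, oracle_traits):
        W = _weights(oracle_tree)
        with pytest.raises(ps.ValidationError, match="alternative"):
            ps.morans_i_test(oracle_traits, W, n_perm=99, seed=0, alternative="weird")

    def test_null_centered_stat_gives_middling_p(self):
        """iid traits on a star tree sit near the permutation median."""
        tree = ps.parse_newick("(" + ",".join(f"t{i}:1" for i in range(40)) + ");")
        W = _weights(tree)
        rng = np.random.default_rng(8)
        ps_vals = [
            ps.morans_i_test(rng.standard_normal(40), W, n_perm=199, seed=i).p_value
            for i in range(20)
        ]
        assert 0.2 < np.mean(ps_vals) < 0.8

    def test_type_i_error_calibration(self):
        """Rejection rate of iid traits on random 30-tip trees stays within
        the exact binomial 99% band around alpha = 0.05 (1000 replicates)."""
        from scipy.stats import binom

        alpha = 0.05
        B = 1000
        rng = np.random.default_rng(123)
        rejections = 0
        for rep in range(B):
            model = "yule" if rep % 2 == 0 else "coalescent"
            tree = ps.random_tree(ps.SimulationConfig(
                n_tips=30, tree_model=model, seed=int(rng.integers(2**31 - 1))
            ))
            W = _weights(tree)
            y = rng.standard_normal(30)
            res = ps.morans_i_test(y, W, n_perm=199, seed=rep)
            rejections += res.p_value <= alpha
        lo = binom.ppf(0.005, B, alpha)
        hi = binom.ppf(0.995, B, alpha)
        assert lo <= rejections <= hi, f"{rejections} outside [{lo}, {hi}]"


class TestAbouheif:
    def test_proximity_hand_computed_three_tips(self):
        # ((A,B),C): raw proximities A-B = 1/2, A-C = B-C = 1/4;
        # row-normalized and symmetrized: A-B = 2/3, A-C = B-C = 5/12
        tree = ps.parse_newick("((A:1,B:1):1,C:1);")
        A = ps.abouheif_proximity(tree)
        idx = {l: i for i, l in enumerate(A.labels)}
        assert A.w[idx["A"], idx["B"]] == pytest.approx(2 / 3)
        assert A.w[idx["A"], idx["C"]] == pytest.approx(5 / 12)
        assert A.w[idx["B"], idx["C"]] == pytest.approx(5 / 12)

    def test_reduces_to_morans_i_under_same_weights(self, oracle_tree, oracle_traits):
        A = ps.abouheif_proximity(oracle_tree)
        assert ps.abouheif_cmean(oracle_traits, oracle_tree) == pytest.approx(
            ps.morans_i(oracle_traits, A), abs=1e-14
        )

    def test_two_tips_degenerate_minus_one(self):
        tree = ps.parse_newick("(A:1,B:1);")
        assert ps.abouheif_cmean([1.0, 4.0], tree) == pytest.approx(-1.0)

    def test_topology_only_ignores_branch_lengths(self, oracle_traits):
        a = ps.abouheif_cmean(oracle_traits, ps.parse_newick(ORACLE_NEWICK))
        stretched = ORACLE_NEWICK.replace(":1.5", ":9").replace(":0.8", ":0.01")
        b = ps.abouheif_cmean(oracle_traits, ps.parse_newick(stretched))
        assert a == pytest.approx(b, abs=1e-12)


class TestBlombergK:
    def test_matches_phytools_on_oracle_tree(self, oracle_tree, oracle_traits):
        assert ps.blomberg_k(oracle_traits, oracle_tree) == pytest.approx(
            PHYTOOLS_BLOMBERG_K, abs=1e-9
        )

    def test_constant_traits_rejected(self, oracle_tree):
        with pytest.raises(ps.ValidationError):
            ps.blomberg_k(np.ones(8), oracle_tree)

    def test_centered_at_one_under_brownian_motion(self):
        """Mean K over 500 BM simulations on the generating tree is ~1."""
        vals = []
        rng = np.random.default_rng(21)
        for rep in range(500):
            cfg = ps.SimulationConfig(
                n_tips=20, trait_model="bm", seed=int(rng.integers(2**31 - 1))
            )
            tree = ps.random_tree(cfg)
            y = ps.simulate_traits(tree, cfg)
            vals.append(ps.blomberg_k(y, tree))
        assert 0.85 <= np.mean(vals) <= 1.15


class TestPagelLambda:
    def test_matches_phytools_on_oracle_tree(self, oracle_tree, oracle_traits):
        lam, ll, _ = ps.pagel_lambda(oracle_traits, oracle_tree)
        assert lam == pytest.approx(PHYTOOLS_LAMBDA, abs=1e-3)
        assert ll == pytest.approx(PHYTOOLS_LAMBDA_LOGLIK, abs=1e-6)

    def test_iid_traits_on_star_tree_hit_zero_boundary(self):
        tree = ps.parse_newick("(" + ",".join(f"t{i}:1" for i in range(30)) + ");")
        rng = np.random.default_rng(4)
        lam, _, p = ps.pagel_lambda(rng.standard_normal(30), tree)
        assert lam == pytest.approx(0.0, abs=1e-4)
        assert p == pytest.approx(1.0)

    def test_recovers_lambda_one_under_bm(self):
        """Mean MLE over 200 BM replicates at n = 50 lands near 1."""
        vals = []
        rng = np.random.default_rng(31)
        for rep in range(200):
            cfg = ps.SimulationConfig(
                n_tips=50, trait_model="bm", seed=int(rng.integers(2**31 - 1))
            )
            tree = ps.random_tree(cfg)
            y = ps.simulate_traits(tree, cfg)
            lam, _, _ = ps.pagel_lambda(tree=tree, traits=y)
            vals.append(lam)
        assert 0.85 <= np.mean(vals) <= 1.05


class TestCorrelogram:
    def test_strong_signal_decays_with_distance(self):
        """Under BM the closest distance class carries more autocorrelation
        than the farthest in nearly all simulations."""
        rng = np.random.default_rng(77)
        wins = 0
        total = 200
        for rep in range(total):
            cfg = ps.SimulationConfig(
                n_tips=30, trait_model="bm", seed=int(rng.integers(2**31 - 1))
            )
            tree = ps.random_tree(cfg)
            y = ps.simulate_traits(tree, cfg)
            D = ps.cophenetic_matrix(tree)
            cg = ps.correlogram(y, D, n_classes=4, n_perm=99, seed=rep)
            ok = ~np.isnan(cg.class_I)
            first = np.flatnonzero(ok)[0]
            last = np.flatnonzero(ok)[-1]
            wins += cg.class_I[first] > cg.class_I[last]
        assert wins / total >= 0.90

    def test_envelope_calibration_under_iid(self):
        """With iid traits roughly `level` of class flags come out 'none'."""
        rng = np.random.default_rng(55)
        flags = []
        for rep in range(100):
            cfg = ps.SimulationConfig(
                n_tips=25, trait_model="iid", seed=int(rng.integers(2**31 - 1))
            )
            tree = ps.random_tree(cfg)
            y = ps.simulate_traits(tree, cfg)
            D = ps.cophenetic_matrix(tree)
            cg = ps.correlogram(y, D, n_classes=4, n_perm=99, seed=rep, level=0.95)
            flags.extend(f for f in cg.class_flag if f != "empty")
        frac_none = np.mean([f == "none" for f in flags])
        assert 0.85 <= frac_none <= 1.0

    def test_classes_partition_distance_range(self, oracle_tree, oracle_traits):
        D = ps.cophenetic_matrix(oracle_tree)
        cg = ps.correlogram(oracle_traits, D, n_classes=3, n_perm=99, seed=0)
        assert cg.class_bounds[0] == 0.0
        assert cg.class_bounds[-1] == pytest.approx(D.off_diagonal().max())
        assert np.all(np.diff(cg.class_bounds) >= 0)
        assert len(cg.class_flag) == 3

    def test_sparse_class_flagged_empty_not_error(self):
        tree = ps.parse_newick("((A:1,B:1):10,(C:1,D:1):10);")
        D = ps.cophenetic_matrix(tree)
        cg = ps.correlogram([0.1, 0.4, 2.2, 2.9], D, n_classes=3, n_perm=99, seed=0)
        assert "empty" in cg.class_flag
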