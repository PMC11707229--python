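"""Association tests, parsimony, Mk likelihoods and the coevolution LRT."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from quinrep.phylostats import (
    TreeIndex,
    build_dependent_q,
    dependent_loglik,
    fitch_parsimony,
    g_statistic,
    joint_states,
    metabolism_by_repertoire,
    mk_loglik,
    pagel_discrete_lrt,
    permutation_association_test,
    phylo_signal_test,
    subsample_species,
)
from quinrep.simulate import make_yule_tree, simulate_discrete_trait

from oracles import mk_loglik_enumeration, sankoff_min_changes


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestGStatistic:
    def test_diagonal_table_by_hand(self):
        # 2*(10 ln2 * 2 + ...) for [[10,0],[0,10]]: every cell O/E = 2 or 0
        assert g_statistic([[10, 0], [0, 10]]) == pytest.approx(40 * math.log(2))
        assert g_statistic([[10, 0], [0, 10]]) == pytest.approx(27.726, abs=1e-3)

    def test_proportional_table_is_zero(self):
        assert g_statistic([[10, 20], [5, 10]]) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 30, size=(3, 4))
            assert g_statistic(t) >= -1e-12


class TestPermutationTest:
    def test_perfect_association_reaches_floor(self):
        ids = [f"g{i}" for i in range(40)]
        a = {g: i % 2 for i, g in enumerate(ids)}
        res = permutation_association_test(a, a, n_perm=1000, seed=0)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_constant_trait_gives_g_zero_p_one(self):
        ids = [f"g{i}" for i in range(30)]
        a = {g: i % 3 for i, g in enumerate(ids)}
        b = {g: "x" for g in ids}
        res = permutation_association_test(a, b, n_perm=200, seed=1)
        assert res.statistic == pytest.approx(0.0) and res.p_value == 1.0

    def test_disjoint_genome_sets_error(self):
        with pytest.raises(ValueError, match="disjoint"):
            permutation_association_test({"a": 1}, {"b": 1})

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(60)]
        a = dict(zip(ids, rng.integers(0, 3, 60)))
        b = dict(zip(ids, rng.integers(0, 4, 60)))
        r1 = permutation_association_test(a, b, n_perm=300, seed=9)
        r2 = permutation_association_test(a, b, n_perm=300, seed=9)
        assert r1.p_value == r2.p_value


class TestFitch:
    def test_four_tip_example_by_hand(self):
        tree = newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert fitch_parsimony(tree, {"A": 0, "B": 0, "C": 1, "D": 1}) == 1

    def test_constant_trait_no_changes(self):
        tree = newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert fitch_parsimony(tree, {t: "x" for t in "ABCD"}) == 0

    def test_equals_sankoff_on_random_trees(self):
        rng = np.random.default_rng(2)
        for rep in range(40):
            n = int(rng.integers(4, 9))
            tree = make_yule_tree(n, seed=100 + rep)
            tips = [t.label for t in tree.taxon_namespace]
            k = int(rng.integers(2, 4))
            trait = {t: int(rng.integers(k)) for t in tips}
            assert fitch_parsimony(tree, trait) == sankoff_min_changes(tree, trait)


class TestSignalTest:
    def test_clustered_trait_is_significant(self):
        tree = make_yule_tree(64, seed=3)
        ti = TreeIndex(tree)
        # paint one clade of >= 8 tips
        node = next(
            nd for nd in tree.postorder_internal_node_iter()
            if 8 <= len(nd.leaf_nodes()) <= 32
        )
        clade = {lf.taxon.label for lf in node.leaf_nodes()}
        trait = {t: int(t in clade) for t in ti.tip_index}
        res = phylo_signal_test(ti, trait, n_rand=10_000, seed=0)
        assert res.statistic == 1.0
        assert res.p_value <= 0.001

    def test_constant_trait_p_one(self):
        tree = make_yule_tree(16, seed=4)
        res = phylo_signal_test(tree, {t.label: "a" for t in tree.taxon_namespace},
                                n_rand=500, seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_null_rejection_rate_conservative(self):
        """Shuffled traits are rejected at most ~alpha of the time (the
        permutation p-value is valid, i.e. conservative under ties)."""
        tree = make_yule_tree(40, seed=5)
        ti = TreeIndex(tree)
        tips = sorted(ti.tip_index)
        rng = np.random.default_rng(6)
        alpha, n_rep = 0.05, 120
        rejections = 0
        base = np.array([0] * 20 + [1] * 20)
        for _ in range(n_rep):
            rng.shuffle(base)
            trait = dict(zip(tips, base.tolist()))
            res = phylo_signal_test(ti, trait, n_rand=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= alpha
        # binomial 3-sigma upper bound around alpha
        assert rejections / n_rep <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_rep)


class TestMkLikelihood:
    def test_two_tip_star_closed_form(self):
        t, a = 0.8, 0.6
        tree = newick(f"(A:{t},B:{t});")
        ll = mk_loglik(tree, {"A": 0, "B": 0}, a, a)
        p00 = 0.5 + 0.5 * math.exp(-2 * a * t)
        p10 = 0.5 - 0.5 * math.exp(-2 * a * t)
        assert math.exp(ll) == pytest.approx(0.5 * (p00**2 + p10**2), abs=1e-14)

    def test_short_branch_limit(self):
        tree = newick("(A:1e-9,B:1e-9);")
        ll = mk_loglik(tree, {"A": 0, "B": 0}, 0.6, 0.6)
        assert math.exp(ll) == pytest.approx(0.5, abs=1e-6)

    def test_equals_enumeration_on_small_trees(self):
        rng = np.random.default_rng(7)
        for rep in range(100):
            n = int(rng.integers(3, 7))
            tree = make_yule_tree(n, seed=200 + rep)
            ti = TreeIndex(tree)
            trait = {t: int(rng.integers(2)) for t in ti.tip_index}
            q01, q10 = rng.uniform(0.05, 2.0, size=2)
            ll = mk_loglik(ti, trait, q01, q10)
            oracle = mk_loglik_enumeration(ti, trait, q01, q10)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_invariant_under_child_order(self):
        t1 = newick("((A:1,B:2):0.5,C:3);")
        t2 = newick("(C:3,(B:2,A:1):0.5);")
        trait = {"A": 0, "B": 1, "C": 1}
        assert mk_loglik(t1, trait, 0.3, 0.7) == pytest.approx(
            mk_loglik(t2, trait, 0.3, 0.7), abs=1e-12
        )


class TestDependentModel:
    def test_independent_embedding_factorizes(self):
        tree = make_yule_tree(40, seed=8)
        ti = TreeIndex(tree)
        a, _ = simulate_discrete_trait(tree, rates=(0.5, 0.3), seed=1)
        b, _ = simulate_discrete_trait(tree, rates=(0.2, 0.6), seed=2)
        lla = mk_loglik(ti, a, 0.5, 0.3)
        llb = mk_loglik(ti, b, 0.2, 0.6)
        rates = dict(
            q12=0.2, q13=0.5, q21=0.6, q24=0.5, q31=0.3, q34=0.2, q42=0.3, q43=0.6
        )
        lld = dependent_loglik(ti, joint_states(a, b), rates)
        assert lld == pytest.approx(lla + llb, abs=1e-10)

    def test_double_transitions_forbidden(self):
        Q = build_dependent_q(dict.fromkeys(
            ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43"), 1.0
        ))
        assert Q[0, 3] == 0 and Q[3, 0] == 0 and Q[1, 2] == 0 and Q[2, 1] == 0
        assert np.allclose(Q.sum(axis=1), 0)

    def test_lrt_nesting_and_reproducibility(self):
        tree = make_yule_tree(60, seed=9)
        ti = TreeIndex(tree)
        a, _ = simulate_discrete_trait(tree, rates=(0.4, 0.4), seed=3)
        b, _ = simulate_discrete_trait(tree, rates=(0.4, 0.4), seed=4)
        res = pagel_discrete_lrt(ti, a, b, n_starts=2, seed=0)
        assert res.details["loglik_dependent"] >= res.details["loglik_independent"] - 1e-6
        res2 = pagel_discrete_lrt(ti, a, b, n_starts=2, seed=0)
        assert res.statistic == pytest.approx(res2.statistic, abs=1e-9)

    def test_missing_tip_trait_errors(self):
        tree = make_yule_tree(8, seed=10)
        ti = TreeIndex(tree)
        tips = sorted(ti.tip_index)
        a = {t: 0 for t in tips}
        b = {t: 0 for t in tips[:-1]}
        with pytest.raises(ValueError, match="missing"):
            pagel_discrete_lrt(ti, a, b, n_starts=2, seed=0)


class TestMetabolismByRepertoire:
    def test_proportions_by_hand(self):
        presence = pd.DataFrame(
            {"UQ": [True] * 4, "Men": [False] * 4}, index=list("abcd")
        )
        met = {"a": "aerobic", "b": "aerobic", "c": "aerobic", "d": "facultative"}
        df = metabolism_by_repertoire(presence, met)
        row = df.iloc[0]
        assert row.combination == "UQ" and row.n_species == 4
        assert row.aerobic == pytest.approx(0.75)
        assert row.facultative == pytest.approx(0.25)
        assert row.microaerophilic == 0 and row.anaerobic == 0

    def test_rows_sum_to_one_and_sorting(self):
        rng = np.random.default_rng(11)
        n = 80
        ids = [f"g{i}" for i in range(n)]
        presence = pd.DataFrame(
            {
                "UQ": rng.integers(0, 2, n).astype(bool),
                "Men": rng.integers(0, 2, n).astype(bool),
            },
            index=ids,
        )
        met = pd.Series(
            rng.choice(["aerobic", "facultative", "anaerobic"], n), index=ids
        )
        df = metabolism_by_repertoire(presence, met)
        sums = df[["aerobic", "facultative", "microaerophilic", "anaerobic"]].sum(axis=1)
        assert np.allclose(sums, 1.0)
        big = df[df.n_species > 10]
        assert (big.aerobic.diff().dropna() <= 1e-12).all()

    def test_planted_conditional_distribution_recovered(self, small_dataset):
        truth = small_dataset.truth
        df = metabolism_by_repertoire(truth.presence, truth.metabolism)
        # recompute one combination by hand from the ground truth
        combo = df.iloc[0].combination
        cols = list(truth.presence.columns)
        mask = truth.presence.apply(
            lambda r: ("+".join(c for c in cols if r[c]) or "(none)") == combo, axis=1
        )
        sub = truth.metabolism.loc[mask[mask].index]
        assert df.iloc[0].n_species == len(sub)
        assert df.iloc[0].aerobic == pytest.approx((sub == "aerobic").mean())


def test_subsample_species_reproducible():
    ids = [f"s{i}" for i in range(50)]
    a = subsample_species(ids, 10, seed=3)
    b = subsample_species(list(reversed(ids)), 10, seed=3)
    assert a == b and len(set(a)) == 10
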