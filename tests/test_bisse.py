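import math
import warnings

import numpy as np
import pytest

from l1dynamics import (
    BisseParams,
    ChangePointSpec,
    PhyloTree,
    RootOptions,
    SimConfig,
    TipStates,
    TreeSample,
    UnitConversion,
    bisse_loglik,
    bisse_td_loglik,
    pooled_loglik,
    simulate_bisse,
)
from oracles import logsumexp_highprec, rk4_bisse_loglik

CONV = UnitConversion()


def _to_generations(t_sub: float) -> float:
    return t_sub / CONV.subst_rate


class TestClosedForms:
    def test_two_tip_pure_birth(self):
        """With mu = q = 0 and both tips low, the likelihood is the
        pure-birth closed form: log lambda - 2 lambda t."""
        t = PhyloTree.from_newick("(A:0.7,B:0.7);")
        states = TipStates({"A": 0, "B": 0})
        lam = 1.3
        ll = bisse_loglik(t, states, BisseParams(lam, 0.9, 0, 0, 0, 0))
        assert ll == pytest.approx(math.log(lam) - 2 * lam * 0.7, rel=1e-8)

    def test_yule_closed_form_many_tips(self, yule_tree):
        """Monomorphic tips, mu = q = 0: logL = (n-1) log lambda - lambda T."""
        tree, states = yule_tree
        for lam in (0.8, 2.2, 5.0):
            ll = bisse_loglik(tree, states, BisseParams(lam, lam, 0, 0, 0, 0))
            expected = (tree.n_tips - 1) * math.log(lam) - lam * tree.total_branch_length
            assert ll == pytest.approx(expected, rel=1e-8)

    def test_label_swap_symmetry(self, medium_sim):
        """With fully symmetric rates the likelihood cannot distinguish
        a global relabeling of the two states."""
        tree = medium_sim.tree
        p = BisseParams(2.0, 2.0, 0.3, 0.3, 0.8, 0.8)
        s1 = {lab: i % 2 for i, lab in enumerate(tree.tip_labels)}
        s2 = {lab: 1 - v for lab, v in s1.items()}
        a = bisse_loglik(tree, TipStates(s1), p)
        b = bisse_loglik(tree, TipStates(s2), p)
        assert a == pytest.approx(b, rel=1e-10)

    def test_unknown_tip_sums_both_states(self, small_sim):
        """An unknown tip's likelihood is the sum of the two resolved cases."""
        tree = small_sim.tree
        p = BisseParams(10, 412, 0, 0, 31, 360)
        lab = tree.tip_labels[0]
        base = dict(small_sim.states.states)
        lls = []
        for s in (0, 1):
            base[lab] = s
            lls.append(bisse_loglik(tree, TipStates(dict(base)), p))
        base[lab] = -1
        ll_unknown = bisse_loglik(tree, TipStates(dict(base)), p)
        assert ll_unknown == pytest.approx(logsumexp_highprec(lls), rel=1e-7)


class TestOracleAgreement:
    def test_matches_rk4_oracle(self, small_sim):
        """Adaptive transfer-matrix path vs independent fixed-step RK4
        pruning on random rate draws, including nonzero extinction."""
        rng = np.random.default_rng(42)
        tree, states = small_sim.tree, small_sim.states
        for _ in range(10):
            pars = BisseParams(*np.exp(rng.uniform(np.log(0.5), np.log(500), 6)))
            a = bisse_loglik(tree, states, pars)
            b = rk4_bisse_loglik(tree, states, pars)
            assert a == pytest.approx(b, rel=1e-6)

    def test_root_modes_match_oracle(self, small_sim):
        tree, states = small_sim.tree, small_sim.states
        p = BisseParams(8, 300, 5, 20, 30, 250)
        for root in (
            RootOptions("flat"),
            RootOptions("equilibrium"),
            RootOptions("fixed", fixed_state=0),
            RootOptions("weighted", condition_on_survival=True),
        ):
            a = bisse_loglik(tree, states, p, root=root)
            b = rk4_bisse_loglik(tree, states, p, root=root)
            assert a == pytest.approx(b, rel=1e-6)

    def test_monotone_decreasing_in_mu(self, small_sim):
        """On a fully sampled tree, raising extinction always lowers the
        likelihood of the observed surviving lineages."""
        tree, states = small_sim.tree, small_sim.states
        lls = [
            bisse_loglik(tree, states, BisseParams(10, 412, mu, mu, 31, 360))
            for mu in (0.0, 5.0, 20.0, 60.0)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestChangePoint:
    def test_unit_multipliers_degenerate_to_constant(self, medium_sim):
        tree, states = medium_sim.tree, medium_sim.states
        p = BisseParams(10, 412, 0, 0, 31, 360)
        cp = ChangePointSpec(
            (_to_generations(tree.depth / 3), _to_generations(tree.depth / 2)),
            (1.0, 1.0),
        )
        a = bisse_td_loglik(tree, states, p, cp)
        b = bisse_loglik(tree, states, p)
        assert a == pytest.approx(b, rel=1e-10)

    def test_boundary_at_present_prescales_lambda(self, small_sim):
        """A boundary at the present puts the whole tree in the scaled epoch."""
        tree, states = small_sim.tree, small_sim.states
        p = BisseParams(10, 412, 0, 0, 31, 360)
        factor = 1.6
        a = bisse_td_loglik(tree, states, p, ChangePointSpec((0.0,), (factor,)))
        scaled = BisseParams(10 * factor, 412 * factor, 0, 0, 31, 360)
        b = bisse_loglik(tree, states, scaled)
        assert a == pytest.approx(b, rel=1e-9)

    def test_matches_segmentwise_oracle(self, paper_params):
        """Factor-1.6 change point at half depth on a 20-tip tree."""
        sim = simulate_bisse(SimConfig(params=paper_params, n_tips=20, seed=23))
        tree, states = sim.tree, sim.states
        cp = ChangePointSpec((_to_generations(tree.depth / 2),), (1.6,))
        for p in (paper_params, BisseParams(8, 300, 5, 20, 30, 250)):
            a = bisse_td_loglik(tree, states, p, cp)
            b = rk4_bisse_loglik(tree, states, p, cp=cp)
            assert a == pytest.approx(b, rel=1e-6)

    def test_boundary_older_than_root_warns_and_is_inert(self, small_sim):
        tree, states = small_sim.tree, small_sim.states
        p = BisseParams(10, 412, 0, 0, 31, 360)
        deep = ChangePointSpec((_to_generations(tree.depth * 5),), (2.5,))
        with pytest.warns(UserWarning, match="predate the root"):
            a = bisse_td_loglik(tree, states, p, deep)
        assert a == pytest.approx(bisse_loglik(tree, states, p), rel=1e-10)


class TestPooling:
    def test_identical_trees_add_log_n(self, small_sim):
        tree, states = small_sim.tree, small_sim.states
        p = BisseParams(10, 412, 0, 0, 31, 360)
        single = bisse_loglik(tree, states, p)
        pooled = pooled_loglik(TreeSample([tree.copy() for _ in range(5)]), states, p)
        assert pooled == pytest.approx(single + math.log(5), rel=1e-10)

    def test_single_tree_equals_bisse_loglik(self, small_sim):
        tree, states = small_sim.tree, small_sim.states
        p = BisseParams(10, 412, 0, 0, 31, 360)
        assert pooled_loglik(TreeSample([tree]), states, p) == pytest.approx(
            bisse_loglik(tree, states, p), rel=1e-12
        )

    def test_distinct_trees_match_highprec_logsumexp(self, paper_params):
        sims = [
            simulate_bisse(SimConfig(params=paper_params, n_tips=8, seed=s))
            for s in (31, 32, 33)
        ]
        # same labels by construction (t1..t8); pool with shared states
        states = sims[0].states
        sample = TreeSample([s.tree for s in sims])
        p = BisseParams(10, 412, 0, 0, 31, 360)
        per_tree = [bisse_loglik(s.tree, states, p) for s in sims]
        assert pooled_loglik(sample, states, p) == pytest.approx(
            logsumexp_highprec(per_tree), rel=1e-10
        )


class TestValidation:
    def test_non_ultrametric_rejected(self):
        t = PhyloTree.from_newick("((A:1,B:1.5):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            bisse_loglik(t, TipStates({"A": 0, "B": 0, "C": 1}), BisseParams(1, 1, 0, 0, 0.1, 0.1))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BisseParams(-1, 1, 0, 0, 0.1, 0.1)

    def test_impossible_data_gives_minus_inf(self):
        """q01 = 0 with a fixed low root cannot produce a high tip."""
        t = PhyloTree.from_newick("(A:0.5,B:0.5);")
        p = BisseParams(1.0, 1.0, 0, 0, 0.0, 0.5)
        ll = bisse_loglik(
            t, TipStates({"A": 1, "B": 1}), p, root=RootOptions("fixed", fixed_state=0)
        )
        assert ll == -math.inf
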