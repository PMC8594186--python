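import math

import numpy as np
import pytest

from l1dynamics import (
    BisseParams,
    ModelConstraint,
    SimConfig,
    TipStates,
    TreeSample,
    builtin_constraints,
    fit_changepoint,
    fit_model,
    model_table,
    simulate_bisse,
)

CONSTRAINTS = {c.id: c for c in builtin_constraints()}


class TestConstraints:
    def test_table_of_nine_with_published_df(self):
        cons = builtin_constraints()
        assert [c.id for c in cons] == [
            "unconstrained",
            "mu0=mu1",
            "lambda0=lambda1",
            "q01=q10",
            "mu0=mu1=0",
            "lambda0=0",
            "q01=0",
            "mu0=mu1=lambda0=0",
            "mu0=mu1=q01=0",
        ]
        assert [c.df for c in cons] == [6, 5, 5, 5, 4, 5, 5, 3, 3]

    def test_constraint_applies_exactly(self):
        c = CONSTRAINTS["mu0=mu1=0"]
        p = c.params_from_free({"lambda0": 1.0, "lambda1": 2.0, "q01": 3.0, "q10": 4.0})
        assert p.mu0 == 0.0 and p.mu1 == 0.0
        c2 = CONSTRAINTS["q01=q10"]
        p2 = c2.params_from_free(
            {"lambda0": 1.0, "lambda1": 2.0, "mu0": 0.1, "mu1": 0.2, "q": 5.0}
        )
        assert p2.q01 == p2.q10 == 5.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ModelConstraint("none", (None,) * 6)


class TestFitModel:
    def test_yule_mle_closed_form(self, yule_tree):
        """Single tree, monomorphic tips, lambda-only model: the ML rate
        is (n-1)/T exactly (Yule MLE)."""
        tree, states = yule_tree
        lam_only = ModelConstraint("yule", ("lambda", "lambda", None, None, None, None))
        fit = fit_model(TreeSample([tree]), states, lam_only, n_starts=3, seed=0)
        assert fit.params.lambda0 == pytest.approx(
            (tree.n_tips - 1) / tree.total_branch_length, rel=1e-5
        )

    def test_aic_identity_and_constraint_satisfied(self, medium_sim):
        sample = TreeSample([medium_sim.tree])
        fit = fit_model(sample, medium_sim.states, CONSTRAINTS["mu0=mu1=0"], n_starts=2, seed=1)
        assert fit.aic == 2.0 * fit.df - 2.0 * fit.loglik
        assert fit.params.mu0 == 0.0 and fit.params.mu1 == 0.0
        assert fit.df == 4

    def test_determinism(self, medium_sim):
        sample = TreeSample([medium_sim.tree])
        a = fit_model(sample, medium_sim.states, CONSTRAINTS["mu0=mu1=0"], n_starts=2, seed=5)
        b = fit_model(sample, medium_sim.states, CONSTRAINTS["mu0=mu1=0"], n_starts=2, seed=5)
        assert a.params == b.params and a.loglik == b.loglik

    def test_nesting_inequality(self, medium_sim):
        """Adding constraints can only lower the maximized log-likelihood."""
        sample = TreeSample([medium_sim.tree])
        ll = {
            cid: fit_model(sample, medium_sim.states, CONSTRAINTS[cid], n_starts=2, seed=2).loglik
            for cid in ("mu0=mu1=0", "mu0=mu1", "unconstrained")
        }
        tol = 1e-4  # optimizer tolerance on the shared optimum
        assert ll["mu0=mu1=0"] <= ll["mu0=mu1"] + tol
        assert ll["mu0=mu1"] <= ll["unconstrained"] + tol


class TestModelTable:
    def _fit_pair(self, sim):
        sample = TreeSample([sim.tree])
        f1 = fit_model(sample, sim.states, CONSTRAINTS["mu0=mu1=0"], n_starts=2, seed=3)
        f2 = fit_model(sample, sim.states, CONSTRAINTS["mu0=mu1"], n_starts=2, seed=3)
        return f1, f2

    def test_ranking_and_delta(self, medium_sim):
        f1, f2 = self._fit_pair(medium_sim)
        tbl = model_table([f2, f1])
        assert tbl["aic"].is_monotonic_increasing
        assert tbl["delta_aic"].iloc[0] == 0.0
        assert tbl["best"].iloc[0]
        # equal logL at the boundary (mu hits 0): fewer df wins the tie
        if abs(f1.loglik - f2.loglik) < 1e-6:
            assert tbl["constraint"].iloc[0] == "mu0=mu1=0"

    def test_single_fit_table(self, medium_sim):
        f1, _ = self._fit_pair(medium_sim)
        tbl = model_table([f1])
        assert len(tbl) == 1 and tbl["delta_aic"].iloc[0] == 0.0

    def test_mixed_data_refused(self, medium_sim, small_sim):
        sample_a = TreeSample([medium_sim.tree])
        sample_b = TreeSample([small_sim.tree])
        fa = fit_model(sample_a, medium_sim.states, CONSTRAINTS["mu0=mu1=0"], n_starts=1, seed=0)
        fb = fit_model(sample_b, small_sim.states, CONSTRAINTS["mu0=mu1=0"], n_starts=1, seed=0)
        with pytest.raises(ValueError, match="different data"):
            model_table([fa, fb])


class TestChangePointFit:
    def test_fixed_unit_multiplier_wastes_one_df(self, medium_sim):
        """Pinning the multiplier at 1 recovers the base optimum but pays
        one AIC-relevant parameter per boundary: AIC = base + 2."""
        sample = TreeSample([medium_sim.tree])
        base = fit_model(sample, medium_sim.states, CONSTRAINTS["mu0=mu1=0"], n_starts=2, seed=4)
        b_gen = medium_sim.tree.depth / 2 / 2.5e-8
        cpf = fit_changepoint(
            sample,
            medium_sim.states,
            CONSTRAINTS["mu0=mu1=0"],
            (b_gen,),
            n_starts=1,
            seed=4,
            fixed_multipliers=(1.0,),
            init=base,
        )
        assert cpf.fit.df == base.df + 1
        assert cpf.aic == pytest.approx(base.aic + 2.0, abs=1e-3)

    def test_unidentifiable_boundary_flagged(self, small_sim):
        sample = TreeSample([small_sim.tree])
        deep = small_sim.tree.depth * 10 / 2.5e-8
        near = small_sim.tree.depth / 2 / 2.5e-8
        cpf = fit_changepoint(
            sample,
            small_sim.states,
            CONSTRAINTS["mu0=mu1=0"],
            (near, deep),
            n_starts=1,
            seed=0,
        )
        assert cpf.multiplier_identifiable == (True, False)

    def test_recovers_speciation_multiplier(self, paper_params):
        """Simulation with both speciation rates 1.6x higher before a
        known boundary; the fitted multiplier should land near 1.6."""
        from l1dynamics import ChangePointSpec

        depth_sub = 0.025
        b_gen = (depth_sub / 2) / 2.5e-8
        cp = ChangePointSpec((b_gen,), (1.6,))
        mults = []
        seed = 100
        while len(mults) < 3 and seed < 160:
            seed += 1
            sim = simulate_bisse(
                SimConfig(params=paper_params, max_time=depth_sub, cp=cp, seed=seed)
            )
            if not 60 <= sim.tree.n_tips <= 400:
                continue  # informative yet tractable replicates only
            cpf = fit_changepoint(
                TreeSample([sim.tree]),
                sim.states,
                CONSTRAINTS["mu0=mu1=0"],
                (b_gen,),
                n_starts=2,
                seed=seed,
            )
            mults.append(cpf.multipliers[0])
        assert len(mults) == 3
        # truth 1.6; wide band reflects single-tree sampling error
        assert 1.0 < float(np.median(mults)) < 2.6
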