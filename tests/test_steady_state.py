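import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import kfp
from kfp import pathways
from kfp.steady_state import _wcdd
from conftest import random_admissible_model

unit = st.floats(0.01, 0.95, allow_nan=False)


class TestSteadyStateProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a1=unit, a2=unit, b12=unit, k1=st.floats(0.05, 3), k2=st.floats(0.05, 3))
    def test_reversible_steady_state_in_unit_box_and_annihilates_rhs(
            self, a1, a2, b12, k1, k2):
        model = kfp.enrichment_model(pathways.two_pool_chain(reversible=True))
        params = kfp.ParameterSet({"k_X1": k1, "alpha_X1": a1,
                                   "beta_X1_X2": b12, "k_X2": k2,
                                   "alpha_X2": a2})
        if not model.admissible(params):  # labeled share must stay positive
            return
        ss = kfp.solve_steady_state(model, params)
        assert ss.wcdd_ok
        assert np.all(ss.xbar_ss >= -1e-12) and np.all(ss.xbar_ss <= 1 + 1e-12)
        np.testing.assert_allclose(kfp.rhs(model, params, ss.xbar_ss), 0,
                                   atol=1e-10)


class TestSolveSteadyState:
    def test_irreversible_closed_form(self, model_irrev, truth_irrev):
        # (alpha1, alpha1 - alpha1*alpha2 + alpha2) at alpha = (1/4, 2/5)
        ss = kfp.solve_steady_state(model_irrev, truth_irrev)
        np.testing.assert_allclose(ss.xbar_ss, [0.25, 0.55], atol=1e-12)

    def test_reversible_closed_form(self, model_rev, truth_rev):
        # scaled by 1 / (1 - beta12 (1 - alpha2)) = 1/0.895
        ss = kfp.solve_steady_state(model_rev, truth_rev)
        np.testing.assert_allclose(ss.xbar_ss, [0.295 / 0.895, 0.475 / 0.895],
                                   atol=1e-12)

    def test_no_unlabeled_input_means_fully_labeled_steady_state(self):
        g = kfp.PathwayGraph(
            nodes=["X1", "X2"],
            labeled_inputs=[("X1", "f1")],
            exits=[("X1", "f3"), ("X2", "f6")],
            internal_edges=[("X1", "X2", "f4")],
        )
        model = kfp.enrichment_model(g)
        params = kfp.ParameterSet({"k_X1": 1.0, "k_X2": 0.5})
        ss = kfp.solve_steady_state(model, params)
        np.testing.assert_allclose(ss.xbar_ss, [0.0, 0.0], atol=1e-15)

    def test_turnover_rates_do_not_move_steady_state(self, model_rev, truth_rev):
        base = kfp.solve_steady_state(model_rev, truth_rev).xbar_ss
        rng = np.random.default_rng(7)
        for _ in range(100):
            scaled = truth_rev.updated(
                k_X1=float(rng.uniform(0.01, 3.0)),
                k_X2=float(rng.uniform(0.01, 3.0)))
            ss = kfp.solve_steady_state(model_rev, scaled).xbar_ss
            np.testing.assert_array_equal(ss, base)  # bit-for-bit: K unused

    def test_matches_long_time_integration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            model, params = random_admissible_model(rng)
            K, B, alpha = model.numeric(params)
            n = model.n_nodes

            def f(t, x):
                return K @ ((B - np.eye(n)) @ x + alpha)

            t_end = 60.0 / np.diag(K).min()
            sol = solve_ivp(f, (0, t_end), np.ones(n), rtol=1e-10, atol=1e-12)
            ss = kfp.solve_steady_state(model, params).xbar_ss
            np.testing.assert_allclose(sol.y[:, -1], ss, atol=1e-6)


class TestWCDD:
    def test_fixture_models_pass(self, model_irrev, truth_irrev,
                                 model_rev, truth_rev):
        for model, params in ((model_irrev, truth_irrev),
                              (model_rev, truth_rev)):
            ok, strict, witness = kfp.wcdd_check(model, params)
            assert ok
            assert 0 in strict   # labeled-input node row is strict

    def test_weak_row_chains_to_strict_row(self, model_rev, truth_rev):
        # alpha2 = 0 leaves row 2 only weakly dominant; the chain through
        # the back edge to the labeled row keeps (I - B) invertible
        params = truth_rev.updated(alpha_X2=0.0)
        ok, strict, witness = kfp.wcdd_check(model_rev, params)
        assert ok
        assert 1 not in strict
        assert witness[1][-1] in strict

    def test_row_sum_above_one_fails(self):
        B = np.array([[0.0, 0.8], [0.9, 0.4]])
        ok, strict, witness = _wcdd(B)
        assert not ok and 1 in witness

    def test_isolated_weak_row_fails(self):
        # row 1 weak with no path to the strict row 0
        B = np.array([[0.5, 0.0], [0.0, 1.0]])
        ok, _, witness = _wcdd(B)
        assert not ok and witness[1] == ()


class TestCountingCondition:
    def test_irreversible_chain_satisfies_condition(self, chain_irrev):
        rep = kfp.ss_identifiability(chain_irrev)
        assert rep.condition_holds            # 1 + 2 + 1 = 4 <= 2 * 2
        assert rep.n_proportional_params == 2
        assert rep.arborescence_closed_form

    def test_reversible_chain_fails_condition(self, chain_rev):
        rep = kfp.ss_identifiability(chain_rev)
        assert not rep.condition_holds        # 1 + 2 + 2 = 5 > 4
        assert rep.n_proportional_params == 3

    def test_condition_matches_reduction_count(self, cycle3, chain_irrev,
                                               chain_rev):
        for g in (cycle3, chain_irrev, chain_rev):
            free, _ = kfp.reduce_parameters(g)
            n_prop = sum(1 for n in free if not n.startswith("k"))
            assert kfp.ss_identifiability(g).n_proportional_params == n_prop

    def test_degenerate_flags(self, model_rev, chain_rev):
        # all-labeled: alpha = 0 everywhere
        params = kfp.ParameterSet({"k_X1": 1.0, "alpha_X1": 0.0,
                                   "beta_X1_X2": 0.1, "k_X2": 1.0,
                                   "alpha_X2": 0.0})
        rep = kfp.ss_identifiability(chain_rev, model_rev, params)
        assert rep.degenerate_all_labeled
        # single parent: X2 fed only by X1, alpha2 = 0
        assert "X2" in rep.degenerate_single_parent


class TestArborescenceRecovery:
    def test_reference_values(self, chain_irrev):
        alpha = kfp.recover_arborescence_alphas(chain_irrev, [0.25, 0.55])
        np.testing.assert_allclose(alpha, [0.25, 0.4], atol=1e-15)

    def test_one_node_identity(self):
        g = kfp.PathwayGraph(nodes=["X1"], labeled_inputs=[("X1", "f1")],
                             unlabeled_inputs=[("X1", "f2")],
                             exits=[("X1", "f3")])
        np.testing.assert_array_equal(
            kfp.recover_arborescence_alphas(g, [0.3]), [0.3])

    def test_three_node_chain_round_trip_exact(self):
        g = kfp.PathwayGraph(
            nodes=["X1", "X2", "X3"],
            labeled_inputs=[("X1", "f1")],
            unlabeled_inputs=[("X1", "u1"), ("X2", "u2"), ("X3", "u3")],
            exits=[("X1", "e1"), ("X2", "e2"), ("X3", "e3")],
            internal_edges=[("X1", "X2", "w1"), ("X2", "X3", "w2")],
        )
        model = kfp.enrichment_model(g)
        params = kfp.ParameterSet({"k_X1": 1.0, "k_X2": 1.0, "k_X3": 1.0,
                                   "alpha_X1": 0.2, "alpha_X2": 0.3,
                                   "alpha_X3": 0.5})
        ss = kfp.solve_steady_state(model, params).xbar_ss
        rec = kfp.recover_arborescence_alphas(g, ss)
        np.testing.assert_allclose(rec, [0.2, 0.3, 0.5], atol=1e-15)

    def test_rejects_non_arborescence(self, chain_rev):
        with pytest.raises(ValueError, match="arborescence"):
            kfp.recover_arborescence_alphas(chain_rev, [0.3, 0.5])

    def test_fully_unlabeled_parent_guard(self, chain_irrev):
        with pytest.raises(ZeroDivisionError):
            kfp.recover_arborescence_alphas(chain_irrev, [1.0, 0.9])
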