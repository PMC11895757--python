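import math

import numpy as np
import pytest

from paleosky import (
    BDSKYParams,
    ValidationError,
    edge_factor,
    fbd_log_likelihood,
    make_time_grid,
    no_sample_prob,
)
from paleosky.core import Node, TimeTree
from paleosky.fbd import FBDWorkspace

from _oracles import fbd_loglik_ode, ode_pq_solution
from conftest import random_fossil_tree


def random_params(rng, n_bins, origin=100.0, rho_choices=(0.0, 0.0, 0.5, 1.0)):
    return BDSKYParams(
        origin_age=origin,
        lam=tuple(rng.uniform(0.01, 0.3, n_bins)),
        mu=tuple(rng.uniform(0.0, 0.3, n_bins)),
        psi=tuple(rng.uniform(0.01, 0.2, n_bins)),
        rho=float(rng.choice(rho_choices)),
    )


def random_grid(rng, n_bins):
    if n_bins == 1:
        return make_time_grid([66.0])
    return make_time_grid([66.0, 66.0 + float(rng.uniform(5.0, 50.0))])


class TestNoSampleProb:
    def test_nothing_can_be_sampled(self, grid1):
        params = BDSKYParams(origin_age=50.0, lam=(0.0,), mu=(0.0,), psi=(0.0,), rho=0.0)
        for t in (0.0, 1.0, 50.0):
            assert no_sample_prob(t, params, grid1) == pytest.approx(1.0)

    def test_certain_present_day_sampling(self, grid1):
        params = BDSKYParams(origin_age=50.0, lam=(0.0,), mu=(0.0,), psi=(0.0,), rho=1.0)
        for t in (0.0, 1.0, 50.0):
            assert no_sample_prob(t, params, grid1) == pytest.approx(0.0)

    def test_one_bin_example_matches_ode(self, grid1):
        params = BDSKYParams(origin_age=50.0, lam=(0.1,), mu=(0.05,), psi=(0.05,), rho=0.0)
        sol = ode_pq_solution(params, grid1, 10.0)
        assert no_sample_prob(10.0, params, grid1) == pytest.approx(
            float(sol(10.0)[0]), abs=1e-8
        )

    def test_negative_age_rejected(self, grid1):
        params = BDSKYParams(origin_age=50.0, lam=(0.1,), mu=(0.1,), psi=(0.1,))
        with pytest.raises(ValidationError):
            no_sample_prob(-1.0, params, grid1)

    def test_length_mismatch_rejected(self, grid8):
        params = BDSKYParams(origin_age=300.0, lam=(0.1,), mu=(0.1,), psi=(0.1,))
        with pytest.raises(ValidationError):
            no_sample_prob(1.0, params, grid8)


class TestEdgeFactor:
    def test_no_events_means_unit_factor(self, grid1):
        params = BDSKYParams(origin_age=50.0, lam=(0.0,), mu=(0.0,), psi=(0.0,))
        assert edge_factor(17.3, params, grid1) == pytest.approx(1.0)

    def test_yule_exponential_decay(self, grid1):
        lam = 0.25
        params = BDSKYParams(origin_age=50.0, lam=(lam,), mu=(0.0,), psi=(0.0,), rho=1.0)
        t = 12.0
        sol = ode_pq_solution(params, grid1, t)
        assert edge_factor(t, params, grid1) == pytest.approx(math.exp(-lam * t), rel=1e-9)
        assert edge_factor(t, params, grid1, log=True) == pytest.approx(
            float(sol(t)[1]), abs=1e-8
        )

    def test_continuity_at_grid_boundary(self):
        grid = make_time_grid([66.0, 96.0])
        rng = np.random.default_rng(7)
        for _ in range(10):
            params = random_params(rng, 2)
            ws = FBDWorkspace(params, grid)
            eps = 1e-9
            assert ws.log_q(30.0 - eps) == pytest.approx(ws.log_q(30.0 + eps), abs=1e-7)
            assert ws.p(30.0 - eps) == pytest.approx(ws.p(30.0 + eps), abs=1e-9)

    def test_log_scale_stays_finite_at_depth(self, grid1):
        params = BDSKYParams(origin_age=200.0, lam=(0.3,), mu=(0.3,), psi=(0.2,))
        logq = edge_factor(180.0, params, grid1, log=True)
        assert math.isfinite(logq)
        assert logq < -90  # q itself is within a rounding error of 0


class TestClosedFormsAgainstODE:
    def test_p_and_q_match_ode_on_random_draws(self):
        """Closed-form per-bin solutions vs numerical integration, one-
        and two-bin grids, 100 random parameter draws."""
        rng = np.random.default_rng(2024)
        for k in range(100):
            n_bins = 1 + (k % 2)
            grid = random_grid(rng, n_bins)
            params = random_params(rng, n_bins)
            ws = FBDWorkspace(params, grid)
            t = float(rng.uniform(0.5, 80.0))
            sol = ode_pq_solution(params, grid, t)
            p_ode, logq_ode = float(sol(t)[0]), float(sol(t)[1])
            assert ws.p(t) == pytest.approx(p_ode, rel=1e-8, abs=1e-8)
            assert ws.log_q(t) == pytest.approx(logq_ode, rel=1e-8, abs=1e-8)

    def test_scalar_fast_paths_match_vector_paths(self):
        rng = np.random.default_rng(5)
        grid = random_grid(rng, 2)
        params = random_params(rng, 2)
        ws = FBDWorkspace(params, grid)
        for t in rng.uniform(0.0, 90.0, 20):
            assert ws.p1(float(t)) == pytest.approx(ws.p(float(t)), abs=1e-14)
            assert ws.log_q1(float(t)) == pytest.approx(ws.log_q(float(t)), abs=1e-12)


class TestFBDLogLikelihood:
    def test_yule_two_tip_closed_form(self, grid1):
        lam = 0.2
        params = BDSKYParams(origin_age=30.0, lam=(lam,), mu=(0.0,), psi=(0.0,), rho=1.0)
        tau = 12.0
        tree = TimeTree(
            Node(age=tau, children=[Node(age=0.0, label="A"), Node(age=0.0, label="B")]),
            origin_age=30.0,
        )
        # pure-birth density from the origin: one lineage survives to the
        # branch point, speciates, and both daughters survive to 0
        analytic = math.log(lam) - lam * 30.0 - lam * tau
        assert fbd_log_likelihood(tree, params, grid1) == pytest.approx(analytic, abs=1e-9)

    def test_tip_at_reference_age_impossible_without_extant_sampling(self, grid1):
        params = BDSKYParams(origin_age=30.0, lam=(0.1,), mu=(0.05,), psi=(0.1,), rho=0.0)
        tree = TimeTree(
            Node(age=5.0, children=[Node(age=0.0, label="A"), Node(age=1.0, label="B")]),
            origin_age=30.0,
        )
        assert fbd_log_likelihood(tree, params, grid1) == -np.inf

    def test_impossible_sampling_gives_minus_inf_not_nan(self, grid1, fossil_tree):
        params = BDSKYParams(origin_age=25.0, lam=(0.1,), mu=(0.05,), psi=(0.0,), rho=0.0)
        assert fbd_log_likelihood(fossil_tree, params, grid1) == -np.inf

    def test_origin_younger_than_root_rejected(self, grid1, fossil_tree):
        params = BDSKYParams(origin_age=10.0, lam=(0.1,), mu=(0.05,), psi=(0.1,))
        with pytest.raises(ValidationError, match="origin"):
            fbd_log_likelihood(fossil_tree, params, grid1)

    def test_matches_ode_oracle_on_five_tip_trees(self, grid1):
        rng = np.random.default_rng(11)
        for _ in range(5):
            tree = random_fossil_tree(rng, n_tips=5)
            params = BDSKYParams(
                origin_age=tree.origin_age,
                lam=(float(rng.uniform(0.05, 0.25)),),
                mu=(float(rng.uniform(0.0, 0.2)),),
                psi=(float(rng.uniform(0.05, 0.2)),),
            )
            got = fbd_log_likelihood(tree, params, grid1)
            want = fbd_loglik_ode(tree, params, grid1)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_matches_ode_oracle_with_sampled_ancestors(self, grid1):
        sa = Node(age=4.0, label="F1", children=[Node(age=1.0, label="F2")])
        tree = TimeTree(
            Node(age=6.0, children=[sa, Node(age=2.0, label="F3")]), origin_age=9.0
        )
        params = BDSKYParams(origin_age=9.0, lam=(0.15,), mu=(0.05,), psi=(0.1,))
        got = fbd_log_likelihood(tree, params, grid1)
        want = fbd_loglik_ode(tree, params, grid1)
        assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_invariant_to_child_order(self, grid1, fossil_tree):
        params = BDSKYParams(origin_age=25.0, lam=(0.12,), mu=(0.07,), psi=(0.09,))
        base = fbd_log_likelihood(fossil_tree, params, grid1)
        flipped = fossil_tree.copy()
        for nd in flipped.preorder():
            nd.children.reverse()
        assert fbd_log_likelihood(flipped, params, grid1) == pytest.approx(base, abs=1e-12)

    def test_grid_refinement_invariance(self, fossil_tree):
        """Splitting one bin into two with identical rates leaves the
        likelihood unchanged."""
        one = make_time_grid([66.0])
        two = make_time_grid([66.0, 76.0])
        p1 = BDSKYParams(origin_age=25.0, lam=(0.12,), mu=(0.07,), psi=(0.09,))
        p2 = BDSKYParams(
            origin_age=25.0, lam=(0.12, 0.12), mu=(0.07, 0.07), psi=(0.09, 0.09)
        )
        assert fbd_log_likelihood(fossil_tree, p2, two) == pytest.approx(
            fbd_log_likelihood(fossil_tree, p1, one), abs=1e-9
        )

    def test_tip_term_decomposes_with_log_psi(self, grid1):
        """The per-tip contribution is log psi + log p - log q, so scaling
        psi's explicit factor shifts that term by exactly the log-ratio."""
        params = BDSKYParams(origin_age=25.0, lam=(0.12,), mu=(0.07,), psi=(0.09,))
        ws = FBDWorkspace(params, grid1)
        y = 4.2
        term = math.log(params.psi[0]) + math.log(ws.p1(y)) - ws.log_q1(y)
        term2 = math.log(2 * params.psi[0]) + math.log(ws.p1(y)) - ws.log_q1(y)
        assert term2 - term == pytest.approx(math.log(2.0), abs=1e-12)
        # and the workspace-level tip term matches this decomposition
        from paleosky.mcmc import _BDSkyModel, _TreeArrays

        tree = TimeTree(
            Node(age=10.0, children=[Node(age=y, label="A"), Node(age=1.0, label="B")]),
            origin_age=25.0,
        )
        model = _BDSkyModel(_TreeArrays(tree), grid1, rho=0.0)
        model.set_scalars(
            {"lambda_0": 0.12, "mu_0": 0.07, "psi_0": 0.09}, origin=25.0
        )
        i = [k for k, lab in enumerate(model.a.labels) if lab == "A"][0]
        assert model.node_term(i) == pytest.approx(term, abs=1e-12)
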