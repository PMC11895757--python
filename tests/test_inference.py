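import math

import numpy as np
import pytest
from scipy import stats

from paleosky import (
    CoalescentParams,
    ValidationError,
    log_prior,
    make_time_grid,
    run_mcmc,
    sample_prior,
    simulate_coalescent,
    simulate_fbd,
)
from paleosky.core import BDSKYParams, Node, TimeTree
from paleosky.coalescent import coalescent_log_likelihood
from paleosky.mcmc import MCMCConfig
from paleosky.moves import scale_move, window_move, node_age_interval, sample_age_interval
from paleosky.priors import Prior, PriorSpec, default_priors
from paleosky.summary import apply_burn_in, ess


class FakeRng:
    """Deterministic stand-in returning preset uniforms."""

    def __init__(self, *values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


class TestPriors:
    def test_flat_density_is_zero_log(self):
        spec = PriorSpec(x=Prior("uniform", {"low": 0.0, "high": 1.0}))
        assert log_prior({"x": 0.5}, spec) == pytest.approx(0.0)

    def test_exponential_density_formula(self):
        spec = PriorSpec(psi=Prior("exponential", {"mean": 0.2}))
        assert log_prior({"psi": 0.2}, spec) == pytest.approx(math.log(5.0) - 1.0)

    def test_hard_bound_gives_minus_inf(self):
        spec = PriorSpec(x=Prior("normal", {"mu": 0.0, "sigma": 1.0}, bounds=(0.0, 10.0)))
        assert log_prior({"x": -0.5}, spec) == -math.inf

    def test_missing_parameter_rejected(self):
        spec = PriorSpec()
        with pytest.raises(ValidationError, match="no prior"):
            log_prior({"x": 1.0}, spec)

    def test_log_pdf_matches_scipy(self):
        cases = [
            (Prior("lognormal", {"mu": math.log(0.2), "sigma": 1.1}), 0.37),
            (Prior("exponential", {"mean": 0.2}), 0.11),
            (Prior("gamma", {"shape": 2.0, "scale": 3.0}), 4.2),
            (Prior("normal", {"mu": 1.0, "sigma": 2.0}), -0.3),
            (Prior("laplace", {"mu": 0.0, "scale": 1.5}), 0.7),
            (Prior("uniform", {"low": 2.0, "high": 5.0}), 3.3),
        ]
        for prior, x in cases:
            assert prior.log_pdf(x) == pytest.approx(
                float(prior._frozen().logpdf(x)), abs=1e-12
            )

    def test_degenerate_uniform_is_point_mass(self):
        prior = Prior("uniform", {"low": 2.0, "high": 2.0})
        rng = np.random.default_rng(0)
        assert prior.sample(rng) == 2.0
        assert prior.log_pdf(2.0) == 0.0
        assert prior.log_pdf(2.1) == -math.inf

    def test_sample_prior_reproducible_and_calibrated(self, grid1):
        spec = default_priors("bdsky", grid1)
        assert sample_prior(spec, 42) == sample_prior(spec, 42)
        rng = np.random.default_rng(1)
        psi = spec["psi_0"].sample(rng, size=200_000)
        # default sampling-rate prior: one sample per lineage per 5 Myr
        assert abs(psi.mean() - 0.2) < 4 * psi.std() / math.sqrt(psi.size)

    def test_default_rate_prior_brackets_published_estimates(self, grid1):
        lam = default_priors("bdsky", grid1)["lambda_0"]
        frozen = lam._frozen()
        lo, hi = frozen.ppf(0.025), frozen.ppf(0.975)
        assert lo < 0.02 and hi > 1.54  # events/lineage/Myr


class TestMoves:
    def test_scale_move_forced_factor(self):
        # u = 0.75 with step log 4 forces s = 2
        prop, log_hr = scale_move(1.0, math.log(4.0), FakeRng(0.75))
        assert prop == pytest.approx(2.0)
        assert log_hr == pytest.approx(math.log(2.0))

    def test_scale_move_zero_step_degenerates(self):
        prop, log_hr = scale_move(3.0, 0.0, FakeRng(0.1))
        assert prop == 3.0 and log_hr == 0.0

    def test_scale_move_requires_positive_value(self):
        with pytest.raises(ValidationError):
            scale_move(0.0, 0.5, FakeRng(0.5))

    def test_scale_move_log_random_walk_is_unbiased(self):
        rng = np.random.default_rng(8)
        step, n = 0.5, 100_000
        value = 1.0
        logs = np.empty(n)
        for i in range(n):
            value, _ = scale_move(value, step, rng)
            logs[i] = math.log(value)
        # each increment is U(-step, step): the accept-all walk has no drift
        drift = logs[-1] / n
        se = step / math.sqrt(3 * n)
        assert abs(drift) < 4 * se

    def test_window_move_symmetric(self):
        prop, log_hr = window_move(5.0, 2.0, FakeRng(1.0))
        assert prop == pytest.approx(7.0) and log_hr == 0.0

    def test_node_age_interval_bounds(self):
        a = Node(age=1.0, label="A")
        b = Node(age=3.0, label="B")
        inner = Node(age=5.0, children=[a, b])
        root = Node(age=9.0, children=[inner, Node(age=0.0, label="C")])
        TimeTree(root, origin_age=12.0)
        assert node_age_interval(inner, None) == (3.0, 9.0)
        assert node_age_interval(root, 12.0) == (5.0, 12.0)
        assert node_age_interval(root, None) is None

    def test_sample_age_interval_intersection(self):
        tip = Node(age=2.0, label="A")
        root = Node(age=3.5, children=[tip, Node(age=0.0, label="B")])
        tree = TimeTree(root, tip_bounds={"A": (4.0, 1.0)})
        # stratigraphic (4, 1) clipped by the parent at 3.5
        assert sample_age_interval(tree, tip) == (1.0, 3.5)

    def test_sample_age_interval_degenerate_cases(self):
        tip = Node(age=2.0, label="A")
        root = Node(age=3.0, children=[tip, Node(age=0.0, label="B")])
        tree = TimeTree(root, tip_bounds={"A": (2.0, 2.0)})
        assert sample_age_interval(tree, tip) is None  # pinned age
        tree2 = TimeTree(root.children[1].parent, tip_bounds={})
        assert sample_age_interval(tree2, tip) is None  # no bounds


def small_coalescent_dataset(seed=1, n_tips=12):
    grid = make_time_grid([66.0])
    params = CoalescentParams(growth=(0.05,), n_final=100.0)
    tree = simulate_coalescent([0.0] * n_tips, params, grid, seed=seed)
    return tree, grid


def small_fbd_dataset(seed=2):
    grid = make_time_grid([66.0])
    params = BDSKYParams(origin_age=40.0, lam=(0.15,), mu=(0.05,), psi=(0.1,))
    sim = simulate_fbd(params, grid, seed=seed, min_tips=8)
    return sim.sampled_tree, grid


class TestRunMCMC:
    def test_same_seed_bit_identical(self):
        tree, grid = small_coalescent_dataset()
        cfg = MCMCConfig(chain_length=2000, thin=10, seed=5, max_chunks=1)
        a = run_mcmc("coalescent", tree, grid, config=cfg)
        b = run_mcmc("coalescent", tree, grid, config=cfg)
        assert a.records.equals(b.records)

    def test_posterior_identity_recomputable_from_scratch(self):
        """With ages held fixed, every retained state's posterior equals
        an independent re-evaluation of likelihood + prior."""
        tree, grid = small_coalescent_dataset()
        priors = default_priors("coalescent", grid)
        cfg = MCMCConfig(
            chain_length=4000, thin=10, seed=3, max_chunks=1, move_weights={"rates": 1.0}
        )
        trace = run_mcmc("coalescent", tree, grid, priors=priors, config=cfg)
        rng = np.random.default_rng(0)
        rows = trace.records.iloc[rng.choice(len(trace.records), 100)]
        for _, row in rows.iterrows():
            params = CoalescentParams(growth=(row["growth_0"],), n_final=row["n_final"])
            lik = coalescent_log_likelihood(tree, params, grid)
            pri = priors["growth_0"].log_pdf(row["growth_0"]) + priors[
                "n_final"
            ].log_pdf(row["n_final"])
            assert row["likelihood"] == pytest.approx(lik, abs=1e-9)
            assert row["posterior"] == pytest.approx(lik + pri, abs=1e-9)
            assert row["posterior"] == pytest.approx(
                row["likelihood"] + row["prior"], abs=1e-9
            )

    def test_trace_identity_holds_with_all_moves(self):
        tree, grid = small_fbd_dataset()
        cfg = MCMCConfig(chain_length=5000, thin=10, seed=4, max_chunks=1)
        trace = run_mcmc("bdsky", tree, grid, config=cfg)
        df = trace.records
        assert np.allclose(df["posterior"], df["likelihood"] + df["prior"], atol=1e-9)

    def test_prior_recovery_coalescent(self):
        """With the likelihood disabled the chain samples the prior:
        posterior moments match analytic prior moments."""
        tree, grid = small_coalescent_dataset()
        priors = default_priors("coalescent", grid)
        cfg = MCMCConfig(
            chain_length=40_000,
            thin=10,
            seed=6,
            max_chunks=1,
            prior_only=True,
            move_weights={"rates": 1.0},
        )
        trace = apply_burn_in(run_mcmc("coalescent", tree, grid, priors=priors, config=cfg), 0.1)
        for name in ("growth_0", "n_final"):
            x = trace.records[name].to_numpy()
            n_eff = ess(x)
            prior = priors[name]
            se_mean = math.sqrt(prior.var() / n_eff)
            assert abs(x.mean() - prior.mean()) < 3 * se_mean

    def test_tip_age_sampling_uniform_within_bounds(self):
        """Prior-only tip-age moves land uniformly on the allowed
        interval (stratigraphic bounds clipped by the parent)."""
        tip = Node(age=2.0, label="A")
        other = Node(age=1.0, label="B")
        root = Node(age=10.0, children=[tip, other])
        tree = TimeTree(root, origin_age=20.0, tip_bounds={"A": (4.0, 1.0)})
        grid = make_time_grid([66.0])
        cfg = MCMCConfig(
            chain_length=30_000,
            thin=10,
            seed=7,
            max_chunks=1,
            prior_only=True,
            move_weights={"tip_ages": 1.0},
        )
        trace = run_mcmc("bdsky", tree, grid, config=cfg)
        x = apply_burn_in(trace, 0.1).records["age_A"].to_numpy()
        # thin to near-independence before the KS test
        x = x[:: 20]
        assert stats.kstest(x, stats.uniform(loc=1.0, scale=3.0).cdf).pvalue > 0.01

    def test_origin_prior_sampling_uniform_above_root(self):
        tree, grid = small_fbd_dataset()
        priors = default_priors("bdsky", grid)
        cfg = MCMCConfig(
            chain_length=30_000,
            thin=10,
            seed=8,
            max_chunks=1,
            prior_only=True,
            move_weights={"rates": 0.5, "origin": 0.5},
        )
        trace = apply_burn_in(run_mcmc("bdsky", tree, grid, priors=priors, config=cfg), 0.1)
        x = trace.records["origin"].to_numpy()[::10]
        root = tree.root_age
        cap = priors["origin"].params["high"]
        assert stats.kstest(x, stats.uniform(loc=root, scale=cap - root).cdf).pvalue > 0.01

    def test_multichain_agreement(self):
        """Four chains from different seeds mix to the same posterior
        (split-free Gelman-Rubin below 1.1 on a fixed dataset)."""
        tree, grid = small_coalescent_dataset(seed=9, n_tips=15)
        chains = []
        for seed in (1, 2, 3, 4):
            cfg = MCMCConfig(
                chain_length=20_000,
                thin=10,
                seed=seed,
                max_chunks=1,
                move_weights={"rates": 1.0},
            )
            tr = apply_burn_in(run_mcmc("coalescent", tree, grid, config=cfg), 0.1)
            chains.append(tr.records["growth_0"].to_numpy())
        m = min(len(c) for c in chains)
        arr = np.stack([c[:m] for c in chains])
        within = arr.var(axis=1, ddof=1).mean()
        between = m * arr.mean(axis=1).var(ddof=1)
        var_hat = (m - 1) / m * within + between / m
        rhat = math.sqrt(var_hat / within)
        assert rhat < 1.1

    def test_ess_stopping_rule(self):
        """The chain keeps extending until every scalar parameter's ESS
        beats the target, and reports convergence only then."""
        tree, grid = small_coalescent_dataset()
        cfg = MCMCConfig(
            chain_length=5000,
            thin=10,
            seed=10,
            target_ess=50.0,
            max_chunks=20,
            move_weights={"rates": 1.0},
        )
        trace = run_mcmc("coalescent", tree, grid, config=cfg)
        assert trace.converged
        assert min(trace.ess.values()) >= 50.0

    def test_unconverged_chain_reported(self):
        tree, grid = small_coalescent_dataset()
        cfg = MCMCConfig(chain_length=500, thin=10, seed=11, max_chunks=1)
        trace = run_mcmc("coalescent", tree, grid, config=cfg)
        assert not trace.converged

    def test_unknown_model_rejected(self, grid1):
        tree, _ = small_coalescent_dataset()
        with pytest.raises(ValidationError):
            run_mcmc("birthdeath", tree, grid1)

    def test_sampled_ancestor_tree_rejected_by_coalescent(self, grid1):
        sa = Node(age=4.0, label="F1", children=[Node(age=1.0, label="F2")])
        tree = TimeTree(Node(age=6.0, children=[sa, Node(age=2.0, label="F3")]))
        with pytest.raises(ValidationError, match="binary"):
            run_mcmc("coalescent", tree, grid1)
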