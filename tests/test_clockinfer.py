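"""Likelihood, prior, MCMC machinery and chain diagnostics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from largeclade import (
    Alignment,
    ClockModel,
    MCMCConfig,
    YuleCladeSpec,
    effective_sample_size,
    hpd_interval,
    jc_log_likelihood,
    run_mcmc,
    simulate_alignment,
    simulate_yule_conditioned,
    yule_log_prior,
)
from largeclade.treesim import sample_branching_ages


def jc_transition(same, d):
    e = np.exp(-4.0 * d / 3.0)
    return 0.25 + 0.75 * e if same else 0.25 - 0.25 * e


class TestJCLikelihood:
    def test_two_tip_single_site_closed_form(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(2, 50.0, 0.01, 2), seed=1)
        aln = Alignment(list(tree.tip_labels), np.array([[0], [0]], dtype=np.int8))
        d_total = 2 * 50.0 * 0.03
        expected = 0.25 * jc_transition(True, d_total)
        ll = jc_log_likelihood(tree, aln, ClockModel(0.03))
        assert ll == pytest.approx(np.log(expected), abs=1e-10)

    def test_invariant_under_base_relabelling(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(6, 20.0, 0.1, 2), seed=2)
        aln = simulate_alignment(tree, 30, ClockModel(0.03), seed=3)
        ll0 = jc_log_likelihood(tree, aln, ClockModel(0.03))
        perm = np.array([2, 3, 0, 1], dtype=np.int8)  # a permutation of ACGT
        permuted = Alignment(aln.taxa, perm[aln.codes])
        assert jc_log_likelihood(tree, permuted, ClockModel(0.03)) == pytest.approx(ll0)

    def test_matches_exhaustive_enumeration(self):
        """Pruning equals brute-force summation over all internal state maps."""
        tree = simulate_yule_conditioned(YuleCladeSpec(5, 30.0, 0.05, 2), seed=4)
        clock = ClockModel(0.03)
        aln = simulate_alignment(tree, 20, clock, seed=5)
        codes = aln.codes[[aln.taxa.index(t) for t in tree.tip_labels]]
        internals = list(range(5, 9))
        ll_brute = 0.0
        for s in range(20):
            site_like = 0.0
            for assign in itertools.product(range(4), repeat=4):
                state = {v: a for v, a in zip(internals, assign)}
                for tip in range(5):
                    state[tip] = codes[tip, s]
                prob = 0.25
                for v in internals:
                    for c in tree.children[v]:
                        d = clock.subst_rate * (tree.ages[v] - tree.ages[int(c)])
                        prob *= jc_transition(state[v] == state[int(c)], d)
                site_like += prob
            ll_brute += np.log(site_like)
        ll = jc_log_likelihood(tree, aln, clock)
        assert ll == pytest.approx(ll_brute, abs=1e-8)

    def test_kernel_agrees_with_reference_likelihood(self):
        # the compiled MCMC kernel and the numpy implementation are
        # independent code paths; they must agree at the starting state
        from largeclade import _kernels

        tree = simulate_yule_conditioned(YuleCladeSpec(30, 80.0, 0.04, 2), seed=6)
        clock = ClockModel(0.03)
        aln = simulate_alignment(tree, 100, clock, seed=7)
        codes = aln.codes[[aln.taxa.index(t) for t in tree.tip_labels]]
        n_int = tree.n_tips - 1
        partials = np.zeros((2 * n_int, 100, 4))
        logscale = np.zeros((2 * n_int, 100))
        cur = np.zeros(n_int, dtype=np.int8)
        pend = np.zeros(n_int, dtype=np.int8)
        ll_kernel = _kernels._propose_full(
            tree.postorder_internal(), tree.children, tree.ages, codes, partials,
            logscale, cur, pend, clock.subst_rate, tree.n_tips, tree.root,
        )
        assert ll_kernel == pytest.approx(jc_log_likelihood(tree, aln, clock), abs=1e-8)

    def test_rejects_mismatched_taxa(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(4, 10.0, 0.1, 2), seed=8)
        aln = Alignment(["x1", "x2", "x3", "x4"], np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            jc_log_likelihood(tree, aln, ClockModel(0.03))


class TestYulePrior:
    def test_log_density_difference_is_linear_in_age_sum(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(10, 50.0, 0.05, 2), seed=9)
        lam = 0.07
        base = yule_log_prior(tree, lam)
        ages = tree.ages.copy()
        # shrink every non-root internal age by 10%
        root = tree.root
        nonroot = [v for v in range(10, tree.n_nodes) if v != root]
        ages[nonroot] = 0.9 * ages[nonroot]
        shifted = yule_log_prior(tree, lam, ages=ages)
        d_sum = tree.ages[nonroot].sum() - ages[nonroot].sum()
        assert shifted - base == pytest.approx(lam * d_sum, rel=1e-9)

    def test_monotone_decreasing_in_node_ages(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(8, 40.0, 0.06, 2), seed=10)
        lam = 0.05
        vals = []
        for shrink in (1.0, 0.8, 0.6):
            ages = tree.ages.copy()
            root = tree.root
            nonroot = [v for v in range(8, tree.n_nodes) if v != root]
            ages[nonroot] = shrink * ages[nonroot]
            vals.append(yule_log_prior(tree, lam, ages=ages))
        assert vals[0] < vals[1] < vals[2]

    def test_invalid_configuration_scores_minus_inf(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(6, 30.0, 0.05, 2), seed=11)
        ages = tree.ages.copy()
        root = tree.root
        v = next(v for v in range(6, tree.n_nodes) if v != root)
        ages[v] = ages[root] + 10.0  # older than its parent
        assert yule_log_prior(tree, 0.05, ages=ages) == -np.inf


class TestPriorSampling:
    def test_prior_only_mcmc_matches_conditioned_simulator(self):
        """With the root fixed and the likelihood off, MCMC node ages must
        reproduce the truncated-exponential law of the conditioned Yule
        simulator — the strongest guard against a mis-specified prior."""
        lam, T, n = 0.05, 60.0, 10
        tree = simulate_yule_conditioned(YuleCladeSpec(n, T, lam, 2), seed=12)
        cfg = MCMCConfig(
            n_steps=400_000, thin=200, burnin=0.2, prior_only=True,
            sample_birth_rate=False, fix_root=True, init_birth_rate=lam, seed=13,
        )
        chain = run_mcmc(None, tree, ClockModel(0.03), cfg)
        # one random non-root age per snapshot, to keep draws near-independent
        rng = np.random.default_rng(14)
        root_col = tree.root - n
        cols = [c for c in range(n - 1) if c != root_col]
        picks = chain.node_ages[np.arange(len(chain.node_ages)), rng.choice(cols, len(chain.node_ages))]
        oracle = sample_branching_ages(4000, T, lam, rng)
        assert stats.ks_2samp(picks, oracle).pvalue > 0.01

    def test_zero_data_equals_prior_only(self):
        # a zero-length alignment contributes nothing: root-height law matches
        # the prior-only chain's
        lam, T, n = 0.08, 40.0, 8
        tree = simulate_yule_conditioned(YuleCladeSpec(n, T, lam, 2), seed=15)
        empty = Alignment(list(tree.tip_labels), np.zeros((n, 0), dtype=np.int8))
        cfg = MCMCConfig(
            n_steps=200_000, thin=100, burnin=0.2, sample_birth_rate=False,
            init_birth_rate=lam, seed=16,
        )
        ch_data = run_mcmc(empty, tree, ClockModel(0.03), cfg)
        ch_prior = run_mcmc(
            None, tree, ClockModel(0.03),
            MCMCConfig(
                n_steps=200_000, thin=100, burnin=0.2, prior_only=True,
                sample_birth_rate=False, init_birth_rate=lam, seed=17,
            ),
        )
        assert stats.ks_2samp(ch_data.root_height[::4], ch_prior.root_height[::4]).pvalue > 0.01


class TestHPD:
    def test_constant_samples(self):
        assert hpd_interval([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_normal_quantiles(self):
        x = np.random.default_rng(18).normal(size=100_000)
        lo, hi = hpd_interval(x, 0.95)
        # HPD endpoints wobble more than plain quantiles at a flat density edge
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_uniform_interval_length(self):
        x = np.random.default_rng(19).random(100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            hpd_interval([])


class TestESS:
    def test_iid_draws(self):
        x = np.random.default_rng(20).normal(size=1000)
        assert effective_sample_size(x) == pytest.approx(1000, rel=0.15)

    def test_ar1_known_act(self):
        # AR(1) with rho=0.5 has ESS = n (1-rho)/(1+rho) = n/3
        rng = np.random.default_rng(21)
        n, rho = 100_000, 0.5
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        assert effective_sample_size(x) == pytest.approx(n / 3, rel=0.1)

    def test_constant_chain_convention(self):
        assert effective_sample_size(np.ones(500)) == 500
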