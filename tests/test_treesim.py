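"""Birth–death trajectories and conditioned Yule tree simulation."""

import numpy as np
import pytest
from scipy import stats

from largeclade import (
    BDParams,
    UltrametricTree,
    YuleCladeSpec,
    expected_clade_size,
    rate_for_expected_size,
    simulate_bd_trajectory,
    simulate_yule_conditioned,
    simulate_yule_forward,
)
from largeclade.cladesize import CladeSizeModel, clade_size_pmf


class TestTrajectory:
    def test_counts_change_by_one_and_zero_absorbs(self):
        traj = simulate_bd_trajectory(BDParams(0.544, 0.5), n0=1, t_max=200.0, seed=1)
        steps = np.diff(traj.counts)
        assert np.all(np.isin(steps, [-1, 1]))
        if traj.outcome == "extinct":
            assert traj.counts[-1] == 0
            assert np.all(traj.counts[:-1] > 0)

    def test_pure_birth_never_decreases(self):
        traj = simulate_bd_trajectory(BDParams(0.1, 0.0), n0=1, t_max=50.0, seed=2)
        assert traj.outcome == "surviving"
        assert np.all(np.diff(traj.counts) == 1)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_bd_trajectory(BDParams(0.5, 0.1), n0=0, t_max=10.0)
        with pytest.raises(ValueError):
            simulate_bd_trajectory(BDParams(0.5, 0.1), n0=1, t_max=0.0)
        with pytest.raises(ValueError):
            BDParams(-0.1, 0.0)

    def test_extinction_fraction_matches_branching_theory(self):
        # ultimate extinction probability of a supercritical birth-death clade
        # started from one species is mu/lambda
        params = BDParams(0.544, 0.5)
        rng = np.random.default_rng(42)
        n_reps = 4000
        extinct = sum(
            simulate_bd_trajectory(params, 1, t_max=400.0, seed=rng, n_cap=2000).outcome
            == "extinct"
            for _ in range(n_reps)
        )
        p_hat = extinct / n_reps
        p_true = 0.5 / 0.544
        se = np.sqrt(p_true * (1 - p_true) / n_reps)
        assert abs(p_hat - p_true) < 4 * se

    def test_small_clades_mostly_die_quickly(self):
        # near-critical regime: most single-founder clades are absorbed early
        params = BDParams(0.544, 0.5)
        rng = np.random.default_rng(7)
        outcomes = [
            simulate_bd_trajectory(params, 1, t_max=1000.0, seed=rng, n_cap=1000)
            for _ in range(300)
        ]
        frac_extinct = np.mean([t.outcome == "extinct" for t in outcomes])
        assert frac_extinct > 0.8


class TestConditionedYule:
    def test_exact_conditioning(self):
        spec = YuleCladeSpec(n_tips=200, age=100.0, birth_rate=0.0461, n_founders=2)
        tree = simulate_yule_conditioned(spec, seed=1)
        assert tree.n_tips == 200
        assert tree.root_age == pytest.approx(100.0)
        tree.validate()

    def test_two_tip_tree_is_deterministic(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(2, 100.0, 0.01, 2), seed=3)
        assert tree.n_tips == 2
        assert tree.branch_length(0) == pytest.approx(100.0)
        assert tree.branch_length(1) == pytest.approx(100.0)

    def test_stem_conditioning_records_origin(self):
        tree = simulate_yule_conditioned(YuleCladeSpec(5, 10.0, 0.3, 1), seed=4)
        assert tree.origin_age == pytest.approx(10.0)
        assert tree.root_age < 10.0

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            YuleCladeSpec(n_tips=1, age=10.0, birth_rate=0.1, n_founders=2)

    def test_matches_rejection_sampling_oracle(self):
        """Oldest non-root branching age agrees in law with the forward-process
        rejection sampler (Yule from 2 lineages, kept iff exactly 5 tips at T=1)."""
        n, T, lam = 5, 1.0, 1.0
        rng = np.random.default_rng(11)
        oracle = []
        while len(oracle) < 3000:
            tips, ages = simulate_yule_forward(lam, T, 2, rng)
            if tips == n:
                oracle.append(ages.max())
        sim = []
        for _ in range(3000):
            tree = simulate_yule_conditioned(YuleCladeSpec(n, T, lam, 2), rng)
            sim.append(tree.internal_ages(include_root=False).max())
        assert stats.ks_2samp(oracle, sim).pvalue > 0.01

    def test_root_split_is_uniform(self):
        # the tip count of one root child is uniform on {1, .., N-1}
        n = 6
        rng = np.random.default_rng(13)
        counts = np.zeros(n - 1, dtype=int)
        for _ in range(4000):
            tree = simulate_yule_conditioned(YuleCladeSpec(n, 1.0, 0.8, 2), rng)
            c0 = int(tree.children[tree.root][0])
            counts[_subtree_tip_count(tree, c0) - 1] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_forward_tip_counts_match_analytic_pmf(self):
        # unconditioned crown Yule sizes are negative binomial (2 successes)
        lam, T = 0.7, 1.0
        rng = np.random.default_rng(17)
        sizes = np.array([simulate_yule_forward(lam, T, 2, rng)[0] for _ in range(8000)])
        model = CladeSizeModel.from_rate_age(lam, T, 2)
        kmax = 14
        observed = np.array([(sizes == k).sum() for k in range(2, kmax)])
        observed = np.append(observed, (sizes >= kmax).sum())
        expect = clade_size_pmf(model, np.arange(2, kmax)) * len(sizes)
        expect = np.append(expect, len(sizes) - expect.sum())
        assert stats.chisquare(observed, expect).pvalue > 0.01


def _subtree_tip_count(tree: UltrametricTree, node: int) -> int:
    stack, count = [node], 0
    while stack:
        v = stack.pop()
        if tree.is_tip(v):
            count += 1
        else:
            stack.extend(int(c) for c in tree.children[v])
    return count


class TestSizeRateRelations:
    @pytest.mark.parametrize(
        "rate, age, f, expected",
        [
            (0.0461, 100.0, 2, 200.97),  # the reference 1x condition
            (0.0230, 100.0, 2, 19.95),  # the 10x-too-large condition
            (0.0, 50.0, 2, 2.0),
        ],
    )
    def test_expected_clade_size(self, rate, age, f, expected):
        assert expected_clade_size(rate, age, f) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "n, age, f, expected",
        [(400, 100.0, 2, 0.0530), (200, 100.0, 2, 0.0461), (2 * np.e, 1.0, 2, 1.0)],
    )
    def test_rate_for_expected_size(self, n, age, f, expected):
        assert rate_for_expected_size(n, age, f) == pytest.approx(expected, abs=5e-5)

    def test_round_trip(self):
        for lam in (0.01, 0.0461, 0.3):
            n = expected_clade_size(lam, 100.0, 2)
            assert rate_for_expected_size(n, 100.0, 2) == pytest.approx(lam, rel=1e-12)

    def test_rejects_tiny_expectation(self):
        with pytest.raises(ValueError):
            rate_for_expected_size(2.0, 100.0, 2)


class TestNewickRoundTrip:
    def test_simulated_tree_round_trips(self, tmp_path):
        tree = simulate_yule_conditioned(YuleCladeSpec(20, 50.0, 0.05, 2), seed=5)
        path = tmp_path / "tree.nwk"
        tree.write(str(path))
        back = UltrametricTree.read(str(path))
        assert back.n_tips == 20
        assert back.root_age == pytest.approx(50.0, abs=1e-6)
        assert sorted(back.tip_labels) == sorted(tree.tip_labels)
        assert np.allclose(
            np.sort(back.ages[back.n_tips:]), np.sort(tree.ages[tree.n_tips:]), atol=1e-6
        )

    def test_nexus_round_trips(self, tmp_path):
        tree = simulate_yule_conditioned(YuleCladeSpec(8, 10.0, 0.2, 2), seed=6)
        path = tmp_path / "tree.nex"
        tree.write(str(path), schema="nexus")
        back = UltrametricTree.read(str(path), schema="nexus")
        assert back.root_age == pytest.approx(10.0, abs=1e-6)
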