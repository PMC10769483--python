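import numpy as np
import pytest

from mmscore import (
    Mixture,
    OptimizerConfig,
    PenaltyConfig,
    PotencyMatrix,
    TargetSpec,
    dilute_to_threshold,
    eligible_pool,
    enumerate_combinations,
    optimize_concentrations,
    run_mms,
)
from mmscore.optimizer import _score_mixture
from tests.conftest import orthogonal_binary_matrix

TIGHT = PenaltyConfig(mu=200.0)


def _matrix(compounds, kinases, values, **kw):
    return PotencyMatrix(compounds, kinases, np.asarray(values, dtype=float), "affinity", **kw)


class TestEligiblePool:
    def test_potency_boundary_at_111_nM(self):
        m = _matrix(["ok", "weak"], ["T"], [[110.0], [120.0]])
        spec = TargetSpec(targets=("T",))
        # 110 nM -> 90.1% activity at 1 uM (eligible); 120 nM -> 89.3%
        assert eligible_pool(m, spec) == ["ok"]

    def test_multitarget_pool_admits_single_target_potency(self):
        m = _matrix(["a", "b"], ["T1", "T2"], [[10.0, 1e5], [1e5, 10.0]])
        spec = TargetSpec(targets=("T1", "T2"))
        assert eligible_pool(m, spec) == ["a", "b"]

    def test_empty_pool(self):
        m = _matrix(["weak"], ["T"], [[5000.0]])
        assert eligible_pool(m, TargetSpec(targets=("T",))) == []


class TestEnumerateCombinations:
    def test_binomial_counts_without_feasibility_pressure(self):
        n = 10
        m = _matrix(
            [f"c{j}" for j in range(n)], ["T"], [[10.0]] * n
        )
        spec = TargetSpec(targets=("T",))
        combos = enumerate_combinations(eligible_pool(m, spec), 3, m, spec)
        assert [len(combos[i]) for i in (1, 2, 3)] == [10, 45, 120]

    def test_complementary_pair_feasible_singles_not(self):
        m = _matrix(["a", "b"], ["T1", "T2"], [[10.0, np.nan], [np.nan, 10.0]])
        spec = TargetSpec(targets=("T1", "T2"))
        combos = enumerate_combinations(["a", "b"], 2, m, spec)
        assert combos[1] == [] and combos[2] == [("a", "b")]

    def test_low_cap_drops_everything(self):
        m = _matrix(["a"], ["T"], [[500.0]])
        spec = TargetSpec(targets=("T",))
        # 90% needs 4.5 uM; a 1 uM cap is insufficient
        combos = enumerate_combinations(["a"], 1, m, spec, max_conc=1000.0)
        assert combos[1] == []
        res = run_mms(m, spec, TIGHT, OptimizerConfig(max_conc=1000.0), seed=0)
        assert res.verdict == "infeasible"


class TestOptimizeConcentrations:
    def test_single_compound_is_dilution_only(self):
        m = _matrix(["a"], ["T", "O"], [[50.0, 500.0]])
        spec = TargetSpec(targets=("T",))
        penalty = TIGHT.build(seed=0)
        mix, score = optimize_concentrations(("a",), m, spec, penalty,
                                             OptimizerConfig(), seed=1)
        expected = dilute_to_threshold(Mixture((("a", 1000.0),)), m, spec)
        assert mix.components == expected.components
        assert 0 <= score.jsd <= 1

    @pytest.mark.parametrize("K", [30.0, 50.0, 80.0])
    def test_matches_exhaustive_grid_on_two_compound_toy(self, K):
        # shared target, disjoint single off-targets, all affinities equal;
        # a 61-point log-grid over the concentration ratio is the oracle.
        # Scoring uses enough noise samples to make the landscape stable.
        m = _matrix(
            ["A", "B"], ["T", "OA", "OB"], [[K, K, np.nan], [K, np.nan, K]]
        )
        spec = TargetSpec(targets=("T",))
        penalty = TIGHT.build(seed=0)
        config = OptimizerConfig(R1=2.0, R2=1.01, samples_per_kinase=10_000)
        seed = 123
        mix, score = optimize_concentrations(("A", "B"), m, spec, penalty, config, seed=seed)

        aff_rows = m.affinities()[[0, 1], :]
        ocols = spec.offtarget_indices(m)
        best_grid = 0.0
        for ratio in np.logspace(-3, 3, 61):
            cand = dilute_to_threshold(
                Mixture((("A", 1000.0 * ratio), ("B", 1000.0))), m, spec, R2=config.R2
            )
            s = _score_mixture(cand, aff_rows, ocols, penalty, config, seed)
            best_grid = max(best_grid, s)
        assert score.jsd >= best_grid - 0.005

    def test_incumbent_trace_is_monotone(self):
        rng = np.random.default_rng(0)
        spec_cols = ["T", "O1", "O2", "O3", "O4"]
        for _ in range(20):
            vals = np.where(
                rng.random((3, 5)) < 0.5, rng.uniform(20, 2000, (3, 5)), np.nan
            )
            vals[:, 0] = rng.uniform(20, 100, 3)  # everyone potent on target
            m = _matrix(["a", "b", "c"], spec_cols, vals)
            spec = TargetSpec(targets=("T",))
            penalty = TIGHT.build(seed=int(rng.integers(2**31)))
            _, _, trace = optimize_concentrations(
                ("a", "b", "c"), m, spec, penalty, OptimizerConfig(),
                seed=int(rng.integers(2**31)), return_trace=True,
            )
            assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_penalty_free_compound_comes_to_dominate(self):
        # B's off-target is inert (activity far below any penalty); the
        # optimizer should push the mixture toward B
        m = _matrix(
            ["A", "B"],
            ["T", "Obad", "Onone"],
            [[50.0, 50.0, np.nan], [50.0, np.nan, 1e6]],
        )
        spec = TargetSpec(targets=("T",))
        penalty = TIGHT.build(seed=0)
        mix, _ = optimize_concentrations(
            ("A", "B"), m, spec, penalty, OptimizerConfig(), seed=5
        )
        conc = dict(mix.components)
        assert conc["B"] > conc["A"]

    def test_self_consistency_of_returned_score(self):
        m = _matrix(
            ["A", "B"],
            ["T", "O1", "O2"],
            [[50.0, 80.0, np.nan], [60.0, np.nan, 120.0]],
        )
        spec = TargetSpec(targets=("T",))
        penalty = TIGHT.build(seed=0)
        config = OptimizerConfig()
        mix, score = optimize_concentrations(("A", "B"), m, spec, penalty, config, seed=77)
        aff_rows = m.affinities()[[0, 1], :]
        rescored = _score_mixture(mix, aff_rows, spec.offtarget_indices(m),
                                  penalty, config, 77)
        assert rescored == score.jsd


class TestRunMMS:
    def test_clean_single_wins(self):
        # one compound hits only the target; no combination can beat it
        m = _matrix(
            ["clean", "dirty"],
            ["T", "O1", "O2"],
            [[50.0, np.nan, np.nan], [50.0, 60.0, 60.0]],
        )
        spec = TargetSpec(targets=("T",))
        res = run_mms(m, spec, PenaltyConfig(mu=1200.0), OptimizerConfig(max_i=2), seed=3)
        assert res.best_single.compounds == ("clean",)
        assert res.verdict == "single_better_or_tied"

    def test_orthogonal_trio_beats_any_single(self):
        m = orthogonal_binary_matrix(3)
        spec = TargetSpec(targets=("T",))
        res = run_mms(m, spec, TIGHT, OptimizerConfig(max_i=3), seed=7)
        assert res.verdict == "combination_better"
        assert res.best_combination.compounds == ("I0", "I1", "I2")
        assert res.delta.p_value < 0.05 and res.delta.mean_delta >= 0.001

    def test_output_mixtures_satisfy_threshold(self):
        m = orthogonal_binary_matrix(3)
        spec = TargetSpec(targets=("T",))
        res = run_mms(m, spec, TIGHT, OptimizerConfig(max_i=3), seed=7)
        from mmscore import mixture_profile

        for r in res.ranked:
            prof = mixture_profile(r.mixture, m, spec)
            assert np.all(prof.target_activities >= spec.on_target_threshold - 1e-9)

    def test_fixed_seed_reproduces_everything(self):
        m = orthogonal_binary_matrix(3)
        spec = TargetSpec(targets=("T",))
        a = run_mms(m, spec, TIGHT, OptimizerConfig(max_i=2), seed=11)
        b = run_mms(m, spec, TIGHT, OptimizerConfig(max_i=2), seed=11)
        assert [r.compounds for r in a.ranked] == [r.compounds for r in b.ranked]
        assert [r.scores for r in a.ranked] == [r.scores for r in b.ranked]
        assert a.best_combination.mixture.components == b.best_combination.mixture.components
        assert a.reproducibility == b.reproducibility

    def test_activity_kind_stays_equimolar(self):
        vals = np.full((3, 4), 2.0)
        vals[:, 0] = 95.0  # all potent on the target
        vals[0, 1] = vals[1, 2] = vals[2, 3] = 95.0
        m = PotencyMatrix(
            ["a", "b", "c"], ["T", "O1", "O2", "O3"], vals, "activity"
        )
        spec = TargetSpec(targets=("T",))
        res = run_mms(m, spec, TIGHT, OptimizerConfig(max_i=3), seed=2)
        for r in res.ranked:
            conc = r.mixture.concentrations
            assert np.allclose(conc, conc[0])

    def test_mutant_target_excluded_from_offtargets(self, small_affinity_matrix):
        spec = TargetSpec(targets=("K4(D835Y)",))
        res = run_mms(
            small_affinity_matrix, spec, TIGHT, OptimizerConfig(max_i=2), seed=4
        )
        assert res.verdict != "infeasible"
        assert "K4(D835Y)" not in spec.resolve_offtargets(small_affinity_matrix)
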