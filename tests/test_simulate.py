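"""Simulators vs exact modules; time-independence; fixture generator."""

import numpy as np
import pytest
from scipy import stats

from clonedist import (
    FateProbabilities,
    MutationModel,
    SimulationConfig,
    clone_count_distribution,
    clone_state_distribution,
    estimate_fate_ratio,
    extinction_probability,
    generate_count_fixture,
    neutral_distribution,
    ruin_probabilities,
    simulate_homeostasis,
    simulate_mutation_growth,
)

FATE = FateProbabilities(0.415, 0.278, 0.307)


class TestSimulateHomeostasis:
    def test_pd_only_keeps_single_progenitor(self):
        config = SimulationConfig(
            fate=FateProbabilities(0.0, 1.0, 0.0), stop_size=9, replicates=64, seed=1
        )
        res = simulate_homeostasis(config)
        assert np.all(res.final_k == 1)
        assert np.all(res.final_n == 9)

    def test_determinism(self):
        config = SimulationConfig(fate=FATE, stop_size=8, replicates=500, seed=9)
        r1 = simulate_homeostasis(config)
        r2 = simulate_homeostasis(config)
        assert np.array_equal(r1.final_k, r2.final_k)
        assert np.array_equal(r1.final_n, r2.final_n)

    def test_matches_exact_state_distribution(self):
        # empirical P(k | active at size n) vs the Motzkin-path distribution
        n = 5
        config = SimulationConfig(fate=FATE, stop_size=n, replicates=20_000, seed=12)
        res = simulate_homeostasis(config)
        active = ~res.absorbed
        exact = np.array([float(p) for p in clone_state_distribution(n, FATE).probs[1:]])
        exact /= exact.sum()
        counts = np.bincount(res.final_k[active] - 1, minlength=n)
        total = active.sum()
        for k_idx in range(n):
            p = exact[k_idx]
            se = np.sqrt(p * (1 - p) / total)
            assert abs(counts[k_idx] / total - p) < 3.5 * se + 1e-9

    def test_absorbed_sizes_match_ruin_series(self):
        config = SimulationConfig(fate=FATE, stop_size=12, replicates=20_000, seed=13)
        res = simulate_homeostasis(config)
        ruin = np.array([float(p) for p in ruin_probabilities(11, FATE).probs])
        for i, p in enumerate(ruin):
            se = np.sqrt(p * (1 - p) / config.replicates)
            emp = float((res.absorbed_sizes == i + 2).sum()) / config.replicates
            assert abs(emp - p) < 3.5 * se + 1e-9

    def test_continuous_mode_records_times(self):
        config = SimulationConfig(
            fate=FATE, stop_size=6, replicates=100, seed=4, time_mode="continuous"
        )
        res = simulate_homeostasis(config)
        assert res.final_time is not None
        assert np.all(res.final_time[res.divisions > 0] > 0)

    def test_embedded_chain_equivalence(self):
        # the continuous-time simulator's embedded chain and the discrete
        # jump chain give the same state distribution at a fixed size
        n = 6
        reps = 50_000
        res_j = simulate_homeostasis(
            SimulationConfig(fate=FATE, stop_size=n, replicates=reps, seed=21)
        )
        res_c = simulate_homeostasis(
            SimulationConfig(
                fate=FATE, stop_size=n, replicates=reps, seed=22, time_mode="continuous"
            )
        )
        table = []
        for res in (res_j, res_c):
            active = ~res.absorbed
            table.append(np.bincount(res.final_k[active], minlength=n + 1)[1:])
        chi2 = stats.chi2_contingency(np.array(table))
        assert chi2.pvalue > 0.01

    def test_missing_fate_rejected(self):
        with pytest.raises(ValueError):
            simulate_homeostasis(SimulationConfig(stop_size=5))


class TestSimulateMutationGrowth:
    def test_no_mutation_no_mutants(self):
        config = SimulationConfig(model=MutationModel(0.0), stop_size=50,
                                  replicates=200, seed=3)
        res = simulate_mutation_growth(config)
        assert np.all(res.mutant_counts == 0)

    def test_determinism(self):
        config = SimulationConfig(model=MutationModel(0.1), stop_size=30,
                                  replicates=300, seed=8)
        assert np.array_equal(
            simulate_mutation_growth(config).mutant_counts,
            simulate_mutation_growth(config).mutant_counts,
        )

    def test_neutral_histogram_matches_exact(self):
        # quick-power version; the full 1e5-replicate TV < 0.01 check runs in
        # the acceptance suite
        k = 100
        config = SimulationConfig(model=MutationModel(0.05), stop_size=k,
                                  replicates=30_000, seed=14)
        res = simulate_mutation_growth(config)
        exact = np.asarray(neutral_distribution(k, MutationModel(0.05)).probs)
        emp = np.bincount(res.mutant_counts, minlength=k) / config.replicates
        assert 0.5 * np.abs(emp - exact).sum() < 0.03

    def test_selection_reduction_distributional(self):
        # rho = 1 growth must be indistinguishable from the neutral exact law
        k = 60
        config = SimulationConfig(model=MutationModel(0.1, rho=1.0), stop_size=k,
                                  replicates=30_000, seed=15)
        res = simulate_mutation_growth(config)
        exact = np.asarray(neutral_distribution(k, MutationModel(0.1)).probs)
        emp = np.bincount(res.mutant_counts, minlength=k) / config.replicates
        assert 0.5 * np.abs(emp - exact).sum() < 0.03

    def test_genotype_clone_count_matches_binomial(self):
        k = 20
        model = MutationModel.from_lambda(0.05)
        config = SimulationConfig(model=model, stop_size=k, replicates=5_000,
                                  seed=16, genotype=True)
        res = simulate_mutation_growth(config)
        cs = np.array([rec.n_clones for rec in res.genotype_records])
        exact = clone_count_distribution(k, model)
        assert abs(cs.mean() - exact.mean()) < 3 * cs.std() / np.sqrt(len(cs))

    def test_genotype_mutation_labels_unique(self):
        config = SimulationConfig(model=MutationModel.from_lambda(0.3), stop_size=15,
                                  replicates=50, seed=17, genotype=True)
        res = simulate_mutation_growth(config)
        for rec in res.genotype_records:
            # every mutation is tracked once and carried by >= 1 cell
            assert all(count >= 1 for count in rec.mutation_cell_counts)
            assert sum(rec.lineage_clone_sizes) == 15
            assert sum(rec.genotype_clone_sizes) == 15

    def test_rho_conflict_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(model=MutationModel(0.1, rho=2.0), beta_n=1.0,
                             beta_m=1.0, stop_size=10)

    def test_stop_size_required(self):
        with pytest.raises(ValueError):
            simulate_mutation_growth(SimulationConfig(model=MutationModel(0.1)))


class TestExtinctionAgreement:
    def test_absorbed_fraction_matches_extinction_probability(self):
        config = SimulationConfig(fate=FATE, max_divisions=2_000,
                                  replicates=20_000, seed=18)
        res = simulate_homeostasis(config)
        p0 = float(extinction_probability(FATE))
        se = np.sqrt(p0 * (1 - p0) / config.replicates)
        assert abs(res.absorbed.mean() - p0) < 3.5 * se


class TestCountFixture:
    def test_dd_only_gives_two_cell_clones(self):
        counts = generate_count_fixture(
            FateProbabilities(0.0, 0.0, 1.0), n_clones=500, seed=5
        )
        assert counts.counts == {2: 500}
        assert counts.n_censored == 0

    def test_determinism(self):
        c1 = generate_count_fixture(FATE, 2_000, seed=6)
        c2 = generate_count_fixture(FATE, 2_000, seed=6)
        assert c1.counts == c2.counts and c1.n_censored == c2.n_censored

    def test_small_size_ratios_match_ruin_series(self):
        counts = generate_count_fixture(FATE, 100_000, seed=19)
        # ratios N3/N2 and N4/N3 estimate b and (b^2+ac)/b
        b = 0.278
        r32 = counts[3] / counts[2]
        r43 = counts[4] / counts[3]
        se32 = np.sqrt(b / counts[2])  # rough Poisson-ratio scale
        assert abs(r32 - b) < 3.5 * se32
        expected43 = (b**2 + 0.415 * 0.307) / b
        se43 = np.sqrt(expected43 / counts[3])
        assert abs(r43 - expected43) < 3.5 * se43

    def test_estimator_round_trip_feasible(self):
        counts = generate_count_fixture(FATE, 50_000, seed=20)
        est = estimate_fate_ratio(counts)
        assert est.feasible
        assert est.fate.b == pytest.approx(0.278, abs=0.02)
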