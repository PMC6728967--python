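import math

import numpy as np
import pandas as pd
import pytest

from coevokit.design import (
    UndefinedCorrelationError,
    classify_thermostability,
    dee_eliminate,
    exhaustive_optimum,
    metropolis_design,
    mutation_scan,
    optimize_alpha,
    stability_table,
)
from coevokit.fixtures import make_stability_table
from coevokit.potts import PottsModel, potts_score
from coevokit.alphabet import reduced_alphabet

from conftest import random_potts


class TestMutationScan:
    def test_self_substitution_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        model = random_potts(8, 4, rng)
        seq = rng.integers(0, 4, 8)
        scan = mutation_scan(model, seq)
        assert np.all(scan.delta[np.arange(8), seq] == 0.0)

    def test_single_coupling_arithmetic(self):
        e = np.zeros((2, 2, 21, 21))
        e[0, 1, 0, 1] = 1.5  # e_12(A, C)
        e[1, 0, 1, 0] = 1.5
        model = PottsModel(np.zeros((2, 21)), e, gauge="none")
        scan = mutation_scan(model, np.array([0, 1]))  # (A, C)
        assert scan.delta[1, 2] == pytest.approx(-1.5)  # C -> D

    @pytest.mark.parametrize("seed", range(4))
    def test_incremental_equals_full_rescoring(self, seed):
        rng = np.random.default_rng(seed)
        model = random_potts(10, 4, rng)
        seq = rng.integers(0, 4, 10)
        scan = mutation_scan(model, seq)
        wt = potts_score(model, seq)
        for i in range(10):
            for b in range(4):
                mut = seq.copy()
                mut[i] = b
                full = potts_score(model, mut)
                expected = (full.E_s + full.E_c) - (wt.E_s + wt.E_c)
                assert scan.delta[i, b] == pytest.approx(expected, abs=1e-10)

    def test_pcc_mode_respects_sigma_filter(self):
        from test_potts import make_profile
        from coevokit.potts import pcc_energy

        rng = np.random.default_rng(5)
        model = random_potts(6, 3, rng)
        profile = make_profile(model, rng.random(6))
        sigma = 0.5
        seq = rng.integers(0, 3, 6)
        scan = mutation_scan(model, seq, profile, sigma)
        base = pcc_energy(model, profile, seq, sigma)
        for i in range(6):
            for b in range(3):
                mut = seq.copy()
                mut[i] = b
                expected = pcc_energy(model, profile, mut, sigma) - base
                assert scan.delta[i, b] == pytest.approx(expected, abs=1e-10)


class TestOptimizeAlpha:
    def test_pure_site_signal_gives_alpha_near_zero(self):
        rng = np.random.default_rng(1)
        es = rng.normal(0, 1, 40)
        ec = rng.normal(0, 1, 40)
        table = stability_table([f"s{i}" for i in range(40)], es, ec,
                                measured=es)
        a, corr = optimize_alpha(table)
        assert abs(a) <= 0.01
        assert corr == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("planted", [-0.43, 0.7])
    def test_planted_alpha_recovered(self, planted):
        sc = make_stability_table(n_families=1, seqs_per_family=60,
                                  planted_alpha=planted, noise_sd=0.05,
                                  seed=4)
        a, corr = optimize_alpha(sc.table)
        assert abs(a - planted) <= 0.0101
        assert abs(corr) > 0.99

    def test_noiseless_recovery_exact_to_grid(self):
        sc = make_stability_table(n_families=1, seqs_per_family=20,
                                  planted_alpha=-0.43, noise_sd=0.0, seed=2)
        a, corr = optimize_alpha(sc.table)
        assert a == pytest.approx(-0.43, abs=1e-9)
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        table = stability_table(["a", "b"], [1.0, 2.0], [0.5, 0.3],
                                measured=[3.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            optimize_alpha(table)  # n = 2 < 3
        table = stability_table(["a", "b", "c"], [1.0, 2.0, 3.0],
                                [0.1, 0.2, 0.3], measured=[5.0, 5.0, 5.0])
        with pytest.raises(UndefinedCorrelationError):
            optimize_alpha(table)  # constant measured


class TestClassifyThermostability:
    def test_separable_planting_fully_distinguished(self):
        sc = make_stability_table(n_families=6, seqs_per_family=10,
                                  planted_alpha=-0.43, noise_sd=0.0, seed=3)
        report = classify_thermostability(sc.table, alpha=-0.43)
        assert report.attrs["fraction_distinguished"] == 1.0
        assert len(report) == 6

    def test_shuffled_labels_near_chance(self):
        sc = make_stability_table(n_families=200, seqs_per_family=8,
                                  planted_alpha=-0.43, noise_sd=0.0, seed=5)
        rng = np.random.default_rng(6)
        shuffled = sc.table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        report = classify_thermostability(shuffled, alpha=-0.43)
        assert 0.3 < report.attrs["fraction_distinguished"] < 0.7

    def test_single_family_one_row(self):
        table = stability_table(
            ["a", "b"], [1.0, 0.0], [0.0, 1.0],
            family=["f1", "f1"], label=["mesophilic", "thermophilic"])
        report = classify_thermostability(table, alpha=1.0)
        assert len(report) == 1

    def test_family_missing_class_skipped_with_warning(self):
        table = stability_table(
            ["a", "b", "c"], [1.0, 0.0, 2.0], [0.0, 1.0, 1.0],
            family=["f1", "f1", "f2"],
            label=["mesophilic", "thermophilic", "mesophilic"])
        with pytest.warns(UserWarning):
            report = classify_thermostability(table, alpha=0.5)
        assert list(report["family"]) == ["f1"]


class TestDEE:
    def test_single_position_keeps_only_argmax(self):
        rng = np.random.default_rng(7)
        h = rng.normal(0, 1, (1, 5))
        model = PottsModel(h, np.zeros((1, 1, 5, 5)), gauge="none",
                           alphabet=reduced_alphabet(5))
        pruned = dee_eliminate(model)
        assert pruned[0] == [int(h[0].argmax())]

    def test_zero_model_eliminates_nothing(self):
        model = PottsModel(np.zeros((3, 4)), np.zeros((3, 3, 4, 4)),
                           alphabet=reduced_alphabet(4))
        pruned = dee_eliminate(model)
        assert all(p == [0, 1, 2, 3] for p in pruned)

    @pytest.mark.parametrize("seed", range(50))
    def test_soundness_optimum_survives(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 6))
        q = int(rng.integers(2, 5))
        model = random_potts(L, q, rng)
        opt_seq, _ = exhaustive_optimum(model)
        pruned = dee_eliminate(model)
        assert all(opt_seq[i] in pruned[i] for i in range(L))

    def test_empty_candidate_set_rejected(self):
        model = random_potts(2, 3, np.random.default_rng(8))
        with pytest.raises(ValueError):
            dee_eliminate(model, [[0, 1], []])


class TestMetropolisDesign:
    def test_uphill_proposals_always_accepted(self):
        rng = np.random.default_rng(9)
        model = random_potts(5, 4, rng)
        state = metropolis_design(model, rng.integers(0, 4, 5),
                                  iterations=3000, n_trials=1, seed=1,
                                  record_trajectory=True)
        for _, _, _, _, delta, accepted in state.trajectory:
            if delta >= 0:
                assert accepted

    def test_fixed_positions_never_mutate(self):
        rng = np.random.default_rng(10)
        model = random_potts(6, 4, rng)
        wt = rng.integers(0, 4, 6)
        state = metropolis_design(model, wt, iterations=3000, n_trials=2,
                                  seed=2, fixed_positions={0, 3})
        assert state.seq[0] == wt[0] and state.seq[3] == wt[3]
        assert state.best_seq[0] == wt[0] and state.best_seq[3] == wt[3]

    def test_best_score_dominates_trajectory(self):
        rng = np.random.default_rng(11)
        model = random_potts(5, 3, rng)
        state = metropolis_design(model, rng.integers(0, 3, 5),
                                  iterations=2000, n_trials=1, seed=3)
        assert state.best_score >= state.score

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        model = random_potts(5, 3, rng)
        wt = rng.integers(0, 3, 5)
        a = metropolis_design(model, wt, iterations=2000, n_trials=3, seed=4)
        b = metropolis_design(model, wt, iterations=2000, n_trials=3, seed=4)
        assert np.array_equal(a.best_seq, b.best_seq)
        assert a.best_score == b.best_score

    def test_no_mutable_positions_rejected(self):
        model = random_potts(2, 3, np.random.default_rng(13))
        with pytest.raises(ValueError):
            metropolis_design(model, np.array([0, 1]),
                              fixed_positions={0, 1}, n_trials=1,
                              iterations=10)

    @pytest.mark.parametrize("seed", range(10))
    def test_finds_exhaustive_optimum_on_small_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = random_potts(5, 4, rng)
        _, opt = exhaustive_optimum(model)
        state = metropolis_design(model, rng.integers(0, 4, 5),
                                  iterations=2000, n_trials=50, seed=seed)
        assert state.best_score == pytest.approx(opt, abs=1e-9)

    def test_two_state_boltzmann_occupancy(self):
        """Long-run occupancy of a 1-site chain matches exp(h)/Z."""
        h = np.array([[math.log(3), 0.0]])
        model = PottsModel(h, np.zeros((1, 1, 2, 2)), gauge="none",
                           alphabet=reduced_alphabet(2))
        state = metropolis_design(model, np.array([1]), iterations=120_000,
                                  n_trials=1, seed=5,
                                  record_trajectory=True)
        occupied, total = 0, 0
        current = 1
        for _, _, _, to, _, accepted in state.trajectory:
            occupied += current == 0
            total += 1
            if accepted:
                current = to
        se = math.sqrt(0.75 * 0.25 / (total / 10))  # autocorrelation margin
        assert occupied / total == pytest.approx(0.75, abs=3 * se)
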