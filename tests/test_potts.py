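import itertools
import math

import numpy as np
import pytest
import scipy.optimize

from coevokit.alphabet import reduced_alphabet
from coevokit.msa import MSA, compute_weights
from coevokit.potts import (
    PottsModel,
    contact_scores,
    fit_plm,
    load_model,
    pcc_energy,
    potts_score,
    sample_potts,
    save_model,
    zero_sum_gauge,
)
from coevokit.seqstats import EntropyProfile

from conftest import random_msa, random_potts


def enumerate_probabilities(model: PottsModel) -> dict[tuple, float]:
    """Exact Boltzmann distribution by full enumeration (small L, q only)."""
    L, q = model.length, model.q
    iu, ju = np.triu_indices(L, k=1)
    logw = {}
    for combo in itertools.product(range(q), repeat=L):
        s = np.asarray(combo)
        logw[combo] = float(model.h[np.arange(L), s].sum()
                            + model.e[iu, ju, s[iu], s[ju]].sum())
    mx = max(logw.values())
    weights = {k: math.exp(v - mx) for k, v in logw.items()}
    z = sum(weights.values())
    return {k: v / z for k, v in weights.items()}


def make_profile(model: PottsModel, d_pos: np.ndarray) -> EntropyProfile:
    L, q = model.length, model.q
    return EntropyProfile(D=np.zeros((L, q)), D_pos=np.asarray(d_pos, float),
                          background=np.full(q, 1.0 / q),
                          query=np.zeros(L, dtype=int))


class TestScore:
    def test_zero_model_scores_zero(self):
        model = PottsModel(np.zeros((4, 3)), np.zeros((4, 4, 3, 3)),
                           alphabet=reduced_alphabet(3))
        s = potts_score(model, np.array([0, 1, 2, 0]))
        assert s.E_s == 0.0 and s.E_c == 0.0

    def test_single_coupling_term(self):
        e = np.zeros((2, 2, 21, 21))
        e[0, 1, 0, 1] = 1.5
        e[1, 0, 1, 0] = 1.5
        model = PottsModel(np.zeros((2, 21)), e, gauge="none")
        s = potts_score(model, np.array([0, 1]))  # sequence (A, C)
        assert s.E_c == pytest.approx(1.5)
        assert s.E_s == 0.0

    def test_score_is_log_probability_up_to_logz(self):
        """E(s) - log P(s) must be one constant (log Z) over all sequences."""
        model = random_potts(3, 3, np.random.default_rng(0))
        probs = enumerate_probabilities(model)
        consts = []
        for combo, p in probs.items():
            s = potts_score(model, np.asarray(combo))
            consts.append(s.E_s + s.E_c - math.log(p))
        assert np.ptp(consts) < 1e-10

    def test_gauge_shift_preserves_score_differences(self):
        rng = np.random.default_rng(1)
        model = random_potts(4, 3, rng, gauge=False)
        h2, e2 = zero_sum_gauge(model.h, model.e)
        gauged = PottsModel(h2, e2, alphabet=model.alphabet)
        s1 = np.asarray([0, 1, 2, 0])
        s2 = np.asarray([2, 2, 1, 1])
        def total(m, s):
            sc = potts_score(m, s)
            return sc.E_s + sc.E_c
        assert (total(model, s1) - total(model, s2)) == pytest.approx(
            total(gauged, s1) - total(gauged, s2), abs=1e-9)

    def test_zero_sum_gauge_constraints(self):
        model = random_potts(5, 4, np.random.default_rng(2))
        assert np.allclose(model.h.sum(axis=1), 0.0, atol=1e-8)
        assert np.allclose(model.e.sum(axis=2), 0.0, atol=1e-8)
        assert np.allclose(model.e.sum(axis=3), 0.0, atol=1e-8)
        assert np.allclose(model.e, model.e.transpose(1, 0, 3, 2))

    def test_length_mismatch_raises(self):
        model = random_potts(4, 3, np.random.default_rng(3))
        with pytest.raises(ValueError):
            potts_score(model, np.array([0, 1]))


class TestPCCEnergy:
    def test_no_filter_equals_full_score(self):
        model = random_potts(5, 3, np.random.default_rng(4))
        profile = make_profile(model, np.full(5, 0.7))
        seq = np.array([0, 1, 2, 1, 0])
        full = potts_score(model, seq)
        assert pcc_energy(model, profile, seq, -np.inf) == pytest.approx(
            full.E_s + full.E_c, abs=1e-12)

    def test_everything_filtered_gives_zero(self):
        model = random_potts(5, 3, np.random.default_rng(5))
        profile = make_profile(model, np.full(5, 0.7))
        assert pcc_energy(model, profile, np.zeros(5, dtype=int), 1.0) == 0.0

    def test_hand_enumerated_toy(self):
        model = random_potts(3, 3, np.random.default_rng(6))
        profile = make_profile(model, [1.0, 0.1, 1.0])
        seq = np.array([0, 1, 2])
        expected = (model.h[0, 0] + model.h[2, 2] + model.e[0, 2, 0, 2])
        assert pcc_energy(model, profile, seq, 0.5) == pytest.approx(
            expected, abs=1e-12)

    def test_either_endpoint_mode_keeps_mixed_pairs(self):
        model = random_potts(3, 3, np.random.default_rng(7))
        profile = make_profile(model, [1.0, 0.1, 1.0])
        seq = np.array([0, 1, 2])
        expected_both = pcc_energy(model, profile, seq, 0.5, "both")
        # field at the unconserved middle position stays excluded, but its
        # two pairs survive because one endpoint is conserved
        expected_either = (expected_both
                           + model.e[0, 1, 0, 1] + model.e[1, 2, 1, 2])
        assert pcc_energy(model, profile, seq, 0.5, "either"
                          ) == pytest.approx(expected_either, abs=1e-12)


class TestFit:
    def test_single_column_matches_independent_logistic_fit(self):
        rng = np.random.default_rng(8)
        q = 3
        matrix = rng.integers(0, q, size=(400, 1), dtype=np.int8)
        msa = MSA(matrix, [f"s{k}" for k in range(400)],
                  alphabet=reduced_alphabet(q))
        model = fit_plm(msa, reg_h=0.01, reg_e=0.01)

        counts = np.bincount(matrix[:, 0], minlength=q) / 400

        def loss(hh):
            m = hh.max()
            logz = m + math.log(np.exp(hh - m).sum())
            return -(counts @ hh - logz) + 0.01 * (hh**2).sum()

        ref = scipy.optimize.minimize(loss, np.zeros(q), method="Nelder-Mead",
                                      options={"xatol": 1e-10,
                                               "fatol": 1e-12}).x
        # compare in a common gauge: both zero-mean
        assert np.allclose(model.h[0], ref - ref.mean(), atol=1e-4)
        assert model.e.shape == (1, 1, q, q)
        assert np.all(model.e == 0)

    def test_null_model_recovers_small_couplings(self):
        # i.i.d. uniform columns are exactly the zero-parameter model
        rng = np.random.default_rng(9)
        msa = random_msa(5000, 6, 4, rng)
        model = fit_plm(msa)
        cs = contact_scores(model, min_separation=1)
        iu, ju = np.triu_indices(6, k=1)
        assert cs.raw[iu, ju].mean() < 0.05

    def test_duplication_with_reweighting_is_invariant(self):
        rng = np.random.default_rng(10)
        msa = random_msa(60, 5, 3, rng)
        doubled = MSA(np.vstack([msa.matrix, msa.matrix]),
                      msa.ids + [f"{i}_d" for i in msa.ids],
                      alphabet=msa.alphabet)
        m1 = fit_plm(msa, compute_weights(msa))
        m2 = fit_plm(doubled, compute_weights(doubled))
        assert np.allclose(m1.h, m2.h, atol=1e-6)
        assert np.allclose(m1.e, m2.e, atol=1e-6)

    def test_nonpositive_regularisation_rejected(self):
        msa = random_msa(10, 4, 3, np.random.default_rng(11))
        with pytest.raises(ValueError):
            fit_plm(msa, reg_h=0.0)


class TestSampler:
    def test_uniform_null_marginals(self):
        model = PottsModel(np.zeros((3, 4)), np.zeros((3, 3, 4, 4)),
                           alphabet=reduced_alphabet(4))
        msa = sample_potts(model, 4000, burn_in=20, seed=0)
        freqs = np.stack([np.bincount(msa.matrix[:, i], minlength=4) / 4000
                          for i in range(3)])
        se = math.sqrt(0.25 * 0.75 / 4000)
        assert np.abs(freqs - 0.25).max() < 3 * se + 0.01

    def test_single_site_boltzmann_marginal(self):
        h = np.array([[math.log(2), 0.0]])
        model = PottsModel(h, np.zeros((1, 1, 2, 2)), gauge="none",
                           alphabet=reduced_alphabet(2))
        msa = sample_potts(model, 30000, burn_in=10, seed=1)
        p0 = np.mean(msa.matrix[:, 0] == 0)
        se = math.sqrt((2 / 3) * (1 / 3) / 30000)
        assert p0 == pytest.approx(2 / 3, abs=4 * se)

    def test_seeded_determinism(self):
        model = random_potts(4, 3, np.random.default_rng(12), scale=0.5)
        a = sample_potts(model, 50, burn_in=30, seed=7)
        b = sample_potts(model, 50, burn_in=30, seed=7)
        assert np.array_equal(a.matrix, b.matrix)

    def test_sampled_marginals_match_generating_model(self):
        """One- and two-site marginals converge to the model's own."""
        model = random_potts(2, 2, np.random.default_rng(13), scale=0.8)
        probs = enumerate_probabilities(model)
        msa = sample_potts(model, 20000, burn_in=50, seed=3)
        emp = {}
        for combo in probs:
            emp[combo] = np.mean((msa.matrix[:, 0] == combo[0])
                                 & (msa.matrix[:, 1] == combo[1]))
        tv = 0.5 * sum(abs(probs[k] - emp[k]) for k in probs)
        assert tv < 0.02


class TestContacts:
    def test_zero_couplings_zero_scores(self):
        model = PottsModel(np.zeros((6, 4)), np.zeros((6, 6, 4, 4)),
                           alphabet=reduced_alphabet(4))
        cs = contact_scores(model)
        assert np.all(cs.raw == 0) and np.all(cs.apc == 0)

    def test_single_planted_coupling_ranks_first(self):
        e = np.zeros((8, 8, 4, 4))
        block = np.random.default_rng(14).normal(0, 1, (3, 3))
        e[0, 5, :3, :3] = block
        e[5, 0, :3, :3] = block.T
        model = PottsModel(np.zeros((8, 4)), e, gauge="none",
                           alphabet=reduced_alphabet(4))
        cs = contact_scores(model, min_separation=5)
        i, j, score = cs.top_pairs(1)[0]
        assert (i, j) == (0, 5)
        assert score > 0

    def test_apc_identity(self):
        rng = np.random.default_rng(15)
        model = random_potts(7, 4, rng, scale=0.3)
        cs = contact_scores(model)
        raw = cs.raw
        expected = raw - np.outer(raw.mean(axis=1),
                                  raw.mean(axis=0)) / raw.mean()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(cs.apc, expected, atol=1e-12)
        assert np.allclose(cs.apc, cs.apc.T)

    def test_min_separation_excluded_from_ranking(self):
        model = random_potts(10, 3, np.random.default_rng(16))
        cs = contact_scores(model, min_separation=5)
        assert all(j - i >= 5 for i, j, _ in cs.top_pairs())


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        model = random_potts(4, 3, np.random.default_rng(17))
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.h, model.h)
        assert np.array_equal(back.e, model.e)
        assert back.alphabet.symbols == model.alphabet.symbols
        assert back.gauge == model.gauge
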