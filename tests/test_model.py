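"""Core model: likelihood oracles, Baum-Welch, Viterbi, variants."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

import cloudsig as cs
from cloudsig.mixture import SignatureMixture
from cloudsig.model import (
    CHAIN,
    MIXTURE,
    brute_force_path_logprobs,
    conditional_loglik,
    forward_loglik,
    indicator_loglik,
    joint_logprob,
)
from _helpers import diagonal_params


def _uniform_sig(K):
    return cs.SignatureMatrix([f"s{k}" for k in range(K)],
                              np.full((K, 96), 1 / 96))


def _uniform_params(K, threshold=2000):
    sig = _uniform_sig(K)
    return cs.CloudSignatureParams(np.full(K, 1 / K), np.full((K, K), 1 / K),
                          np.full(2, 0.5), np.full((2, 2), 0.5), sig, threshold)


class TestParameterCount:
    @pytest.mark.parametrize("K,n", [(12, 146), (1, 3), (2, 6), (5, 27)])
    def test_formula(self, K, n):
        assert cs.count_free_parameters(K) == n

    def test_invalid_K(self):
        with pytest.raises(ValueError):
            cs.count_free_parameters(0)


class TestTransitionCpd:
    def test_chain_to_chain_uses_A(self, sig3, random_params):
        p = random_params(sig3, np.random.default_rng(0))
        np.testing.assert_array_equal(
            cs.transition_cpd(p, 1, CHAIN, CHAIN), p.A[1])

    @pytest.mark.parametrize("prev_f,cur_f",
                             [(MIXTURE, CHAIN), (CHAIN, MIXTURE),
                              (MIXTURE, MIXTURE)])
    def test_any_mixture_side_uses_pi(self, sig3, random_params, prev_f, cur_f):
        p = random_params(sig3, np.random.default_rng(1))
        np.testing.assert_array_equal(
            cs.transition_cpd(p, 2, prev_f, cur_f), p.pi)


class TestJointLogprob:
    def test_single_position(self, sig3, random_params):
        p = random_params(sig3, np.random.default_rng(2))
        part = cs.label_sky_cloud([100], 2000, [7])
        got = joint_logprob(p, part, [MIXTURE], [1])
        expected = np.log(p.rho[1]) + np.log(p.pi[1]) + sig3.log_E[1, 7]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_chain_at_sky_position_is_excluded(self, sig3, random_params):
        p = random_params(sig3, np.random.default_rng(3))
        part = cs.label_sky_cloud([100, 50_000], 2000, [1, 2])
        assert joint_logprob(p, part, [CHAIN, MIXTURE], [0, 0]) == -np.inf

    def test_three_position_hand_product(self, sig3, random_params):
        # direct term-by-term expansion of the factorization
        p = random_params(sig3, np.random.default_rng(4))
        part = cs.label_sky_cloud([100, 600, 1100], 2000, [3, 3, 9])
        I, Q = [CHAIN, CHAIN, MIXTURE], [1, 1, 2]
        expected = (
            np.log(p.rho[0]) + np.log(p.pi[1]) + sig3.log_E[1, 3]
            + np.log(p.B[0, 0]) + np.log(p.A[1, 1]) + sig3.log_E[1, 3]
            + np.log(p.B[0, 1]) + np.log(p.pi[2]) + sig3.log_E[2, 9]
        )
        assert joint_logprob(p, part, I, Q) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_length_mismatch_raises(self, sig3, random_params):
        p = random_params(sig3, np.random.default_rng(5))
        part = cs.label_sky_cloud([100], 2000, [0])
        with pytest.raises(ValueError, match="length"):
            joint_logprob(p, part, [1, 1], [0])


class TestForwardAgainstEnumeration:
    def test_forward_matches_brute_force(self, sig3, random_instance):
        rng = np.random.default_rng(10)
        for _ in range(60):
            params, part = random_instance(sig3, rng)
            f = forward_loglik(params, part)
            b = cs.brute_force_loglik(params, part)
            assert f == pytest.approx(b, rel=1e-9)

    def test_uniform_emissions_conditional_score(self):
        params = _uniform_params(3)
        part = cs.label_sky_cloud([100, 200, 300, 9000], 2000,
                                  [0, 10, 20, 30])
        # the signature layer contributes exactly T log(1/96)
        assert conditional_loglik(params, part) == pytest.approx(
            4 * np.log(1 / 96), rel=1e-10)

    def test_all_sky_reduces_to_mixture_loglik(self, sig3, random_params):
        p = random_params(sig3, np.random.default_rng(11))
        part = cs.label_sky_cloud([1, 10_000, 50_000], 2000, [5, 6, 7])
        from cloudsig.mixture import MmmParams, mmm_loglik

        expected = mmm_loglik(MmmParams(p.pi, sig3), part.categories)
        assert forward_loglik(p, part) == pytest.approx(
            expected + indicator_loglik(p, part), rel=1e-10)

    def test_brute_force_refuses_large_instances(self, sig4, random_params):
        p = random_params(sig4, np.random.default_rng(12))
        part = cs.label_sky_cloud(np.arange(1, 31) * 100, 2000,
                                  np.zeros(30, int))
        with pytest.raises(ValueError, match="too large"):
            cs.brute_force_loglik(p, part)

    def test_point_mass_params_equal_single_path(self, sig3):
        # deterministic parameters leave exactly one admissible path
        K = 3
        pi = np.array([0.0, 1.0, 0.0])
        A = np.eye(K)
        rho = np.array([0.0, 1.0])
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = cs.CloudSignatureParams(pi, A, rho, B, sig3, 2000)
        part = cs.label_sky_cloud([100, 600, 9000], 2000, [1, 2, 3])
        expected = joint_logprob(p, part, [MIXTURE] * 3, [1, 1, 1])
        assert cs.brute_force_loglik(p, part) == pytest.approx(expected,
                                                               rel=1e-12)


class TestViterbi:
    def test_matches_enumeration(self, sig3, random_instance):
        rng = np.random.default_rng(20)
        for _ in range(60):
            params, part = random_instance(sig3, rng)
            v = cs.viterbi_decode(params, part)
            lps = brute_force_path_logprobs(params, part)
            mx = lps.max()
            tol = 1e-9 * max(abs(mx), 1.0)
            assert v.logprob == pytest.approx(mx, abs=tol)
            # consistency: the returned path really attains its log-probability
            assert joint_logprob(params, part, v.indicators,
                                 v.signatures) == pytest.approx(mx, abs=tol)
            if (lps >= mx - tol).sum() == 1:  # unique argmax
                bq, bi, _ = cs.brute_force_decode(params, part)
                np.testing.assert_array_equal(v.signatures, bq)
                np.testing.assert_array_equal(v.indicators, bi)

    def test_forced_emissions_pin_the_signature_path(self):
        E = np.full((2, 96), 1e-12)
        E[0, :48] = 1 / 48
        E[1, 48:] = 1 / 48
        sig = cs.SignatureMatrix(["a", "b"], E / E.sum(1, keepdims=True))
        p = cs.CloudSignatureParams(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                           np.full(2, 0.5), np.full((2, 2), 0.5), sig, 2000)
        part = cs.label_sky_cloud([100, 600, 1100], 2000, [0, 90, 2])
        v = cs.viterbi_decode(p, part)
        assert list(v.signatures) == [0, 1, 0]

    def test_symmetric_params_tie_break(self):
        p = _uniform_params(3)
        part = cs.label_sky_cloud([100, 600, 1100, 50_000], 2000,
                                  [0, 1, 2, 3])
        v = cs.viterbi_decode(p, part)
        assert np.all(v.signatures == 0)       # lowest signature index
        assert np.all(v.indicators == MIXTURE)  # then mixture indicator

    def test_sky_positions_always_mixture(self, sig3, random_instance):
        rng = np.random.default_rng(21)
        for _ in range(20):
            params, part = random_instance(sig3, rng)
            v = cs.viterbi_decode(params, part)
            assert np.all(v.indicators[part.sky_flag == 1] == MIXTURE)


class TestBaumWelch:
    def test_loglik_trace_non_decreasing(self, sig3):
        rng = np.random.default_rng(30)
        for seed in range(5):
            spec = cs.LayoutSpec(n_chromosomes=2,
                                 sky_per_chromosome=int(rng.integers(5, 15)),
                                 clouds_per_chromosome=int(rng.integers(2, 6)),
                                 cloud_size_mean=3.0)
            table, _ = cs.sample_cohort(spec, cs.default_params(sig3), 1,
                                        seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = cs.CloudSignatureModel(
                    signatures=sig3, n_restarts=1, tol=1e-8, max_iter=120,
                    random_state=seed).fit(table)
            tr = np.array(est.loglik_trace_)
            assert np.all(np.diff(tr) >= -1e-8 * np.maximum(np.abs(tr[:-1]), 1))

    def test_no_cloud_sample_warns_and_keeps_A(self, sig3):
        part = cs.label_sky_cloud([1, 10_000, 99_000], 2000, [5, 6, 7])
        with pytest.warns(RuntimeWarning, match="no cloud"):
            est = cs.CloudSignatureModel(
                signatures=sig3, tol=1e-8, max_iter=50,
                init=dict(pi=np.full(3, 1 / 3))).fit(part)
        np.testing.assert_array_equal(est.A_, np.full((3, 3), 1 / 3))

    def test_all_sky_pi_equals_mixture_weights(self, sig4):
        spec = cs.LayoutSpec(n_chromosomes=3, sky_per_chromosome=300,
                             clouds_per_chromosome=0)
        table, _ = cs.sample_cohort(spec, cs.default_params(sig4), 1, seed=8)
        g0 = np.full(4, 0.25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = cs.CloudSignatureModel(signatures=sig4, tol=1e-14,
                                         max_iter=400,
                                         init=dict(pi=g0)).fit(table)
            mm = SignatureMixture(signatures=sig4, tol=1e-14, max_iter=400,
                                  init=g0).fit(
                table["category"].map(cs.parse_category_label).to_numpy())
        assert np.abs(est.pi_ - mm.weights_).sum() < 1e-6

    def test_empty_sample_raises(self, sig3):
        with pytest.raises(ValueError, match="no mutations"):
            cs.CloudSignatureModel(signatures=sig3).fit([])

    def test_seeded_refit_is_reproducible(self, sig3):
        spec = cs.LayoutSpec(n_chromosomes=2, sky_per_chromosome=20,
                             clouds_per_chromosome=5, cloud_size_mean=3.0)
        table, _ = cs.sample_cohort(spec, cs.default_params(sig3), 1, seed=3)
        kw = dict(signatures=sig3, n_restarts=2, tol=1e-7, max_iter=100,
                  random_state=77)
        a = cs.CloudSignatureModel(**kw).fit(table)
        b = cs.CloudSignatureModel(**kw).fit(table)
        np.testing.assert_array_equal(a.pi_, b.pi_)
        np.testing.assert_array_equal(a.A_, b.A_)


class TestVariants:
    def _sample(self, sig):
        spec = cs.LayoutSpec(n_chromosomes=2, sky_per_chromosome=40,
                             clouds_per_chromosome=15, cloud_size_mean=3.0)
        table, _ = cs.sample_cohort(spec, cs.default_params(sig), 1, seed=6)
        return table

    def test_single_signature_runs_are_constant(self, sig4):
        table = self._sample(sig4)
        est = cs.CloudSignatureModel(signatures=sig4, variant="single",
                                     n_restarts=1, tol=1e-6, max_iter=100,
                                     random_state=0).fit(table)
        np.testing.assert_array_equal(est.A_, np.eye(4))
        dec = est.predict(table)
        for _, grp in dec.groupby(["sample", "chrom"]):
            ind = grp.sort_values("pos")["indicator"].to_numpy()
            sigs = grp.sort_values("pos")["signature_index"].to_numpy()
            both_chain = (ind[:-1] == CHAIN) & (ind[1:] == CHAIN)
            assert np.all(sigs[:-1][both_chain] == sigs[1:][both_chain])

    def test_restricted_chain_states_stay_in_set(self, sig4):
        table = self._sample(sig4)
        allowed = ["Signature 2", "Signature 3"]
        est = cs.CloudSignatureModel(
            signatures=sig4, variant="restricted", cloud_signatures=allowed,
            n_restarts=1, tol=1e-6, max_iter=100, random_state=0).fit(table)
        dec = est.predict(table)
        chain = dec[dec["indicator"] == CHAIN]
        assert set(chain["signature"]) <= set(allowed)

    def test_restricted_set_must_be_known(self, sig4):
        with pytest.raises(ValueError, match="unknown"):
            cs.constrain_variant("restricted", sig4,
                                 cloud_signatures=["Signature 9"])

    def test_restricted_set_must_be_non_empty(self, sig4):
        with pytest.raises(ValueError, match="non-empty"):
            cs.constrain_variant("restricted", sig4, cloud_signatures=[])


class TestSequenceDependentFraction:
    def _decoded_frame(self, indicators, cloud_ids):
        return pd.DataFrame({
            "indicator": indicators, "cloud_id": cloud_ids,
        })

    def test_all_chain_gives_one(self):
        df = self._decoded_frame([0, 0, 1], [0, 0, -1])
        assert cs.sequence_dependent_fraction(df) == 1.0

    def test_mixture_forcing_gives_zero(self, sig3):
        # B absorbing at mixture: no chain states can be decoded
        p = cs.CloudSignatureParams(np.full(3, 1 / 3), np.full((3, 3), 1 / 3),
                           np.array([0.0, 1.0]),
                           np.array([[0.0, 1.0], [0.0, 1.0]]), sig3, 2000)
        part = cs.label_sky_cloud([100, 600, 1100], 2000, [0, 1, 2])
        v = cs.viterbi_decode(p, part)
        assert cs.sequence_dependent_fraction([v]) == 0.0

    def test_no_clouds_is_undefined(self):
        df = self._decoded_frame([1, 1], [-1, -1])
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(cs.sequence_dependent_fraction(df))

    def test_recovered_at_planted_parameters(self, random_params):
        # near-deterministic emissions: decoding at the generating parameters
        # reproduces the planted chain fraction closely
        sig = cs.synthetic_signatures(4, separation=0.99, seed=7)
        params = diagonal_params(sig, 0.95, [[0.95, 0.05], [0.80, 0.20]])
        spec = cs.LayoutSpec(n_chromosomes=3, sky_per_chromosome=60,
                             clouds_per_chromosome=80, cloud_size_mean=4.0)
        table, truth = cs.sample_cohort(spec, params, 1, seed=13)
        seqs = cs.build_sample_sequences(table)
        parts = cs.partition_sequences(seqs, 2000)
        decoded = cs.decode_sample(params, parts)
        got = cs.sequence_dependent_fraction(decoded)
        assert got == pytest.approx(truth.sequence_dependent_fraction,
                                    abs=0.05)


def test_params_json_round_trip(sig3, random_params):
    p = random_params(sig3, np.random.default_rng(40))
    doc = p.to_json(seed=1)
    back = cs.CloudSignatureParams.from_json(doc, sig3)
    np.testing.assert_allclose(back.pi, p.pi)
    np.testing.assert_allclose(back.A, p.A)
    np.testing.assert_allclose(back.B, p.B)
    assert back.threshold == p.threshold
    assert json.loads(doc)["seed"] == 1
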