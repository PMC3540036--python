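import numpy as np
import pytest
from scipy.special import expit

from promsig import (BackgroundModel, FrequencyMatrix, SignatureModel,
                     SpatialParams, initiation_rate, forward_backward,
                     posterior_regulation, sample_promoter,
                     brute_force_likelihood, log_consistency_mass)
from promsig.model import (PreparedSet, brute_force_consistency,
                           model_from_dict, model_to_dict)
from promsig.pwm import encode

from conftest import consensus_matrix, make_model, random_small_model


class TestInitiationRate:
    def test_zero_lambda_means_pure_background(self):
        p = SpatialParams(rho=0.5, mu=100, omega=50, tau=0.5, lam=0.0)
        assert initiation_rate(p, np.arange(200)).max() == 0.0

    def test_full_forward_bias_kills_reverse_rate(self):
        p = SpatialParams(rho=0.5, mu=100, omega=50, tau=1.0, lam=0.01)
        assert np.all(initiation_rate(p, np.arange(200), "-") == 0.0)
        assert initiation_rate(p, 100.0, "+") > 0.0

    def test_plateau_closed_form(self):
        p = SpatialParams(rho=0.5, mu=200, omega=100, tau=0.5, lam=0.01,
                          eta=0.1)
        # both logistic ramps evaluate at 10 slope-units in the middle
        sigma10 = 1.0 / (1.0 + np.exp(-10.0))
        assert initiation_rate(p, 200.0, "+") == pytest.approx(
            0.01 * 0.5 * sigma10 ** 2, rel=1e-12)

    def test_plateau_centred_and_soft_edged(self):
        p = SpatialParams(rho=0.5, mu=200, omega=100, tau=0.5, lam=0.01,
                          eta=0.1)
        q = initiation_rate(p, np.arange(500), "+")
        assert q[200] == q.max()
        # half-height at the plateau edges
        assert q[100] == pytest.approx(q[200] / 2, rel=0.01)
        assert q[300] == pytest.approx(q[200] / 2, rel=0.01)
        assert q[450] < q[200] / 100

    def test_negative_position_rejected(self):
        p = SpatialParams(rho=0.5, mu=10, omega=5, tau=0.5, lam=0.01)
        with pytest.raises(ValueError):
            initiation_rate(p, -1.0)

    def test_parameter_bounds_validated(self):
        with pytest.raises(ValueError):
            SpatialParams(rho=1.2, mu=10, omega=5, tau=0.5, lam=0.01)
        with pytest.raises(ValueError):
            SpatialParams(rho=0.5, mu=10, omega=5, tau=0.5, lam=1.0)


class TestForwardBackward:
    def test_rho_zero_is_pure_background(self, bg, medium6):
        model = make_model(medium6, bg, rho=0.0)
        seq = "ACGTAC" * 20
        post = forward_backward(model, seq)
        lbg = bg.log_probs[encode(seq)].sum()
        assert post.loglik == pytest.approx(lbg, rel=1e-12)
        assert post.e_r == 0.0
        assert post.expected_sites == 0.0

    def test_rho_one_forces_regulation(self, bg, medium6):
        model = make_model(medium6, bg, rho=1.0)
        post = forward_backward(model, "ACGTAC" * 20)
        assert post.e_r == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            model, seq = random_small_model(rng)
            ll = brute_force_likelihood(model, seq)
            fb = forward_backward(model, seq)
            assert fb.loglik == pytest.approx(ll, rel=1e-9)

    def test_posterior_site_starts_match_enumeration(self):
        """Site-start posteriors agree with a weighted path enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            model, seq = random_small_model(rng, max_len=10, max_w=2)
            fb = forward_backward(model, seq)
            exp_post = _enumerate_site_posteriors(model, seq)
            assert np.allclose(fb.site_start, exp_post, atol=1e-9)

    def test_monosite_expected_sites_at_most_one(self, bg, medium6):
        rng = np.random.default_rng(3)
        model = make_model(medium6, bg, variant="monosite", rho=0.9,
                           lam=0.05)
        for _ in range(5):
            seq, _ = sample_promoter(model, rng, length=120)
            fb = forward_backward(model, seq)
            assert fb.expected_sites <= 1.0 + 1e-9

    def test_normalization_over_sequence_space(self):
        """P(seq, C=1) sums over all 4^L sequences to the consistency mass."""
        rng = np.random.default_rng(7)
        import itertools
        for _ in range(3):
            model, _ = random_small_model(rng, max_len=6, max_w=2)
            L = model.length
            total = sum(np.exp(brute_force_likelihood(model, "".join(t)))
                        for t in itertools.product("ACGT", repeat=L))
            expected = (1 - model.params.rho) + \
                model.params.rho * brute_force_consistency(model, L)
            assert total == pytest.approx(expected, abs=1e-6)
            assert np.exp(log_consistency_mass(model, L)) == pytest.approx(
                expected, rel=1e-9)

    def test_expected_sites_monotone_in_lambda(self, bg, medium6):
        seq = ("ACGTAC" + "GGATCC" * 4) * 5
        prev = -1.0
        for lam in [0.001, 0.005, 0.02, 0.08]:
            model = make_model(medium6, bg, rho=1.0, lam=lam, length=len(seq))
            fb = forward_backward(model, seq)
            assert fb.expected_sites >= prev - 1e-12
            prev = fb.expected_sites

    def test_strand_symmetry_at_tau_half(self, bg):
        """tau=.5: replacing the matrix by its reverse complement leaves
        every likelihood unchanged."""
        rng = np.random.default_rng(8)
        m = FrequencyMatrix(rng.dirichlet(np.ones(4), size=4))
        model = make_model(m, bg, tau=0.5, length=60)
        model_rc = SignatureModel(matrix=m.reverse_complement(), bg=bg,
                                  params=model.params, length=60)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            assert forward_backward(model, seq).loglik == pytest.approx(
                forward_backward(model_rc, seq).loglik, rel=1e-12)

    def test_masked_fill_forbids_sites(self, bg, medium6):
        model = make_model(medium6, bg, rho=1.0, lam=0.05, length=60)
        seq = "ACGTTG" * 10  # consensus everywhere
        open_post = forward_backward(model, seq)
        masked = forward_backward(model, seq, mask=[(0, 30)])
        assert masked.site_start[:25].max() == 0.0
        assert open_post.expected_sites > masked.expected_sites


def _enumerate_site_posteriors(model, seq):
    """Posterior site-start probabilities by explicit path enumeration."""
    L, w = len(seq), model.w
    codes = encode(seq)
    prm = model.params
    bgp = np.append(model.bg.probs, 1.0)
    mprob = model.matrix.probs
    qf = [float(initiation_rate(prm, L - w - i, "+")) if i <= L - w else 0.0
          for i in range(L)]
    qr = [float(initiation_rate(prm, L - w - i, "-")) if i <= L - w else 0.0
          for i in range(L)]

    def site_emission(i, s):
        prob = 1.0
        for k in range(w):
            b = codes[i + k]
            prob *= mprob[k][b] if s == 0 else mprob[w - 1 - k][3 - b]
        return prob

    acc_post = np.zeros((L, 2))
    total_r1 = 0.0

    def walk(i, sites, acc):
        nonlocal total_r1
        if i == L:
            if sites:
                total_r1 += acc
                for j, s in sites:
                    acc_post[j, s] += acc
            return
        can = i <= L - w and not (model.monosite and sites)
        if can:
            walk(i + w, sites + [(i, 0)], acc * qf[i] * site_emission(i, 0))
            walk(i + w, sites + [(i, 1)], acc * qr[i] * site_emission(i, 1))
            stay = 1.0 - qf[i] - qr[i]
        else:
            stay = 1.0
        walk(i + 1, sites, acc * stay * bgp[codes[i]])

    walk(0, [], 1.0)
    bg_lik = float(np.prod(bgp[codes]))
    joint_r1 = prm.rho * total_r1
    joint = (1 - prm.rho) * bg_lik + joint_r1
    if joint == 0 or total_r1 == 0:
        return np.zeros((L, 2))
    e_r = joint_r1 / joint
    return acc_post / total_r1 * e_r


class TestPosteriorRegulation:
    def test_override_zero_and_one(self, bg, medium6):
        model = make_model(medium6, bg)
        seq = "ACGTAC" * 10
        assert posterior_regulation(model, seq, rho_override=0.0) == 0.0
        assert posterior_regulation(model, seq, rho_override=1.0) == 1.0

    def test_background_sequence_scores_below_half(self, bg):
        """With a weak plateau and no matching subsequence, E[R] < .5."""
        m = consensus_matrix("CCCGGG", 0.9)
        model = make_model(m, bg, rho=0.5, lam=0.002, length=60)
        seq = "ATATTA" * 10
        assert posterior_regulation(model, seq, rho_override=0.5) < 0.5

    def test_planted_consensus_scores_above_half(self, bg):
        m = consensus_matrix("CCCGGG", 0.9)
        model = make_model(m, bg, rho=0.5, mu=30, omega=20, lam=0.02,
                           length=60)
        seq = "ATATTA" * 4 + "CCCGGG" + "ATATTA" * 1 + "ATATTA"
        assert posterior_regulation(model, seq, rho_override=0.5) > 0.5

    def test_bayes_from_enumeration(self):
        rng = np.random.default_rng(21)
        model, seq = random_small_model(rng, max_len=10, max_w=2)
        rho = 0.5
        model_r1 = SignatureModel(matrix=model.matrix, bg=model.bg,
                                  params=model.params.replace(rho=1.0),
                                  variant=model.variant, length=model.length)
        ll_r1 = brute_force_likelihood(model_r1, seq)
        lbg = model.bg.log_probs[encode(seq)].sum()
        expected = 1.0 / (1.0 + np.exp(np.log(1 - rho) + lbg
                                       - np.log(rho) - ll_r1))
        got = posterior_regulation(model, seq, rho_override=0.5)
        assert got == pytest.approx(expected, rel=1e-9)


class TestSampler:
    def test_rho_zero_background_composition(self, bg, medium6):
        model = make_model(medium6, bg, rho=0.0, length=250)
        rng = np.random.default_rng(0)
        seqs = [sample_promoter(model, rng)[0] for _ in range(100)]
        joined = "".join(seqs)
        gc = (joined.count("G") + joined.count("C")) / len(joined)
        assert gc == pytest.approx(0.38, abs=0.01)
        assert all(s == [] for s in
                   [sample_promoter(model, rng)[1] for _ in range(10)])

    def test_monosite_rho_one_exactly_one_site(self, bg, medium6):
        model = make_model(medium6, bg, variant="monosite", rho=1.0,
                           lam=0.05, length=150)
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq, sites = sample_promoter(model, rng)
            assert len(sites) == 1
            start, strand = sites[0]
            assert 0 <= start <= 150 - 6

    def test_truth_sites_match_planted_consensus(self, bg):
        m = consensus_matrix("ACGTTG", 0.97)
        model = make_model(m, bg, rho=1.0, lam=0.03, tau=1.0, length=200)
        rng = np.random.default_rng(2)
        seq, sites = sample_promoter(model, rng)
        for start, strand in sites:
            assert strand == "+"
            matches = sum(a == b for a, b in
                          zip(seq[start:start + 6], "ACGTTG"))
            assert matches >= 4

    def test_site_count_consistent_with_posterior(self, bg, medium6):
        """Empirical site counts agree with the model's own expectation."""
        model = make_model(medium6, bg, rho=1.0, mu=20, omega=15, lam=0.04,
                           length=60)
        rng = np.random.default_rng(3)
        n = 4000
        counts = np.empty(n)
        seqs = []
        for i in range(n):
            seq, sites = sample_promoter(model, rng)
            counts[i] = len(sites)
            seqs.append(seq)
        prep = PreparedSet(model, seqs)
        _, _, post = prep.posteriors(model.params)
        expected = post.sum(axis=(1, 2))
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - expected.mean()) < 3 * se

    def test_impossible_consistency_raises(self, bg, medium6):
        model = make_model(medium6, bg, rho=1.0, lam=0.0)
        with pytest.raises(RuntimeError):
            sample_promoter(model, np.random.default_rng(0),
                            max_attempts=20)


class TestSerialization:
    def test_round_trip(self, bg, medium6):
        model = make_model(medium6, bg, variant="monosite", rho=0.3)
        clone = model_from_dict(model_to_dict(model))
        assert clone.params == model.params
        assert clone.variant == model.variant
        assert np.allclose(clone.matrix.probs, model.matrix.probs)
        assert clone.bg.gc == model.bg.gc
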