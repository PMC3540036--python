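import numpy as np
import pandas as pd
import pytest

from promsig import (binomial_wins_test, bootstrap_method_comparison,
                     evaluate_topk, generate_benchmark, rank_by_chip,
                     rank_by_signature, rank_by_thermodynamic,
                     rank_by_top_site, roc_binding, sample_promoter,
                     score_density_profile, scan_scores)
from promsig.ranking import RankedTargets

from conftest import consensus_matrix, make_model


class TestTopSite:
    def test_consensus_ranks_above_background(self, bg, medium6):
        proms = {"hit": "AAAAAA" + "ACGTTG" + "AAAAAA",
                 "miss": "AAAAAA" * 3}
        ranked = rank_by_top_site(medium6, bg, proms)
        assert ranked.table.iloc[0]["id"] == "hit"

    def test_ties_are_id_ordered(self, bg, medium6):
        proms = {"b": "ACGTACGT", "a": "ACGTACGT"}
        ranked = rank_by_top_site(medium6, bg, proms)
        assert ranked.table["id"].tolist() == ["a", "b"]
        assert ranked.table["rank"].tolist() == [1, 2]

    def test_equals_scan_track_maximum(self, bg, medium6):
        rng = np.random.default_rng(0)
        proms = {f"p{i}": "".join(rng.choice(list("ACGT"), size=80))
                 for i in range(10)}
        ranked = rank_by_top_site(medium6, bg, proms)
        scores = ranked.scores()
        for pid, seq in proms.items():
            assert scores[pid] == pytest.approx(
                scan_scores(medium6, bg, seq).max())

    def test_short_promoter_ranked_last(self, bg, medium6):
        proms = {"ok": "ACGTTGAC", "tiny": "ACG"}
        ranked = rank_by_top_site(medium6, bg, proms)
        assert ranked.table.iloc[-1]["id"] == "tiny"


class TestThermodynamic:
    def test_single_promoter_scores_one(self, bg, medium6):
        ranked = rank_by_thermodynamic(medium6, bg, {"only": "ACGTTG"})
        assert ranked.table["score"].iloc[0] == pytest.approx(1.0)

    def test_scores_sum_to_one(self, bg, medium6):
        rng = np.random.default_rng(1)
        proms = {f"p{i}": "".join(rng.choice(list("ACGT"), size=120))
                 for i in range(30)}
        ranked = rank_by_thermodynamic(medium6, bg, proms)
        assert ranked.table["score"].sum() == pytest.approx(1.0)

    def test_two_sites_double_the_share(self, bg):
        m = consensus_matrix("CCGGCC", 0.97)
        pad = "ATATAT" * 3
        proms = {"two": pad + "CCGGCC" + pad + "CCGGCC" + pad,
                 "one": pad + "CCGGCC" + pad + "ATATAT" + pad}
        ranked = rank_by_thermodynamic(m, bg, proms)
        s = ranked.scores()
        assert s["two"] / s["one"] == pytest.approx(2.0, rel=0.05)

    def test_empty_set_rejected(self, bg, medium6):
        with pytest.raises(ValueError):
            rank_by_thermodynamic(medium6, bg, {})


class TestSignatureRanking:
    def test_model_samples_outrank_background(self, bg):
        """Signature-carrying promoters dominate the head of the ranking
        against equal-length background promoters: in >=90% of seeded
        trials (n=50+50) the top ranks are exclusively model-sampled."""
        m = consensus_matrix("ACGTTG", 0.85)
        model = make_model(m, bg, rho=1.0, mu=80, omega=40, lam=0.03,
                           length=250)
        successes = 0
        n_trials = 10
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            proms = {f"sig{i:02d}": sample_promoter(model, rng)[0]
                     for i in range(50)}
            for i in range(50):
                proms[f"bg{i:02d}"] = "".join(
                    "ACGT"[c] for c in rng.choice(4, size=250, p=bg.probs))
            ranked = rank_by_signature(model, proms)
            successes += ranked.table.head(10)["id"].str.startswith(
                "sig").all()
            # the bulk of the top-50 is model-sampled in every trial
            assert ranked.table.head(50)["id"].str.startswith(
                "sig").mean() > 0.6
        assert successes >= 0.9 * n_trials

    def test_rho_override_is_monotone_transform(self, bg, medium6):
        model = make_model(medium6, bg, rho=0.3, length=150)
        rng = np.random.default_rng(3)
        proms = {f"p{i}": sample_promoter(model, rng)[0] for i in range(20)}
        orders = []
        for rho in (0.1, 0.5, 0.9):
            ranked = rank_by_signature(model, proms, rho_override=rho)
            orders.append(ranked.table["id"].tolist())
        assert orders[0] == orders[1] == orders[2]

    def test_identical_promoters_equal_scores(self, bg, medium6):
        model = make_model(medium6, bg, length=60)
        ranked = rank_by_signature(model, {"a": "ACGTTG" * 10,
                                           "b": "ACGTTG" * 10})
        assert ranked.table["score"].nunique() == 1


class TestChipRanking:
    def test_single_condition_rank_is_p_order(self):
        tbl = pd.DataFrame({"c1": [0.5, 0.01, 0.2]},
                           index=["x", "y", "z"])
        ranked = rank_by_chip(tbl)
        assert ranked.table["id"].tolist() == ["y", "z", "x"]

    def test_keyed_on_smallest_condition(self):
        tbl = pd.DataFrame({"c1": [0.2, 0.5], "c2": [0.01, 0.6]},
                           index=["a", "b"])
        ranked = rank_by_chip(tbl)
        assert ranked.scores()["a"] == pytest.approx(-0.01)

    def test_condition_order_invariance(self):
        rng = np.random.default_rng(4)
        tbl = pd.DataFrame(rng.uniform(size=(20, 4)),
                           index=[f"p{i}" for i in range(20)])
        shuffled = tbl[tbl.columns[::-1]]
        assert (rank_by_chip(tbl).table["id"].tolist()
                == rank_by_chip(shuffled).table["id"].tolist())

    def test_all_missing_rows_excluded(self):
        tbl = pd.DataFrame({"c1": [0.1, np.nan], "c2": [0.2, np.nan]},
                           index=["a", "gone"])
        ranked = rank_by_chip(tbl)
        assert ranked.table["id"].tolist() == ["a"]


class TestEvaluateTopK:
    def _ranked(self, ids):
        return RankedTargets.from_scores(ids, np.arange(len(ids), 0, -1),
                                         "test")

    def test_zero_expression_not_significant(self):
        ids = [f"p{i}" for i in range(100)]
        expr = pd.Series(0.0, index=ids)
        res = evaluate_topk(self._ranked(ids), expr, k=20, resamples=500,
                            seed=0)
        assert res.mean_change == 0.0
        assert not res.significant

    def test_planted_effect_significant(self):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(300)]
        vals = rng.normal(size=300)
        vals[:50] = -2.0  # the top-50 by construction
        expr = pd.Series(vals, index=ids)
        res = evaluate_topk(self._ranked(ids), expr, k=50, resamples=5000,
                            seed=1)
        assert res.significant
        assert res.mean_change == pytest.approx(-2.0)
        assert res.ci_low < 0 < res.ci_high

    @pytest.mark.parametrize("k", [10, 25, 50, 100, 200, 400])
    def test_cutoff_sweep_runs(self, k):
        rng = np.random.default_rng(6)
        ids = [f"p{i}" for i in range(450)]
        expr = pd.Series(rng.normal(size=450), index=ids)
        res = evaluate_topk(self._ranked(ids), expr, k=k, resamples=200,
                            seed=2)
        assert res.k == k

    def test_reduced_k_with_warning(self):
        ids = [f"p{i}" for i in range(10)]
        expr = pd.Series(1.0, index=ids[:5])
        with pytest.warns(UserWarning):
            res = evaluate_topk(self._ranked(ids), expr, k=50,
                                resamples=100, seed=3)
        assert res.k == 5

    def test_training_exclusion(self):
        ids = [f"p{i}" for i in range(60)]
        vals = np.zeros(60)
        vals[:10] = -5.0
        expr = pd.Series(vals, index=ids)
        res = evaluate_topk(self._ranked(ids), expr, k=10, resamples=100,
                            seed=4, exclude=ids[:10])
        assert res.mean_change == 0.0


class TestBootstrapComparison:
    def test_identical_rankings_p_one(self):
        rng = np.random.default_rng(7)
        ids = [f"p{i}" for i in range(80)]
        r = RankedTargets.from_scores(ids, rng.normal(size=80), "a")
        expr = pd.Series(rng.normal(size=80), index=ids)
        p = bootstrap_method_comparison(r, r, expr, k=20, reps=500, seed=5)
        assert p == 1.0

    def test_planted_double_effect_wins(self):
        rng = np.random.default_rng(8)
        n = 200
        ids = [f"p{i}" for i in range(n)]
        effect = np.zeros(n)
        effect[:40] = -2.0    # method A's favourites
        effect[40:80] = -1.0  # method B's favourites
        expr = pd.Series(effect + rng.normal(0, 0.3, size=n), index=ids)
        sa = np.zeros(n); sa[:40] = 1.0
        sb = np.zeros(n); sb[40:80] = 1.0
        ra = RankedTargets.from_scores(ids, sa, "A")
        rb = RankedTargets.from_scores(ids, sb, "B")
        p = bootstrap_method_comparison(ra, rb, expr, k=40, reps=2000,
                                        seed=6)
        assert p < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        ids = [f"p{i}" for i in range(60)]
        ra = RankedTargets.from_scores(ids, rng.normal(size=60), "a")
        rb = RankedTargets.from_scores(ids, rng.normal(size=60), "b")
        expr = pd.Series(rng.normal(size=60), index=ids)
        p1 = bootstrap_method_comparison(ra, rb, expr, k=15, reps=400,
                                         seed=7)
        p2 = bootstrap_method_comparison(ra, rb, expr, k=15, reps=400,
                                         seed=7)
        assert p1 == p2


class TestBinomialWins:
    def test_twelve_of_fifteen_wins(self):
        assert binomial_wins_test(12, 15) == pytest.approx(0.0176, abs=5e-5)

    def test_all_wins_closed_form(self):
        assert binomial_wins_test(10, 10) == pytest.approx(2.0 ** -10)

    def test_zero_wins_certain(self):
        assert binomial_wins_test(0, 7) == 1.0

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            binomial_wins_test(6, 5)


class TestScoreDensity:
    def test_background_mostly_inside_band(self, bg, medium6):
        rng = np.random.default_rng(10)
        proms = ["".join("ACGT"[c] for c in rng.choice(4, size=300,
                                                       p=bg.probs))
                 for _ in range(40)]
        prof = score_density_profile(medium6, bg, proms, sims=60, seed=11)
        ok = ((prof.density >= prof.bg_lo) &
              (prof.density <= prof.bg_hi)).mean()
        assert ok >= 0.9

    def test_planted_plateau_peak_near_mu(self, bg):
        m = consensus_matrix("ACGTTG", 0.95)
        model = make_model(m, bg, rho=1.0, mu=150, omega=30, lam=0.04,
                           length=400)
        rng = np.random.default_rng(12)
        proms = [sample_promoter(model, rng)[0] for _ in range(60)]
        prof = score_density_profile(m, bg, proms, window=20, sims=20,
                                     seed=13)
        peak = prof.loc[prof.density.idxmax()]
        assert peak.p_lo - 20 <= 150 <= peak.p_hi + 20

    def test_all_ambiguous_zero_density(self, bg, medium6):
        prof = score_density_profile(medium6, bg, ["N" * 100], sims=5,
                                     seed=14)
        assert np.nansum(prof.density) == 0.0


class TestROC:
    def test_perfect_separation(self):
        ids = list("abcdef")
        ranked = RankedTargets.from_scores(ids, [6, 5, 4, 3, 2, 1], "m")
        labels = pd.Series([1, 1, 1, 0, 0, 0], index=ids)
        _, _, auc = roc_binding(ranked, labels)
        assert auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(15)
        aucs = []
        for s in range(10):
            ids = [f"p{i}" for i in range(200)]
            ranked = RankedTargets.from_scores(ids, rng.normal(size=200),
                                               "m")
            labels = pd.Series(rng.integers(0, 2, size=200), index=ids)
            aucs.append(roc_binding(ranked, labels)[2])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_label_inversion_flips_auc(self):
        rng = np.random.default_rng(16)
        ids = [f"p{i}" for i in range(100)]
        ranked = RankedTargets.from_scores(ids, rng.normal(size=100), "m")
        labels = pd.Series(rng.integers(0, 2, size=100), index=ids)
        _, _, auc = roc_binding(ranked, labels)
        _, _, auc_inv = roc_binding(ranked, 1 - labels)
        assert auc_inv == pytest.approx(1.0 - auc, abs=1e-9)

    def test_single_class_flagged(self):
        ids = list("abc")
        ranked = RankedTargets.from_scores(ids, [3, 2, 1], "m")
        with pytest.warns(UserWarning):
            _, _, auc = roc_binding(ranked, pd.Series(1, index=ids))
        assert np.isnan(auc)


class TestSignatureVsTopSiteOnDensityBenchmark:
    def test_density_signal_favours_signature(self, bg):
        """When multisite density carries the signal, the signature ranker
        recovers more true targets at equal K than the best-single-site
        ranker."""
        m = consensus_matrix("ACGTTG", 0.8)
        model = make_model(m, bg, rho=0.15, mu=120, omega=60, lam=0.035,
                           length=400)
        proms, truth = generate_benchmark(model, 250, effect=-2.0,
                                          noise_sd=1.0, seed=17)
        k = int(truth.regulated.sum())
        reg = {pid for pid, r in zip(proms, truth.regulated) if r}
        sig = rank_by_signature(model, proms)
        top = rank_by_top_site(m, bg, proms)
        hits_sig = len(set(sig.top(k)["id"]) & reg)
        hits_top = len(set(top.top(k)["id"]) & reg)
        assert hits_sig > hits_top
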