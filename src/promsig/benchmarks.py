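"""Reproducible validation studies at desk scale.

Each function defines one self-contained study — inference correctness
against the enumeration oracle, estimator validation, parameter recovery,
control calibration, and the end-to-end expression benchmark — with fixed
study conditions and a single seed argument.  They are used by the
acceptance test suite and by ``scripts/acceptance.py``; problem sizes are
chosen so the whole battery runs on a single CPU in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .controls import ScrambleConfig, lrt_strand, scramble_set, \
    spacing_control_test
from .fitting import AnnealSchedule, em_fit
from .information import exact_kl, sampled_kl, single_site_baseline
from .model import (PreparedSet, SignatureModel, SpatialParams,
                    brute_force_consistency, brute_force_likelihood,
                    sample_promoter)
from .pwm import (BackgroundModel, FrequencyMatrix, consensus_matrix,
                  scan_scores)
from .ranking import (evaluate_topk, rank_by_signature,
                      rank_by_thermodynamic, rank_by_top_site)
from .simulate import generate_benchmark

BG = BackgroundModel(gc=0.38)

#: annealing schedule for the simulation studies (small but sufficient for
#: the smooth likelihood surfaces these fixtures produce)
STUDY_SCHEDULE = AnnealSchedule(initial_temp=0.8, cooling=0.6, steps=8,
                                min_temp=0.1)
STUDY_FIT = dict(schedule=STUDY_SCHEDULE, tol=1e-3, max_iter=12, n_starts=2)


# ---------------------------------------------------------------------------
# inference correctness


def _n_paths(L: int, w: int) -> int:
    """Number of legal site-placement sets (both strands) on L positions."""
    f = [1] + [0] * L
    for i in range(1, L + 1):
        f[i] = f[i - 1] + (2 * f[i - w] if i >= w else 0)
    return f[L]


def oracle_agreement(n_instances: int = 200, seed: int = 0,
                     max_paths: int = 50000) -> dict:
    """Forward message passing vs path enumeration on random instances.

    Instances draw L <= 30, w <= 5, random matrices, spatial parameters and
    variants; L is capped per width so the explicit enumeration stays below
    ``max_paths`` placement sets (narrow motifs admit exponentially many).
    Returns the maximum relative log-likelihood error.
    """
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    for _ in range(n_instances):
        w = int(rng.integers(1, 6))
        feasible = [L for L in range(max(w, 4), 31)
                    if _n_paths(L, w) <= max_paths]
        L = int(rng.choice(feasible))
        matrix = FrequencyMatrix(rng.dirichlet(np.ones(4) * 0.7, size=w))
        params = SpatialParams(
            rho=float(rng.uniform(0, 1)), mu=float(rng.uniform(0, L)),
            omega=float(rng.uniform(1, L)), tau=float(rng.uniform(0, 1)),
            lam=float(rng.uniform(0.001, 0.3)),
            eta=float(rng.uniform(0.05, 1.0)))
        variant = "monosite" if rng.random() < 0.5 else "multisite"
        model = SignatureModel(matrix=matrix, bg=BG, params=params,
                               variant=variant, length=L)
        seq = "".join(rng.choice(list("ACGT"), size=L))
        ll_oracle = brute_force_likelihood(model, seq)
        ll_fb = float(PreparedSet(model, [seq])._per_seq_loglik(params)[0])
        max_rel = max(max_rel, abs(ll_fb - ll_oracle) / abs(ll_oracle))
    return {"n": n_instances, "max_rel_err": max_rel}


def normalization_check(n_instances: int = 3, seed: int = 0) -> dict:
    """Total model probability over the whole sequence space.

    For enumerable instances (L <= 6 here, w <= 2), sums P(seq, C=1) over
    all 4^L sequences and compares with the closed-form consistency mass;
    reports the worst deviation of the conditioned distribution's total
    mass from one.
    """
    import itertools
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        w = int(rng.integers(1, 3))
        L = int(rng.integers(max(w, 4), 7))
        matrix = FrequencyMatrix(rng.dirichlet(np.ones(4), size=w))
        params = SpatialParams(
            rho=float(rng.uniform(0.2, 0.9)), mu=float(rng.uniform(0, L)),
            omega=float(rng.uniform(1, L)), tau=float(rng.uniform(0, 1)),
            lam=float(rng.uniform(0.01, 0.3)))
        variant = "monosite" if rng.random() < 0.5 else "multisite"
        model = SignatureModel(matrix=matrix, bg=BG, params=params,
                               variant=variant, length=L)
        total = sum(np.exp(brute_force_likelihood(model, "".join(t)))
                    for t in itertools.product("ACGT", repeat=L))
        mass = (1 - params.rho) + params.rho * brute_force_consistency(
            model, L)
        worst = max(worst, abs(total / mass - 1.0))
    return {"n": n_instances, "max_mass_dev": worst}


# ---------------------------------------------------------------------------
# information estimator


def kl_validation(n_samples: int = 10000, seed: int = 0) -> dict:
    """Sampled KL vs exact enumeration on a 10-bp single-site model.

    The fixture carries one Ste12-like TGAAAC site in a 10-bp promoter,
    mirroring the short-model validation of the sampling estimator.
    """
    matrix = consensus_matrix("TGAAAC", 0.85)
    model = single_site_baseline(matrix, BG, 10)
    exact = exact_kl(model)
    est = sampled_kl(model, n_samples=n_samples, seed=seed)
    z = abs(est.nats - exact) / est.se
    return {"exact_nats": exact, "sampled_nats": est.nats, "se": est.se,
            "z": z, "n": n_samples}


# ---------------------------------------------------------------------------
# EM recovery

RECOVERY_TRUTH = SpatialParams(rho=0.6, mu=250.0, omega=120.0, tau=0.8,
                               lam=0.008)
RECOVERY_MATRIX = consensus_matrix("ACGGTAAC", 0.88)


def recovery_study(n_replicates: int = 20, n_promoters: int = 200,
                   length: int = 1003, seed: int = 0) -> dict:
    """Parameter recovery from data sampled at known spatial parameters.

    Each replicate samples ``n_promoters`` promoters at the fixed truth
    (rho=.6, mu=250, omega=120, tau=.8, lam=.008) and refits; reports the
    median absolute errors and the number of EM ascent violations
    (log-likelihood decreases beyond 1e-6) across all replicates.
    """
    truth = RECOVERY_TRUTH
    model = SignatureModel(matrix=RECOVERY_MATRIX, bg=BG, params=truth,
                           length=length)
    errs = {"rho": [], "mu": [], "omega": [], "tau": [], "lam": []}
    violations = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        seqs = [sample_promoter(model, rng)[0] for _ in range(n_promoters)]
        fit = em_fit(RECOVERY_MATRIX, BG, seqs,
                     seed=int(rng.integers(2 ** 31)),
                     schedule=AnnealSchedule(initial_temp=1.0, cooling=0.65,
                                             steps=8, min_temp=0.08),
                     tol=1e-3, max_iter=20, n_starts=2)
        violations += int(np.sum(np.diff(fit.trace) < -1e-6))
        for name in errs:
            errs[name].append(abs(getattr(fit.params, name)
                                  - getattr(truth, name)))
    return {"n_replicates": n_replicates, "n_promoters": n_promoters,
            "ascent_violations": violations,
            **{f"median_abs_err_{k}": float(np.median(v))
               for k, v in errs.items()}}


# ---------------------------------------------------------------------------
# control calibration

_CTRL_MATRIX = consensus_matrix("ACGTTG", 0.9)


def _strand_replicate(tau: float, rep_seed) -> float:
    rng = np.random.default_rng(rep_seed)
    params = SpatialParams(rho=0.8, mu=80, omega=40, tau=tau, lam=0.03)
    model = SignatureModel(matrix=_CTRL_MATRIX, bg=BG, params=params,
                           length=250)
    seqs = [sample_promoter(model, rng)[0] for _ in range(50)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = em_fit(_CTRL_MATRIX, BG, seqs,
                      seed=int(rng.integers(2 ** 31)), **STUDY_FIT)
        cmp_ = lrt_strand(_CTRL_MATRIX, BG, seqs, full,
                          seed=int(rng.integers(2 ** 31)), **STUDY_FIT)
    return cmp_.p


def strand_calibration(n_replicates: int, planted_tau: float,
                       seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of the strand LRT at planted tau (0.5 = null)."""
    ps = [_strand_replicate(planted_tau,
                            np.random.SeedSequence((seed, 11, rep)))
          for rep in range(n_replicates)]
    rate = float(np.mean(np.asarray(ps) < alpha))
    return {"n_replicates": n_replicates, "planted_tau": planted_tau,
            "rejection_rate": rate}


def _spacing_replicate(tight: bool, rep_seed) -> float:
    rng = np.random.default_rng(rep_seed)
    seqs = []
    for _ in range(35):
        L = int(rng.integers(150, 300))
        if tight:
            params = SpatialParams(rho=0.9, mu=60, omega=25, lam=0.04,
                                   tau=0.5)
        else:
            # sites uniform over this promoter's own length
            params = SpatialParams(rho=0.9, mu=L / 2.0, omega=float(L),
                                   lam=0.02, tau=0.5)
        model = SignatureModel(matrix=_CTRL_MATRIX, bg=BG, params=params,
                               length=L)
        seqs.append(sample_promoter(model, rng, length=L)[0])
    cfg = ScrambleConfig(min_set_size=105, iterations=30000,
                         seed=int(rng.integers(2 ** 31)))
    fit_kw = dict(schedule=STUDY_SCHEDULE, tol=1e-3, max_iter=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = em_fit(_CTRL_MATRIX, BG, seqs,
                      seed=int(rng.integers(2 ** 31)), n_starts=2, **fit_kw)
        scrambled, _ = scramble_set(seqs, _CTRL_MATRIX, BG, cfg)
        scrambled_fit = em_fit(_CTRL_MATRIX, BG, scrambled,
                               seed=int(rng.integers(2 ** 31)), n_starts=1,
                               **fit_kw)
        cmp_ = spacing_control_test(_CTRL_MATRIX, BG, seqs, full,
                                    scrambled_fit=scrambled_fit,
                                    seed=int(rng.integers(2 ** 31)),
                                    n_starts=1, **fit_kw)
    return cmp_.p


def spacing_calibration(n_replicates: int, tight: bool,
                        seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of the scramble spacing control.

    ``tight=True`` plants a narrow plateau on variable-length promoters
    (the effect the control must detect); ``tight=False`` plants sites
    uniformly over each promoter's own length (the length-confound null).
    """
    ps = [_spacing_replicate(tight, np.random.SeedSequence((seed, 13, rep)))
          for rep in range(n_replicates)]
    rate = float(np.mean(np.asarray(ps) < alpha))
    return {"n_replicates": n_replicates, "tight": tight,
            "rejection_rate": rate}


def scramble_diagnostics(seed: int = 0, iterations: int = 10 ** 6) -> dict:
    """Base conservation and plateau flattening of the scrambler."""
    import collections
    rng = np.random.default_rng(seed)
    params = SpatialParams(rho=1.0, mu=200, omega=80, lam=0.025, tau=0.5)
    model = SignatureModel(matrix=_CTRL_MATRIX, bg=BG, params=params,
                           length=500)
    seqs = [sample_promoter(model, rng)[0] for _ in range(60)]
    cfg = ScrambleConfig(min_set_size=300, iterations=iterations,
                         seed=int(rng.integers(2 ** 31)))
    scrambled, skipped = scramble_set(seqs, _CTRL_MATRIX, BG, cfg)
    dup = seqs * 5
    conserved = (collections.Counter("".join(scrambled))
                 == collections.Counter("".join(dup))
                 and sorted(map(len, scrambled)) == sorted(map(len, dup)))
    pos = []
    for s in scrambled:
        track = scan_scores(_CTRL_MATRIX, BG, s).max(axis=1)
        pos.extend(np.flatnonzero(track >= 8.0))
    hist, _ = np.histogram(pos, bins=15, range=(0, 500 - 6 + 1))
    gof_p = float(stats.chisquare(hist).pvalue)
    return {"base_counts_conserved": bool(conserved),
            "flatten_gof_p": gof_p, "skipped": skipped,
            "n_sites_pooled": len(pos)}


# ---------------------------------------------------------------------------
# end-to-end expression benchmark

_BENCH_MATRIX = consensus_matrix("ACGTTGA", 0.78)


def expression_benchmark(n_promoters: int = 500, effect: float = -2.0,
                         noise_sd: float = 1.0, k: int = 50,
                         resamples: int = 5000, seed: int = 0) -> dict:
    """Synthetic deletion-expression benchmark comparing the rankers.

    Promoters carry a multisite density signal (rho=.1); expression change
    is concentrated on the truly regulated promoters.  Reports the top-K
    mean |change| of the signature and best-single-site rankers, the
    significance call of the signature ranking, and the thermodynamic
    probability total.
    """
    params = SpatialParams(rho=0.1, mu=250, omega=120, tau=0.5, lam=0.02)
    model = SignatureModel(matrix=_BENCH_MATRIX, bg=BG, params=params,
                           length=600)
    proms, truth = generate_benchmark(model, n_promoters, effect=effect,
                                      noise_sd=noise_sd, seed=seed)
    sig = rank_by_signature(model, proms)
    top = rank_by_top_site(_BENCH_MATRIX, BG, proms)
    thermo = rank_by_thermodynamic(_BENCH_MATRIX, BG, proms)
    ev_sig = evaluate_topk(sig, truth.expression, k=k, resamples=resamples,
                           seed=seed + 1)
    ev_top = evaluate_topk(top, truth.expression, k=k, resamples=resamples,
                           seed=seed + 1)
    return {
        "n_promoters": n_promoters, "k": k,
        "signature_top_mean_abs": abs(ev_sig.mean_change),
        "top_site_top_mean_abs": abs(ev_top.mean_change),
        "signature_significant": bool(ev_sig.significant),
        "top_site_significant": bool(ev_top.significant),
        "thermo_prob_sum": float(thermo.table["score"].sum()),
        "n_regulated": int(truth.regulated.sum()),
    }
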