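"""Model selection and negative controls for trained signatures.

Three questions are asked of every trained signature:

* is the strand bias real? — likelihood ratio test against a refit with
  tau pinned at 0.5 (df=1);
* is the spatial restriction more than promoter lengths explain? — the
  training set is spatially scrambled by segment swaps that conserve
  lengths, base composition and site strength/number; the original data are
  then refit with (mu, omega) pinned at the scramble-derived values and
  compared by a df=2 likelihood ratio test;
* is the signature an artifact of the background model? — the model is fit
  to sets of regions unbound in every condition; if an appreciable rho is
  trainable there, the signature is discarded.

Site density (multisite vs monosite) is selected by BIC, since the variants
are not nested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import _kernels
from .fitting import AnnealSchedule, FitResult, em_fit
from .model import PreparedSet, SignatureModel, SpatialParams
from .pwm import BackgroundModel, FrequencyMatrix, _score_tables, encode, decode

logger = logging.getLogger(__name__)

#: effective parameter counts for the information criterion
N_PARAMS = {"multisite": 5, "monosite": 4}


@dataclass
class ModelComparison:
    loglik_full: float
    loglik_null: float
    df: int
    statistic: float = field(init=False)
    p: float = field(init=False)
    criterion_full: Optional[float] = None
    criterion_null: Optional[float] = None

    def __post_init__(self):
        stat = 2.0 * (self.loglik_full - self.loglik_null)
        if stat < -1e-6:
            raise ValueError(
                f"nested null out-scored the full model (stat={stat:.3g}); "
                "refit did not converge")
        self.statistic = max(stat, 0.0)
        self.p = float(stats.chi2.sf(self.statistic, self.df))


@dataclass
class ScrambleConfig:
    min_set_size: int = 600
    segment_min: int = 5
    segment_max: int = 75
    iterations: int = 1_000_000   # 1e8 recovers the exhaustive regime
    border_threshold: float = 0.0  # log2 score marking a site
    max_attempts: int = 200
    seed: Optional[int] = None

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 1 <= self.segment_min <= self.segment_max:
            raise ValueError("bad segment length range")


@dataclass
class ScreenResult:
    set_max_rho: list
    median_max_rho: float
    signature_rho: float
    any_exceeds_signature: bool
    verdict: str   # "keep" | "discard"
    reason: str


# ---------------------------------------------------------------------------
# likelihood ratio tests


def _refit_null(matrix, bg, sequences, start_params: SpatialParams,
                fixed, seed, schedule, **fit_kw) -> FitResult:
    return em_fit(matrix, bg, sequences, init_params=[start_params],
                  fixed=fixed, seed=seed, schedule=schedule, **fit_kw)


def lrt_strand(matrix: FrequencyMatrix, bg: BackgroundModel,
               sequences: Sequence[str], fit_full: FitResult,
               seed=None, schedule: Optional[AnnealSchedule] = None,
               **fit_kw) -> ModelComparison:
    """Test the strand-bias parameter: null has tau pinned at 0.5 (df=1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = _refit_null(matrix, bg, sequences,
                           fit_full.params.replace(tau=0.5), ("tau",),
                           seed, schedule, variant=fit_full.variant, **fit_kw)
        full_ll = fit_full.loglik
        if null.loglik > full_ll + 1e-6:
            # the null's annealing found a better spatial triple; refit the
            # full model from there with tau free
            refit = em_fit(matrix, bg, sequences,
                           init_params=[null.params.replace(
                               tau=fit_full.params.tau)],
                           seed=seed, schedule=schedule,
                           variant=fit_full.variant, **fit_kw)
            full_ll = max(full_ll, refit.loglik)
    return ModelComparison(loglik_full=max(full_ll, null.loglik),
                           loglik_null=null.loglik, df=1)


def lrt_spacing_uniform(matrix: FrequencyMatrix, bg: BackgroundModel,
                        sequences: Sequence[str], fit_full: FitResult,
                        seed=None, schedule: Optional[AnnealSchedule] = None,
                        **fit_kw) -> ModelComparison:
    """Initial spacing test: null pins the plateau to cover everything.

    The null fixes mu = L/2 and omega = L (a plateau spanning every
    promoter), leaving rho, tau, lam free; df=2.
    """
    L = max(len(s) for s in sequences)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = _refit_null(
            matrix, bg, sequences,
            fit_full.params.replace(mu=L / 2.0, omega=float(L)),
            ("mu", "omega"), seed, schedule, variant=fit_full.variant,
            **fit_kw)
    return ModelComparison(loglik_full=max(fit_full.loglik, null.loglik),
                           loglik_null=null.loglik, df=2)


# ---------------------------------------------------------------------------
# spatial scrambling


def scramble_set(sequences: Sequence[str], matrix: FrequencyMatrix,
                 bg: BackgroundModel, config: ScrambleConfig):
    """Segment-swap scrambling preserving lengths, composition and sites.

    The set is first duplicated to ``config.min_set_size`` sequences; then
    ``config.iterations`` times a random segment (length uniform in the
    configured range) whose borders are not overlapped by any site scoring
    at or above the threshold is swapped with an equal-length, equally
    border-clean segment of another sequence.  Scores are re-scanned locally
    after each swap.  Returns (scrambled sequences, skipped iterations).
    """
    if not sequences:
        raise ValueError("empty sequence set")
    seqs = list(sequences)
    while len(seqs) < config.min_set_size:
        seqs.append(seqs[len(seqs) % len(sequences)])
    m = len(seqs)
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    Lmax = int(lengths.max())
    w = matrix.width
    codes = np.full((m, Lmax), 4, dtype=np.int8)
    for j, s in enumerate(seqs):
        codes[j, :len(s)] = encode(s)
    fwd, rev = _score_tables(matrix, bg, base=2.0, invalid=-np.inf)
    tracks = np.full((m, Lmax), -np.inf)
    for j in range(m):
        _kernels._rescan(codes, tracks, j, 0, int(lengths[j]), w, fwd, rev,
                         lengths)
    seed = np.random.default_rng(config.seed).integers(2**31)
    skipped = _kernels.scramble_kernel(
        codes, lengths, tracks, w, config.segment_min, config.segment_max,
        config.border_threshold, config.iterations, config.max_attempts,
        fwd, rev, seed)
    if skipped:
        logger.info("scramble: %d/%d iterations skipped", skipped,
                    config.iterations)
    out = [decode(codes[j, :lengths[j]]) for j in range(m)]
    return out, int(skipped)


def spacing_control_test(matrix: FrequencyMatrix, bg: BackgroundModel,
                         sequences: Sequence[str], fit_full: FitResult,
                         config: Optional[ScrambleConfig] = None,
                         seed=None, schedule: Optional[AnnealSchedule] = None,
                         scrambled_fit: Optional[FitResult] = None,
                         **fit_kw) -> ModelComparison:
    """Length-confound control (df=2).

    Fits the model to the scrambled training set, then refits the original
    data with (mu, omega) pinned at the scramble-derived values; a
    significant likelihood ratio means the spatial restriction exceeds what
    promoter lengths alone explain.
    """
    config = config or ScrambleConfig(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if scrambled_fit is None:
            scrambled, _ = scramble_set(sequences, matrix, bg, config)
            scrambled_fit = em_fit(matrix, bg, scrambled, seed=seed,
                                   schedule=schedule,
                                   variant=fit_full.variant, **fit_kw)
        pinned = fit_full.params.replace(mu=scrambled_fit.params.mu,
                                         omega=scrambled_fit.params.omega)
        null = _refit_null(matrix, bg, sequences, pinned, ("mu", "omega"),
                           seed, schedule, variant=fit_full.variant, **fit_kw)
    return ModelComparison(loglik_full=max(fit_full.loglik, null.loglik),
                           loglik_null=null.loglik, df=2)


# ---------------------------------------------------------------------------
# density selection


@dataclass
class DensitySelection:
    choice: str                  # "multisite" | "monosite"
    bic_multisite: float
    bic_monosite: float
    expected_sites: float        # per promoter, under the multisite fit


def compare_density(matrix: FrequencyMatrix, bg: BackgroundModel,
                    sequences: Sequence[str], fit_multisite: FitResult,
                    fit_monosite: FitResult) -> DensitySelection:
    """BIC selection between the multisite and monosite variants."""
    n = len(sequences)
    bic_multi = N_PARAMS["multisite"] * np.log(n) - 2.0 * fit_multisite.loglik
    bic_mono = N_PARAMS["monosite"] * np.log(n) - 2.0 * fit_monosite.loglik
    choice = "multisite" if bic_multi < bic_mono else "monosite"
    L = max(len(s) for s in sequences)
    model = fit_multisite.model(matrix, bg, L)
    prep = PreparedSet(model, sequences)
    _, _, post = prep.posteriors(model.params)
    return DensitySelection(choice=choice, bic_multisite=float(bic_multi),
                            bic_monosite=float(bic_mono),
                            expected_sites=float(post.sum() / n))


# ---------------------------------------------------------------------------
# unbound-region screen


def unbound_screen(matrix: FrequencyMatrix, bg: BackgroundModel,
                   unbound_sequences: Sequence[str], signature_rho: float,
                   seed=None, n_sets: int = 20, set_size: int = 20,
                   n_starts: int = 20, median_threshold: float = 0.15,
                   schedule: Optional[AnnealSchedule] = None,
                   **fit_kw) -> ScreenResult:
    """Fit the model to sets of unbound regions and screen the signature.

    Assembles ``n_sets`` random sets from the unbound pool and fits each
    from ``n_starts`` starts.  The signature is discarded if the median of
    the per-set maximum trained rho exceeds ``median_threshold``, or if any
    trained rho exceeds the signature's own rho.
    """
    pool = list(unbound_sequences)
    if len(pool) < set_size:
        raise ValueError(
            f"unbound pool ({len(pool)}) smaller than one screen set "
            f"({set_size})")
    rng = np.random.default_rng(seed)
    set_max = []
    all_rhos = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sets):
            idx = rng.choice(len(pool), size=set_size, replace=False)
            subset = [pool[i] for i in idx]
            fit = em_fit(matrix, bg, subset, n_starts=n_starts,
                         seed=int(rng.integers(2**31)), schedule=schedule,
                         **fit_kw)
            rhos = [p.rho for p, _ in fit.starts]
            all_rhos.extend(rhos)
            set_max.append(max(rhos))
    median_max = float(np.median(set_max))
    exceeds = bool(any(r > signature_rho for r in all_rhos))
    if median_max > median_threshold:
        verdict, reason = "discard", (
            f"median of per-set max rho = {median_max:.3f} > "
            f"{median_threshold}")
    elif exceeds:
        verdict, reason = "discard", (
            "a screen fit reached rho above the signature's "
            f"({signature_rho:.3f})")
    else:
        verdict, reason = "keep", (
            f"median of per-set max rho = {median_max:.3f} <= "
            f"{median_threshold} and no screen rho exceeded the signature's")
    return ScreenResult(set_max_rho=set_max, median_max_rho=median_max,
                        signature_rho=signature_rho,
                        any_exceeds_signature=exceeds, verdict=verdict,
                        reason=reason)
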