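"""Target prediction and expression-change evaluation.

Four ways of ranking promoters as targets of a factor:

* ``signature`` — posterior probability of the regulation variable,
  E[R | sequence], computed with the prior rho fixed at 0.5;
* ``thermodynamic`` — the promoter's share of total Boltzmann-weighted site
  affinity across the whole set (a single protein molecule competed for by
  all promoters: the probability it is bound somewhere in that promoter);
* ``top_site`` — the best single log-odds site score;
* ``chip`` — smallest binding p-value across conditions (used as the
  experimental reference).

Rankings are evaluated against per-ORF expression changes upon factor
deletion: the mean change of the top-K predictions is compared with a null
distribution from resampled random K-sets, methods are compared by
bootstrap over the whole data set, and across factors by an exact binomial
test on the number of "wins".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

from .model import PreparedSet, SignatureModel, _posterior_r
from .pwm import BackgroundModel, FrequencyMatrix, scan_scores

logger = logging.getLogger(__name__)


@dataclass
class RankedTargets:
    """Per-promoter scores and deterministic ranks for one method.

    ``table`` has columns (id, score, rank); rank 1 is the best score, ties
    broken by promoter id.
    """

    table: pd.DataFrame
    method: str

    @classmethod
    def from_scores(cls, ids, scores, method: str,
                    sort_keys=None) -> "RankedTargets":
        """``sort_keys`` optionally orders by a monotone transform of the
        score with better floating-point resolution (e.g. log odds for a
        posterior that saturates at 1)."""
        df = pd.DataFrame({"id": list(ids), "score": np.asarray(scores,
                                                                dtype=float)})
        df["_key"] = (df["score"] if sort_keys is None
                      else np.asarray(sort_keys, dtype=float))
        df = df.sort_values(["_key", "id"],
                            ascending=[False, True], kind="mergesort")
        df = df.drop(columns="_key")
        df["rank"] = np.arange(1, len(df) + 1)
        return cls(table=df.reset_index(drop=True), method=method)

    def top(self, k: int) -> pd.DataFrame:
        return self.table.nsmallest(k, "rank")

    def scores(self) -> pd.Series:
        return self.table.set_index("id")["score"]


def rank_by_top_site(matrix: FrequencyMatrix, bg: BackgroundModel,
                     promoters: dict) -> RankedTargets:
    """Rank promoters by their highest-scoring site on either strand."""
    ids, scores = [], []
    for pid, seq in promoters.items():
        track = scan_scores(matrix, bg, seq)
        score = float(track.max()) if track.size else -np.inf
        ids.append(pid)
        scores.append(score)
    return RankedTargets.from_scores(ids, scores, "top_site")


def rank_by_thermodynamic(matrix: FrequencyMatrix, bg: BackgroundModel,
                          promoters: dict) -> RankedTargets:
    """Rank promoters by their share of total site affinity.

    Each possible site contributes affinity e^score (natural-log PWM
    score); Z is the total over every site in every promoter, and a
    promoter's score is the summed affinity of its own sites divided by Z —
    the probability that a single protein molecule is bound within it.
    Scores over the set sum to one.
    """
    if not promoters:
        raise ValueError("empty promoter set")
    ids, aff = [], []
    log2e = np.log(2.0)
    for pid, seq in promoters.items():
        track = scan_scores(matrix, bg, seq)  # log2 units
        ids.append(pid)
        if track.size == 0:
            aff.append(-np.inf)
        else:
            # convert to natural log and sum affinities over sites/strands
            nat = track.ravel() * log2e
            aff.append(float(_logsumexp(nat)))
    aff = np.array(aff)
    z = _logsumexp(aff[np.isfinite(aff)])
    probs = np.exp(aff - z)
    probs[~np.isfinite(aff)] = 0.0
    return RankedTargets.from_scores(ids, probs, "thermodynamic")


def _logsumexp(x):
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return -np.inf
    m = x.max()
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.exp(x - m).sum()))


def rank_by_signature(model: SignatureModel, promoters: dict,
                      rho_override: float = 0.5, masks=None) -> RankedTargets:
    """Rank promoters by E[R | sequence] with the prior rho fixed at 0.5.

    Ordering uses the posterior log odds so strong promoters stay ordered
    even where the probability itself saturates at 1.
    """
    ids = list(promoters.keys())
    prep = PreparedSet(model, [promoters[i] for i in ids], masks=masks)
    m1 = prep.log_m1(model.params)
    scores = _posterior_r(rho_override, m1)
    if 0.0 < rho_override < 1.0:
        log_odds = np.log(rho_override) - np.log1p(-rho_override) + m1
    else:
        log_odds = scores
    return RankedTargets.from_scores(ids, scores, "signature",
                                     sort_keys=log_odds)


def rank_by_chip(pvalue_table: pd.DataFrame) -> RankedTargets:
    """Rank promoters by smallest binding p-value across conditions.

    ``pvalue_table`` is indexed by promoter id with one column per
    condition; rows that are entirely missing are excluded (logged).
    """
    pmin = pvalue_table.min(axis=1, skipna=True)
    missing = pmin.isna()
    if missing.any():
        logger.info("rank_by_chip: %d promoters without any p-value excluded",
                    int(missing.sum()))
        pmin = pmin[~missing]
    return RankedTargets.from_scores(pmin.index, -pmin.values, "chip")


BOUND_PVALUE = 0.05  # convention for calling a region "bound"


# ---------------------------------------------------------------------------
# evaluation against expression change


@dataclass
class EvaluationResult:
    method: str
    k: int
    mean_change: float
    ci_low: float
    ci_high: float
    significant: bool
    n_joined: int
    resamples: int


def evaluate_topk(ranked: RankedTargets, expression: pd.Series, k: int = 50,
                  resamples: int = 5000, seed=None,
                  exclude: Optional[Sequence[str]] = None
                  ) -> EvaluationResult:
    """Mean expression change of the top-K predictions vs a resampled null.

    The null 95% CI is the [2.5, 97.5] percentile band of the mean change
    of ``resamples`` random K-sets drawn from the expression table; the
    observed mean is significant if it falls outside.  ``exclude`` removes
    ORFs (e.g. the training set) from both the ranking and the null.
    """
    expr = expression.dropna()
    if exclude:
        drop = set(exclude)
        expr = expr[~expr.index.isin(drop)]
    joined = ranked.table[ranked.table["id"].isin(expr.index)]
    n = len(joined)
    if n == 0:
        raise ValueError("no ranked promoter matches the expression table")
    if n < k:
        warnings.warn(f"only {n} ranked ORFs have expression; evaluating "
                      f"at K={n}", stacklevel=2)
        k = n
    top = joined.nsmallest(k, "rank")["id"]
    mean_change = float(expr.loc[top].mean())
    rng = np.random.default_rng(seed)
    vals = expr.to_numpy()
    draws = rng.choice(vals.size, size=(resamples, k), replace=True)
    null_means = vals[draws].mean(axis=1)
    lo, hi = np.percentile(null_means, [2.5, 97.5])
    return EvaluationResult(
        method=ranked.method, k=k, mean_change=mean_change,
        ci_low=float(lo), ci_high=float(hi),
        significant=bool(mean_change < lo or mean_change > hi),
        n_joined=n, resamples=resamples)


def bootstrap_method_comparison(ranked_a: RankedTargets,
                                ranked_b: RankedTargets,
                                expression: pd.Series, k: int = 50,
                                reps: int = 10000, seed=None) -> float:
    """Bootstrap p-value that method B matches or beats method A.

    Resamples (promoter, expression) pairs over the common universe; in
    each replicate the top-K of each method is retrieved and the magnitude
    of its mean expression change computed.  Returns the fraction of
    replicates in which |mean change of B's top-K| >= |mean change of A's
    top-K| (A = signature, B = thermodynamic in the headline comparison).
    """
    expr = expression.dropna()
    sa = ranked_a.scores()
    sb = ranked_b.scores()
    universe = sorted(set(sa.index) & set(sb.index) & set(expr.index))
    n = len(universe)
    if n == 0:
        raise ValueError("no common promoters between rankings and "
                         "expression")
    k = min(k, n)
    a = sa.loc[universe].to_numpy()
    b = sb.loc[universe].to_numpy()
    e = expr.loc[universe].to_numpy()
    rng = np.random.default_rng(seed)
    wins = 0
    chunk = max(1, int(2e7 // max(n, 1)))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        idx = rng.integers(0, n, size=(m, n))
        ea = np.take_along_axis(e[idx], np.argpartition(-a[idx], k - 1,
                                                        axis=1)[:, :k],
                                axis=1).mean(axis=1)
        eb = np.take_along_axis(e[idx], np.argpartition(-b[idx], k - 1,
                                                        axis=1)[:, :k],
                                axis=1).mean(axis=1)
        wins += int(np.sum(np.abs(eb) >= np.abs(ea)))
        done += m
    return wins / reps


def binomial_wins_test(k_wins: int, n_factors: int) -> float:
    """Exact one-sided binomial test: P(X >= k) with X ~ Bin(n, 1/2)."""
    if not 0 <= k_wins <= n_factors:
        raise ValueError("k_wins must be between 0 and n_factors")
    return float(stats.binom.sf(k_wins - 1, n_factors, 0.5))


# ---------------------------------------------------------------------------
# diagnostics


def score_density_profile(matrix: FrequencyMatrix, bg: BackgroundModel,
                          promoters: Sequence[str], window: int = 20,
                          sims: int = 100, seed=None) -> pd.DataFrame:
    """Positive log2 score density by distance from the TSS, with a
    simulated background band.

    For each ``window``-bp bin of proximal-end distance p, density is the
    sum of positive site scores (both strands) divided by the number of
    possible site positions falling in that bin across the set.  The
    background line and 95% band come from ``sims`` sets of GC-matched
    random sequences with the same length distribution.  Bins reached by no
    promoter are NaN.
    """
    w = matrix.width
    lengths = [len(s) for s in promoters]
    pmax = max(L - w for L in lengths)
    nbins = pmax // window + 1

    def profile(seqs):
        pos_sum = np.zeros(nbins)
        count = np.zeros(nbins)
        for seq in seqs:
            track = scan_scores(matrix, bg, seq)
            if track.size == 0:
                continue
            L = len(seq)
            bins = (L - w - np.arange(track.shape[0])) // window
            pos_sum += np.bincount(bins, weights=track.clip(min=0).sum(axis=1),
                                   minlength=nbins)
            count += 2 * np.bincount(bins, minlength=nbins)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(count > 0, pos_sum / count, np.nan), count

    density, count = profile(promoters)
    rng = np.random.default_rng(seed)
    bgp = bg.probs
    sim_densities = np.empty((sims, nbins))
    for s in range(sims):
        sim_seqs = ["".join("ACGT"[c] for c in rng.choice(4, size=L, p=bgp))
                    for L in lengths]
        sim_densities[s], _ = profile(sim_seqs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bg_mean = np.nanmean(sim_densities, axis=0)
        lo = np.nanpercentile(sim_densities, 2.5, axis=0)
        hi = np.nanpercentile(sim_densities, 97.5, axis=0)
    return pd.DataFrame({
        "p_lo": np.arange(nbins) * window,
        "p_hi": (np.arange(nbins) + 1) * window,
        "density": density,
        "bg_mean": bg_mean, "bg_lo": lo, "bg_hi": hi,
        "n_positions": count,
    })


def roc_binding(ranked: RankedTargets, bound_labels: pd.Series):
    """ROC of a ranking against binary bound labels.

    Returns (fpr, tpr, auc); auc is NaN (with a warning) when the labels
    are single-class.
    """
    common = ranked.table[ranked.table["id"].isin(bound_labels.index)]
    y = bound_labels.loc[common["id"]].astype(int).to_numpy()
    s = common["score"].to_numpy()
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: AUC undefined", stacklevel=2)
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), float("nan")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return fpr, tpr, float(_skm.auc(fpr, tpr))
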