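"""The generative promoter-signature model and exact inference.

A promoter is modelled 5'->3' with the transcription start site (TSS) at the
right end.  A binary regulation variable R (prior rho) decides whether the
promoter carries the factor's signature.  Given R=1, the hidden chain walks
the sequence emitting background bases or complete binding-site blocks; the
probability of starting a site whose TSS-proximal end lies p bp upstream of
the TSS is

    q(p, strand) = lam * sigma(eta*(p - (mu - omega)))
                       * sigma(eta*((mu + omega) - p)) * s

with sigma the logistic function and s = tau (forward) or 1 - tau (reverse):
an approximately plateau-shaped site distribution of height lam centred at
mu with half-width omega and edge slope eta.  Given R=0 the chain emits pure
background.  An observed consistency variable C=1 forces R=1 promoters to
contain at least one complete site.  The "monosite" variant permits exactly
one site; the default "multisite" variant any positive number.

All likelihoods are natural-log and computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from . import _kernels
from .pwm import (BackgroundModel, FrequencyMatrix, _score_tables, encode,
                  decode)

DEFAULT_LENGTH = 1003
DEFAULT_ETA = 0.1
NEG_INF = -np.inf


@dataclass(frozen=True)
class SpatialParams:
    """The five trained spatial parameters plus the fixed edge slope eta."""

    rho: float    # fraction of promoters carrying the signature
    mu: float     # plateau centre, bp upstream of the TSS
    omega: float  # plateau half-width, bp
    tau: float    # forward-strand fraction of emitted sites
    lam: float    # per-position site initiation rate on the plateau
    eta: float = DEFAULT_ETA

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0,1], got {self.rho}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0,1], got {self.tau}")
        if self.mu < 0 or self.omega < 0:
            raise ValueError("mu and omega must be non-negative")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not 0.0 <= self.lam < 1.0:
            raise ValueError(
                f"lam must be in [0,1) so that total initiation probability "
                f"stays below one, got {self.lam}")

    def replace(self, **kw) -> "SpatialParams":
        return replace(self, **kw)


def initiation_rate(params: SpatialParams, p, strand: str = "+"):
    """Probability of a site (proximal end at distance ``p``) on ``strand``.

    Vectorised over ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("p must be non-negative")
    plateau = expit(params.eta * (p - (params.mu - params.omega))) * \
        expit(params.eta * ((params.mu + params.omega) - p))
    s = params.tau if strand in ("+", "fwd") else 1.0 - params.tau
    q = params.lam * plateau * s
    return q if q.ndim else float(q)


@dataclass(frozen=True)
class SignatureModel:
    """Frequency matrix + background + spatial parameters + variant."""

    matrix: FrequencyMatrix
    bg: BackgroundModel
    params: SpatialParams
    variant: str = "multisite"
    length: int = DEFAULT_LENGTH
    name: str = ""

    def __post_init__(self):
        if self.variant not in ("multisite", "monosite"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.length < self.matrix.width:
            raise ValueError("promoter length contract shorter than motif")
        # total initiation probability at the plateau top must stay below 1
        if self.params.lam >= 1.0:
            raise ValueError("lam >= 1 gives initiation probability >= 1")

    @property
    def monosite(self) -> bool:
        return self.variant == "monosite"

    @property
    def w(self) -> int:
        return self.matrix.width


@dataclass
class LatticePosteriors:
    """Exact per-promoter inference output."""

    loglik: float               # ln P(N, C=1)
    e_r: float                  # E[R | N, C=1]
    site_start: np.ndarray      # (L, 2) posterior of a site starting there
    expected_sites: float       # sum of site_start

    def __post_init__(self):
        self.expected_sites = float(self.site_start.sum())


# ---------------------------------------------------------------------------
# batched preparation


def _transition_arrays(model: SignatureModel, pmax: int):
    """(log_qf, log_qr, log_stay) indexed by proximal-end distance p."""
    p = np.arange(pmax + 1, dtype=float)
    prm = model.params
    qf = initiation_rate(prm, p, "+")
    qr = initiation_rate(prm, p, "-")
    qtot = qf + qr
    if np.any(qtot >= 1.0):
        raise ValueError("site initiation probability >= 1; reduce lam")
    with np.errstate(divide="ignore"):
        return np.log(qf), np.log(qr), np.log1p(-qtot)


def _site_logratio_tables(model: SignatureModel):
    # natural-log ratio tables; ambiguous/masked base forbids the site
    fwd, rev = _score_tables(model.matrix, model.bg, base=np.e,
                             invalid=NEG_INF)
    return fwd, rev


def _encode_batch(seqs: Sequence[str], masks=None):
    n = len(seqs)
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    Lmax = int(lengths.max()) if n else 0
    codes = np.full((n, Lmax), 4, dtype=np.int8)
    for j, s in enumerate(seqs):
        codes[j, :len(s)] = encode(s)
    if masks is not None:
        for j, mask in enumerate(masks):
            if mask is None:
                continue
            for lo, hi in mask:
                codes[j, lo:hi] = 4
    return codes, lengths


def _site_logW(model: SignatureModel, codes: np.ndarray,
               lengths: np.ndarray) -> np.ndarray:
    """(n, Lmax, 2) site log-likelihood-ratios; -inf where a site is illegal."""
    fwd, rev = _site_logratio_tables(model)
    n, Lmax = codes.shape
    w = model.w
    logW = np.full((n, Lmax, 2), NEG_INF)
    if Lmax < w:
        return logW
    m = Lmax - w + 1
    acc_f = np.zeros((n, m))
    acc_r = np.zeros((n, m))
    for k in range(w):
        window = codes[:, k:k + m]
        acc_f += fwd[k, window]
        acc_r += rev[k, window]
    logW[:, :m, 0] = acc_f
    logW[:, :m, 1] = acc_r
    # sites must fit within each sequence
    pos = np.arange(m)[None, :]
    bad = pos > (lengths[:, None] - w)
    logW[:, :m, 0][bad] = NEG_INF
    logW[:, :m, 1][bad] = NEG_INF
    return logW


class PreparedSet:
    """Per-dataset precomputation shared across likelihood evaluations.

    The frequency matrix is fixed during fitting, so the per-position site
    log-ratios and background log-likelihoods are computed once; evaluating
    the marginal likelihood at new spatial parameters only rebuilds the
    transition arrays.
    """

    def __init__(self, model: SignatureModel, seqs: Sequence[str], masks=None,
                 codes: Optional[np.ndarray] = None,
                 lengths: Optional[np.ndarray] = None):
        self.model = model
        if codes is not None:
            self.codes, self.lengths = codes, lengths
        else:
            self.codes, self.lengths = _encode_batch(seqs, masks)
        self.n = self.codes.shape[0]
        self.w = model.w
        if self.n and int(self.lengths.min()) < self.w:
            raise ValueError("sequence shorter than the motif")
        self.logW = _site_logW(model, self.codes, self.lengths)
        lbg = np.append(model.bg.log_probs, 0.0)  # masked bases emit bg; the
        # constant cancels between model and background, so contribute 0
        self.logbg = lbg[self.codes].sum(axis=1)
        self.pmax = int(self.lengths.max()) - self.w if self.n else 0

    def log_m1(self, params: SpatialParams) -> np.ndarray:
        """ln P(N, C=1 | R=1) - ln BG(N), per sequence."""
        model = replace(self.model, params=params)
        lqf, lqr, lst = _transition_arrays(model, max(self.pmax, 0))
        return _kernels.forward_batch(self.lengths, self.logW, lqf, lqr, lst,
                                      self.w, model.monosite)

    def loglik(self, params: SpatialParams) -> float:
        """Total ln P(N, C=1) over the set."""
        return float(self._per_seq_loglik(params).sum())

    def _per_seq_loglik(self, params: SpatialParams) -> np.ndarray:
        m1 = self.log_m1(params)
        return self.logbg + _mix(params.rho, m1)

    def posteriors(self, params: SpatialParams):
        """(loglik_per_seq, e_r, site_start) with full-model weighting."""
        model = replace(self.model, params=params)
        lqf, lqr, lst = _transition_arrays(model, max(self.pmax, 0))
        m1, post = _kernels.forward_backward_batch(
            self.lengths, self.logW, lqf, lqr, lst, self.w, model.monosite)
        ll = self.logbg + _mix(params.rho, m1)
        e_r = _posterior_r(params.rho, m1)
        return ll, e_r, post * e_r[:, None, None]


def _mix(rho: float, log_m1: np.ndarray) -> np.ndarray:
    """ln[(1-rho) + rho*exp(log_m1)] handling the degenerate priors."""
    if rho <= 0.0:
        return np.zeros_like(log_m1)
    if rho >= 1.0:
        return np.log(rho) + log_m1
    return np.logaddexp(np.log1p(-rho), np.log(rho) + log_m1)


def _posterior_r(rho: float, log_m1: np.ndarray) -> np.ndarray:
    if rho <= 0.0:
        return np.zeros_like(log_m1)
    if rho >= 1.0:
        return np.ones_like(log_m1)
    # odds = rho*M1 / (1-rho)
    log_odds = np.log(rho) - np.log1p(-rho) + log_m1
    return expit(log_odds)


# ---------------------------------------------------------------------------
# public single-sequence interface


def forward_backward(model: SignatureModel, seq: str, mask=None
                     ) -> LatticePosteriors:
    """Exact posteriors for one promoter by message passing.

    ``mask`` is an optional list of (start, end) half-open intervals of
    padded fill; masked bases emit background and cannot be part of a site.
    """
    ps = PreparedSet(model, [seq], masks=[mask] if mask is not None else None)
    ll, e_r, post = ps.posteriors(model.params)
    if model.params.rho > 0 and not np.isfinite(ll[0]):
        raise ValueError("sequence admits no consistent path (likelihood 0)")
    return LatticePosteriors(loglik=float(ll[0]), e_r=float(e_r[0]),
                             site_start=post[0, :len(seq)],
                             expected_sites=0.0)


def posterior_regulation(model: SignatureModel, seq: str,
                         rho_override: Optional[float] = None,
                         mask=None) -> float:
    """E[R | N, C=1], optionally with the prior rho replaced (for ranking)."""
    rho = model.params.rho if rho_override is None else rho_override
    if rho <= 0.0:
        return 0.0
    if rho >= 1.0:
        return 1.0
    ps = PreparedSet(model, [seq], masks=[mask] if mask is not None else None)
    m1 = ps.log_m1(model.params)
    return float(_posterior_r(rho, m1)[0])


# ---------------------------------------------------------------------------
# sampling


def sample_promoter(model: SignatureModel, rng: np.random.Generator,
                    length: Optional[int] = None, max_attempts: int = 10000):
    """Draw one promoter (sequence, truth sites) from the model.

    R ~ Bernoulli(rho); if R=1 the emission walk is rejection-resampled until
    the consistency constraint (at least one complete site; exactly one for
    the monosite variant) is met.  Truth sites are (start, strand) with start
    the 0-based 5' string index.
    """
    L = model.length if length is None else int(length)
    if L < model.w:
        raise ValueError("length shorter than the motif")
    prm = model.params
    if rng.random() >= prm.rho:
        return _sample_background(model.bg, L, rng), []
    lqf = initiation_rate(prm, np.arange(L - model.w + 1, dtype=float), "+")
    lqr = initiation_rate(prm, np.arange(L - model.w + 1, dtype=float), "-")
    for _ in range(max_attempts):
        seq, sites = _emission_walk(model, L, lqf, lqr, rng)
        if sites:
            return seq, sites
    raise RuntimeError(
        "could not satisfy the consistency constraint; initiation rate may "
        "be zero over the whole promoter")


def _sample_background(bg: BackgroundModel, L: int, rng) -> str:
    cum = np.cumsum(bg.probs)
    return decode(np.searchsorted(cum, rng.random(L)).astype(np.int8))


def _emission_walk(model: SignatureModel, L, qf, qr, rng):
    w = model.w
    cum_m = np.cumsum(model.matrix.probs, axis=1)
    # reverse orientation: position k emits complement of matrix pos w-1-k
    cum_rc = np.cumsum(model.matrix.probs[::-1, ::-1], axis=1)
    cum_bg = np.cumsum(model.bg.probs)
    # pre-drawn randomness indexed by position keeps the walk cheap
    u_init = rng.random(L)
    bg_bases = np.searchsorted(cum_bg, rng.random(L)).astype(np.int8)
    out = np.empty(L, dtype=np.int8)
    sites = []
    i = 0
    allow = True
    while i < L:
        if allow and i <= L - w:
            p = L - w - i
            u = u_init[i]
            if u < qf[p] + qr[p]:
                fwd = u < qf[p]
                cum = cum_m if fwd else cum_rc
                draws = rng.random(w)
                for k in range(w):
                    out[i + k] = np.searchsorted(cum[k], draws[k])
                sites.append((i, "+" if fwd else "-"))
                i += w
                if model.monosite:
                    allow = False
                continue
        out[i] = bg_bases[i]
        i += 1
    return decode(out), sites


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)


def brute_force_likelihood(model: SignatureModel, seq: str) -> float:
    """ln P(N, C=1) by explicit enumeration of all site placements.

    Independent of the message-passing code path; refuses instances large
    enough to make enumeration infeasible.
    """
    L = len(seq)
    w = model.w
    if L > 30 or w > 5:
        raise ValueError("instance too large for path enumeration")
    codes = encode(seq)
    prm = model.params
    bgp = np.append(model.bg.probs, 1.0)
    mprob = model.matrix.probs

    qf = [float(initiation_rate(prm, L - w - i, "+")) if i <= L - w else 0.0
          for i in range(L)]
    qr = [float(initiation_rate(prm, L - w - i, "-")) if i <= L - w else 0.0
          for i in range(L)]

    def site_emission(i, strand):
        prob = 1.0
        for k in range(w):
            b = codes[i + k]
            if b >= 4:
                return 0.0
            prob *= mprob[k][b] if strand == 0 else mprob[w - 1 - k][3 - b]
        return prob

    total_r1 = 0.0

    def walk(i, nsites, acc):
        nonlocal total_r1
        if acc == 0.0:
            return
        if i == L:
            if nsites >= 1:
                total_r1 += acc
            return
        fits = i <= L - w and np.all(codes[i:i + w] < 4)
        can_start = fits and not (model.monosite and nsites >= 1)
        if can_start:
            walk(i + w, nsites + 1, acc * qf[i] * site_emission(i, 0))
            walk(i + w, nsites + 1, acc * qr[i] * site_emission(i, 1))
            stay = 1.0 - qf[i] - qr[i]
        else:
            stay = 1.0
        walk(i + 1, nsites, acc * stay * bgp[codes[i]])

    walk(0, 0, 1.0)
    bg_lik = float(np.prod(bgp[codes]))
    lik = (1.0 - prm.rho) * bg_lik + prm.rho * total_r1
    return float(np.log(lik)) if lik > 0 else NEG_INF


def brute_force_consistency(model: SignatureModel, L: int) -> float:
    """P(C=1 | R=1) by placement enumeration (emissions marginalised)."""
    w = model.w
    if L > 30 or w > 5:
        raise ValueError("instance too large for path enumeration")
    prm = model.params
    qf = [float(initiation_rate(prm, L - w - i, "+")) if i <= L - w else 0.0
          for i in range(L)]
    qr = [float(initiation_rate(prm, L - w - i, "-")) if i <= L - w else 0.0
          for i in range(L)]
    total = 0.0

    def walk(i, nsites, acc):
        nonlocal total
        if i == L:
            if nsites >= 1:
                total += acc
            return
        can_start = i <= L - w and not (model.monosite and nsites >= 1)
        if can_start:
            walk(i + w, nsites + 1, acc * qf[i])
            walk(i + w, nsites + 1, acc * qr[i])
            stay = 1.0 - qf[i] - qr[i]
        else:
            stay = 1.0
        walk(i + 1, nsites, acc * stay)

    walk(0, 0, 1.0)
    return total


def log_consistency_mass(model: SignatureModel, length: Optional[int] = None
                         ) -> float:
    """ln P(C=1) under the model for an unmasked promoter of given length."""
    L = model.length if length is None else int(length)
    prm = model.params
    lqf, lqr, lst = _transition_arrays(model, max(L - model.w, 0))
    lm = _kernels.consistency_mass(L, lqf, lqr, lst, model.w, model.monosite)
    return float(_mix(prm.rho, np.array([lm]))[0])


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: SignatureModel) -> dict:
    return {
        "name": model.name,
        "variant": model.variant,
        "length": model.length,
        "gc": model.bg.gc,
        "matrix": [[float(v) for v in row] for row in model.matrix.probs],
        "params": {
            "rho": model.params.rho, "mu": model.params.mu,
            "omega": model.params.omega, "tau": model.params.tau,
            "lam": model.params.lam, "eta": model.params.eta,
        },
    }


def model_from_dict(d: dict) -> SignatureModel:
    return SignatureModel(
        matrix=FrequencyMatrix(np.array(d["matrix"]), name=d.get("name", ""),
                               pseudocount=0.0),
        bg=BackgroundModel(gc=d.get("gc", 0.38)),
        params=SpatialParams(**d["params"]),
        variant=d.get("variant", "multisite"),
        length=int(d.get("length", DEFAULT_LENGTH)),
        name=d.get("name", ""),
    )
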