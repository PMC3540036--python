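"""Kullback-Leibler specificity of a signature model.

The specificity of a promoter-recognition signature is measured as the KL
divergence between the distribution of promoter sequences the model emits
(conditioned on the consistency constraint) and an iid GC background over
the same length:

    KL = sum_s P_mod(s) [ln P_mod(s) - ln P_bg(s)]

Exact summation over 4^L sequences is feasible only for toy lengths; for
real promoter lengths the divergence is approximated by sampling N promoters
from the model and averaging the log ratio, which replaces P_mod by 1/N.
The spacing-agnostic baseline emits a single site, without strand bias, at
an (approximately) uniform position: the information it carries is that of
the binding site alone, so the difference between a full model's KL and its
baseline's KL quantifies the spatial contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import (PreparedSet, SignatureModel, SpatialParams,
                    _transition_arrays, sample_promoter)
from .pwm import BackgroundModel, FrequencyMatrix

_EXACT_MAX_LEN = 10


def _log_density(model: SignatureModel, prep: PreparedSet, L: int
                 ) -> np.ndarray:
    """ln of the emitted-sequence density, per sequence in ``prep``.

    The model's sequence distribution mixes background (weight 1-rho) with
    the R=1 branch conditioned on carrying at least one site (weight rho):
    the distribution the rejection sampler draws from.
    """
    prm = model.params
    m1 = prep.log_m1(prm)
    lqf, lqr, lst = _transition_arrays(model, max(L - model.w, 0))
    log_c1_r1 = _kernels.consistency_mass(L, lqf, lqr, lst, model.w,
                                          model.monosite)
    if prm.rho >= 1.0:
        return prep.logbg + m1 - log_c1_r1
    return prep.logbg + np.logaddexp(
        np.log1p(-prm.rho), np.log(prm.rho) + m1 - log_c1_r1)


@dataclass
class KLEstimate:
    nats: float
    se: float          # Monte-Carlo standard error of the sample mean
    n_samples: int
    model_id: str = ""

    @property
    def bits(self) -> float:
        return self.nats / np.log(2.0)


def sampled_kl(model: SignatureModel, bg: BackgroundModel = None,
               n_samples: int = 10000, seed=None,
               length: int = None) -> KLEstimate:
    """Monte-Carlo KL divergence of the model from the background, in nats.

    Samples promoters from the model (R drawn from the trained rho,
    consistency enforced by rejection) and averages
    ln P_mod(s) - ln P_bg(s), with P_mod the consistency-conditioned
    likelihood from message passing.
    """
    bg = bg or model.bg
    L = model.length if length is None else int(length)
    if model.params.rho == 0.0:
        return KLEstimate(0.0, 0.0, n_samples, model.name)
    rng = np.random.default_rng(seed)
    seqs = [sample_promoter(model, rng, length=L)[0]
            for _ in range(n_samples)]
    prep = PreparedSet(model, seqs)
    terms = _log_density(model, prep, L) - prep.logbg
    return KLEstimate(nats=float(terms.mean()),
                      se=float(terms.std(ddof=1) / np.sqrt(n_samples)),
                      n_samples=n_samples, model_id=model.name)


def exact_kl(model: SignatureModel, bg: BackgroundModel = None,
             length: int = None) -> float:
    """Exact KL divergence by summation over all 4^L sequences (L <= 10)."""
    bg = bg or model.bg
    L = model.length if length is None else int(length)
    if L > _EXACT_MAX_LEN:
        raise ValueError(
            f"exact summation limited to length {_EXACT_MAX_LEN}, got {L}")
    if model.params.rho == 0.0:
        return 0.0
    kl = 0.0
    total = 0.0
    n_seq = 4 ** L
    for lo in range(0, n_seq, 65536):
        idx = np.arange(lo, min(lo + 65536, n_seq))
        codes = np.empty((idx.size, L), dtype=np.int8)
        rem = idx.copy()
        for k in range(L - 1, -1, -1):  # base-4 digits enumerate sequences
            codes[:, k] = rem % 4
            rem //= 4
        lengths = np.full(idx.size, L, dtype=np.int64)
        prep = PreparedSet(model, [], codes=codes, lengths=lengths)
        log_p = _log_density(model, prep, L)
        p = np.exp(log_p)
        kl += float(np.sum(p * (log_p - prep.logbg)))
        total += float(p.sum())
    if abs(total - 1.0) > 1e-6:
        raise AssertionError(
            f"model mass over sequence space = {total}, expected 1")
    return kl


def single_site_baseline(matrix: FrequencyMatrix, bg: BackgroundModel,
                         length: int, lam: float = None) -> SignatureModel:
    """Spacing-agnostic single-site model over a promoter of given length.

    Monosite, rho=1, tau=0.5, with the plateau spanning the whole promoter
    (mu at the centre, half-width equal to the length, so the logistic edges
    sit far outside the sequence).  A small lam keeps the geometric tilt of
    the site-position distribution negligible, approximating a uniform
    placement; its KL is then the site information at promoter scale.
    """
    if length < matrix.width:
        raise ValueError("length shorter than the motif")
    if lam is None:
        lam = min(0.25, 1.0 / (2.0 * length))
    params = SpatialParams(rho=1.0, mu=length / 2.0, omega=float(length),
                           tau=0.5, lam=lam)
    return SignatureModel(matrix=matrix, bg=bg, params=params,
                          variant="monosite", length=length,
                          name=(matrix.name or "motif") + "_single_site")
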