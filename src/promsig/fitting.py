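"""Maximum-likelihood training of the spatial parameters.

EM over the hidden regulation and site variables: the E-step is exact
message passing; rho and tau have closed-form M-steps (posterior mean of R,
and the forward share of posterior site-start mass); the spatial triple
(lam, mu, omega) is updated by simulated annealing on the marginal
log-likelihood with rho and tau held at their refreshed values.  Training
runs from several random starts and keeps the best final likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import PreparedSet, SignatureModel, SpatialParams
from .pwm import BackgroundModel, FrequencyMatrix

TRAINING_MINIMUM = 20


@dataclass
class AnnealSchedule:
    """Geometric-cooling Metropolis schedule for the spatial triple."""

    initial_temp: float = 1.0
    cooling: float = 0.9
    steps: int = 50           # proposals per temperature
    min_temp: float = 0.05
    scale_lam: float = 0.25   # multiplied by the current lam
    scale_mu: float = 50.0    # bp
    scale_omega: float = 50.0  # bp

    def __post_init__(self):
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.steps < 1:
            raise ValueError("steps per temperature must be >= 1")

    def temperatures(self):
        t = self.initial_temp
        while t >= self.min_temp:
            yield t
            t *= self.cooling


#: small schedule for simulation studies and tests
FAST_SCHEDULE = AnnealSchedule(initial_temp=1.0, cooling=0.7, steps=12,
                               min_temp=0.08)


@dataclass
class FitResult:
    params: SpatialParams
    loglik: float
    trace: list
    start_index: int
    converged: bool
    variant: str = "multisite"
    n_sequences: int = 0
    starts: list = field(default_factory=list)  # (params, loglik) per start

    def model(self, matrix: FrequencyMatrix, bg: BackgroundModel,
              length: int, name: str = "") -> SignatureModel:
        return SignatureModel(matrix=matrix, bg=bg, params=self.params,
                              variant=self.variant, length=length, name=name)


def mstep_rho(e_r: np.ndarray) -> float:
    """Closed-form update: the mean posterior regulation probability."""
    return float(np.mean(e_r))


def mstep_tau(site_post: np.ndarray) -> float:
    """Closed-form update: forward share of posterior site-start mass.

    ``site_post`` is (n, L, 2); 0.5 when there is no site mass at all.
    """
    fwd = float(site_post[..., 0].sum())
    rev = float(site_post[..., 1].sum())
    tot = fwd + rev
    return 0.5 if tot <= 0.0 else fwd / tot


def anneal_spatial(objective, params: SpatialParams,
                   schedule: AnnealSchedule, rng: np.random.Generator,
                   free=("lam", "mu", "omega"),
                   mu_max: float = 2000.0, omega_max: float = 2000.0):
    """Metropolis search over the free members of (lam, mu, omega).

    ``objective(params) -> loglik``.  Proposals outside the parameter bounds
    are rejected without evaluation.  Returns (best_params, best_loglik);
    deterministic given the generator state.
    """
    free = tuple(f for f in free if f in ("lam", "mu", "omega"))
    cur = params
    cur_ll = objective(cur)
    best, best_ll = cur, cur_ll
    if not free:
        return best, best_ll
    for temp in schedule.temperatures():
        for _ in range(schedule.steps):
            prop = _propose(cur, schedule, rng, free)
            if prop is None:
                continue
            if prop.lam >= 0.5 or prop.lam <= 1e-9 or prop.mu > mu_max \
                    or prop.omega > omega_max or prop.omega < 1.0:
                continue
            ll = objective(prop)
            if ll >= cur_ll or rng.random() < np.exp((ll - cur_ll) / temp):
                cur, cur_ll = prop, ll
                if ll > best_ll:
                    best, best_ll = prop, ll
    return best, best_ll


def _propose(cur: SpatialParams, schedule: AnnealSchedule, rng, free):
    kw = {}
    if "lam" in free:
        kw["lam"] = cur.lam + rng.normal(0.0, schedule.scale_lam * cur.lam)
    if "mu" in free:
        kw["mu"] = cur.mu + rng.normal(0.0, schedule.scale_mu)
    if "omega" in free:
        kw["omega"] = cur.omega + rng.normal(0.0, schedule.scale_omega)
    if kw.get("lam", 1e-3) <= 0 or kw.get("mu", 0.0) < 0 \
            or kw.get("omega", 1.0) <= 0:
        return None
    return cur.replace(**kw)


def _random_start(rng, L: int, eta: float) -> SpatialParams:
    return SpatialParams(
        rho=0.5, tau=0.5,
        mu=float(rng.uniform(0.0, L)),
        omega=float(rng.uniform(25.0, L / 2.0)),
        lam=float(rng.uniform(1.0 / L, 20.0 / L)),
        eta=eta,
    )


def em_fit(matrix: FrequencyMatrix, bg: BackgroundModel,
           sequences: Sequence[str], variant: str = "multisite",
           n_starts: int = 15, schedule: Optional[AnnealSchedule] = None,
           seed: Optional[int] = None, eta: float = 0.1, tol: float = 1e-4,
           max_iter: int = 200, masks=None,
           init_params: Optional[Sequence[SpatialParams]] = None,
           fixed: Sequence[str] = (), length: Optional[int] = None
           ) -> FitResult:
    """Fit the spatial parameters by multi-start annealed EM.

    ``init_params`` replaces the random starts (useful for warm-started
    nested-model refits); ``fixed`` names parameters pinned at their start
    values ("rho", "tau", "lam", "mu", "omega").
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("empty sequence set")
    if len(sequences) < TRAINING_MINIMUM:
        warnings.warn(
            f"training on {len(sequences)} promoters; at least "
            f"{TRAINING_MINIMUM} is recommended", stacklevel=2)
    schedule = schedule or AnnealSchedule()
    L = max(len(s) for s in sequences) if length is None else int(length)
    probe = SignatureModel(
        matrix=matrix, bg=bg, variant=variant, length=L,
        params=SpatialParams(rho=0.5, mu=L / 2, omega=L / 4, tau=0.5,
                             lam=1.0 / L, eta=eta))
    prep = PreparedSet(probe, sequences, masks=masks)
    if not np.any(np.isfinite(prep.logW[..., 0])):
        raise ValueError("no legal site placement in any sequence "
                         "(all masked?)")
    fixed = frozenset(fixed)
    free_spatial = tuple(f for f in ("lam", "mu", "omega") if f not in fixed)

    if init_params is not None:
        starts = list(init_params)
    else:
        root = np.random.default_rng(seed)
        starts = [_random_start(np.random.default_rng(root.integers(2**31)),
                                L, eta) for _ in range(n_starts)]

    results = []
    best = None
    for idx, start in enumerate(starts):
        rng = np.random.default_rng(
            np.random.SeedSequence((0 if seed is None else seed, idx)))
        res = _em_single(prep, start, schedule, rng, tol, max_iter, fixed,
                         free_spatial, L)
        results.append(res)
        if best is None or res[1] > best[1]:
            best = res + (idx,)
    params, loglik, trace, converged, idx = best
    return FitResult(params=params, loglik=loglik, trace=trace,
                     start_index=idx, converged=converged, variant=variant,
                     n_sequences=len(sequences),
                     starts=[(r[0], r[1]) for r in results])


def _em_single(prep: PreparedSet, params: SpatialParams,
               schedule: AnnealSchedule, rng, tol, max_iter, fixed,
               free_spatial, L):
    trace = []
    ll = prep.loglik(params)
    converged = False
    for _ in range(max_iter):
        trace.append(ll)
        _, e_r, post = prep.posteriors(params)
        kw = {}
        if "rho" not in fixed:
            kw["rho"] = float(np.clip(mstep_rho(e_r), 1e-6, 1 - 1e-6))
        if "tau" not in fixed:
            kw["tau"] = float(np.clip(mstep_tau(post), 1e-9, 1 - 1e-9))
        if kw:
            params = params.replace(**kw)
        if free_spatial:
            # best-visited includes the incumbent, so this never decreases
            # the marginal log-likelihood
            params, new_ll = anneal_spatial(
                prep.loglik, params, schedule, rng, free=free_spatial,
                mu_max=float(L), omega_max=float(L))
        else:
            new_ll = prep.loglik(params)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    trace.append(ll)
    return params, ll, trace, converged
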