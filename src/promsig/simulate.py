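"""Synthetic promoters, benchmarks, and promoter preparation.

Everything here is generated from the signature model itself, so every
downstream stage — fitting, controls, information, ranking — can be
exercised and calibrated without external data.  The benchmark generator
emulates the shape of a deletion-expression evaluation: promoters sampled
from the model, a per-ORF log fold-change concentrated on the truly
regulated promoters, and surrogate ChIP-style binding p-values that are
Beta-skewed small for regulated promoters and uniform otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import SignatureModel, sample_promoter
from .pwm import BackgroundModel, decode

MAX_PROMOTER_LENGTH = 1003

LengthSpec = Union[int, tuple, Callable]


@dataclass
class TrainingTruth:
    """Ground truth for a sampled training set."""

    regulated: np.ndarray          # (n,) bool
    sites: pd.DataFrame            # columns: promoter, start, strand

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class BenchmarkTruth:
    """Ground truth and surrogate measurements for a ranking benchmark."""

    regulated: np.ndarray          # (n,) bool
    sites: pd.DataFrame
    expression: pd.Series          # per-ORF log fold-change on deletion
    chip_pvalues: pd.DataFrame     # promoters x conditions
    effect: float
    noise_sd: float


def _draw_length(spec: LengthSpec, rng) -> int:
    if callable(spec):
        return int(spec(rng))
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def generate_training_set(model: SignatureModel, n: int,
                          length_distribution: LengthSpec = None,
                          seed=None):
    """Sample ``n`` promoters from the model with truth annotations.

    ``length_distribution`` may be a fixed int, a (lo, hi) tuple for a
    uniform draw, or a callable(rng) -> int; lengths are capped at 1,003 bp.
    Returns ({id: sequence}, TrainingTruth).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = model.length if length_distribution is None else length_distribution
    rng = np.random.default_rng(seed)
    promoters = {}
    regulated = np.zeros(n, dtype=bool)
    rows = []
    for j in range(n):
        L = _draw_length(spec, rng)
        if L > MAX_PROMOTER_LENGTH:
            raise ValueError(f"length {L} exceeds {MAX_PROMOTER_LENGTH} bp")
        if L < model.w:
            raise ValueError("length shorter than the motif")
        pid = f"prom{j:05d}"
        seq, sites = sample_promoter(model, rng, length=L)
        promoters[pid] = seq
        regulated[j] = bool(sites)
        for start, strand in sites:
            rows.append((pid, start, strand))
    sites = pd.DataFrame(rows, columns=["promoter", "start", "strand"])
    return promoters, TrainingTruth(regulated=regulated, sites=sites)


def generate_benchmark(model: SignatureModel, n_promoters: int,
                       effect: float = -2.0, noise_sd: float = 1.0,
                       seed=None, n_conditions: int = 3,
                       chip_beta=(0.5, 10.0),
                       length_distribution: LengthSpec = None):
    """Synthetic target-prediction benchmark.

    Promoters are sampled from the model (the regulated fraction follows
    the model's rho); each ORF's expression change is
    effect * regulated + Normal(0, noise_sd), and ChIP-style p-values are
    Beta(a, b)-distributed for regulated promoters and uniform otherwise.
    Returns ({id: sequence}, BenchmarkTruth).
    """
    promoters, truth = generate_training_set(
        model, n_promoters, length_distribution=length_distribution,
        seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    ids = list(promoters.keys())
    change = effect * truth.regulated + rng.normal(0.0, noise_sd,
                                                   size=n_promoters)
    expression = pd.Series(change, index=ids, name="change")
    a, b = chip_beta
    pvals = np.where(
        truth.regulated[:, None],
        rng.beta(a, b, size=(n_promoters, n_conditions)),
        rng.uniform(0.0, 1.0, size=(n_promoters, n_conditions)))
    chip = pd.DataFrame(pvals, index=ids,
                        columns=[f"cond{c + 1}" for c in range(n_conditions)])
    return promoters, BenchmarkTruth(
        regulated=truth.regulated, sites=truth.sites, expression=expression,
        chip_pvalues=chip, effect=effect, noise_sd=noise_sd)


@dataclass
class PreparedPromoter:
    seq: str
    fill: int             # number of masked fill bases at the 5' end

    @property
    def mask(self):
        """Masked fill as a list of half-open (start, end) intervals."""
        return [(0, self.fill)] if self.fill else []


def prepare_promoter(seq: str, max_len: int = MAX_PROMOTER_LENGTH,
                     gc: float = 0.38, seed=None,
                     rng: Optional[np.random.Generator] = None
                     ) -> PreparedPromoter:
    """Trim/pad a raw upstream sequence (TSS at the 3' end) to ``max_len``.

    Longer inputs are trimmed from the 5' end (the TSS-proximal bases are
    preserved); shorter inputs are padded at the 5' end with random
    GC-content fill that is flagged as masked, so no binding site may be
    placed within it.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) >= max_len:
        return PreparedPromoter(seq=seq[len(seq) - max_len:], fill=0)
    n_fill = max_len - len(seq)
    rng = rng or np.random.default_rng(seed)
    bg = BackgroundModel(gc=gc)
    fill = decode(rng.choice(4, size=n_fill, p=bg.probs))
    return PreparedPromoter(seq=fill + seq, fill=n_fill)
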