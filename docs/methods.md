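# Methods

## Model

A promoter of length L (5′→3′, TSS at the 3′ end, ≤ 1,003 bp) is modelled
by a hidden Markov lattice with four variable classes: a per-promoter
binary regulation variable R; per-position hidden site states S; observed
nucleotides N; and an observed consistency variable C. The S alphabet is
{b₀, b₁, bₓ} ∪ {matrix states}: b₀ is background before any site, b₁
background after at least one completed site, and bₓ the absorbing
background of the R=0 branch. Matrix states occur only as contiguous
width-w runs (one per site, forward or reverse orientation). C=1 —
always observed — holds iff the chain ends in b₁/end-of-matrix with R=1,
or in bₓ with R=0; it couples R to the actual presence of a site, which
lets ρ absorb false positives in a training set.

Coordinates: position p is the distance in bp from the TSS to the site's
TSS-proximal end (p = 0 is the base adjacent to the TSS). The transition
probability from background into a site at p is

    q(p, strand) = λ · σ(η(p − (μ − ω))) · σ(η((μ + ω) − p)) · s,

σ the logistic function, s = τ forward / (1 − τ) reverse. The product of
two logistic ramps yields a plateau of height ≈ λ between μ − ω and
μ + ω with soft edges of slope η; η is fixed at 0.1. A perfectly sharp
plateau is expressible but the soft edges make the likelihood surface far
easier to optimise. The total q over both strands is λ·plateau ≤ λ,
independent of τ; λ < 1 is enforced. Note the plateau attaches to the
site's *proximal end*; attaching it to the start or centre would shift
everything by at most w bp.

Structural rules: sites may not overlap and must complete within the
sequence; at positions where no site fits (the last w − 1 positions, or
anywhere a site would overlap masked fill or an ambiguous base) the
background transition takes probability 1. Masked bases emit background
and contribute equally to the model and background likelihoods, so they
are signature-neutral.

Variants: the default *multisite* model lets b₁ initiate further sites
(site count is plateau-thinned geometric/Poisson-like); the *monosite*
variant forbids it, emitting exactly one site per regulated promoter.

The emitted-sequence distribution of the model (used for sampling and for
information calculations) draws R ~ Bernoulli(ρ) and, when R=1,
conditions the emission walk on C=1 by rejection. Its density is
therefore (1−ρ)·BG(s) + ρ·P(s, C=1|R=1)/P(C=1|R=1), which sums to one
exactly; the likelihood used for fitting and ranking is the joint
P(N, C=1).

## Inference

Because matrix runs are deterministic once entered, forward/backward
message passing collapses to two log-mass tracks per position ("no site
completed yet" / "at least one"), giving O(L) updates per sequence
independent of w after a one-off O(Lw) scan that precomputes each
placement's emission log-ratio. All computation is in natural-log space
with hard log-sum-exp; terms more than 40 nats below the running maximum
are dropped, which is below double-precision resolution. The inner loops
are compiled with numba. Correctness is pinned to a brute-force
path-enumeration oracle (all site placements × strands × R) on instances
up to L = 30, w = 5, at 1e-9 relative log-likelihood error, and to exact
normalisation of the model over the full 4^L sequence space on enumerable
instances.

Per-promoter outputs: ln P(N, C=1); E[R | N, C=1]; the posterior
probability of a site starting at each position/strand (weighted by the
regulation posterior); and the expected site count (their sum, ≤ 1 for
the monosite variant by construction).

## Fitting

EM with exact E-steps. M-steps: ρ ← mean posterior E[R] and
τ ← forward share of posterior site-start mass are the exact analytic
maximisers of the expected complete-data log-likelihood (τ's background
factor λ·plateau does not involve τ, so the strand counts separate).
(λ, μ, ω) are updated jointly by Metropolis simulated annealing on the
*marginal* data log-likelihood with ρ, τ held at their refreshed values —
annealing the marginal rather than the ECDLL makes the ascent property
directly measurable on the reported quantity. The annealer returns the
best visited triple and always evaluates the incumbent first, so each EM
iteration is non-decreasing up to floating-point tolerance (asserted at
1e-6 nats in the tests). Annealing runs inside every EM iteration.

Defaults: 15 starts with μ ~ U[0, L], ω ~ U[25, L/2], λ ~ U[1/L, 20/L],
ρ = τ = 0.5; geometric cooling 0.9 from temperature 1.0 to 0.05 with 50
proposals per temperature; Gaussian proposals with scales (0.25·λ, 50 bp,
50 bp); convergence at |Δ log-lik| < 1e-4 or 200 iterations. The
simulation studies use a reduced schedule (temperature 0.8, cooling
0.6–0.65, 8 proposals per temperature, 2 starts, ≤ 20 iterations, tol
1e-3): the likelihood surfaces of the synthetic fixtures are smooth
enough that this recovers the generating parameters, and it keeps the
whole replicated battery within minutes on one CPU. Everything is
configurable per call. Bounds: λ ∈ (1e-9, 0.5), μ ∈ [0, L],
ω ∈ [1, L]; out-of-bounds proposals are rejected unevaluated. A
training-set minimum of 20 promoters is enforced as a warning, not an
error.

## Statistical controls

*Strand*: likelihood-ratio test against a null refit with τ pinned at ½
(df = 1, χ² tail). The null is warm-started from the full fit's
parameters; if the null's annealing nevertheless out-scores the full fit,
the full model is refit from the null's triple before the statistic is
formed, and the statistic is floored at 0.

*Spacing / length confound*: the training set is duplicated to a minimum
size (600 by default) and spatially scrambled by iterated segment swaps:
a random 5–75 bp segment whose two borders are not overlapped by any site
scoring ≥ 0 (log2) on either strand is exchanged with an equal-length,
equally border-clean segment of another sequence. Lengths and per-set
base counts are conserved exactly; segment-internal sites move intact
(new border junctions can occasionally create sites — inherent to the
procedure). Scores are re-scanned locally after each swap. The default
is 10⁶ iterations (10⁸, the exhaustive regime, is a flag away); the model is fit
to the scrambled set, and the original data refit with (μ, ω) pinned to
the scramble-derived values gives a df = 2 LRT. A second nested test
(`lrt_spacing_uniform`) pins the plateau to cover the whole promoter.
Calibration at desk scale (100 seeded replicates, 35–50 promoters of
150–300 bp): both tests hold their size at α = .05 (strand ≈ 3%, spacing
conservative near 0 because the null's (μ, ω) are estimated from data
equivalent under H₀) and reject planted effects (τ = .95, or a tight
plateau on variable-length promoters) in ≥ 95% of replicates.

*Density*: multisite vs monosite are non-nested, so the choice is by BIC
with 5 vs 4 effective parameters. The expected number of sites per
promoter under the multisite fit is reported alongside.

*Unbound screen*: 20 random sets (20 promoters each) are assembled from
regions unbound in every condition and each fit from 20 starts; the
signature is discarded if the median per-set maximum trained ρ exceeds
0.15, or any screen ρ exceeds the signature's own ρ. The screen-set size
of 20 matches the training minimum (the source procedure does not state
one).

## Information

Signature specificity is the KL divergence between the model's
promoter-sequence distribution and the iid GC background over the same
length, in nats (a bits conversion is provided). For L ≤ 10 it is
computed exactly by summing over all 4^L sequences; otherwise it is
estimated by sampling N promoters from the model and averaging
ln P_mod − ln P_bg (the 1/N estimator), with the Monte-Carlo standard
error reported (default N = 10,000). The estimator is validated against
the exact value on a 10-bp single-site fixture. The spacing-agnostic
baseline is a monosite model with ρ = 1, τ = ½ and a plateau spanning
the whole promoter; λ is set small (1/(2L)) so the geometric tilt toward
the 5′ end is negligible and the placement is near-uniform. The full
model's KL minus the baseline's isolates the spatial contribution.

## Target ranking and evaluation

Four rankers over a promoter set: (1) *signature* — posterior
E[R | sequence] with the prior fixed at ρ = ½ (the prior is a monotone
transform of the score, so the ranking is ρ-free; ordering is done on the
posterior log-odds to avoid saturation of the probability at 1);
(2) *thermodynamic* — each site contributes affinity e^score (natural
log), a promoter's score is its summed affinity over the set total Z
(scores sum to one: the probability a single protein molecule is bound in
that promoter); (3) *top site* — best single log-odds score; (4) *chip*
— smallest binding p-value across conditions (p < .05 is the bound-call
convention for ROC use). Ties are broken by promoter id.

Evaluation joins a ranking to per-ORF expression changes: the mean change
of the top K (default 50) is compared with the [2.5, 97.5] percentile
band of 5,000 random K-sets resampled from the expression table; the call
is significant if the mean falls outside. Widespread expression changes
can legitimately shift the null band off zero. Two methods are compared
by resampling the (promoter, expression) pairs 10,000 times and counting
replicates where |mean change of B's top-K| ≥ |A's|; per-factor wins
aggregate across a panel with an exact one-sided binomial test at
p = ½. Magnitudes are |mean(change)| — the absolute value of the signed
mean, not the mean of absolute values. A flag excludes training ORFs
from the evaluation.

## Synthetic data

The generator is the model itself: training sets sample promoters (with
per-promoter truth annotations) at fixed or drawn lengths; the ranking
benchmark adds per-ORF expression changes effect·regulated + N(0, σ)
(defaults: effect −2, σ = 1, matching a clear deletion phenotype against
array noise) and surrogate ChIP p-values — Beta(0.5, 10) for regulated
promoters (small, right-skewed), uniform otherwise, over 3 conditions.
`prepare_promoter` reproduces the preprocessing contract: trim to
1,003 bp from the 5′ end, pad short sequences at the 5′ end with random
38%-GC fill recorded in a sidecar BED of masked intervals (FASTA stays
standard; sites may not be placed in fill).

What the generator does *not* emulate: nucleosome structure,
conservation, condition structure of real binding data, divergent
promoters, correlated indirect expression effects. Passing the benchmark
therefore demonstrates the machinery end to end under the model's own
assumptions — it does not certify performance on real genomes.

## Study conditions

The validation battery (`promsig.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 200 random
oracle instances; KL validation at N = 10,000 on the 10-bp fixture;
recovery of (ρ=.6, μ=250, ω=120, τ=.8, λ=.008) from 20 replicates of 200
promoters × 1,003 bp with a strong non-palindromic 8-bp motif (median
absolute errors |ρ̂−ρ| ≤ .1, |μ̂−μ| ≤ 50 bp, |τ̂−τ| ≤ .1); control
calibration with 100 replicates per condition as above; scrambler
diagnostics at 10⁶ iterations on 300 sequences; and the expression
benchmark at n = 500, ρ = .1, effect −2, noise 1, K = 50, 5,000
resamples. These sizes are the package's desk-scale defaults; every
function accepts larger values.

## Known limitations

* Position-independent emissions within sites; no inter-site spacing or
  pairing constraints; a single signature per factor (no
  condition-specific mixtures).
* The iid GC background is deliberately simple; the unbound screen exists
  precisely to catch signatures that exploit its flaws.
* The annealed M-step is stochastic: the fitted (λ, μ, ω) carry
  seed-dependent jitter on the order of the proposal scales near
  convergence, and monotonicity holds only up to the stated tolerance.
* The monosite baseline's "uniform" placement has a ≤ λL geometric tilt.
* The scrambler preserves the border-site multiset but can create new
  sites at swap junctions; at the default segment lengths this is a
  percent-level effect on site counts.
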