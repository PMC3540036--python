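# promsig — spatial promoter-recognition signatures

Transcription factors bind short, degenerate sites, and in eukaryotes a
single site rarely carries enough information to pick a factor's true
target promoters out of the genome. `promsig` models the *promoter
recognition signature* — the factor-specific joint pattern of binding-site
**location**, **strand orientation**, and **density** within a promoter —
as a generative probabilistic sequence model, and asks how much
discriminatory information that spatial structure adds beyond the sites
themselves.

## The model

Promoters are stored 5′→3′ with the transcription start site (TSS) at the
3′ end. For each promoter a hidden Markov lattice is arranged as follows:

* a binary regulation variable R, with prior P(R=1) = ρ, says whether the
  promoter carries the factor's signature;
* given R=1, the hidden chain emits background bases or complete
  binding-site blocks drawn from a frequency matrix (either orientation);
  the probability of starting a site whose TSS-proximal end lies *p* bp
  upstream of the TSS is

  ```
  q(p, strand) = λ · σ(η(p − (μ − ω))) · σ(η((μ + ω) − p)) · s
  ```

  with σ the logistic function and s = τ (forward) or 1 − τ (reverse): an
  approximately plateau-shaped site distribution of height λ centred at μ
  with half-width ω and edge slope η (fixed at 0.1);
* given R=0 the chain emits pure GC-content background (38% GC default);
* an observed consistency variable C=1 forces R=1 promoters to contain at
  least one complete site. A *monosite* variant emits exactly one site;
  the default *multisite* variant any positive number.

The five parameters (ρ, μ, ω, τ, λ) are trained by EM: exact posteriors by
message passing in log space, closed-form M-steps for ρ and τ, and
simulated annealing for (λ, μ, ω), from multiple random starts. Model
checks include a strand likelihood-ratio test (τ = ½ null), a
segment-swap scrambling control that asks whether promoter lengths alone
explain an apparent spatial restriction, a BIC choice between the
multisite and monosite variants, and a screen that refits the model on
unbound regions and discards signatures trainable there.

Signature specificity is measured as the Kullback–Leibler divergence
between the model's promoter-sequence distribution and the background,
estimated by sampling (validated against exact enumeration on short
models). For target prediction the package ranks promoters by the
posterior E[R | sequence] and compares against three spatially naive
references: the best single site score, a thermodynamic occupancy model
(Boltzmann-weighted affinity share), and experimental binding p-values.

## Worked example

`examples/02_simulate_and_fit.py` samples 150 promoters from a known
signature (ρ=.7, μ=150, ω=80, τ=.85, λ=.012, 8-bp motif) and refits it:

```
sampled 150 promoters, 104 regulated, 225 planted sites
           truth   fitted
rho        0.700    0.666
mu       150.000  146.815
omega     80.000   79.334
tau        0.850    0.828
lam        0.012    0.017
log-likelihood -121757.9 after 8 EM iterations (start 1)
```

Each row compares a generating parameter with its maximum-likelihood
estimate: the plateau centre μ is recovered to ~3 bp and the
signature-carrying fraction ρ and strand bias τ to a few percent.
`examples/03_information.py` shows the specificity decomposition for a
6-bp motif: the single-site baseline carries 0.27 nats at promoter scale
while the full multisite signature carries 2.68 nats — a spatial
information gain of 2.4 nats from placement, orientation, and density.
The other examples cover scanning, the statistical controls (strand LRT,
scramble spacing control, unbound-region screen), and the four-way
target-ranking comparison.

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
promsig simulate --model model.yaml --n 200 --seed 1 --out sim/
promsig fit --fasta sim/promoters.fasta --matrix matrix.txt --out fit/
promsig info --model fit/model.yaml --out info.tsv
promsig rank --fasta sim/promoters.fasta --model fit/model.yaml \
        --method signature --out ranks.tsv
promsig evaluate --ranking ranks.tsv --expression sim/expression.tsv \
        --out eval.tsv
```

All runs are deterministic given `--seed` and write an effective-config
YAML next to their outputs.

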