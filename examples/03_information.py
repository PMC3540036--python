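"""How much specificity does spatial structure add?

Compares the Kullback-Leibler specificity of a full multisite signature
with the single-site, spacing-agnostic baseline built from the same motif:
the difference is the information carried by location, strand, and density.
"""

from promsig import (BackgroundModel, SignatureModel, SpatialParams,
                     motif_information, sampled_kl, single_site_baseline)
from promsig import consensus_matrix

bg = BackgroundModel(gc=0.38)
matrix = consensus_matrix("ACGTTG", 0.8)
LENGTH = 300

full = SignatureModel(
    matrix=matrix, bg=bg, length=LENGTH,
    params=SpatialParams(rho=1.0, mu=120, omega=60, tau=0.8, lam=0.03))
baseline = single_site_baseline(matrix, bg, LENGTH)

est_full = sampled_kl(full, n_samples=3000, seed=1)
est_base = sampled_kl(baseline, n_samples=3000, seed=2)

print(f"motif information          {motif_information(matrix, bg):6.2f} nats")
print(f"single-site baseline KL    {est_base.nats:6.2f} +- {est_base.se:.2f}")
print(f"full signature KL          {est_full.nats:6.2f} +- {est_full.se:.2f}")
print(f"spatial information gain   {est_full.nats - est_base.nats:6.2f}")
# The baseline's KL is the binding-site information at promoter scale; the
# gain shows how placement, orientation and (mostly) multiple sites let a
# weakly specified motif define a much more specific promoter signature.
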