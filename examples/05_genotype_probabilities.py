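"""Bayesian genotype probabilities from the Gibbs admixture sampler.

Rather than hard-calling genotypes, each (individual, SNP) cell gets a
posterior distribution over dosage 0/1/2 that combines its read data with an
admixture-structured population prior (k = 2, two chains, Gelman-Rubin
convergence screen).
"""

import numpy as np

import gbsconcord as gc

rng = np.random.default_rng(0)
n, s = 14, 200
freqs = rng.uniform(0.1, 0.5, s)
dosage = rng.binomial(2, freqs, (n, s))

# read counts at depth ~8 with 1% base error, converted to log-likelihoods
depth = rng.poisson(8, (n, s))
alt = rng.binomial(depth, dosage / 2 * 0.99 + (1 - dosage / 2) * 0.01)
gl = np.transpose(gc.genotype_likelihood(depth - alt, alt, 0.01), (1, 0, 2))

gp = gc.genotype_probabilities(
    gl, gc.MCMCConfig(k=2, iterations=2000, burn_in=400, thin=10, chains=2, seed=1),
    override=True,
)
acc = (gp.probs.argmax(axis=2) == dosage).mean()
print(f"max R-hat over monitored p and q parameters: {gp.rhat_max:.3f}")
print(f"posterior-mode genotype accuracy vs truth: {acc:.1%}")
missing = depth == 0
print(f"mean posterior dosage at the {missing.sum()} zero-depth cells: "
      f"{gp.mean_dosage[missing].mean():.2f} "
      f"(shrinks to the Hardy-Weinberg prior mean {2 * freqs.mean():.2f}, "
      f"not to a confident genotype)")
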