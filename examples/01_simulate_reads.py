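"""Simulate a two-arm GBS replicate study with known ground truth.

Fourteen diploid individuals are genotyped once, then "sequenced" twice:
under a tissue-biopsy-like profile (many reads, broad locus capture) and a
visceral-swab-like profile (fewer reads, narrow capture, deeper per locus).
"""

import numpy as np

import gbsconcord as gc

cfg = gc.SimConfig(n_individuals=14, n_loci=400, seed=1)
truth = gc.simulate_truth(cfg)
dosage, sites = truth.dosage_matrix()
print(f"{truth.n_loci} loci of 84-86 bp, {dosage.shape[1]} variant sites, "
      f"{truth.n_individuals} individuals at two collection sites")

for label in ("tissue", "swab"):
    pool = gc.simulate_method_reads(truth, cfg.profiles[label], seed=7, arm=label)
    reads = np.array(list(pool.per_individual_reads.values()))
    print(f"{label:>6}: {pool.n_reads:>7} reads total "
          f"({reads.mean():,.0f} +/- {reads.std():,.0f} per individual), "
          f"{pool.capturable_loci.mean():.0%} of loci capturable")

# The per-individual read yields mirror field-scale mean +/- SD profiles
# (scaled down 100x); the breadth contrast (90% vs 15% of loci) is what later
# drives the many-shallow-SNPs vs few-deep-SNPs difference between methods.
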