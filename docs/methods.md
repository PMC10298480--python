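# Methods

This note documents the models, parameter choices, and numerical decisions
behind `gbsconcord`, and is explicit about what the synthetic data generator
does and does not emulate — hence what passing tests do and do not show about
real data.

## The synthetic study

The generator emulates a two-arm technical-replicate design: the same 14
diploid individuals are "sequenced" twice under two method profiles.
Defaults (all overridable through `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 14 | study individuals, labelled across 2 collection sites |
| `n_loci` | 2,000 | independent GBS loci |
| `locus_length_range` | 84–86 bp | post-trim read length of a double-digest library |
| `fragment_size_range` | 300–400 bp | carried as metadata only |
| `n_variable_sites_per_locus` | 2 | biallelic candidate SNPs per locus |
| `maf_range` | [0.05, 0.5] | true alternative-allele frequency, uniform |
| `base_error_rate` | 0.005 | per-base substitution probability |
| `barcode_length_range` | 10–14 bp | MID barcodes, drawn mutually prefix-free |
| `site_divergence` | 0 | allele-frequency divergence between collection sites |

Method profiles are (mean, SD) of per-individual read totals plus a capture
breadth and a depth-overdispersion parameter:

* tissue-like — 16,089 ± 3,071 reads, breadth 0.90;
* swab-like — 5,190 ± 2,381 reads, breadth 0.15;
* control — tissue-like yield at breadth 0.98 (for the shared-reference design).

The yield profiles are per-individual means/SDs representative of reported
tissue-vs-swab GBS yields, scaled by 1/100 so a full two-arm study runs in
about a minute and a half on one CPU; the 3.1× yield ratio and the
breadth/depth contrast are preserved. Read totals are normal draws truncated
at zero (so printed mean ± SD profiles are directly representable, unlike a
Poisson). The capturable locus subset is drawn *once per arm* and shared by
all individuals — capture is treated as a property of the fragment and the
library chemistry, not of the animal — and each individual's reads are
allocated over capturable loci by a Dirichlet(α)-multinomial with
α = `depth_overdispersion` (default 10); smaller α trades breadth for depth.
Genotypes are Hardy–Weinberg: each of the two haplotypes draws its allele
independently at the locus frequency, and both arms of the same individual
share the resulting genotypes exactly. Base qualities come from a
two-component model — correct bases ~ N(38, 2), error bases ~ N(15, 3),
clipped to [2, 40] — which is what gives the allele-quality rank filter
signal to act on.

**What is deliberately not emulated:** restriction-site sequence content,
PCR duplicates, indels, paired ends, contaminant reads (the screen is
exercised on planted fixtures), and — most consequentially — any
inter-individual structure: no relatedness, no inbreeding variance, no
allele-frequency divergence between collection sites (a `site_divergence`
knob exists but defaults to 0).

### Consequence: ordination concordance under the null

With independent Hardy–Weinberg genotypes the expected covariance between
individuals is zero, so the 14×14 centered Gram matrix any PCA works from is
*pure locus-sampling noise*; its leading eigenvectors are not estimating any
underlying structure. Two arms' noise matrices correlate only through the
overlap of their marker sets — approximately `o/√(L_A·L_B)` ≈
270/√(1800·300) ≈ 0.37 at the default breadths — which caps the symmetric
Procrustes R between the arms' 2-axis ordinations near 0.3–0.7 (the
acceptance run reports the measured median, ~0.3). High replicate
concordance (R > 0.95) is therefore a property of *structured* samples:
real populations carry realized relatedness and inbreeding variation that
both marker subsets estimate consistently. Passing the directional tests
(subsample ordinations more concordant than independent-genotype negative
controls; tissue ≫ swab SNP counts; swab > tissue per-SNP depth) shows the
pipeline is correct; it does not show that an unstructured simulation can
reproduce the high R values that structured real data can reach.

## Pipeline models and numerical choices

**Identity comparator.** All sequence comparison (clustering, mapping,
contaminant screen) is best-ungapped-offset identity: the shorter sequence
slides fully inside the longer, identity = matches / max(length). Reads are
84–86 bp near-identical stacks, so gapped alignment would add cost without
information. Clustering order is (abundance desc, length desc, lexicographic
asc); a sequence joins the *first-founded* representative at ≥ 80% identity,
which makes clustering deterministic and guarantees representatives are
pairwise below threshold.

**Retention rule.** Unique reads are retained iff total copies ≥ 4 AND
shared individuals ≥ 4 (the conjunctive ≥ reading of the conventional
"fewer than four" removal rule; the boundary is tested explicitly).

**Mapper.** Best-identity contig at best ungapped offset, minimum identity
0.9; ties between contigs leave the read unmapped. The mapping-quality
surrogate is `round(−10·log10 p_err)` with `p_err = 1/(1 + 10^Δ)`, Δ the
match-count gap to the second-best contig, capped at 60. For large problems
a shared-k-mer (k = 16) shortlist stands in for the full scan — the standard
seeded-alignment heuristic; `method="full"` forces the exact scan.

**Genotype likelihoods.** Single symmetric error rate ε = 0.01 (configurable)
for all reads; per-base qualities are carried for the filters but do not
weight the likelihood. Candidate sites are pileup columns with ≥ 2 alleles
each seen ≥ 2 times pooled; a third allele at that count flags the site
non-biallelic. The pooled major allele is the reference (ties break to the
lexicographically smaller base); coordinates are 0-based internally,
1-based in VCF.

**Allele frequencies.** EM under Hardy–Weinberg on genotype posteriors,
convergence |Δf| < 1e-8 or 200 iterations; all-flat input returns 0.5 with a
no-data flag. Agreement with a dense grid-search oracle is tested to 1e-4.

**Filter cascade.** Fixed order: biallelic, presence (ceil(0.8·n)
individuals with data — ceiling because "at least 80%"), depth floor
(summed site depth ≥ 2n, inclusive), paralog depth (site mean depth >
assembly-wide mean + 2 SD of per-site means, computed once before removal),
site MQ ≥ 30 (kept at exactly 30), Mann–Whitney |z| > 1.96 on pooled ref- vs
alt-allele base and mapping qualities (strict inequality, midrank ties,
tie-corrected variance `n₁n₂/12·((n+1) − Σ(t³−t)/(n(n−1))`, no continuity
correction by default), MAF ≥ 0.05 (kept at exactly 0.05), then one uniform
random SNP per contig. The thinning RNG hashes (seed, contig id) so
survivorship is stable under site reordering. The ledger enforces
`sites_in = sites_removed + sites_out` at every stage.

**Admixture sampler.** The full conditionals are conjugate: genotype dosage
given (q, p) and the likelihood; per-copy ancestries given dosage; Beta
updates for p; Dirichlet updates for q. Genotype probabilities are
Rao-Blackwellised (per-sweep conditional posteriors averaged, not sampled
indicators). No hyper-priors on the Dirichlet/Beta parameters — this is a
deliberate simplification relative to fuller hierarchical samplers, and
equivalence with any published implementation is not claimed. The default
preset is desk-scale (5,000 iterations, burn-in 500, thin 10, k = 2, two
chains); `MCMCConfig.preset("field")` selects the full-length field protocol
(50,000 / 5,000 / 10). Monitored parameters for the Gelman–Rubin screen are
all `p_kl` and `q_ik` after aligning population labels across chains (labels
are matched by allele-frequency vectors; genotype probabilities are
label-invariant, so averaging them is always safe). The pipeline defaults to
warn-and-proceed on an R-hat above 1.2 (`rhat_strict=False`) because with
k = 2 on unstructured data the population split is weakly identified and
occasional slow-mixing q coordinates are expected; the strict mode raises
`ConvergenceError` listing the offending parameters.

**Ordination and concordance.** PCA on posterior mean dosage,
column-centered, unscaled (no variance standardization — dosages share a
scale), scores from the SVD. Procrustes is the symmetric variant (both
configurations scaled to unit sum of squares; reflections allowed), with
`R = √(1 − m²)` by construction and an optional seeded permutation test.
Two axes by default, matching how such ordinations are plotted and compared;
configurable. The paired t-test handles the all-zero-difference case as
t = 0, p = 1 (flagged degenerate) and flags zero-variance non-zero
differences as undefined. ANCOVA is OLS on [intercept, covariate, two-level
group indicator] with residual df = n − 3.

## Problem sizes

The acceptance computation runs three seeded replicates of the default
conditions (14 individuals × 2,000 loci, both arms, own-reference design)
and reports the median Procrustes R; the test suite exercises the same
stages at 6–14 individuals and 50–2,000 loci. These sizes were chosen so a
laptop reproduces everything in minutes while every stage still has
non-trivial work (thousands of unique reads, hundreds to thousands of
candidate sites).

## Known limitations

* The mapper and contaminant screen are heuristic, ungapped stand-ins for
  full aligners; they are exact on the scales tested (and `method="full"`
  is exact by construction) but are not substitutes for BWA/Bowtie on real
  data with indels or repeats.
* The genotype-likelihood model ignores per-base quality and mapping
  uncertainty beyond the site-level filters.
* k is fixed in the admixture model; no model choice (DIC/WAIC) is offered.
* The unstructured default simulation cannot — by design, see above — show
  high absolute ordination concordance between arms; it validates pipeline
  correctness and the direction of method contrasts, not the absolute R of
  structured real datasets.
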