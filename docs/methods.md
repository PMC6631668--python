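# Methods

This note documents the models, conventions and deliberate design
choices behind `radpanel`, in the spirit of a statistical-software
methods appendix.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A genotype call is an **unordered pair of allele identifiers** or a
missing sentinel; the same container serves biallelic SNPs,
multiallelic microsatellites (fragment sizes as string alleles) and
haploid mitochondrial markers.  Mitochondrial calls are stored as
homozygous pairs so every downstream routine sees one call shape, but
frequency and copy counting treat them as **one gene copy per
individual**.  Within-tag SNP offsets are 0-based; linkage positions
are cM reals.  Missing values are `"./."` in VCF and a configurable
sentinel (default `"NA"`) in delimited tables.

## Filtering conventions

* **MAF**: min(p, 1−p) over non-missing gene copies of all individuals
  pooled across lineages.  The retention rule is boundary-inclusive,
  MAF ≥ threshold (default 0.05).  Monomorphic and all-missing loci are
  always removed at any positive threshold.
* **Edge windows**: "first or last 30 bp" is read as offsets
  {0..29} and {len−30..len−1}; offset 30 itself passes.  The same
  convention applies to the 50 bp primer zones, and the assay filter
  additionally requires **exactly one** SNP per tag.
* **Cascade order**: the frequency cut runs before the sequence checks,
  and per-tag SNP counts are taken after low-MAF SNPs are pruned —
  mirroring a pipeline where a VCF-level frequency filter feeds a
  tag-level cleanliness pass.  On inputs where frequency and sequence
  violations hit disjoint tags the order provably cannot matter, and a
  test pins that commutativity.

## Panel selection

"Evenly spread with a minimum spacing" is implemented as a
**deterministic greedy left-to-right scan** per linkage group: keep the
first position-sorted candidate, then every candidate at least
`min_spacing_cM` (default 3.5) beyond the last kept one.  Greedy
attains the spacing constraint, never skips a feasible marker, and is
reproducible; optimal (max-count or min-gap-variance) placement is a
non-goal.  Co-located candidates — common on dense linkage maps — are
ordered by decreasing MAF then id, so the more informative marker wins
the slot deterministically.  Down-sampling to a plate size is a seeded
uniform draw without replacement; because removing markers only widens
gaps, the spacing guarantee survives any subsetting.  Failed-assay
replacement prefers a reserve on the same linkage group nearest in cM
(an invented but natural policy); any spacing violation a replacement
introduces is recorded in provenance rather than silently dropped.
The coarse density figure is total map length divided by the mapped
marker count (cM per marker).

## Statistical conventions

* He = 1 − Σ pⱼ² from sample frequencies; Ho = fraction of non-missing
  diploid calls that are heterozygous; Fis = 1 − Ho/He (NaN when
  He = 0).  Site-level summaries are **means of per-locus values over
  polymorphic loci**; the site-uniqueness Fst column is
  1 − He_site/He_total with both terms multilocus means (ratio of
  means), He_total from all individuals pooled.
* Pairwise Fst = (H_T − H̄_S)/H_T with H̄_S the gene-copy-weighted mean
  within-population diversity and H_T the pooled-pair diversity, summed
  over loci before the ratio (ratio of sums).  Slightly negative
  sampling estimates are returned as computed; only the symmetric
  matrix container clips at zero to satisfy the distance contract.
* Allelic richness: Ar(n) = Σⱼ [1 − C(N−cⱼ, n)/C(N, n)], the expected
  allele count in a hypergeometric subsample of n gene copies, averaged
  over loci; n defaults to the smallest copy count in the comparison
  set.
* Outlier scan: per-locus global (all-population) Nei Fst against total
  He; loci are split into equal-count He bins (default 10), empirical
  (1−γ)/2 and 1−(1−γ)/2 Fst quantiles (γ = 0.95) are interpolated
  linearly across bin midpoints, and loci outside the envelope are
  flagged.  The cited field method's exact smoother is unspecified, so
  the envelope construction is a documented choice.  Flagged loci are
  retained downstream by default — removing them is the user's call.
* Informativeness for assignment uses the **natural logarithm**, so a
  locus fixed for opposite alleles in two populations scores ln 2, the
  standard closed form for this statistic.  Multi-locus Iₙ is the sum
  over loci, which is what makes the informativeness-vs-panel-size
  relation near-linear and the marker-equivalence extrapolation
  (⌈(target − b)/a⌉ from the fitted I = a·N + b) meaningful.  Note
  (2.48 − 0.0038)/0.023 ≈ 107.66: the ceiling convention reports 108,
  the value a "smallest sufficient panel" reading implies; the floor
  (107) appears when the quotient is rounded down.
* Mantel test: Pearson r of the off-diagonal vectors, one-tailed
  permutation p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), permuting the
  site labels of one matrix; fully seeded.  Because the permutation
  sample is random, p is invariant to joint site relabeling only up to
  Monte-Carlo resolution.

## Supervised admixture estimator

The Bayesian MCMC clustering program used in the field (with its
burn-in/run-compilation protocol) is **not** reimplemented.  In its
place stands an explicitly labelled supervised maximum-likelihood
hybrid index: with reference allele frequencies f_captive and f_wild,
an individual's ancestry q maximises
Σ_loci log Binom(g | 2, q·f_captive + (1−q)·f_wild) over a dense
deterministic grid (1001 points, 10⁻³ resolution; no refinement step is
needed at that resolution).  Reference frequencies are floored at
1/(2n+1) — the standard pseudo-count for n reference individuals — so
alleles unseen in one reference cannot produce infinite log-likelihoods.
Classification follows the strict rule: captive-bred iff
q > 0.7, wild iff 1−q > 0.7, otherwise admixed; q = 0.7 exactly is
admixed.  The substitution is recorded in the result's metadata.

## Synthetic-data generators

The generators emulate a two-lineage salmonid setting: a 1453 cM map in
40 linkage groups (Dirichlet-proportional group lengths, concentration
5), 230 bp RAD tags (two 125 bp reads minus overlap; configurable) with
planted, labelled filter violations, and genotypes under a
Balding–Nichols divergence model (ancestral frequency ~ U(0.05, 0.95),
per-deme frequency Beta-distributed with variance c·p(1−p), genotypes
Binomial(2, f)).

**Calibration of `divergence_F`.**  Two demes drawn independently with
per-deme coefficient c show expected pairwise Nei Fst of
(c/2)/(1 − c/2), not c.  The generators therefore draw with
c = 2F/(1+F), which makes `divergence_F` equal the expected **pairwise**
Fst between two demes — the quantity the estimator it exercises
actually measures.  At F = 0.10 this was verified by simulation
(literal parameterization recovers ≈ 0.055; calibrated ≈ 0.101).

**IBD river networks** place sites uniformly on a 15 km line with
pairwise Fst = 0.01 + 2·10⁻⁶·d + ε, ε ~ N(0, 0.008) symmetrised and
clipped at zero.  These defaults came from an a-priori power analysis:
they give mean Mantel r ≈ 0.75 and essentially full one-tailed
detection power at 8 sites, emulating the clearly detectable IBD
patterns reported from field rivers (r ≈ 0.55–0.65) rather than a
borderline case.

**What the simulations do not emulate**: linkage between loci (loci are
exchangeable and independent), genotyping error, allele dropout or
locus-specific missingness, microsatellite mutation models (stepwise
sizes are cosmetic), and real riverscape topology (sites sit on a
line).  Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not robustness to those
real-data features.

## Problem sizes and determinism

Every generator and every stochastic routine is a pure function of
(parameters, seed); regenerated fixtures are byte-identical.  The test
and acceptance workloads use study-scale sizes chosen to make each
check statistically meaningful at interactive runtimes: 1000 tags for
filter truth-label checks, 1000 random candidate maps for the spacing
guarantee, 20 Balding–Nichols replicates of 50 loci × 100
individuals/deme for Fst recovery, a 90-locus diagnostic panel for
admixture recovery, and 50 river networks × 199 permutations for IBD
power.

## Known limitations

* The greedy selector maximises neither marker count nor spacing
  evenness; on adversarial candidate layouts an optimal selector could
  keep more markers.
* Pairwise Nei Fst (ratio of sums) is a plug-in estimator without the
  small-sample bias correction of variance-component estimators; the
  synthetic calibration accounts for its expectation, real-data values
  inherit its known downward bias at small divergence.
* The hybrid-index estimator assumes known (well-estimated) reference
  frequencies and independent loci; strong drift since reference
  sampling, or linked diagnostic markers, will overstate its
  confidence.
* `read_genotype_table` handles generic wide tables, not proprietary
  genotyping-service report layouts.
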