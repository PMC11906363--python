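# Methods

This note documents the models implemented in `secondhit`, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical choices that matter.

## The inference problem

A person with a heterozygous germline mutation in a recessive
cancer-predisposition gene (modeled on *NF1*, an 8.5 kb coding footprint on
17q) loses gene function in a cell only when the second, wild-type allele
is also inactivated. Such "second hits" — truncating point mutations, or
LOH by copy-neutral exchange or deletion — can found small clones in
histologically normal tissue. Detecting them requires (i) ruling out that
apparent signal is infiltrating tumor, (ii) squeezing sub-percent allelic
imbalance out of aggregate SNP counts, (iii) distinguishing real low-VAF
point mutations from sequencing error, and (iv) asking whether the
phenomenon reflects selection rather than chance.

## Tumor contamination from truncal mutations

Mutations on the trunk of the tumor phylogeny are present in every tumor
cell. Assuming they are diploid-heterozygous in the tumor, a sample with
tumor fraction *t* has expected truncal VAF *t*/2, so the estimator is
`purity = min(1, 2·Σalt/Σdepth)` pooled over truncal sites, with a
Clopper–Pearson binomial CI mapped through the same ×2 transform.

Pooling (rather than per-site summaries) is essential at contamination
below 1%, where most sites have zero alternate reads. Truncal sites inside
tumor LOH segments are hemizygous and would break the ×2 map; the
estimator expects diploid-het truncal sites (the simulator places the
trunk off chromosome 17 for this reason), and copy-number-aware purity
deconvolution is out of scope.

## Haplotype phasing and the LOH test

A tumor with complete chromosome-17 LOH retains exactly one parental
haplotype — the one carrying the germline hit. Each heterozygous SNP is
phased by which allele has the larger VAF in a near-pure tumor sample
(default minimum tumor depth 10×; exactly tied VAFs are dropped and
logged, since an ambiguous SNP only adds noise). With a 95%-pure tumor at
40× this assigns >99% of SNPs correctly; phasing errors are symmetric
noise that dilutes, but does not bias, the downstream test.

In every other sample, using only phased SNPs with ≥10× local coverage:

* trials = Σ depth, successes = Σ retained-allele depth,
* null success probability `p0 = purity + (1−purity)·0.5` (the tumor locus
  is 2+0; normal cells contribute each parental allele equally; p0 is 0.5
  exactly at purity 0 and 1.0 at purity 1),
* two-sided exact binomial p-value; BH correction across all samples
  tested in a run (one family per phased panel per run);
* flagged only if q < 0.01 AND median site coverage ≥ 30× AND purity < 1%,
  so that imbalance cannot be explained by tumor infiltration.

Direction is `wt_loss` when the retained (mutant-haplotype) fraction
exceeds p0, `mutant_loss` otherwise — the latter is a real phenomenon
(clones that discard the germline-mutant allele) and is reported, not
suppressed. Because the mechanism behind an imbalance is not identifiable
from aggregate counts alone, clone size is reported under both models,
writing a = successes/trials (deviation side max(a, 1−a)): copy-neutral
LOH gives cell fraction `2a−1`; one-copy deletion gives `(2a−1)/a`. The
raw a is used (no purity re-adjustment) since flagged samples are gated to
purity < 1%, where the adjustment is below the estimate's noise.

## Error-aware presence genotyping

For a known candidate mutation, the locus-specific error background is the
pooled (alt, depth) of control samples that cannot carry it. Presence in a
sample is a one-sided (enrichment) Fisher exact test of the sample's
counts against the pool — computed as the hypergeometric upper tail, which
is vectorized and exactly equals `scipy.stats.fisher_exact(...,
"greater")`. BH runs over all (mutation × sample) pairs tested in one call
(a global family: more conservative than per-mutation families and simpler
to audit); presence requires q < 0.01. Zero-depth pairs are reported
untested rather than absent. No minimum alt-read floor is applied by
default — the error model is the floor — but the leave-one-out
("Shearwater-like") configuration used for sharing analyses adds a ≥2
alt-read floor, because there each sample is tested against all others and
single stray reads at fragile sites are common. The full beta-binomial
site-specific dispersion model of Shearwater is not implemented; this
caller keeps the same contract (per-site error-aware presence decisions)
with a simpler error model.

## Shared-ancestry permutation test

Two tissues share a somatic substitution either by descent from a common
ancestral cell or by independent recurrence. The statistic is the mean
pairwise shared-substitution count over the pairs of tissues carrying the
same second hit, where "shared" means called present in both samples by
the presence caller. Under the null, equally many pair counts are drawn
without replacement from a control pool (pairs of low-contamination,
no-second-hit normal tissues; comparisons should be stratified by germ
layer, and pairs from the same original biopsy excluded). P = fraction of
1,000 draws whose mean is *strictly* greater than the test mean — ties
count as non-exceedances, and no small-sample (+1) correction is applied;
a zero exceedance count is displayed as "<0.001" and stored as 0.0. The
sampled test agrees with exhaustive enumeration wherever enumeration is
feasible, and the strictly-greater rule makes P mildly conservative when
sharing counts are heavily tied (it is calibrated for genome-scale
counts, where ties among means are rare).

## Single-gene dN/dS

All 3L single-base substitutions of the L-base coding sequence are
enumerated and classified by codon translation (standard genetic code;
stop-gain = nonsense; stop-loss is counted as protein-altering,
non-truncating). Configured essential splice-site positions (donor and
acceptor ±2 of each internal intron boundary) are classified truncating.
Neutral class proportions (e_syn, e_mis, e_trunc) weight each possible
substitution by a trinucleotide-context × alternate-base spectrum; the
default spectrum is uniform over the 192 classes because a fitted
context spectrum is dataset-specific (a measured spectrum can be
supplied). Context at the first/last CDS base and at splice rows is
undefined within the CDS and falls back to the mean spectrum rate — exact
under the uniform default, a ≤2-row approximation otherwise.

With observed counts n ~ Poisson(λ·e_class·ω_class), ω_syn ≡ 1 and λ
profiled out, the MLE is the intuitive ratio
`ω_c = (n_c/e_c)/(n_syn/e_syn)` and the 95% interval comes from
profile-likelihood inversion at the χ²₁ 0.95 quantile (bracket expansion
plus Brent root-finding on log ω). ω_trunc and ω_mis separate cleanly
because the likelihood factorizes given λ. n_syn = 0 yields ω = +∞ with a
finite, reported lower bound; `positive_selection` is true exactly when
the truncating lower bound exceeds 1. Neutral simulations at n = 50
observed mutations give ~95% CI coverage of ω = 1, and a 10-fold
truncating excess is detected in >90% of simulations at n ≥ 30. No
genome-wide covariate model and no indel-rate model are included: this is
deliberately the one-gene core of the dN/dS machinery.

## Duplex consensus calling

Bundles arrive grouped by molecule with strand labels. Within a strand,
consensus is a simple majority of that strand's reads, ties yielding no
consensus — the simplest rule faithful to the two-strand principle; no
end-trimming or other read-level filters are applied (bundles are assumed
pre-filtered). A call requires ≥1 molecule with variant consensus on both
strands (configurable per-strand read floor, default 1) and absence of the
site from the matched-normal call set. Duplex coverage counts molecules
with both strands present regardless of variant content. With
single-strand error e per base, both strands of a molecule err to the same
specific alternate base with probability (e/3)² — the measured false-call
floor matches this analytic value in simulation.

## Driver annotation

The rules are applied literally, with closed thresholds:

* small variants: missense/in-frame at a hotspot (recurrence > 4 at the
  residue) in a dominant-acting gene, or loss-of-function (nonsense,
  frameshift, essential splice) in a recessive-acting gene. The
  predisposition gene is special-cased: any inactivating variant is a
  probable driver; missense only at recurrent residues.
* copy number: oncogene amplification at total CN ≥5 (ploidy < 2.7) or ≥9
  (ploidy ≥ 2.7); TSG loss at CN = 0 (ploidy < 2.7) or CN ≤ ploidy − 2.7
  (ploidy ≥ 2.7). Tier 1 requires membership in the 39-gene pediatric
  high-grade-glioma list, width ≤ 10 Mb, and the copy-number change being
  a recognized mechanism for the gene (fusion-only genes are excluded);
  tier 2 requires width ≤ 1 Mb. A segment passing the CN rule but neither
  tier criterion is still reported as a driver with tier none.
* structural variants: recognized oncogenic fusion, TSG-footprint
  truncation, or activating intragenic deletion of a flagged oncogene.

Gene roles, the tier-1 list, hotspot recurrences and known fusions ship as
TSV fixtures. The tier-1 gene list is the published 39-gene set; the
role/mechanism flags are a minimal defensible encoding, and the hotspot
and fusion tables are synthetic stand-ins for database extracts (marked
`_synthetic` in their filenames) whose counts matter only relative to the
>4 threshold.

## Burden model for recent clonal expansion

Substitution count is regressed on second-hit status, modality (bulk vs
microdissection) and mean coverage as fixed effects with a random
intercept per tissue piece (statsmodels MixedLM, REML), falling back to
OLS with a warning when only one piece is present. A Gaussian response on
raw counts is used deliberately — the contract is a *linear* mixed model,
and at burdens of hundreds the Gaussian approximation is adequate. The
expansion verdict compares the fitted effect against a configurable
~100-mutation yardstick, derived from postnatal substitution rates of
tens per year (glia ≈27/yr, neurons ≈17/yr — stored as documented
constants, not used in computation): a clone that expanded recently must
carry its founder's accumulated burden. A statistically significant but
small effect (e.g. +7 mutations) therefore does *not* indicate expansion.

## The synthetic cohorts

`simulate_cohort` builds a proband and two unaffected controls. The
proband carries the germline hit in every cell, a tumor node with complete
chromosome-17 copy-neutral LOH retaining the mutant haplotype and its own
300-mutation trunk, and an explicit clone plan (clone placement is
configuration, never random, so ground truth is exact): a truncating point
hit sampled at 56% cell fraction in a microdissection and 19% in bulk,
wild-type-loss CN-LOH clones at 13% and 2%, a mutant-loss deletion clone
at 10% in mesodermal tissue, and clean samples. Defaults: 200
heterozygous chr-17 SNPs, 30× target depth (WGS-of-microdissection
scale), 1e-3 per-base error, 0.5% tumor contamination of normal samples
(the contamination distribution across real samples is unreported;
0.5% sits inside the <1% gate), 95%-pure tumor sample. The proband and
control lineages use a star topology so clones are mutually unrelated by
construction; `simulate_lineage` also provides random topologies for
shared-ancestry studies. Reads are diploid two-copy sampling everywhere
except LOH segments: depth ~ Poisson(target), alt ~ Binomial(depth, v')
with v' = v(1−e) + (1−v)e/3 (errors uniform over the three non-reference
bases), so clone size = 2×VAF for heterozygous hits. Duplex bundles
default to one read per strand, matching the (e/3)² analytic floor used in
validation.

Seeding is hierarchical: one master seed, with per-stage child seeds
derived by hashing `(master, label)`, so adding a stage never perturbs the
streams of others and identical (config, seed) runs are byte-identical.

What the simulator does **not** emulate: read-level artifacts (mapping
error, strand bias, indel realignment), overdispersed site-specific error
(errors are binomial at a flat rate), sex chromosomes, subclonal
copy-number complexity beyond single LOH events, and duplex barcode
clashes (bundles arrive pre-grouped). Passing tests therefore demonstrate
correctness of the statistics under their stated sampling assumptions, not
robustness to alignment artifacts; on real data the Fisher caller's error
pool and the duplex floor should be regarded as lower bounds on achievable
specificity.

## Problem sizes used in validation

Calibration suites run at: 500 replicates × 200 samples × 3 sites (null
genotyping), 500 replicates × 100 samples × 1,000 SNPs at 40× (null LOH),
1,000 permutation draws against 45 control pairs (shared ancestry),
400–1,000 replicates for dN/dS coverage and 60–200 mixed-model fits for
burden recovery/power — sizes chosen so each suite completes in minutes on
one CPU while keeping Monte-Carlo error well below the tolerances tested.

## Known limitations

* The contamination estimator assumes diploid-het truncal sites; heavily
  rearranged tumors violate this and would need the copy-number-aware
  treatment that is explicitly out of scope.
* The LOH caller tests whole-panel aggregate imbalance; it does not
  segment, so a small focal event inside a large panel is diluted
  (breakpoint inference is out of scope).
* The presence caller's flat binomial error model underestimates error at
  overdispersed sites relative to a beta-binomial treatment.
* dN/dS here has no covariate or indel model and, with the uniform default
  spectrum, will mis-weight classes for genes with extreme context
  composition; supply a measured spectrum in that case.
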