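# Methods

This note documents the statistical models, default parameters, and design
choices behind each stage, and what the synthetic-data generator does and
does not emulate.

## Coordinates and data model

All on-disk formats (cytosine reports, GFF3, BED, depth tables) are 1-based
inclusive; internally every interval is 0-based half-open, converted exactly
once at the I/O boundary.  CpG sites are kept per cytosine — the two Cs of a
CpG dyad are not merged — matching the per-C records bisulphite aligners
emit; a destranding option can be layered on top of `SiteCounts.merge` but
is not applied by default.  Zero-coverage sites are retained at I/O and
excluded only by analysis filters: filtering is analysis policy, not I/O
policy.  When a gene has several mRNAs, methylation aggregation uses the
union of exons and CDS statistics use the longest CDS.

## Conversion error and the site caller

Incomplete bisulphite conversion makes a truly unmethylated C read as
methylated with probability λ.  λ is estimated from a control genome with no
methylation system as the pooled fraction Σm/Σ(m+u) over all contexts,
samples and sites (per-sample rates are reported for QC; a single global λ
feeds the caller).  The caller tests each site in each sample with the
one-sided binomial tail p = P(X ≥ m | n = m+u, λ) — one-sided because the
alternative of interest is methylation *exceeding* the error rate — after
restricting to sites with ≥ 5 reads in every sample.  BH adjustment is
applied within sample; a site is methylated at q < fdr (default 0.05).  The
λ = 0 limit is defined as p = 0 for m > 0 and p = 1 otherwise.
"Methylated in ≥ 1 sample" (the PCA input set) means called in at least one
sample.

## Feature aggregation and metagene profiles

Feature and gene methylation levels pool reads across replicates:
level = Σm/Σ(m+u) over the sites in the feature.  This makes the pooled
level the coverage-weighted mean of per-sample levels (asserted as a test
invariant).  Intergenic is the complement of gene spans.  Gene-level
aggregation uses the gene span only; the ±1 kb flank enters solely in
DM-site/gene overlap counting.  Metagene profiles scale each gene body to
60 bins and add 1 kb flanks in 20 × 50 bp bins, oriented TSS→TES
(minus-strand genes are flipped); genes shorter than the bin count are
skipped and counted.  The bin numbers are resolution choices, not
biological constants.  Expression stratification uses the level bins
[0,1)%, [1,25)%, [25,50)%, [50,75)%, [75,100]% — a gene at exactly 1 % is
"methylated" — restricted to genes with ≥ 1 FPKM in both morphs.

## Differential methylation

Each unit (site or gene) is modelled as binomial-logistic:
logit(π_r) = β₀ + β₁·morph over replicates r, each replicate one binomial
observation.  Because the single categorical covariate saturates the group
means, the MLE under the alternative is the pooled per-group proportion and
the likelihood-ratio statistic equals the G-statistic of the pooled 2×2
table for any number of replicates; the implementation computes this closed
form, vectorised, and the test suite cross-checks it against an iteratively
fitted binomial GLM.  No overdispersion correction is applied in the LRT
(the per-unit replicate structure at three replicates gives it little to
estimate); p-values are referred to χ²(1) and BH-adjusted across units.
Sites are DM at |Δ| ≥ 15 percentage points with q < 0.05; genes at
|Δ| ≥ 10 points — a laxer threshold because gene-body pooling dilutes
site-level signal.  Coverage filters: sites need ≥ 5 reads in every sample
and drop the top 0.1 % of each sample's coverage distribution; genes need
≥ 20 reads and drop the top 1 %.

BH is used for multiple-testing adjustment throughout.  q-value estimators
that fit the p-value density (e.g. SLIM-style π₀ estimation) would be less
conservative but are harder to reproduce exactly; the FDR level is a config
parameter.

### The sex-balanced pair null

To check that DM counts reflect sex rather than between-sample noise, the
3+3 replicates are regrouped into every nonredundant 2v2 pseudo-comparison:
sex-pure groupings ({F_i,F_j} vs {M_k,M_l}; C(3,2)² = 9) and mixed
groupings ({F_i,M_j} vs {F_k,M_l} with distinct females and males,
group-label swaps collapsed; C(3,2)² × 2 = 18).  This construction is the
unique reading that yields both counts 9 and 18 at three replicates per
sex.  Each grouping runs through the identical filter→LRT→BH pipeline, and
the by-sex and mixed DM-count samples are compared by a two-sided
Mann–Whitney test (normal approximation with continuity correction), with
W the U statistic of the by-sex sample; complete separation gives
W = 9 × 18 = 162.

### Methylation PCA

Sample scores come from a column-centred (per-site), unscaled SVD of the
sample × site level matrix restricted to sites methylated in ≥ 1 sample
with nonzero coverage everywhere — the same convention as R's `prcomp`
defaults.  Component signs are fixed by making each component's
largest-magnitude loading positive.

## Differential expression

FPKM = count/(length_kb × library_millions); CPM analogous.  Genes enter DE
when CPM > 2 in ≥ 3 samples (strict inequality).  The DE test is a
negative-binomial quasi-likelihood F-test built in-package:

1. median-of-ratios size factors over genes positive in all samples;
2. a single global working dispersion — the across-gene median of
   within-group method-of-moments estimates α = (s² − μ)/μ² (floored at
   1e-8);
3. group means fitted by damped Newton iteration with size-factor offsets;
4. the likelihood-ratio deviance drop divided by a per-gene
   quasi-dispersion (residual deviance of the two-group fit over its n − 2
   degrees of freedom), referred to F(1, n − 2).

The F reference with a data-driven quasi-dispersion is the small-sample
correction: simulation at 6+6 replicates and dispersion 0.1 shows the plain
χ²(1) LRT with per-gene plug-in dispersions is anticonservative (type-I
error ≈ 0.07–0.08 at nominal 0.05), while the quasi-likelihood form sits at
0.043–0.052 with p-values uniform under the null and full power on 4-fold
shifts.  This stage is a deliberately small surrogate for heavyweight DE
frameworks — no empirical-Bayes moderation, no trended dispersions — and is
validated by the calibration and power simulations in the test suite rather
than by agreement with any external package.

Sex-bias classes: significance from the NB test (BH q < 0.05), magnitude
from the fold change of mean FPKM (offset 0.01 against zero means): UB if
not significant or fold < 1.5; FAB/MB at 1.5 ≤ fold < 10 by direction;
FAB+/MB+ at fold ≥ 10.  Direction excess is a one-sided exact binomial test
of the larger class count against half — one-sided because the question is
whether the observed majority direction is an excess.

## X-chromosome assignment

Per morph, per scaffold: the median of per-position depth (all assembled
positions included by default; a flag drops zero-depth positions), plus the
genome-wide mean depth.  The assignment statistic is
norm_ratio = median_M × (mean_F/mean_M)/median_F; scaffolds ≥ 20 kb are X
when norm_ratio < 1 and autosomal when > 1.  Ratio exactly 1, zero female
median, or short scaffolds stay unassigned.  Normalisation uses genome-wide
means (the natural analogue of scaling pooled male coverage to female
coverage); a histogram with a valley-depth heuristic warns — without
failing — when the ratio distribution does not look bimodal.  Marker
validation compares coverage calls with externally known X/autosomal marker
scaffolds and reports concordance.  Composition contrasts use a
two-proportion χ² on CDS base counts, a Mann–Whitney rank-sum on per-gene
CDS lengths (the X and autosomal gene sets are unpaired samples), and an
exact binomial test of the X gene count against the assembled-length share.

## Integration

Qualifying genes are methylated above 1 % and expressed above 1 FPKM in at
least one morph.  FC_Expr = log₂((mean_M+ε)/(mean_F+ε)) on FPKM and
FC_Meth likewise on percent methylation, ε = 0.01 in both units.  The
correlation is Spearman's ρ (midranks).  The chromosome-interaction model
is ordinary least squares FC_Expr ~ FC_Meth × linkage — a Gaussian GLM with
identity link — with the interaction F-test on (1, n − 4) df asking whether
the X and autosomal slopes run parallel.  Enrichment contrasts build, per
bias class, the 2×2 class × chromosome table: cross-product odds ratio and
χ²(1) without continuity correction (large-sample usage), BH across
classes.  Paired within-gene shifts between morphs use the Wilcoxon
signed-rank test (zeros dropped, midranks; exact up to 25 nonzero pairs,
else normal approximation with continuity correction).  The X vs autosome
level-distribution contrast is the k-sample Anderson–Darling test (midrank
version); note scipy clamps its interpolated p-value to [0.001, 0.25].

## The synthetic-data generator

`SimulationConfig` defaults encode the emulated study design: 3 bisulphite
and 6 expression replicates per morph; mean coverage 30× (within the
24–37× replicate range of the emulated design) with Poisson coverage (an NB
option with configurable overdispersion exists); conversion error
λ = 0.0045; male total depth scaled by 90/79 with X sites at factor 0.5
(hemizygosity); 35 % of genes methylated, their per-site levels i.i.d.
Beta(5, 1.7), everything else truly unmethylated; methylated-site placement
density ramping linearly to 3× toward the gene 3′ end; 30 % of methylated
genes differentially methylated, shifted −0.20 in males on autosomes and
+0.20 on the X; 33 % of genes sex-biased in expression with MB:FAB odds
1.18, ~4.5 % of biased genes extreme (~12-fold), extreme male bias enriched
4-fold on the X; NB expression with dispersion 0.05, methylated genes
coupled to higher mean (2 log₂ units per unit methylation) and lower
dispersion (CV factor 0.7); and expression fold changes coupled to
methylation shifts with slope 1 on autosomes and 4 on X, which produces the
X-dominant FC correlation.  Observation model: coverage n ~ Poisson, then
m ~ Binomial(n, m_true + (1 − m_true)·λ) — conversion failure only ever
inflates apparent methylation, matching the chemistry.  Generation is a
pure function of (config, seed); ground truth (scaffold linkage, per-gene
methylation/DM/expression class, per-site levels) is serialised alongside.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence content and mapping artefacts, spatial
autocorrelation of methylation within genes (per-site levels are i.i.d.
given the gene), non-CpG methylation above the error floor, GC- or
mappability-driven coverage structure, batch effects, and biological
variation between replicates beyond counting noise.  Tests on it validate
calibration and recovery of the estimators, not biology.

## Problem sizes and checks

Null-calibration checks are run in the regime the asymptotic references are
built for: DM null simulations use per-site levels in [0.2, 0.8] at ~90
pooled reads per group (boundary-level sites at low coverage would probe
small-sample exactness of an asymptotic χ² test instead of implementation
correctness); DE nulls use the 6+6, dispersion-0.1, 5,000-gene design; the
interaction-GLM null uses 200 Gaussian replicates.  Recovery and detection
checks use ground-truthed simulations: X assignment on 200 scaffolds at
30×, DM-gene recovery on ~1,300-gene genomes with 20-point shifts, pair-null
separation over 20 replicate simulations, and the X-specific coupling
contrast on ~5,600-gene genomes (≈ 2,000 qualifying joint genes) over 20
replicates.

## Known limitations

* The DM test ignores replicate overdispersion; with strong between-replicate
  heterogeneity its q-values are optimistic.  A scaled-deviance correction
  would be the natural extension.
* The DE engine has no dispersion moderation, so very small replicate
  numbers (2+2) will be noisier than moderated frameworks.
* The valley-depth bimodality heuristic is a warning aid, not a test.
* Gene models assume non-overlapping exons within a gene after union; the
  union-of-exons choice slightly overstates exonic territory for genes with
  mutually exclusive isoforms.
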