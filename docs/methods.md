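# Methods

This note describes the models and procedures implemented in
`allodosage`, the choices made where the design was genuinely open, and
what the synthetic-data validation does and does not demonstrate.

## Generative model (`allodosage.simulate`)

The generator produces the data layout an interspecies hybrid presents
when short reads are mapped to the combined parental reference: for
each of `n_chromosomes_per_subgenome` chromosome indices there is an
`Sc` and an `Se` reference chromosome, each carrying the same
deterministic gene layout (equal slots, gene body = central 60% of the
slot), so every ancestral gene exists as an Sc/Se allele pair sharing a
base id.

**Karyotype.** Each chromosome is one copy-number segment with CN drawn
uniformly from `cn_range` (default 1–6).  `n_hybrid_chromosomes`
indices additionally carry a recombination breakpoint: a gene with
midpoint in the middle 80% of the chromosome is chosen, a position
drawn uniformly inside its body, and both parental tracks of that index
change CN at that position (left and right CNs drawn from `cn_range`,
redrawn to differ when the range allows — a recombinant chromosome that
produces no coverage step is invisible to any coverage-based method and
is excluded by construction).  This "two tracks stepping at the same
bp" picture is how a hybrid chromosome manifests on a combined parental
reference; the alternative of simulating the hybrid molecule as its own
contig was rejected because the analysis consumes parental-reference
coverage.

**Coverage.** Bin counts are Poisson with mean `segment CN x
depth_per_copy` (default 50 reads/500-bp bin/copy, a realistic yeast
WGS depth).  The recorded library size is the realized total over all
chromosomes, as a mapper would report.

**Counts.** The expected count for allele *a* of gene *g* in sample *j*
is

    mu = s_j * b_g * cn_{g,a} * bias_a * f_{g, cond(j)}

with `b_g` log-normal (`base_expression_log_mean=4`, `log_sd=1`, i.e.
typical per-copy means of ~50 with a 10-fold spread), `s_j` a mild
log-normal library-scale factor (`sample_scale_sd=0.1`), `bias_a` the
Se/Sc per-copy expression ratio (`allele_bias`, default 1 = pure
dosage), and `f` a per-(gene, condition) effect, `2^N(0,
condition_effect_sd)` with `condition_effect_sd=1` on the log2 scale.
Counts are negative-binomial with `Var = mu + alpha mu^2`
(`nb_dispersion=0.1`, a typical bulk RNA-seq value; `alpha=0` falls
back to Poisson).  Counts are simulated directly at the matrix level;
read-level simulation (mapping, GC bias, mappability) is out of scope.

**Seeding.** One master seed; every stage (genome, coverage, counts,
expression parameters, condition effects) draws from its own derived
substream, so adding a stage never perturbs another's draws.
Expression parameters (`b_g` and `f`) come from `expression_seed`
(defaulting to the master seed): giving two strain configurations the
same `expression_seed` but different master seeds yields strains with
divergent karyotypes that share regulation, which is the setting in
which a cross-strain dosage effect is identifiable at all.

**What the generator does not emulate.** Sequence divergence and
mapping ambiguity between sub-genomes, GC/mappability waves in
coverage, batch effects, outlier replicates, and correlated
condition responses between neighbouring genes.  Passing the recovery
studies therefore shows the pipeline is correct under its own model
assumptions — clean Poisson coverage and NB counts — not that real
libraries meet those assumptions.

## Karyotyping (`allodosage.karyotype`)

Coverage is normalized to reads per bin per million mapped reads
(`raw / library_size * 1e6`).  Chromosomes are segmented by recursive
binary segmentation on mean shift: the best split of a segment (by SSE
reduction, computed in O(n) with cumulative sums) is kept iff the
reduction exceeds `penalty * log(n_bins) * sigma^2` and both children
have >= `min_seg_bins` bins.  `sigma^2` is estimated once per
chromosome from the MAD of first differences (robust to the few true
steps).  Defaults: `min_seg_bins=20` (10 kb at 500-bp bins, suppressing
noise splits), `penalty=5`, chosen so that a pure-noise chromosome of
a few hundred bins essentially never splits (the null maximum SSE gain
grows like ~2 log n sigma^2) while a one-copy step at 50x per copy
exceeds the threshold by orders of magnitude.

The haploid unit *u* (normalized coverage per chromosome copy) is found
by grid search over `[max_mean/(max_cn+0.5), max_mean]` (4001 points
plus the exact `mean/k` ratios), minimizing the length-weighted squared
distance of `mean_s/u` from the nearest integer.  The lower bound
enforces `CN <= max_cn`; the upper bound prevents the degenerate
`u -> infinity` solution in which every segment rounds to zero.  Among
units within 1% of the optimal cost the largest wins, resolving the
`u` vs `u/2` ambiguity toward smaller copy numbers; with a single
segment this makes the (unidentifiable) answer CN 1, which is
documented behaviour.

Integer calls round half away from zero (calls sit near x.5 under
noise, and banker's rounding would alternate), clipped to
`[0, max_cn=8]` with a warning.  A chromosome's copy number is its
length-weighted modal segment CN (ties to the lower CN), so a hybrid
chromosome contributes one well-defined count per copy and genome
totals are sums of modal CNs.  Breakpoints are internal segment
boundaries with a CN change, mapped to the gene whose span contains the
boundary, else the nearest gene by midpoint (ties to the lower
coordinate).  Genes take the CN of the segment containing their
midpoint — on a parental-reference track that segment CN already totals
all chromosome copies carrying the allele, including the matching arm
of hybrid copies.  Sub-genome labels on annotated recombinant
chromosomes follow the breakpoint side containing the gene midpoint;
the breakpoint-spanning gene takes the side holding the larger fraction
of its length (a sequence-identity tie-break would need the reads
themselves, which are out of scope).

## Differential expression (`allodosage.expression`)

A deliberately compact NB testing stack.  Detection filter: CPM >= 0.5
in >= 1 library, boundaries inclusive; filtered genes are removed
before testing *and* before BH (they do not count toward the number of
tests).  The log-CPM transform adds its pseudocount (default 4) on the
count scale before scaling and exists for clustering/visualization
only; the test itself uses raw counts.  Size factors are
median-of-ratios over genes expressed in every sample; only factor
*ratios* are identified (the geometric-mean reference cancels in the
GLM offset), which is the property the tests assert.

Dispersion: per-gene method of moments on normalized counts,
`alpha = max((pooled within-group variance - mean)/mean^2, 1e-8)`,
then shrunk toward a fitted trend `alpha(mu) = a0 + a1/mu` (OLS over
genes with mean > 1, coefficients clipped non-negative).  The shrinkage
weight defaults to 0.8 toward the trend: with three replicates per
group the per-gene moment estimate is noisy enough that weaker blends
leave the downstream Wald test anticonservative (measured empirical
type-I error ~0.06–0.08 at a 50/50 blend versus ~0.055 at 0.8, with
the truth-dispersion test exactly calibrated at 0.05).  The weight is
an argument for users who want the rawer per-gene estimates.

The test is a per-gene NB GLM with design `[1, group]`, log link and
`log(size factor)` offset, fitted by IRLS vectorized across genes
(closed-form 2x2 solves); the Wald statistic `beta1/SE` is referred to
the standard normal, two-sided.  Non-converged genes (50 iterations,
coefficients clipped at |beta| <= 30) are flagged with missing p.
No Cox–Reid adjustment, no MAP fold-change shrinkage, no independent
filtering or outlier replacement — reproductions of results produced
with the full DESeq2 machinery are therefore approximate by design.
BH is the standard step-up with monotonicity enforcement; missing p
values propagate and shrink the number of tests.  Calls: up iff
log2FC >= 1 and padj < 0.05; down symmetrically; the fold-change
boundary is inclusive and the FDR boundary strict, matching the
stated thresholds literally.

## Orthologue dosage (`allodosage.dosage`)

Alleles are paired by base id (more than one allele per sub-genome per
base id is an error; partnerless genes are returned separately, as
happens for whole lost chromosomes).  The within-strain allele
log-ratio is defined as an NB Wald contrast with the two alleles as
groups over the same replicate libraries, each pseudo-sample inheriting
its library's size factor — the source data do not pair reads at the
molecule level, so an unpaired contrast in the same NB framework used
everywhere else is the consistent choice.  Copy-number ratio categories
are gcd-reduced `sc:se` strings; pairs with CN 0 on either side are
summarized separately and never regressed (their log-ratio is
undefined).  The primary regression is per-category mean log2FC on
`log2(cn_sc/cn_se)`, weighted by category size, slope p from a
t-test with (categories - 2) degrees of freedom; an unbinned per-pair
fit is reported alongside.  Regressing on the log ratio (rather than
ordinal category position) makes "slope 1" the literal dosage
prediction.

## Representation, consolidation, enrichment

Sub-genome representation uses a df=1 chi-squared goodness of fit with
expected proportions taken from the strain's detected transcripts (not
annotated gene models; configurable), no continuity correction (pools
are large), and inclusive star thresholds (`**` p <= 0.001, `*`
p <= 0.05).  Expected cells below 1 attach a small-sample warning.
DEG-list set operations return all exclusive Venn regions with
membership; counts sum to the union size.

The consolidated transcriptome sums the Sc and Se allele counts per
base id, passes unmatched genes through, and drops rows that are zero
in every sample; column sums are conserved.  Cross-strain comparison
intersects base ids (strain-exclusive genes are reported separately,
not tested), computes size factors jointly over both strains' samples
— the two strains are columns of one experiment, and per-strain
normalization would absorb genuine global differences — and contrasts
strain within the same NB machinery.  Total gene copy number is
`cn_sc + cn_se` (single allele if unmatched); the cross-strain
regression mirrors the dosage regression on `log2(cn_A/cn_B)` with
zero-CN genes excluded.

Enrichment is upper-tail hypergeometric (`P[X >= k]`) per term against
the detected-gene universe, BH over all tested terms, then the pathway
filters: k >= 4, k/K >= 0.25, p < 0.05.  The two-sided variant and
kappa-score term clustering used by some GUI tools are deliberately not
reproduced.  The composition score of an enriched term is the observed
Sc fraction of its overlap minus the expected Sc fraction, in
`[-p_sc, 1-p_sc]`; all-Se overlaps score exactly `-p_sc` and are
flagged exclusive (likewise all-Sc).

## Validation studies (`allodosage.benchmarks`)

Problem sizes were chosen to exercise the full pipeline in seconds on
one CPU while leaving the statistical bands comfortably identified:

* **Karyotype recovery** — 10 genomes of 16+16 chromosomes (200 bins
  each) with 2 hybrid pairs, CN 1–6 at 50x/copy; per-chromosome modal
  CN accuracy and breakpoint placement within +/-2 bins.  Expected and
  measured: ~100% on both.
* **Dosage recovery** — 512 orthologue pairs, CNs taken from the called
  karyotype (not truth), allele ratios from the NB contrast at 3
  replicates; the regression recovers slope 1 +/- ~0.05 with R^2 >
  0.99 across seeds.  `allele_bias` moves the intercept to
  `-log2(bias)` and leaves the slope at 1, which separates a global
  allele preference from dosage.
* **Cross-strain recovery** — two strains with independent karyotypes
  sharing `expression_seed`; consolidated log2FC vs total-CN log-ratio
  recovers slope 1, R^2 > 0.99.
* **NB calibration** — ~5000-gene null (uniform CN, no condition
  effects) at 3 vs 3: empirical type-I error at nominal 0.05 lands at
  0.046–0.058 across seeds.  Planted 2-fold effects (10% of genes,
  half up and half down — a one-sided shift is partially absorbed by
  size-factor normalization, which cannot distinguish a global fold
  change from sequencing depth) are recovered with median log2FC
  within ~0.04 of +/-1.

## Known limitations

* Breakpoint resolution is one bin (500 bp); sub-bin placement would
  need read-level data.
* A hybrid chromosome whose two arms happen to have equal copy number
  on a track is invisible to coverage-based detection.
* The Wald test at 2–3 replicates relies on the trend-shrunk
  dispersion; genuinely gene-specific dispersion outliers are pulled
  toward the trend and can be mildly liberal.
* The allele contrast treats replicates as unpaired; a paired design
  would gain power if allele counts covaried within libraries.
* The haploid unit is unidentifiable from a single uniform chromosome;
  the largest-unit tie rule then reports CN 1 by convention.
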