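# Methods

This note documents the statistical procedures, the generative model behind
the synthetic trio, the defaults and why they were chosen, and the known
limits of what a green test establishes.

## Methylation calling and profiles

The methylation level of a cytosine is mC/C — methylated-read count over
covering reads.  A site is *called methylated* by a one-sided binomial
test: with conversion-failure rate *f* (the probability an unmethylated
cytosine escapes bisulfite conversion and reads as methylated), the site is
methylated when P(X ≥ mc | total, f) ≤ α under Binomial(total, f).
Defaults: α = 0.05, no multiple-testing correction (a Benjamini–Hochberg
variant can be layered on by the caller).  *f* is estimated from the lambda
spike-in as 1 − (Σ mC / Σ C) pooled over the contig; with the default
simulated failure of 0.006 this recovers ≈ 99.4 % conversion.

Chromosome and element means are **unweighted per-site means** of mC/C over
sites with ≥ 4 covering reads (a read-weighted variant is exposed via
`weighted=True`).  Site-weighting makes the summaries robust to coverage
variation; the coverage floor excludes sites whose level estimate is too
noisy to average meaningfully.  Mid-parent value is the arithmetic mean of
the two parental summaries.

Metaplots length-normalize gene bodies into 20 bins and tile 2 kb flanks
into 20 fixed-width bins each; minus-strand genes are mirrored bin-wise
(mirroring the bin index, not the coordinate, so the plus/minus symmetry is
exact at bin boundaries).

## DMRs

Windows (default 1000 bp, step 100 bp) qualify when ≥ 5 cytosines of the
context are covered (≥ 4 reads) in *both* samples.  Counts are pooled per
window; the two-sided Fisher exact test (minimum-likelihood convention, the
same as R's `fisher.test` and `scipy.stats.fisher_exact`) gives the
p-value, and fold change is (level_a + ε)/(level_b + ε) with ε = 0.001 to
bound the ratio at unmethylated windows.  Windows with p ≤ 0.05 and fold
≥ 2 are merged when overlapping or adjacent with the same direction; the
merged region reports levels recomputed from its pooled counts, the
minimum window p, and its jointly covered site count.  A merged span that
no longer meets the fold threshold after recomputation is dropped, so
every emitted DMR satisfies all thresholds.  Window geometry is not
dictated by any published convention we could adopt verbatim; 1 kb / 100 bp
with per-site coverage ≥ 4 is common WGBS practice and every parameter is
exposed.

Inheritance of a parental (mother-vs-father) DMR is decided purely by
interval overlap with the two F1 comparisons, mirroring a Venn construction
over DMR sets: the call is FATHER-like when the region overlaps an
F1-vs-mother DMR whose direction matches the father's side (and no
F1-vs-father DMR at all), MOTHER-like symmetrically, otherwise UNRESOLVED.
Venn-region counts are computed over interval *clusters*: intervals from
the three sets are pooled, maximal overlapping groups form clusters, and
each cluster is counted once per membership pattern.  This makes the seven
region counts well defined even though the three sets have different
region boundaries.

## DMSs and the eight-way classification

Sites covered ≥ 4 reads in all three samples are tested pairwise (father
vs mother, F1 vs each parent) with two-sided Fisher exact tests; a site is
a DMS when any pairwise p < 0.01 (uncorrected, configurable).  The
taxonomy is resolved into mutually exclusive significance-pattern rules:

| parents differ (p_ab < α) | condition |
|---|---|
| ADDITIVE | F1 differs from both parents, level strictly between them |
| ABOVE_HIGH / BELOW_LOW_PARENT | F1 differs from both, beyond the higher/lower |
| LOW/HIGH_PARENT | F1 indistinguishable from that parent, distinguishable from the other |
| AMBIGUOUS | any other pattern |

With parents indistinguishable, ABOVE/BELOW_PARENT require the F1 to
differ significantly from both parents in the same direction; everything
else is AMBIGUOUS.  Low-coverage sites are excluded *before* testing —
they are untestable rather than unclassifiable, so the Ambiguous fraction
refers to tested sites only.  The classification is total and exclusive on
DMS inputs (fuzz-tested against an independent scalar restatement of the
rules) and invariant under relabeling the parents.

The genome-scan implementation vectorizes the Fisher test by looping over
the (short, coverage-scale) hypergeometric support; it is oracle-tested
against full enumeration for pooled totals up to 200.

## Allelic expression

Per-gene allele counts are **per-PSNP means** (not sums) of allele-resolved
read counts over covered PSNPs, rounded to integers: summing would conflate
expression with PSNP density.  TMM factors are computed from log2 ratios of
**raw counts** against a reference library (the one whose upper-quartile
count is closest to the mean upper quartile), double-trimmed (30 % on M,
5 % on A), precision-weighted, then rescaled to geometric mean 1.  Note
this differs from edgeR's convention, which computes M on library-size-
normalized counts; here the factor deliberately absorbs sequencing depth,
so dividing each library by its factor puts all libraries on one scale
(for two identical libraries the factors are (1, 1); for an exactly
doubled library they are (2^-1/2, 2^1/2)).

The bias test is an exact conditional negative-binomial test: under the
null both normalized counts share mean μ = (x₁+x₂)/2 and a common
dispersion φ (var = μ + φμ²); conditional on the pair total, the two-sided
p sums the probabilities of all splits no more likely than the observed
one.  φ = 0 reduces to a Binomial(n, ½) split.  φ is estimated across
genes by method of moments, Σ(s²_g − m_g) / Σ(m²_g − s²_g/2), floored at 0
(the denominator is the unbiased estimate of Σμ²_g); with < 20 genes the
pipeline falls back to a fixed φ = 0.1 with a warning.  A gene is called
biased only when p < 0.05 **and** the normalized fold change is ≥ 1.5,
directed by the larger normalized count.  The α for the bias call and the
application of the fold threshold to normalized (not raw) counts are
package choices, both configurable.

## PSMS rules

Rule (iii) — genotype/WGBS concordance — is operationalized as
presence/absence concordance of methylome records at the SNP position and
strand: bisulfite reads cannot distinguish a C→T variant from an
unmethylated C on the converted strand, so direct base comparison is not
possible; record presence on the cytosine strand is the standard
resolution of this ambiguity.  Rule (iv)'s "zero methylated reads on the
non-C allele" is literal — no tolerance.  Rule (v) uses the binomial
caller (α = 0.05) rather than "≥ 1 methylated read": at ~99.4 % conversion
and 15× coverage, a raw ≥ 1 criterion would be dominated by conversion
noise (P(≥1 failure in 15 reads) ≈ 8.6 %).  The rules are conjunctive:
ablation of any rule can only enlarge the output (tested).  The origin
parent is always the allele carrying the cytosine on the recorded strand;
a C/G SNP can legitimately yield one PSMS per strand with opposite
origins.

## Integration

Per gene, PSMSs are split by origin; BIPARENTAL requires both origins
present.  The allelic methylation level of an allele is the F1 mC/C of
reads assigned to the cytosine-carrying allele at each PSMS.  The two
alleles' per-PSMS level lists are different genomic positions and cannot
be paired, so the comparison is an unpaired two-sided rank-sum test
(exact permutation enumeration for ≤ 12 pooled observations — valid under
ties — otherwise scipy's default), requiring ≥ 3 sites per allele.
Welch's t-test is additionally run on the subset of genes where both
allele lists pass a Shapiro normality screen (p > 0.05); the rank-sum test
is reported for all eligible genes.  Running both tests with an explicit,
reproducible gate was chosen because no principled sequential rule between
them presents itself; the two cohorts are therefore not designed to match
any particular published split.

## The synthetic trio

The generator states a world and the tests measure recovery in it:

* two 250 kb chromosomes at GC 0.38, 300 genes (0.5–1.5 kb, placed with
  random gaps), SNP rate 0.005/bp, half of SNPs creating/destroying a
  cytosine in exactly one parent (origin balanced between parents; non-C
  SNPs are A↔T swaps so they never touch a cytosine);
* per-site latent methylation propensities drawn from U-shaped betas with
  means ≈ 0.8 (CG), 0.7 (CHG), 0.2 (CHH); parents share the base draw,
  with 2 % of sites redrawn for one random parent and 10 % of 5 kb regions
  flipped (p → 1−p) in one random parent — the substrate for DMSs and
  DMRs;
* F1 inheritance modes per 5 kb region: additive 60 %, maternal-like 15 %,
  paternal-like 15 %, above-parent 5 %, below-parent 5 % (transgressive
  shift δ = 0.3);
* reads: Poisson(15) coverage, fair Bernoulli allele choice per F1 read,
  mC ~ Binomial(cov, p(1−f) + (1−p)f) with conversion failure f = 0.006;
  at a C↔non-C SNP the non-C parent emits no record and non-C-allele F1
  reads count toward depth but never toward mC (as a force-called C→T
  variant behaves in real data);
* lambda spike-in: a 48.5 kb contig with true propensity 0 everywhere;
* RNA: negative-binomial allele counts per PSNP (per-allele mean 300,
  dispersion 0.1), 10 % of genes truly biased at fold 3 with the total
  held constant.

Where the study this emulates does not state an effect-size spectrum,
these defaults are engineering choices of realistic magnitude, fixed once
and exposed in `SimulationConfig`.  All randomness flows from a single
seed; identical configs give byte-identical outputs.

What the simulator does **not** emulate: read-level errors and mapping
bias, linkage between neighboring sites beyond region-level propensity
structure, CpG-island/repeat architecture, context-specific inheritance
differences, or allele-assignment errors in RNA counts.  A green recovery
test therefore establishes correctness of the statistical machinery on
clean count data, not robustness to alignment artifacts.

## Numerical conventions

Two-sided exact tests use the minimum-likelihood rule with a 1 + 1e−7
relative tolerance when comparing table probabilities (the R/scipy
convention).  Fold changes use ε = 0.001 pseudo-levels (DMRs) or a 0.5
pseudo-count in reported log2 folds (allelic calls); the bias-call fold
itself is the raw normalized ratio (infinite when one allele is 0, which
correctly exceeds any threshold).  Genes with both normalized counts 0
are NONE with p = 1.  Zero-coverage methylome records are carried in the
tables (they exercise coverage filters) but excluded from every level
computation.  DMR/DMS outputs are sorted by genomic coordinate so results
are independent of input row order.

## Known limitations

* The DMR inheritance call is overlap-based only; a secondary equivalence
  test between F1 and the matching parent is not applied.
* The common-dispersion NB model ignores gene-specific dispersion; with
  strong dispersion heterogeneity the type-I error of the bias test can
  exceed its nominal level for the most variable genes.
* TMM on two libraries trims against a single reference; with few genes
  (< ~50) the trimmed set can be small and the factor noisy.
* Rule (iii) presence/absence concordance cannot detect a genotyping error
  that is consistent between resequencing and WGBS.
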