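# Methods

## Design and data model

The experiment is a 2 × 2 factorial: genotype ∈ {WT, C3S} (wild-type vs
redox-insensitive cysteine-to-serine mutant of Stat3) × treatment ∈
{basal, oxidation}, with a small number of biological replicates per cell
(two by default, matching the experimental design the package targets).
Counts for gene *g*, sample *s* are modelled as negative binomial with
mean μ and dispersion α under the parameterisation

    var = μ + α·μ²

(α = 0 is Poisson). This parameterisation is fixed throughout — the
simulator, the test and every oracle use the same α — so moment
calculations in tests match the generator exactly.

Four pairwise comparisons are analysed, in a fixed order that defines the
positions of the pattern code:

| position | comparison (B vs A; logFC = log2(B/A)) |
|---|---|
| 1 | WT oxidation vs WT basal |
| 2 | C3S vs WT, basal |
| 3 | C3S oxidation vs C3S basal |
| 4 | C3S vs WT, post oxidation |

## Expression filter and normalisation

A gene is *expressed* when the maximum over the four conditions of its
replicate-averaged count is ≥ 10 (strict ≥; the filter is idempotent).
Library sizes are estimated by median-of-ratios: factor_s = median over
genes of count_gs / geometric-mean_g, using only genes with nonzero
counts in every sample. The median is taken on the ratio scale (not the
log scale — for an even number of reference genes the two differ), which
makes the factors invariant to a global rescaling of the matrix and
equivariant to scaling a single sample relative to the others.

## Conditional NB exact test

Normalised counts are rounded to the nearest integer (ties to even)
because the exact test needs integer totals; the rounding is applied only
inside the test, while means and logFC use the unrounded values. For a
comparison with group sizes n_a, n_b and dispersion α, the group-A
subtotal conditioned on the gene's two-group total t is negative
hypergeometric (two-category Dirichlet-multinomial) with sizes
r_a = n_a/α, r_b = n_b/α. The two-sided p-value sums the probabilities of
every split s = 0..t whose probability is ≤ that of the observed split,
with a 1e-7 relative tie tolerance (the convention used by R's
`fisher.test`); summing is done in log space via log-gamma. The
"doubled one-tail" alternative was rejected because the conditional law
is asymmetric for unequal group sizes. When α falls at or below the floor
(1e-8) the implementation switches to the exact Poisson-limit conditional,
Binomial(t, n_a/(n_a+n_b)) — algebraically the α → 0 limit, and
numerically necessary because at r ≈ 1e8 differences of log-gamma values
lose the precision the test's 1e-10 enumeration tolerance demands.

### Dispersion estimation

Per gene, a pooled method-of-moments estimate is formed from the two
groups of the comparison: per group α̂ = (s² − m)/m² (sample variance,
ddof 1), pooled with degrees-of-freedom weights. At two replicates per
group this estimator has ~2 df; roughly half the genes then land below
the Poisson line and would be floored, which empirically inflates the
null rejection rate threefold (measured 0.16 at nominal 0.05; with the
true dispersion the conditional test gives 0.0575). The per-gene
estimate is therefore shrunk toward the df-weighted mean across all
genes:

    α_g = (df_g·α̂_g + d₀·ᾱ) / (df_g + d₀),   d₀ = 10 (prior df)

floored at 1e-8 afterwards. This is the standard moderation used for
small-replicate RNA-seq dispersion estimation; d₀ = 10 restores null
calibration at two replicates (measured 0.0595) while still letting
gene-specific estimates dominate when replication is deep.
`dispersion_prior_df=0` disables the shrinkage and recovers the plain
per-gene estimator. The logFC uses a pseudocount of 0.5 on both
normalised means so zero-count genes stay finite; both are configurable.

### Significance

BH step-up adjustment runs within each comparison; a gene is called when
q < 0.05 **and** |log2FC| > 1, both strict. Whether the published
threshold "P < 0.05" refers to raw or adjusted p is ambiguous in the
source analysis; this package interprets it as the BH-adjusted value
(the stricter reading) and exposes both thresholds as configuration.

## Pattern codes and cluster selection

Each comparison contributes sign(logFC) if called, else 0; the ordered
4-tuple over {−1,0,1} is the gene's pattern code. Genes whose code is all
zeros are not DE and form no cluster, so at most 3⁴ − 1 = 80 clusters can
occur. The default oxidation-responsive selection keeps a code iff
position 1 ≠ 0, position 3 = 0, and (position 2 ≠ 0 or position 4 ≠ 0):
the WT cell responds to oxidant, the redox-insensitive mutant's response
is absent, and the dis-regulation is visible in at least one
WT-vs-mutant contrast. This predicate admits exactly 16 of the 80 codes
and reproduces every selected code named in the analysis it re-implements;
because that analysis never formalised its rule, the rule here is
configuration — an explicit list of code strings can be supplied
verbatim instead. Direction is read from position 1. Codes serialise as
comma-joined signed integers (`-1,0,0,1`).

## Synthetic counts

Planted condition means are derived from the WT-basal anchor μ₀:
positions 1, 2 and 4 successively fix WT-oxidation, C3S-basal and
C3S-oxidation as μ₀·2^(±e); position 3 must then be consistent, checked
in log2 space with tolerance 1e-9. With a single effect magnitude e a
code is realisable iff c₁ + c₄ = c₂ + c₃; unrealisable codes are rejected
by name at design construction. Defaults emulate the study conditions:
2 replicates per condition, baseline mean 100 (a comfortably expressed
gene), dispersion α = 0.05 (typical biological-replicate variability for
cell lines), planted |log2FC| = 3 (the clearly-responding regime),
per-sample library-size factors uniform in [0.7, 1.3] to exercise
normalisation. The generator plants deterministic block sizes
(round(fraction·n)) onto a seed-shuffled gene order, so planted counts
are exact and recovery fractions have a fixed denominator.

## Motif scanning

Consensus patterns are IUPAC strings; a window position mismatches when
the sequence base is outside the pattern letter's class. Non-ACGT bases
in the *sequence* (N) always count as mismatches, including against the
pattern's N — an unknown genome base should never silently satisfy a
binding site. Both strands are scanned by also matching the
reverse-complement pattern against the forward sequence; offsets are
0-based from the window's 5′ end in coding orientation internally, and
1-based in written reports (stated in every output header). For
reverse-complement-palindromic patterns (the SIE) plus- and minus-strand
hit sets coincide, so only the plus strand is reported. Promoter windows
default to 3 kb upstream of the ATG (the translation start from CDS
features), matching the scan the package re-implements; a TSS anchor is
a flag away. Minus-strand windows are reverse-complemented so every
returned sequence reads 5′→3′ toward the anchor; windows are clipped at
contig edges with the actual length recorded. Default consensi beyond
the SIE — HRE `RCGTG`, TRE `TGACTCA`, ARE `TGACNNNGC`, with the
2-mismatch budget applied to SIE and ARE only — are placeholders at the
level of ordinary practice for these factors, exposed as configuration,
and every output names the consensus and budget used.

The synthetic promoter generator writes planted instances exactly
(ambiguity letters realised uniformly at random) and refuses *any*
overlapping plants within a gene, not just same-strand collisions: an
opposite-strand overwrite would silently falsify the planted truth.

## Gene-set statistics

The upper tail P(X ≥ k) of Hypergeometric(N, K, m) is computed in log
space (log-gamma pmf, log-sum-exp over the tail support) for stability at
genome-scale N; tests verify agreement with direct summation of exact
binomial-coefficient pmfs to 1e-10 relative for all configurations with
N ≤ 200 and spot-check N ≤ 500. Enrichment intersects query and
collection sets with the universe, reports (k, m, K, N, p, q) per set,
and applies the same BH implementation as the DE module (shared code, not
a re-implementation). Overlap tests are one-sided (over-representation).
The universe defaults to the expression-filtered gene set for synthetic
runs and is required configuration for real data — enrichment p-values
are meaningless without an explicit universe. Frequency pruning keeps
sets whose annotation frequency K/N lies strictly between 0.1% and 1%,
then the top 5 by p; semantic-similarity dispensability filtering is out
of scope.

## Peak filtering and annotation

Fold enrichment is (sample + c)/(control + c) with pseudocount c = 1 on
both depths (zero-control peaks otherwise have undefined fold); peaks
pass at fold strictly > 2. Promoter windows are [tss − 5000, tss + 500)
on the plus strand and the mirror image on the minus strand; any overlap
≥ 1 base assigns a peak to a gene, a peak may assign to several genes,
and the returned gene set is de-duplicated. Classification precedence is
promoter > exon > intron > intergenic, where intron means inside a gene
span without exon or promoter overlap. The synthetic peak generator
multiplies a base depth (20) by the planted fold and independent
lognormal noise exp(σZ) per depth; merging of ChIP replicates is
upstream of this module (inputs are interval + depth tables).

## Problem sizes and numerical choices

Tests and the acceptance script run at 500–2000 genes, 100–200 promoters,
and 500–10 000 peaks — sizes where planted-recovery fractions have small
binomial noise yet the whole suite completes in minutes. Tolerances:
1e-10 absolute for exact-test enumeration agreement, 1e-10 relative for
hypergeometric tails, 1e-9 (log2 space) for planted-code consistency,
strict equality for discrete outputs (hit sets, kept peak sets, BH hand
cases). Rounding of normalised counts is nearest-integer, ties to even.

## What the synthetic data does and does not show

The generator matches the analysis assumptions exactly: NB counts with
common dispersion, means constant within condition, i.i.d. promoter
background, independent lognormal depth noise. Passing recovery tests
therefore demonstrates correctness of the inference chain, not
robustness to real-data pathologies — gene-length and GC effects,
correlated genes, dispersion trends with mean, promoter sequence
composition structure, or peak-width variation are all absent. The
published genome-scale counts (3617 DE genes, 45 clusters, 199 genes in
10 selected clusters, 927 peak-associated genes) depend on unreleased
raw reads and supplementary tables and are therefore not reproduction
targets here; the package exposes the exact thresholds and rules needed
to recompute them when those inputs are supplied.

## Known limitations

- No GLM with covariates and no dispersion trend fitting; the moderation
  shrinks toward a single common value.
- The exact test conditions on rounded normalised totals; for very low
  counts the rounding can shift a total by 1 (documented, shared by the
  reference approach of testing normalised counts).
- IUPAC scanning is consensus/mismatch based; no PWM scoring.
- GO DAG propagation and semantic-similarity pruning are out of scope;
  frequency pruning operates on the supplied sets as-is.
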