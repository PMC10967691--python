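# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical choices behind `allelome`, in the order the pipeline runs
them.

## Coordinates and data model

All internal coordinates are 0-based half-open; conversion to the 1-based
conventions of cytosine reports and GFF3 happens only at the I/O boundary
(`allelome.io`). A methylation "track" is one sample's per-cytosine table
(chromosome, position, strand, context, methylated count, unmethylated
count). CG sites are deliberately **not** strand-merged: each cytosine is an
independent observation, which keeps counts auditable and makes the
weighted level of any region a plain ratio of summed counts.

## Methylation levels and profiles

The site-level methylation level is mC/(mC+uC), defined only at coverage
≥ 5 (`min_cov`, the conventional threshold for 30× bisulfite data). Region
levels are coverage-weighted: Σ mC / Σ (mC + uC) over qualifying sites, and
are *flagged undefined* (NaN), never reported as 0, when a region contains
no covered cytosine — averaging treats them as missing.

For genome summaries a site is *called* methylated by a one-sided binomial
test of its methylated count against the bisulfite non-conversion rate
(default 0.005), BH-corrected within each context at α = 0.01. The level
histogram over called sites uses the conventional low/mid/high bands
[0, 0.2), [0.2, 0.8], (0.8, 1].

Metagene/TE profiles use 80 bins per feature: 20 fixed-width 100-bp bins
over each 2-kb flank and 40 proportional bins over the body, ordered along
transcription (on the minus strand the 5′-most bin is the highest-coordinate
flank bin). The "40 + 40 upstream/downstream + body" accounting only totals
80 as 20/40/20, which is the split adopted; flank bins are fixed-width
because the flank length is fixed. Features shorter than 40 bp are excluded
with a warning (proportional bins would collapse below 1 bp).

Genome-wide sliding bins are 200 bp at step 100. Trailing clipped bins are
kept when ≥ 100 bp long and dropped when fully contained in their
predecessor, so every position is covered ≥ 1 and ≤ 2 times and a 1,000-bp
chromosome yields exactly 9 bins.

## Differential methylation (DMR/ASMR)

Bins enter the test only if they contain ≥ 5 cytosines of the context in
*every* sample. The model is a binomial logistic regression of methylated
proportion on group membership with each replicate as a separate binomial
observation, compared against the intercept-only model by likelihood ratio.
Because the group model's MLE is the group-pooled proportion, the LRT
statistic reduces exactly to the pooled-count G statistic, which is what the
code computes (vectorised over all bins); the equivalence is verified
against a statsmodels binomial GLM in the tests. Multiplicity is handled by
Benjamini–Hochberg (a deliberate substitution for methylKit's SLIM
q-values: standard and dependency-free). A bin is a DMR when
|level₂ − level₁| (pooled) exceeds the per-context threshold (0.25 CG,
0.25 CHG, 0.15 CHH) and q < 0.05. An optional beta-binomial variance
inflation (method-of-moments on replicate heterogeneity) can be switched on;
it is off by default because BH across ~60k mostly-null bins already
controls the realised false-positive fraction far below 5% at the default
replicate overdispersion.

The chi-square LRT and Fisher's exact test agree within one order of
magnitude on tables drawn from a shared binomial proportion (the ensemble
where p-value calibration matters); on arbitrary extreme tables any
asymptotic test diverges from the exact tail, which is expected behaviour
and not specific to this implementation.

Allele-specific methylation (ASMR) applies the identical test (shared code
path) with the two alleles as groups, on the 80 gene bins, matched across
alleles **by ordinal bin index** — allele bodies differ in length, so
coordinate matching is not meaningful. ASMGs are pairs with ≥ 1 ASMR. The
bias-shift fraction counts a region (pair, bin, context) as *matched* when
significant in ≥ 2 phases and *shifted* when those calls disagree in
direction; regions significant in a single phase are stable by default (the
stricter of the two possible readings).

DMGs are genes with ≥ 1 DMR in the body or 2-kb strand-aware flanks; each
DMR takes one primary feature by the precedence promoter > gene body >
downstream > intergenic (overlap by ≥ 1 bp).

Time-course clustering of DMR levels follows the short-time-series
profile-assignment idea: candidate profiles are integer-step trajectories
starting at 0 with per-step change in [−c, c] (c = 2), greedily thinned to
50 by max–min distance; each standardised series joins its
highest-correlation profile (constant series join the flat profile by the
zero-distance rule); profile significance compares assigned counts with the
distribution under permutations of each series' time order (all T!
permutations enumerated when T! ≤ the permutation budget), via a binomial
tail. Enrichment of gene sets is a one-sided hypergeometric test with BH
across sets — database-agnostic, sets supplied by the caller.

## Expression and the methylation–expression association

TPM is count/length rates scaled to 10⁶ per sample over exon-union lengths;
columns sum to 10⁶ to machine precision. Differential expression is the
package's own NB2 GLM: median-of-ratios size factors, per-gene
method-of-moments dispersion with a 1e-4 floor (no shrinkage toward a
trend — a documented simplification relative to shrinkage-based tools),
IRLS fitting (tolerance 1e-8, ≤ 100 iterations), Wald test on the condition
coefficient, BH FDR, and the |log2FC| > 1 & FDR < 0.05 flag. The IRLS core
is validated coefficient-for-coefficient against statsmodels' NB GLM and
against the Poisson limit.

Expression classes are I (TPM = 0), II (0, 1], III (1, 10], IV (10, 100],
V (> 100). Class-wise methylation comparisons use the Wilcoxon–Mann–Whitney
test: exact enumeration over midrank combinations when both groups have
n ≤ 8 (tie-safe, so identical samples give p = 1), otherwise the normal
approximation with tie correction; letters come from an insert–absorb
compact letter display at p < 0.05.

The per-bin methylation–expression correlation uses one value per phase:
replicate-mean TPM and replicate-pooled bin levels over the six WGBS
phases (the single-value-per-phase choice matches the
"across the six phases" framing; using all replicates as points is possible
by passing them as columns). Pearson r with the two-sided t-transform p;
significance requires **both** |r| > 0.6 and p < 0.05 — at n = 6 the p
criterion dominates (|r| = 0.6 gives p ≈ 0.21). Bins with undefined levels
in any phase, or constant series (including constant to float precision),
are skipped. No genome-wide correction is applied to this scan, matching
the stated criterion. Gene-level sign summaries count each gene by its
strongest significant bin.

## Allele pairing

Homology scores come from k-mer-seeded global alignment: candidate pairs
share ≥ 3 distinct 8-mers; the score is len(A) + len(B) − 2·editDistance
(edlib), i.e. 2·matches − gaps, positive only for genuine homologs. (A
max-length-minus-distance score fails here: a short CDS embeds in a random
4×-longer sequence almost as a subsequence.) The c-score filter keeps hit
(A, B) iff score ≥ 0.99 · max(best(A), best(B)). Synteny chains are longest
strictly monotonic anchor chains (both orientations) per chromosome pair
with rank gaps ≤ 20, extracted greedily, blocks ≥ 4 anchors; anchors unique
within a block become pairs. Remaining genes go through bidirectional best
hits (score ties broken lexicographically and logged), then a single-copy
fallback (reciprocal pairs among genes with exactly one hit each). Tiers
are computed on shrinking residual sets, so the merged table is a partial
matching by construction; a cross-tier conflict is an internal error, not a
warning. min_block = 4 and max_gap = 20 are conventional collinearity
defaults; scoring is nucleotide-space at desk scale, with 12-column tabular
protein alignments accepted as an alternative input.

## Allele-specific expression

Size factors are computed jointly across all alleles per sample — the two
alleles share a library, and per-allele normalisation would distort the
allelic ratio. Per-phase bias is a Wald test on the allele coefficient
(maternal over paternal), BH within phase, bias iff |log2FC| > 1 and
FDR < 0.05. Phase-dependent bias fits counts ~ phase + allele +
phase:allele on {baseline, phase} and tests the interaction by LRT (df 1);
the interaction effect is log2FC(phase) − log2FC(baseline). Wald for the
marginal tests and LRT for the interaction keeps the interaction df
explicit. Consistency classes across phases: consistent (same non-none call
everywhere), shifting (both directions occur), phase-specific (biased
somewhere, one direction, not everywhere), unbiased. At 3 replicates the
per-pair interaction estimate has standard error ≈ 0.4 on the log2 scale;
recovery claims are therefore about the mean estimate across pairs (bias
< 0.05 at μ ≥ 100), not about individual pairs.

## Promoter TFBS analysis

Promoters are the 2-kb windows transcribed-upstream of each TSS
(strand-aware), scanned on both strands with log-odds scores over a 0-order
background estimated from the scanned promoter set (pseudocount 0.1 per
cell). Scores are integerised at 0.01-bit resolution and the null score
distribution is computed exactly by DP convolution of the per-column score
distributions, so every hit p-value is an exact tail mass; hits require
p < 1e-4 (no q-filtering on hits). Ambiguous bases contribute a log-odds of
0. Presence vectors are binary over the library; cosine similarity of two
all-zero vectors is defined as 1 with an "identical absence" flag (the
promoters agree about every motif — flagged so callers can exclude them).
CS classes are 0.2-wide bands with class V closed at 1.0. The group
comparison (all pairs vs phase-dependent ASEGs) correlates maternal vs
paternal expression — mean log2(TPM+1) across phases by default — within
each CS class and compares groups by the two-sample Fisher r-to-z test.
TFBS methylation pools cytosine counts over each hit footprint through the
same region-level code as everywhere else.

## The synthetic generator

The generator emulates a two-subgenome hybrid at desk scale: 2 chromosomes
per subgenome (not the real 19 — runtime), 500 gene pairs, lognormal body
lengths (median ≈ 1.3 kb, clipped to [0.4, 6] kb), 2-kb promoters, gene
units separated by 4.2–5.4-kb intergenic gaps carrying TEs (LTR/LINE/SINE/
DNA with SINEs shortest), mixed strands, ~50% two-exon genes. Paternal
gene, promoter and opposite-flank sequences are maternal copies mutated at
the SNP rate (default 1%); a configurable fraction (default 10%) of pairs
is relocated to random positions to exercise the homology fallback.
Infeasible packings raise.

True site methylation is a two-component Beta mixture: each site is
"methylated-class" with probability f(context) × feature scale (gene body,
promoter, TE class — SINEs highest at 1.8×), drawing its level from a
context-specific high Beta, otherwise from a low Beta (mean ≈ 0.02).
Defaults put the explant genome summaries near the magnitudes typical of a
poplar methylome (CG ≫ CHG ≫ CHH; high-band fractions ~44/22/<1%); they are
defaults, not assertions. Crucially, the latent profile over each gene
unit's full 80-bin footprint (both flanks + body) is **pair-shared**: both
alleles read the same per-offset random field, so with no designated
effects the allele methylomes agree up to sampling noise and the
allele-methylation null holds by construction (residual discordance comes
only from SNP-changed contexts). Non-expressed ("silent") genes (8%) get a
1.8× methylated-class elevation, reproducing the
hypermethylation-of-non-expressed-genes contrast.

Phase effects multiply the true level: the explant is 1.0, the first direct
and indirect induction phases drop total methylation by ≈ 16.7% and ≈ 9.1%
respectively, and the CHH trajectory dips then recovers above baseline —
the decrease-then-increase pattern. True DMR windows (100 per context per
subgenome) are of two kinds: intergenic windows drawn clear of gene units
(per subgenome), and genic windows drawn per non-ASMG pair at a shared
offset in the pair footprint and applied to both alleles at homologous
positions — so genic DMRs exist (promoter/body feature fractions are
non-trivial) without inducing spurious allelic bias. Window baselines are
redrawn inside an offset-compatible range so the configured additive offset
(default 0.4, 70% hypo) is realised unclipped; offsets apply at all
non-explant phases. Designated ASMG pairs (20%) get a ± offset over the
maternal promoter + body in one context; hypo-direction offsets on
low-baseline contexts (especially CHH) are often unrealisable after
clipping — the truth table still records them, and recovery statements are
made for the realisable maternal-hyper CG condition. Observed data:
coverage ~ Poisson(30), replicate-level p ~ Beta(pκ, (1−p)κ) with κ = 150
(mild replicate overdispersion), observed methylation probability
p′ = p + (1−p)ε with non-conversion ε = 0.005 simulated but never corrected
downstream, methylated counts ~ Binomial(coverage, p′).

Expression: per pair lognormal base mean (median ≈ 66 counts), per-phase
lognormal wobble (σ = 0.25) shared by the two alleles, per-sample depth
factors in [0.75, 1.3] to exercise size factors, NB dispersion 0.05,
3 replicates. ASEGs (15%) split the fold change symmetrically
(μ·2^{±lfc/2}, |lfc| ∈ [1.5, 3]); phase-dependent ASEGs (5%) either acquire
their bias after the explant phase ("appear") or reverse it ("flip").
Silent genes have mean 0.05. Motifs: a deterministic toy library of 24
informative PWMs (width 8–12, dominant base 0.85); per pair, each motif is
present with probability 0.35, and the paternal presence toggles with the
flip probability — 0.05 background, 0.35 for phase-dependent ASEGs, which
couples promoter divergence to expression divergence. Present motifs embed
their consensus word in reserved non-overlapping promoter slots, identical
in both alleles, so scanner detection matches the designed vectors.

All randomness flows from a single seed through per-stage child streams
(`default_rng([seed, stage])`, plus per-pair and per-window streams for the
shared fields), so stages are independently reproducible and two pipeline
runs at the same seed are byte-identical.

### What the generator does not emulate

Read-level artefacts (mapping bias, duplicate reads, M-bias), realistic TE
sequence families, linked methylation between neighbouring sites beyond
the shared latent field, trans-acting expression networks, and any coupling
between phase methylation dynamics and phase expression dynamics (the
methylation–expression correlation scan therefore finds ~50% negative
signs on synthetic data rather than the strong negative skew real CG data
shows). Passing tests demonstrate correctness of the estimators and error
control under the stated generative model, not biological conclusions.

## Problem sizes and runtime choices

Default desk scale — 2 chromosomes/subgenome (~3 Mb per subgenome), 500
pairs, ~63k 200-bp bins per context, 6 × 3 WGBS samples, 8 × 3 count
columns — was chosen so the full pipeline completes in a few minutes on one
CPU and the whole test suite in well under half an hour. Null and recovery
checks in the acceptance script run at this same scale. Interval queries
use prefix-sum track indexes built once per sample.
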